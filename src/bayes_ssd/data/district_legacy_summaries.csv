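district,n,mean_ln_zn,var_ln_zn,prop_deficient
Anantapur,49114,-0.73,0.96,0.77
Chittoor,37978,-0.06,0.41,0.495
East Godavari,30353,0.24,0.70,0.33
Guntur,63956,-0.37,0.82,0.61
Kadapa,21739,-0.66,0.60,0.77
Krishna,30481,-0.05,0.80,0.39
Kurnool,79775,-0.39,1.12,0.59
Nellore,48053,-1.22,1.19,0.858
Prakasam,50392,-0.64,1.35,0.67
Srikakulam,40823,0.01,0.44,0.40
Visakhapatnam,8678,-0.41,0.97,0.57
Vizianagaram,28321,-0.35,0.46,0.64
West Godavari,20211,0.37,0.77,0.259
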