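"""Precision requirements and sample-size results shared by all SSD routines."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PrecisionSpec", "SSDResult", "CRITERIA", "APPROACHES"]

CRITERIA = ("alc", "acc", "woc", "frequentist")
APPROACHES = ("fully_bayesian", "mixed", "frequentist")

_CRITERION_ALIASES = {"alc": "alc", "acc": "acc", "woc": "woc",
                      "frequentist": "frequentist", "freq": "frequentist"}
_APPROACH_ALIASES = {"fully_bayesian": "fully_bayesian", "bayes": "fully_bayesian",
                     "fb": "fully_bayesian", "mixed": "mixed", "mbl": "mixed",
                     "frequentist": "frequentist", "freq": "frequentist"}


@dataclass(frozen=True)
class PrecisionSpec:
    """Precision requirement for an interval estimate.

    Parameters
    ----------
    lmax : float
        Maximum (average / worst-case) interval length, on the scale of the
        parameter being estimated.
    alpha : float
        One minus the interval coverage; ``alpha = 0.05`` asks for 95%
        credible (confidence) intervals.
    criterion : str
        ``"alc"`` (average length), ``"acc"`` (average coverage),
        ``"woc"`` (modified worst outcome) or ``"frequentist"``.
    approach : str
        ``"fully_bayesian"``, ``"mixed"`` (Bayesian-likelihood: the prior
        only shapes the preposterior of the data, inference uses a uniform
        prior) or ``"frequentist"``.  Aliases ``bayes``/``mbl``/``freq``
        are accepted.
    worst_level : float
        For WOC: the fraction of preposterior probability mass of data sets
        on which the requirement must hold (e.g. 0.8).
    """

    lmax: float
    alpha: float = 0.05
    criterion: str = "alc"
    approach: str = "fully_bayesian"
    worst_level: float = 0.8

    def __post_init__(self) -> None:
        if not self.lmax > 0:
            raise ValueError(f"lmax must be positive, got {self.lmax}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0 < self.worst_level <= 1:
            raise ValueError(f"worst_level must be in (0, 1], got {self.worst_level}")
        crit = _CRITERION_ALIASES.get(str(self.criterion).lower())
        if crit is None:
            raise ValueError(f"unknown criterion {self.criterion!r}; choose from {CRITERIA}")
        appr = _APPROACH_ALIASES.get(str(self.approach).lower())
        if appr is None:
            raise ValueError(f"unknown approach {self.approach!r}; choose from {APPROACHES}")
        object.__setattr__(self, "criterion", crit)
        object.__setattr__(self, "approach", appr)

    @property
    def coverage(self) -> float:
        return 1.0 - self.alpha


@dataclass(frozen=True)
class SSDResult:
    """Smallest sample size meeting a precision requirement.

    Attributes
    ----------
    n : int
        The returned sample size.
    achieved : float
        Value of the criterion at ``n`` (average length, average coverage,
        or worst-case length depending on the criterion).
    criterion, approach : str
        Echo of the request.
    mc_error : float
        Monte-Carlo standard error of `achieved` when the criterion was
        evaluated by simulation; 0 for deterministic evaluation.
    """

    n: int
    achieved: float
    criterion: str
    approach: str
    mc_error: float = 0.0
    diagnostics: dict = field(default_factory=dict, compare=False)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tail = f" (MC SE {self.mc_error:.2g})" if self.mc_error else ""
        return (f"n = {self.n} [{self.criterion.upper()}, {self.approach}], "
                f"achieved = {self.achieved:.5g}{tail}")
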