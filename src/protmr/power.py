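"""Closed-form power for two-sample MR with a binary outcome.

For a case-control outcome of N = n_cases + n_controls with case fraction
phi and an instrument explaining a proportion ``pve`` of the exposure
variance, the non-centrality of the MR Wald test at a true odds ratio OR is
|ln OR| * sqrt(N * pve * phi * (1 - phi)), giving

    power = Phi( |ln OR| sqrt(N pve phi (1 - phi)) - z_{1 - alpha/2} )

and, inverted, the smallest detectable OR above 1 at a target power

    ln OR = (z_power + z_{1 - alpha/2}) / sqrt(N pve phi (1 - phi)).

Alpha is the nominal two-sided 0.05 level, not a multiplicity-corrected
one; protective equivalents of detectable ORs are their reciprocals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats


@dataclass(frozen=True)
class CaseControlDesign:
    n_cases: int
    n_controls: int
    pve: float = 0.01
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("case and control counts must be >= 1")
        if not (0 < self.pve < 1):
            raise ValueError("pve must lie in (0, 1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_total

    @property
    def ncp_scale(self) -> float:
        phi = self.case_fraction
        return math.sqrt(self.n_total * self.pve * phi * (1.0 - phi))


def mr_power(or_alt: float, design: CaseControlDesign) -> float:
    """Power of the two-sided Wald test at a true odds ratio ``or_alt``."""
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    z_crit = stats.norm.ppf(1.0 - design.alpha / 2.0)
    return float(stats.norm.cdf(abs(math.log(or_alt)) * design.ncp_scale - z_crit))


def detectable_or(power_target: float, design: CaseControlDesign) -> float:
    """Smallest odds ratio above 1 detectable at ``power_target``."""
    if not (design.alpha / 2.0 < power_target < 1.0):
        raise ValueError("power_target must lie in (alpha/2, 1)")
    z_crit = stats.norm.ppf(1.0 - design.alpha / 2.0)
    z_pow = stats.norm.ppf(power_target)
    return math.exp((z_pow + z_crit) / design.ncp_scale)
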