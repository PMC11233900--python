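"""Two-sample Mendelian randomisation estimators.

Single-instrument effects are Wald ratios beta_out / beta_exp on the
log-odds-per-SD scale; multiple independent instruments for the same
protein are pooled by fixed-effect inverse-variance weighting, with a
multiplicative random-effects (MRE) standard error inflated by
sqrt(Q / (k - 1)) when Cochran's Q exceeds its degrees of freedom.
Per-outcome multiple testing uses a Bonferroni threshold 0.05 / N_proteins
with a strict inequality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import HarmonisedPair, z_and_p


@dataclass
class WaldEstimate:
    rsid: str
    beta: float
    se: float
    p: float
    or_point: float
    ci_low: float
    ci_high: float


@dataclass
class IVWEstimate:
    k: int
    beta: float
    se_fixed: float
    se_mre: float
    Q: float
    p_fixed: float
    p_mre: float
    or_point: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class MRConfig:
    alpha: float = 0.05
    use_mre: bool = True  # headline IVW interval uses MRE when Q/(k-1) > 1
    second_order_se: bool = False


def or_with_ci(beta: float, se: float, level: float = 0.95,
               ) -> tuple[float, float, float]:
    """Odds ratio and CI from a log-odds estimate: exp(beta +/- z se)."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return math.exp(beta), math.exp(beta - z * se), math.exp(beta + z * se)


def wald_ratio(pair: HarmonisedPair,
               config: MRConfig = MRConfig()) -> WaldEstimate:
    """Single-instrument Wald estimate beta_out / beta_exp.

    The SE is the first-order delta approximation se_out / |beta_exp|; a
    second-order term adding the exposure uncertainty is available behind
    ``config.second_order_se``.
    """
    if pair.beta_exp == 0:
        raise ZeroDivisionError(f"{pair.rsid}: undefined Wald ratio (beta_exp = 0)")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    if config.second_order_se:
        se = math.sqrt(
            pair.se_out ** 2 / pair.beta_exp ** 2
            + pair.beta_out ** 2 * pair.se_exp ** 2 / pair.beta_exp ** 4
        )
    _, p = z_and_p(beta, se)
    or_point, lo, hi = or_with_ci(beta, se)
    return WaldEstimate(pair.rsid, beta, se, p, or_point, lo, hi)


def ivw_combine(estimates: Sequence[WaldEstimate],
                config: MRConfig = MRConfig()) -> IVWEstimate:
    """Fixed-effect IVW pooling of independent Wald estimates.

    weights w_i = 1/se_i^2; Q is Cochran's heterogeneity statistic and the
    MRE standard error is se_fixed * max(1, sqrt(Q/(k-1))).
    """
    k = len(estimates)
    if k < 2:
        raise ValueError("IVW requires at least 2 instruments; use wald_ratio")
    betas = np.array([e.beta for e in estimates])
    ses = np.array([e.se for e in estimates])
    w = 1.0 / ses ** 2
    beta = float(np.sum(w * betas) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    Q = float(np.sum(w * (betas - beta) ** 2))
    se_mre = se_fixed * max(1.0, math.sqrt(Q / (k - 1)))
    _, p_fixed = z_and_p(beta, se_fixed)
    _, p_mre = z_and_p(beta, se_mre)
    se_head = se_mre if config.use_mre else se_fixed
    or_point, lo, hi = or_with_ci(beta, se_head)
    return IVWEstimate(k, beta, se_fixed, se_mre, Q, p_fixed, p_mre,
                       or_point, lo, hi)


def bonferroni_threshold(n_proteins: int, alpha: float = 0.05) -> float:
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    return alpha / n_proteins


def bonferroni_filter(results: pd.DataFrame,
                      n_proteins_per_outcome: dict[str, int],
                      alpha: float = 0.05) -> pd.DataFrame:
    """Flag per-outcome Bonferroni passes (strict p < alpha / N_proteins).

    ``results`` needs columns ``outcome`` and ``p``; the threshold used is
    recorded per row.
    """
    out = results.copy()
    thresholds = out["outcome"].map(
        lambda o: bonferroni_threshold(n_proteins_per_outcome[o], alpha))
    out["bonferroni_threshold"] = thresholds
    out["pass_bonferroni"] = out["p"] < thresholds
    return out
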