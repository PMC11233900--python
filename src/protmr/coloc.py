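"""Bayesian colocalisation via Wakefield approximate Bayes factors.

For a region of m variants and two traits, each of the five hypotheses
(H0 no association, H1/H2 one trait only, H3 two distinct causal variants,
H4 one shared causal variant) receives an unnormalised log evidence built
from per-variant log ABFs

    lABF = 0.5 * (ln(1 - r) + r z^2),    r = W / (W + se^2),  z = beta / se

with prior per-variant probabilities p1, p2 and p12.  Posteriors PP0..PP4
are the softmax of the five log evidences.  Multi-signal regions are
handled by approximate conditional analysis on an LD reference: stepwise
lead selection per trait, conditioned z-vectors
z' = z - R[:,C] (R[C,C] + ridge I)^-1 z_C, and a colocalisation run for
every combination of per-trait signals; the decision uses the highest PP4
of any run.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

from .instruments import LDMatrix
from .sumstats import harmonise_frames


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant prior probabilities: trait-1 only, trait-2 only, shared."""

    p1: float = 1e-3
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self):
        if not (0 < self.p12 <= self.p2 <= self.p1 < 1):
            raise ValueError("priors must satisfy 0 < p12 <= p2 <= p1 < 1")


@dataclass(frozen=True)
class ColocConfig:
    region_halfwidth: int = 75_000
    pp4_threshold: float = 0.70
    w_quant: float = 0.15 ** 2  # prior effect variance, per-SD trait
    w_binary: float = 0.2 ** 2  # prior effect variance, log-odds trait
    max_conditional_signals: int = 3
    conditional_p_stop: float = 5e-5
    ridge: float = 1e-6

    def __post_init__(self):
        if not (0 < self.pp4_threshold < 1):
            raise ValueError("pp4_threshold must lie in (0, 1)")
        if self.w_quant <= 0 or self.w_binary <= 0:
            raise ValueError("prior effect variances must be positive")


@dataclass
class RegionData:
    """Allele-aligned per-variant statistics for two traits in one region."""

    rsids: list[str]
    pos: np.ndarray
    beta1: np.ndarray
    se1: np.ndarray
    beta2: np.ndarray
    se2: np.ndarray
    trait1_type: str = "quant"
    trait2_type: str = "cc"
    ld: Optional[LDMatrix] = None

    def __post_init__(self):
        m = len(self.rsids)
        if m < 1:
            raise ValueError("region must contain at least one variant")
        for name in ("pos", "beta1", "se1", "beta2", "se2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (m,):
                raise ValueError(f"{name} has wrong length")
            setattr(self, name, arr)

    @property
    def n_variants(self) -> int:
        return len(self.rsids)


@dataclass
class ColocResult:
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_variants: int
    label: str = "single"

    def as_array(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_labf(beta, se, W: float):
    """Log approximate Bayes factor for a single variant (vectorised)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if W < 0:
        raise ValueError("W must be non-negative")
    r = W / (W + se ** 2)
    z = beta / se
    with np.errstate(divide="ignore"):  # r == 1 gives lABF = -inf, by design
        out = 0.5 * (np.log1p(-r) + r * z ** 2)
    return float(out) if out.ndim == 0 else out


def prior_shared_probability(n_variants: int,
                             priors: ColocPriors = ColocPriors()) -> float:
    """Prior probability of a shared causal variant in an m-variant region,
    m * p12 (the 'prior belief in colocalisation')."""
    return n_variants * priors.p12


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a - e^b) for a >= b, -inf when equal within fp noise."""
    if b >= a:
        return -np.inf
    return a + math.log1p(-math.exp(b - a))


def coloc_posteriors(region: RegionData,
                     priors: ColocPriors = ColocPriors(),
                     config: ColocConfig = ColocConfig(),
                     label: str = "single") -> ColocResult:
    """Posterior probabilities PP0..PP4 for one region.

    The H3 evidence sums lABF1_i + lABF2_j over i != j, computed stably as
    the log-difference between the full cross product sum and the diagonal.
    """
    W1 = config.w_quant if region.trait1_type == "quant" else config.w_binary
    W2 = config.w_quant if region.trait2_type == "quant" else config.w_binary
    l1 = wakefield_labf(region.beta1, region.se1, W1)
    l2 = wakefield_labf(region.beta2, region.se2, W2)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)

    lse1 = logsumexp(l1)
    lse2 = logsumexp(l2)
    lse12 = logsumexp(l1 + l2)

    s0 = 0.0
    s1 = math.log(priors.p1) + lse1
    s2 = math.log(priors.p2) + lse2
    s4 = math.log(priors.p12) + lse12
    cross = lse1 + lse2
    s3 = math.log(priors.p1) + math.log(priors.p2) + _log_diff_exp(cross, lse12)

    s = np.array([s0, s1, s2, s3, s4])
    pp = np.exp(s - logsumexp(s))
    pp /= pp.sum()
    return ColocResult(*(float(x) for x in pp),
                       n_variants=region.n_variants, label=label)


def extract_region(index_rsid: str, exposure, outcome,
                   config: ColocConfig = ColocConfig(),
                   ld: Optional[LDMatrix] = None,
                   trait1_type: str = "quant",
                   trait2_type: str = "cc") -> RegionData:
    """Build a :class:`RegionData` around an index variant.

    Takes all variants within ``region_halfwidth`` (closed interval) of the
    index position that are present in both sumstats frames, allele-aligned
    via harmonisation; variants present in only one trait are excluded.
    """
    hit = exposure[exposure["rsid"] == index_rsid]
    if not len(hit):
        raise KeyError(f"index {index_rsid} absent from exposure sumstats")
    if not len(outcome[outcome["rsid"] == index_rsid]):
        raise KeyError(f"index {index_rsid} absent from outcome sumstats")
    centre = int(hit["pos"].iloc[0])
    lo, hi = centre - config.region_halfwidth, centre + config.region_halfwidth
    exp_win = exposure[(exposure["pos"] >= lo) & (exposure["pos"] <= hi)]
    out_win = outcome[(outcome["pos"] >= lo) & (outcome["pos"] <= hi)]
    pairs, audit = harmonise_frames(exp_win, out_win)
    if not pairs:
        raise ValueError(f"no harmonisable variants in region around {index_rsid}")
    pos_by_rsid = dict(zip(exp_win["rsid"], exp_win["pos"]))
    rsids = [p.rsid for p in pairs]
    region = RegionData(
        rsids=rsids,
        pos=np.array([pos_by_rsid[r] for r in rsids], dtype=float),
        beta1=np.array([p.beta_exp for p in pairs]),
        se1=np.array([p.se_exp for p in pairs]),
        beta2=np.array([p.beta_out for p in pairs]),
        se2=np.array([p.se_out for p in pairs]),
        trait1_type=trait1_type, trait2_type=trait2_type, ld=ld,
    )
    return region


def _condition_z(z: np.ndarray, R: np.ndarray, cond: Sequence[int],
                 ridge: float) -> np.ndarray:
    """Approximate conditional z-scores given a conditioning set of indices."""
    if not len(cond):
        return z.copy()
    C = list(cond)
    Rcc = R[np.ix_(C, C)] + ridge * np.eye(len(C))
    try:
        sol = np.linalg.solve(Rcc, z[C])
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular LD submatrix while conditioning; increase ridge") from exc
    return z - R[:, C] @ sol


def _stepwise_leads(z: np.ndarray, R: np.ndarray,
                    config: ColocConfig) -> list[int]:
    """Stepwise lead-variant selection on conditioned z-scores."""
    leads: list[int] = []
    z_work = z
    while len(leads) < config.max_conditional_signals:
        i = int(np.argmax(np.abs(z_work)))
        p = 2.0 * stats.norm.sf(abs(z_work[i]))
        if p > config.conditional_p_stop:
            break
        leads.append(i)
        z_work = _condition_z(z, R, leads, config.ridge)
    return leads


def conditional_iterate(region: RegionData, ld: Optional[LDMatrix] = None,
                        priors: ColocPriors = ColocPriors(),
                        config: ColocConfig = ColocConfig(),
                        ) -> list[ColocResult]:
    """Single + conditional-iterative colocalisation runs for one region.

    Per trait, stepwise leads are found on the LD reference; each signal is
    isolated by conditioning on the other leads of its trait, and a
    colocalisation run is performed for every (trait-1 signal, trait-2
    signal) combination.  With at most one signal per trait the list holds
    only the single run.
    """
    ld = ld if ld is not None else region.ld
    single = coloc_posteriors(region, priors, config, label="single")
    if ld is None:
        return [single]
    R = ld.submatrix(region.rsids)
    z1 = region.beta1 / region.se1
    z2 = region.beta2 / region.se2
    leads1 = _stepwise_leads(z1, R, config)
    leads2 = _stepwise_leads(z2, R, config)
    if len(leads1) <= 1 and len(leads2) <= 1:
        return [single]

    results = [single]
    for a, b in itertools.product(range(max(len(leads1), 1)),
                                  range(max(len(leads2), 1))):
        cond1 = [l for k, l in enumerate(leads1) if k != a]
        cond2 = [l for k, l in enumerate(leads2) if k != b]
        if not cond1 and not cond2:
            continue  # identical to the single run
        z1c = _condition_z(z1, R, cond1, config.ridge)
        z2c = _condition_z(z2, R, cond2, config.ridge)
        sub = RegionData(
            rsids=region.rsids, pos=region.pos,
            beta1=z1c * region.se1, se1=region.se1,
            beta2=z2c * region.se2, se2=region.se2,
            trait1_type=region.trait1_type, trait2_type=region.trait2_type,
        )
        results.append(
            coloc_posteriors(sub, priors, config,
                             label=f"conditional:{a + 1}x{b + 1}"))
    return results


@dataclass
class ColocDecision:
    max_pp4: float
    passed: bool
    best_label: str


def pp4_decision(results: Sequence[ColocResult],
                 config: ColocConfig = ColocConfig()) -> ColocDecision:
    """Highest PP4 of any run; pass iff strictly above the threshold."""
    if not results:
        raise ValueError("at least one colocalisation result is required")
    best = max(results, key=lambda r: r.pp4)
    return ColocDecision(max_pp4=float(best.pp4),
                         passed=bool(best.pp4 > config.pp4_threshold),
                         best_label=best.label)
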