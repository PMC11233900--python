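"""Synthetic GWAS summary statistics with known causal structure.

The generator produces cis regions under a summary-statistics likelihood:
given an LD correlation matrix R and true per-variant z-scores z_true, the
observed z-scores are drawn as

    z_obs ~ MVN(R @ z_true, R)

and converted to betas via the per-variant standard error.  For a
quantitative exposure measured in SD units the SE of variant j is
1/sqrt(2 maf_j (1-maf_j) n); for a case-control outcome on the log-odds
scale the sample size is replaced by the effective size
n_cases * n_controls / (n_cases + n_controls).

The causal pQTL's standardized effect b is set so that it explains a chosen
proportion of exposure variance: 2 maf (1-maf) b^2 = pve.  The true
protein->outcome effect theta induces a log-odds effect theta * b at the
shared causal variant, so the Wald ratio at that variant recovers theta.

Every draw is reproducible bit-for-bit from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SUMSTATS_COLUMNS

SCENARIOS = ("shared", "distinct", "null", "multi_signal")


@dataclass(frozen=True)
class LDBlockSpec:
    """A single cis LD block with AR(1)-style correlation decay.

    The implied correlation matrix has entries R_ij = decay^|i-j|, which is
    symmetric, unit-diagonal and positive definite for decay in [0, 1).
    """

    n_variants: int
    decay: float
    positions: tuple = field(default=None)
    maf: tuple = field(default=None)
    chrom: str = "1"
    rsid_prefix: str = "rs"

    def __post_init__(self):
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not (0 <= self.decay < 1):
            raise ValueError("decay must lie in [0, 1)")
        if self.positions is not None:
            pos = tuple(int(p) for p in self.positions)
            if len(pos) != self.n_variants:
                raise ValueError("positions length != n_variants")
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise ValueError("positions must be strictly increasing")
            object.__setattr__(self, "positions", pos)
        if self.maf is not None:
            maf = tuple(float(m) for m in self.maf)
            if len(maf) != self.n_variants:
                raise ValueError("maf length != n_variants")
            if any(not (0 < m <= 0.5) for m in maf):
                raise ValueError("maf must lie in (0, 0.5]")
            object.__setattr__(self, "maf", maf)

    @classmethod
    def create(cls, n_variants: int, decay: float = 0.9, *,
               start: int = 1_000_000, spacing: int = 1_000,
               maf: Optional[float] = None, chrom: str = "1",
               seed: int = 0, rsid_prefix: str = "rs") -> "LDBlockSpec":
        """Convenience factory: evenly spaced positions 1 kb apart and MAFs
        drawn uniform(0.05, 0.5) from ``seed`` (or constant ``maf``)."""
        positions = tuple(start + spacing * i for i in range(n_variants))
        if maf is None:
            rng = np.random.default_rng(seed)
            mafs = tuple(rng.uniform(0.05, 0.5, size=n_variants))
        else:
            mafs = tuple([float(maf)] * n_variants)
        return cls(n_variants=n_variants, decay=decay, positions=positions,
                   maf=mafs, chrom=chrom, rsid_prefix=rsid_prefix)

    @property
    def rsids(self) -> list[str]:
        return [f"{self.rsid_prefix}{i + 1:05d}" for i in range(self.n_variants)]

    def resolved_positions(self) -> np.ndarray:
        if self.positions is not None:
            return np.asarray(self.positions)
        return np.arange(self.n_variants) * 1_000 + 1_000_000

    def resolved_maf(self) -> np.ndarray:
        if self.maf is not None:
            return np.asarray(self.maf)
        return np.full(self.n_variants, 0.25)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating parameters of one synthetic protein-outcome study."""

    scenario: str = "shared"
    theta: float = 0.5
    pve: float = 0.01
    exposure_causal_index: int = 0
    outcome_causal_index: Optional[int] = None
    n_exposure: int = 35_000
    n_cases: int = 15_000
    n_controls: int = 50_000
    seed: int = 0
    #: true outcome log-odds effect at the outcome causal variant in the
    #: distinct scenario; defaults to theta * b_true (same magnitude as shared)
    outcome_effect: Optional[float] = None
    #: secondary exposure causal index for multi_signal
    secondary_causal_index: Optional[int] = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (0 < self.pve < 1):
            raise ValueError("pve must lie in (0, 1)")
        if self.scenario == "null" and self.theta != 0:
            raise ValueError("null scenario requires theta = 0")
        if self.scenario == "shared" and self.outcome_causal_index not in (
                None, self.exposure_causal_index):
            raise ValueError("shared scenario requires identical causal indices")


@dataclass
class SimTruth:
    """Everything the generator knows: the recoverable ground truth."""

    config: ScenarioConfig
    b_exposure: float  # standardized causal effect on the exposure
    b_outcome: float  # causal log-odds effect on the outcome
    exposure_causal_index: int
    outcome_causal_index: Optional[int]
    true_marginal_beta_exp: np.ndarray
    true_marginal_beta_out: np.ndarray
    causal: bool  # theta != 0 or distinct outcome signal present


@lru_cache(maxsize=64)
def _chol(n: int, decay: float) -> np.ndarray:
    R = _r_matrix(n, decay)
    return np.linalg.cholesky(R + 1e-12 * np.eye(n))


def _r_matrix(n: int, decay: float) -> np.ndarray:
    idx = np.arange(n)
    return decay ** np.abs(idx[:, None] - idx[None, :])


def make_ld_matrix(spec: LDBlockSpec) -> pd.DataFrame:
    """Dense LD correlation matrix as a labelled DataFrame (R_ij = decay^|i-j|)."""
    R = _r_matrix(spec.n_variants, spec.decay)
    return pd.DataFrame(R, index=spec.rsids, columns=spec.rsids)


def _se_vector(maf: np.ndarray, n_eff: float) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)


def _draw_sumstats(spec: LDBlockSpec, z_true: np.ndarray, se: np.ndarray,
                   rng: np.random.Generator, *, n=None, n_cases=None,
                   n_controls=None) -> pd.DataFrame:
    L = _chol(spec.n_variants, spec.decay)
    R = _r_matrix(spec.n_variants, spec.decay)
    mean = R @ z_true
    z_obs = mean + L @ rng.standard_normal(spec.n_variants)
    beta = z_obs * se
    pval = 2.0 * stats.norm.sf(np.abs(z_obs))
    maf = spec.resolved_maf()
    df = pd.DataFrame({
        "rsid": spec.rsids,
        "chr": spec.chrom,
        "pos": spec.resolved_positions(),
        "ea": "A",
        "oa": "G",
        "eaf": maf,
        "beta": beta,
        "se": se,
        "pval": pval,
        "n": n if n is not None else np.nan,
        "n_cases": n_cases if n_cases is not None else np.nan,
        "n_controls": n_controls if n_controls is not None else np.nan,
    })
    return df


def _causal_b(maf_c: float, pve: float) -> float:
    b2 = pve / (2.0 * maf_c * (1.0 - maf_c))
    if b2 > 1.0:  # per-allele effect above 1 SD: pve incompatible with maf
        raise ValueError("pve incompatible with maf at the causal variant")
    return float(np.sqrt(b2))


def simulate_exposure_sumstats(
        spec: LDBlockSpec, config: ScenarioConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate a protein (exposure) GWAS for the cis block.

    Returns the sumstats frame and the :class:`SimTruth` needed to simulate
    the matched outcome and to score parameter recovery.
    """
    maf = spec.resolved_maf()
    se = _se_vector(maf, config.n_exposure)
    ci = config.exposure_causal_index
    if not (0 <= ci < spec.n_variants):
        raise ValueError("exposure_causal_index out of range")
    b = _causal_b(maf[ci], config.pve)

    z_true = np.zeros(spec.n_variants)
    z_true[ci] = b / se[ci]
    if config.scenario == "multi_signal":
        si = config.secondary_causal_index
        if si is None:
            raise ValueError("multi_signal requires secondary_causal_index")
        z_true[si] = _causal_b(maf[si], config.pve) / se[si]

    ss_exp, ss_out = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ss_exp)
    df = _draw_sumstats(spec, z_true, se, rng, n=config.n_exposure)

    R = _r_matrix(spec.n_variants, spec.decay)
    true_marg_exp = (R @ z_true) * se

    # outcome truth (marginals filled by simulate_outcome_sumstats)
    theta = config.theta
    if config.scenario == "null":
        b_out = 0.0
        oci = None
    elif config.scenario == "distinct":
        oci = config.outcome_causal_index
        if oci is None or oci == ci:
            raise ValueError("distinct scenario requires a distinct outcome_causal_index")
        b_out = config.outcome_effect if config.outcome_effect is not None else theta * b
    elif config.scenario == "multi_signal":
        # the outcome may share either exposure signal; default: the primary
        oci = ci if config.outcome_causal_index is None else config.outcome_causal_index
        b_out = theta * _causal_b(maf[oci], config.pve)
    else:
        oci = ci
        b_out = theta * b

    truth = SimTruth(
        config=config, b_exposure=b, b_outcome=b_out,
        exposure_causal_index=ci, outcome_causal_index=oci,
        true_marginal_beta_exp=true_marg_exp,
        true_marginal_beta_out=np.zeros(spec.n_variants),
        causal=(config.scenario == "distinct") or (theta != 0.0),
    )
    return df, truth


def simulate_outcome_sumstats(
        spec: LDBlockSpec, config: ScenarioConfig, truth: SimTruth,
) -> pd.DataFrame:
    """Simulate the matched case-control (outcome) GWAS on the log-odds scale."""
    if truth is None:
        raise ValueError("truth from simulate_exposure_sumstats is required")
    maf = spec.resolved_maf()
    n_eff = config.n_cases * config.n_controls / (config.n_cases + config.n_controls)
    se = _se_vector(maf, n_eff)

    z_true = np.zeros(spec.n_variants)
    if truth.outcome_causal_index is not None and truth.b_outcome != 0.0:
        oci = truth.outcome_causal_index
        z_true[oci] = truth.b_outcome / se[oci]

    _, ss_out = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(ss_out)
    df = _draw_sumstats(spec, z_true, se, rng,
                        n_cases=config.n_cases, n_controls=config.n_controls)
    R = _r_matrix(spec.n_variants, spec.decay)
    truth.true_marginal_beta_out = (R @ z_true) * se
    return df


@dataclass
class StudySim:
    """One protein's simulated study: exposure + outcome + LD + truth."""

    protein: str
    exposure: pd.DataFrame
    outcome: pd.DataFrame
    spec: LDBlockSpec
    truth: SimTruth


def simulate_study_set(
        n_proteins: int, fraction_causal: float,
        config: ScenarioConfig, *, n_variants: int = 25,
        decay: float = 0.9, seed: Optional[int] = None,
) -> tuple[list[StudySim], pd.DataFrame]:
    """Simulate a set of protein studies; the first ``round(n * fraction)``
    proteins are causal (scenario from ``config``), the rest are nulls.

    Returns the studies and a truth table recording which proteins carry a
    real protein->outcome effect.  Deterministic under ``seed`` (defaults to
    ``config.seed``).
    """
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    if not (0 <= fraction_causal <= 1):
        raise ValueError("fraction_causal must lie in [0, 1]")
    base_seed = config.seed if seed is None else seed
    n_causal = int(round(n_proteins * fraction_causal))
    child_seeds = np.random.SeedSequence(base_seed).generate_state(n_proteins)

    studies: list[StudySim] = []
    rows = []
    for p in range(n_proteins):
        name = f"PROT{p + 1:04d}"
        causal = p < n_causal
        pseed = int(child_seeds[p] % (2 ** 31))
        if causal:
            cfg = ScenarioConfig(
                scenario=config.scenario, theta=config.theta, pve=config.pve,
                exposure_causal_index=config.exposure_causal_index,
                outcome_causal_index=config.outcome_causal_index,
                n_exposure=config.n_exposure, n_cases=config.n_cases,
                n_controls=config.n_controls, seed=pseed,
                outcome_effect=config.outcome_effect,
                secondary_causal_index=config.secondary_causal_index,
            )
        else:
            cfg = ScenarioConfig(
                scenario="null", theta=0.0, pve=config.pve,
                exposure_causal_index=config.exposure_causal_index,
                n_exposure=config.n_exposure, n_cases=config.n_cases,
                n_controls=config.n_controls, seed=pseed,
            )
        spec = LDBlockSpec.create(
            n_variants, decay, maf=0.3, chrom="1",
            start=1_000_000, rsid_prefix=f"{name}_rs",
        )
        exp_df, truth = simulate_exposure_sumstats(spec, cfg)
        out_df = simulate_outcome_sumstats(spec, cfg, truth)
        studies.append(StudySim(name, exp_df, out_df, spec, truth))
        rows.append({
            "protein": name, "causal": causal, "scenario": cfg.scenario,
            "theta": cfg.theta, "pve": cfg.pve, "seed": pseed,
            "causal_rsid": spec.rsids[truth.exposure_causal_index],
        })
    return studies, pd.DataFrame(rows)


def write_study_set(studies: list[StudySim], truth_table: pd.DataFrame,
                    outdir) -> dict[str, Path]:
    """Write a study set as pipeline-ready inputs.

    Produces ``exposure.tsv`` (all proteins, with a ``protein`` column),
    ``outcome.tsv``, a block-diagonal ``ld.tsv`` over all variants,
    ``meta.tsv`` (TSS at each block centre) and ``truth.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exp_frames, out_frames, meta_rows = [], [], []
    for study in studies:
        e = study.exposure.copy()
        e["protein"] = study.protein
        exp_frames.append(e)
        out_frames.append(study.outcome)
        pos = study.spec.resolved_positions()
        meta_rows.append({
            "uniprot_id": f"UP_{study.protein}",
            "gene_symbol": study.protein,
            "tss_chr": study.spec.chrom,
            "tss_pos": int(pos[len(pos) // 2]),
        })
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "ld": outdir / "ld.tsv",
        "meta": outdir / "meta.tsv",
        "truth": outdir / "truth.tsv",
    }
    pd.concat(exp_frames).to_csv(paths["exposure"], sep="\t", index=False)
    pd.concat(out_frames).to_csv(paths["outcome"], sep="\t", index=False)

    all_ids = [r for s in studies for r in s.spec.rsids]
    n = len(all_ids)
    big = np.zeros((n, n))
    off = 0
    for s in studies:
        m = s.spec.n_variants
        big[off:off + m, off:off + m] = _r_matrix(m, s.spec.decay)
        off += m
    pd.DataFrame(big, index=all_ids, columns=all_ids).to_csv(
        paths["ld"], sep="\t", index_label="rsid")
    pd.DataFrame(meta_rows).to_csv(paths["meta"], sep="\t", index=False)
    truth_table.to_csv(paths["truth"], sep="\t", index=False)
    return paths


def write_study(study: StudySim, outdir) -> None:
    """Write one study's exposure/outcome/LD tables as TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    study.exposure.to_csv(outdir / f"{study.protein}_exposure.tsv",
                          sep="\t", index=False, columns=SUMSTATS_COLUMNS)
    study.outcome.to_csv(outdir / f"{study.protein}_outcome.tsv",
                         sep="\t", index=False, columns=SUMSTATS_COLUMNS)
    make_ld_matrix(study.spec).to_csv(outdir / f"{study.protein}_ld.tsv",
                                      sep="\t", index_label="rsid")
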