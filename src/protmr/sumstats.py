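"""Reading, validation and harmonisation of GWAS summary statistics.

Summary statistics live in plain TSV files, one row per variant, and are
held in memory as :class:`pandas.DataFrame` objects with the canonical
column set in :data:`SUMSTATS_COLUMNS`.  Exposure (protein) and outcome
(cancer) rows are matched by rsID and by effect/other allele, and every
harmonised pair is oriented to the protein-increasing allele so that the
exposure effect is non-negative.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order for summary-statistics TSVs
SUMSTATS_COLUMNS = [
    "rsid", "chr", "pos", "ea", "oa", "eaf",
    "beta", "se", "pval", "n", "n_cases", "n_controls",
]

REQUIRED_COLUMNS = ["rsid", "chr", "pos", "ea", "oa", "beta", "se"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class AssocRecord:
    """Marginal association statistics for one variant and one trait.

    ``beta`` is the effect per SD for a quantitative trait or the log-odds
    for a binary one; ``se`` its standard error; ``eaf`` the effect-allele
    frequency when known.
    """

    rsid: str
    chr: str
    pos: int
    ea: str
    oa: str
    beta: float
    se: float
    eaf: Optional[float] = None
    pval: Optional[float] = None
    n: Optional[float] = None
    n_cases: Optional[float] = None
    n_controls: Optional[float] = None

    def __post_init__(self) -> None:
        self.ea = str(self.ea).upper()
        self.oa = str(self.oa).upper()
        if self.se is None or not self.se > 0:
            raise ValueError(f"{self.rsid}: nonpositive se")
        if self.ea == self.oa:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf outside (0,1)")


@dataclass
class HarmonisedPair:
    """An exposure/outcome variant pair on a common allele orientation.

    Invariant: ``beta_exp >= 0`` (protein-increasing allele is the effect
    allele after orientation).
    """

    rsid: str
    ea: str
    oa: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None
    orientation_flipped: bool = False
    proxy_used: Optional[str] = None


class SumStatsFormatError(ValueError):
    """Raised when a summary-statistics file violates the expected dialect."""


def read_sumstats(path, trait_meta: Optional[dict] = None) -> pd.DataFrame:
    """Read and validate a summary-statistics TSV.

    Rows with non-positive standard errors are dropped and recorded in
    ``df.attrs['audit']`` as ``(rsid, reason)`` tuples; duplicated rsIDs or
    missing/non-numeric required columns raise :class:`SumStatsFormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"rsid": str, "chr": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    for col in ("beta", "se", "eaf", "pval"):
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            lines = [i + 2 for i in df.index[bad]]  # +2: header + 1-based
            raise SumStatsFormatError(
                f"{path}: non-numeric {col} at line(s) {lines}"
            )
        df[col] = coerced

    dup = df["rsid"][df["rsid"].duplicated()]
    if len(dup):
        raise SumStatsFormatError(
            f"{path}: duplicated rsid(s): {', '.join(sorted(set(dup)))}"
        )

    audit: list[tuple[str, str]] = []
    bad_se = ~(df["se"] > 0)
    if bad_se.any():
        audit.extend((r, "nonpositive se") for r in df.loc[bad_se, "rsid"])
        df = df.loc[~bad_se]

    df = df.reset_index(drop=True)
    # fill in p when absent; warn when stored p disagrees grossly with beta/se
    if "pval" not in df.columns:
        df["pval"] = np.nan
    recomputed = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
    have_p = df["pval"].notna()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.abs(np.log(df.loc[have_p, "pval"] / recomputed[have_p]))
    n_off = int((rel > np.log(1.1)).sum()) if have_p.any() else 0
    if n_off:
        logger.warning(
            "%s: %d rows where stored p disagrees with beta/se by >10%%",
            path, n_off,
        )
    df.loc[~have_p, "pval"] = recomputed[~have_p]
    df["ea"] = df["ea"].str.upper()
    df["oa"] = df["oa"].str.upper()
    df.attrs["audit"] = audit
    if trait_meta:
        df.attrs["trait_meta"] = dict(trait_meta)
    logger.info("%s: read %d records (%d rejected)", path, len(df), len(audit))
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    cols = [c for c in SUMSTATS_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def se_from_ci(or_point: float, ci_low: float, ci_high: float,
               level: float = 0.95) -> float:
    """Back out the log-scale SE from an odds ratio and its CI.

    ``se = (ln ci_high - ln ci_low) / (2 z)`` with z the two-sided normal
    critical value for ``level``.
    """
    if not (0 < ci_low <= or_point <= ci_high):
        raise ValueError(
            f"CI ordering violated: {ci_low} <= {or_point} <= {ci_high}"
        )
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * z)


def z_and_p(beta: float, se: float) -> tuple[float, float]:
    """Wald z-score and two-sided normal p-value."""
    if not se > 0:
        raise ValueError("se must be positive")
    z = beta / se
    return z, 2.0 * stats.norm.sf(abs(z))


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def _complement_alleles(rec: AssocRecord) -> Optional[AssocRecord]:
    try:
        return replace(rec, ea=_COMPLEMENT[rec.ea], oa=_COMPLEMENT[rec.oa])
    except KeyError:
        return None


class HarmonisationDrop(Exception):
    """Signals that a pair cannot be harmonised; ``reason`` is machine-readable."""

    def __init__(self, rsid: str, reason: str):
        super().__init__(f"{rsid}: {reason}")
        self.rsid = rsid
        self.reason = reason


def harmonise_pair(exposure: AssocRecord, outcome: AssocRecord,
                   palindromic_eaf_margin: float = 0.08) -> HarmonisedPair:
    """Align an outcome record to an exposure record and orient to the
    protein-increasing allele.

    Allele labels are matched directly, by effect/other swap (negating the
    outcome beta), or after strand complementation.  Palindromic (A/T, C/G)
    variants are kept only when both allele frequencies are present, lie on
    the same side of 0.5, and are at least ``palindromic_eaf_margin`` away
    from 0.5; otherwise they are dropped.  Raises
    :class:`HarmonisationDrop` with reason ``allele_mismatch`` or
    ``palindromic_ambiguous``.
    """
    if exposure.rsid != outcome.rsid:
        raise ValueError("records refer to different rsids")
    rsid = exposure.rsid

    out = outcome
    exp_set = {exposure.ea, exposure.oa}
    if {out.ea, out.oa} != exp_set:
        flipped = _complement_alleles(out)
        if flipped is not None and {flipped.ea, flipped.oa} == exp_set:
            out = flipped
        else:
            raise HarmonisationDrop(rsid, "allele_mismatch")

    beta_out = out.beta
    eaf_out = out.eaf
    if out.ea != exposure.ea:  # swapped labels: flip outcome effect
        beta_out = -beta_out
        if eaf_out is not None:
            eaf_out = 1.0 - eaf_out

    if _is_palindromic(exposure.ea, exposure.oa):
        m = palindromic_eaf_margin
        ok = (
            exposure.eaf is not None and eaf_out is not None
            and (exposure.eaf - 0.5) * (eaf_out - 0.5) > 0
            and abs(exposure.eaf - 0.5) > m and abs(eaf_out - 0.5) > m
        )
        if not ok:
            raise HarmonisationDrop(rsid, "palindromic_ambiguous")

    beta_exp = exposure.beta
    eaf_exp = exposure.eaf
    ea, oa = exposure.ea, exposure.oa
    orientation_flipped = False
    if beta_exp < 0:  # orient to the protein-increasing allele
        beta_exp, beta_out = -beta_exp, -beta_out
        ea, oa = oa, ea
        if eaf_exp is not None:
            eaf_exp = 1.0 - eaf_exp
        if eaf_out is not None:
            eaf_out = 1.0 - eaf_out
        orientation_flipped = True

    return HarmonisedPair(
        rsid=rsid, ea=ea, oa=oa,
        beta_exp=beta_exp, se_exp=exposure.se,
        beta_out=beta_out, se_out=out.se,
        eaf_exp=eaf_exp, eaf_out=eaf_out,
        orientation_flipped=orientation_flipped,
    )


def record_from_row(row) -> AssocRecord:
    """Build an :class:`AssocRecord` from a sumstats DataFrame row."""
    def _get(key):
        v = row.get(key) if hasattr(row, "get") else getattr(row, key, None)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return v

    return AssocRecord(
        rsid=str(row["rsid"]), chr=str(row["chr"]), pos=int(row["pos"]),
        ea=str(row["ea"]), oa=str(row["oa"]),
        beta=float(row["beta"]), se=float(row["se"]),
        eaf=_get("eaf"), pval=_get("pval"), n=_get("n"),
        n_cases=_get("n_cases"), n_controls=_get("n_controls"),
    )


def harmonise_frames(exposure: pd.DataFrame, outcome: pd.DataFrame,
                     palindromic_eaf_margin: float = 0.08,
                     ) -> tuple[list[HarmonisedPair], list[tuple[str, str]]]:
    """Harmonise every rsID shared by two sumstats frames.

    Returns the harmonised pairs and an audit list of ``(rsid, reason)``
    drops (including ``absent_in_outcome`` for exposure-only variants).
    """
    out_by_rsid = {r.rsid: r for r in outcome.itertuples()}
    pairs: list[HarmonisedPair] = []
    audit: list[tuple[str, str]] = []
    for row in exposure.itertuples():
        orow = out_by_rsid.get(row.rsid)
        if orow is None:
            audit.append((row.rsid, "absent_in_outcome"))
            continue
        try:
            pairs.append(
                harmonise_pair(
                    record_from_row(row._asdict()),
                    record_from_row(orow._asdict()),
                    palindromic_eaf_margin=palindromic_eaf_margin,
                )
            )
        except HarmonisationDrop as drop:
            audit.append((drop.rsid, drop.reason))
    return pairs, audit
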