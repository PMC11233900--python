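"""cis-pQTL instrument selection.

Instruments for a protein are variants within 1 Mb of the transcription
start site of its encoding gene, taken at genome-wide significance
(p < 5e-8, tier "primary") or, when no variant reaches it, at a relaxed
threshold (p < 5e-5, tier "relaxed").  Candidates are greedily LD-clumped
at r^2 < 0.01, weak instruments (F = beta^2/se^2 < 10) are excluded, and
instruments absent from the outcome GWAS may be replaced by the
highest-r^2 proxy with r^2 > 0.8.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ProteinMeta:
    uniprot_id: str
    gene_symbol: str
    tss_chr: str
    tss_pos: int

    def __post_init__(self):
        if self.tss_pos < 1:
            raise ValueError("tss_pos must be >= 1")


@dataclass(frozen=True)
class InstrumentConfig:
    cis_halfwidth: int = 1_000_000
    p_primary: float = 5e-8
    p_relaxed: float = 5e-5
    clump_r2: float = 0.01
    proxy_r2_min: float = 0.8
    f_min: float = 10.0

    def __post_init__(self):
        if self.p_relaxed < self.p_primary:
            raise ValueError("p_relaxed must be >= p_primary")
        for name in ("cis_halfwidth", "p_primary", "p_relaxed",
                     "clump_r2", "proxy_r2_min", "f_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class LDMatrix:
    """Dense LD correlation matrix with variant labels.

    Stores signed correlations r; ``r2`` is their square.
    """

    def __init__(self, ids, values):
        self.ids = list(ids)
        self.values = np.asarray(values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("LD matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-6):
            raise ValueError("LD matrix must have unit diagonal")
        self._index = {v: i for i, v in enumerate(self.ids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def r(self, a: str, b: str) -> float:
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]} absent from LD matrix") from None

    def r2(self, a: str, b: str) -> float:
        return self.r(a, b) ** 2

    def submatrix(self, rsids) -> np.ndarray:
        idx = [self._index[r] for r in rsids]
        return self.values[np.ix_(idx, idx)]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LDMatrix":
        return cls(df.columns, df.to_numpy())

    @classmethod
    def from_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df.columns, df.to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            Path(path), sep="\t", index_label="rsid")


def cis_window(meta: ProteinMeta,
               config: InstrumentConfig = InstrumentConfig()) -> tuple[str, int, int]:
    """Closed cis interval [max(1, tss - halfwidth), tss + halfwidth]."""
    start = max(1, meta.tss_pos - config.cis_halfwidth)
    end = meta.tss_pos + config.cis_halfwidth
    return meta.tss_chr, start, end


def select_cis_candidates(sumstats: pd.DataFrame, window: tuple[str, int, int],
                          config: InstrumentConfig = InstrumentConfig(),
                          ) -> tuple[pd.DataFrame, Optional[str]]:
    """Two-tier candidate selection inside the cis window.

    If any in-window variant reaches ``p_primary`` return all such variants
    with tier ``primary``; otherwise fall back to ``p_relaxed`` variants
    (tier ``relaxed``); otherwise an empty frame and tier ``None``.
    """
    chrom, start, end = window
    inwin = sumstats[
        (sumstats["chr"].astype(str) == str(chrom))
        & (sumstats["pos"] >= start) & (sumstats["pos"] <= end)
    ]
    primary = inwin[inwin["pval"] < config.p_primary]
    if len(primary):
        return primary.copy(), "primary"
    relaxed = inwin[inwin["pval"] < config.p_relaxed]
    if len(relaxed):
        return relaxed.copy(), "relaxed"
    return inwin.iloc[0:0].copy(), None


def ld_clump(candidates: pd.DataFrame, ld: LDMatrix,
             config: InstrumentConfig = InstrumentConfig()) -> pd.DataFrame:
    """Greedy clumping: visit candidates by ascending p (ties: position,
    then rsid) and keep each iff r^2 < ``clump_r2`` with all kept so far."""
    for rsid in candidates["rsid"]:
        if rsid not in ld:
            raise KeyError(f"candidate {rsid} absent from LD matrix")
    order = candidates.sort_values(
        ["pval", "pos", "rsid"], kind="mergesort").reset_index(drop=True)
    kept: list[int] = []
    for i, row in order.iterrows():
        if all(ld.r2(row["rsid"], order.loc[j, "rsid"]) < config.clump_r2
               for j in kept):
            kept.append(i)
    return order.loc[kept].reset_index(drop=True)


def f_statistic(beta: float, se: float) -> float:
    """Instrument-strength F statistic, (beta/se)^2."""
    if not se > 0:
        raise ValueError("se must be positive")
    return (beta / se) ** 2


def filter_weak(candidates: pd.DataFrame,
                config: InstrumentConfig = InstrumentConfig(),
                ) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Exclude weak instruments (F < f_min); audit lists the exclusions."""
    f = (candidates["beta"] / candidates["se"]) ** 2
    weak = f < config.f_min
    audit = [(r, f"weak_instrument F={fv:.2f}")
             for r, fv in zip(candidates.loc[weak, "rsid"], f[weak])]
    out = candidates.loc[~weak].copy()
    out["f_stat"] = f[~weak]
    return out, audit


def compute_pve(beta: Optional[float] = None, eaf: Optional[float] = None,
                n: Optional[float] = None, f_stat: Optional[float] = None,
                ) -> tuple[float, str]:
    """Proportion of exposure variance explained by one variant.

    Uses 2 eaf (1-eaf) beta^2 for a standardized trait when the allele
    frequency is known, else the F-based approximation F / (F + n - 2).
    Returns (pve, method).
    """
    if eaf is not None and beta is not None:
        return 2.0 * eaf * (1.0 - eaf) * beta ** 2, "af_beta"
    if f_stat is not None and n is not None:
        return f_stat / (f_stat + n - 2.0), "f_n"
    raise ValueError("need either (beta, eaf) or (f_stat, n) to compute PVE")


def find_proxy(target: str, available, ld: LDMatrix,
               config: InstrumentConfig = InstrumentConfig(),
               positions: Optional[dict] = None,
               ) -> Optional[tuple[str, float]]:
    """Best LD proxy for ``target`` among ``available`` variants.

    Returns ``(rsid, r)`` for the variant with maximal r^2 > proxy_r2_min
    (ties broken by distance to the target when positions are supplied,
    then by rsid), or ``None`` when no variant qualifies.  The sign of r is
    returned so callers can align effect alleles.
    """
    if target not in ld:
        raise KeyError(f"target {target} absent from LD matrix")
    best = None
    tpos = positions.get(target) if positions else None
    for rsid in available:
        if rsid == target or rsid not in ld:
            continue
        r = ld.r(target, rsid)
        if r ** 2 <= config.proxy_r2_min:
            continue
        dist = abs(positions[rsid] - tpos) if (positions and tpos is not None) else 0
        key = (-r ** 2, dist, rsid)
        if best is None or key < best[0]:
            best = (key, rsid, r)
    if best is None:
        return None
    return best[1], best[2]


def read_protein_meta(path) -> dict[str, ProteinMeta]:
    """Protein metadata TSV (uniprot_id, gene_symbol, tss_chr, tss_pos) keyed
    by gene symbol."""
    df = pd.read_csv(path, sep="\t", dtype={"tss_chr": str})
    out = {}
    for row in df.itertuples():
        out[row.gene_symbol] = ProteinMeta(
            uniprot_id=str(row.uniprot_id), gene_symbol=str(row.gene_symbol),
            tss_chr=str(row.tss_chr), tss_pos=int(row.tss_pos))
    return out
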