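"""Spot-level QC and per-histology expression summaries.

Operates on generic spot x gene matrices of raw non-negative integer
counts with a histology label per spot (e.g. Benign, GG1, GG2, GG4 for
Gleason grade groups).  Spots with fewer than 500 total UMIs are removed;
per-label summaries report the median and quartiles of raw counts (linear
interpolation between order statistics); group comparisons use a
tie-corrected Kruskal-Wallis omnibus test with Dunn's post test and
Bonferroni adjustment across label pairs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.io import mmread


@dataclass
class SpotMatrix:
    """Counts (spots x genes) with per-spot histology labels and section ids."""

    counts: pd.DataFrame
    labels: pd.Series
    sections: pd.Series = None

    def __post_init__(self):
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.labels = pd.Series(self.labels, index=self.counts.index)
        if self.sections is None:
            self.sections = pd.Series("S1", index=self.counts.index)

    @property
    def umi(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @classmethod
    def from_dense_tsv(cls, counts_path, annot_path) -> "SpotMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        annot = pd.read_csv(annot_path, sep="\t", index_col=0)
        return cls(counts, annot["label"],
                   annot["section"] if "section" in annot else None)

    @classmethod
    def from_mtx(cls, mtx_path, genes_path, annot_path) -> "SpotMatrix":
        mat = mmread(mtx_path).tocsr()
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].tolist()
        annot = pd.read_csv(annot_path, sep="\t", index_col=0)
        counts = pd.DataFrame(mat.toarray(), index=annot.index, columns=genes)
        return cls(counts, annot["label"],
                   annot["section"] if "section" in annot else None)


def qc_filter_spots(matrix: SpotMatrix, min_umi: int = 500,
                    ) -> tuple[SpotMatrix, list[str]]:
    """Remove spots with total UMI strictly below ``min_umi``.

    Returns the filtered matrix and the list of removed spot ids; raises
    when no spot survives.
    """
    keep = matrix.umi >= min_umi
    removed = list(matrix.counts.index[~keep])
    if not keep.any():
        raise ValueError("QC removed every spot")
    return SpotMatrix(matrix.counts.loc[keep], matrix.labels.loc[keep],
                      matrix.sections.loc[keep]), removed


def histology_summary(matrix: SpotMatrix, gene: str) -> pd.DataFrame:
    """Median and quartiles of raw counts per histology label for one gene."""
    if gene not in matrix.counts.columns:
        raise KeyError(f"gene {gene} not present in matrix")
    rows = []
    for label, idx in matrix.labels.groupby(matrix.labels).groups.items():
        vals = matrix.counts.loc[idx, gene].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(vals, [25, 50, 75])  # linear interpolation
        rows.append({"gene": gene, "label": label, "n_spots": len(vals),
                     "q1": q1, "median": med, "q3": q3})
    return pd.DataFrame(rows)


def _dunn_pairwise(values: np.ndarray, groups: np.ndarray,
                   p_adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction."""
    N = len(values)
    ranks = stats.rankdata(values)
    labels = pd.unique(groups)
    mean_rank = {g: ranks[groups == g].mean() for g in labels}
    n = {g: int((groups == g).sum()) for g in labels}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(labels, 2))
    rows = []
    for a, b in pairs:
        sd = np.sqrt(var_base * (1.0 / n[a] + 1.0 / n[b]))
        z = (mean_rank[a] - mean_rank[b]) / sd if sd > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "z": z, "p": p})
    df = pd.DataFrame(rows)
    if p_adjust == "bonferroni":
        df["p_adj"] = np.minimum(df["p"] * len(pairs), 1.0)
    elif p_adjust == "none":
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    return df


def kruskal_dunn(matrix: SpotMatrix, gene: str,
                 p_adjust: str = "bonferroni") -> tuple[float, float, pd.DataFrame]:
    """Kruskal-Wallis omnibus H (tie-corrected) and Dunn pairwise post tests.

    Labels with zero spots are excluded with a warning; with exactly two
    labels Dunn reduces to a single rank-sum comparison.  Returns
    ``(H, omnibus_p, pairwise_frame)``.
    """
    if gene not in matrix.counts.columns:
        raise KeyError(f"gene {gene} not present in matrix")
    values = matrix.counts[gene].to_numpy(dtype=float)
    groups = matrix.labels.to_numpy()
    present = [g for g in pd.unique(groups) if (groups == g).sum() > 0]
    declared = getattr(matrix.labels, "cat", None)
    if declared is not None:
        empty = set(declared.categories) - set(present)
        if empty:
            warnings.warn(f"labels with no spots excluded: {sorted(empty)}")
    if len(present) < 2:
        raise ValueError("need at least two labels with spots")
    samples = [values[groups == g] for g in present]
    if all(np.all(s == samples[0][0]) for s in samples):
        H, omnibus_p = 0.0, 1.0  # scipy rejects the all-identical case
    else:
        H, omnibus_p = stats.kruskal(*samples)
    pairwise = _dunn_pairwise(values, groups, p_adjust=p_adjust)
    return float(H), float(omnibus_p), pairwise
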