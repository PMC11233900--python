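"""Replication assessment and drug-target annotation.

A discovery association replicates in an external GWAS when the external
estimate is directionally concordant and its Wald p-value is below 0.05
(strict).  Drug-target annotation is a pure left join of risk proteins on
a user-supplied gene -> drug mapping table; the restricted analysis
recomputes the Bonferroni threshold against the size of the drug-target
universe (default 525 mappable proteins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mr import bonferroni_threshold


@dataclass
class ReplicationResult:
    protein: str
    outcome: str
    discovery_beta: float
    external_beta: float
    external_p: float
    concordant: bool
    replicated: bool


def assess_replication(protein: str, outcome: str, discovery_beta: float,
                       external_beta: float, external_p: float,
                       ) -> ReplicationResult:
    """Directional concordance + external p < 0.05 replication rule.

    An external beta of exactly zero is non-concordant by convention.
    """
    concordant = bool(np.sign(discovery_beta) == np.sign(external_beta) != 0)
    replicated = concordant and external_p < 0.05
    return ReplicationResult(protein, outcome, discovery_beta,
                             external_beta, external_p, concordant, replicated)


def assess_replication_frame(discovery: pd.DataFrame,
                             external: pd.DataFrame) -> pd.DataFrame:
    """Row-wise replication of a discovery results table against external
    results, joined on (protein, outcome).

    Both frames need columns ``protein``, ``outcome``, ``beta``; the
    external one also needs ``p``.
    """
    ext = external[["protein", "outcome", "beta", "p"]].rename(
        columns={"beta": "beta_external", "p": "p_external"})
    merged = discovery.merge(ext, on=["protein", "outcome"], how="left")
    rows = []
    for r in merged.itertuples():
        ext_beta = getattr(r, "beta_external")
        ext_p = getattr(r, "p_external")
        if pd.isna(ext_beta) or pd.isna(ext_p):
            rows.append((False, False, True))
            continue
        res = assess_replication(r.protein, r.outcome, r.beta, ext_beta, ext_p)
        rows.append((res.concordant, res.replicated, False))
    merged[["concordant", "replicated", "external_missing"]] = pd.DataFrame(
        rows, index=merged.index)
    return merged


def read_drug_mapping(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "drug", "phase") if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: malformed drug mapping, missing column(s) {missing}")
    return df


def annotate_drug_targets(results: pd.DataFrame, mapping: pd.DataFrame,
                          n_drug_universe: int = 525,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Left-join drug/phase annotation onto MR results by gene symbol
    (case-insensitive) and recompute the Bonferroni threshold against the
    drug-target universe.

    Numeric MR/coloc columns are untouched; unmatched proteins keep empty
    annotations.
    """
    out = results.copy()
    mapping = mapping.copy()
    mapping["_gene_key"] = mapping["gene"].str.upper()
    out["_gene_key"] = out["protein"].str.upper()
    out = out.merge(mapping[["_gene_key", "drug", "phase"]],
                    on="_gene_key", how="left").drop(columns="_gene_key")
    thr = bonferroni_threshold(n_drug_universe, alpha)
    out["drug_bonferroni_threshold"] = thr
    if "p" in out.columns:
        out["pass_drug_bonferroni"] = out["drug"].notna() & (out["p"] < thr)
    return out
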