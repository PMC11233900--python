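"""End-to-end discovery pipeline.

instruments -> harmonisation -> Wald/IVW MR -> per-outcome Bonferroni ->
colocalisation (single + conditional) -> risk-protein decisions ->
optional replication and drug-target annotation.

A protein is declared a risk protein for an outcome iff at least one of
its instruments passes the Bonferroni-corrected MR threshold AND its
region colocalises (max PP4 > 0.70).  When two or more independent
instruments individually pass both, an IVW summary row pools them.
Colocalisation is run only for Bonferroni-passing associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import instruments as instr_mod
from . import mr as mr_mod
from . import replication as repl_mod
from .sumstats import (AssocRecord, HarmonisedPair, HarmonisationDrop,
                       harmonise_pair, read_sumstats, record_from_row)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    exposure_path: str
    outcome_paths: dict[str, str]
    ld_path: str
    meta_path: str
    mapping_path: Optional[str] = None
    external_path: Optional[str] = None
    out_dir: str = "protmr_out"
    seed: int = 0
    instrument: instr_mod.InstrumentConfig = field(
        default_factory=instr_mod.InstrumentConfig)
    mr: mr_mod.MRConfig = field(default_factory=mr_mod.MRConfig)
    priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    coloc: coloc_mod.ColocConfig = field(default_factory=coloc_mod.ColocConfig)
    #: override the per-outcome protein counts used for Bonferroni
    n_proteins_per_outcome: Optional[dict[str, int]] = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        for key, klass in (("instrument", instr_mod.InstrumentConfig),
                           ("mr", mr_mod.MRConfig),
                           ("priors", coloc_mod.ColocPriors),
                           ("coloc", coloc_mod.ColocConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)


@dataclass
class ResultsBundle:
    instruments: pd.DataFrame
    mr_results: pd.DataFrame
    coloc_results: pd.DataFrame
    decisions: pd.DataFrame
    audit: list[tuple[str, str, str]]  # (protein, rsid, reason)
    thresholds: dict[str, float]


def _aligned_outcome_beta(exp_proxy: AssocRecord, out_proxy: AssocRecord) -> float:
    """Outcome beta for the exposure-labelled effect allele of the proxy."""
    h = harmonise_pair(exp_proxy, out_proxy)
    return -h.beta_out if h.orientation_flipped else h.beta_out


def _pair_with_proxy(exp_index: AssocRecord, exp_proxy: AssocRecord,
                     out_proxy: AssocRecord, r: float) -> HarmonisedPair:
    """Build a harmonised pair for an index instrument whose outcome record
    comes from an LD proxy; the sign of r carries the allele orientation."""
    beta_out = _aligned_outcome_beta(exp_proxy, out_proxy)
    beta_out *= 1.0 if r >= 0 else -1.0
    beta_exp, flipped = exp_index.beta, False
    ea, oa = exp_index.ea, exp_index.oa
    if beta_exp < 0:
        beta_exp, beta_out = -beta_exp, -beta_out
        ea, oa = oa, ea
        flipped = True
    return HarmonisedPair(
        rsid=exp_index.rsid, ea=ea, oa=oa,
        beta_exp=beta_exp, se_exp=exp_index.se,
        beta_out=beta_out, se_out=out_proxy.se,
        eaf_exp=exp_index.eaf, orientation_flipped=flipped,
        proxy_used=out_proxy.rsid,
    )


def run_discovery(config: PipelineConfig) -> ResultsBundle:
    """Run the discovery pipeline from files named in ``config``."""
    exposure = read_sumstats(config.exposure_path)
    if "protein" not in exposure.columns:
        raise ValueError("exposure sumstats need a 'protein' column")
    outcomes = {name: read_sumstats(path)
                for name, path in config.outcome_paths.items()}
    ld = instr_mod.LDMatrix.from_tsv(config.ld_path)
    meta = instr_mod.read_protein_meta(config.meta_path)

    icfg = config.instrument
    audit: list[tuple[str, str, str]] = []
    instr_rows, mr_rows = [], []

    for protein, exp_prot in exposure.groupby("protein"):
        if protein not in meta:
            audit.append((protein, "", "no_metadata"))
            continue
        window = instr_mod.cis_window(meta[protein], icfg)
        candidates, tier = instr_mod.select_cis_candidates(exp_prot, window, icfg)
        if tier is None:
            audit.append((protein, "", "no_cis_candidates"))
            continue
        strong, weak_audit = instr_mod.filter_weak(candidates, icfg)
        audit.extend((protein, r, reason) for r, reason in weak_audit)
        if not len(strong):
            audit.append((protein, "", "all_instruments_weak"))
            continue
        clumped = instr_mod.ld_clump(strong, ld, icfg)
        for row in clumped.itertuples():
            pve, pve_method = instr_mod.compute_pve(
                beta=row.beta, eaf=None if pd.isna(row.eaf) else row.eaf,
                n=None if pd.isna(row.n) else row.n, f_stat=row.f_stat)
            instr_rows.append({
                "protein": protein, "rsid": row.rsid, "chr": row.chr,
                "pos": row.pos, "tier": tier, "f_stat": row.f_stat,
                "pve": pve, "pve_method": pve_method,
            })

        exp_by_rsid = {r.rsid: r for r in exp_prot.itertuples()}
        for name, out_df in outcomes.items():
            out_by_rsid = {r.rsid: r for r in out_df.itertuples()}
            positions = dict(zip(exp_prot["rsid"], exp_prot["pos"]))
            for row in clumped.itertuples():
                exp_rec = record_from_row(exp_by_rsid[row.rsid]._asdict())
                proxy_used = None
                if row.rsid in out_by_rsid:
                    out_rec = record_from_row(out_by_rsid[row.rsid]._asdict())
                    try:
                        pair = harmonise_pair(exp_rec, out_rec)
                    except HarmonisationDrop as drop:
                        audit.append((protein, row.rsid, drop.reason))
                        continue
                else:
                    available = [r for r in out_df["rsid"]
                                 if r in ld and r in exp_by_rsid]
                    found = instr_mod.find_proxy(row.rsid, available, ld, icfg,
                                                 positions=positions)
                    if found is None:
                        audit.append((protein, row.rsid, "absent_no_proxy"))
                        continue
                    proxy_rsid, r_val = found
                    exp_proxy = record_from_row(exp_by_rsid[proxy_rsid]._asdict())
                    out_proxy = record_from_row(out_by_rsid[proxy_rsid]._asdict())
                    try:
                        pair = _pair_with_proxy(exp_rec, exp_proxy, out_proxy, r_val)
                    except HarmonisationDrop as drop:
                        audit.append((protein, row.rsid, drop.reason))
                        continue
                    proxy_used = proxy_rsid
                try:
                    est = mr_mod.wald_ratio(pair, config.mr)
                except ZeroDivisionError:
                    audit.append((protein, row.rsid, "zero_exposure_beta"))
                    continue
                mr_rows.append({
                    "outcome": name, "protein": protein, "rsid": row.rsid,
                    "method": "wald", "beta": est.beta, "se": est.se,
                    "p": est.p, "or": est.or_point, "ci_low": est.ci_low,
                    "ci_high": est.ci_high, "proxy_used": proxy_used,
                })
                logger.info("mr protein=%s outcome=%s rsid=%s p=%.3g",
                            protein, name, row.rsid, est.p)

    instruments_df = pd.DataFrame(
        instr_rows, columns=["protein", "rsid", "chr", "pos", "tier",
                             "f_stat", "pve", "pve_method"])
    mr_df = pd.DataFrame(
        mr_rows, columns=["outcome", "protein", "rsid", "method", "beta",
                          "se", "p", "or", "ci_low", "ci_high", "proxy_used"])
    if not len(mr_df):
        reasons = pd.Series([a[2] for a in audit]).value_counts().to_dict()
        raise RuntimeError(f"no usable instruments for any protein: {reasons}")

    counts = config.n_proteins_per_outcome or {
        name: mr_df.loc[mr_df["outcome"] == name, "protein"].nunique()
        for name in outcomes}
    mr_df = mr_mod.bonferroni_filter(mr_df, counts, config.mr.alpha)
    thresholds = {name: mr_mod.bonferroni_threshold(counts[name],
                                                    config.mr.alpha)
                  for name in outcomes}

    # colocalisation only for Bonferroni-passing associations
    coloc_rows = []
    for row in mr_df[mr_df["pass_bonferroni"]].itertuples():
        exp_prot = exposure[exposure["protein"] == row.protein]
        out_df = outcomes[row.outcome]
        index_rsid = row.proxy_used or row.rsid
        try:
            region = coloc_mod.extract_region(index_rsid, exp_prot, out_df,
                                              config.coloc, ld=ld)
        except (KeyError, ValueError) as exc:
            audit.append((row.protein, row.rsid, f"coloc_region: {exc}"))
            continue
        runs = coloc_mod.conditional_iterate(region, ld, config.priors,
                                             config.coloc)
        decision = coloc_mod.pp4_decision(runs, config.coloc)
        for run in runs:
            coloc_rows.append({
                "outcome": row.outcome, "protein": row.protein,
                "rsid": row.rsid, "run": run.label,
                "n_variants": run.n_variants,
                "pp0": run.pp0, "pp1": run.pp1, "pp2": run.pp2,
                "pp3": run.pp3, "pp4": run.pp4,
                "max_pp4": decision.max_pp4, "pass_coloc": decision.passed,
            })
        logger.info("coloc protein=%s outcome=%s max_pp4=%.3f",
                    row.protein, row.outcome, decision.max_pp4)
    coloc_df = pd.DataFrame(
        coloc_rows, columns=["outcome", "protein", "rsid", "run", "n_variants",
                             "pp0", "pp1", "pp2", "pp3", "pp4", "max_pp4",
                             "pass_coloc"])

    decisions_df = _decide(mr_df, coloc_df, config)

    if config.external_path:
        external = pd.read_csv(config.external_path, sep="\t")
        decisions_df = repl_mod.assess_replication_frame(decisions_df, external)
    if config.mapping_path:
        mapping = repl_mod.read_drug_mapping(config.mapping_path)
        decisions_df = repl_mod.annotate_drug_targets(decisions_df, mapping)

    return ResultsBundle(instruments_df, mr_df, coloc_df, decisions_df,
                         audit, thresholds)


def _decide(mr_df: pd.DataFrame, coloc_df: pd.DataFrame,
            config: PipelineConfig) -> pd.DataFrame:
    """Risk-protein declarations: Bonferroni AND coloc, IVW when >= 2
    instruments individually pass both."""
    best_pp4 = (coloc_df.groupby(["outcome", "protein", "rsid"])["max_pp4"]
                .max() if len(coloc_df) else pd.Series(dtype=float))
    rows = []
    for (outcome, protein), grp in mr_df.groupby(["outcome", "protein"]):
        passing = []
        for _, row in grp.iterrows():
            pp4 = best_pp4.get((outcome, protein, row["rsid"]), 0.0) \
                if len(coloc_df) else 0.0
            if row["pass_bonferroni"] and pp4 > config.coloc.pp4_threshold:
                passing.append((row, pp4))
        if not passing:
            continue
        for row, pp4 in passing:
            rows.append({
                "outcome": outcome, "protein": protein, "rsid": row["rsid"],
                "method": "wald", "beta": row["beta"], "se": row["se"],
                "p": row["p"], "or": row["or"], "ci_low": row["ci_low"],
                "ci_high": row["ci_high"], "max_pp4": pp4,
                "risk_protein": True,
            })
        if len(passing) >= 2:
            ests = [mr_mod.WaldEstimate(r["rsid"], r["beta"], r["se"], r["p"],
                                        r["or"], r["ci_low"], r["ci_high"])
                    for r, _ in passing]
            ivw = mr_mod.ivw_combine(ests, config.mr)
            p_head = ivw.p_mre if config.mr.use_mre else ivw.p_fixed
            rows.append({
                "outcome": outcome, "protein": protein,
                "rsid": ";".join(e.rsid for e in ests), "method": "ivw",
                "beta": ivw.beta,
                "se": ivw.se_mre if config.mr.use_mre else ivw.se_fixed,
                "p": p_head, "or": ivw.or_point, "ci_low": ivw.ci_low,
                "ci_high": ivw.ci_high,
                "max_pp4": max(pp for _, pp in passing),
                "risk_protein": True,
            })
    return pd.DataFrame(
        rows, columns=["outcome", "protein", "rsid", "method", "beta", "se",
                       "p", "or", "ci_low", "ci_high", "max_pp4",
                       "risk_protein"])


def write_report(bundle: ResultsBundle, out_dir) -> Path:
    """Write all result tables as TSV plus a human-readable summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.instruments.to_csv(out / "instruments.tsv", sep="\t", index=False)
    bundle.mr_results.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    bundle.coloc_results.to_csv(out / "coloc_results.tsv", sep="\t", index=False)
    bundle.decisions.to_csv(out / "decisions.tsv", sep="\t", index=False)
    pd.DataFrame(bundle.audit, columns=["protein", "rsid", "reason"]).to_csv(
        out / "harmonisation_audit.tsv", sep="\t", index=False)

    lines = ["protmr discovery report", "=" * 24, ""]
    for outcome, thr in sorted(bundle.thresholds.items()):
        sub = bundle.decisions[bundle.decisions["outcome"] == outcome] \
            if len(bundle.decisions) else bundle.decisions
        n_risk = sub["protein"].nunique() if len(sub) else 0
        n_tested = bundle.mr_results.loc[
            bundle.mr_results["outcome"] == outcome, "protein"].nunique()
        lines.append(f"outcome {outcome}: {n_tested} proteins tested, "
                     f"Bonferroni threshold {thr:.4g}, "
                     f"{n_risk} risk protein(s) declared")
    if not len(bundle.decisions):
        lines.append("")
        lines.append("zero risk-protein declarations")
    report = out / "report.txt"
    report.write_text("\n".join(lines) + "\n")
    return report
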