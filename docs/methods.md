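# Methods

## The estimand and the pipeline

The package estimates the effect of a one-SD increment in genetically
predicted circulating protein level on the log-odds of a binary disease
outcome, using *cis*-pQTL as instruments. The discovery logic is a strict
conjunction: a protein is declared a risk protein for an outcome only
when (i) at least one instrument's Wald ratio passes the per-outcome
Bonferroni threshold 0.05/N_proteins (strict `<`), and (ii) the ±75 kb
region around that instrument colocalises (highest PP4 of any single or
conditional run strictly above 0.70). Associations failing the MR
threshold are never sent to colocalisation. When two or more independent
instruments for one protein individually satisfy both conditions, an IVW
summary row pools them.

## Two-sample MR

The Wald ratio is β_out/β_exp with first-order delta SE σ_out/|β_exp|.
This matches common two-sample MR practice and the intervals printed in
the literature this package is designed to reproduce; a second-order SE
(adding β_out²σ_exp²/β_exp⁴) is available behind
`MRConfig(second_order_se=True)`. The first-order SE is slightly
conservative at realistic instrument strength (F ≈ 350 for
PVE = 0.01 at n = 35,000); empirical CI coverage on shared-scenario
simulations is 0.94–0.95.

IVW pools per-instrument estimates with weights 1/σᵢ²; Cochran's
Q = Σwᵢ(βᵢ−β̄)² measures heterogeneity, and the headline interval uses a
multiplicative random-effects SE, σ_fixed·max(1, √(Q/(k−1))). MRE was
chosen because the worked plasminogen example's printed interval
(0.62–0.92) is consistent with MRE and not with the fixed-effect
interval; the point estimate is identical either way.

Bonferroni counts are per outcome: the number of unique proteins with at
least one analysable instrument for that outcome (overridable in
`PipelineConfig.n_proteins_per_outcome`).

## Harmonisation

Outcome records are aligned to exposure records by rsID and alleles:
direct match, effect/other swap (negating β and reflecting the allele
frequency), or strand complementation, in that order; irreconcilable
allele sets are dropped with reason `allele_mismatch`. Palindromic (A/T,
C/G) variants are retained only when both allele frequencies are present,
on the same side of 0.5, and more than 0.08 from 0.5 — a conventional
margin, configurable. Every pair is then oriented so the exposure effect
allele is protein-increasing (β_exp ≥ 0). Proxies substitute the outcome
record of the best LD partner (max r², strictly above 0.8; ties broken by
distance then rsID) with the sign of r carrying the allele orientation.

## Instrument selection

The cis window is the closed interval ±1 Mb around the TSS, clamped at
position 1. Candidate selection is two-tier: all in-window variants at
p < 5×10⁻⁸ (tier `primary`); if none, all at p < 5×10⁻⁵ (tier
`relaxed`). Greedy clumping visits candidates by ascending p (ties:
position, then rsID — determinism requires a total order) and keeps a
variant iff r² < 0.01 against everything already kept; the result is
provably the lexicographically greatest pairwise-independent subset in
that order, which the test suite checks against exhaustive enumeration.
Weak instruments are excluded at F = β²/σ² < 10. PVE per variant is
2·eaf·(1−eaf)·β² for a standardized trait when the allele frequency is
known, else F/(F+n−2); the method used is recorded, since published
tables rarely state theirs.

## Colocalisation

Per-variant evidence is the Wakefield log approximate Bayes factor
lABF = ½(ln(1−r) + r·z²) with r = W/(W+σ²). Prior effect-standard
deviations default to 0.15 for quantitative traits and 0.2 for log-odds
traits — the conventional defaults of the ABF framework; both are
configurable (`ColocConfig.w_quant`, `w_binary`). Hypothesis evidences
are assembled in log space; the H3 sum over ordered distinct pairs is
computed stably as log(exp(LSE₁+LSE₂) − exp(LSE₁₂)), which degrades
gracefully to −∞ for single-variant regions instead of producing NaN.
Priors default to p1 = 10⁻³, p2 = 10⁻⁴, p12 = 10⁻⁵, i.e. roughly a 0.1%
prior probability of colocalisation in a 100-variant region (m·p12).

Multi-signal regions use approximate conditional analysis on the LD
reference: per trait, stepwise lead selection (up to 3 signals, stopping
when the conditioned lead's p > 5×10⁻⁵), conditioned z-vectors
z′ = z − R[:,C](R[C,C]+10⁻⁶I)⁻¹z_C, and one colocalisation run per
combination of isolated per-trait signals alongside the unconditioned
run. The decision statistic is the maximum PP4 over runs. These
mechanics are this package's own documented construction of
"conditional iterative" colocalisation from summary statistics; the
ridge guards near-singular LD submatrices and is configurable.

## Power

For N = n_cases+n_controls with case fraction φ and instrument R² = PVE,
power = Φ(|ln OR|·√(N·PVE·φ(1−φ)) − z_{1−α/2}), inverted for the minimum
detectable OR. α is the nominal two-sided 0.05, not a
multiplicity-corrected level — that is the only reading under which the
published worked examples (1.14 overall, 1.29 aggressive) reproduce.
The published early-onset value of 1.36 does *not* reproduce from the
printed counts (6,988/44,256 gives ≈1.43 under this formula); it is
documented here rather than asserted anywhere. The formula treats the
instrument effect as known; the validation experiment therefore simulates
a very large exposure GWAS, and at realistic exposure sample sizes the
first-order Wald test is mildly conservative relative to the formula.

## Synthetic data generator

The generator works at the level of summary statistics, not genotypes.
An LD block has R_ij = ρ^|i−j| (symmetric, unit-diagonal, positive
definite for ρ ∈ [0,1)); default blocks use 1 kb spacing and MAFs either
fixed or uniform(0.05, 0.5). Observed z-scores are drawn from
MVN(R·z_true, R) — the standard summary-statistics likelihood — and
converted to betas via σ_j = 1/√(2·maf_j(1−maf_j)·n), with n replaced by
the effective size n_cases·n_controls/N for case-control traits, matching
the log-odds approximation used by the power formula. The causal pQTL's
standardized effect satisfies 2·maf(1−maf)·b² = PVE (default PVE 0.01,
the median instrument strength the pipeline targets); PVE above
2·maf(1−maf) would imply a per-allele effect above 1 SD and is rejected.
A true protein→outcome effect θ induces a log-odds effect θ·b at the
shared variant, so the Wald ratio recovers θ. Scenarios: `shared`,
`distinct` (independent outcome causal, LD confounding), `null` (θ = 0),
and `multi_signal` (two exposure causals). Exposure and outcome noise are
independent (two-sample setting) and every draw is bit-reproducible from
the scenario seed via spawned seed sequences.

What the generator does **not** emulate: realistic human LD (block
boundaries, long-range LD, ancestry differences), allele-frequency–
dependent effect sizes, sample overlap, imputation noise, or
binary-trait non-collapsibility — the log-odds scale is taken as exact.
Passing recovery tests therefore shows the estimators are correct under
the stated model, not that real-data complications are handled.

## Validation experiments and problem sizes

`protmr.experiments` scores the pipeline against generator truth, using
problem sizes chosen to give stable Monte-Carlo estimates at desk scale:

- **Wald recovery** — 500 shared-scenario studies (θ = 0.5, PVE 0.01,
  n_exp 35,000, 15,000/50,000 case-control, 150-variant blocks): median
  estimate within 0.03 of θ; 95% CI coverage 0.95 ± 0.02.
- **FWER** — 500 replicates of a 100-protein all-null proteome
  (25-variant blocks; the block size does not affect the null Wald p):
  family-wise error after Bonferroni ≤ 0.08 (theoretical ≈ 0.049).
- **Coloc discrimination** — 200 replicates each of strong shared
  signals (PP4 > 0.7 required in ≥ 90%) and distinct causals at r² = 0.5
  exactly (adjacent variants with ρ = √0.5; PP3 > PP4 in ≥ 90%), using
  the overall-design outcome sample sizes.
- **Power agreement** — empirical rejection rates at three (OR, design)
  grid points within 2 MC standard errors of the closed form at 20,000
  replicates.

## Numerical and degenerate-input choices

- Normal tails via `scipy.stats.norm.sf`; z₀.₉₇₅ = 1.959964 used for CI
  conversion, matching printed-table precision.
- Quantiles by linear interpolation between order statistics (IQRs
  depend on this convention).
- Kruskal–Wallis and Dunn use pooled midranks with tie correction; with
  all observations identical the omnibus is defined as H = 0, p = 1.
  Dunn p-values are Bonferroni-adjusted across pairs and capped at 1.
- Clumping/proxy ties broken by (p, position, rsID) / (r², distance,
  rsID) for determinism.
- Strict inequalities at all decision boundaries: Bonferroni
  (p < 0.05/N), PP4 (> 0.70), replication (p < 0.05), UMI filter
  (keep ≥ 500).
- A zero exposure beta makes the Wald ratio undefined and is reported as
  an error, not silently dropped. A zero external beta is
  non-concordant by convention in replication.

## Known limitations

- The conditional-iterative colocalisation mechanics are one reasonable
  construction; published analyses using other implementations may
  differ in multi-signal regions.
- Only biallelic SNVs are handled; no indel normalisation, multi-allelic
  splitting, or genome-build liftover (positions are carried as given,
  hg19 convention).
- The PVE formula for published instruments is a reconstruction; tables
  computed with other conventions will not match exactly.
- Drug-target annotation is a pure table join; curating the mapping is
  the user's responsibility.
- Spatial summaries operate on raw counts by design (matching
  "RNA count" presentations); no normalisation or spatial statistics.
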