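import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protmr.coloc import (ColocConfig, ColocPriors, RegionData,
                          coloc_posteriors, conditional_iterate,
                          extract_region, pp4_decision,
                          prior_shared_probability, wakefield_labf,
                          _condition_z)
from protmr.instruments import LDMatrix
from protmr.synthetic import LDBlockSpec, make_ld_matrix


def _region(l1_z, l2_z, se=0.1, W=None):
    """Region with betas chosen to hit given z-scores at constant se."""
    m = len(l1_z)
    return RegionData(
        rsids=[f"rs{i}" for i in range(m)],
        pos=np.arange(m, dtype=float),
        beta1=np.asarray(l1_z) * se, se1=np.full(m, se),
        beta2=np.asarray(l2_z) * se, se2=np.full(m, se),
    )


def _enumeration_oracle(region, priors, config):
    """Independent brute force: sum ABF products over every single-causal
    configuration of the five hypotheses, in plain (non-log) arithmetic."""
    W1 = config.w_quant if region.trait1_type == "quant" else config.w_binary
    W2 = config.w_quant if region.trait2_type == "quant" else config.w_binary

    def abf(beta, se, W):
        r = W / (W + se ** 2)
        return math.sqrt(1 - r) * math.exp(r * (beta / se) ** 2 / 2)

    a1 = [abf(b, s, W1) for b, s in zip(region.beta1, region.se1)]
    a2 = [abf(b, s, W2) for b, s in zip(region.beta2, region.se2)]
    m = region.n_variants
    h0 = 1.0
    h1 = priors.p1 * sum(a1)
    h2 = priors.p2 * sum(a2)
    h3 = priors.p1 * priors.p2 * sum(
        a1[i] * a2[j] for i, j in itertools.product(range(m), range(m))
        if i != j)
    h4 = priors.p12 * sum(a1[i] * a2[i] for i in range(m))
    total = h0 + h1 + h2 + h3 + h4
    return np.array([h0, h1, h2, h3, h4]) / total


class TestPriors:
    def test_defaults(self):
        p = ColocPriors()
        assert (p.p1, p.p2, p.p12) == (1e-3, 1e-4, 1e-5)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=1e-5, p2=1e-4, p12=1e-3)

    def test_prior_shared_probability_100_variants(self):
        """Q * p12: a 0.1% prior belief in colocalisation at m=100."""
        assert prior_shared_probability(100) == pytest.approx(1e-3)


class TestWakefield:
    def test_vanishing_prior_variance(self):
        assert wakefield_labf(0.5, 0.1, 0.0) == pytest.approx(0.0)

    def test_worked_example(self):
        # r = 0.04/0.05 = 0.8, z = 5: 0.5 (ln 0.2 + 0.8 * 25)
        assert wakefield_labf(0.5, 0.1, 0.04) == pytest.approx(9.195, abs=1e-3)

    def test_null_z_negative(self):
        assert wakefield_labf(0.0, 0.1, 0.04) < 0

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            wakefield_labf(0.1, 0.0, 0.04)


class TestPosteriors:
    def test_single_variant_flat(self):
        """m=1 with lABF=0 in both traits: posteriors proportional to
        {1, p1, p2, 0, p12}."""
        region = _region([0.0], [0.0])
        cfg = ColocConfig(w_quant=1e-12, w_binary=1e-12)
        res = coloc_posteriors(region, config=cfg)
        assert res.pp0 == pytest.approx(1 / 1.00111, rel=1e-4)
        assert res.pp3 == 0.0

    def test_flat_100_variants_prior_dominated(self):
        region = _region([0.0] * 100, [0.0] * 100)
        cfg = ColocConfig(w_quant=1e-12, w_binary=1e-12)
        res = coloc_posteriors(region, config=cfg)
        assert res.pp4 == pytest.approx(9.0e-4, rel=1e-2)

    def test_strong_shared_signal(self):
        z1 = np.zeros(50); z2 = np.zeros(50)
        z1[20] = z2[20] = 8.0
        res = coloc_posteriors(_region(z1, z2))
        assert res.pp4 > 0.99

    def test_sum_to_one(self):
        rng = np.random.default_rng(0)
        region = _region(rng.normal(size=30), rng.normal(size=30))
        res = coloc_posteriors(region)
        assert res.as_array().sum() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_enumeration_oracle_small_regions(self, seed):
        """Exact match with brute-force configuration enumeration, m <= 5."""
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 6)
        region = _region(rng.normal(0, 2, m), rng.normal(0, 2, m),
                         se=float(rng.uniform(0.05, 0.3)))
        priors, cfg = ColocPriors(), ColocConfig()
        res = coloc_posteriors(region, priors, cfg)
        expected = _enumeration_oracle(region, priors, cfg)
        np.testing.assert_allclose(res.as_array(), expected, atol=1e-10)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        z1, z2 = rng.normal(0, 3, 12), rng.normal(0, 3, 12)
        perm = rng.permutation(12)
        a = coloc_posteriors(_region(z1, z2))
        b = coloc_posteriors(_region(z1[perm], z2[perm]))
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-12)

    def test_invariant_to_impossible_variant(self):
        """Adding a variant with lABF = -inf in both traits changes nothing."""
        z1, z2 = [1.0, 2.0], [0.5, 2.5]
        a = coloc_posteriors(_region(z1, z2))
        # beta = 0 with se -> 0 drives r -> 1 and lABF -> -inf
        impossible = RegionData(
            rsids=["rs0", "rs1", "rs2"], pos=np.arange(3, dtype=float),
            beta1=np.array([0.1, 0.2, 0.0]), se1=np.array([0.1, 0.1, 1e-12]),
            beta2=np.array([0.05, 0.25, 0.0]), se2=np.array([0.1, 0.1, 1e-12]),
        )
        b = coloc_posteriors(impossible)
        np.testing.assert_allclose(a.as_array(), b.as_array(), atol=1e-9)

    def test_monotone_in_shared_signal(self):
        """Scaling the shared variant's z upward never decreases PP4."""
        rng = np.random.default_rng(2)
        base1, base2 = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        last = -1.0
        for scale in (1.0, 2.0, 4.0, 6.0, 8.0):
            z1, z2 = base1.copy(), base2.copy()
            z1[10] = z2[10] = scale
            pp4 = coloc_posteriors(_region(z1, z2)).pp4
            assert pp4 >= last - 1e-12
            last = pp4


class TestExtractRegion:
    def _frames(self):
        import pandas as pd
        rows = []
        for i, pos in enumerate([925_000 - 1, 925_000, 1_000_000, 1_075_000]):
            rows.append({"rsid": f"rs{i}", "chr": "1", "pos": pos,
                         "ea": "A", "oa": "G", "eaf": 0.3,
                         "beta": 0.1, "se": 0.02, "pval": 1e-6})
        exp = pd.DataFrame(rows)
        out = exp.copy()
        return exp, out

    def test_window_bounds_closed(self):
        exp, out = self._frames()
        region = extract_region("rs2", exp, out)
        assert set(region.rsids) == {"rs1", "rs2", "rs3"}  # 925000 included

    def test_one_sided_variant_excluded(self):
        exp, out = self._frames()
        out = out[out["rsid"] != "rs1"]
        region = extract_region("rs2", exp, out)
        assert "rs1" not in region.rsids

    def test_missing_index_raises(self):
        exp, out = self._frames()
        with pytest.raises(KeyError):
            extract_region("rs99", exp, out)


class TestConditional:
    def test_single_signal_returns_single_run_only(self):
        spec = LDBlockSpec.create(40, 0.9, maf=0.3)
        ld = LDMatrix.from_frame(make_ld_matrix(spec))
        z = np.zeros(40); z[20] = 9.0
        z1 = ld.values @ z
        region = _region(z1, z1 * 0.5, se=0.05)
        region.rsids = spec.rsids
        runs = conditional_iterate(region, ld)
        assert [r.label for r in runs] == ["single"]

    def test_secondary_shared_signal_found_by_conditioning(self):
        """Two exposure signals; only the secondary is shared with the
        outcome: the single run misses colocalisation, a conditional run
        finds it."""
        spec = LDBlockSpec.create(60, 0.9, maf=0.3)
        ld = LDMatrix.from_frame(make_ld_matrix(spec))
        R = ld.values
        z1_true = np.zeros(60); z1_true[15] = 40.0; z1_true[45] = 9.0
        z2_true = np.zeros(60); z2_true[45] = 9.0
        region = _region(R @ z1_true, R @ z2_true, se=0.05)
        region.rsids = spec.rsids
        single = coloc_posteriors(region)
        assert single.pp4 < 0.7  # distinct lead pair dominates
        runs = conditional_iterate(region, ld)
        decision = pp4_decision(runs)
        assert decision.max_pp4 > 0.7
        assert decision.passed
        assert decision.best_label.startswith("conditional")

    def test_conditioning_on_causal_zeroes_its_z(self):
        spec = LDBlockSpec.create(30, 0.8, maf=0.3)
        R = make_ld_matrix(spec).to_numpy()
        z = R @ np.r_[np.zeros(14), 10.0, np.zeros(15)]
        zc = _condition_z(z, R, [14], 1e-6)
        assert abs(zc[14]) < 1e-3


class TestDecision:
    @pytest.mark.parametrize("pp4,passed", [(0.71, True), (0.70, False)])
    def test_strict_boundary(self, pp4, passed):
        from protmr.coloc import ColocResult
        res = ColocResult(0, 0, 0, 1 - pp4, pp4, 10)
        assert pp4_decision([res]).passed is passed

    def test_max_over_runs(self):
        from protmr.coloc import ColocResult
        runs = [ColocResult(0, 0, 0, 0.8, 0.2, 10, "single"),
                ColocResult(0, 0, 0, 0.1, 0.9, 10, "conditional:2x1")]
        d = pp4_decision(runs)
        assert d.max_pp4 == pytest.approx(0.9)
        assert d.passed and d.best_label == "conditional:2x1"
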