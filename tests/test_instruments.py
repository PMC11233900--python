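import itertools

import numpy as np
import pandas as pd
import pytest

from protmr.instruments import (InstrumentConfig, LDMatrix, ProteinMeta,
                                cis_window, compute_pve, f_statistic,
                                filter_weak, find_proxy, ld_clump,
                                select_cis_candidates)
from protmr.synthetic import (LDBlockSpec, ScenarioConfig, make_ld_matrix,
                              simulate_exposure_sumstats)


def _candidates(rows):
    return pd.DataFrame(rows, columns=["rsid", "chr", "pos", "pval"])


class TestCisWindow:
    def test_centred(self):
        w = cis_window(ProteinMeta("P1", "G1", "2", 5_000_000))
        assert w == ("2", 4_000_000, 6_000_000)

    def test_clamped_at_chromosome_start(self):
        w = cis_window(ProteinMeta("P1", "G1", "2", 500_000))
        assert w == ("2", 1, 1_500_000)

    def test_length_bounded(self):
        for tss in (1, 10, 10 ** 6, 10 ** 8):
            _, s, e = cis_window(ProteinMeta("P", "G", "1", tss))
            assert e - s + 1 <= 2_000_001


class TestSelectCandidates:
    def _ss(self, pvals):
        return pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(len(pvals))],
            "chr": "1", "pos": [1_000_000 + i for i in range(len(pvals))],
            "pval": pvals,
        })

    def test_primary_tier(self):
        sub, tier = select_cis_candidates(self._ss([1e-9, 1e-6]),
                                          ("1", 1, 2_000_000))
        assert tier == "primary" and list(sub["rsid"]) == ["rs0"]

    def test_relaxed_tier(self):
        sub, tier = select_cis_candidates(self._ss([1e-6, 2e-5]),
                                          ("1", 1, 2_000_000))
        assert tier == "relaxed" and len(sub) == 2

    def test_no_candidates(self):
        sub, tier = select_cis_candidates(self._ss([1e-4]),
                                          ("1", 1, 2_000_000))
        assert tier is None and len(sub) == 0

    def test_out_of_window_excluded(self):
        ss = self._ss([1e-9])
        sub, tier = select_cis_candidates(ss, ("1", 1, 999_999))
        assert tier is None


def _brute_force_clump(cands: pd.DataFrame, ld: LDMatrix, r2: float):
    """Independent oracle: among all pairwise-independent subsets, take the
    lexicographically greatest membership vector in (p, pos, rsid) order."""
    order = cands.sort_values(["pval", "pos", "rsid"],
                              kind="mergesort").reset_index(drop=True)
    n = len(order)
    best = None
    for mask in itertools.product([1, 0], repeat=n):
        chosen = [i for i in range(n) if mask[i]]
        ok = all(ld.r2(order.loc[a, "rsid"], order.loc[b, "rsid"]) < r2
                 for a, b in itertools.combinations(chosen, 2))
        if ok:
            best = mask if best is None else max(best, mask)
    return [order.loc[i, "rsid"] for i in range(n) if best[i]]


class TestClump:
    def _ld(self, ids, r2_pairs):
        n = len(ids)
        V = np.eye(n)
        idx = {v: i for i, v in enumerate(ids)}
        for (a, b), r2 in r2_pairs.items():
            V[idx[a], idx[b]] = V[idx[b], idx[a]] = np.sqrt(r2)
        return LDMatrix(ids, V)

    def test_worked_example(self):
        ld = self._ld(["A", "B", "C"],
                      {("A", "B"): 0.5, ("A", "C"): 0.001, ("B", "C"): 0.001})
        cands = _candidates([("A", "1", 1, 1e-10), ("B", "1", 2, 1e-9),
                             ("C", "1", 3, 1e-8)])
        kept = ld_clump(cands, ld)
        assert list(kept["rsid"]) == ["A", "C"]

    def test_single_candidate(self):
        ld = self._ld(["A"], {})
        kept = ld_clump(_candidates([("A", "1", 1, 1e-10)]), ld)
        assert list(kept["rsid"]) == ["A"]

    def test_all_independent_retained(self):
        ld = self._ld(["A", "B", "C"], {})
        kept = ld_clump(_candidates([("A", "1", 1, 1e-8), ("B", "1", 2, 1e-9),
                                     ("C", "1", 3, 1e-10)]), ld)
        assert set(kept["rsid"]) == {"A", "B", "C"}

    def test_missing_variant_raises(self):
        ld = self._ld(["A"], {})
        with pytest.raises(KeyError, match="B"):
            ld_clump(_candidates([("B", "1", 1, 1e-9)]), ld)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        """Greedy clumping equals exhaustive-subset oracle on <=10 candidates."""
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 9)
        spec = LDBlockSpec.create(int(n), float(rng.uniform(0.3, 0.95)))
        ld = LDMatrix.from_frame(make_ld_matrix(spec))
        cands = _candidates([
            (rs, "1", 1_000_000 + i, float(rng.uniform(1e-12, 1e-4)))
            for i, rs in enumerate(spec.rsids)])
        kept = list(ld_clump(cands, ld)["rsid"])
        assert kept == _brute_force_clump(cands, ld, 0.01)
        # pairwise independence asserted directly
        for a, b in itertools.combinations(kept, 2):
            assert ld.r2(a, b) < 0.01


class TestFStat:
    def test_strong(self):
        assert f_statistic(0.5, 0.05) == pytest.approx(100)

    def test_weak_excluded(self):
        df = pd.DataFrame({"rsid": ["a", "b"], "beta": [0.5, 0.1],
                           "se": [0.05, 0.1]})
        kept, audit = filter_weak(df)
        assert list(kept["rsid"]) == ["a"]
        assert audit[0][0] == "b" and "weak" in audit[0][1]

    def test_equals_z_squared(self):
        from protmr.sumstats import z_and_p
        z, _ = z_and_p(0.37, 0.021)
        assert f_statistic(0.37, 0.021) == pytest.approx(z ** 2)


class TestPve:
    def test_af_beta_formula(self):
        pve, method = compute_pve(beta=0.1581, eaf=0.5)
        assert pve == pytest.approx(0.0125, abs=1e-4)
        assert method == "af_beta"

    def test_zero_beta(self):
        assert compute_pve(beta=0.0, eaf=0.3)[0] == 0.0

    def test_f_n_fallback(self):
        pve, method = compute_pve(f_stat=100, n=10_002)
        assert pve == pytest.approx(100 / 10_100)
        assert method == "f_n"

    def test_missing_inputs(self):
        with pytest.raises(ValueError):
            compute_pve()


class TestProxy:
    def _ld(self):
        ids = ["t", "p1", "p2", "p3"]
        V = np.eye(4)
        for i, r in [(1, np.sqrt(0.95)), (2, np.sqrt(0.85)),
                     (3, np.sqrt(0.50))]:
            V[0, i] = V[i, 0] = r
        return LDMatrix(ids, V)

    def test_argmax_r2(self):
        rsid, r = find_proxy("t", ["p1", "p2", "p3"], self._ld())
        assert rsid == "p1" and r == pytest.approx(np.sqrt(0.95))

    def test_none_when_below_threshold(self):
        assert find_proxy("t", ["p3"], self._ld()) is None

    def test_threshold_is_strict(self):
        ids = ["t", "p"]
        V = np.array([[1.0, np.sqrt(0.8)], [np.sqrt(0.8), 1.0]])
        assert find_proxy("t", ["p"], LDMatrix(ids, V)) is None

    def test_negative_r_sign_carried(self):
        ids = ["t", "p"]
        V = np.array([[1.0, -np.sqrt(0.95)], [-np.sqrt(0.95), 1.0]])
        rsid, r = find_proxy("t", ["p"], LDMatrix(ids, V))
        assert rsid == "p" and r < 0

    def test_missing_target(self):
        with pytest.raises(KeyError):
            find_proxy("zz", ["p1"], self._ld())


class TestInstrumentRecovery:
    def test_causal_variant_selected_in_shared_scenario(self):
        """With pve=0.01 and n=35,000 the causal pQTL is selected as an
        instrument in >= 95% of replicates."""
        spec = LDBlockSpec.create(25, 0.9, maf=0.3)
        ld = LDMatrix.from_frame(make_ld_matrix(spec))
        cfg_i = InstrumentConfig()
        window = ("1", 1, 2_000_000)
        hits = 0
        n_reps = 500
        for rep in range(n_reps):
            cfg = ScenarioConfig(scenario="shared", pve=0.01,
                                 exposure_causal_index=12, seed=rep)
            df, _ = simulate_exposure_sumstats(spec, cfg)
            cands, tier = select_cis_candidates(df, window, cfg_i)
            if tier is None:
                continue
            strong, _ = filter_weak(cands, cfg_i)
            kept = ld_clump(strong, ld, cfg_i)
            hits += spec.rsids[12] in set(kept["rsid"])
        assert hits / n_reps >= 0.95
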