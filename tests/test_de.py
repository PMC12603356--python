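import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vice.de import (
    bh_fdr,
    call_degs,
    effect_stratum,
    estimate_dispersion,
    nb_lrt,
    replication_exact_test,
    snr,
    true_positive_rate,
)

LABELS = ["a"] * 3 + ["b"] * 3


class TestEstimateDispersion:
    def test_poisson_limit(self, nb_rng):
        mu = nb_rng.lognormal(np.log(50), 1.0, 500)
        y = nb_rng.poisson(np.broadcast_to(mu[:, None], (500, 6)))
        alpha = estimate_dispersion(y, LABELS)
        assert np.median(alpha) <= 0.05

    def test_parameter_recovery(self, nb_rng):
        from conftest import nb_counts

        mu = nb_rng.lognormal(np.log(100), 1.0, 2000)
        y = nb_counts(mu[:, None], 0.4, (2000, 6), nb_rng)
        alpha = estimate_dispersion(y, LABELS)
        assert 0.2 <= np.median(alpha) <= 0.6

    def test_constant_counts_give_zero(self):
        y = np.tile([[10], [3]], (1, 6))
        alpha = estimate_dispersion(y, LABELS, lib_sizes=np.ones(6))
        np.testing.assert_allclose(alpha, 0.0)

    def test_small_group_rejected(self):
        y = np.ones((5, 3), dtype=int)
        with pytest.raises(ValueError, match="fewer than 2"):
            estimate_dispersion(y, ["a", "a", "b"])


@pytest.fixture
def nb_rng():
    return np.random.default_rng(123)


class TestNBLRT:
    def test_identical_groups_identical_counts(self):
        y = np.tile([[30], [7], [150]], (1, 6))
        table = nb_lrt(y, LABELS, lib_sizes=np.ones(6))
        np.testing.assert_allclose(table.log2fc, 0.0, atol=1e-6)
        np.testing.assert_allclose(table.p, 1.0, atol=1e-6)
        assert not table.is_deg.any()

    def test_relabel_within_group_invariance(self, nb_rng):
        from conftest import nb_counts

        mu = nb_rng.lognormal(np.log(80), 1.0, 300)
        y = nb_counts(mu[:, None], 0.1, (300, 6), nb_rng)
        a = nb_lrt(y, LABELS)
        b = nb_lrt(y[:, [1, 2, 0, 5, 3, 4]], LABELS)  # permute within groups
        np.testing.assert_allclose(a.p, b.p, rtol=1e-6, atol=1e-12)
        np.testing.assert_allclose(a.log2fc, b.log2fc, rtol=1e-6, atol=1e-9)

    def test_group_swap_negates_log2fc(self, nb_rng):
        from conftest import nb_counts

        mu = nb_rng.lognormal(np.log(80), 1.0, 300)
        y = nb_counts(mu[:, None], 0.1, (300, 6), nb_rng)
        fwd = nb_lrt(y, LABELS)
        rev = nb_lrt(y[:, [3, 4, 5, 0, 1, 2]], LABELS)
        np.testing.assert_allclose(fwd.log2fc, -rev.log2fc, rtol=1e-5, atol=1e-8)
        np.testing.assert_allclose(fwd.p, rev.p, rtol=1e-6, atol=1e-12)

    def test_strong_shift_detected(self, nb_rng):
        from conftest import nb_counts

        mu = np.full(50, 200.0)
        y1 = nb_counts(mu[:, None], 0.05, (50, 3), nb_rng)
        y2 = nb_counts(8 * mu[:, None], 0.05, (50, 3), nb_rng)
        table = nb_lrt(np.hstack([y1, y2]), LABELS, lib_sizes=np.ones(6))
        assert table.is_deg.mean() > 0.9
        assert np.median(table.log2fc) == pytest.approx(3.0, abs=0.3)

    def test_all_zero_gene_is_null(self):
        y = np.vstack([np.zeros(6, dtype=int), np.full(6, 50)])
        table = nb_lrt(y, LABELS, lib_sizes=np.ones(6))
        assert table.p.iloc[0] == pytest.approx(1.0)
        assert not table.is_deg.iloc[0]


class TestBH:
    def test_hand_computed_four_values(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_hand_computed_staggered(self):
        # ranks: 0.001*4/1, min(...) cascade computed by hand
        np.testing.assert_allclose(
            bh_fdr([0.001, 0.1, 0.02, 0.9]), [0.004, 0.13333333, 0.04, 0.9]
        )

    def test_single_and_degenerate(self):
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False), min_size=1, max_size=30)
    )
    @settings(max_examples=100, deadline=None)
    def test_dominates_raw_p_and_monotone(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestCallDegs:
    def make(self, fdr, lfc):
        return pd.DataFrame({"gene_id": ["g"], "log2fc": [lfc], "p": [0.0], "fdr": [fdr]})

    def test_fdr_only_criterion(self):
        assert call_degs(self.make(0.04, 0.01)).is_deg.item()

    def test_lfc_criterion_excludes_small_effects(self):
        assert not call_degs(self.make(0.04, 0.05), lfc_min=0.1).is_deg.item()
        assert call_degs(self.make(0.04, 0.15), lfc_min=0.1).is_deg.item()

    def test_boundary_is_strict(self):
        assert not call_degs(self.make(0.05, 1.0)).is_deg.item()
        assert not call_degs(self.make(0.01, 0.1), lfc_min=0.1).is_deg.item()


class TestTruePositiveRate:
    def make_table(self, n, deg_idx, lfc=None):
        lfc = np.zeros(n) if lfc is None else np.asarray(lfc, dtype=float)
        t = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(n)], "log2fc": lfc, "p": 0.0, "fdr": 1.0}
        )
        t["is_deg"] = t.index.isin(deg_idx)
        return t

    def test_partial_recovery(self):
        truth = self.make_table(20, range(10))
        test = self.make_table(20, range(7))
        res = true_positive_rate(test, truth)
        assert res.tpr_overall == pytest.approx(0.7)
        assert res.n_truth_degs == 10

    def test_self_comparison_perfect(self):
        lfc = np.linspace(-3, 3, 30)
        truth = self.make_table(30, range(0, 30, 2), lfc)
        res = true_positive_rate(truth, truth)
        assert res.tpr_overall == 1.0
        assert set(res.tpr_by_stratum.values()) == {1.0}
        assert set(res.tpr_by_stratum) == {"high", "medium", "low"}

    def test_set_intersection_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            truth_set = set(rng.choice(50, size=rng.integers(1, 20), replace=False))
            test_set = set(rng.choice(50, size=rng.integers(0, 30), replace=False))
            truth = self.make_table(50, truth_set)
            test = self.make_table(50, test_set)
            res = true_positive_rate(test, truth)
            assert res.tpr_overall == pytest.approx(
                len(truth_set & test_set) / len(truth_set)
            )

    def test_zero_truth_degs_undefined(self):
        truth = self.make_table(5, [])
        test = self.make_table(5, [0, 1])
        res = true_positive_rate(test, truth)
        assert res.undefined and np.isnan(res.tpr_overall)

    def test_liberality_monotonicity(self):
        """Tightening the test-set FDR threshold can only lower the TPR."""
        rng = np.random.default_rng(9)
        n = 200
        fdrs = rng.uniform(0, 1, n)
        lfc = rng.normal(0, 2, n)
        truth = self.make_table(n, rng.choice(n, 50, replace=False), lfc)
        tprs = []
        for fdr_max in (0.2, 0.1, 0.05, 0.01):
            test = pd.DataFrame(
                {"gene_id": [f"g{i}" for i in range(n)], "log2fc": lfc, "p": fdrs, "fdr": fdrs}
            )
            test = call_degs(test, fdr_max=fdr_max)
            tprs.append(true_positive_rate(test, truth).tpr_overall)
        assert tprs == sorted(tprs, reverse=True)

    def test_strata_partition(self):
        assert effect_stratum(2.0) == "high"
        assert effect_stratum(-2.5) == "high"
        assert effect_stratum(1.5) == "medium"
        assert effect_stratum(1.0) == "low"
        assert effect_stratum(0.0) == "low"


class TestSNR:
    def test_forced_by_definition(self):
        lfc = pd.Series({"g1": 2.0, "g2": 0.0})
        cv = pd.Series({"g1": 0.5, "g2": 0.2})
        out = snr(lfc, cv)
        assert out["g1"] == pytest.approx(4.0)
        assert out["g2"] == 0.0

    def test_zero_or_missing_cv_excluded(self):
        lfc = pd.Series({"g1": 1.0, "g2": 1.0, "g3": 1.0})
        cv = pd.Series({"g1": 0.0, "g2": np.nan, "g3": 0.5})
        assert list(snr(lfc, cv).index) == ["g3"]


class TestReplicationExactTest:
    def test_worked_case(self):
        # all of B inside A over a 10-gene universe: 1 / C(10,5)
        assert replication_exact_test(10, 5, 5, 5) == pytest.approx(1 / 252)

    def test_empty_sets(self):
        assert replication_exact_test(100, 0, 0, 0) == 1.0

    def test_brute_force_enumeration(self):
        """Exact match with enumerating every possible B over small universes."""
        rng = np.random.default_rng(10)
        for _ in range(10):
            n = int(rng.integers(4, 13))
            a = int(rng.integers(0, n + 1))
            b = int(rng.integers(0, n + 1))
            a_set = set(range(a))
            total = 0
            at_least = {}
            for combo in itertools.combinations(range(n), b):
                total += 1
                k = len(a_set & set(combo))
                at_least[k] = at_least.get(k, 0) + 1
            lo = max(0, a + b - n)
            for overlap in range(lo, min(a, b) + 1):
                expected = sum(v for k, v in at_least.items() if k >= overlap) / total
                assert replication_exact_test(n, a, b, overlap) == pytest.approx(expected)

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            replication_exact_test(10, 5, 5, 6)
        with pytest.raises(ValueError):
            replication_exact_test(10, 20, 5, 2)
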