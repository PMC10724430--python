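"""DNB statistics, composite index laws, candidate search and ranking."""
import numpy as np
import pytest

from dnbpipe import (
    ExpressionMatrix,
    ModuleStats,
    SimulationParams,
    candidate_modules,
    composite_index,
    exhaustive_best_module,
    module_stats,
    rank_modules,
    simulate_sample,
    top_markers,
)
from dnbpipe.core import PanelSummary

# Expected statistics of module {A, B} on the conftest toy matrix, frozen
# from an independent brute-force script (loops over scipy.stats.pearsonr;
# see conftest.TOY_VALUES).
ORACLE_SD_IN = 1.655657361237882
ORACLE_PCC_IN = 0.7978024895877591
ORACLE_PCC_OUT = 0.5821760145553934
ORACLE_INDEX = 2.2688761865815668


class TestModuleStats:
    def test_matches_independent_pairwise_oracle(self, toy_matrix):
        # module_stats requires >= 50 cells for real data; bypass via the
        # summary layer to hit the exact toy values
        s = PanelSummary.from_matrix(toy_matrix).module_stats(("A", "B"))
        assert s.sd_in == pytest.approx(ORACLE_SD_IN, rel=1e-12)
        assert s.pcc_in == pytest.approx(ORACLE_PCC_IN, rel=1e-12)
        assert s.pcc_out == pytest.approx(ORACLE_PCC_OUT, rel=1e-12)
        assert s.index == pytest.approx(ORACLE_INDEX, rel=1e-9)

    def test_duplicate_columns_give_perfect_intra_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100),
                             rng.normal(size=100)])
        s = module_stats(ExpressionMatrix(X, ("a", "b", "c", "d")), ("a", "b"))
        assert s.pcc_in == pytest.approx(1.0)

    def test_anticorrelated_pair_counts_as_one(self):
        """|r| convention: y = -x is as coupled as y = x."""
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        X = np.column_stack([x, -x, rng.normal(size=100),
                             rng.normal(size=100)])
        s = module_stats(ExpressionMatrix(X, ("a", "b", "c", "d")), ("a", "b"))
        assert s.pcc_in == pytest.approx(1.0)

    def test_zero_variance_markers_contribute_zero_correlation(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(100, 4))
        X[:, 1] = 5.0  # constant marker inside the module
        s = module_stats(ExpressionMatrix(X, ("a", "b", "c", "d")), ("a", "b"))
        assert s.pcc_in == 0.0
        assert s.n_zero_variance_pairs > 0

    def test_too_few_cells_or_nonmembers_rejected(self, toy_matrix):
        with pytest.raises(ValueError):
            module_stats(toy_matrix, ("A", "B"))  # only 6 cells
        big = ExpressionMatrix(np.random.default_rng(3).normal(size=(60, 4)),
                               ("A", "B", "C", "D"))
        with pytest.raises(ValueError):
            module_stats(big, ("A", "B", "C"))  # only 1 non-member
        with pytest.raises(KeyError):
            module_stats(big, ("A", "Z"))


class TestCompositeIndex:
    def test_forced_arithmetic(self):
        frozen = ModuleStats(("a", "b"), sd_in=0.0, pcc_in=0.5, pcc_out=0.5)
        assert composite_index(frozen) == 0.0
        decoupled = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=1.0, pcc_out=0.0)
        assert composite_index(decoupled) == pytest.approx(1e6)
        s = ModuleStats(("a", "b"), sd_in=0.5, pcc_in=0.8, pcc_out=0.2)
        assert composite_index(s) == pytest.approx(0.4 / 0.200001)

    def test_monotone_in_each_argument(self):
        base = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=0.5, pcc_out=0.3)
        up_sd = ModuleStats(("a", "b"), sd_in=1.5, pcc_in=0.5, pcc_out=0.3)
        up_in = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=0.7, pcc_out=0.3)
        up_out = ModuleStats(("a", "b"), sd_in=1.0, pcc_in=0.5, pcc_out=0.5)
        assert composite_index(up_sd) > composite_index(base)
        assert composite_index(up_in) > composite_index(base)
        assert composite_index(up_out) < composite_index(base)

    def test_scale_equivariance_on_data(self):
        """Multiplying member columns by c scales sd_in and I by c and
        leaves both correlation means unchanged."""
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 6))
        names = tuple("ABCDEF")
        base = module_stats(ExpressionMatrix(X, names), ("A", "B", "C"))
        c = 3.7
        Y = X.copy()
        Y[:, :3] *= c
        scaled = module_stats(ExpressionMatrix(Y, names), ("A", "B", "C"))
        assert scaled.sd_in == pytest.approx(c * base.sd_in, rel=1e-10)
        assert scaled.pcc_in == pytest.approx(base.pcc_in, abs=1e-10)
        assert scaled.pcc_out == pytest.approx(base.pcc_out, abs=1e-10)
        assert scaled.index == pytest.approx(c * base.index, rel=1e-8)

    def test_affine_invariance_of_correlations(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(200, 5))
        names = tuple("ABCDE")
        base = module_stats(ExpressionMatrix(X, names), ("A", "B"))
        Y = X.copy()
        Y[:, 0] += 17.0
        shifted = module_stats(ExpressionMatrix(Y, names), ("A", "B"))
        assert abs(shifted.sd_in - base.sd_in) < 1e-10
        assert abs(shifted.pcc_in - base.pcc_in) < 1e-10
        assert abs(shifted.pcc_out - base.pcc_out) < 1e-10


class TestCandidateModules:
    def test_planted_perfect_triple_appears(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=300)
        X = np.column_stack([x, x, x] + [rng.normal(size=300)
                                         for _ in range(3)])
        names = ("t1", "t2", "t3", "b1", "b2", "b3")
        cands = candidate_modules(ExpressionMatrix(X, names))
        assert ("t1", "t2", "t3") in cands

    def test_all_constant_panel_warns_and_returns_empty(self):
        m = ExpressionMatrix(np.full((100, 5), 2.0), tuple("ABCDE"))
        with pytest.warns(UserWarning):
            assert candidate_modules(m) == []

    def test_order_deterministic_by_size_then_name(self, planted_sample):
        cands = candidate_modules(planted_sample.matrices[2.0])
        assert cands == sorted(cands, key=lambda mod: (len(mod), mod))
        assert len(set(cands)) == len(cands)
        # sizes respect the >= 2 non-member bound
        assert all(2 <= len(c) <= 23 for c in cands)


class TestRankModules:
    def test_planted_module_is_rank_one(self, planted_sample, default_params):
        res = rank_modules(planted_sample)
        assert res.best_module.members == default_params.module_marker_names
        assert res.best_module.peak_time == default_params.transition_time

    def test_time_constant_sample_degenerates_deterministically(
            self, planted_sample):
        """Identical matrices at all timepoints: every surge is exactly 1
        and ranking falls through to the documented tie-breakers."""
        m0 = planted_sample.matrices[0.0]
        frozen = type(planted_sample)(
            patient_id="F", group="HC",
            matrices={t: m0 for t in planted_sample.timepoints},
        )
        res1 = rank_modules(frozen)
        res2 = rank_modules(frozen)
        assert all(rm.fold_change == pytest.approx(1.0, abs=1e-12)
                   for rm in res1.ranked_modules)
        peaks = [rm.peak_index for rm in res1.ranked_modules]
        assert peaks == sorted(peaks, reverse=True)
        assert [rm.members for rm in res1.ranked_modules] == \
               [rm.members for rm in res2.ranked_modules]

    def test_null_sample_surges_far_less_than_planted(self, planted_sample):
        """Paired comparison: the planted scenario's best surge dwarfs the
        null scenario's (factor >= 5 here)."""
        flat = (0.05,) * 5
        null_params = SimulationParams(
            rho_in=flat, rho_out=flat, sigma_in=(1.0,) * 5, seed=7,
        )
        null_sample = simulate_sample(null_params, "N")
        planted_fc = rank_modules(planted_sample).best_module.fold_change
        null_fc = rank_modules(null_sample).best_module.fold_change
        assert planted_fc > 5 * null_fc


class TestTopMarkers:
    def test_exactly_k_unique_markers_led_by_best_module(
            self, planted_sample, default_params):
        res = rank_modules(planted_sample, k=5)
        assert len(res.top_markers) == 5
        assert len(set(res.top_markers)) == 5
        best = set(res.best_module.members)
        assert set(res.top_markers[:len(best)]) == best

    def test_small_best_module_extended_from_next_ranked(self, small_params):
        """A best module smaller than k borrows members from the
        next-ranked modules in order."""
        sample = simulate_sample(small_params, "S")
        res = rank_modules(sample, k=5)
        assert len(res.top_markers) == 5
        assert len(set(res.top_markers)) == 5

    def test_truncation(self, planted_sample):
        res = rank_modules(planted_sample, k=5)
        assert top_markers(res, k=1) == res.top_markers[:1]

    def test_panel_smaller_than_k_returns_all_with_warning(self):
        from dnbpipe import TimeCourseSample

        rng = np.random.default_rng(8)
        mats = {
            t: ExpressionMatrix(rng.normal(size=(100, 4)), tuple("ABCD"))
            for t in (0.0, 0.5, 1.0, 2.0, 4.0)
        }
        sample = TimeCourseSample("P", "HC", mats)
        with pytest.warns(UserWarning):
            res = rank_modules(sample, k=5)
        assert set(res.top_markers) == set("ABCD")


def test_pipeline_equals_exhaustive_search_on_small_panel(small_params):
    """On an 8-marker panel the clustering-based search must find the same
    best module as scoring every subset under the identical ranking key."""
    sample = simulate_sample(small_params, "S", amplitude=1.0)
    assert rank_modules(sample).best_module.members == \
        exhaustive_best_module(sample).members
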