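"""Matched subsets, re-scaling, concatenation and the grid search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import screscale as s
from screscale import (
    RunConfig,
    baseline_integrate,
    build_matched_subsets,
    concatenate,
    rescale,
    subset_sd,
)
from screscale.datatypes import AlignmentMap, Clustering, ScaledMatrix
from screscale.integration import safe_factors


def _clustering(labels):
    return Clustering(np.asarray(labels), 1.0)


class TestBuildMatchedSubsets:
    def test_equal_sizes_keep_everything(self):
        am = AlignmentMap(pairs=[(0, 0)])
        cl_a = _clustering([0] * 10)
        cl_q = _clustering([0] * 10)
        idx_a, idx_q = build_matched_subsets(am, cl_a, cl_q, seed=0)
        assert len(idx_a) == len(idx_q) == 10

    def test_compositions_match_across_sides(self):
        am = AlignmentMap(pairs=[(0, 0), (1, 1)])
        cl_a = _clustering([0] * 100 + [1] * 30)
        cl_q = _clustering([0] * 20 + [1] * 60)
        idx_a, idx_q = build_matched_subsets(am, cl_a, cl_q, seed=0)
        assert len(idx_a) == len(idx_q) == 20 + 30
        la, lq = cl_a.labels[idx_a], cl_q.labels[idx_q]
        assert np.sum(la == 0) == np.sum(lq == 0) == 20
        assert np.sum(la == 1) == np.sum(lq == 1) == 30

    def test_empty_alignment_raises(self):
        with pytest.raises(ValueError, match="baseline"):
            build_matched_subsets(AlignmentMap(pairs=[]),
                                  _clustering([0]), _clustering([0]), seed=0)

    def test_merged_anchor_group_pooled(self):
        am = AlignmentMap(pairs=[(0, 0), (1, 0)],
                          merged_anchor_groups=[[0, 1]])
        cl_a = _clustering([0] * 30 + [1] * 30)
        cl_q = _clustering([0] * 40)
        idx_a, idx_q = build_matched_subsets(am, cl_a, cl_q, seed=0)
        assert len(idx_a) == len(idx_q) == 40


class TestSubsetSdRescale:
    def test_full_index_sd_is_one(self, gaussian_scaled):
        sd = subset_sd(gaussian_scaled, np.arange(gaussian_scaled.n_cells))
        nonconst = gaussian_scaled.values.std(axis=1) > 0
        assert np.allclose(sd[nonconst], 1.0, atol=1e-8)

    def test_two_cell_subset_hand_computed(self):
        sm = ScaledMatrix(np.array([[0.0, 2.0, 5.0]]), ["g"],
                          ["a", "b", "c"])
        assert subset_sd(sm, [0, 1])[0] == pytest.approx(np.sqrt(2.0))

    def test_singleton_subset_raises(self, gaussian_scaled):
        with pytest.raises(ValueError):
            subset_sd(gaussian_scaled, [0])

    def test_rescale_identity_for_unit_factors(self, gaussian_scaled):
        out = rescale(gaussian_scaled, np.ones(gaussian_scaled.n_genes))
        assert np.array_equal(out.values, gaussian_scaled.values)

    def test_rescale_divides(self):
        sm = ScaledMatrix(np.array([[-1.0, 1.0]]), ["g"], ["a", "b"])
        out = rescale(sm, np.array([2.0]))
        assert np.allclose(out.values, [[-0.5, 0.5]])

    def test_rescale_length_mismatch_raises(self, gaussian_scaled):
        with pytest.raises(ValueError):
            rescale(gaussian_scaled, np.ones(3))

    def test_zero_factor_replaced_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = safe_factors(np.array([0.0, 2.0]))
        assert np.array_equal(out, [1.0, 2.0])

    @settings(deadline=None, max_examples=100)
    @given(st.integers(0, 2**31 - 1))
    def test_rescale_self_consistency(self, seed):
        """rescale by a subset's sd makes that subset unit-variance again."""
        rng = np.random.default_rng(seed)
        genes = int(rng.integers(2, 20))
        cells = int(rng.integers(4, 30))
        values = rng.normal(size=(genes, cells)) * rng.uniform(0.2, 5, (genes, 1))
        sm = ScaledMatrix(values, [f"g{i}" for i in range(genes)],
                          [f"c{j}" for j in range(cells)])
        k = int(rng.integers(2, cells + 1))
        idx = rng.choice(cells, size=k, replace=False)
        out = rescale(sm, safe_factors(subset_sd(sm, idx)))
        sd = out.values[:, np.sort(idx)].std(axis=1, ddof=1)
        varying = subset_sd(sm, idx) > 0
        assert np.allclose(sd[varying], 1.0, atol=1e-8)


class TestConcatenate:
    def test_shapes_and_batches(self, gaussian_scaled):
        other = ScaledMatrix(gaussian_scaled.values[:, :10].copy(),
                             gaussian_scaled.gene_ids,
                             [f"o{j}" for j in range(10)], platform="q")
        merged, batch = concatenate(gaussian_scaled, other)
        assert merged.values.shape == (gaussian_scaled.n_genes,
                                       gaussian_scaled.n_cells + 10)
        assert list(np.unique(batch)) == sorted({gaussian_scaled.platform
                                                 or "batch0", "q"})

    def test_gene_order_mismatch_raises(self, gaussian_scaled):
        other = ScaledMatrix(gaussian_scaled.values.copy(),
                             gaussian_scaled.gene_ids[::-1].copy(),
                             gaussian_scaled.cell_ids.copy())
        with pytest.raises(ValueError, match="gene"):
            concatenate(gaussian_scaled, other)

    def test_self_concatenation_doubles_cells(self, gaussian_scaled):
        merged, _ = concatenate(gaussian_scaled, gaussian_scaled)
        assert merged.n_cells == 2 * gaussian_scaled.n_cells
        assert len(set(merged.cell_ids.astype(str))) == merged.n_cells


class TestBaseline:
    def test_identical_datasets_mix_well(self, rng):
        cfg = s.scenario("equal_composition", n_cells=(200, 200), n_genes=300)
        datasets, _ = s.simulate_pair(cfg)
        sm = s.scale_genes(s.lognormalize(datasets[0]))
        sm2 = ScaledMatrix(sm.values.copy(), sm.gene_ids,
                           [f"dup_{c}" for c in sm.cell_ids], platform="dup")
        res = baseline_integrate(sm, sm2, RunConfig(mixing_k_max=60))
        assert res.baseline_used and res.factors is None
        # identical interleaved copies: close to the theoretical optimum
        assert res.mixing_score < 12

    def test_symmetry_up_to_order(self, gaussian_scaled):
        other = ScaledMatrix(gaussian_scaled.values + 0.5,
                             gaussian_scaled.gene_ids,
                             [f"o{j}" for j in range(gaussian_scaled.n_cells)],
                             platform="q")
        cfg = RunConfig(n_pcs=5, mixing_k_max=20)
        r1 = baseline_integrate(gaussian_scaled, other, cfg)
        r2 = baseline_integrate(other, gaussian_scaled, cfg)
        assert r1.mixing_score == pytest.approx(r2.mixing_score, abs=1e-6)


@pytest.fixture(scope="module")
def small_pair_result():
    cfg = s.scenario("skewed_composition", n_cells=(350, 350), n_genes=400)
    datasets, truth = s.simulate_pair(cfg)
    rc = RunConfig(resolution_step=0.6, mixing_k_max=120)
    res = s.integrate_pair(datasets[0], datasets[1], rc)
    return datasets, truth, rc, res


class TestIntegratePair:
    def test_mixing_score_is_min_of_trace_and_baseline(self, small_pair_result):
        _, _, rc, res = small_pair_result
        finite = [t["mixing"] for t in res.search_trace
                  if np.isfinite(t["mixing"])]
        if res.baseline_used:
            assert all(res.mixing_score <= m + 1e-12 for m in finite)
        else:
            assert res.mixing_score == pytest.approx(min(finite))

    def test_anchor_is_first_on_ties_larger_otherwise(self, small_pair_result):
        datasets, _, _, res = small_pair_result
        assert res.anchor_name in ("plate", "droplet")

    def test_deterministic_rerun(self, small_pair_result):
        datasets, _, rc, res = small_pair_result
        res2 = s.integrate_pair(datasets[0], datasets[1], rc)
        assert res2.chosen_resolutions == res.chosen_resolutions
        assert res2.search_trace == res.search_trace
        assert np.array_equal(res2.integrated.values, res.integrated.values)

    def test_rescaling_preserves_within_dataset_rank_structure(
            self, small_pair_result):
        """Per-gene monotone scaling leaves every gene's cell ranking — hence
        any rank-based within-dataset structure — exactly unchanged."""
        from scipy.stats import rankdata
        datasets, _, rc, res = small_pair_result
        if res.factors is None:
            pytest.skip("baseline chosen; nothing to compare")
        sm = s.scale_genes(s.lognormalize(datasets[0]))
        sm = sm.restrict_genes(res.integrated.gene_ids)
        ids = res.integrated.cell_ids.astype(str)
        col_of = {c: j for j, c in enumerate(ids)}
        take = [col_of[c] for c in sm.cell_ids.astype(str)[:40]]
        before = rankdata(sm.values[:, :40], axis=1)
        after = rankdata(res.integrated.values[:, take], axis=1)
        assert np.array_equal(before, after)

    def test_disjoint_types_fall_back_to_baseline(self):
        cfg = s.scenario("disjoint_types", n_cells=(300, 300), n_genes=400)
        datasets, _ = s.simulate_pair(cfg)
        rc = RunConfig(resolution_step=0.95, mixing_k_max=120)
        res = s.integrate_pair(datasets[0], datasets[1], rc)
        assert res.baseline_used
        assert res.factors is None
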