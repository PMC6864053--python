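"""Contrast tensors, slab permutation, fixed-factor refit, permutation test."""

import numpy as np
import pytest

from tmstensor.cpd import DecomposeConfig, Tensor5D, nncp_als, normalize_model
from tmstensor.inference import (
    ContrastModel,
    build_model_tensor,
    master_decomposition,
    permutation_test,
    permute_tensor,
    project_loadings,
    refit_loadings,
    standard_model,
)
from tmstensor.synthdata import SimConfig, make_ground_truth, synth_tensor5d
from tmstensor.tfr import TFRTensor


@pytest.fixture(scope="module")
def tiny_tensor():
    cfg = SimConfig(n_channels=8, n_freqs=6, n_times=10, n_subjects=6,
                    n_conditions=4, seed=21, noise_level=0.05)
    return synth_tensor5d(make_ground_truth(cfg), cfg)


@pytest.fixture(scope="module")
def tiny_master(tiny_tensor):
    return master_decomposition(
        tiny_tensor, DecomposeConfig(rank=3, seed=21, n_restarts=2, tol=1e-9)
    )


class TestContrastModels:
    @pytest.mark.parametrize("model_id,expected_labels", [
        (1, ("pre-placebo", "post-placebo", "pre-LEV", "pre-LTG")),
        (2, ("pre-LEV", "post-LEV", "pre-LTG", "post-LTG")),
        (3, ("pre-placebo", "post-placebo", "pre-LEV", "post-LEV")),
        (4, ("pre-placebo", "post-placebo", "pre-LTG", "post-LTG")),
    ])
    def test_standard_condition_sets(self, model_id, expected_labels):
        m = standard_model(model_id)
        assert m.condition_labels == expected_labels
        assert all(post in expected_labels and pre in expected_labels
                   for post, pre in m.contrasts)

    def test_model2_carries_between_drug_contrast(self):
        m = standard_model(2)
        assert m.between is not None
        assert "(post-LEV - pre-LEV) - (post-LTG - pre-LTG)" in m.contrast_names

    def test_invalid_contrast_labels_rejected(self):
        with pytest.raises(ValueError, match="unknown labels"):
            ContrastModel(1, ("a", "b", "c", "d"), (("a", "z"),))


class TestBuildModelTensor:
    def _store(self, n_subjects, labels, shape=(3, 4, 5), seed=0):
        rng = np.random.default_rng(seed)
        store = {}
        for s in range(n_subjects):
            for c in labels:
                store[(f"S{s:02d}", c)] = TFRTensor(
                    values=rng.normal(size=shape),
                    ch_names=[f"ch{i}" for i in range(shape[0])],
                    freqs=np.arange(shape[1], dtype=float),
                    times=np.arange(shape[2], dtype=float),
                )
        return store

    def test_stacking_arithmetic(self):
        contrast = standard_model(2)
        store = self._store(2, contrast.condition_labels)
        t = build_model_tensor(store, contrast)
        assert t.values.shape == (3, 4, 5, 2, 4)
        assert t.condition_labels == list(contrast.condition_labels)

    def test_values_land_under_their_labels(self):
        contrast = standard_model(2)
        store = self._store(2, contrast.condition_labels)
        t = build_model_tensor(store, contrast)
        for si, s in enumerate(t.subjects):
            for ci, c in enumerate(t.condition_labels):
                np.testing.assert_array_equal(
                    t.values[:, :, :, si, ci], store[(s, c)].values
                )
        # subject insertion order does not change the label->value mapping
        reordered = dict(reversed(list(store.items())))
        t2 = build_model_tensor(reordered, contrast)
        np.testing.assert_array_equal(t.values, t2.values)
        assert t.subjects == t2.subjects

    def test_missing_cell_and_axis_mismatch_raise(self):
        contrast = standard_model(2)
        store = self._store(2, contrast.condition_labels)
        del store[("S01", "post-LTG")]
        with pytest.raises(ValueError, match="S01.*post-LTG"):
            build_model_tensor(store, contrast)
        store = self._store(2, contrast.condition_labels)
        bad = store[("S01", "post-LTG")]
        store[("S01", "post-LTG")] = TFRTensor(
            values=bad.values[:, :, :-1], ch_names=bad.ch_names,
            freqs=bad.freqs, times=bad.times[:-1],
        )
        with pytest.raises(ValueError, match="axis mismatch"):
            build_model_tensor(store, contrast)


class TestPermuteTensor:
    def test_identity_permutation_is_a_no_op(self, tiny_tensor):
        S, C = tiny_tensor.values.shape[3:]
        out = permute_tensor(tiny_tensor, np.random.default_rng(0),
                             perm=np.arange(S * C))
        np.testing.assert_array_equal(out.values, tiny_tensor.values)

    def test_slab_norm_multiset_preserved(self, tiny_tensor):
        rng = np.random.default_rng(5)
        out = permute_tensor(tiny_tensor, rng)
        norms_in = np.sort(np.linalg.norm(
            tiny_tensor.values.reshape(-1, np.prod(tiny_tensor.values.shape[3:])), axis=0))
        norms_out = np.sort(np.linalg.norm(
            out.values.reshape(-1, np.prod(out.values.shape[3:])), axis=0))
        np.testing.assert_allclose(norms_in, norms_out, atol=1e-12)

    def test_uniformity_of_slab_positions(self):
        """Each slab lands in each position with frequency 1/(S·C) over many
        draws (tolerance: 5 sigma of the exact binomial)."""
        S, C = 3, 2
        values = np.arange(S * C, dtype=float).reshape(1, 1, 1, S, C)
        t = Tensor5D(values=values, channels=["a"], freqs=np.zeros(1),
                     times=np.zeros(1), subjects=list("xyz"),
                     condition_labels=["c1", "c2"])
        rng = np.random.default_rng(77)
        n_draws = 10_000
        counts = np.zeros((S * C, S * C))
        for _ in range(n_draws):
            out = permute_tensor(t, rng)
            flat = out.values.reshape(-1).astype(int)
            for pos, slab in enumerate(flat):
                counts[slab, pos] += 1
        p = 1.0 / (S * C)
        sigma = np.sqrt(n_draws * p * (1 - p))
        assert np.all(np.abs(counts - n_draws * p) < 5 * sigma)

    def test_within_subject_scheme_keeps_subject_rows(self, tiny_tensor):
        rng = np.random.default_rng(3)
        out = permute_tensor(tiny_tensor, rng, scheme="within_subject")
        for s in range(tiny_tensor.values.shape[3]):
            in_slabs = {tiny_tensor.values[..., s, c].tobytes()
                        for c in range(tiny_tensor.values.shape[4])}
            out_slabs = {out.values[..., s, c].tobytes()
                         for c in range(out.values.shape[4])}
            assert in_slabs == out_slabs


class TestRefitLoadings:
    def test_unpermuted_refit_is_a_fixed_point(self, tiny_tensor, tiny_master):
        refit = refit_loadings(tiny_tensor, tiny_master)
        np.testing.assert_allclose(
            refit.factors[4], tiny_master.factors[4], rtol=1e-6, atol=1e-9
        )

    def test_frozen_modes_bit_identical(self, tiny_tensor, tiny_master):
        permuted = permute_tensor(tiny_tensor, np.random.default_rng(1))
        refit = refit_loadings(permuted, tiny_master)
        for m in range(3):
            assert refit.factors[m] is tiny_master.factors[m]

    def test_projection_shortcut_equals_naive_full_tensor_refit(
        self, tiny_tensor, tiny_master
    ):
        """Oracle: the G-projection refit must match an independent refit
        that runs full-tensor fixed-mode ALS on the permuted array."""
        permuted = permute_tensor(tiny_tensor, np.random.default_rng(2))
        fast = refit_loadings(permuted, tiny_master, max_sweeps=60, tol=1e-10)
        naive = nncp_als(
            permuted,
            DecomposeConfig(
                rank=3, fixed_modes=(0, 1, 2),
                init_factors=[np.array(f) for f in tiny_master.factors],
                max_iterations=60, tol=1e-10, seed=0,
            ),
        )
        naive = normalize_model(naive, strict=False)
        scale = np.abs(naive.factors[4]).max()
        np.testing.assert_allclose(fast.factors[4], naive.factors[4],
                                   atol=1e-8 * scale)
        np.testing.assert_allclose(fast.factors[3], naive.factors[3], atol=1e-8)


class TestPermutationTest:
    def test_reproducible_and_consistent(self, tiny_tensor, tiny_master):
        contrast = standard_model(2)
        a = permutation_test(tiny_tensor, tiny_master, contrast, n_perm=60, seed=4)
        b = permutation_test(tiny_tensor, tiny_master, contrast, n_perm=60, seed=4)
        np.testing.assert_array_equal(a.null, b.null)
        assert a.null.shape == (60, 3, 3)  # two pre/post contrasts + between
        assert np.all(a.pvalues >= 1.0 / 61.0)
        assert np.all(a.pvalues <= 1.0)

    def test_decision_matches_quantile_rule(self, tiny_tensor, tiny_master):
        contrast = standard_model(2)
        res = permutation_test(tiny_tensor, tiny_master, contrast, n_perm=80,
                               seed=9, scheme="within_subject")
        expected = (res.observed < res.quantiles[0]) | (res.observed > res.quantiles[1])
        np.testing.assert_array_equal(res.decisions, expected)

    def test_observed_at_null_median_is_not_significant(self, tiny_master):
        """If the observed difference sits at the centre of its null the
        add-one p-value is ~1 and the decision negative."""
        rng = np.random.default_rng(0)
        null = rng.normal(0, 1, 200)
        observed = np.median(null)
        p = (1 + np.sum(np.abs(null) >= abs(observed))) / (len(null) + 1)
        assert p > 0.4
        q = np.quantile(null, [0.025, 0.975])
        assert q[0] < observed < q[1]

    def test_small_n_perm_warns(self, tiny_tensor, tiny_master):
        with pytest.warns(UserWarning, match="2.5%"):
            permutation_test(tiny_tensor, tiny_master, standard_model(2),
                             n_perm=10, seed=0)

    def test_label_mismatch_rejected(self, tiny_tensor, tiny_master):
        with pytest.raises(ValueError, match="condition axis"):
            permutation_test(tiny_tensor, tiny_master, standard_model(3),
                             n_perm=50, seed=0)
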