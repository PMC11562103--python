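"""Planted-module generator: determinism, calibration, ground-truth contracts."""

import numpy as np
import pytest
from scipy import stats

from gtomnet import (
    ModuleSpec,
    SyntheticSpec,
    correlation_matrix,
    default_spec,
    generate_lowrank_noiseless,
    generate_planted_expression,
)


def small_spec(seed=0, **overrides) -> SyntheticSpec:
    layout = [
        ModuleSpec("c1", 40, "core"),
        ModuleSpec("b1", 25, "bridge", attached_core="c1"),
        ModuleSpec("c2", 20, "core"),
        ModuleSpec("iso", 15, "isolated"),
    ]
    kwargs = dict(
        n_tfs=100,
        n_samples_major=40,
        n_samples_minor=10,
        module_layout=layout,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)


class TestSpecValidation:
    def test_size_mismatch_rejected(self):
        spec = small_spec()
        spec.n_tfs = 99
        with pytest.raises(ValueError, match="sum"):
            generate_planted_expression(spec)

    def test_bridge_needs_existing_core(self):
        layout = [ModuleSpec("b", 10, "bridge", attached_core="nope"),
                  ModuleSpec("c", 10, "core")]
        spec = small_spec()
        spec.module_layout = layout
        spec.n_tfs = 20
        with pytest.raises(ValueError, match="attached_core"):
            spec.validate()

    def test_core_must_exceed_bridge_correlation(self):
        spec = small_spec(within_module_corr={"core": 0.5, "bridge": 0.8, "isolated": 0.2},
                          bridge_to_core_corr=0.3)
        with pytest.raises(ValueError, match="core must exceed"):
            spec.validate()

    def test_unknown_differential_module_rejected(self):
        spec = small_spec(differential_modules=frozenset({"ghost"}))
        with pytest.raises(ValueError, match="ghost"):
            spec.validate()


class TestGeneration:
    def test_bit_reproducible_given_seed(self):
        x1, t1 = generate_planted_expression(small_spec(seed=7))
        x2, t2 = generate_planted_expression(small_spec(seed=7))
        np.testing.assert_array_equal(x1.values, x2.values)
        assert t1.tf_module_labels == t2.tf_module_labels
        x3, _ = generate_planted_expression(small_spec(seed=8))
        assert not np.array_equal(x1.values, x3.values)

    def test_values_non_negative_and_labels_cover_everything(self):
        x, truth = generate_planted_expression(small_spec())
        assert x.values.min() >= 0.0
        assert len(truth.tf_module_labels) == x.n_genes
        assert len(truth.patient_group_labels) == x.n_samples
        assert set(truth.tf_module_labels) == {"c1", "b1", "c2", "iso"}
        assert truth.patient_group_labels.count("4") == 40
        assert truth.patient_group_labels.count("4S") == 10

    def test_single_noiseless_common_factor_gives_perfect_correlation(self):
        spec = SyntheticSpec(
            n_tfs=30,
            n_samples_major=15,
            n_samples_minor=5,
            module_layout=[ModuleSpec("only", 30, "core")],
            within_module_corr={"core": 1.0, "bridge": 0.5, "isolated": 0.2},
            bridge_to_core_corr=0.3,
            n_subfactors={"core": 1, "bridge": 1, "isolated": 1},
            noise_sd=0.0,
            seed=3,
        )
        x, _ = generate_planted_expression(spec)
        corr = correlation_matrix(x).values
        assert np.min(np.abs(corr)) > 1.0 - 1e-10

    def test_within_module_correlation_matches_factor_model_closed_form(self):
        # one-factor module with w = 0.8 and no measurement noise: the
        # factor-model closed form gives r = w / (1 + noise_sd^2) = 0.8
        vals = []
        for seed in range(20):
            spec = SyntheticSpec(
                n_tfs=60,
                n_samples_major=125,
                n_samples_minor=25,
                module_layout=[ModuleSpec("m", 60, "core")],
                within_module_corr={"core": 0.8, "bridge": 0.5, "isolated": 0.2},
                bridge_to_core_corr=0.3,
                n_subfactors={"core": 1, "bridge": 1, "isolated": 1},
                noise_sd=0.0,
                seed=seed,
            )
            x, _ = generate_planted_expression(spec)
            c = correlation_matrix(x).values
            off = c[np.triu_indices(60, 1)]
            vals.append(off.mean())
        assert np.mean(vals) == pytest.approx(0.8, abs=0.05)

    def test_within_module_exceeds_between_module_correlation(self):
        within, between = [], []
        for seed in range(20):
            x, truth = generate_planted_expression(small_spec(seed=seed, n_samples_major=125,
                                                              n_samples_minor=25))
            lab = np.array(truth.tf_module_labels)
            c = correlation_matrix(x).values
            for mod in ("c1", "c2"):
                i = np.flatnonzero(lab == mod)
                block = c[np.ix_(i, i)]
                within.append((block.sum() - len(i)) / (len(i) * (len(i) - 1)))
            i, j = np.flatnonzero(lab == "c1"), np.flatnonzero(lab == "c2")
            between.append(c[np.ix_(i, j)].mean())
        assert np.mean(within) > np.mean(between)

    def test_group_difference_only_in_differential_modules(self):
        # t-test p-values of non-differential genes are null (uniform by KS);
        # the differential module carries real shifts
        spec = small_spec(seed=1, n_samples_major=100, n_samples_minor=25,
                          differential_modules=frozenset({"c1"}), effect_size=1.5)
        x, truth = generate_planted_expression(spec)
        lab = np.array(truth.tf_module_labels)
        grp = np.array(truth.patient_group_labels)
        a, b = x.values[:, grp == "4"], x.values[:, grp == "4S"]
        _, pvals = stats.ttest_ind(a, b, axis=1, equal_var=False)
        null_p = pvals[(lab != "c1") & (lab != "b1")]  # bridge couples to c1
        assert stats.kstest(null_p, "uniform").pvalue > 0.05
        diff_p = pvals[lab == "c1"]
        assert np.median(diff_p) < np.median(null_p)

    def test_decoys_are_low_expression_and_low_amplitude(self):
        spec = small_spec(seed=2, n_decoys=10)
        x, truth = generate_planted_expression(spec)
        lab = np.array(truth.tf_module_labels)
        iso = np.flatnonzero(lab == "iso")
        decoys, plain = iso[:10], iso[10:]
        med = np.median(x.values, axis=1)
        assert med[decoys].mean() < med[plain].mean() - 1.0
        assert x.values[decoys].std(axis=1).max() < x.values[plain].std(axis=1).min()

    def test_default_spec_matches_study_conditions(self):
        spec = default_spec(seed=0)
        assert spec.n_tfs == 1500
        assert spec.n_samples_major == 127 and spec.n_samples_minor == 21
        roles = [m.role for m in spec.module_layout]
        assert roles.count("core") == 2 and roles.count("bridge") == 2
        assert roles.count("isolated") == 1
        spec.validate()
        # the noise-stress variant keeps measurement noise exactly isotropic
        assert default_spec(noise_sd=0.5).n_decoys == 0


class TestLowRankFixture:
    def test_two_gene_rank_one_rows_affinely_dependent(self):
        x = generate_lowrank_noiseless(d=2, n=3, rank=1, seed=0)
        centered = x.values - x.values.mean(axis=1, keepdims=True)
        sv = np.linalg.svd(centered, compute_uv=False)
        assert sv[1] < 1e-10 * sv[0]

    def test_covariance_has_exactly_requested_rank(self):
        x = generate_lowrank_noiseless(d=10, n=8, rank=3, seed=4)
        centered = x.values - x.values.mean(axis=1, keepdims=True)
        lam = np.linalg.eigvalsh(centered @ centered.T / 7)[::-1]
        assert np.all(lam[:3] > 1e-10 * lam[0])
        assert np.all(np.abs(lam[3:]) < 1e-10 * lam[0])

    @pytest.mark.parametrize("rank", [0, 8, -1])
    def test_invalid_rank_rejected(self, rank):
        with pytest.raises(ValueError):
            generate_lowrank_noiseless(d=10, n=8, rank=rank, seed=0)
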