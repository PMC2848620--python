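import numpy as np
import pytest

from genesync import (
    AnalysisConfig,
    ValidationError,
    bh_fdr,
    bootstrap_diff_pvalues,
    classify_gain_loss,
    run_differential_pipeline,
    select_high_synchrony_genes,
)
from genesync.simulate import RhoDistribution, SimConfig, generate_paired_cohort


def brute_force_bh(p, q):
    """Literal step-up definition, independent of the implementation path."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    reject = np.zeros(m, dtype=bool)
    below = np.flatnonzero(p[order] <= (np.arange(1, m + 1) * q / m))
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return adj, reject


class TestSelection:
    @pytest.mark.parametrize(
        "rc, rk, selected",
        [
            (0.8, 0.1, True),
            (0.5, 0.6, False),
            (-0.75, 0.0, True),  # absolute-value rule: negative synchrony counts
        ],
    )
    def test_cutoff_rule(self, rc, rk, selected):
        sel = select_high_synchrony_genes(np.array([rc]), np.array([rk]), 0.7)
        assert (0 in sel) == selected

    def test_nan_only_genes_never_selected(self):
        sel = select_high_synchrony_genes(
            np.array([np.nan, np.nan]), np.array([np.nan, 0.9]), 0.7
        )
        assert list(sel) == [1]


class TestBHFDR:
    def test_hand_computed_step_up(self):
        # p_(i) <= i*0.05/5 for all i, so the full set is significant
        q, sig = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05)
        assert sig.all()
        np.testing.assert_allclose(q, 0.05)

    def test_single_pvalue(self):
        q, sig = bh_fdr(np.array([0.04]), 0.05)
        assert sig[0]
        assert q[0] == pytest.approx(0.04)

    def test_empty_input(self):
        q, sig = bh_fdr(np.array([]), 0.05)
        assert q.size == 0 and sig.size == 0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr(np.array([0.5, 1.5]), 0.05)

    def test_agrees_with_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            q_level = rng.uniform(0.01, 0.4)
            q1, sig1 = bh_fdr(p, q_level)
            q2, sig2 = brute_force_bh(p, q_level)
            np.testing.assert_allclose(q1, q2, atol=1e-12)
            np.testing.assert_array_equal(sig1, sig2)


class TestClassification:
    @pytest.mark.parametrize(
        "rc, rk, label",
        [
            (0.85, 0.05, "loss"),  # high in controls, lost in cases
            (0.1, 0.8, "gain"),  # acquired in cases
            (0.75, 0.5, "not_classified"),  # fails the low threshold
            (-0.85, 0.05, "loss"),  # magnitude rule for negative synchrony
        ],
    )
    def test_threshold_bands(self, rc, rk, label):
        out = classify_gain_loss(
            np.array([rc]), np.array([rk]), np.array([True]), high=0.7, low=0.2
        )
        assert out[0] == label

    def test_non_significant_never_labeled(self):
        out = classify_gain_loss(
            np.array([0.9]), np.array([0.0]), np.array([False])
        )
        assert out[0] == "not_classified"


@pytest.fixture(scope="module")
def null_groups():
    """Two groups simulated from identical rho = 0.5 (no true shift)."""
    cfg = SimConfig(
        n_genes=1200,
        n_subjects_per_group=14,
        rho_distribution=RhoDistribution(family="constant", value=0.5),
        rng_seed=0,
    )
    datasets, _ = generate_paired_cohort(cfg)
    return datasets["control"], datasets["mdd"]


@pytest.fixture(scope="module")
def shifted_groups():
    """200 gain genes (rho 0 -> 0.9) among intrinsic rho = 0.5 genes."""
    cfg = SimConfig(
        n_genes=400,
        n_subjects_per_group=14,
        n_gain_genes=200,
        gain_rho=(0.0, 0.9),
        rho_distribution=RhoDistribution(family="constant", value=0.5),
        rng_seed=1,
    )
    return generate_paired_cohort(cfg)


class TestBootstrapDiffPvalues:
    def test_seeded_determinism(self, null_groups):
        ctrl, case = null_groups
        genes = np.arange(30)
        cfg = AnalysisConfig(n_bootstrap=200, rng_seed=5)
        p1 = bootstrap_diff_pvalues(ctrl, case, genes, cfg)
        p2 = bootstrap_diff_pvalues(ctrl, case, genes, cfg)
        np.testing.assert_array_equal(p1, p2)

    def test_null_rejection_rate_near_nominal(self, null_groups):
        """No true shift: ~5-7% of genes fall below 0.05 (the percentile
        bootstrap runs slightly hot at n = 14)."""
        ctrl, case = null_groups
        cfg = AnalysisConfig(n_bootstrap=1000, rng_seed=0)
        p = bootstrap_diff_pvalues(ctrl, case, np.arange(ctrl.n_genes), cfg)
        assert np.mean(p < 0.05) == pytest.approx(0.05, abs=0.03)
        assert (p >= 1.0 / (cfg.n_bootstrap + 1)).all()

    def test_gain_genes_detected_with_high_power(self, shifted_groups):
        datasets, truth = shifted_groups
        gain = truth.genes_of_class("gain")
        cfg = AnalysisConfig(n_bootstrap=2000, rng_seed=1)
        p = bootstrap_diff_pvalues(datasets["control"], datasets["mdd"], gain, cfg)
        assert np.mean(p < 0.05) >= 0.8

    def test_invariant_to_gene_and_subject_order(self, null_groups):
        ctrl, case = null_groups
        cfg = AnalysisConfig(n_bootstrap=200, rng_seed=7)
        genes = np.arange(20)
        p = bootstrap_diff_pvalues(ctrl, case, genes, cfg)
        # permute the gene subset
        perm = np.random.default_rng(2).permutation(20)
        p_perm = bootstrap_diff_pvalues(ctrl, case, genes[perm], cfg)
        np.testing.assert_array_equal(p_perm, p[perm])
        # permute subject columns of one input
        shuf = np.random.default_rng(3).permutation(ctrl.subject_ids)
        p_shuf = bootstrap_diff_pvalues(
            ctrl.subset_subjects(shuf), case, genes, cfg
        )
        np.testing.assert_array_equal(p_shuf, p)

    def test_same_object_both_groups_gives_p_one(self, null_groups):
        ctrl, _ = null_groups
        cfg = AnalysisConfig(n_bootstrap=200, rng_seed=9)
        p = bootstrap_diff_pvalues(ctrl, ctrl, np.arange(10), cfg)
        np.testing.assert_allclose(p, 1.0)


class TestPipeline:
    def test_label_swap_symmetry_is_exact(self, shifted_groups):
        datasets, _ = shifted_groups
        cfg = AnalysisConfig(n_bootstrap=500, rng_seed=2)
        fwd = run_differential_pipeline(datasets["control"], datasets["mdd"], cfg)
        rev = run_differential_pipeline(datasets["mdd"], datasets["control"], cfg)
        np.testing.assert_array_equal(fwd.gene_ids, rev.gene_ids)
        np.testing.assert_array_equal(fwd.delta, -rev.delta)
        np.testing.assert_array_equal(fwd.p_boot, rev.p_boot)
        swap = {"gain": "loss", "loss": "gain", "not_classified": "not_classified"}
        np.testing.assert_array_equal(
            np.array([swap[l] for l in fwd.label], dtype=object), rev.label
        )

    def test_designed_gains_and_losses_recovered(self):
        cfg_sim = SimConfig(
            n_genes=2000,
            n_gain_genes=120,
            n_loss_genes=60,
            rng_seed=3,
        )
        datasets, truth = generate_paired_cohort(cfg_sim)
        cfg = AnalysisConfig(n_bootstrap=1000, fdr_q=0.2, rng_seed=3)
        res = run_differential_pipeline(datasets["control"], datasets["mdd"], cfg)
        id_to_class = dict(zip(truth.table["gene_id"], truth.table["gene_class"]))
        called_gain = res.gene_ids[res.label == "gain"]
        called_loss = res.gene_ids[res.label == "loss"]
        assert len(called_gain) >= 0.4 * 120
        assert len(called_loss) >= 0.4 * 60
        # classified calls should be overwhelmingly the designed genes
        wrong = sum(id_to_class[g] != "gain" for g in called_gain)
        wrong += sum(id_to_class[g] != "loss" for g in called_loss)
        n_called = len(called_gain) + len(called_loss)
        assert wrong <= 0.3 * max(n_called, 1)

    def test_identical_groups_yield_no_discoveries(self, null_groups):
        ctrl, _ = null_groups
        small = ctrl.subset_genes(ctrl.gene_ids[:300])
        cfg = AnalysisConfig(n_bootstrap=200, fdr_q=0.05, rng_seed=4)
        res = run_differential_pipeline(small, small, cfg)
        assert (res.p_boot == 1.0).all()
        assert not (res.label != "not_classified").any()

    def test_equal_rho_genes_sit_on_the_diagonal(self, null_groups):
        ctrl, case = null_groups
        cfg = AnalysisConfig(n_bootstrap=200, rng_seed=6)
        res = run_differential_pipeline(ctrl, case, cfg, select_all=True)
        # no group effect: r_case - r_ctrl centers on zero with both groups'
        # r estimates scattered around the common rho = 0.5
        assert abs(np.mean(res.delta)) < 0.05
        assert np.mean(res.r_ctrl) == pytest.approx(np.mean(res.r_case), abs=0.05)
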