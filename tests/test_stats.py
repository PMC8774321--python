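"""Group comparison, ROC machinery, DeLong test and the threshold sweep."""

import itertools
import subprocess

import numpy as np
import pytest

from shapefeature.stats import (
    bootstrap_compare_roc_paired,
    compare_roc_paired,
    mann_whitney,
    roc,
    spearman,
    threshold_sweep,
)


class TestMannWhitney:
    def test_fully_separated_groups(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]).u == 0.0
        assert mann_whitney([4, 5, 6], [1, 2, 3]).u == 9.0

    def test_identical_multisets(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(x, x)
        assert res.u == len(x) ** 2 / 2
        assert res.p > 0.95

    def test_exact_p_matches_permutation_oracle(self):
        rng = np.random.default_rng(3)
        pooled = rng.normal(size=10)
        x, y = pooled[:5], pooled[5:]
        res = mann_whitney(x, y)
        assert res.method == "exact"
        # enumerate every 5-of-10 split of the pooled sample
        count = 0
        total = 0
        observed = res.u
        n = len(pooled)
        for idx in itertools.combinations(range(n), 5):
            mask = np.zeros(n, bool)
            mask[list(idx)] = True
            u = (pooled[mask][:, None] > pooled[~mask][None, :]).sum()
            stat = max(u, 25 - u)  # two-sided: distance from either tail
            count += stat >= max(observed, 25 - observed)
            total += 1
        assert res.p == pytest.approx(count / total, abs=1e-12)

    def test_asymptotic_p_matches_monte_carlo_permutations(self):
        rng = np.random.default_rng(8)
        pooled = np.round(rng.normal(size=60), 1)  # rounding forces ties
        x, y = pooled[:25], pooled[25:]
        res = mann_whitney(x, y)
        assert res.method == "asymptotic"
        reps = 4000
        stats = np.empty(reps)
        for i in range(reps):
            perm = rng.permutation(pooled)
            diff = perm[:25][:, None] - perm[25:][None, :]
            stats[i] = ((diff > 0) + 0.5 * (diff == 0)).sum()
        observed = res.u
        center = 25 * 35 / 2
        p_mc = np.mean(np.abs(stats - center) >= abs(observed - center) - 1e-9)
        se = np.sqrt(p_mc * (1 - p_mc) / reps)
        assert abs(res.p - p_mc) < 4 * se + 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestROC:
    def test_perfect_separation(self):
        res = roc([3, 4, 5, 0.1, 0.2], [1, 1, 1, 0, 0])
        assert res.auc == 1.0
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0
        assert res.optimal_cutoff == 3  # smallest positive score separates

    def test_hand_counted_auc(self):
        # 3 of the 4 (positive, negative) pairs are concordant
        res = roc([0.9, 0.8, 0.85, 0.7], [1, 1, 0, 0])
        assert res.auc == pytest.approx(0.75)

    def test_auc_equals_rank_sum_identity_on_random_cohorts(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n1, n0 = rng.integers(3, 20, 2)
            scores = np.concatenate([rng.normal(0.5, 1, n1), rng.normal(0, 1, n0)])
            if seed % 3 == 0:
                scores = np.round(scores, 1)  # exercise tie handling
            labels = np.array([1] * n1 + [0] * n0)
            auc = roc(scores, labels).auc
            u = mann_whitney(scores[labels == 1], scores[labels == 0]).u
            assert auc * n1 * n0 == pytest.approx(u, abs=1e-9)

    def test_matches_sklearn_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        scores = np.round(rng.normal(size=40), 1)
        labels = rng.integers(0, 2, 40)
        labels[0], labels[1] = 0, 1
        assert roc(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)

    def test_optimal_cutoff_matches_exhaustive_youden_scan(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            scores = np.round(rng.normal(size=30), 1)
            labels = rng.integers(0, 2, 30)
            labels[:2] = [0, 1]
            res = roc(scores, labels)
            pos, neg = scores[labels == 1], scores[labels == 0]
            best = max(
                np.unique(scores),
                key=lambda t: ((pos >= t).mean() + (neg < t).mean() - 1,
                               (neg < t).mean(), t),
            )
            assert res.optimal_cutoff == best
            assert res.optimal_cutoff in scores  # an observed value, not a midpoint

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        assert roc(np.exp(scores), labels).auc == pytest.approx(
            roc(scores, labels).auc, abs=1e-12)

    def test_inverted_polarity_warned_not_flipped(self):
        with pytest.warns(UserWarning, match="polarity"):
            res = roc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0])
        assert res.auc == 0.0
        assert res.inverted

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1, 2, 3], [1, 1, 1])

    def test_auc_equals_trapezoid_of_own_operating_points(self):
        rng = np.random.default_rng(9)
        scores = np.round(rng.normal(size=25), 1)
        labels = rng.integers(0, 2, 25)
        labels[:2] = [0, 1]
        res = roc(scores, labels)
        fpr = np.concatenate([[0.0], 1.0 - res.specificity])
        tpr = np.concatenate([[0.0], res.sensitivity])
        assert res.auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)


class TestPairedROCComparison:
    @staticmethod
    def _cohort(seed=42, n1=23, n0=27):
        rng = np.random.default_rng(seed)
        latent = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n0)])
        labels = np.array([1] * n1 + [0] * n0, bool)
        return latent + rng.normal(0, 0.8, n1 + n0), \
            latent + rng.normal(0, 1.2, n1 + n0), labels

    def test_self_comparison_is_null(self):
        s1, _, labels = self._cohort()
        res = compare_roc_paired(s1, s1, labels)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_monotone_transform_gives_identical_aucs(self):
        s1, _, labels = self._cohort()
        res = compare_roc_paired(s1, np.exp(s1 / 3), labels)
        assert res.delta == pytest.approx(0.0, abs=1e-12)
        assert res.p == 1.0

    def test_matches_reference_r_implementation(self):
        """The DeLong z and p agree with pROC's roc.test to high precision."""
        s1, s2, labels = self._cohort()
        res = compare_roc_paired(s1, s2, labels)
        rcode = (
            "suppressMessages(library(pROC));"
            f"s1 <- c({','.join(map(str, s1))});"
            f"s2 <- c({','.join(map(str, s2))});"
            f"lab <- c({','.join(map(str, labels.astype(int)))});"
            's<-roc.test(roc(lab,s1,direction="<",quiet=TRUE),'
            'roc(lab,s2,direction="<",quiet=TRUE),method="delong",paired=TRUE);'
            'cat(sprintf("%.12f %.12f", s$statistic, s$p.value))'
        )
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, check=True)
        z_ref, p_ref = map(float, out.stdout.split())
        assert res.z == pytest.approx(z_ref, abs=1e-9)
        assert res.p == pytest.approx(p_ref, abs=1e-9)

    def test_decisions_agree_with_bootstrap_oracle(self):
        agree = 0
        n_cohorts = 60
        for i in range(n_cohorts):
            s1, s2, labels = self._cohort(seed=900 + i)
            p_delong = compare_roc_paired(s1, s2, labels).p
            p_boot = bootstrap_compare_roc_paired(s1, s2, labels,
                                                  n_boot=1000, seed=i).p
            agree += (p_delong < 0.05) == (p_boot < 0.05)
        assert agree / n_cohorts >= 0.95

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_roc_paired([1, 2], [1, 2, 3], [True, False, True])


class TestSpearman:
    def test_monotone_function_gives_unit_correlation(self):
        x = np.array([1.0, 2.5, 4.0, 7.0, 9.0])
        res = spearman(x, np.exp(x))
        assert res.rho == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        res = spearman([1, 2, 3], [3, 1, 2])
        assert res.rho == pytest.approx(-0.5)
        assert res.method == "exact-permutation"

    def test_t_approximation_close_to_exact_at_small_n(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(12)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            exact = spearman(x, y)
            assert abs(spearmanr(x, y).pvalue - exact.p) < 0.05

    def test_constant_vector_flagged(self):
        res = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert res.constant_input
        assert np.isnan(res.rho)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])


@pytest.fixture(scope="module")
def small_cohort():
    from shapefeature.phantom import simulate_cohort

    return simulate_cohort(n_pos=6, n_neg=6, seed=31, keep_volumes=True,
                           grid_shape=(36, 36, 26), base_radius=20)


class TestThresholdSweep:

    def test_singleton_k_is_trivial_argmax(self, small_cohort):
        res = threshold_sweep(small_cohort.cases, [1.5])
        assert res.argmax_k == (1.5,)
        assert len(res.table) == 1

    def test_argmax_matches_brute_force_recomputation(self, small_cohort):
        from shapefeature.geometry import quantify_case
        from shapefeature.errors import EmptyVOIError, MeshExtractionError

        ks = [1.3, 1.5, 1.7]
        res = threshold_sweep(small_cohort.cases, ks)
        best_auc, best_k = -1.0, None
        for k in ks:
            scores, labels = [], []
            for case in small_cohort.cases:
                try:
                    s = quantify_case(case.pet, case.brain_mask, k=k)
                except (EmptyVOIError, MeshExtractionError):
                    continue
                scores.append(s.shape_feature)
                labels.append(case.label)
            auc = roc(np.array(scores), np.array(labels)).auc
            if auc > best_auc + 1e-12:
                best_auc, best_k = auc, k
        assert best_k in res.argmax_k

    def test_invariant_under_global_pet_rescaling(self, small_cohort):
        from shapefeature.phantom import CaseVolumes
        from shapefeature.grid import VoxelGrid
        import pandas as pd

        doubled = [
            CaseVolumes(case_id=c.case_id,
                        pet=VoxelGrid(values=c.pet.values * 2.0,
                                      spacing=c.pet.spacing),
                        brain_mask=c.brain_mask, label=c.label)
            for c in small_cohort.cases
        ]
        a = threshold_sweep(small_cohort.cases, [1.4, 1.6]).table
        b = threshold_sweep(doubled, [1.4, 1.6]).table
        pd.testing.assert_frame_equal(a, b)

    def test_empty_k_values_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            threshold_sweep(small_cohort.cases, [])
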