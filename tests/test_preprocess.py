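"""QC chain: missingness filter, kNN imputation, beta mixture, normalization,
PCA outlier removal, BH adjustment — each checked against an independent
brute-force oracle where one exists."""

import numpy as np
import pytest

from pediclock import (
    BetaMatrix,
    NormalizationReference,
    ValidationError,
    bh_adjust,
    bmiq_normalize,
    filter_probes_by_missingness,
    fit_beta_mixture,
    knn_impute,
    pca_outlier_filter,
)

from conftest import make_matrix


class TestMissingnessFilter:
    def test_boundary_at_max_missing(self, rng):
        values = np.tile(rng.uniform(0.2, 0.8, size=(2, 1)), (1, 716))
        values[0, :11] = np.nan  # 11 missing -> dropped
        values[1, :10] = np.nan  # 10 missing -> kept
        m = make_matrix(values)
        kept = filter_probes_by_missingness(m, max_missing=10)
        assert kept.probe_ids == [m.probe_ids[1]]

    def test_zero_threshold_on_complete_matrix_is_identity(self, random_beta):
        out = filter_probes_by_missingness(random_beta, max_missing=0)
        assert out.probe_ids == random_beta.probe_ids
        np.testing.assert_array_equal(out.values, random_beta.values)

    @pytest.mark.parametrize("max_missing", [0, 1, 3])
    def test_matches_bruteforce_count_filter(self, rng, max_missing):
        values = rng.uniform(0, 1, size=(40, 25))
        values[rng.random(values.shape) < 0.08] = np.nan
        m = make_matrix(values)
        expected = [
            p for p, row in zip(m.probe_ids, values)
            if sum(np.isnan(v) for v in row) <= max_missing
        ]
        assert filter_probes_by_missingness(m, max_missing).probe_ids == expected


def _knn_oracle(values, k):
    """Exhaustive-search reference implementation of the probe-kNN rule."""
    p, n = values.shape
    out = values.copy()
    for i in range(p):
        for j in range(n):
            if not np.isnan(values[i, j]):
                continue
            dists = []
            for other in range(p):
                if other == i or np.isnan(values[other, j]):
                    continue
                shared = ~np.isnan(values[i]) & ~np.isnan(values[other])
                if not shared.any():
                    continue
                d = np.sqrt(np.mean((values[i, shared] - values[other, shared]) ** 2))
                dists.append((d, other))
            dists.sort()
            neighbors = [o for _, o in dists[:k]]
            out[i, j] = np.mean([values[o, j] for o in neighbors])
    return np.clip(out, 0, 1)


class TestKnnImpute:
    def test_complete_matrix_is_identity(self, random_beta):
        out = knn_impute(random_beta)
        np.testing.assert_array_equal(out.values, random_beta.values)

    def test_zero_distance_neighbor_copies_value(self):
        values = np.array([
            [0.1, 0.2, 0.3, np.nan],
            [0.1, 0.2, 0.3, 0.8],   # identical elsewhere -> distance 0
            [0.9, 0.9, 0.9, 0.1],
        ])
        out = knn_impute(make_matrix(values), k=1)
        assert out.values[0, 3] == 0.8

    @pytest.mark.parametrize("seed,k", [(0, 3), (1, 3), (2, 1), (3, 5)])
    def test_matches_exhaustive_oracle(self, seed, k):
        rng = np.random.default_rng(seed)
        values = rng.uniform(0, 1, size=(20, 10))
        idx = rng.choice(values.size, size=5, replace=False)
        values.ravel()[idx] = np.nan
        m = make_matrix(values)
        out = knn_impute(m, k=k)
        np.testing.assert_allclose(out.values, _knn_oracle(values, k), atol=1e-12)
        assert out.n_missing() == 0

    def test_underobserved_probe_named_in_error(self):
        values = np.array([[np.nan, np.nan, 0.5], [0.1, 0.2, 0.3]])
        with pytest.raises(ValidationError, match="cg00000"):
            knn_impute(make_matrix(values))


class TestBetaMixture:
    def test_recovers_well_separated_components(self):
        rng = np.random.default_rng(3)
        comps = [(2.0, 18.0, 0.5), (12.0, 10.0, 0.3), (25.0, 3.0, 0.2)]
        data = np.concatenate(
            [rng.beta(a, b, int(w * 5000)) for a, b, w in comps]
        )
        fit = fit_beta_mixture(data)
        true_means = np.array(sorted(a / (a + b) for a, b, _ in comps))
        assert np.abs(fit.component_means - true_means).max() < 0.02
        assert np.abs(np.sort(fit.weights) - np.sort([w for *_, w in comps])).max() < 0.05

    def test_log_likelihood_is_monotone(self, rng):
        data = np.concatenate([rng.beta(2, 10, 300), rng.beta(15, 4, 300)])
        fit = fit_beta_mixture(data)
        assert np.all(np.diff(fit.log_likelihood) >= -1e-8)

    def test_identical_values_flagged_degenerate(self):
        fit = fit_beta_mixture(np.full(100, 0.42))
        assert fit.degenerate

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_beta_mixture(np.linspace(0.1, 0.9, 10))


class TestNormalization:
    def test_quantile_mode_sorted_values_equal_reference(self, rng):
        values = rng.uniform(0, 1, size=(50, 4))
        m = make_matrix(values)
        ref = NormalizationReference(m.probe_ids, rng.uniform(0, 1, 50))
        out = bmiq_normalize(m, ref, mode="quantile")
        for j in range(4):
            np.testing.assert_allclose(
                np.sort(out.values[:, j]), np.sort(ref.reference_values), atol=1e-12
            )

    def test_quantile_mode_undoes_monotone_shift(self, rng):
        base = rng.uniform(0.05, 0.95, size=200)
        shifted = np.clip(0.9 * base + 0.04, 0, 1)  # strictly monotone map
        m = make_matrix(shifted[:, None])
        ref = NormalizationReference(m.probe_ids, base)
        out = bmiq_normalize(m, ref, mode="quantile")
        np.testing.assert_allclose(out.values[:, 0], base, atol=1e-12)

    def test_identity_limit_small_change(self, rng):
        values = rng.uniform(0.05, 0.95, size=300)
        m = make_matrix(values[:, None])
        ref = NormalizationReference(m.probe_ids, values.copy())
        out = bmiq_normalize(m, ref, mode="quantile")
        assert np.abs(out.values[:, 0] - values).max() < 0.01

    def test_bmiq_mode_tracks_reference_mixture(self):
        # Sample and reference drawn from nearby well-separated 3-state
        # mixtures; mapped values must stay in [0,1], preserve rank order,
        # and move the sample's component means toward the reference's.
        rng = np.random.default_rng(7)
        sample = np.concatenate(
            [rng.beta(3, 22, 2000), rng.beta(14, 12, 1200), rng.beta(24, 4, 800)]
        )
        reference = np.concatenate(
            [rng.beta(2, 24, 2000), rng.beta(12, 12, 1200), rng.beta(28, 3, 800)]
        )
        m = make_matrix(sample[:, None])
        ref = NormalizationReference(m.probe_ids, reference)
        out = bmiq_normalize(m, ref, mode="bmiq")
        v = out.values[:, 0]
        assert v.min() >= 0 and v.max() <= 1
        from scipy.stats import spearmanr

        assert spearmanr(sample, v).statistic > 0.99
        # low/high state means move toward the reference mixture
        assert abs(v[sample < 0.25].mean() - reference[reference < 0.25].mean()) < 0.03
        assert abs(v[sample > 0.75].mean() - reference[reference > 0.75].mean()) < 0.03

    def test_reference_probe_mismatch_rejected(self, random_beta, rng):
        ref = NormalizationReference(["other"], [0.5])
        with pytest.raises(ValidationError):
            bmiq_normalize(random_beta, ref, mode="quantile")


class TestPcaOutlierFilter:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_outlier_removed_in_first_iteration(self, seed):
        rng = np.random.default_rng(seed)
        sd = 0.05
        values = 0.5 + sd * rng.standard_normal((300, 100))
        values[:, 17] += 10 * sd  # ten-sigma shift on every probe
        m = make_matrix(np.clip(values, 0, 1))
        filtered, report = pca_outlier_filter(m)
        assert m.sample_ids[17] in report.iterations[0].removed_sample_ids
        assert m.sample_ids[17] not in filtered.sample_ids

    def test_age_structured_cohort_mostly_retained(self):
        from pediclock import CohortSpec, generate_cohort

        beta, _, _ = generate_cohort(
            CohortSpec(n_samples=150, n_probes=400, n_clock_probes=40,
                       missing_rate=0.0, seed=13)
        )
        filtered, report = pca_outlier_filter(beta)
        assert report.total_removed < 0.2 * beta.n_samples
        assert report.total_removed == beta.n_samples - filtered.n_samples

    def test_sample_removed_at_most_once(self):
        rng = np.random.default_rng(5)
        values = np.clip(0.5 + 0.05 * rng.standard_normal((200, 60)), 0, 1)
        _, report = pca_outlier_filter(make_matrix(values))
        removed = report.removed_sample_ids
        assert len(removed) == len(set(removed))

    def test_too_few_samples_rejected(self, rng):
        m = make_matrix(rng.uniform(0, 1, size=(20, 9)))
        with pytest.raises(ValidationError):
            pca_outlier_filter(m)


def _bh_naive(p):
    """Quadratic-time step-up BH: adjusted_i = min over j with p_j >= p_i of
    m * p_j / rank_j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running_min = min(running_min, m * p[i] / (pos + 1))
        adjusted[i] = running_min
    return adjusted


class TestBHAdjust:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_stepup(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, size=rng.integers(1, 200))
        np.testing.assert_allclose(bh_adjust(p), _bh_naive(p), atol=1e-12)

    def test_ties_handled(self):
        p = np.array([0.01, 0.01, 0.5, 0.5, 1.0])
        np.testing.assert_allclose(bh_adjust(p), _bh_naive(p), atol=1e-12)
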