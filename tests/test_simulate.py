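"""Synthetic-data generator: determinism, noiseless limit, planted truth."""

import numpy as np
import pytest
from scipy import stats as sps

from dnamclock import SyntheticSpec, generate_dataset, generate_pd_series, transform_age


def _logit(p):
    return np.log(p / (1 - p))


class TestGenerateDataset:
    def test_same_spec_same_seed_bitwise_identical(self):
        spec = SyntheticSpec(n_samples=40, n_causal=10, n_null=30, seed=9)
        m1, ann1, t1 = generate_dataset(spec)
        m2, ann2, t2 = generate_dataset(spec)
        assert np.array_equal(m1.values, m2.values)
        assert ann1.equals(ann2)
        assert np.array_equal(t1.slopes, t2.slopes)
        m3, _, _ = generate_dataset(SyntheticSpec(n_samples=40, n_causal=10,
                                                  n_null=30, seed=10))
        assert not np.array_equal(m1.values, m3.values)

    def test_noiseless_limit_perfect_monotone_tracking(self):
        """Without noise every causal probe is an exact monotone (logistic)
        function of transformed age: Spearman |rho| = 1, and Pearson r of the
        probe's logit with transformed age is exactly ±1."""
        spec = SyntheticSpec(n_samples=60, n_causal=10, n_null=20,
                             noise_sd=0.0, disease_frac=0.0, seed=3)
        m, ann, truth = generate_dataset(spec)
        z = np.asarray(transform_age(ann["age"].to_numpy(), spec.transform))
        for i, probe in enumerate(truth.causal_probes):
            row = m.values[m.probe_ids.index(probe)]
            rho = sps.spearmanr(row, z).statistic
            assert abs(rho) == pytest.approx(1.0, abs=1e-12)
            r = np.corrcoef(_logit(row), z)[0, 1]
            assert abs(r) == pytest.approx(1.0, abs=1e-9)
            assert np.sign(r) == np.sign(truth.slopes[i])

    def test_bounds_and_annotation_ranges(self):
        spec = SyntheticSpec(n_samples=80, n_causal=15, n_null=25,
                             noise_sd=0.2, ages=(5.0, 30.0), seed=4)
        m, ann, _ = generate_dataset(spec)
        assert np.nanmin(m.values) >= 0 and np.nanmax(m.values) <= 1
        assert ann["age"].between(5.0, 30.0).all()

    def test_ground_truth_recomputes_planted_means(self):
        spec = SyntheticSpec(n_samples=25, n_causal=8, n_null=12,
                             noise_sd=0.0, seed=6)
        m, ann, truth = generate_dataset(spec)
        z = truth.samples["z"].to_numpy()
        mean = 1 / (1 + np.exp(-(truth.intercepts[:, None]
                                 + truth.slopes[:, None] * z[None, :])))
        assert np.allclose(m.values[: spec.n_causal], mean, atol=1e-12)
        assert np.allclose(m.values[spec.n_causal:],
                           truth.null_means[:, None], atol=1e-12)

    def test_balanced_slope_signs(self):
        _, _, truth = generate_dataset(SyntheticSpec(n_causal=20, n_null=0, seed=0))
        assert (truth.slopes > 0).sum() == 10 and (truth.slopes < 0).sum() == 10

    def test_platform_split_manifests(self):
        spec = SyntheticSpec(n_samples=10, n_causal=20, n_null=180,
                             platform_split=0.3, seed=2)
        m, _, truth = generate_dataset(spec)
        man_a, man_b = truth.manifests
        n_private = round(0.3 * 200)
        shared = man_a.probe_ids & man_b.probe_ids
        assert man_a.probe_ids | man_b.probe_ids == set(m.probe_ids)
        assert len(shared) == 200 - 2 * (n_private // 2)

    def test_disease_offset_on_transformed_scale(self):
        spec = SyntheticSpec(n_samples=200, disease_frac=0.5, disease_offset=0.3, seed=8)
        _, ann, truth = generate_dataset(spec)
        z_age = np.asarray(transform_age(ann["age"].to_numpy(), spec.transform))
        cases = (ann["disease"] == "case").to_numpy()
        assert cases.any() and (~cases).any()
        z = truth.samples["z"].to_numpy()
        assert np.allclose(z[~cases], z_age[~cases])
        assert np.allclose(z[cases], z_age[cases] + 0.3)

    def test_explicit_age_list(self):
        spec = SyntheticSpec(ages=(1.0, 7.0, 30.0), n_causal=5, n_null=5, seed=1)
        m, ann, _ = generate_dataset(spec)
        assert ann["age"].tolist() == [1.0, 7.0, 30.0]
        assert m.shape == (10, 3)

    @pytest.mark.parametrize(
        "kw", [dict(disease_frac=1.5), dict(noise_sd=-0.1), dict(n_causal=-1),
               dict(tissue_labels=("a", "b"), tissue_offsets=(0.0,))],
    )
    def test_spec_validation(self, kw):
        with pytest.raises(ValueError):
            SyntheticSpec(**kw)


class TestGeneratePdSeries:
    def test_deterministic(self):
        spec = SyntheticSpec(n_causal=10, n_null=20, seed=5)
        r1, m1, t1 = generate_pd_series(spec, n_passages=6, drift_per_pd=0.05)
        r2, m2, t2 = generate_pd_series(spec, n_passages=6, drift_per_pd=0.05)
        assert r1 == r2
        assert np.array_equal(m1.values, m2.values)
        assert t1.equals(t2)

    def test_probes_shared_with_cross_sectional_dataset(self):
        spec = SyntheticSpec(n_causal=10, n_null=20, seed=5)
        m_cross, _, truth = generate_dataset(spec)
        _, m_pd, _ = generate_pd_series(spec, n_passages=4)
        assert m_pd.probe_ids == m_cross.probe_ids

    def test_zero_drift_gives_flat_trend(self):
        """With no planted drift the estimated DNAm-age-vs-PD slope of a
        clock trained on matched cross-sectional data is within 2 SE of 0."""
        from dnamclock import PreselectionSpec, estimate_dnam_age, train_clock

        spec = SyntheticSpec(n_samples=100, n_causal=20, n_null=20,
                             noise_sd=0.01, seed=7)
        m_cross, ann, _ = generate_dataset(spec)
        clock = train_clock(m_cross, ann,
                            PreselectionSpec(k_pos=20, k_neg=20, k_null=0),
                            folds=4, seed=0)
        _, m_pd, truth = generate_pd_series(spec, n_passages=15, drift_per_pd=0.0)
        pred = estimate_dnam_age(clock, m_pd)
        fit = sps.linregress(truth["cum_pd"], pred["dnam_age"])
        assert abs(fit.slope) <= 2 * fit.stderr

    def test_harvests_achieve_target_doubling(self):
        spec = SyntheticSpec(n_causal=5, n_null=5, seed=3)
        recs, _, truth = generate_pd_series(spec, n_passages=10,
                                            pd_per_passage=1.0, pd_jitter=0.05)
        assert np.all(np.diff([r.passage for r in recs]) > 0)
        assert truth["pd"].mean() == pytest.approx(1.0, abs=0.15)
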