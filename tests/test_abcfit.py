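"""Sequential ABC: quantiles, determinism, recovery, and fit diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fivehit as fh
from fivehit.abcfit import (
    ABCConfig,
    PosteriorSample,
    fit,
    goodness_of_fit,
    summarize,
    weighted_quantile,
)

#: cheap configuration for tests that only need a working posterior
SMALL = ABCConfig(n_particles=250, n_rounds=4, ess_gate=20, ess_floor=20,
                  max_restarts=1)


# ---------------------------------------------------------------------------
# weighted quantiles
# ---------------------------------------------------------------------------

class TestWeightedQuantile:
    def test_two_point_median_is_midpoint(self):
        assert weighted_quantile(np.array([1.0, 3.0]), np.array([0.5, 0.5]), 0.5) == 2.0

    def test_all_equal_samples_zero_width(self):
        v = np.full(10, 4.2)
        w = np.random.default_rng(0).random(10)
        assert weighted_quantile(v, w, 0.025) == weighted_quantile(v, w, 0.975) == 4.2

    @staticmethod
    def _scan_oracle(values, weights, q):
        """Brute-force sorted cumulative-weight quantile (midpoint rule),
        written as an explicit scan independent of the vectorised path."""
        pairs = sorted(zip(values, weights))
        total = sum(w for _, w in pairs)
        positions, cum = [], 0.0
        for _, w in pairs:
            positions.append((cum + 0.5 * w) / total)
            cum += w
        if q <= positions[0]:
            return pairs[0][0]
        if q >= positions[-1]:
            return pairs[-1][0]
        for i in range(len(pairs) - 1):
            if positions[i] <= q <= positions[i + 1]:
                frac = (q - positions[i]) / (positions[i + 1] - positions[i])
                return pairs[i][0] + frac * (pairs[i + 1][0] - pairs[i][0])
        raise AssertionError("unreachable")

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), q=st.sampled_from([0.025, 0.25, 0.5, 0.975]))
    def test_matches_cumulative_weight_scan_oracle(self, seed, q):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=8)
        weights = rng.random(8) + 0.05
        ours = weighted_quantile(values, weights, q)
        oracle = self._scan_oracle(values.tolist(), weights.tolist(), q)
        assert ours == pytest.approx(oracle, abs=1e-12)


# ---------------------------------------------------------------------------
# the fit
# ---------------------------------------------------------------------------

class TestFit:
    def test_degenerate_prior_returns_prior(self, table1_series, table1_seq):
        truth = fh.fitted_for(table1_seq.id)
        cfg = ABCConfig(
            prior_log10_v=(np.log10(truth.v),) * 2,
            prior_mu=tuple((m, m) for m in truth.mu),
        )
        post = fit(table1_series, table1_seq, config=cfg, seed=3)
        assert np.allclose(post.particles[:, 0], truth.v)
        assert np.allclose(post.particles[:, 1:], truth.mu)
        assert post.distances[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(post.weights, post.weights[0])

    def test_seed_determinism(self, table1_series, table1_seq):
        a = fit(table1_series, table1_seq, config=SMALL, seed=11)
        b = fit(table1_series, table1_seq, config=SMALL, seed=11)
        assert np.array_equal(a.particles, b.particles)
        assert np.array_equal(a.weights, b.weights)
        assert a.epsilon == b.epsilon

    def test_prior_support_respected(self, table1_series, table1_seq):
        post = fit(table1_series, table1_seq, config=SMALL, seed=2)
        assert np.all(post.particles[:, 1:] > 0)
        assert np.all(post.particles[:, 1:] < 1e-2)
        assert np.all(post.particles[:, 0] > 0)
        assert abs(post.weights.sum() - 1.0) < 1e-12

    def test_empty_series_rejected(self, table1_seq):
        with pytest.raises(ValueError):
            fh.IncidenceSeries(ages=np.array([]), rates=np.array([]))

    def test_recovery_of_kras_first_rates(self, table1_series, table1_seq):
        """Noise-free self-fit puts every stage rate inside its published CI
        for the majority of seeds."""
        truth = fh.fitted_for(table1_seq.id)
        hits = 0
        for seed in (1, 2, 3):
            post = fit(table1_series, table1_seq, seed=seed)
            mu = post.median_parameters().mu
            if all(lo <= m <= hi for m, (lo, hi) in zip(mu, truth.mu_ci)):
                hits += 1
        assert hits >= 2

    def test_posterior_contraction_with_less_noise(self, table1_params, table1_seq):
        """Credible intervals narrow when Poisson counting noise is removed."""
        noisy = fh.generate(fh.SyntheticConfig(
            truth=table1_params, pathway=table1_seq, ages=np.arange(85.0),
            noise="poisson", person_years=1e5, fraction_triple_mutant=1.0, seed=4,
        ))
        clean = fh.generate(fh.SyntheticConfig(
            truth=table1_params, pathway=table1_seq, ages=np.arange(85.0),
            noise="none", fraction_triple_mutant=1.0, seed=4,
        ))
        widths = {}
        for name, series in (("noisy", noisy), ("clean", clean)):
            post = fit(series, table1_seq, config=SMALL, seed=8)
            rows = summarize(post)
            widths[name] = np.mean(
                [(r["ci_high"] - r["ci_low"]) / r["median"] for r in rows]
            )
        assert widths["clean"] < widths["noisy"]


# ---------------------------------------------------------------------------
# summaries and goodness of fit
# ---------------------------------------------------------------------------

class TestSummaries:
    def test_summary_table_shape(self, table1_series, table1_seq):
        post = fit(table1_series, table1_seq, config=SMALL, seed=5)
        rows = summarize(post)
        assert [r["parameter"] for r in rows] == ["v", "mu1", "mu2", "mu3", "mu4"]
        for r in rows:
            assert r["ci_low"] <= r["median"] <= r["ci_high"]

    def test_effective_sample_floor_enforced(self, table1_series, table1_seq):
        post = fit(table1_series, table1_seq, config=SMALL, seed=5)
        spiked = PosteriorSample(
            particles=post.particles,
            weights=np.eye(1, post.weights.size).ravel(),
            distances=post.distances,
            epsilon=post.epsilon, pathway=post.pathway,
            config=post.config, seed=post.seed,
        )
        with pytest.raises(RuntimeError):
            summarize(spiked)

    def test_goodness_accepts_self_fit_and_rejects_gross_misfit(
        self, table1_series, table1_seq
    ):
        post = fit(table1_series, table1_seq, config=SMALL, seed=6)
        d, ok = goodness_of_fit(table1_series, table1_seq, post)
        assert ok and d < 0.1
        shifted = fh.IncidenceSeries(
            ages=table1_series.ages, rates=table1_series.rates * 10.0
        )
        d10, ok10 = goodness_of_fit(shifted, table1_seq, post)
        assert not ok10 and d10 > 0.5

    def test_posterior_file_roundtrip(self, tmp_path, table1_series, table1_seq):
        post = fit(table1_series, table1_seq, config=SMALL, seed=7)
        path = tmp_path / "post.tsv"
        post.write(path)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == post.particles.shape[0] + 1
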