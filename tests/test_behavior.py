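"""Event pairing, relation estimation, and the synthetic event generator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from cascadenet import (
    estimate_relations,
    generate_synthetic_events,
    load_events,
    pair_events,
    save_events,
)


def table_from_rows(rows):
    return pd.DataFrame(rows, columns=["subject", "trial", "t_ms", "magnitude"])


class TestPairing:
    def test_definitional_pairs(self):
        table = table_from_rows([(1, 1, 100.0, 1.0), (1, 1, 400.0, 2.0),
                                 (1, 1, 900.0, 3.0)])
        pairs = pair_events(table)
        mi = pairs.magnitude_interval
        assert list(zip(mi["M"], mi["TI"])) == [(1.0, 300.0), (2.0, 500.0)]
        ii = pairs.interval_interval
        assert list(zip(ii["TI_n"], ii["TI_next"])) == [(300.0, 500.0)]

    def test_single_event_trials_are_skipped(self):
        table = table_from_rows([(1, 1, 100.0, 1.0), (1, 2, 250.0, 2.0)])
        pairs = pair_events(table)
        assert len(pairs.magnitude_interval) == 0
        assert pairs.n_skipped_trials == 2

    def test_pairs_never_cross_trial_boundaries(self):
        table = table_from_rows([(1, 1, 100.0, 1.0), (1, 1, 300.0, 1.5),
                                 (1, 2, 50.0, 2.0), (1, 2, 500.0, 2.5),
                                 (2, 1, 10.0, 3.0), (2, 1, 400.0, 3.5)])
        pairs = pair_events(table)
        # Sum over trials of (k_t - 1) and (k_t - 2)
        assert len(pairs.magnitude_interval) == 3
        assert len(pairs.interval_interval) == 0

    def test_pair_counts_match_trial_sizes(self, rng):
        rows = []
        sizes = {}
        for trial in range(12):
            k = int(rng.integers(0, 6))
            sizes[trial] = k
            t = np.sort(rng.uniform(0, 10020, k))
            for ti, mag in zip(t, rng.uniform(0.5, 3.0, k)):
                rows.append((1, trial, ti, mag))
        pairs = pair_events(table_from_rows(rows))
        assert len(pairs.magnitude_interval) == sum(max(0, k - 1) for k in sizes.values())
        assert len(pairs.interval_interval) == sum(max(0, k - 2) for k in sizes.values())

    @given(st.randoms(use_true_random=False))
    def test_row_order_invariance(self, pyrandom):
        table = table_from_rows([(s, tr, 100.0 * (i + 1) + 7 * s, 0.5 + i)
                                 for s in (1, 2) for tr in (1, 2)
                                 for i in range(4)])
        shuffled = table.sample(frac=1.0, random_state=pyrandom.randrange(2 ** 16))
        a = pair_events(table)
        b = pair_events(shuffled)
        pd.testing.assert_frame_equal(
            a.magnitude_interval.reset_index(drop=True),
            b.magnitude_interval.reset_index(drop=True))

    def test_nonpositive_magnitude_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pair_events(table_from_rows([(1, 1, 10.0, -1.0)]))

    def test_duplicate_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            pair_events(table_from_rows([(1, 1, 10.0, 1.0), (1, 1, 10.0, 1.0)]))


class TestGenerator:
    def test_same_seed_reproduces_table(self):
        kw = dict(n_subjects=2, trials_per_subject=3, seed=42)
        pd.testing.assert_frame_equal(generate_synthetic_events(**kw),
                                      generate_synthetic_events(**kw))

    def test_structure_and_invariants(self):
        table = generate_synthetic_events(n_subjects=3, trials_per_subject=4,
                                          seed=7)
        assert set(table.columns) == {"subject", "trial", "t_ms", "magnitude"}
        assert (table["magnitude"] > 0).all()
        assert (table["t_ms"] <= 10020.0).all()
        for _, grp in table.groupby(["subject", "trial"]):
            assert np.all(np.diff(grp["t_ms"]) > 0)

    def test_io_round_trip(self, tmp_path):
        table = generate_synthetic_events(n_subjects=1, trials_per_subject=2,
                                          seed=3)
        path = tmp_path / "events.tsv"
        save_events(table, path)
        back = load_events(path)
        pd.testing.assert_frame_equal(back, table)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            generate_synthetic_events(n_subjects=0, seed=1)
        with pytest.raises(ValueError):
            generate_synthetic_events(rho=1.2, seed=1)
        with pytest.raises(ValueError):
            generate_synthetic_events(noise_sd=-0.5, seed=1)


class TestEstimation:
    def test_noiseless_limit_recovers_interval_model(self):
        table = generate_synthetic_events(n_subjects=2, trials_per_subject=10,
                                          rho=0.0, noise_sd=0.0, seed=11)
        est = estimate_relations(pair_events(table))
        c = est["magnitude_interval"].fitted.coefficients
        assert c["a"] == pytest.approx(600.0, rel=1e-6)
        assert c["b"] == pytest.approx(0.5, rel=1e-6)
        assert c["c"] == pytest.approx(100.0, rel=1e-6)

    def test_independent_intervals_have_near_zero_lag1_slope(self):
        table = generate_synthetic_events(n_subjects=5, trials_per_subject=40,
                                          rho=0.0, noise_sd=0.3, seed=5)
        est = estimate_relations(pair_events(table))
        fit = est["interval_interval"].fitted
        # no serial dependence: slope indistinguishable from zero
        assert abs(fit.coefficients["m"]) < 4 * fit.stderr["m"] + 0.02

    def test_lag1_slope_matches_generator_expectation(self):
        """With AR(1) log-interval noise the population lag-1 regression
        slope has a closed form from the lognormal moments; the fitted
        slope should match it within Monte-Carlo error."""
        rho, sd = 0.4, 0.3
        table = generate_synthetic_events(n_subjects=5, trials_per_subject=60,
                                          rho=rho, noise_sd=sd, seed=17)
        est = estimate_relations(pair_events(table))
        fit = est["interval_interval"].fitted

        # moments of mu(M) under the truncated lognormal magnitude law
        mean, sdm = 2.0, 0.7
        s2 = np.log(1 + (sdm / mean) ** 2)
        mu_log = np.log(mean) - s2 / 2
        pdf_norm = stats.lognorm(np.sqrt(s2), scale=np.exp(mu_log))
        lo, hi = 0.3, 6.0
        z = pdf_norm.cdf(hi) - pdf_norm.cdf(lo)

        def mu(m):
            return 600.0 * np.exp(-0.5 * m) + 100.0

        e_mu = integrate.quad(lambda m: mu(m) * pdf_norm.pdf(m) / z, lo, hi)[0]
        e_mu2 = integrate.quad(lambda m: mu(m) ** 2 * pdf_norm.pdf(m) / z, lo, hi)[0]
        cov = e_mu ** 2 * np.exp(sd ** 2) * (np.exp(rho * sd ** 2) - 1)
        var = e_mu2 * np.exp(2 * sd ** 2) - e_mu ** 2 * np.exp(sd ** 2)
        expected_slope = cov / var

        assert fit.coefficients["m"] > 0
        assert fit.coefficients["m"] == pytest.approx(
            expected_slope, abs=4 * fit.stderr["m"] + 0.01)

    def test_positive_lag1_coupling_gives_positive_slope(self):
        table = generate_synthetic_events(n_subjects=5, trials_per_subject=20,
                                          rho=0.3, noise_sd=0.3, seed=23)
        est = estimate_relations(pair_events(table))
        assert est["interval_interval"].fitted.coefficients["m"] > 0

    def test_insufficient_pairs_rejected(self):
        table = table_from_rows([(1, 1, 100.0, 1.0), (1, 1, 400.0, 2.0)])
        with pytest.raises(ValueError, match="pairs"):
            estimate_relations(pair_events(table))

    def test_binned_means_partition_all_pairs(self):
        table = generate_synthetic_events(n_subjects=2, trials_per_subject=8,
                                          seed=31)
        est = estimate_relations(pair_events(table), n_bins=8)
        mi = est["magnitude_interval"]
        assert mi.binned["count"].sum() == mi.n_pairs

    def test_per_subject_mode_runs(self):
        table = generate_synthetic_events(n_subjects=4, trials_per_subject=10,
                                          seed=37)
        est = estimate_relations(pair_events(table), mode="per_subject")
        assert est["magnitude_interval"].fitted.coefficients["b"] > 0
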