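import numpy as np
import pytest

from mitodemog.alignment import pairwise_differences
from mitodemog.errors import DomainError
from mitodemog.mismatch import (
    MismatchDistribution,
    bootstrap_expansion_test,
    equilibrium_mismatch,
    expected_mismatch,
    fit_sudden_expansion,
    observed_mismatch,
    raggedness,
    ssd,
)
from mitodemog.simulate import SimConfig, simulate_alignment

from .conftest import make_aln


def _freq_dist(freqs, n_pairs=10**6):
    counts = np.asarray(freqs) * n_pairs
    return MismatchDistribution(counts=counts, n_pairs=n_pairs)


class TestObservedMismatch:
    def test_small_example(self):
        m = observed_mismatch(pairwise_differences(make_aln("AA", "AT", "TT")))
        assert m.counts.tolist() == [0, 2, 1]

    def test_identical_sequences(self):
        m = observed_mismatch(pairwise_differences(make_aln("AA", "AA", "AA")))
        assert m.counts.tolist() == [3]

    def test_pair_conservation(self, rng):
        aln, _ = simulate_alignment(SimConfig.constant(10, 4.0, L=2000), rng=rng)
        m = observed_mismatch(pairwise_differences(aln))
        assert m.counts.sum() == 45  # n(n-1)/2
        assert m.freqs.sum() == pytest.approx(1.0)


class TestExpectedMismatch:
    def test_theta_one_equilibrium_geometric(self):
        f = equilibrium_mismatch(1.0, 4)
        assert f == pytest.approx([0.5, 0.25, 0.125, 0.0625, 0.03125])

    def test_tau_zero_is_theta0_equilibrium(self):
        f, _ = expected_mismatch(0.0, 2.0, 1000.0, 8)
        assert f == pytest.approx(equilibrium_mismatch(2.0, 8))

    def test_large_tau_approaches_theta1_equilibrium(self):
        f, _ = expected_mismatch(200.0, 5.0, 1.0, 10)
        assert np.abs(f - equilibrium_mismatch(1.0, 10)).max() < 1e-6

    def test_negative_parameters_rejected(self):
        for bad in [(-1, 1, 1), (1, -1, 1), (1, 1, -1), (1, 0, 1)]:
            with pytest.raises(DomainError):
                expected_mismatch(*bad, 5)

    @pytest.mark.parametrize(
        "tau,theta0,theta1",
        [(0.0, 1.0, 1.0), (5.0, 0.5, 200.0), (10.0, 1.0, 1e4), (2.5, 3.0, 3.0),
         (50.0, 0.1, 1e5)],
    )
    def test_total_mass_is_one(self, tau, theta0, theta1):
        f, tail = expected_mismatch(tau, theta0, theta1, 200)
        assert f.sum() + tail == pytest.approx(1.0, abs=1e-9)
        assert (f >= 0).all() and tail >= 0

    def test_simulation_oracle_transcription_check(self):
        # mean simulated mismatch frequencies vs the closed form, per class,
        # within 3 Monte-Carlo standard errors (5000 pair simulations)
        tau, theta0, theta1 = 5.0, 0.5, 200.0
        reps = 5000
        rng = np.random.default_rng(99)
        cfg = SimConfig(n=2, tau=tau, theta0=theta0, theta1=theta1, L=16038)
        d_max = 30
        hits = np.zeros((reps, d_max + 1))
        for r in range(reps):
            aln, _ = simulate_alignment(cfg, rng=rng)
            d = int(pairwise_differences(aln).pair_values()[0])
            if d <= d_max:
                hits[r, d] = 1.0
        expect, _tail = expected_mismatch(tau, theta0, theta1, d_max)
        mean = hits.mean(axis=0)
        se = np.sqrt(expect * (1 - expect) / reps)
        # classes with enough expected mass for the normal approximation
        mask = expect * reps >= 10
        z = np.abs(mean[mask] - expect[mask]) / se[mask]
        assert mask.sum() >= 12
        assert z.max() < 3
        assert np.abs(mean - expect).max() < 0.01


class TestRaggedness:
    def test_two_equal_classes(self):
        # terminal-zero convention: (0.5-0.5)^2 + (0-0.5)^2
        assert raggedness(_freq_dist([0.5, 0.5])) == pytest.approx(0.25)

    def test_single_class(self):
        # stated sum with one terminal zero term gives (0-1)^2 = 1.0
        assert raggedness(_freq_dist([1.0])) == pytest.approx(1.0)

    def test_decreases_with_smoothing(self):
        vals = [
            raggedness(_freq_dist([1.0 / k] * k)) for k in (2, 4, 8, 16)
        ]
        assert vals == sorted(vals, reverse=True)
        assert vals[-1] < 0.05


class TestSSD:
    def test_zero_iff_identical(self):
        a = np.array([0.5, 0.3, 0.2])
        assert ssd(a, a) == 0.0
        assert ssd(a, np.array([0.5, 0.2, 0.3])) > 0.0


class TestFit:
    def test_noiseless_self_consistency(self):
        f, tail = expected_mismatch(10.0, 1.0, 1000.0, 60)
        freqs = f.copy()
        freqs[-1] += tail
        fit = fit_sudden_expansion(_freq_dist(freqs))
        assert fit.tau == pytest.approx(10.0, abs=0.2)
        assert fit.tau == pytest.approx(10.0, rel=0.02)
        assert fit.SSD < 1e-10

    def test_monomorphic_degenerate_limit(self):
        m = observed_mismatch(pairwise_differences(make_aln("AA", "AA", "AA")))
        fit = fit_sudden_expansion(m)
        assert fit.tau == pytest.approx(0.0, abs=1e-6)
        assert fit.theta0 == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_on_simulations(self):
        # scaled down from the 100-dataset experiment (run in acceptance):
        # median tau-hat within 25% of truth over 30 datasets
        rng = np.random.default_rng(17)
        cfg = SimConfig(n=50, tau=10.0, theta0=1.0, theta1=1000.0, L=16038)
        taus = []
        for _ in range(30):
            aln, _ = simulate_alignment(cfg, rng=rng)
            m = observed_mismatch(pairwise_differences(aln))
            taus.append(fit_sudden_expansion(m).tau)
        assert abs(np.median(taus) - 10.0) / 10.0 < 0.25

    def test_theta_ordering_enforced(self, rng):
        aln, _ = simulate_alignment(SimConfig.constant(12, 3.0, L=2000), rng=rng)
        fit = fit_sudden_expansion(observed_mismatch(pairwise_differences(aln)))
        assert 0 <= fit.theta0 <= fit.theta1


@pytest.fixture(scope="module")
def fitted():
    aln, _ = simulate_alignment(
        SimConfig(n=15, tau=6.0, theta0=0.5, theta1=1e4, L=8000, seed=4)
    )
    m = observed_mismatch(pairwise_differences(aln))
    return aln, fit_sudden_expansion(m)


class TestBootstrap:
    def test_determinism(self, fitted):
        aln, fit = fitted
        b1 = bootstrap_expansion_test(aln, fit, reps=100, seed=5)
        b2 = bootstrap_expansion_test(aln, fit, reps=100, seed=5)
        assert (b1.p_SSD, b1.p_r, b1.tau_CI) == (b2.p_SSD, b2.p_r, b2.tau_CI)

    def test_completed_fit_fields(self, fitted):
        aln, fit = fitted
        b = bootstrap_expansion_test(aln, fit, reps=100, seed=5)
        assert 0.0 <= b.p_SSD <= 1.0 and 0.0 <= b.p_r <= 1.0
        assert b.tau_CI[0] <= b.tau <= b.tau_CI[1]
        assert b.reps == 100

    def test_model_not_rejected_for_expansion_data(self, fitted):
        # expansion-simulated data must usually emit "model not rejected"
        aln, fit = fitted
        b = bootstrap_expansion_test(aln, fit, reps=100, seed=5)
        assert b.expansion_rejected_05 is False

    def test_reps_floor(self, fitted):
        aln, fit = fitted
        with pytest.raises(ValueError):
            bootstrap_expansion_test(aln, fit, reps=10, seed=0)
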