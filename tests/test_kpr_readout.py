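import numpy as np
import pytest

from ligandsense import LigandMixture, MessengerParams, sample_trace, simulate_messengers
from ligandsense.approx_estimator import analytic_variance
from ligandsense.kpr_readout import (
    KPRNetwork,
    expected_long_fraction,
    invert_exact,
    invert_linear,
    mean_readouts,
    readout,
    readout_relvar,
    renormalized_cutoff,
)


@pytest.fixture
def net():
    return KPRNetwork(kA=5.0, kB=3.0, rA=1.0, rB=2.0, Tc_mean=3.0)


class TestMeans:
    def test_empty_environment_gives_zero(self, net):
        mix = LigandMixture.two_species(1.0, 0.1, 0.0, 1.0, 1.0, 0.0)
        A, B = mean_readouts(mix, net)
        assert A == 0.0 and B == 0.0

    def test_gates_coincide_at_zero_cutoff(self, standard_mixture):
        net0 = KPRNetwork(kA=5.0, kB=3.0, rA=1.0, rB=2.0, Tc_mean=0.0)
        A, B = mean_readouts(standard_mixture, net0)
        assert A / (net0.kA / net0.rA) == pytest.approx(B / (net0.kB / net0.rB))

    def test_closed_forms(self, standard_mixture, net):
        # occupancy denominator 1 + sum k_i c_i / r_i
        A, B = mean_readouts(standard_mixture, net)
        Q = 1 + 0.5 / 0.1 + 0.5 / 1.0
        expected_A = (0.5 / 0.1 * np.exp(-0.3) + 0.5 * np.exp(-3)) / Q * 5.0
        expected_B = (0.5 / 0.1 + 0.5) / Q * 1.5
        assert A == pytest.approx(expected_A)
        assert B == pytest.approx(expected_B)

    def test_matches_stochastic_messenger_simulation(self, standard_mixture, net):
        trace = sample_trace(standard_mixture, 25_000, seed=41)
        stats = simulate_messengers(
            trace,
            [
                MessengerParams(net.kA, net.rA, "bound-longer-than-Tc", net.Tc_mean),
                MessengerParams(net.kB, net.rB, "bound"),
            ],
            seed=42,
        )
        A, B = mean_readouts(standard_mixture, net)
        assert stats[0].mean == pytest.approx(A, rel=0.1)
        assert stats[1].mean == pytest.approx(B, rel=0.05)


class TestInversion:
    def test_exact_round_trip_deep_proofreading(self):
        # Tc = 20/r_nc: the cognate-only reading of the A branch is
        # essentially exact and the inversion recovers truth
        mix = LigandMixture.two_species(1.0, 0.1, 0.3, 1.0, 1.0, 0.7)
        net = KPRNetwork(kA=5.0, kB=3.0, rA=1.0, rB=2.0, Tc_mean=20.0)
        terms = mix.on_rates / mix.r
        Q = 1 + terms.sum()
        A_cognate_only = terms[0] * np.exp(-mix.r[0] * net.Tc_mean) / Q * net.kA / net.rA
        _, B = mean_readouts(mix, net)
        c_c, c_nc = invert_exact(A_cognate_only, B, net, mix)
        assert c_c == pytest.approx(0.3, rel=1e-9)
        assert c_nc == pytest.approx(0.7, rel=1e-9)

    def test_bias_from_noncognate_long_events(self):
        # with the full A mean, the recovered cognate concentration carries a
        # positive bias that decays like exp(-(r_nc - r_c) Tc), the same
        # exponential as the threshold estimator's bias
        mix = LigandMixture.two_species(1.0, 0.1, 0.3, 1.0, 1.0, 0.7)
        biases = []
        for Tc in (3.0, 5.0, 7.0):
            net = KPRNetwork(kA=5.0, kB=3.0, rA=1.0, rB=2.0, Tc_mean=Tc)
            A, B = mean_readouts(mix, net)
            c_c, _ = invert_exact(A, B, net, mix)
            expected = (mix.c[1] * mix.r[0] / mix.r[1]) * np.exp(
                -(mix.r[1] - mix.r[0]) * Tc
            )
            assert c_c - mix.c[0] == pytest.approx(expected, rel=1e-9)
            biases.append(c_c - mix.c[0])
        assert biases[0] > biases[1] > biases[2] > 0

    def test_saturation_raises(self, standard_mixture, net):
        with pytest.raises(ValueError, match="saturation"):
            invert_exact(0.1, net.kB / net.rB, net, standard_mixture)

    def test_linear_agrees_with_exact_at_low_occupancy(self, net):
        # dilute mixture: eps << 1, discrepancy bounded by 2 eps
        mix = LigandMixture.two_species(1.0, 0.1, 0.002, 1.0, 1.0, 0.002)
        r = readout(mix, net)
        assert r.eps < 0.05
        for lin, ex in zip(r.c_linear, r.c_exact):
            assert abs(lin - ex) <= 2 * r.eps * abs(ex)

    def test_zero_proofread_signal_gives_zero_cognate(self, standard_mixture, net):
        c_c, _ = invert_linear(0.0, 0.3, net, standard_mixture)
        assert c_c == 0.0

    def test_subtraction_structure(self, standard_mixture, net):
        # c_nc^KPR rises with the B readout and falls with the A readout:
        # the incoherent feedforward subtraction
        _, base = invert_linear(0.2, 0.3, net, standard_mixture)
        _, more_B = invert_linear(0.2, 0.35, net, standard_mixture)
        _, more_A = invert_linear(0.25, 0.3, net, standard_mixture)
        assert more_B > base
        assert more_A < base


class TestRandomDelay:
    def test_zero_variance_keeps_cutoff(self, standard_mixture):
        net = KPRNetwork(kA=1, kB=1, rA=1, rB=1, Tc_mean=4.0, Tc_var=0.0)
        assert renormalized_cutoff(net, standard_mixture) == 4.0

    def test_erlang_delay_matches_renormalized_count(self, standard_mixture):
        # per-event Erlang-distributed cutoffs with matched mean/variance
        # reproduce the second-order renormalized long-event count
        r_c = standard_mixture.r[0]
        # many proofreading steps: narrow Erlang, so that random short
        # cutoffs do not admit non-cognate events
        Tc_mean, shape = 8.0, 16
        scale = Tc_mean / shape
        Tc_var = shape * scale**2
        assert r_c * np.sqrt(Tc_var) <= 0.3
        rng = np.random.default_rng(404)
        trace = sample_trace(standard_mixture, 200_000, rng)
        cutoffs = rng.gamma(shape, scale, size=trace.n)
        frac = np.mean(trace.tau_b >= cutoffs)
        expected = expected_long_fraction(standard_mixture, Tc_mean, Tc_var)
        se = np.sqrt(expected * (1 - expected) / trace.n)
        assert abs(frac - expected) < 4 * se

    def test_renormalized_cutoff_removes_delay_bias(self, standard_mixture):
        # rescaling the long-event count with the renormalized cutoff
        # re-centers the cognate estimate; the naive mean cutoff leaves a
        # systematic offset
        r_c = standard_mixture.r[0]
        Tc_mean, shape = 8.0, 16
        scale = Tc_mean / shape
        Tc_var = shape * scale**2
        net = KPRNetwork(kA=1, kB=1, rA=1, rB=1, Tc_mean=Tc_mean, Tc_var=Tc_var)
        Tc_eff = renormalized_cutoff(net, standard_mixture)
        rng = np.random.default_rng(405)
        est_eff, est_naive = [], []
        for _ in range(300):
            trace = sample_trace(standard_mixture, 3000, rng)
            cutoffs = rng.gamma(shape, scale, size=trace.n)
            n_l = np.count_nonzero(trace.tau_b >= cutoffs)
            est_eff.append(n_l * np.exp(r_c * Tc_eff) / trace.Tu)
            est_naive.append(n_l * np.exp(r_c * Tc_mean) / trace.Tu)
        est_eff = np.array(est_eff)
        se = est_eff.std(ddof=1) / np.sqrt(len(est_eff))
        assert abs(est_eff.mean() - standard_mixture.c[0]) < 4 * se
        naive_bias = np.mean(est_naive) - standard_mixture.c[0]
        assert naive_bias > 4 * se


class TestReadoutNoise:
    def test_independent_of_production_rate(self, standard_mixture):
        n1 = KPRNetwork(kA=1.0, kB=1, rA=0.5, rB=1, Tc_mean=5.0)
        n2 = KPRNetwork(kA=100.0, kB=1, rA=0.5, rB=1, Tc_mean=5.0)
        assert readout_relvar(standard_mixture, n1) == readout_relvar(
            standard_mixture, n2
        )

    def test_grows_with_cutoff(self, standard_mixture):
        vals = [
            readout_relvar(
                standard_mixture,
                KPRNetwork(kA=1, kB=1, rA=0.5, rB=1, Tc_mean=T),
            )
            for T in (3.0, 5.0, 8.0)
        ]
        assert vals[0] < vals[1] < vals[2]

    def test_proportional_to_threshold_estimator_variance(self, standard_mixture):
        # both error formulas share the exp(r_c Tc) amplification of rare
        # long events
        r_c = standard_mixture.r[0]
        v = [
            readout_relvar(
                standard_mixture, KPRNetwork(kA=1, kB=1, rA=0.5, rB=1, Tc_mean=T)
            )
            for T in (6.0, 8.0)
        ]
        assert v[1] / v[0] == pytest.approx(np.exp(r_c * 2.0))
        a = [analytic_variance(standard_mixture, T, 1000) for T in (30.0, 32.0)]
        assert a[1] / a[0] == pytest.approx(np.exp(r_c * 2.0), rel=0.01)

    def test_matches_stochastic_simulation(self):
        # rare-long-event regime; intrinsic production noise suppressed by a
        # large production rate
        mix = LigandMixture.two_species(1.0, 0.2, 0.5, 1.0, 2.0, 0.5)
        net = KPRNetwork(kA=20.0, kB=1.0, rA=0.5, rB=1.0, Tc_mean=12.0)
        trace = sample_trace(mix, 20_000, seed=500)
        (st,) = simulate_messengers(
            trace,
            [MessengerParams(net.kA, net.rA, "bound-longer-than-Tc", net.Tc_mean)],
            seed=501,
        )
        simulated = st.var / st.mean**2
        assert simulated == pytest.approx(readout_relvar(mix, net), rel=0.3)
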