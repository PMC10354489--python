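"""Linearization, transfer functions, gains, time constants, sweeps."""

import numpy as np
import pytest

import bgsens as bg
from bgsens.linear_analysis import gain_vs_operating_point
from bgsens.sensitivity import PerturbationTarget, augment, perturbed_steady_state


class TestLinearize:
    def test_single_state_and_pole(self, abc_lin):
        """Only xB is dynamic; d xB~/dt = -(kappa1+kappa2)*KB * xB~."""
        assert abc_lin.n_states == 1
        assert abc_lin.state_labels == ["B"]
        assert abc_lin.a == pytest.approx(np.array([[-10.0]]))

    def test_direct_feedthrough_entries(self, abc_lin):
        d = abc_lin.d
        i = abc_lin.output_labels.index("r1")
        j = abc_lin.input_labels.index("lambda[A]")
        assert d[i, j] == pytest.approx(2.0)  # kappa1*KA*xA

    def test_non_steady_point_rejected(self, abc, abc_sens):
        from bgsens.kinetics import SteadyState

        bad = SteadyState(x=np.array([2.0, 2.0, 1.0]), f=np.zeros(2), residual=1.0)
        with pytest.raises(ValueError, match="not steady"):
            bg.linearize(abc_sens, bad)

    def test_closed_two_species_moiety_reduced(self):
        """A<->B with conserved total: one state, first-order minimal G."""
        net = bg.build_network(
            [bg.SpeciesSpec("A", x_init=2.0), bg.SpeciesSpec("B")],
            [bg.ReactionSpec("r", kappa=1.0, forward={"A": 1}, reverse={"B": 1})],
        )
        ss = bg.steady_state(net)
        lin = bg.linearize(augment(net), ss)
        assert lin.n_states == 1
        ts = bg.transfer_function(lin)
        num, den = ts.channel("r", "lambda[A]")
        assert len(den) == 2  # single pole, no cancelling pair
        # pole at -(kappa*KA + kappa*KB) = -2
        assert den[1] / den[0] == pytest.approx(2.0)

    def test_external_chemostat_flow_output(self, abc_sens, abc_steady):
        """ext:A output is the net flow into chemostat A, i.e. -f1 here."""
        lin = bg.linearize(abc_sens, abc_steady, outputs=["ext:A", "r1"])
        g = bg.dc_gain(lin)
        assert g[0] == pytest.approx(-g[1], abs=1e-12)


class TestTransferFunction:
    def test_printed_channels(self, abc_lin):
        ts = bg.transfer_function(abc_lin)
        num, den = ts.channel("r1", "lambda[A]")
        assert den == pytest.approx([1.0, 10.0])
        assert num == pytest.approx([2.0, 18.0])
        num, den = ts.channel("r2", "lambda[B]")
        assert num == pytest.approx([9.9, 0.0])

    def test_zero_channel(self, abc_sens, abc_steady):
        """With only a KB target, no direct path from lambda_B to... instead
        check a network where an input genuinely cannot reach an output."""
        net = bg.build_network(
            [
                bg.SpeciesSpec("A", x_init=2.0, is_chemostat=True),
                bg.SpeciesSpec("B", is_chemostat=True),
                bg.SpeciesSpec("P", is_chemostat=True),
                bg.SpeciesSpec("Q", is_chemostat=True),
            ],
            [
                bg.ReactionSpec("r1", kappa=1.0, forward={"A": 1}, reverse={"B": 1}),
                bg.ReactionSpec("r2", kappa=1.0, forward={"P": 1}, reverse={"Q": 1}),
            ],
        )
        ss = bg.steady_state(net)
        lin = bg.linearize(augment(net), ss)
        ts = bg.transfer_function(lin)
        num, _ = ts.channel("r2", "lambda[A]")
        assert np.allclose(num, 0.0)

    def test_proper_and_consistent_with_gain(self, abc_lin):
        ts = bg.transfer_function(abc_lin)
        g0 = bg.initial_gain(abc_lin)
        ginf = bg.dc_gain(abc_lin)
        for i in range(abc_lin.n_outputs):
            for j in range(abc_lin.n_inputs):
                num, den = ts.channel(i, j)
                assert len(num) <= len(den)
                assert ts.evaluate(i, j, 0.0).real == pytest.approx(ginf[i, j], abs=1e-12)
                if len(num) == len(den):
                    assert num[0] / den[0] == pytest.approx(g0[i, j], abs=1e-12)


class TestGains:
    def test_dc_gain_matches_printed_matrix(self, abc_lin):
        expected = np.array(
            [[1.8, 0.0, -0.9, 0.81, 0.09], [1.8, 0.0, -0.9, 0.81, 0.09]]
        )
        assert bg.dc_gain(abc_lin) == pytest.approx(expected, abs=1e-12)

    def test_initial_gain_matches_printed_matrix(self, abc_lin):
        expected = np.array(
            [[2.0, -1.1, 0.0, 0.9, 0.0], [0.0, 9.9, -9.0, 0.0, 0.9]]
        )
        assert bg.initial_gain(abc_lin) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("fixture_name", ["abc_chain", "enzyme_module"])
    def test_dc_gain_matches_finite_difference_oracle(self, fixture_name):
        """ginf equals the central difference of perturbed steady flows."""
        net = bg.fixture(fixture_name)
        ss = bg.steady_state(net)
        sys_ = augment(net)
        lin = bg.linearize(sys_, ss)
        g = bg.dc_gain(lin)
        delta = 1e-6
        for j, tgt in enumerate(sys_.targets):
            fp = perturbed_steady_state(sys_, sys_.assignment({tgt: 1 + delta}), ss.x).f
            fm = perturbed_steady_state(sys_, sys_.assignment({tgt: 1 - delta}), ss.x).f
            fd = (fp - fm) / (2 * delta)
            assert g[:, j] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_unstable_dc_gain_rejected(self, abc_lin):
        import dataclasses

        bad = dataclasses.replace(abc_lin, a=np.array([[1.0]]))
        with pytest.raises(ValueError, match="Hurwitz"):
            bg.dc_gain(bad)


class TestTimeConstant:
    def test_first_order_channel(self, abc_lin):
        """(f2, lambda_A): G = 18/(s+10) -> tau = 0.1."""
        assert bg.time_constant(abc_lin, "r2", "lambda[A]") == pytest.approx(0.1)

    def test_instantaneous_channel(self, abc_lin):
        """(f1, lambda_A) has g0 = 2 != 0 -> tau = 0."""
        assert bg.time_constant(abc_lin, "r1", "lambda[A]") == 0.0

    def test_zero_channel_nan(self):
        net = bg.build_network(
            [
                bg.SpeciesSpec("A", x_init=2.0, is_chemostat=True),
                bg.SpeciesSpec("B"),
                bg.SpeciesSpec("P", is_chemostat=True),
                bg.SpeciesSpec("Q", is_chemostat=True),
            ],
            [
                bg.ReactionSpec("r1", kappa=1.0, forward={"A": 1}, reverse={"B": 1}),
                bg.ReactionSpec("rb", kappa=1.0, forward={"B": 1}, reverse={"A": 1}),
                bg.ReactionSpec("r2", kappa=1.0, forward={"P": 1}, reverse={"Q": 1}),
            ],
        )
        lin = bg.linearize(augment(net), bg.steady_state(net))
        tau = bg.time_constant(lin, "r2", "lambda[A]")
        assert np.isnan(tau)

    def test_balanced_reduction_on_second_order_channel(self):
        """Two-state chain: tau from order-1 truncation approximates the slow mode."""
        net = bg.build_network(
            [
                bg.SpeciesSpec("A", x_init=2.0, is_chemostat=True),
                bg.SpeciesSpec("B"),
                bg.SpeciesSpec("C"),
                bg.SpeciesSpec("D", is_chemostat=True),
            ],
            [
                bg.ReactionSpec("r1", kappa=1.0, forward={"A": 1}, reverse={"B": 1}),
                bg.ReactionSpec("r2", kappa=2.0, forward={"B": 1}, reverse={"C": 1}),
                bg.ReactionSpec("r3", kappa=1.0, forward={"C": 1}, reverse={"D": 1}),
            ],
        )
        lin = bg.linearize(augment(net), bg.steady_state(net))
        tau = bg.time_constant(lin, "r3", "lambda[A]")
        poles = np.sort(lin.poles.real)
        assert -1 / poles[0] < tau < -1 / poles[1] * 3
        assert tau > 0


class TestStepResponse:
    def test_closed_form_first_order_channel(self, abc_lin):
        """(f2, lambda_A): g(t) = 1.8*(1 - exp(-10 t))."""
        t = np.linspace(0.0, 1.0, 50)
        g = bg.step_response(abc_lin, t)
        i = abc_lin.output_labels.index("r2")
        j = abc_lin.input_labels.index("lambda[A]")
        assert g[:, i, j] == pytest.approx(1.8 * (1 - np.exp(-10 * t)), abs=1e-10)

    def test_endpoints_match_gains(self, abc_lin):
        t = np.array([0.0, 5.0])
        g = bg.step_response(abc_lin, t)
        assert g[0] == pytest.approx(bg.initial_gain(abc_lin), abs=1e-12)
        assert g[-1] == pytest.approx(bg.dc_gain(abc_lin), abs=1e-6)

    def test_matches_nonlinear_step_and_improves_as_step_shrinks(self, abc_sens, abc_lin):
        """Nonlinear lambda-step responses, scaled by the step, approach the
        unit step response of the linearization as the step shrinks."""
        t = np.linspace(0.0, 1.0, 41)
        j = abc_lin.input_labels.index("lambda[r1]")
        glin = bg.step_response(abc_lin, t)[:, :, j]
        tgt = PerturbationTarget("reaction-kappa", "r1")
        errs = []
        for dl in (0.1, 0.01):
            traj = bg.step_perturbation_response(
                abc_sens, abc_sens.assignment({tgt: 1 + dl}), t
            )
            scaled = (traj.flows - abc_lin.steady.f) / dl
            errs.append(np.max(np.abs(scaled - glin)))
        assert errs[0] < 0.02
        assert errs[1] < errs[0] / 5


@pytest.fixture(scope="module")
def sweep(enzyme):
    sys_ = augment(enzyme)
    amounts = np.geomspace(0.02, 500.0, 10)
    return sys_, gain_vs_operating_point(sys_, "A", amounts, output_flow="r2")


class TestOperatingPointSweep:
    def test_flow_saturates(self, sweep):
        _, df = sweep
        assert df["converged"].all()
        flows = df["flow"].to_numpy()
        assert np.all(np.diff(flows) > 0)  # monotone in substrate
        assert flows[-1] == pytest.approx(10.0, rel=0.05)  # Vmax = e0*kappa2*KC

    def test_gains_vanish_at_saturation_except_catalytic(self, sweep):
        _, df = sweep
        last = df.iloc[-1]
        assert abs(last["lambda[A]"]) < 0.25
        assert abs(last["lambda[r1]"]) < 0.25
        assert abs(last["lambda[Act]"]) < 0.25
        assert last["lambda[r2]"] > 9.0  # catalytic channel keeps its gain

    def test_gains_small_at_small_flow(self, sweep):
        _, df = sweep
        first = df.iloc[0]
        for col in ("lambda[A]", "lambda[r1]", "lambda[Act]"):
            assert abs(first[col]) < 0.1

    def test_activator_inhibitor_antisymmetric(self, sweep):
        _, df = sweep
        act = df["lambda[Act]"].to_numpy()
        inh = df["lambda[Inh]"].to_numpy()
        assert act == pytest.approx(-inh, rel=1e-6, abs=1e-12)
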