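"""Flux-space parameterization, least-squares fitting, chi-square test,
and parameter-continuation confidence intervals."""

import numpy as np
import pytest

from xylflux.core_network import parse_network
from xylflux.flux_fit import (FitResult, FreeFluxParam, biomass_drain_fluxes,
                              confidence_interval_continuation, fit_fluxes,
                              goodness_of_fit, sample_steady_state_fluxes)
from xylflux.isotope_forward import Fragment, MeasurementSpec, TracerSpec
from xylflux.synthetic_data import MidNoiseModel, generate_mid_dataset

# Two routes writing the same product pool with different carbon orientations:
# the observed M[1]/M[3] labeling is exactly linear in the 'direct' flux, so
# the SSR profile is exactly quadratic — an analytic testbed for the CIs.
MIX_NET = """
@substrate A.ext
@uptake upt
@unbalanced A.ext
upt: A.ext (abc) -> A (abc)
direct: A (abc) -> M (abc)
alt: A (abc) -> M (cba)
outM: M ->
"""

MIX_SPEC = MeasurementSpec([Fragment("M1", (("M", (1,)),)),
                            Fragment("M3", (("M", (3,)),))])
MIX_TRACER = TracerSpec("A.ext", (((1,), 1.0),))


def mix_setup(direct=60.0, noise_sd=0.0, seed=None):
    net = parse_network(MIX_NET)
    pfp = FreeFluxParam(net, {"upt": 100.0}, ["direct"])
    truth = pfp.to_distribution([direct])
    ds, _ = generate_mid_dataset(net, truth, MIX_TRACER, MIX_SPEC,
                                 MidNoiseModel(sd=noise_sd, seed=seed))
    return net, pfp, truth, ds


class TestFreeFluxParam:
    def test_flux_vectors_satisfy_steady_state(self, net, pfp):
        S, _, rxns = net.stoichiometric_matrix()
        rng = np.random.default_rng(1)
        for _ in range(10):
            theta = rng.uniform(-50, 120, size=pfp.n_free)
            v = pfp.flux_vector(theta)
            assert np.abs(S @ v).max() < 1e-8
            assert v[rxns.index("upt")] == pytest.approx(100.0)

    def test_free_coordinates_round_trip(self, pfp):
        theta = np.array([89.0, 12.0, 10.0, 1.0, 0.0])
        flux = pfp.to_distribution(theta)
        np.testing.assert_allclose(pfp.theta_of(flux), theta, atol=1e-9)

    def test_auto_selection_completes_rank(self, net):
        fixed = biomass_drain_fluxes(0.08, 1.45) | {"upt": 100.0}
        auto = FreeFluxParam(net, fixed)  # no free set supplied
        assert auto.n_free == 5

    def test_sampling_respects_irreversibility(self, pfp):
        from conftest import sample_edemp_fluxes

        rng = np.random.default_rng(2)
        for _ in range(5):
            flux = sample_edemp_fluxes(pfp, rng, min_flux=0.1)
            for rid, v in flux.net.items():
                if not pfp.net.reactions[rid].reversible:
                    floor = 0.0 if rid in pfp.fixed else 0.1
                    assert v >= floor - 1e-9, rid

    def test_inconsistent_fixed_fluxes_rejected(self, net):
        bad = {"upt": 100.0, "xylA": 50.0, "xylB": 80.0}
        with pytest.raises(ValueError, match="inconsistent"):
            FreeFluxParam(net, bad, ["pgi", "ppc", "maeB", "pyc", "fbp"])


class TestFitting:
    def test_mix_toy_recovery_and_determinism(self):
        net, pfp, truth, ds = mix_setup(direct=60.0)
        fits = [fit_fluxes(net, ds, MIX_TRACER, MIX_SPEC, fixed_fluxes={},
                           free_reactions=["direct"], exchange_reactions=[],
                           n_starts=4, seed=7) for _ in range(2)]
        assert fits[0].flux.net["direct"] == pytest.approx(60.0, abs=1e-4)
        # identical seed and inputs -> bit-identical result
        assert fits[0].ssr == fits[1].ssr
        np.testing.assert_array_equal(fits[0].theta, fits[1].theta)

    def test_noisy_recovery_major_fluxes(self, net, spec, tracer, truth,
                                         measured_rates):
        """Median absolute error of major net fluxes (>10% of uptake) stays
        within 3 percentage points over noisy replicates at SD 0.004."""
        major = [r for r, v in truth.net.items()
                 if abs(v) > 10.0 and r != "upt"]
        errors = []
        for seed in range(1, 11):
            ds, _ = generate_mid_dataset(net, truth, tracer, spec,
                                         MidNoiseModel(sd=0.004, seed=seed))
            fit = fit_fluxes(net, ds, tracer, spec,
                             measured_rates=measured_rates, n_starts=4,
                             seed=seed)
            errors.extend(abs(fit.flux.net[r] - truth.net[r]) for r in major)
        assert np.median(errors) <= 3.0


class TestGoodnessOfFit:
    def fit_result(self, ssr, dof):
        from xylflux.core_network import FluxDistribution

        return FitResult(FluxDistribution(net={}), ssr, dof, dof, np.array([]),
                         np.array([]), [], [], 0, None)

    def test_ssr_equal_dof_passes(self):
        assert goodness_of_fit(self.fit_result(20.0, 20)).passed

    def test_zero_ssr_on_noisy_data_flags_fail_low(self):
        g = goodness_of_fit(self.fit_result(0.0, 20))
        assert not g.passed and g.fail_low

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError, match="overparameterized"):
            goodness_of_fit(self.fit_result(1.0, 0))

    def test_chi2_calibration_under_iid_noise(self):
        """When the noise satisfies the chi-square assumptions (Gaussian,
        interior MIDs so clipping never binds), at least 17/20 seeded
        replicates fall inside the 95% acceptance band."""
        passes = 0
        for seed in range(1, 21):
            net, pfp, truth, ds = mix_setup(direct=60.0, noise_sd=0.004,
                                            seed=seed)
            fit = fit_fluxes(net, ds, MIX_TRACER, MIX_SPEC, fixed_fluxes={},
                             free_reactions=["direct"], exchange_reactions=[],
                             n_starts=2, seed=seed)
            passes += goodness_of_fit(fit).passed
        assert passes >= 17


class TestContinuationCI:
    def test_quadratic_profile_matches_curvature(self):
        """On the exactly linear measurement map the continuation interval
        must match +/- 1.96 * SE from the analytic curvature within 5%."""
        net, pfp, truth, ds = mix_setup(direct=60.0, noise_sd=0.002, seed=3)
        fit = fit_fluxes(net, ds, MIX_TRACER, MIX_SPEC, fixed_fluxes={},
                         free_reactions=["direct"], exchange_reactions=[],
                         n_starts=3, seed=3)
        lo, hi, info = confidence_interval_continuation(
            net, ds, MIX_TRACER, MIX_SPEC, fit, "direct", fixed_fluxes={},
            step=0.05, tol=0.001)
        # residuals: 4 points, each with |d sim/d theta| = 1/200 (two routes
        # move two mass fractions each by 1/100 of the flux fraction, split
        # over M1 and M3), weight 1/sd
        sd = np.concatenate([ds["M1"].sd, ds["M3"].sd])
        grads = np.array([-0.01, 0.01, 0.01, -0.01]) / sd
        se = 1.0 / np.sqrt(np.sum(grads ** 2))
        half = 1.96 * se
        assert hi - fit.flux.net["direct"] == pytest.approx(half, rel=0.05)
        assert fit.flux.net["direct"] - lo == pytest.approx(half, rel=0.05)

    def test_unsensed_flux_has_open_interval(self):
        """A drain that no fragment senses is unidentifiable: its profile is
        flat and the interval spans the feasible range."""
        text = MIX_NET + "side: A (abc) -> N (abc)\noutN: N ->\n"
        net = parse_network(text)
        pfp = FreeFluxParam(net, {"upt": 100.0}, ["direct", "side"])
        truth = pfp.to_distribution([50.0, 20.0])
        ds, _ = generate_mid_dataset(net, truth, MIX_TRACER, MIX_SPEC,
                                     MidNoiseModel(sd=0.0))
        fit = fit_fluxes(net, ds, MIX_TRACER, MIX_SPEC, fixed_fluxes={},
                         free_reactions=["direct", "side"],
                         exchange_reactions=[], n_starts=4, seed=5)
        lo, hi, info = confidence_interval_continuation(
            net, ds, MIX_TRACER, MIX_SPEC, fit, "side", fixed_fluxes={},
            step=2.0)
        assert lo == pytest.approx(0.0, abs=0.5)
        assert info["open_lower"]
        assert hi > 90.0

    def test_gnd_ci_excludes_zero_on_recovery_run(self, net, spec, tracer,
                                                  truth, measured_rates,
                                                  noise_free_dataset):
        fit = fit_fluxes(net, noise_free_dataset, tracer, spec,
                         measured_rates=measured_rates, n_starts=4, seed=2)
        lo, hi, _ = confidence_interval_continuation(
            net, noise_free_dataset, tracer, spec, fit, "gnd",
            measured_rates=measured_rates)
        assert lo > 0.0
        assert lo <= truth.net["gnd"] <= hi
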