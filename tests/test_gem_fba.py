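"""Genome-scale model surgery, MFA-derived bounds, FBA, cofactor accounting."""

import json

import numpy as np
import pytest
from importlib.resources import files

import cobra

from xylflux.gem_fba import (BoundEntry, BoundsSpec, added_reaction_imbalances,
                             apply_mfa_bounds, apply_xylose_surgery,
                             cofactor_summary, compare_models,
                             fix_xylose_uptake, load_bigg_json,
                             load_gem_mapping, load_packaged_gem_mapping,
                             solve_fba, write_bigg_json)

MINIMAL_JSON = json.dumps({
    "id": "mini", "version": "1",
    "compartments": {"c": "cytosol", "e": "extracellular"},
    "metabolites": [
        {"id": "a_e", "compartment": "e", "formula": "C1"},
        {"id": "b_c", "compartment": "c", "formula": "C1"},
    ],
    "reactions": [
        {"id": "EX_a_e", "metabolites": {"a_e": -1},
         "lower_bound": -10, "upper_bound": 0, "gene_reaction_rule": ""},
        {"id": "T", "metabolites": {"a_e": -1, "b_c": 1},
         "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": ""},
        {"id": "SINK", "metabolites": {"b_c": -1},
         "lower_bound": 0, "upper_bound": 1000, "gene_reaction_rule": "",
         "objective_coefficient": 1},
    ],
    "genes": [],
})


@pytest.fixture(scope="module")
def toy_gem():
    text = files("xylflux.data").joinpath("toy_gem.json").read_text()
    return load_bigg_json(text)


@pytest.fixture(scope="module")
def cured(toy_gem):
    m = apply_xylose_surgery(toy_gem)
    fix_xylose_uptake(m, 1.45)
    return m


class TestIO:
    def test_minimal_model_shape(self):
        m = load_bigg_json(MINIMAL_JSON)
        assert len(m.metabolites) == 2 and len(m.reactions) == 3
        S = cobra.util.array.create_stoichiometric_matrix(m)
        assert S.shape == (2, 3)

    def test_round_trip_preserves_bounds(self, toy_gem):
        again = load_bigg_json(write_bigg_json(toy_gem))
        for r in toy_gem.reactions:
            assert again.reactions.get_by_id(r.id).bounds == r.bounds

    def test_invalid_json_rejected(self):
        with pytest.raises(ValueError, match="BIGG"):
            load_bigg_json("{not json")


class TestSurgery:
    def test_adds_route_and_removes_gcd(self, toy_gem):
        m = apply_xylose_surgery(toy_gem)
        ids = {r.id for r in m.reactions}
        assert {"EX_xyl__D_e", "XYLtex", "XYLt2pp", "XYLI1", "XYLK"} <= ids
        assert "GCD" not in ids
        assert len(m.reactions) == len(toy_gem.reactions) + 5 - 1

    def test_applying_twice_collides(self, toy_gem):
        once = apply_xylose_surgery(toy_gem)
        with pytest.raises(ValueError, match="collide"):
            apply_xylose_surgery(once, remove_gcd=False)

    def test_missing_cofactors_rejected(self):
        m = load_bigg_json(MINIMAL_JSON)
        with pytest.raises(ValueError, match="lacks required species"):
            apply_xylose_surgery(m, remove_gcd=False)

    def test_added_reactions_elementally_balanced(self, cured):
        for rid, bal in added_reaction_imbalances(cured).items():
            for el, v in bal.items():
                assert v == pytest.approx(0.0, abs=1e-9), (rid, el)

    def test_xyli1_knockout_starves_growth(self, cured):
        m = cured.copy()
        m.reactions.get_by_id("XYLI1").bounds = (0.0, 0.0)
        assert solve_fba(m).status != "optimal"


class TestBounds:
    def test_entry_window(self):
        lo, hi = BoundEntry("x", ("R",), (1,), 50.0, 2.0).bounds()
        assert (lo, hi) == pytest.approx((46.08, 53.92))

    def test_zero_se_fixes_flux(self, cured):
        spec = BoundsSpec([BoundEntry("eff", ("EFF",), (1,), 0.7, 0.0)])
        m = apply_mfa_bounds(cured, spec)
        assert m.reactions.get_by_id("EFF").bounds == pytest.approx((0.7, 0.7))
        sol = solve_fba(m)
        assert sol.fluxes["EFF"] == pytest.approx(0.7, abs=1e-8)

    def test_grouped_constraint_binds_sum(self, cured):
        spec = BoundsSpec([BoundEntry("pair", ("EFF", "BYPASS"), (1, 1),
                                      0.9, 0.05)])
        m = apply_mfa_bounds(cured, spec)
        sol = solve_fba(m, "parsimonious")
        total = sol.fluxes["EFF"] + sol.fluxes["BYPASS"]
        lo, hi = spec.entries[0].bounds()
        assert lo - 1e-6 <= total <= hi + 1e-6

    def test_unknown_reaction_rejected_or_skipped(self, cured):
        spec = BoundsSpec([BoundEntry("x", ("NOPE",), (1,), 1.0, 0.1)])
        with pytest.raises(KeyError):
            apply_mfa_bounds(cured, spec)
        m = apply_mfa_bounds(cured, spec, missing="skip")
        assert "NOPE" not in {r.id for r in m.reactions}

    def test_packaged_mapping_parses(self, fixture_flux):
        mapping = load_packaged_gem_mapping()
        assert mapping["mdh"] == [("MDH", 1), ("MDH2", 1)]
        assert mapping["upt"] == [("EX_xyl__D_e", -1)]
        spec = BoundsSpec.from_flux_distribution(fixture_flux, mapping)
        mdh = next(e for e in spec.entries if e.core_id == "mdh")
        assert mdh.mean_abs == pytest.approx(
            fixture_flux.net["mdh"] * 1.45 / 100.0)


class TestSolve:
    def test_hand_lp_yield(self):
        """A -> B at yield 0.5, uptake capped at 10: objective 5."""
        m = cobra.Model("hand")
        a = cobra.Metabolite("a_c", compartment="c")
        b = cobra.Metabolite("b_c", compartment="c")
        up = cobra.Reaction("UP", lower_bound=0, upper_bound=10)
        up.add_metabolites({a: 1})
        conv = cobra.Reaction("CONV", lower_bound=0, upper_bound=1000)
        conv.add_metabolites({a: -1, b: 0.5})
        bio = cobra.Reaction("BIO", lower_bound=0, upper_bound=1000)
        bio.add_metabolites({b: -1})
        m.add_reactions([up, conv, bio])
        m.objective = "BIO"
        m.solver = "glpk"
        sol = solve_fba(m)
        assert sol.objective == pytest.approx(5.0)

    def test_constraints_never_raise_optimum(self, cured):
        base = solve_fba(cured).objective
        rng = np.random.default_rng(0)
        rids = [r.id for r in cured.reactions if not r.boundary]
        for _ in range(5):
            m = cured.copy()
            rid = rids[rng.integers(len(rids))]
            r = m.reactions.get_by_id(rid)
            lo, hi = r.bounds
            r.bounds = (lo, max(lo, hi * rng.uniform(0.0, 0.5)))
            sol = solve_fba(m)
            if sol.status == "optimal":
                assert sol.objective <= base + 1e-6

    def test_parsimonious_keeps_objective(self, cured):
        plain = solve_fba(cured, "none")
        pars = solve_fba(cured, "parsimonious")
        assert pars.objective == pytest.approx(plain.objective, rel=1e-9)
        # and the pFBA flux vector satisfies S.v = 0 independently of cobra
        S = cobra.util.array.create_stoichiometric_matrix(cured)
        v = pars.fluxes[[r.id for r in cured.reactions]].to_numpy()
        assert np.abs(S @ v).max() < 1e-6


class TestCofactors:
    def make_single_producer(self, flux, sink_flux=None):
        m = cobra.Model("cof")
        nadph = cobra.Metabolite("nadph_c", compartment="c")
        nadh = cobra.Metabolite("nadh_c", compartment="c")
        co2 = cobra.Metabolite("co2_c", compartment="c")
        r = cobra.Reaction("R", lower_bound=-10, upper_bound=10)
        r.add_metabolites({nadph: 1})
        sink = cobra.Reaction("S", lower_bound=-10, upper_bound=10)
        sink.add_metabolites({nadph: -1})
        dummy = cobra.Reaction("D", lower_bound=0, upper_bound=10)
        dummy.add_metabolites({nadh: 1, co2: 1})
        dsink = cobra.Reaction("DS", lower_bound=0, upper_bound=10)
        dsink.add_metabolites({nadh: -1, co2: -1})
        m.add_reactions([r, sink, dummy, dsink])
        m.objective = "R"
        m.solver = "glpk"
        import pandas as pd

        from xylflux.gem_fba import FbaSolution

        sink_flux = flux if sink_flux is None else sink_flux
        fluxes = pd.Series({"R": flux, "S": sink_flux, "D": 0.0, "DS": 0.0})
        return m, FbaSolution(flux, fluxes, "optimal", "none")

    def test_producer_counted(self):
        m, sol = self.make_single_producer(2.0)
        assert cofactor_summary(m, sol)["nadph_sum"] == pytest.approx(2.0)

    def test_consumption_excluded(self):
        m, sol = self.make_single_producer(-2.0, sink_flux=0.0)
        assert cofactor_summary(m, sol)["nadph_sum"] == pytest.approx(0.0)

    def test_missing_species_reports_candidates(self, cured):
        sol = solve_fba(cured)
        with pytest.raises(KeyError, match="NADPH"):
            cofactor_summary(cured, sol, nadph_species=("nadph_x",))


class TestComparison:
    def test_identical_constraints_give_unit_ratios(self, cured):
        report = compare_models(cured, BoundsSpec([]), with_fva=False)
        for key, val in report.ratios.items():
            assert val == pytest.approx(1.0, abs=1e-6), key

    def test_forced_bypass_raises_co2_and_nadph(self, cured):
        """Pinning the decarboxylating bypass open (the Gnd-like wasteful
        route) must raise CO2 loss and NADPH formation relative to the
        growth-optimal solution."""
        spec = BoundsSpec([BoundEntry("bypass", ("BYPASS",), (1,), 0.6, 0.05)])
        report = compare_models(cured, spec)
        assert report.status == "ok"
        assert report.ratios["co2_net"] > 1.0
        assert report.summary_mfa["nadph_sum"] > 0.0
        assert report.ratios["growth"] < 1.0
        assert "co2_mfa" in report.fva_ranges

    def test_infeasible_reported_not_fabricated(self, cured):
        spec = BoundsSpec([BoundEntry("x", ("EFF",), (1,), 50.0, 0.0)])
        report = compare_models(cured, spec, with_fva=False)
        assert report.status != "ok"
        assert np.isnan(report.growth_mfa)
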