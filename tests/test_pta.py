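"""PTA orchestration: grids, combination rule, sensitivity sweep, reporting."""

import numpy as np
import pandas as pd
import pytest

from blipta.library import SCENARIOS, TIER_ORDER
from blipta.metrics import attainment_vector, fraction_above, to_site
from blipta.pta import PTAEngine, ScenarioKey, figure_grid_keys, report
from blipta.simulate import simulate_population_profiles
from blipta.synthetic import make_mixture_population


def key(combo="SYN", comp="BL", ind="cIAI", scen="TRC", tier="EUCAST", mic=1.0):
    return ScenarioKey(
        combination=combo, component=comp, indication=ind,
        scenario=scen, tier=tier, mic=mic,
    )


@pytest.fixture(scope="module")
def syn_grid(engine):
    keys = figure_grid_keys(engine.library, "SYN") + figure_grid_keys(
        engine.library, "SYN2"
    )
    return engine.run_scenario_grid(keys)


class TestComputePta:
    def test_zero_iiv_typical_attainer_gives_100(self, degenerate_library):
        eng = PTAEngine(degenerate_library, n=50, seed=1)
        res = eng.compute_pta(key(combo="REF", ind="bacteraemia", mic=2.0))
        assert res.pta == 100.0
        assert res.ci_high == 100.0

    def test_deterministic_under_seed(self, synlib):
        a = PTAEngine(synlib, n=200, seed=42).compute_pta(key())
        b = PTAEngine(synlib, n=200, seed=42).compute_pta(key())
        assert (a.attained, a.pta) == (b.attained, b.pta)

    def test_ci_brackets_point_estimate(self, engine):
        res = engine.compute_pta(key(mic=4.0))
        assert res.ci_low <= res.pta <= res.ci_high
        assert res.n == engine.n

    def test_mixture_population_pta_recovery(self):
        """Observed PTA of an engineered two-point mixture must fall inside the
        95% binomial CI around the true 78%."""
        pop, fx, true_pta, mask = make_mixture_population(0.78, 5000, seed=13)
        prof = simulate_population_profiles(fx.model, pop, fx.regimen)
        site = to_site(prof, fx.penetration, "ELF")
        values = fraction_above(
            site.time_h, site.conc_mg_per_L, 2.0, site.interval_window
        )
        attained = attainment_vector(values, fx.target, "EUCAST", mic=2.0)
        # the engineered mixture attains exactly on the low-clearance patients
        assert np.array_equal(attained, mask)
        observed = 100.0 * attained.mean()
        se = 100.0 * np.sqrt(0.78 * 0.22 / 5000)
        assert abs(observed - true_pta) < 1.96 * se + 1e-9

    def test_mixture_degenerate_extremes(self):
        for p, expected in ((0.0, 0.0), (1.0, 100.0)):
            pop, fx, true_pta, mask = make_mixture_population(p, 200, seed=3)
            assert true_pta == expected
            assert mask.mean() * 100.0 == expected


class TestCombinationRule:
    def test_trivial_bli_target_gives_equality(self, degenerate_library):
        """When the BLI target is met by every patient, combined PTA equals the
        BL PTA exactly (same draws)."""
        eng = PTAEngine(degenerate_library, n=100, seed=5)
        kb = key(combo="REF", comp="BL", ind="bacteraemia", mic=4.0)
        kc = key(combo="REF", comp="combined", ind="bacteraemia", mic=4.0)
        assert eng.compute_pta(kc).attained == eng.compute_pta(kb).attained

    def test_intersection_bound_on_every_cell(self, syn_grid):
        wide = syn_grid.pivot_table(
            index=["combination", "indication", "scenario", "tier", "mic_mg_per_L"],
            columns="component",
            values="pta_percent",
        )
        assert (wide["combined"] <= wide[["BL", "BLI"]].min(axis=1) + 1e-9).all()


class TestGridOrderings:
    def test_tier_monotonicity(self, syn_grid):
        wide = syn_grid.pivot_table(
            index=["combination", "component", "indication", "scenario", "mic_mg_per_L"],
            columns="tier",
            values="pta_percent",
        )
        assert (wide["EUCAST"] >= wide["Severe"] - 1e-9).all()
        assert (wide["Severe"] >= wide["Aggressive"] - 1e-9).all()

    def test_mic_monotonicity_and_ct_invariance(self, syn_grid, synlib):
        for (combo, comp, ind, scen, tier), sub in syn_grid.groupby(
            ["combination", "component", "indication", "scenario", "tier"]
        ):
            sub = sub.sort_values("mic_mg_per_L")
            ptas = sub["pta_percent"].to_numpy()
            metric = (
                synlib.combination(combo).component(comp).target.metric
                if comp != "combined"
                else None
            )
            if metric == "ft_above_ct":
                assert np.all(ptas == ptas[0]), "C_T targets must be MIC-invariant"
            else:
                assert np.all(np.diff(ptas) <= 1e-9), "PTA must not increase with MIC"

    def test_arc_not_above_trc(self, syn_grid):
        wide = syn_grid.pivot_table(
            index=["combination", "component", "indication", "tier", "mic_mg_per_L"],
            columns="scenario",
            values="pta_percent",
        )
        assert (wide["ARC"] <= wide["TRC"] + 1e-9).all()

    def test_site_ordering_tpr_below_one(self, engine):
        """With TPR <= 1, a tissue site can never outperform unbound plasma."""
        plasma = engine.compute_pta(key(ind="bacteraemia", mic=4.0))
        lung = engine.compute_pta(key(ind="HAP/VAP", mic=4.0))
        assert lung.pta <= plasma.pta + 1e-9


class TestGridStructure:
    def test_cardinality_synthetic(self, syn_grid):
        # SYN: 5 indications (incl. implicit prostatitis) x 2 x 3 x 4 x 3 = 360
        # SYN2: 3 indications, no cUTI hence no prostatitis -> 216
        assert (syn_grid["combination"] == "SYN").sum() == 360
        assert (syn_grid["combination"] == "SYN2").sum() == 216

    def test_empty_grid_rejected(self, engine):
        with pytest.raises(ValueError, match="empty"):
            engine.run_scenario_grid([])

    def test_unknown_penetration_cells_absent(self, reallib):
        keys = figure_grid_keys(reallib, "CET-TAZ")
        prost = [k for k in keys if k.indication == "prostatitis"]
        # ceftolozane prostate is unknown: only the BLI (tazobactam) cells remain
        assert {k.component for k in prost} == {"BLI"}
        assert all(k.component != "combined" for k in prost)


class TestSensitivity:
    def test_base_base_identity(self, engine):
        k = key(comp="BL", ind="cIAI", mic=2.0)
        table = engine.sensitivity_sweep(k)
        base = table[(table.fu_sel == "base") & (table.tpr_sel == "base")]
        assert base["pta_percent"].iloc[0] == engine.compute_pta(k).pta

    def test_monotone_in_bounds(self, engine):
        k = key(comp="BL", ind="cIAI", tier="Severe", mic=4.0)
        table = engine.sensitivity_sweep(k)
        by = {(r.fu_sel, r.tpr_sel): r.pta_percent for r in table.itertuples()}
        assert by[("low", "low")] <= by[("base", "base")] <= by[("high", "high")]
        assert by[("base", "low")] <= by[("base", "high")]

    def test_missing_bounds_warns_and_uses_base(self, engine):
        # synthebactam declares no fu bounds
        k = key(comp="BLI", ind="HAP/VAP", mic=1.0)
        with pytest.warns(UserWarning, match="no fu bounds"):
            table = engine.sensitivity_sweep(k, tpr_selections=("base",))
        assert table["pta_percent"].nunique() == 1

    def test_tazobactam_swap_direction(self, reallib):
        """Swapping in the partner entry's larger peritoneal TPR (0.95 vs 0.79)
        cannot lower tazobactam's intra-abdominal PTA (same draws)."""
        eng = PTAEngine(reallib, n=300, seed=7)
        k = ScenarioKey(
            combination="PIP-TAZ", component="BLI", indication="cIAI",
            scenario="TRC", tier="EUCAST", mic=1.0,
        )
        table = eng.sensitivity_sweep(
            k, fu_selections=("base",), tpr_selections=("base",),
            swap_partner_key="tazobactam_cet",
        )
        own = table[table.tpr_variant == "own"]["pta_percent"].iloc[0]
        swapped = table[table.tpr_variant.str.startswith("swap")]["pta_percent"].iloc[0]
        assert swapped >= own


class TestReport:
    def test_csv_deterministic_and_complete(self, syn_grid, tmp_path):
        p1 = report(syn_grid, tmp_path / "a", stem="grid", plot=False)
        p2 = report(syn_grid, tmp_path / "b", stem="grid", plot=False)
        b1 = p1["csv"].read_bytes()
        assert b1 == p2["csv"].read_bytes()
        assert len(pd.read_csv(p1["csv"])) == len(syn_grid)

    def test_empty_table_errors_without_writing(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            report(pd.DataFrame(), tmp_path, stem="nothing")
        assert not (tmp_path / "nothing.csv").exists()

    def test_plot_file_written(self, syn_grid, tmp_path):
        sub = syn_grid[syn_grid["combination"] == "SYN"]
        paths = report(sub, tmp_path, stem="syn")
        assert paths["plot"].exists() and paths["plot"].stat().st_size > 0
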