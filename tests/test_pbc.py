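"""PBC index algebra, labelling and mode-of-action classification."""
import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from platephen import pbc
from platephen.exceptions import AnalysisError
from platephen.pbc import classify_mode, compute_pbc, export_charts, trait_log2_ratio
from platephen.synthetic import generate_trait_table


class TestTraitLog2Ratio:
    def test_equal_values_are_zero(self):
        assert trait_log2_ratio(0.37, 0.37) == 0.0

    def test_doubling_and_halving_are_antisymmetric(self):
        assert trait_log2_ratio(2.0, 1.0) == 1.0
        assert trait_log2_ratio(0.5, 1.0) == -1.0

    def test_22_percent_greenness_gain(self):
        # a 1.22x GLI ratio is ~ +0.287 log2 units
        assert trait_log2_ratio(1.22 * 0.45, 0.45) == pytest.approx(0.287, abs=0.002)

    def test_nonpositive_values_named_in_error(self):
        with pytest.raises(AnalysisError, match="Put@1.0/growth"):
            trait_log2_ratio(-1.0, 2.0, trait="growth", variant="Put@1.0")


def trait_frame(rows):
    return pd.DataFrame(rows)


def control_row(cond, g=0.02, e=500.0, gr=2000.0, c=0.5):
    return {"compound": "none", "conc_mM": 0.0, "condition": cond,
            "germination": g, "establishment": e, "growth": gr, "color": c}


def variant_row(cond, mult, compound="Put", conc=1.0):
    base = control_row(cond)
    return {"compound": compound, "conc_mM": conc, "condition": cond,
            **{t: base[t] * mult.get(t, 1.0)
               for t in ("germination", "establishment", "growth", "color")}}


class TestComputePBC:
    def test_all_traits_equal_to_control_is_neutral_zero(self):
        df = trait_frame([control_row("control"), variant_row("control", {})])
        out = compute_pbc(df)
        assert out["pbc"][0] == 0.0 and out["label"][0] == "neutral"

    def test_four_doubled_traits_sum_to_four(self):
        mult = {t: 2.0 for t in ("germination", "establishment", "growth", "color")}
        df = trait_frame([control_row("control"), variant_row("control", mult)])
        out = compute_pbc(df)
        assert out["pbc"][0] == pytest.approx(4.0)
        assert out["label"][0] == "biostimulant"

    def test_stress_conditions_sum_three_traits_only(self):
        mult = {t: 2.0 for t in ("germination", "establishment", "growth", "color")}
        df = trait_frame([control_row("NaCl75"), variant_row("NaCl75", mult)])
        out = compute_pbc(df)
        assert out["pbc"][0] == pytest.approx(3.0)  # establishment not summed
        assert np.isnan(out["log2_establishment"][0])

    def test_planted_uniform_growth_effect(self):
        # growth x1.5 in every condition: pbc = log2 1.5 everywhere; with a
        # benefit both with and without stress the rule labels it combined
        rows = []
        for cond in ("control", "NaCl75", "NaCl150"):
            rows += [control_row(cond), variant_row(cond, {"growth": 1.5})]
        out = compute_pbc(trait_frame(rows))
        assert np.allclose(out["pbc"], np.log2(1.5))
        assert (out["mode"] == "combined").all()

    def test_missing_matched_control_rejected(self):
        with pytest.raises(AnalysisError, match="control"):
            compute_pbc(trait_frame([variant_row("control", {})]))


class TestClassifyMode:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ({"control": 2.0, "NaCl75": 2.5, "NaCl150": 3.0}, "combined"),
            ({"control": 0.0, "NaCl150": 1.2}, "stress_alleviator"),
            ({"control": -1.0, "NaCl75": -0.2, "NaCl150": 0.0}, "growth_inhibitor"),
            ({"control": 1.0, "NaCl75": 0.0, "NaCl150": -0.3}, "growth_promotor"),
            ({"control": 0.05, "NaCl75": -0.05}, "none"),
        ],
    )
    def test_rule_table(self, scores, expected):
        assert classify_mode(scores, eps=0.1) == expected

    def test_needs_control_and_a_stress_condition(self):
        with pytest.raises(AnalysisError):
            classify_mode({"control": 1.0})
        with pytest.raises(AnalysisError):
            classify_mode({"NaCl75": 1.0})


class TestAlgebraicProperties:
    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.2, 5.0), min_size=4, max_size=4))
    def test_additivity_over_traits(self, mults):
        traits = ("germination", "establishment", "growth", "color")
        mult = dict(zip(traits, mults))
        df = trait_frame([control_row("control"), variant_row("control", mult)])
        out = compute_pbc(df)
        assert out["pbc"][0] == pytest.approx(sum(np.log2(m) for m in mults), abs=1e-12)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.floats(0.25, 4.0), st.floats(0.25, 4.0))
    def test_swapping_variant_and_control_negates_pbc(self, m1, m2):
        mult = {"growth": m1, "color": m2}
        fwd = compute_pbc(trait_frame([control_row("control"), variant_row("control", mult)]))
        # swap: the variant's values become the control's
        v = variant_row("control", mult)
        c = control_row("control")
        swapped_ctrl = {**v, "compound": "none", "conc_mM": 0.0}
        swapped_var = {**c, "compound": "Put", "conc_mM": 1.0}
        bwd = compute_pbc(trait_frame([swapped_ctrl, swapped_var]))
        assert bwd["pbc"][0] == pytest.approx(-fwd["pbc"][0], abs=1e-12)

    def test_increasing_one_trait_strictly_increases_pbc(self):
        base = compute_pbc(trait_frame(
            [control_row("control"), variant_row("control", {"growth": 1.2})]))
        more = compute_pbc(trait_frame(
            [control_row("control"), variant_row("control", {"growth": 1.3})]))
        assert more["pbc"][0] > base["pbc"][0]


class TestGeneratedTraitTables:
    def test_planted_multipliers_recovered_exactly(self):
        rng = np.random.default_rng(11)
        effects = {}
        for comp in ("Put", "Spd", "Spm", "Pro"):
            for conc in (0.001, 0.01, 0.1, 1.0):
                effects[(comp, conc)] = {
                    t: float(rng.uniform(0.5, 2.0))
                    for t in ("germination", "establishment", "growth", "color")
                }
        traits, expected = generate_trait_table(effects)
        out = compute_pbc(traits)
        merged = out.merge(expected, on=["compound", "conc_mM", "condition"])
        assert len(merged) == 48
        assert np.abs(merged["pbc"] - merged["expected_pbc"]).max() < 1e-12

    def test_neutral_table_gives_all_zero_pbc(self):
        effects = {("Put", 1.0): {}, ("Pro", 0.01): {}}
        traits, _ = generate_trait_table(effects)
        out = compute_pbc(traits)
        assert np.all(out["pbc"] == 0.0)
        assert (out["label"] == "neutral").all()


class TestExportCharts:
    def _records(self):
        rows = []
        for cond in ("control", "NaCl75", "NaCl150"):
            for comp in ("Put", "Spd", "Spm", "Pro"):
                for conc in (0.001, 0.01, 0.1, 1.0):
                    rows.append({control_row(cond)["condition"]: None})  # placeholder
        effects = {(c, k): {"growth": 1.5} for c in ("Put", "Spd", "Spm", "Pro")
                   for k in (0.001, 0.01, 0.1, 1.0)}
        traits, _ = generate_trait_table(effects)
        return compute_pbc(traits)

    def test_radar_shape_and_parallel_coords_round_trip(self, tmp_path):
        records = self._records()
        paths = export_charts(records, tmp_path / "pbc")
        radar = json.loads(paths["radar"].read_text())
        assert set(radar["conditions"]) == {"control", "NaCl75", "NaCl150"}
        for block in radar["conditions"].values():
            assert len(block["axes_conc_mM"]) == 4
            assert len(block["series"]) == 4
            assert all(len(v) == 4 for v in block["series"].values())
        par = pd.read_csv(paths["parallel_coords"])
        merged = par.merge(records, on=["compound", "conc_mM", "condition"],
                           suffixes=("_csv", ""))
        for t in ("germination", "growth", "color"):
            col = merged[[f"log2_{t}_csv", f"log2_{t}"]].dropna()
            assert np.abs(col[f"log2_{t}_csv"] - col[f"log2_{t}"]).max() < 1e-9

    def test_empty_records_rejected(self, tmp_path):
        with pytest.raises(AnalysisError):
            export_charts(pd.DataFrame(), tmp_path / "pbc")
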