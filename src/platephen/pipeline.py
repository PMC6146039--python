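"""End-to-end screening pipeline: synthetic experiment driver and reporting.

Wires all stages together the way a screening run does: a pre-germination
seed scan is counted per well, the MTT absorbance plate is normalised per
seed, the rosette time-lapse yields establishment/growth/colour traits, and
everything funnels into the per-variant trait table and PBC index.  The
synthetic experiment plants known per-trait effect multipliers so the
recovered PBC scores can be checked against their analytic expectation.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, color_indices, germination, pbc, rosette, seed_counter
from .exceptions import ConfigError
from .plate_io import (
    CONDITIONS,
    PlateLayout,
    Treatment,
    TreatmentMap,
    write_results_table,
)
from .synthetic import (
    GrowthScenario,
    MTTScenario,
    SeedScanScenario,
    default_seed_layout,
    generate_mtt_table,
    generate_seed_scan,
    iter_growth_frames,
    plan_growth,
)

__all__ = [
    "design_summary",
    "default_trait_effects",
    "ExperimentScenario",
    "ExperimentResult",
    "run_experiment",
    "analyze_growth_plate",
]

COMPOUNDS = ("Put", "Spd", "Spm", "Pro")
CONCENTRATIONS = (0.001, 0.01, 0.1, 1.0)


# ---------------------------------------------------------------------------
# design arithmetic
# ---------------------------------------------------------------------------

def design_summary(
    n_plates: int = 119,
    wells_per_plate: int = 48,
    plates_per_variant: int = 2,
    sessions_per_day: int = 2,
    n_days: int = 7,
) -> dict[str, int]:
    """Throughput arithmetic of an experimental design.

    With the default large-scale design (119 x 48-well plates, two replicate
    plates per variant, imaging twice daily for a week) this reports 5712
    plants in the run, 96 replicate seedlings per variant and 14 timepoints
    per plant.
    """
    if min(n_plates, wells_per_plate, plates_per_variant, sessions_per_day, n_days) < 1:
        raise ConfigError("design parameters must be positive")
    return {
        "total_plants": n_plates * wells_per_plate,
        "replicate_seedlings_per_variant": plates_per_variant * wells_per_plate,
        "timepoints_per_plant": sessions_per_day * n_days,
    }


# ---------------------------------------------------------------------------
# the stated synthetic world
# ---------------------------------------------------------------------------

def default_trait_effects() -> dict[tuple[str, float], dict[str, dict[str, float]]]:
    """Planted per-variant trait multipliers for the synthetic experiment.

    The pattern mirrors the qualitative screening narrative: Put acts as a
    combined growth promotor and stress alleviator at every concentration,
    Spd similarly but strongest when dilute, Spm promotes growth without
    stress only, and Pro is inhibitory when dilute but alleviates salt
    stress at 1 mM.
    """
    effects: dict[tuple[str, float], dict[str, dict[str, float]]] = {}

    def var(compound, conc, control, nacl75, nacl150):
        effects[(compound, conc)] = {
            "control": control, "NaCl75": nacl75, "NaCl150": nacl150,
        }

    for conc, s in zip(CONCENTRATIONS, (1.00, 1.05, 1.10, 1.15)):
        var("Put", conc,
            {"establishment": 1.25, "growth": 1.45 * s / 1.0, "color": 1.10},
            {"growth": 1.40, "color": 1.12, "germination": 1.10},
            {"growth": 1.45, "color": 1.15, "germination": 1.30})
    for conc, s in zip(CONCENTRATIONS, (1.15, 1.10, 1.05, 1.00)):
        var("Spd", conc,
            {"establishment": 1.20, "growth": 1.30 * s / 1.0, "color": 1.08},
            {"growth": 1.30, "color": 1.10, "germination": 1.05},
            {"growth": 1.30 * s / 1.0, "color": 1.10, "germination": 1.20})
    for conc, s in zip(CONCENTRATIONS, (1.40, 1.35, 1.30, 1.25)):
        var("Spm", conc,
            {"establishment": 1.10, "growth": s, "color": 1.02},
            {"growth": 0.85, "color": 1.0},
            {"growth": 0.85, "color": 1.0})
    var("Pro", 0.001, {"growth": 0.70, "color": 0.97}, {"growth": 0.75}, {"growth": 0.75})
    var("Pro", 0.01, {"growth": 0.75, "color": 0.98}, {"growth": 0.80}, {"growth": 0.80})
    var("Pro", 0.1, {"growth": 1.0}, {"growth": 1.0}, {"growth": 1.05})
    var("Pro", 1.0, {"growth": 0.90},
        {"growth": 1.30, "germination": 1.10}, {"growth": 1.50, "germination": 1.30})
    return effects


def expected_pbc_table(
    effects: Mapping[tuple[str, float], Mapping],
    conditions: Sequence[str] = CONDITIONS,
    eps: float = pbc.DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Analytic PBC expectation (sum of planted log2 multipliers) per variant."""
    from .synthetic import _effect

    rows = []
    for (compound, conc) in effects:
        scores = {}
        for cond in conditions:
            used = pbc.TRAITS_BY_CONDITION[cond]
            scores[cond] = float(sum(
                math.log2(_effect(effects, (compound, conc), cond, t)) for t in used
            ))
        mode = pbc.classify_mode(scores, eps) if "control" in scores and len(scores) > 1 else "none"
        for cond in conditions:
            rows.append({
                "compound": compound, "conc_mM": conc, "condition": cond,
                "expected_pbc": scores[cond], "expected_mode": mode,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# treatment-map construction for the synthetic plates
# ---------------------------------------------------------------------------

def _variant_list() -> list[tuple[str, float]]:
    return [(c, k) for c in COMPOUNDS for k in CONCENTRATIONS]


def _allocate(layout: PlateLayout, condition: str, per_variant: int,
              n_control: int) -> TreatmentMap:
    labels = layout.labels()
    need = n_control + per_variant * len(_variant_list())
    if need != len(labels):
        raise ConfigError(f"allocation {need} does not fill the {len(labels)}-well plate")
    tm = TreatmentMap()
    i = 0
    for _ in range(n_control):
        tm[labels[i]] = Treatment("none", 0.0, condition)
        i += 1
    for comp, conc in _variant_list():
        for _ in range(per_variant):
            tm[labels[i]] = Treatment(comp, conc, condition)
            i += 1
    return tm


# ---------------------------------------------------------------------------
# growth-plate analysis (shared by synthetic and file-based runs)
# ---------------------------------------------------------------------------

def analyze_growth_plate(
    frames,
    treatments: Mapping[str, Treatment] | None = None,
    exg_threshold: float = rosette.DEFAULT_EXG_THRESHOLD,
    min_alive_area: float = rosette.DEFAULT_MIN_ALIVE_AREA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every frame, build per-well series and day-7 colour indices.

    ``frames`` is an iterable of PlateImage ordered by time (a generator is
    fine; frames are processed one at a time).  Returns the growth table and
    the colour-index table of alive plants on the final frame.
    """
    masks_by_well: dict[str, list[rosette.PlantMask]] = {}
    last_image = None
    layout = None
    for image in frames:
        layout = image.layout
        last_image = image
        for well in layout.labels():
            masks_by_well.setdefault(well, []).append(
                rosette.segment_rosette(image, well, exg_threshold)
            )
    if last_image is None:
        raise ConfigError("no frames to analyze")
    series = {
        well: rosette.build_timeseries(
            m, min_alive_area=min_alive_area,
            treatment=(treatments or {}).get(well),
        )
        for well, m in masks_by_well.items()
    }
    growth_df = rosette.growth_table(series)
    index_records = []
    for well, s in series.items():
        if s.status != "alive":
            continue
        rec = color_indices.plant_indices(last_image, masks_by_well[well][-1])
        index_records.append(rec)
    idx_df = color_indices.indices_table(index_records)
    if not idx_df.empty and treatments:
        idx_df["condition"] = [treatments[w].condition for w in idx_df["well"]]
        idx_df["compound"] = [treatments[w].compound for w in idx_df["well"]]
        idx_df["conc_mM"] = [treatments[w].conc_mM for w in idx_df["well"]]
    return growth_df, idx_df


# ---------------------------------------------------------------------------
# the synthetic end-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentScenario:
    """Full synthetic screening run: 4 compounds x 4 concentrations x 3
    growth conditions, with one 96-well germination plate and one (two for
    severe stress, after the design's extra replication) 48-well growth
    plate per condition."""

    rng_seed: int = 0
    conditions: Sequence[str] = CONDITIONS
    trait_effects: Mapping = field(default_factory=default_trait_effects)
    #: salt suppresses the metabolic (formazan) signal per seed far more than
    #: it blocks activation outright at 24-48 h; the graded per-seed
    #: suppression carries the condition effect and cancels in the
    #: variant/control ratio
    germination_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"control": 0.98, "NaCl75": 0.96, "NaCl150": 0.94})
    mtt_mu_factor: Mapping[str, float] = field(
        default_factory=lambda: {"control": 1.0, "NaCl75": 0.75, "NaCl150": 0.50})
    mtt_plates_per_condition: int = 2
    mtt_timepoints: Sequence[float] = (24.0, 48.0)
    #: replicate growth plates; severe stress gets one more, mirroring the
    #: design's extra replication against mortality
    growth_plates_per_condition: Mapping[str, int] = field(
        default_factory=lambda: {"control": 2, "NaCl75": 2, "NaCl150": 3})
    a0_noise_sd: float = 0.03
    rate_noise_sd: float = 0.015
    epsilon: float = pbc.DEFAULT_EPSILON
    solidity_threshold: float = seed_counter.DEFAULT_SOLIDITY_THRESHOLD


@dataclass
class ExperimentResult:
    counts: pd.DataFrame
    germination_records: pd.DataFrame
    growth: pd.DataFrame
    indices: pd.DataFrame
    traits: pd.DataFrame
    pbc_records: pd.DataFrame
    expected: pd.DataFrame
    manifest: dict


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_experiment(
    scenario: ExperimentScenario,
    out_dir: str | Path | None = None,
) -> ExperimentResult:
    """Generate the synthetic experiment and run the full analysis chain.

    Per condition: a 96-well seed scan is generated and counted, an MTT
    plate is simulated from the *true* counts and normalised with the
    *estimated* counts, and the 48-well growth plates are rendered and
    analysed.  Variant means feed the trait table; the PBC index and modes
    come out of :func:`platephen.pbc.compute_pbc`.
    """
    seed96 = default_seed_layout()
    layout48 = PlateLayout.plate48()
    effects = scenario.trait_effects
    counts_tables, germ_tables, growth_tables, idx_tables = [], [], [], []
    trait_rows = []
    for ci, cond in enumerate(scenario.conditions):
        # --- germination assay: scans -> counts -> MTT (24 h + 48 h) ->
        #     per-seed records pooled across plates and timepoints
        tm96 = _allocate(seed96, cond, per_variant=5, n_control=16)
        mults = {
            w: _effect_of(effects, tm96[w], cond, "germination") for w in seed96.labels()
        }
        germ_frac = {w: scenario.germination_fractions.get(cond, 1.0) for w in seed96.labels()}
        mu_factor = scenario.mtt_mu_factor.get(cond, 1.0)
        cond_records = []
        for rep in range(scenario.mtt_plates_per_condition):
            scan_scn = SeedScanScenario(
                rng_seed=_sub_seed(scenario.rng_seed, 10 + 10 * ci + rep))
            scan, scan_manifest = generate_seed_scan(scan_scn, seed96)
            counts_df, _detections = seed_counter.count_plate(
                scan, solidity_threshold=scenario.solidity_threshold)
            counts_df["condition"] = cond
            counts_df["plate_id"] = f"scan_{cond}_rep{rep}"
            counts_tables.append(counts_df)
            true_counts = {w: scan_manifest["wells"][w]["n_seeds"] for w in seed96.labels()}
            est_counts = dict(zip(counts_df["well"], counts_df["seed_count"]))
            for tp in scenario.mtt_timepoints:
                base = MTTScenario.at_48h() if tp == 48.0 else MTTScenario()
                mtt_scn = MTTScenario(
                    mu_seed=base.mu_seed * mu_factor, sd_seed=base.sd_seed,
                    timepoint_h=tp,
                    rng_seed=_sub_seed(scenario.rng_seed, 1000 + 100 * ci + 10 * rep + int(tp)))
                plate, _ = generate_mtt_table(
                    mtt_scn, true_counts, signal_multipliers=mults,
                    germination_fractions=germ_frac,
                    plate_id=f"mtt_{cond}_rep{rep}_{tp:g}h")
                cond_records.append(
                    germination.per_seed_absorbance(plate, est_counts, treatments=tm96))
        records = pd.concat(cond_records, ignore_index=True)
        germ_tables.append(records)
        germ_summary = germination.summarize_by_variant(records, by="abs_per_seed")

        # --- growth assay: one or two 48-well plates
        plate_growth, plate_idx = [], []
        for rep in range(scenario.growth_plates_per_condition.get(cond, 1)):
            tm48 = _allocate(layout48, cond, per_variant=2, n_control=16)
            growth_scn = GrowthScenario(
                treatments=tm48,
                trait_effects=effects,
                a0_noise_sd=scenario.a0_noise_sd,
                rate_noise_sd=scenario.rate_noise_sd,
                rng_seed=_sub_seed(scenario.rng_seed, 100 + 10 * ci + rep),
            )
            frames = iter_growth_frames(growth_scn, layout48)
            gdf, idf = analyze_growth_plate(frames, treatments=tm48)
            gdf["plate"] = idf_plate = f"{cond}_rep{rep}"
            if not idf.empty:
                idf["plate"] = idf_plate
            plate_growth.append(gdf)
            plate_idx.append(idf)
        growth_df = pd.concat(plate_growth, ignore_index=True)
        idx_df = pd.concat([d for d in plate_idx if not d.empty], ignore_index=True)
        growth_tables.append(growth_df)
        idx_tables.append(idx_df)

        # --- per-variant trait means for this condition
        for comp, conc in [("none", 0.0)] + _variant_list():
            gsub = germ_summary[
                (germ_summary["compound"] == comp) & (germ_summary["conc_mM"] == conc)
            ]
            alive = growth_df[(growth_df["compound"] == comp)
                              & (growth_df["conc_mM"] == conc)
                              & (growth_df["status"] == "alive")]
            anyrow = growth_df[(growth_df["compound"] == comp)
                               & (growth_df["conc_mM"] == conc)
                               & (growth_df["status"] != "excluded")]
            isub = idx_df[(idx_df["compound"] == comp) & (idx_df["conc_mM"] == conc)] \
                if not idx_df.empty else idx_df
            trait_rows.append({
                "compound": comp, "conc_mM": conc, "condition": cond,
                "germination": float(gsub["mean"].iloc[0]) if len(gsub) else np.nan,
                "establishment": float(anyrow["t0_area_px"].mean()) if len(anyrow) else np.nan,
                "growth": float(alive["final_area_px"].mean()) if len(alive) else np.nan,
                "color": float(isub["gli"].mean()) if len(isub) else np.nan,
            })

    traits = pd.DataFrame(trait_rows)
    pbc_records = pbc.compute_pbc(traits, eps=scenario.epsilon)
    expected = expected_pbc_table(effects, scenario.conditions, scenario.epsilon)
    result = ExperimentResult(
        counts=pd.concat(counts_tables, ignore_index=True),
        germination_records=pd.concat(germ_tables, ignore_index=True),
        growth=pd.concat(growth_tables, ignore_index=True),
        indices=pd.concat(idx_tables, ignore_index=True),
        traits=traits,
        pbc_records=pbc_records,
        expected=expected,
        manifest={
            "software": "platephen",
            "version": __version__,
            "schema_version": 1,
            "rng_seed": scenario.rng_seed,
            "conditions": list(scenario.conditions),
            "epsilon": scenario.epsilon,
        },
    )
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _effect_of(effects, treatment: Treatment, condition: str, trait: str) -> float:
    from .synthetic import _effect

    if treatment.is_control:
        return 1.0
    return _effect(effects, treatment.variant, condition, trait)


def _write_outputs(result: ExperimentResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_results_table(result.counts, out_dir / "counts.csv")
    write_results_table(result.germination_records, out_dir / "germination.csv")
    write_results_table(result.growth, out_dir / "growth.csv")
    write_results_table(result.indices, out_dir / "indices.csv")
    write_results_table(result.traits, out_dir / "traits.csv")
    write_results_table(result.pbc_records, out_dir / "pbc_index.csv")
    pbc.export_charts(result.pbc_records, out_dir / "pbc")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
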