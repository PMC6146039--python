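"""The Plant Biostimulant Characterization (PBC) index.

Each treatment variant (compound x concentration) is compared against the
untreated control grown under the same condition, trait by trait, as a log2
ratio.  Summing the log2 ratios gives a single signed score per variant and
condition: positive = biostimulant, negative = inhibitor.  Under control
conditions four traits enter (germination proxy, seedling establishment
area, growth capacity, leaf-colour GLI); under salt stress the establishment
trait is dropped and three traits are summed, so scores are only compared
within a condition.

The pattern of scores across conditions classifies the mode of action:
a benefit only without stress is a growth promotor, a benefit only under
stress a stress alleviator, both a combined action, and a deficit without
stress an inhibitor.  A dead-zone of +/- epsilon log2 units around zero
keeps labels stable against measurement noise.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ParameterError

__all__ = [
    "PBCRecord",
    "TRAITS_BY_CONDITION",
    "DEFAULT_EPSILON",
    "trait_log2_ratio",
    "compute_pbc",
    "classify_mode",
    "export_charts",
]

DEFAULT_EPSILON = 0.1

TRAITS_BY_CONDITION: dict[str, tuple[str, ...]] = {
    "control": ("germination", "establishment", "growth", "color"),
    "NaCl75": ("germination", "growth", "color"),
    "NaCl150": ("germination", "growth", "color"),
}

MODES = ("growth_promotor", "growth_inhibitor", "stress_alleviator", "combined", "none")


@dataclass
class PBCRecord:
    compound: str
    conc_mM: float
    condition: str
    trait_log2: dict[str, float]
    pbc: float
    label: str  # biostimulant | inhibitor | neutral
    mode: str = "none"


def trait_log2_ratio(variant_value: float, control_value: float,
                     trait: str = "", variant: str = "") -> float:
    """log2(variant / control) for one positive-valued trait."""
    if not (variant_value > 0 and control_value > 0):
        raise AnalysisError(
            f"non-positive trait value for {variant or 'variant'}/{trait or 'trait'}: "
            f"{variant_value!r} vs control {control_value!r}"
        )
    return math.log2(variant_value / control_value)


def _label(pbc: float, eps: float) -> str:
    if pbc > eps:
        return "biostimulant"
    if pbc < -eps:
        return "inhibitor"
    return "neutral"


def classify_mode(pbc_by_condition: Mapping[str, float], eps: float = DEFAULT_EPSILON) -> str:
    """Mode-of-action label from one variant's PBC scores across conditions.

    Requires the control condition plus at least one stress condition.
    Benefit only without stress -> growth promotor; only under stress ->
    stress alleviator; both -> combined; deficit without stress (and no
    stress benefit) -> growth inhibitor; otherwise none.
    """
    if "control" not in pbc_by_condition:
        raise AnalysisError("classify_mode needs a control-condition PBC score")
    stresses = {k: v for k, v in pbc_by_condition.items() if k != "control"}
    if not stresses:
        raise AnalysisError("classify_mode needs at least one stress condition")
    ctrl = pbc_by_condition["control"]
    stress_benefit = any(v > eps for v in stresses.values() if np.isfinite(v))
    if np.isnan(ctrl):
        return "none"
    if ctrl > eps:
        return "combined" if stress_benefit else "growth_promotor"
    if stress_benefit:
        return "stress_alleviator"
    if ctrl < -eps:
        return "growth_inhibitor"
    return "none"


def compute_pbc(
    traits: pd.DataFrame,
    eps: float = DEFAULT_EPSILON,
    control_compound: str = "none",
) -> pd.DataFrame:
    """PBC scores for every variant x condition in a trait table.

    ``traits`` needs columns compound, conc_mM, condition and one column per
    trait named in :data:`TRAITS_BY_CONDITION`; the control row of each
    condition has ``compound == control_compound``.  Missing trait values
    (NaN) propagate to a NaN PBC with a neutral label rather than failing
    the whole table.  Modes are assigned per compound x concentration from
    the across-condition score pattern when a control-condition row exists.
    """
    required = {"compound", "conc_mM", "condition"}
    if not required <= set(traits.columns):
        raise ParameterError(f"trait table needs columns {sorted(required)}")
    records: list[dict] = []
    for cond, grp in traits.groupby("condition", sort=False):
        if cond not in TRAITS_BY_CONDITION:
            raise ParameterError(f"unknown condition {cond!r}")
        used = [t for t in TRAITS_BY_CONDITION[cond] if t in traits.columns]
        if not used:
            raise ParameterError(f"no trait columns found for condition {cond!r}")
        ctrl = grp[grp["compound"] == control_compound]
        if len(ctrl) != 1:
            raise AnalysisError(
                f"condition {cond!r}: need exactly one control row, found {len(ctrl)}"
            )
        ctrl = ctrl.iloc[0]
        for _, row in grp[grp["compound"] != control_compound].iterrows():
            logs: dict[str, float] = {}
            for t in used:
                v, c = row[t], ctrl[t]
                if pd.isna(v) or pd.isna(c):
                    logs[t] = np.nan
                else:
                    logs[t] = trait_log2_ratio(
                        float(v), float(c), trait=t,
                        variant=f"{row['compound']}@{row['conc_mM']}",
                    )
            vals = list(logs.values())
            pbc = float(np.sum(vals)) if not any(np.isnan(v) for v in vals) else np.nan
            records.append({
                "compound": row["compound"],
                "conc_mM": float(row["conc_mM"]),
                "condition": cond,
                **{f"log2_{t}": logs.get(t, np.nan) for t in ("germination", "establishment", "growth", "color")},
                "pbc": pbc,
                "label": _label(pbc, eps) if np.isfinite(pbc) else "neutral",
            })
    out = pd.DataFrame(records)
    if out.empty:
        raise AnalysisError("trait table contains no variant rows")
    # mode of action per compound x concentration across conditions
    modes = {}
    for (comp, conc), grp in out.groupby(["compound", "conc_mM"]):
        scores = dict(zip(grp["condition"], grp["pbc"]))
        if "control" in scores and len(scores) > 1:
            modes[(comp, conc)] = classify_mode(scores, eps)
        else:
            modes[(comp, conc)] = "none"
    out["mode"] = [modes[(c, k)] for c, k in zip(out["compound"], out["conc_mM"])]
    return out


def export_charts(
    records: pd.DataFrame,
    out_prefix: str | Path,
    plot: bool = False,
) -> dict[str, Path]:
    """Write parallel-coordinate CSV and radar-chart JSON (optionally PNGs).

    The parallel-coordinate file has one row per variant x condition and one
    column per trait log2 ratio; the radar file groups PBC scores per
    condition with the concentrations as axes and one series per compound.
    """
    if records.empty:
        raise AnalysisError("no PBC records to export")
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    log_cols = [c for c in records.columns if c.startswith("log2_")]
    par = records[["compound", "conc_mM", "condition"] + log_cols + ["pbc", "label", "mode"]]
    paths["parallel_coords"] = out_prefix.with_name(out_prefix.name + "_parallel_coords.csv")
    par.to_csv(paths["parallel_coords"], index=False, float_format="%.12g")

    radar: dict[str, dict] = {}
    for cond, grp in records.groupby("condition"):
        concs = sorted(grp["conc_mM"].unique())
        series = {}
        for comp, sub in grp.groupby("compound"):
            by_conc = dict(zip(sub["conc_mM"], sub["pbc"]))
            series[comp] = [
                None if not np.isfinite(by_conc.get(c, np.nan)) else float(by_conc[c])
                for c in concs
            ]
        radar[cond] = {"axes_conc_mM": [float(c) for c in concs], "series": series}
    paths["radar"] = out_prefix.with_name(out_prefix.name + "_radar.json")
    with open(paths["radar"], "w") as fh:
        json.dump({"schema_version": 1, "conditions": radar}, fh, indent=2, sort_keys=True)

    if plot:
        paths.update(_render_charts(records, radar, out_prefix))
    return paths


def _render_charts(records: pd.DataFrame, radar: dict, out_prefix: Path) -> dict[str, Path]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths: dict[str, Path] = {}
    log_cols = [c for c in records.columns if c.startswith("log2_")]
    conds = list(records["condition"].unique())
    fig, axes = plt.subplots(1, len(conds), figsize=(4.2 * len(conds), 3.4), squeeze=False)
    for ax, cond in zip(axes[0], conds):
        grp = records[records["condition"] == cond]
        cols = [c for c in log_cols if grp[c].notna().any()]
        for _, row in grp.iterrows():
            ax.plot(range(len(cols)), [row[c] for c in cols], marker="o", alpha=0.6,
                    label=f"{row['compound']} {row['conc_mM']:g} mM")
        ax.axhline(0.0, color="k", lw=0.7)
        ax.set_xticks(range(len(cols)), [c.removeprefix("log2_") for c in cols], rotation=30)
        ax.set_title(cond)
        ax.set_ylabel("log2(variant / control)")
    fig.tight_layout()
    paths["parallel_coords_png"] = out_prefix.with_name(out_prefix.name + "_parallel_coords.png")
    fig.savefig(paths["parallel_coords_png"], dpi=120)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(radar), figsize=(3.8 * len(radar), 3.6),
                             subplot_kw={"projection": "polar"}, squeeze=False)
    for ax, (cond, block) in zip(axes[0], radar.items()):
        concs = block["axes_conc_mM"]
        angles = np.linspace(0, 2 * np.pi, len(concs), endpoint=False)
        for comp, vals in block["series"].items():
            v = [np.nan if x is None else x for x in vals]
            ax.plot(np.concatenate([angles, angles[:1]]), v + v[:1], marker="o", label=comp)
        ax.set_xticks(angles, [f"{c:g}" for c in concs])
        ax.set_title(cond)
    axes[0][-1].legend(loc="upper right", bbox_to_anchor=(1.45, 1.1), fontsize=7)
    fig.tight_layout()
    paths["radar_png"] = out_prefix.with_name(out_prefix.name + "_radar.png")
    fig.savefig(paths["radar_png"], dpi=120)
    plt.close(fig)
    return paths
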