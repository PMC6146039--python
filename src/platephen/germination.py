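"""MTT germination scoring: per-seed absorbance and variant summaries.

The formazan absorbance of a well (A570 - A690) scales with the number of
metabolically active (germinating) seeds it contains, so the per-well reading
confounds germination activity with how many seeds the dispenser happened to
deliver (~21 +/- 5.4 per well, CV ~25 %).  Dividing by the counted seed
number removes that component: the per-seed absorbance is the germination
proxy that variant summaries, calibrations and the PBC index use.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import stats
from .exceptions import AnalysisError, DataAlignmentError
from .plate_io import AbsorbancePlate, Treatment

__all__ = [
    "VariantSummary",
    "GerminationCalibration",
    "per_seed_absorbance",
    "summarize_variant",
    "summarize_by_variant",
    "fit_germination_calibration",
    "compare_to_control",
]


@dataclass(frozen=True)
class VariantSummary:
    treatment: tuple[str, float, str] | None
    n_wells: int
    mean: float
    sd: float
    cv_pct: float


@dataclass(frozen=True)
class GerminationCalibration:
    """Linear map abs_per_seed -> germination rate (%), clamped to [0, 100]."""

    slope: float
    intercept: float
    fit_r2: float

    def predict(self, abs_per_seed) -> np.ndarray:
        return np.clip(self.slope * np.asarray(abs_per_seed, dtype=float) + self.intercept, 0.0, 100.0)


def per_seed_absorbance(
    plate: AbsorbancePlate,
    counts: Mapping[str, int],
    treatments: Mapping[str, Treatment] | None = None,
) -> pd.DataFrame:
    """Per-well net and per-seed absorbance records.

    ``counts`` must cover every well present in the plate.  Wells counted at
    zero seeds get an undefined (NaN) ``abs_per_seed`` and are flagged so
    summaries can exclude them; negative net absorbances are kept but
    flagged.
    """
    missing = sorted(set(plate.wells) - set(counts))
    if missing:
        raise DataAlignmentError(f"no seed counts for wells: {missing}")
    rows = []
    for well in plate.wells:
        n = int(counts[well])
        net = float(plate.a570[well] - plate.a690[well])
        tr = treatments.get(well) if treatments else None
        rows.append({
            "well": well,
            "a570": float(plate.a570[well]),
            "a690": float(plate.a690[well]),
            "net_abs": net,
            "seed_count": n,
            "abs_per_seed": net / n if n >= 1 else np.nan,
            "flag_no_seeds": n == 0,
            "flag_negative": net < 0,
            "timepoint_h": plate.timepoint_h,
            "plate_id": plate.plate_id,
            "compound": tr.compound if tr else "none",
            "conc_mM": tr.conc_mM if tr else 0.0,
            "condition": tr.condition if tr else "control",
        })
    return pd.DataFrame(rows)


def _usable(records: pd.DataFrame, keep_negative: bool) -> pd.DataFrame:
    usable = records[~records["flag_no_seeds"]]
    if not keep_negative:
        usable = usable[~usable["flag_negative"]]
    return usable


def summarize_variant(
    records: pd.DataFrame,
    by: str = "abs_per_seed",
    keep_negative: bool = False,
) -> VariantSummary:
    """Mean / sample SD / CV% of one variant's wells.

    ``by`` selects the summarised quantity (``net_abs`` or ``abs_per_seed``).
    Wells without counted seeds are always excluded; negative net values only
    enter when ``keep_negative`` is set.
    """
    if by not in ("net_abs", "abs_per_seed"):
        raise AnalysisError(f"cannot summarize by {by!r}")
    usable = _usable(records, keep_negative)
    if len(usable) < 2:
        raise AnalysisError(f"variant summary needs >= 2 usable wells, got {len(usable)}")
    mean, sd, cv, n = stats.descriptive(usable[by].to_numpy())
    tr = None
    if {"compound", "conc_mM", "condition"} <= set(records.columns):
        uniq = records[["compound", "conc_mM", "condition"]].drop_duplicates()
        if len(uniq) == 1:
            tr = tuple(uniq.iloc[0])
    return VariantSummary(treatment=tr, n_wells=n, mean=mean, sd=sd, cv_pct=cv)


def summarize_by_variant(
    records: pd.DataFrame,
    by: str = "abs_per_seed",
    keep_negative: bool = False,
) -> pd.DataFrame:
    """One summary row per (compound, conc_mM, condition) group."""
    rows = []
    for key, grp in records.groupby(["compound", "conc_mM", "condition"], sort=True):
        s = summarize_variant(grp, by=by, keep_negative=keep_negative)
        rows.append({"compound": key[0], "conc_mM": key[1], "condition": key[2],
                     "n_wells": s.n_wells, "mean": s.mean, "sd": s.sd, "cv_pct": s.cv_pct})
    return pd.DataFrame(rows)


def fit_germination_calibration(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
) -> GerminationCalibration:
    """OLS fit of observed germination % against per-seed absorbance.

    The calibration coefficients are assay-specific and must be fitted by
    the user from microscopy-scored reference wells; the package ships no
    default constants.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise AnalysisError("calibration needs >= 3 (abs_per_seed, germination %) pairs")
    res = stats.linear_fit(arr[:, 0], arr[:, 1])
    return GerminationCalibration(float(res.slope), float(res.intercept), float(res.rvalue**2))


def compare_to_control(
    records: pd.DataFrame,
    value: str = "abs_per_seed",
    test: str = "kruskal_wallis",
    control_key: tuple[str, float] = ("none", 0.0),
    keep_negative: bool = False,
) -> pd.DataFrame:
    """Per-condition comparison of each variant against the untreated control.

    Runs the omnibus test (Kruskal-Wallis by default, one-way ANOVA with
    Dunn-Sidak by flag) within each growth condition, then the control-vs-
    variant post hoc contrasts with Sidak-adjusted p-values and significance
    flags at 0.05 / 0.01 / 0.001.
    """
    usable = _usable(records, keep_negative)
    out = []
    for cond, grp in usable.groupby("condition"):
        groups = {
            f"{c}@{k}": sub[value].to_numpy()
            for (c, k), sub in grp.groupby(["compound", "conc_mM"])
        }
        ctrl_name = f"{control_key[0]}@{control_key[1]}"
        if ctrl_name not in groups:
            raise AnalysisError(f"no control wells for condition {cond!r}")
        if len(groups) < 2:
            continue
        stat, p, post = stats.group_comparison(groups, test=test, control=ctrl_name)
        post = post.copy()
        post.insert(0, "condition", cond)
        post["omnibus_stat"] = stat
        post["omnibus_p"] = p
        out.append(post)
    if not out:
        raise AnalysisError("no conditions with both control and variant wells")
    return pd.concat(out, ignore_index=True)
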