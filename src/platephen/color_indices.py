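"""RGB vegetation indices over rosette masks: NGRDI, GLI and VARI.

Per-pixel definitions on [0, 1] channels:

    NGRDI = (G - R) / (G + R)
    GLI   = (2G - R - B) / (2G + R + B)
    VARI  = (G - R) / (G + R - B)

All three are ratios of channel differences, hence invariant to a uniform
brightness rescaling; NGRDI and GLI are bounded in [-1, 1] while VARI has a
singularity at G + R = B.  Singular pixels are excluded from the VARI mean
and tallied rather than clipped.  Aggregation follows pixel -> plant-mean ->
plate-mean-of-plant-means (never pixel-pooled across plants).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import AnalysisError, ParameterError
from .plate_io import PlateImage
from .rosette import PlantMask

__all__ = [
    "ColorIndexRecord",
    "pixel_indices",
    "plant_indices",
    "plate_indices",
    "SINGULARITY_EPS",
]

SINGULARITY_EPS = 1e-9


@dataclass
class ColorIndexRecord:
    well_label: str
    ngrdi: float
    gli: float
    vari: float
    n_pixels: int
    n_undefined_px: int  # pixels excluded from the VARI mean

    @property
    def defined(self) -> bool:
        return self.n_pixels > 0


def _safe_ratio(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.full(np.broadcast(num, den).shape, np.nan)
    ok = np.abs(den) >= SINGULARITY_EPS
    np.divide(num, den, out=out, where=ok)
    return out


def pixel_indices(r, g, b) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised (NGRDI, GLI, VARI) for channels in [0, 1].

    Each index is NaN where its denominator vanishes (|den| < 1e-9): NGRDI
    and GLI only for pure black, VARI whenever G + R = B.
    """
    r = np.asarray(r, dtype=float)
    g = np.asarray(g, dtype=float)
    b = np.asarray(b, dtype=float)
    for name, ch in (("r", r), ("g", g), ("b", b)):
        if ch.size and (float(ch.min()) < 0.0 or float(ch.max()) > 1.0):
            raise ParameterError(f"channel {name} outside [0, 1]")
    ngrdi = _safe_ratio(g - r, g + r)
    gli = _safe_ratio(2 * g - r - b, 2 * g + r + b)
    vari = _safe_ratio(g - r, g + r - b)
    return ngrdi, gli, vari


def plant_indices(image: PlateImage, mask: PlantMask) -> ColorIndexRecord:
    """Mean per-pixel indices over one plant mask.

    An empty mask yields a flagged undefined record (NaN means, zero
    pixels), not an exception, so dead plants flow through reporting.
    """
    patch, _ = image.well_patch(mask.well_label)
    if patch.shape[:2] != mask.mask.shape:
        raise AnalysisError(f"mask shape mismatch for well {mask.well_label}")
    if mask.green_area_px == 0:
        return ColorIndexRecord(mask.well_label, np.nan, np.nan, np.nan, 0, 0)
    r = patch[:, :, 0][mask.mask]
    g = patch[:, :, 1][mask.mask]
    b = patch[:, :, 2][mask.mask]
    ngrdi, gli, vari = pixel_indices(r, g, b)
    n_undef = int(np.isnan(vari).sum())
    vari_mean = float(np.nanmean(vari)) if n_undef < vari.size else np.nan
    return ColorIndexRecord(
        well_label=mask.well_label,
        ngrdi=float(np.nanmean(ngrdi)),
        gli=float(np.nanmean(gli)),
        vari=vari_mean,
        n_pixels=int(mask.green_area_px),
        n_undefined_px=n_undef,
    )


def plate_indices(records: Iterable[ColorIndexRecord]) -> dict[str, float]:
    """Unweighted per-plate mean of plant-level indices.

    Plants enter with equal weight regardless of their pixel count; this is
    deliberately *not* the pixel-pooled mean.
    """
    defined = [rec for rec in records if rec.defined]
    if not defined:
        raise AnalysisError("no defined plant records on this plate")
    return {
        "ngrdi": float(np.mean([rec.ngrdi for rec in defined])),
        "gli": float(np.mean([rec.gli for rec in defined])),
        "vari": float(np.nanmean([rec.vari for rec in defined])),
        "n_plants": len(defined),
    }


def indices_table(records: Iterable[ColorIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "well": rec.well_label,
                "ngrdi": rec.ngrdi,
                "gli": rec.gli,
                "vari": rec.vari,
                "n_pixels": rec.n_pixels,
                "n_undefined_px": rec.n_undefined_px,
            }
            for rec in records
        ]
    )
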