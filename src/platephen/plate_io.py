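"""Plate geometry, image and table I/O.

Defines the well coordinate system shared by every analysis module: a plate is
a regular grid of circular (or square) wells, located in the image by the
centre of well A1 (``origin_px``), the centre-to-centre pitch and the well
radius.  Well labels follow the microplate convention: row letter + 1-based
column number, A1 at the top-left, image row 0 at the top.

Images are normalised to float RGB in [0, 1] on load so that all downstream
index arithmetic is scale free.  Absorbance tables are read from two CSV
dialects: the plate-reader style 8x12 grid (one block per wavelength) and a
long (well, wavelength, value) format.
"""
from __future__ import annotations

import csv
import json
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError, ParameterError

CONDITIONS = ("control", "NaCl75", "NaCl150")

__all__ = [
    "CONDITIONS",
    "PlateLayout",
    "PlateImage",
    "AbsorbancePlate",
    "Treatment",
    "TreatmentMap",
    "read_plate_image",
    "write_plate_image",
    "read_absorbance_csv",
    "write_absorbance_csv",
    "read_results_table",
    "write_results_table",
    "write_run_manifest",
]


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateLayout:
    """Parametric grid of wells on a plate image.

    Parameters
    ----------
    n_rows, n_cols
        Grid shape (8 x 12 for a 96-well plate, 6 x 8 for a 48-well plate).
    origin_px
        (row, col) pixel coordinates of the centre of well A1.
    pitch_px
        Centre-to-centre distance between neighbouring wells, pixels.
    radius_px
        Well radius (circle) or half-width (square), pixels.
    """

    n_rows: int
    n_cols: int
    origin_px: tuple[float, float]
    pitch_px: float
    radius_px: float
    well_shape: str = "circle"
    plate_id: str = "plate"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1 or self.n_rows > 26:
            raise ParameterError(f"invalid grid {self.n_rows}x{self.n_cols}")
        if self.well_shape not in ("circle", "square"):
            raise ParameterError(f"unknown well_shape {self.well_shape!r}")
        if self.radius_px <= 0 or self.pitch_px <= 0:
            raise ParameterError("pitch_px and radius_px must be positive")
        if self.pitch_px < 2 * self.radius_px:
            raise ParameterError(
                "well regions overlap: pitch_px < 2 * radius_px"
            )

    # -- labels ------------------------------------------------------------
    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def labels(self) -> list[str]:
        rows = string.ascii_uppercase[: self.n_rows]
        return [f"{r}{c + 1}" for r in rows for c in range(self.n_cols)]

    def parse_label(self, label: str) -> tuple[int, int]:
        """Return 0-based (row, col) for a label like ``"B11"``."""
        if not label or not label[0].isalpha():
            raise ParameterError(f"bad well label {label!r}")
        row = string.ascii_uppercase.index(label[0].upper())
        try:
            col = int(label[1:]) - 1
        except ValueError as exc:
            raise ParameterError(f"bad well label {label!r}") from exc
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ParameterError(f"well {label!r} outside {self.n_rows}x{self.n_cols} grid")
        return row, col

    def well_center(self, label: str) -> tuple[float, float]:
        row, col = self.parse_label(label)
        return (
            self.origin_px[0] + row * self.pitch_px,
            self.origin_px[1] + col * self.pitch_px,
        )

    @property
    def well_centers(self) -> dict[str, tuple[float, float]]:
        return {lab: self.well_center(lab) for lab in self.labels()}

    # -- pixel regions -----------------------------------------------------
    def well_bbox(self, label: str) -> tuple[int, int, int, int]:
        """Half-open pixel bounding box (r0, r1, c0, c1) of the well region."""
        cr, cc = self.well_center(label)
        r = self.radius_px
        return (
            int(np.floor(cr - r)),
            int(np.ceil(cr + r)) + 1,
            int(np.floor(cc - r)),
            int(np.ceil(cc + r)) + 1,
        )

    def well_mask(self, label: str) -> np.ndarray:
        """Boolean mask of the well region inside :meth:`well_bbox`."""
        r0, r1, c0, c1 = self.well_bbox(label)
        cr, cc = self.well_center(label)
        rr, cc_ = np.ogrid[r0:r1, c0:c1]
        if self.well_shape == "circle":
            return (rr - cr) ** 2 + (cc_ - cc) ** 2 <= self.radius_px**2
        return (np.abs(rr - cr) <= self.radius_px) & (np.abs(cc_ - cc) <= self.radius_px)

    def image_shape(self, margin: int = 8) -> tuple[int, int]:
        """Minimal (rows, cols) image shape that contains every well."""
        h = self.origin_px[0] + (self.n_rows - 1) * self.pitch_px + self.radius_px
        w = self.origin_px[1] + (self.n_cols - 1) * self.pitch_px + self.radius_px
        return int(np.ceil(h)) + margin, int(np.ceil(w)) + margin

    # -- serialisation -----------------------------------------------------
    @classmethod
    def plate96(cls, plate_id: str = "plate96") -> "PlateLayout":
        return cls(8, 12, (58.0, 58.0), 92.0, 40.0, "circle", plate_id)

    @classmethod
    def plate48(cls, plate_id: str = "plate48") -> "PlateLayout":
        return cls(6, 8, (72.0, 72.0), 132.0, 62.0, "circle", plate_id)

    def to_dict(self) -> dict:
        return {
            "rows": self.n_rows,
            "cols": self.n_cols,
            "origin_px": list(self.origin_px),
            "pitch_px": self.pitch_px,
            "radius_px": self.radius_px,
            "well_shape": self.well_shape,
            "plate_id": self.plate_id,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PlateLayout":
        try:
            return cls(
                int(d["rows"]),
                int(d["cols"]),
                tuple(float(v) for v in d["origin_px"]),
                float(d["pitch_px"]),
                float(d["radius_px"]),
                str(d.get("well_shape", "circle")),
                str(d.get("plate_id", "plate")),
            )
        except KeyError as exc:
            raise ConfigError(f"layout config missing key {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "plate" not in doc:
            raise ConfigError(f"{path}: expected a top-level 'plate' mapping")
        return cls.from_dict(doc["plate"])

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"plate": self.to_dict()}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------

@dataclass
class PlateImage:
    """An RGB plate raster with its layout and acquisition time (hours)."""

    pixels: np.ndarray  # (H, W, 3) float in [0, 1]
    timestamp_h: float
    layout: PlateLayout
    source_path: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.pixels)
        if p.ndim != 3 or p.shape[2] != 3:
            raise FormatError("PlateImage requires an (H, W, 3) RGB array")
        if not np.isfinite(self.timestamp_h):
            raise ParameterError("timestamp_h must be finite")
        if p.size and (float(p.min()) < 0.0 or float(p.max()) > 1.0):
            raise FormatError("PlateImage channels must lie in [0, 1]")
        h, w = self.layout.image_shape(margin=0)
        if p.shape[0] < h or p.shape[1] < w:
            raise FormatError(
                f"image {p.shape[:2]} too small for layout needing >= {(h, w)}"
            )
        self.pixels = p

    def well_patch(self, label: str) -> tuple[np.ndarray, np.ndarray]:
        """Return (rgb patch, in-well mask) for one well's bounding box."""
        r0, r1, c0, c1 = self.layout.well_bbox(label)
        return self.pixels[r0:r1, c0:c1], self.layout.well_mask(label)


def _normalise_raster(arr: np.ndarray, path: str) -> np.ndarray:
    if arr.ndim == 2:
        raise FormatError(f"{path}: grayscale image, RGB required")
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(np.float64) / 65535.0
    arr = arr.astype(np.float64)
    if arr.size and (arr.min() < 0 or arr.max() > 1):
        raise FormatError(f"{path}: float image values outside [0, 1]")
    return arr


def read_plate_image(path: str | Path, layout: PlateLayout, timestamp_h: float = 0.0) -> PlateImage:
    """Load a PNG/TIFF plate scan, scaling 8- or 16-bit channels onto [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"image not found: {path}")
    try:
        arr = iio.imread(path)
    except FormatError:
        raise
    except Exception as exc:  # decoding failure
        raise IOError(f"cannot decode image {path}: {exc}") from exc
    return PlateImage(_normalise_raster(np.asarray(arr), str(path)), timestamp_h, layout, str(path))


def write_plate_image(image: PlateImage | np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Write a [0,1] RGB raster as an 8- or 16-bit PNG/TIFF."""
    pix = image.pixels if isinstance(image, PlateImage) else np.asarray(image)
    if bit_depth == 8:
        out = np.round(np.clip(pix, 0, 1) * 255).astype(np.uint8)
    elif bit_depth == 16:
        out = np.round(np.clip(pix, 0, 1) * 65535).astype(np.uint16)
    else:
        raise ParameterError("bit_depth must be 8 or 16")
    iio.imwrite(Path(path), out)


# ---------------------------------------------------------------------------
# absorbance tables
# ---------------------------------------------------------------------------

@dataclass
class AbsorbancePlate:
    """Per-well A570/A690 optical densities for one plate and timepoint."""

    a570: "pd.Series"
    a690: "pd.Series"
    plate_id: str = "plate"
    timepoint_h: float = 24.0

    def __post_init__(self) -> None:
        self.a570 = pd.Series(self.a570, dtype=float)
        self.a690 = pd.Series(self.a690, dtype=float)
        if set(self.a570.index) != set(self.a690.index):
            raise FormatError("a570 and a690 cover different well sets")
        self.a690 = self.a690.reindex(self.a570.index)
        if not np.isfinite(self.a570.to_numpy()).all() or not np.isfinite(self.a690.to_numpy()).all():
            raise FormatError("absorbance values must be finite")

    @property
    def wells(self) -> list[str]:
        return list(self.a570.index)

    @property
    def net(self) -> "pd.Series":
        """Background-corrected absorbance A570 - A690 per well."""
        return self.a570 - self.a690


def _norm_well(label: str) -> str:
    label = label.strip().upper()
    if len(label) < 2 or not label[0].isalpha() or not label[1:].isdigit():
        raise FormatError(f"bad well label {label!r}")
    return f"{label[0]}{int(label[1:])}"


def _read_grid_blocks(rows: list[list[str]], path: str) -> dict[int, dict[str, float]]:
    blocks: dict[int, dict[str, float]] = {}
    i = 0
    while i < len(rows):
        row = [c.strip() for c in rows[i]]
        if row and row[0].lower() == "wavelength":
            wl = int(float(row[1]))
            grid: dict[str, float] = {}
            i += 1
            # optional column-number header line
            if i < len(rows) and rows[i] and not rows[i][0].strip():
                i += 1
            while i < len(rows) and rows[i] and rows[i][0].strip() and rows[i][0].strip().lower() != "wavelength":
                letter = rows[i][0].strip().upper()
                vals = [v for v in rows[i][1:] if v.strip() != ""]
                for j, v in enumerate(vals):
                    grid[f"{letter}{j + 1}"] = float(v)
                i += 1
            blocks[wl] = grid
        else:
            i += 1
    return blocks


def read_absorbance_csv(
    path: str | Path,
    dialect: str = "auto",
    plate_id: str | None = None,
    timepoint_h: float = 24.0,
) -> AbsorbancePlate:
    """Read a dual-wavelength plate-reader CSV.

    ``dialect`` is ``"grid8x12"`` (a block per wavelength introduced by a
    ``wavelength,<nm>`` line, rows A..H x 12 columns), ``"long"``
    (``well,wavelength,value`` rows) or ``"auto"`` (sniff the first line).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"absorbance file not found: {path}")
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh) if any(c.strip() for c in r)]
    if not rows:
        raise FormatError(f"{path}: empty CSV")
    if dialect == "auto":
        head = [c.strip().lower() for c in rows[0]]
        dialect = "grid8x12" if head and head[0] == "wavelength" else "long"

    if dialect == "grid8x12":
        blocks = _read_grid_blocks(rows, str(path))
        if 570 not in blocks or 690 not in blocks:
            raise FormatError(f"{path}: grid dialect needs both 570 and 690 nm blocks")
        a570, a690 = blocks[570], blocks[690]
        if set(a570) != set(a690):
            raise FormatError(f"{path}: 570 and 690 blocks cover different wells")
    elif dialect == "long":
        head = [c.strip().lower() for c in rows[0]]
        try:
            iw, il, iv = head.index("well"), head.index("wavelength"), head.index("value")
        except ValueError as exc:
            raise FormatError(f"{path}: long dialect needs well,wavelength,value columns") from exc
        a570, a690 = {}, {}
        for r in rows[1:]:
            well = _norm_well(r[iw])
            wl = int(float(r[il]))
            target = {570: a570, 690: a690}.get(wl)
            if target is None:
                raise FormatError(f"{path}: unexpected wavelength {wl}")
            if well in target:
                raise FormatError(f"{path}: duplicate reading for well {well} at {wl} nm")
            target[well] = float(r[iv])
        if set(a570) != set(a690):
            missing = sorted(set(a570) ^ set(a690))
            raise FormatError(f"{path}: wells missing one wavelength: {missing}")
        if not a570:
            raise FormatError(f"{path}: no readings")
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")

    order = sorted(a570, key=lambda w: (w[0], int(w[1:])))
    return AbsorbancePlate(
        pd.Series({w: a570[w] for w in order}),
        pd.Series({w: a690[w] for w in order}),
        plate_id=plate_id or path.stem,
        timepoint_h=timepoint_h,
    )


def write_absorbance_csv(plate: AbsorbancePlate, path: str | Path, dialect: str = "long") -> None:
    path = Path(path)
    if dialect == "long":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["well", "wavelength", "value"])
            for well in plate.wells:
                w.writerow([well, 570, repr(float(plate.a570[well]))])
            for well in plate.wells:
                w.writerow([well, 690, repr(float(plate.a690[well]))])
    elif dialect == "grid8x12":
        letters = sorted({w[0] for w in plate.wells})
        ncol = max(int(w[1:]) for w in plate.wells)
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            for wl, series in ((570, plate.a570), (690, plate.a690)):
                w.writerow(["wavelength", wl])
                w.writerow([""] + list(range(1, ncol + 1)))
                for letter in letters:
                    w.writerow([letter] + [repr(float(series[f"{letter}{c}"])) for c in range(1, ncol + 1)])
    else:
        raise ParameterError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# treatments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Treatment:
    """Compound / concentration / growth-condition triple for one well."""

    compound: str = "none"
    conc_mM: float = 0.0
    condition: str = "control"

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ConfigError(
                f"condition {self.condition!r} not one of {CONDITIONS}"
            )

    @property
    def variant(self) -> tuple[str, float]:
        return (self.compound, self.conc_mM)

    @property
    def is_control(self) -> bool:
        return self.compound in ("none", "") or self.conc_mM == 0.0


class TreatmentMap(dict):
    """Mapping well label -> :class:`Treatment`, validated against a layout."""

    @classmethod
    def from_yaml(cls, path: str | Path, layout: PlateLayout | None = None) -> "TreatmentMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict) or "treatments" not in doc:
            raise ConfigError(f"{path}: expected a top-level 'treatments' mapping")
        return cls.from_dict(doc["treatments"], layout)

    @classmethod
    def from_dict(cls, d: Mapping, layout: PlateLayout | None = None) -> "TreatmentMap":
        tm = cls()
        for well, spec in d.items():
            tm[_norm_well(str(well))] = Treatment(
                str(spec.get("compound", "none")),
                float(spec.get("conc_mM", 0.0)),
                str(spec.get("condition", "control")),
            )
        if layout is not None:
            missing = sorted(set(layout.labels()) - set(tm))
            if missing:
                raise ConfigError(f"treatment map missing wells: {missing[:8]}...")
        return tm

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "treatments": {
                w: {"compound": t.compound, "conc_mM": t.conc_mM, "condition": t.condition}
                for w, t in self.items()
            }
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# result tables and manifests
# ---------------------------------------------------------------------------

def write_results_table(records: "pd.DataFrame", path: str | Path) -> None:
    """Write a result table as CSV with a header and >= 9 significant digits."""
    df = pd.DataFrame(records)
    if df.empty:
        raise ParameterError("refusing to write an empty results table")
    df.to_csv(path, index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> "pd.DataFrame":
    return pd.read_csv(path)


def write_run_manifest(path: str | Path, inputs: Mapping, parameters: Mapping, seeds: Mapping | None = None) -> None:
    from . import __version__

    doc = {
        "software": "platephen",
        "version": __version__,
        "schema_version": 1,
        "inputs": dict(inputs),
        "parameters": dict(parameters),
        "seeds": dict(seeds or {}),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True, default=str)
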