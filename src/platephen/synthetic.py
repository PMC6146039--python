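"""Synthetic fixture generators with exact ground truth.

Three data streams are emulated so every analysis stage is testable without
real scans:

* 96-well pre-germination seed scans — seeds as filled ellipses, touching
  pairs/triples forming clusters, with the true per-well count in a manifest;
* dual-wavelength MTT absorbance tables — per-seed formazan signal drawn
  around the cohort defaults (0.019 +/- 0.002 OD/seed at 24 h) plus reader
  noise, with the true per-well signal recorded exactly;
* 48-well rosette time-lapse series — star-convex green blobs whose rendered
  pixel count equals round(A(t)) exactly for an exponential area trajectory
  with day/night rate modulation, stress suppression and optional mortality.

All randomness flows from one ``numpy`` generator per scenario, so identical
``rng_seed`` values give bit-identical images, tables and manifests.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ScenarioError
from .plate_io import (
    CONDITIONS,
    AbsorbancePlate,
    PlateImage,
    PlateLayout,
    Treatment,
    TreatmentMap,
)

__all__ = [
    "SeedScanScenario",
    "MTTScenario",
    "GrowthScenario",
    "generate_seed_scan",
    "generate_mtt_table",
    "generate_growth_images",
    "iter_growth_frames",
    "plan_growth",
    "generate_trait_table",
    "color_for_gli",
    "imaging_times",
]


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _gli(r: float, g: float, b: float) -> float:
    return (2 * g - r - b) / (2 * g + r + b)


def color_for_gli(target: float) -> tuple[float, float, float]:
    """RGB colour (blend yellow-green -> deep green) with the requested GLI.

    Used to plant leaf-colour effect sizes: a uniform-colour rosette has a
    plant-level GLI equal to its pixel GLI, so the planted trait ratio is
    exact.  Valid targets lie in roughly (0.16, 0.76).
    """
    lo = np.array([0.55, 0.50, 0.18])  # stressed yellow-green
    hi = np.array([0.10, 0.75, 0.10])  # healthy deep green
    f = lambda t: _gli(*((1 - t) * lo + t * hi))
    if not (f(0.0) < target < f(1.0)):
        raise ScenarioError(f"GLI target {target:.3f} outside renderable range "
                            f"({f(0.0):.3f}, {f(1.0):.3f})")
    t0, t1 = 0.0, 1.0
    for _ in range(60):
        tm = 0.5 * (t0 + t1)
        if f(tm) < target:
            t0 = tm
        else:
            t1 = tm
    return tuple(float(v) for v in (1 - t0) * lo + t0 * hi)


def imaging_times(sessions: Sequence[float] = (10.0, 16.0), n_days: int = 7) -> np.ndarray:
    """Imaging timestamps in hours with t=0 at the first session of day 1.

    The default schedule (10:00 and 16:00 daily for 7 days) yields 14
    timepoints with alternating 6 h / 18 h intervals.
    """
    first = sessions[0]
    return np.array([24.0 * d + (s - first) for d in range(n_days) for s in sessions])


# ---------------------------------------------------------------------------
# seed scans
# ---------------------------------------------------------------------------

@dataclass
class SeedScanScenario:
    """World description for a pre-germination 96-well plate scan.

    Per-well counts follow the seed-dispensing distribution achieved with a
    multi-step pipette and 0.05 % agarose suspension: Normal(21, 5.4^2),
    truncated at zero and rounded.  A fraction of seeds lands touching a
    neighbour, forming clusters of two or three.
    """

    mean_seeds: float = 21.0
    sd_seeds: float = 5.4
    seed_axes_px: tuple[float, float] = (6.0, 5.0)
    seed_axes_sd: tuple[float, float] = (0.35, 0.30)
    cluster_fraction: float = 0.15
    p_triple: float = 0.2  # cluster size 3 (else 2)
    cluster_gap: tuple[float, float] = (0.95, 0.90)  # pair, triple, x(b_i+b_j)
    seed_color: tuple[float, float, float] = (0.34, 0.23, 0.13)
    background_color: tuple[float, float, float] = (0.83, 0.80, 0.72)
    color_jitter: float = 0.02
    image_noise_sd: float = 0.01
    rng_seed: int = 0


def _ellipse_pixels(cy: float, cx: float, a: float, b: float, theta: float):
    """(rows, cols) integer pixel coordinates covered by an ellipse."""
    ext = max(a, b) + 1.0
    r0, r1 = int(math.floor(cy - ext)), int(math.ceil(cy + ext)) + 1
    c0, c1 = int(math.floor(cx - ext)), int(math.ceil(cx + ext)) + 1
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    u = dx * math.cos(theta) + dy * math.sin(theta)
    v = -dx * math.sin(theta) + dy * math.cos(theta)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _hex_sites(radius: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice points inside a disk of the given radius."""
    dy = spacing * math.sqrt(3) / 2
    pts = []
    n = int(radius / dy) + 1
    for i in range(-n, n + 1):
        y = i * dy
        off = spacing / 2 if i % 2 else 0.0
        m = int(radius / spacing) + 1
        for j in range(-m, m + 1):
            x = j * spacing + off
            if x * x + y * y <= radius * radius:
                pts.append((y, x))
    return np.array(pts) if pts else np.empty((0, 2))


def default_seed_layout(plate_id: str = "seedscan") -> PlateLayout:
    """96-well layout sized for the default synthetic seed-scan geometry."""
    return PlateLayout(8, 12, (75.0, 75.0), 136.0, 67.0, "circle", plate_id)


def generate_seed_scan(
    scenario: SeedScanScenario,
    layout: PlateLayout | None = None,
) -> tuple[PlateImage, dict]:
    """Render a synthetic seed-scan plate and its ground-truth manifest.

    The manifest records the exact number of seeds placed per well (the
    oracle for counting accuracy) and the number of planted clusters.
    """
    if layout is None:
        layout = default_seed_layout()
    a_mu, b_mu = scenario.seed_axes_px
    a_sd, b_sd = scenario.seed_axes_sd
    if 2 * (a_mu + 2 * a_sd) > layout.radius_px:
        raise ScenarioError("seed axes too large for the well radius")
    rng = np.random.default_rng(scenario.rng_seed)
    shape = layout.image_shape()
    img = np.empty(shape + (3,), dtype=np.float64)
    for ch in range(3):
        img[:, :, ch] = scenario.background_color[ch]
    if scenario.image_noise_sd > 0:
        img += rng.normal(0.0, scenario.image_noise_sd, img.shape)

    def draw_axes():
        a = float(np.clip(rng.normal(a_mu, a_sd), a_mu - 2 * a_sd, a_mu + 2 * a_sd))
        b = float(np.clip(rng.normal(b_mu, b_sd), b_mu - 2 * b_sd, b_mu + 2 * b_sd))
        return a, b

    def paint(cy, cx, a, b, theta):
        rr, cc = _ellipse_pixels(cy, cx, a, b, theta)
        col = np.clip(
            np.asarray(scenario.seed_color) + rng.normal(0, scenario.color_jitter, 3),
            0.0, 1.0,
        )
        img[rr, cc] = col

    wells: dict[str, dict] = {}
    spacing = 2 * (a_mu + 2 * a_sd) + 2.6
    for well in layout.labels():
        cy0, cx0 = layout.well_center(well)
        r_place = layout.radius_px - (a_mu + 2 * a_sd) - 2.0
        n = max(0, int(np.floor(rng.normal(scenario.mean_seeds, scenario.sd_seeds) + 0.5)))

        # each seed lands touching a neighbour with prob cluster_fraction;
        # clustered seeds group into pairs (or triples with prob p_triple)
        clusters: list[int] = []
        pool = int(rng.binomial(n, scenario.cluster_fraction)) if n else 0
        while pool >= 2:
            size = 3 if (pool >= 3 and rng.random() < scenario.p_triple) else 2
            clusters.append(size)
            pool -= size
        n_singles = n - sum(clusters)

        placed = 0
        occupied: list[tuple[float, float, float]] = []  # (y, x, keep-out radius)

        # clusters first: chains of ellipses with b-scaled gaps, lobes
        # perpendicular to the chain axis so the waist stays concave
        for size in clusters:
            gap = scenario.cluster_gap[0] if size == 2 else scenario.cluster_gap[1]
            extent = (size - 1) * gap * 2 * b_mu / 2 + a_mu + 2
            for _attempt in range(200):
                rho = math.sqrt(rng.random()) * max(r_place - extent, 1.0)
                ang = rng.random() * 2 * math.pi
                y, x = cy0 + rho * math.sin(ang), cx0 + rho * math.cos(ang)
                if all((y - oy) ** 2 + (x - ox) ** 2 >= (orad + extent) ** 2 for oy, ox, orad in occupied):
                    break
            else:
                raise ScenarioError(f"cannot place cluster in well {well}")
            phi = rng.random() * math.pi
            pos = 0.0
            prev_b = None
            start = (-(size - 1) / 2.0) * gap * 2 * b_mu
            for j in range(size):
                a, b = draw_axes()
                if prev_b is not None:
                    pos += gap * (prev_b + b)
                prev_b = b
                theta = phi + math.pi / 2 + rng.uniform(-0.21, 0.21)
                paint(y + (start + pos) * math.sin(phi), x + (start + pos) * math.cos(phi), a, b, theta)
            occupied.append((y, x, extent))
            placed += size

        # singles on a jittered hexagonal lattice, skipping cluster keep-outs;
        # stragglers fall back to rejection sampling
        sites = _hex_sites(r_place, spacing)
        rng.shuffle(sites)
        single_pts: list[tuple[float, float]] = []

        def place_single(y: float, x: float) -> None:
            a, b = draw_axes()
            paint(y, x, a, b, rng.uniform(0, math.pi))
            single_pts.append((y, x))

        for y_off, x_off in sites:
            if len(single_pts) >= n_singles:
                break
            jy, jx = rng.uniform(-1.0, 1.0, 2)
            y, x = cy0 + y_off + jy, cx0 + x_off + jx
            if any((y - oy) ** 2 + (x - ox) ** 2 < (orad + a_mu + 2) ** 2 for oy, ox, orad in occupied):
                continue
            place_single(y, x)
        attempts = 0
        while len(single_pts) < n_singles and attempts < 4000:
            attempts += 1
            rho = math.sqrt(rng.random()) * r_place
            ang = rng.random() * 2 * math.pi
            y, x = cy0 + rho * math.sin(ang), cx0 + rho * math.cos(ang)
            if any((y - oy) ** 2 + (x - ox) ** 2 < (orad + a_mu + 2) ** 2 for oy, ox, orad in occupied):
                continue
            if any((y - sy) ** 2 + (x - sx) ** 2 < (spacing - 1.0) ** 2 for sy, sx in single_pts):
                continue
            place_single(y, x)
        if len(single_pts) < n_singles:
            raise ScenarioError(
                f"well {well}: could only place {len(single_pts)}/{n_singles} singles"
            )
        placed += n_singles
        wells[well] = {"n_seeds": placed, "n_clusters": len(clusters),
                       "requested": n}

    img = np.clip(img, 0.0, 1.0)
    manifest = {
        "kind": "seed_scan",
        "schema_version": 1,
        "rng_seed": scenario.rng_seed,
        "layout": layout.to_dict(),
        "wells": wells,
        "mean_seed_area_px": math.pi * a_mu * b_mu,
    }
    return PlateImage(img, 0.0, layout, "synthetic"), manifest


# ---------------------------------------------------------------------------
# MTT absorbance
# ---------------------------------------------------------------------------

@dataclass
class MTTScenario:
    """World description for a formazan absorbance plate.

    Each germinated seed contributes an independent Normal(mu_seed,
    sd_seed^2) optical density (defaults are the 24 h cohort values:
    0.019 +/- 0.002 OD per seed; at 48 h use 0.041 +/- 0.003).  The reader
    adds Normal noise with ``reader_noise_sd`` repeatability (0.01 OD, a
    typical microplate-reader figure).  Non-germinated seeds contribute a
    near-zero residual signal.
    """

    mu_seed: float = 0.019
    sd_seed: float = 0.002
    reader_noise_sd: float = 0.01
    baseline_a690: float = 0.06
    baseline_sd: float = 0.004
    germination_fraction: float = 1.0
    nongerm_mu: float = 0.001
    nongerm_sd: float = 0.0005
    timepoint_h: float = 24.0
    rng_seed: int = 0

    @classmethod
    def at_48h(cls, **kw) -> "MTTScenario":
        return cls(mu_seed=0.041, sd_seed=0.003, timepoint_h=48.0, **kw)


def generate_mtt_table(
    scenario: MTTScenario,
    counts: Mapping[str, int],
    signal_multipliers: Mapping[str, float] | None = None,
    germination_fractions: Mapping[str, float] | None = None,
    plate_id: str = "mtt",
) -> tuple[AbsorbancePlate, dict]:
    """Simulate A570/A690 readings for wells with known seed counts.

    ``signal_multipliers`` and ``germination_fractions`` optionally scale the
    per-seed signal / germination probability per well (used to plant
    treatment effects).  The manifest stores the exact summed seed signal per
    well, so ``net_abs = true_signal + reader_noise`` by construction.
    """
    rng = np.random.default_rng(scenario.rng_seed)
    a570, a690, truth = {}, {}, {}
    for well, n in counts.items():
        mult = 1.0 if signal_multipliers is None else float(signal_multipliers.get(well, 1.0))
        germ = (
            scenario.germination_fraction
            if germination_fractions is None
            else float(germination_fractions.get(well, scenario.germination_fraction))
        )
        signal = 0.0
        for _ in range(int(n)):
            if rng.random() < germ:
                signal += rng.normal(scenario.mu_seed * mult, scenario.sd_seed)
            else:
                signal += rng.normal(scenario.nongerm_mu, scenario.nongerm_sd)
        base = scenario.baseline_a690 + (rng.normal(0, scenario.baseline_sd) if scenario.baseline_sd else 0.0)
        noise = rng.normal(0, scenario.reader_noise_sd) if scenario.reader_noise_sd else 0.0
        a690[well] = base
        a570[well] = base + signal + noise
        truth[well] = {"n_seeds": int(n), "true_signal": signal, "reader_noise": noise}
    plate = AbsorbancePlate(pd.Series(a570), pd.Series(a690), plate_id, scenario.timepoint_h)
    manifest = {
        "kind": "mtt",
        "schema_version": 1,
        "rng_seed": scenario.rng_seed,
        "timepoint_h": scenario.timepoint_h,
        "wells": truth,
    }
    return plate, manifest


# ---------------------------------------------------------------------------
# rosette growth time-lapse
# ---------------------------------------------------------------------------

#: suppression of the growth rate by salt stress (multiplies both day and
#: night rates); severe stress roughly halves exponential growth
DEFAULT_STRESS_RATE_FACTOR = {"control": 1.0, "NaCl75": 0.7, "NaCl150": 0.45}
#: per-plant probability of dying during the assay
DEFAULT_MORTALITY = {"control": 0.0, "NaCl75": 0.02, "NaCl150": 0.25}
#: leaf-colour (GLI) attenuation under stress: rosettes yellow as salt rises
DEFAULT_STRESS_GLI_FACTOR = {"control": 1.0, "NaCl75": 0.90, "NaCl150": 0.75}


@dataclass
class GrowthScenario:
    """World description for a 48-well rosette growth time-lapse.

    Plants grow exponentially from ``a0_px`` with a higher rate during the
    day (imaging sessions at 10:00 and 16:00 bracket the high-rate window),
    salt suppresses the rate, and severe stress kills a fraction of plants.
    Planted per-variant trait multipliers (establishment area, final growth
    area, leaf GLI) are stored in the manifest as the recovery oracle.
    """

    a0_px: float = 500.0
    rate_day_per_h: float = 0.010
    rate_night_per_h: float = 0.008
    day_window: tuple[float, float] = (6.0, 18.0)  # clock hours of "day" rate
    sessions: tuple[float, float] = (10.0, 16.0)
    n_days: int = 7
    a0_noise_sd: float = 0.0  # lognormal sigma on A0 per plant
    rate_noise_sd: float = 0.0  # lognormal sigma on the rate per plant
    base_gli: float = 0.55
    stress_rate_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_RATE_FACTOR))
    stress_gli_factor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRESS_GLI_FACTOR))
    mortality: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MORTALITY))
    death_window_h: tuple[float, float] = (24.0, 126.0)
    lobes: int = 5
    lobe_amplitude: float = 0.30
    background_color: tuple[float, float, float] = (0.42, 0.36, 0.30)
    dead_color: tuple[float, float, float] = (0.32, 0.27, 0.20)
    image_noise_sd: float = 0.005
    treatments: Mapping[str, Treatment] | None = None
    #: (compound, conc_mM) -> {trait -> multiplier} or
    #: (compound, conc_mM) -> {condition -> {trait -> multiplier}}
    trait_effects: Mapping | None = None
    rng_seed: int = 0

    def times_h(self) -> np.ndarray:
        return imaging_times(self.sessions, self.n_days)


def _effect(effects: Mapping | None, variant: tuple[str, float], condition: str, trait: str) -> float:
    if not effects or variant not in effects:
        return 1.0
    spec = effects[variant]
    if spec and all(isinstance(v, Mapping) for v in spec.values()):
        spec = spec.get(condition, {})
    return float(spec.get(trait, 1.0))


def _clock(t_h: float, first_session: float) -> float:
    return (first_session + t_h) % 24.0


def _log_growth(scn: GrowthScenario, t0: float, t1: float, rate_day: float, rate_night: float) -> float:
    """Integral of the piecewise day/night rate over [t0, t1] (hours)."""
    total = 0.0
    step = 0.25
    t = t0
    while t < t1 - 1e-9:
        dt = min(step, t1 - t)
        c = _clock(t + dt / 2, scn.sessions[0])
        r = rate_day if scn.day_window[0] <= c < scn.day_window[1] else rate_night
        total += r * dt
        t += dt
    return total


def plan_growth(scenario: GrowthScenario, layout: PlateLayout) -> dict:
    """Draw all per-plant parameters and compute exact area trajectories.

    Deterministic given the scenario seed; rendering frames afterwards adds
    no randomness beyond per-frame image noise (seeded by frame index).
    """
    rng = np.random.default_rng(scenario.rng_seed)
    times = scenario.times_h()
    span = float(times[-1] - times[0])
    treatments = scenario.treatments or {w: Treatment() for w in layout.labels()}
    plants = {}
    for well in layout.labels():
        tr = treatments.get(well)
        if tr is None:
            continue
        cond = tr.condition
        m_est = _effect(scenario.trait_effects, tr.variant, cond, "establishment")
        m_growth = _effect(scenario.trait_effects, tr.variant, cond, "growth")
        m_color = _effect(scenario.trait_effects, tr.variant, cond, "color")
        sf = float(scenario.stress_rate_factor.get(cond, 1.0))
        a0 = scenario.a0_px * m_est
        if scenario.a0_noise_sd > 0:
            a0 *= math.exp(rng.normal(0, scenario.a0_noise_sd))
        rate_day = scenario.rate_day_per_h * sf
        rate_night = scenario.rate_night_per_h * sf
        if scenario.rate_noise_sd > 0:
            jitter = math.exp(rng.normal(0, scenario.rate_noise_sd))
            rate_day *= jitter
            rate_night *= jitter
        # planted growth multiplier acts on the *final* area relative to the
        # same-condition control: shift both rates by a constant
        dr = math.log(m_growth / m_est) / span if span > 0 else 0.0
        rate_day += dr
        rate_night += dr
        gli = scenario.base_gli * float(scenario.stress_gli_factor.get(cond, 1.0)) * m_color
        color = color_for_gli(gli)
        p_die = float(scenario.mortality.get(cond, 0.0))
        death_t = None
        if p_die > 0 and rng.random() < p_die:
            death_t = float(rng.uniform(*scenario.death_window_h))
        areas, areas_exact = [], []
        for t in times:
            if death_t is not None and t >= death_t:
                areas.append(0)
                areas_exact.append(0.0)
            else:
                lg = _log_growth(scenario, times[0], t, rate_day, rate_night)
                exact = a0 * math.exp(lg)
                areas.append(int(round(exact)))
                areas_exact.append(exact)
        plants[well] = {
            "treatment": tr,
            "a0": a0,
            "rate_day": rate_day,
            "rate_night": rate_night,
            "gli": gli,
            "color": color,
            "death_t": death_t,
            "areas": areas,
            "areas_exact": areas_exact,
            "lobe_phase": float(rng.uniform(0, 2 * math.pi)),
            "planted": {"establishment": m_est, "growth": m_growth, "color": m_color},
        }
    return {
        "kind": "growth",
        "schema_version": 1,
        "rng_seed": scenario.rng_seed,
        "times_h": [float(t) for t in times],
        "layout": layout.to_dict(),
        "plants": plants,
    }


def _render_blob(img: np.ndarray, layout: PlateLayout, well: str, n_px: int,
                 color, lobes: int, amp: float, phase: float) -> None:
    if n_px <= 0:
        return
    cy, cx = layout.well_center(well)
    r0, r1, c0, c1 = layout.well_bbox(well)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dy, dx = rr - cy, cc - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    score = dist / (1.0 + amp * np.cos(lobes * theta + phase))
    flat = np.argsort(score, axis=None, kind="stable")[:n_px]
    max_r = dist.ravel()[flat].max()
    if max_r > layout.radius_px - 1.5:
        raise ScenarioError(
            f"plant blob of {n_px} px exceeds well {well} (radius {layout.radius_px})"
        )
    sel_r, sel_c = np.unravel_index(flat, dist.shape)
    img[r0 + sel_r, c0 + sel_c] = color


def iter_growth_frames(scenario: GrowthScenario, layout: PlateLayout,
                       plan: dict | None = None) -> Iterator[PlateImage]:
    """Yield one rendered PlateImage per imaging timepoint (memory-lean)."""
    if plan is None:
        plan = plan_growth(scenario, layout)
    times = plan["times_h"]
    shape = layout.image_shape()
    for i, t in enumerate(times):
        img = np.empty(shape + (3,), dtype=np.float64)
        for ch in range(3):
            img[:, :, ch] = scenario.background_color[ch]
        if scenario.image_noise_sd > 0:
            frame_rng = np.random.default_rng((scenario.rng_seed, 1000 + i))
            img += frame_rng.normal(0, scenario.image_noise_sd, img.shape)
        for well, p in plan["plants"].items():
            if p["death_t"] is not None and t >= p["death_t"]:
                _render_blob(img, layout, well, 14, scenario.dead_color,
                             scenario.lobes, scenario.lobe_amplitude, p["lobe_phase"])
            else:
                _render_blob(img, layout, well, p["areas"][i], p["color"],
                             scenario.lobes, scenario.lobe_amplitude, p["lobe_phase"])
        yield PlateImage(np.clip(img, 0.0, 1.0), float(t), layout, f"synthetic:t={t}")


def generate_growth_images(scenario: GrowthScenario, layout: PlateLayout | None = None
                           ) -> tuple[list[PlateImage], dict]:
    """Materialise the full frame series plus the ground-truth manifest."""
    if layout is None:
        layout = PlateLayout.plate48()
    plan = plan_growth(scenario, layout)
    return list(iter_growth_frames(scenario, layout, plan)), plan


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

#: per-condition baseline trait values for synthetic trait tables: mean
#: abs_per_seed (OD), establishment area (px), final green area (px), GLI
DEFAULT_TRAIT_BASE = {
    "control": {"germination": 0.019, "establishment": 500.0, "growth": 1900.0, "color": 0.55},
    "NaCl75": {"germination": 0.012, "establishment": 500.0, "growth": 1300.0, "color": 0.50},
    "NaCl150": {"germination": 0.006, "establishment": 500.0, "growth": 800.0, "color": 0.41},
}

_TRAITS_BY_CONDITION = {
    "control": ("germination", "establishment", "growth", "color"),
    "NaCl75": ("germination", "growth", "color"),
    "NaCl150": ("germination", "growth", "color"),
}


def generate_trait_table(
    effects: Mapping[tuple[str, float], Mapping],
    conditions: Sequence[str] = CONDITIONS,
    base: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exact trait table from planted multipliers, plus the expected PBC.

    Returns ``(traits, expected)``: one control row per condition plus one
    row per variant x condition with each trait multiplied by its planted
    effect, and the analytically expected PBC (sum of log2 multipliers over
    the traits entering that condition).
    """
    base = base or DEFAULT_TRAIT_BASE
    rows, exp_rows = [], []
    for cond in conditions:
        b = base[cond]
        rows.append({"compound": "none", "conc_mM": 0.0, "condition": cond, **b})
        for (compound, conc), _spec in effects.items():
            mults = {t: _effect(effects, (compound, conc), cond, t) for t in b}
            if any(m <= 0 for m in mults.values()):
                raise ScenarioError("trait multipliers must be positive")
            rows.append({
                "compound": compound, "conc_mM": conc, "condition": cond,
                **{t: b[t] * mults[t] for t in b},
            })
            used = _TRAITS_BY_CONDITION[cond]
            exp_rows.append({
                "compound": compound, "conc_mM": conc, "condition": cond,
                "expected_pbc": float(sum(math.log2(mults[t]) for t in used)),
            })
    return pd.DataFrame(rows), pd.DataFrame(exp_rows)
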