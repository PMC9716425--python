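"""Synthetic RGB-D plate scenes with exact ground truth.

Emulates an overhead depth-camera rig photographing plated foods: a bright
circular plate on a darker table, food items as coloured textured blobs with
slab / dome / granular height profiles, a stack of 10 noisy depth frames per
plate, and progressive-removal intake series. Every scene carries its true
per-class map, volumes and intake fractions, so downstream stages can be
validated without any external imagery.

Conventions
-----------
* Images are (H, W) row-major; depth is in abstract "depth units" converted
  to mm by ``PlateGeometry.depth_scale``; larger depth = farther from camera.
* Class ids are positive integers; 0 is background everywhere.
* Intake removal shrinks an item's footprint (radius scales with sqrt of the
  remaining fraction) while keeping its height profile, the way a plate is
  re-plated with less food; the rendered noiseless height field is rescaled
  so the integrated volume equals fraction x full-portion volume exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .exceptions import PlacementError, UnsupportedSceneError

N_DEPTH_FRAMES = 10
PLATE_RGB = (236, 233, 226)
TABLE_RGB = (62, 60, 66)
TABLE_DROP_UNITS = 50.0  # table surface this many depth units below the plate
_PLACEMENT_MARGIN = 3.0  # px kept free between footprints and the plate rim


@dataclass(frozen=True)
class FoodSpec:
    """One menu item: appearance, height profile, density and nutrition."""

    name: str
    class_id: int
    base_color: tuple  # RGB in [0, 255]
    color_jitter_sd: float  # per-channel SD, uint8 units
    texture_amp: float  # speckle amplitude, uint8 units
    texture_scale: float  # speckle correlation length, px
    height_profile: str  # slab | dome | granular
    peak_height_mm: float
    density_g_ml: float
    full_portion_mass_g: float
    nutrients: dict  # per full portion, keys from nutrients.NUTRIENT_UNITS

    def __post_init__(self):
        if self.density_g_ml <= 0:
            raise ValueError("density must be > 0")
        if self.peak_height_mm <= 0:
            raise ValueError("peak height must be > 0")
        if self.height_profile not in ("slab", "dome", "granular"):
            raise ValueError(f"unknown height profile {self.height_profile!r}")
        if any(v is not None and v < 0 for v in self.nutrients.values()):
            raise ValueError("nutrients must be elementwise >= 0")

    @property
    def full_portion_volume_ml(self) -> float:
        return self.full_portion_mass_g / self.density_g_ml

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["base_color"] = list(self.base_color)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["base_color"] = tuple(d["base_color"])
        return cls(**d)


@dataclass(frozen=True)
class PlateGeometry:
    """Camera/plate calibration for one imaging rig."""

    image_height: int = 480
    image_width: int = 640
    plate_center: tuple = (240.0, 320.0)  # (row, col) px
    plate_radius: float = 220.0  # px
    plate_surface_depth: float = 1000.0  # depth units
    depth_scale: float = 0.5  # mm per depth unit
    pixel_area: float = 1.0 / 3.0  # mm^2 per pixel at the plate plane

    def __post_init__(self):
        cy, cx = self.plate_center
        if not (self.plate_radius <= cy <= self.image_height - self.plate_radius
                and self.plate_radius <= cx <= self.image_width - self.plate_radius):
            raise ValueError("plate circle must fit inside the image")
        if self.depth_scale <= 0 or self.pixel_area <= 0:
            raise ValueError("depth_scale and pixel_area must be > 0")

    def plate_mask(self):
        yy, xx = np.mgrid[: self.image_height, : self.image_width]
        cy, cx = self.plate_center
        return (yy - cy) ** 2 + (xx - cx) ** 2 <= self.plate_radius ** 2

    def to_dict(self):
        d = dataclasses.asdict(self)
        d["plate_center"] = list(self.plate_center)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        d["plate_center"] = tuple(d["plate_center"])
        return cls(**d)


@dataclass
class PlateScene:
    """One imaged plate: RGB, a 10-frame depth stack, and full ground truth."""

    rgb: np.ndarray  # (H, W, 3) uint8
    depth_stack: np.ndarray  # (10, H, W) float32, depth units
    geometry: PlateGeometry
    truth_class_map: np.ndarray  # (H, W) int16, 0 = background
    truth_volumes: dict  # class_id -> mL (noiseless)
    truth_fractions: dict  # class_id -> remaining fraction in [0, 1]
    seed: int
    items: tuple = ()  # FoodSpecs of the meal (diagnostic convenience)
    truth_heights: np.ndarray | None = None  # (H, W) float32 mm, noiseless

    @property
    def truth_food_mask(self):
        return self.truth_class_map > 0


def footprint_radius(spec: FoodSpec, geometry: PlateGeometry) -> float:
    """Full-portion footprint radius (px) implied by volume and profile."""
    v_mm3 = spec.full_portion_volume_ml * 1000.0
    h_eff = spec.peak_height_mm * (0.5 if spec.height_profile == "dome" else 1.0)
    area_px = v_mm3 / (h_eff * geometry.pixel_area)
    return float(np.sqrt(area_px / np.pi))


def generate_food_library(n_foods: int, seed: int,
                          volume_range_ml=(50.0, 250.0),
                          peak_height_range_mm=(12.0, 35.0),
                          density_range=(0.3, 1.1)) -> list:
    """Deterministically generate `n_foods` distinguishable FoodSpecs.

    Hues are evenly spaced around the colour wheel (library is hue-ordered),
    so any stride-sampled subset of the library is well separated in colour.
    Nutrient vectors are drawn from serving-size-plausible ranges.
    """
    if n_foods < 1:
        raise ValueError("n_foods must be >= 1")
    from matplotlib.colors import hsv_to_rgb

    from .nutrients import NUTRIENT_RANGES

    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_foods):
        hue = (i + rng.uniform(-0.25, 0.25)) / n_foods % 1.0
        sat = rng.uniform(0.55, 0.95)
        val = rng.uniform(0.55, 0.95)
        color = tuple(float(c) for c in 255.0 * hsv_to_rgb((hue, sat, val)))
        profile = rng.choice(("slab", "dome", "granular"), p=(0.35, 0.40, 0.25))
        volume = rng.uniform(*volume_range_ml)
        density = rng.uniform(*density_range)
        nutrients = {key: float(np.round(rng.uniform(lo, hi), 3))
                     for key, (lo, hi) in NUTRIENT_RANGES.items()}
        specs.append(FoodSpec(
            name=f"food_{i + 1:03d}",
            class_id=i + 1,
            base_color=color,
            color_jitter_sd=float(rng.uniform(4.0, 10.0)),
            texture_amp=float(rng.uniform(4.0, 14.0)),
            texture_scale=float(rng.uniform(1.5, 4.0)),
            height_profile=str(profile),
            peak_height_mm=float(rng.uniform(*peak_height_range_mm)),
            density_g_ml=float(density),
            full_portion_mass_g=float(volume * density),
            nutrients=nutrients,
        ))
    return specs


def scale_meal_to_plate(meal, geometry, max_fill=0.40):
    """Return copies of the specs with portion volumes shrunk (if needed) so
    total full-portion footprint is at most `max_fill` of the plate area.

    Densities are untouched; masses scale with volumes so density stays
    mass/volume. Returns the meal unchanged when it already fits.
    """
    plate_area = np.pi * geometry.plate_radius ** 2
    total = sum(np.pi * footprint_radius(s, geometry) ** 2 for s in meal)
    if total <= max_fill * plate_area:
        return list(meal)
    shrink = max_fill * plate_area / total
    return [dataclasses.replace(s, full_portion_mass_g=s.full_portion_mass_g * shrink)
            for s in meal]


def place_items(meal, geometry, seed, max_tries=400, max_restarts=25):
    """Rejection-sample non-overlapping footprint centres inside the plate.

    Greedy largest-first placement with a fixed per-item retry cap; a failed
    pass restarts from scratch (crowded plates can paint the first item into
    a corner), up to `max_restarts` passes.
    """
    rng = np.random.default_rng([seed, 1])
    cy, cx = geometry.plate_center
    radii = [footprint_radius(s, geometry) for s in meal]
    order = np.argsort(radii)[::-1]
    for j in order:
        if geometry.plate_radius - radii[j] - _PLACEMENT_MARGIN <= 0:
            raise PlacementError(f"item {meal[j].name} does not fit on the plate")
    for _ in range(max_restarts):
        centers = [None] * len(meal)
        placed = []
        for j in order:
            r = radii[j]
            allowed = geometry.plate_radius - r - _PLACEMENT_MARGIN
            for _ in range(max_tries):
                rad = allowed * np.sqrt(rng.uniform())
                ang = rng.uniform(0, 2 * np.pi)
                c = (cy + rad * np.sin(ang), cx + rad * np.cos(ang))
                if all(np.hypot(c[0] - pc[0], c[1] - pc[1])
                       >= r + pr + _PLACEMENT_MARGIN for pc, pr in placed):
                    centers[j] = c
                    placed.append((c, r))
                    break
            else:
                break  # this pass failed; restart
        else:
            return centers
    raise PlacementError(
        f"could not place {len(meal)} items after {max_restarts} passes")


def _smooth_noise(shape, sigma, rng):
    """Zero-mean, unit-SD smoothed white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def _height_field(spec, r, local_shape, center_local, rng):
    """Noiseless height field (mm) of one item on its bounding-box grid."""
    yy, xx = np.mgrid[: local_shape[0], : local_shape[1]]
    d2 = (yy - center_local[0]) ** 2 + (xx - center_local[1]) ** 2
    inside = d2 <= r * r
    h = np.zeros(local_shape)
    if spec.height_profile == "slab":
        h[inside] = spec.peak_height_mm
    elif spec.height_profile == "dome":
        h[inside] = spec.peak_height_mm * (1.0 - d2[inside] / (r * r))
    else:  # granular: slab + correlated surface roughness
        rough = _smooth_noise(local_shape, 2.0, rng)
        rough -= rough[inside].mean()
        h[inside] = spec.peak_height_mm * np.clip(1.0 + 0.35 * rough[inside], 0.05, None)
    return h, inside


def render_plate(meal, fractions, geometry=None, noise_sd=3.0, seed=0,
                 centers=None) -> PlateScene:
    """Render one plate of `meal` items at the given remaining fractions.

    Each item's noiseless integrated volume equals fraction x full-portion
    volume exactly (the rendered field is rescaled to remove quadrature
    error). Depth frames are the noiseless depth plus i.i.d. Gaussian noise
    of SD `noise_sd` depth units. Deterministic given (inputs, seed).
    """
    geometry = geometry or PlateGeometry()
    fractions = np.asarray(fractions, dtype=float)
    if len(fractions) != len(meal):
        raise ValueError("fractions must match meal length")
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("fractions must lie in [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    ids = [s.class_id for s in meal]
    if len(set(ids)) != len(ids):
        raise ValueError("class_ids must be unique within a meal")
    if centers is None:
        centers = place_items(meal, geometry, seed)

    rng_tex = np.random.default_rng([seed, 2])
    rng_noise = np.random.default_rng([seed, 3])
    h_img, w_img = geometry.image_height, geometry.image_width
    plate = geometry.plate_mask()

    rgb = np.empty((h_img, w_img, 3))
    rgb[...] = TABLE_RGB
    rgb[plate] = PLATE_RGB
    rgb += rng_tex.normal(0.0, 1.5, rgb.shape)

    heights = np.zeros((h_img, w_img))
    class_map = np.zeros((h_img, w_img), dtype=np.int16)
    truth_volumes = {}
    truth_fractions = {}

    for spec, frac, (cy, cx) in zip(meal, fractions, centers):
        truth_fractions[spec.class_id] = float(frac)
        if frac <= 0:
            truth_volumes[spec.class_id] = 0.0
            continue
        r = footprint_radius(spec, geometry) * np.sqrt(frac)
        y0, y1 = int(np.floor(cy - r - 2)), int(np.ceil(cy + r + 3))
        x0, x1 = int(np.floor(cx - r - 2)), int(np.ceil(cx + r + 3))
        box = (slice(max(y0, 0), min(y1, h_img)), slice(max(x0, 0), min(x1, w_img)))
        local_shape = (box[0].stop - box[0].start, box[1].stop - box[1].start)
        center_local = (cy - box[0].start, cx - box[1].start)
        h_loc, inside = _height_field(spec, r, local_shape, center_local, rng_tex)
        target_ml = frac * spec.full_portion_volume_ml
        integral_ml = h_loc.sum() * geometry.pixel_area / 1000.0
        if integral_ml <= 0:
            raise PlacementError(
                f"fraction {frac} of {spec.name} renders to an empty footprint")
        h_loc *= target_ml / integral_ml
        heights[box][inside] = h_loc[inside]
        class_map[box][inside] = spec.class_id
        truth_volumes[spec.class_id] = float(target_ml)

        npx = int(inside.sum())
        speckle = _smooth_noise(local_shape, spec.texture_scale, rng_tex)
        col = (np.asarray(spec.base_color)
               + rng_tex.normal(0.0, spec.color_jitter_sd, (npx, 3))
               + spec.texture_amp * speckle[inside][:, None])
        rgb[box][inside] = col

    rgb = np.clip(rgb, 0, 255).astype(np.uint8)

    depth = np.empty((h_img, w_img))
    depth[...] = geometry.plate_surface_depth + TABLE_DROP_UNITS
    depth[plate] = geometry.plate_surface_depth
    depth -= heights / geometry.depth_scale
    stack = np.broadcast_to(depth, (N_DEPTH_FRAMES, h_img, w_img)).astype(np.float32)
    if noise_sd > 0:
        stack = stack + rng_noise.normal(0.0, noise_sd,
                                         (N_DEPTH_FRAMES, h_img, w_img)).astype(np.float32)
    else:
        stack = stack.copy()

    return PlateScene(
        rgb=rgb,
        depth_stack=stack,
        geometry=geometry,
        truth_class_map=class_map,
        truth_volumes=truth_volumes,
        truth_fractions=truth_fractions,
        seed=int(seed),
        items=tuple(meal),
        truth_heights=heights.astype(np.float32),
    )


RTF_FRACTION_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)


def simulate_intake_series(meal, design, geometry=None, noise_sd=3.0, seed=0,
                           fractions=None) -> list:
    """Progressive-removal intake series.

    design="rtf_permutation": every combination of the 25% fraction grid over
    the meal's items (5**n scenes). design="mtf_steps": a single-item meal
    imaged at a monotone decreasing fraction sequence starting at 1.0
    (default 1.0, 0.75, 0.5, 0.25, 0.0). Item placement is shared across the
    series, as when the same plate is re-plated with less food.
    """
    return list(iter_intake_series(meal, design, geometry, noise_sd, seed, fractions))


def iter_intake_series(meal, design, geometry=None, noise_sd=3.0, seed=0,
                       fractions=None):
    """Generator form of :func:`simulate_intake_series` (memory-friendly)."""
    if len(meal) == 0:
        raise ValueError("meal must contain at least one item")
    geometry = geometry or PlateGeometry()
    centers = place_items(meal, geometry, seed)
    if design == "rtf_permutation":
        grids = np.meshgrid(*([RTF_FRACTION_GRID] * len(meal)), indexing="ij")
        combos = np.stack([g.ravel() for g in grids], axis=-1)
    elif design == "mtf_steps":
        if len(meal) != 1:
            raise ValueError("mtf_steps series are single-item")
        fr = np.asarray(RTF_FRACTION_GRID[::-1] if fractions is None else fractions,
                        dtype=float)
        if fr[0] != 1.0 or np.any(np.diff(fr) >= 0):
            raise ValueError("mtf_steps needs a monotone decreasing sequence from 1.0")
        combos = fr[:, None]
    else:
        raise ValueError(f"unknown design {design!r}")
    for i, combo in enumerate(combos):
        yield render_plate(meal, combo, geometry, noise_sd,
                           seed=series_plate_seed(seed, i), centers=centers)


def series_plate_seed(series_seed: int, index: int) -> int:
    """Per-plate seed within a series (stable, 31-bit)."""
    return (series_seed * 100003 + index) % (2 ** 31)


def naive_pixel_volume(scene: PlateScene, class_id: int) -> float:
    """Pixel-integrated apparent volume (mL) of a class from the noiseless
    height field — what an overhead camera believes it sees."""
    sel = scene.truth_class_map == class_id
    return float(scene.truth_heights[sel].sum() * scene.geometry.pixel_area / 1000.0)


def inject_occlusion(scene: PlateScene, overhang_fraction: float) -> PlateScene:
    """Tilt/stack a rigid slab item so part of its footprint overhangs air.

    The apparent (depth-visible) surface over the overhang is raised by the
    slab height, inflating the naive pixel-integral volume while the true
    volume is unchanged — the overhead-imaging occlusion artifact.
    """
    if not (0 <= overhang_fraction < 1):
        raise ValueError("overhang_fraction must be in [0, 1)")
    slabs = [s for s in scene.items
             if s.height_profile == "slab" and scene.truth_fractions.get(s.class_id, 0) > 0]
    if not slabs:
        raise UnsupportedSceneError("scene has no slab-profile item to occlude")
    spec = slabs[0]
    sel = scene.truth_class_map == spec.class_id
    heights = scene.truth_heights.astype(np.float64).copy()
    stack = scene.depth_stack.copy()
    if overhang_fraction > 0:
        xs = np.nonzero(sel)[1]
        thr = np.quantile(xs, 1.0 - overhang_fraction)
        overhang = sel & (np.arange(scene.rgb.shape[1])[None, :] > thr)
        lift = float(heights[sel].max())
        heights[overhang] += lift
        stack[:, overhang] -= lift / scene.geometry.depth_scale
    return dataclasses.replace(scene, depth_stack=stack,
                               truth_heights=heights.astype(np.float32))


def add_flat_decal(scene: PlateScene, color, center, radius) -> PlateScene:
    """Paint a zero-height coloured disk on the bare plate (RGB only).

    The decal has food-like colour but no depth, so it exercises the
    height-threshold refinement of the segmentation stage. Ground truth is
    untouched: the decal is not food.
    """
    rgb = scene.rgb.astype(float).copy()
    yy, xx = np.mgrid[: rgb.shape[0], : rgb.shape[1]]
    disk = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2)
    disk &= scene.geometry.plate_mask() & (scene.truth_class_map == 0)
    rgb[disk] = color
    return dataclasses.replace(scene, rgb=np.clip(rgb, 0, 255).astype(np.uint8))


# ---------------------------------------------------------------------------
# On-disk scene container: PNGs + JSON per scene, CSV manifest per dataset.

_DEPTH_PNG_SCALE = 16.0  # depth units -> uint16 counts
_HEIGHT_PNG_SCALE = 100.0  # mm -> uint16 counts


def save_scene(scene: PlateScene, path) -> None:
    import imageio.v3 as iio

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path / "rgb.png", scene.rgb)
    for i, frame in enumerate(scene.depth_stack):
        counts = np.clip(np.round(frame * _DEPTH_PNG_SCALE), 0, 65535).astype(np.uint16)
        iio.imwrite(path / f"depth_{i:02d}.png", counts)
    iio.imwrite(path / "truth_class_map.png",
                scene.truth_class_map.astype(np.uint16))
    if scene.truth_heights is not None:
        counts = np.clip(np.round(scene.truth_heights * _HEIGHT_PNG_SCALE),
                         0, 65535).astype(np.uint16)
        iio.imwrite(path / "truth_heights.png", counts)
    meta = {
        "geometry": scene.geometry.to_dict(),
        "truth_volumes": {str(k): v for k, v in scene.truth_volumes.items()},
        "truth_fractions": {str(k): v for k, v in scene.truth_fractions.items()},
        "seed": scene.seed,
        "depth_png_scale": _DEPTH_PNG_SCALE,
        "height_png_scale": _HEIGHT_PNG_SCALE,
        "n_depth_frames": int(scene.depth_stack.shape[0]),
        "items": [s.to_dict() for s in scene.items],
    }
    (path / "scene.json").write_text(json.dumps(meta, indent=1))


def load_scene(path) -> PlateScene:
    import imageio.v3 as iio

    path = Path(path)
    meta = json.loads((path / "scene.json").read_text())
    rgb = iio.imread(path / "rgb.png")
    frames = []
    for i in range(meta["n_depth_frames"]):
        counts = iio.imread(path / f"depth_{i:02d}.png")
        frames.append(counts.astype(np.float32) / meta["depth_png_scale"])
    heights = None
    if (path / "truth_heights.png").exists():
        heights = (iio.imread(path / "truth_heights.png").astype(np.float32)
                   / meta["height_png_scale"])
    return PlateScene(
        rgb=rgb,
        depth_stack=np.stack(frames),
        geometry=PlateGeometry.from_dict(meta["geometry"]),
        truth_class_map=iio.imread(path / "truth_class_map.png").astype(np.int16),
        truth_volumes={int(k): v for k, v in meta["truth_volumes"].items()},
        truth_fractions={int(k): v for k, v in meta["truth_fractions"].items()},
        seed=meta["seed"],
        items=tuple(FoodSpec.from_dict(d) for d in meta["items"]),
        truth_heights=heights,
    )


def save_dataset(scenes, directory) -> "pandas.DataFrame":
    """Write scenes as numbered sub-directories plus a CSV manifest."""
    import pandas as pd

    directory = Path(directory)
    rows = []
    for i, scene in enumerate(scenes):
        name = f"scene_{i:04d}"
        save_scene(scene, directory / name)
        rows.append({
            "scene": name,
            "seed": scene.seed,
            "n_items": int(len(scene.truth_volumes)),
            "total_volume_ml": float(sum(scene.truth_volumes.values())),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
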