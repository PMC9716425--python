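"""Per-class volume integration and differential-volume intake.

Volume of a class is the sum over its labelled pixels of height (mm) x
pixel area (mm^2) / 1000, in mL. Intake is the difference between the
classified full-portion plate and the classified leftover plate, per class;
bulk (class-agnostic) intake uses plate totals. The error metrics match the
reporting convention of depth-imaging intake studies: food-volume error
(signed, = mean error bias), absolute food-volume error, intake error
(signed, = volume intake error), absolute intake error, and 3D percent
(absolute) intake error relative to the full portion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .imaging import HeightMap
from .meal import ClassMap
from .synthetic import PlateGeometry

RESIDUAL_CLASS = -1  # food pixels carrying no class label (external masks)


@dataclass
class VolumeEstimate:
    """Per-class volumes (mL) of one plate; total = sum of classes."""

    volumes: dict  # class_id -> mL (may include RESIDUAL_CLASS)
    pixel_counts: dict = field(default_factory=dict)

    @property
    def total(self) -> float:
        return float(sum(self.volumes.values()))


@dataclass
class ItemIntake:
    class_id: int
    full_ml: float
    leftover_ml: float
    intake_ml: float
    fraction: float | None
    flags: tuple = ()


@dataclass
class IntakeRecord:
    """Differential intake between a full plate and its leftover plate."""

    items: list  # ItemIntake per class
    full_total_ml: float
    leftover_total_ml: float
    # truth (when available) for error metrics
    truth_intake_ml: float | None = None
    truth_full_ml: float | None = None
    truth_leftover_ml: float | None = None
    meal_id: str = ""
    plate_id: str = ""

    @property
    def intake_total_ml(self) -> float:
        return self.full_total_ml - self.leftover_total_ml

    def item(self, class_id) -> ItemIntake:
        return next(it for it in self.items if it.class_id == class_id)


def class_volume(heights: HeightMap, classes, geometry: PlateGeometry,
                 class_id: int) -> float:
    """Integrated volume (mL) of `class_id` over its labelled valid pixels."""
    labels = classes.labels if isinstance(classes, ClassMap) else np.asarray(classes)
    if labels.shape != heights.heights.shape:
        raise ValueError("class map and height map grids are not congruent")
    sel = (labels == class_id) & heights.valid_mask
    if not sel.any():
        warnings.warn(f"class {class_id} absent from the plate", stacklevel=2)
        return 0.0
    return float(heights.heights[sel].sum() * geometry.pixel_area / 1000.0)


def plate_volumes(heights: HeightMap, classes, geometry: PlateGeometry,
                  class_ids, food_mask=None) -> VolumeEstimate:
    """Per-class volumes for a plate; food-mask pixels left unlabelled go to
    a separate residual bucket (possible only with externally supplied masks).
    """
    labels = classes.labels if isinstance(classes, ClassMap) else np.asarray(classes)
    volumes, counts = {}, {}
    for cid in class_ids:
        sel = (labels == cid) & heights.valid_mask
        counts[cid] = int(sel.sum())
        volumes[cid] = float(heights.heights[sel].sum() * geometry.pixel_area / 1000.0)
    if food_mask is not None:
        m = food_mask.mask if hasattr(food_mask, "mask") else np.asarray(food_mask, bool)
        sel = m & (labels == 0) & heights.valid_mask
        if sel.any():
            counts[RESIDUAL_CLASS] = int(sel.sum())
            volumes[RESIDUAL_CLASS] = float(
                heights.heights[sel].sum() * geometry.pixel_area / 1000.0)
    return VolumeEstimate(volumes=volumes, pixel_counts=counts)


UNDEFINED_FRACTION = "undefined_fraction"
FRACTION_OUT_OF_RANGE = "fraction_out_of_range"


def intake(full: VolumeEstimate, leftover: VolumeEstimate) -> IntakeRecord:
    """Differential-volume intake per class, full minus leftover.

    Fractions are intake/full and are NOT clipped: noisy estimates can fall
    outside [0, 1] and are flagged, because signed errors are reported.
    A class with zero full volume but nonzero leftover gets an undefined
    fraction flag.
    """
    if set(full.volumes) - {RESIDUAL_CLASS} != set(leftover.volumes) - {RESIDUAL_CLASS}:
        raise ValueError("full and leftover plates carry different class sets")
    items = []
    for cid in sorted(set(full.volumes) | set(leftover.volumes)):
        v_full = full.volumes.get(cid, 0.0)
        v_left = leftover.volumes.get(cid, 0.0)
        v_in = v_full - v_left
        flags = []
        if v_full > 0:
            frac = v_in / v_full
            if not (0.0 <= frac <= 1.0):
                flags.append(FRACTION_OUT_OF_RANGE)
        else:
            frac = None
            if v_left > 0:
                flags.append(UNDEFINED_FRACTION)
        items.append(ItemIntake(class_id=cid, full_ml=v_full, leftover_ml=v_left,
                                intake_ml=v_in, fraction=frac, flags=tuple(flags)))
    return IntakeRecord(items=items, full_total_ml=full.total,
                        leftover_total_ml=leftover.total)


def intake_report_frame(records) -> "pandas.DataFrame":
    """Per-plate, per-item intake table (not averaged across the plate):
    meal, plate, item, full/leftover/intake mL, fraction, flags."""
    import pandas as pd

    rows = []
    for rec in records:
        for it in rec.items:
            rows.append({
                "meal_id": rec.meal_id,
                "plate_id": rec.plate_id,
                "class_id": it.class_id,
                "full_ml": round(it.full_ml, 1),
                "leftover_ml": round(it.leftover_ml, 1),
                "intake_ml": round(it.intake_ml, 1),
                "fraction": None if it.fraction is None else round(it.fraction, 4),
                "flags": ";".join(it.flags),
            })
    return pd.DataFrame(rows)


def intake_error_metrics(records) -> dict:
    """Bulk intake error metrics over plates, each as (mean, sample SD).

    Per plate (leftover image is the assessed plate):
      food volume error      = V_hat_food - V_food        (signed, mL)
      absolute ...           = |food volume error|
      intake error           = IN_hat - IN                (signed, mL)
      absolute intake error  = |intake error|
      3D % intake error      = 100 * (IN_hat - IN) / V_full
      3D % absolute ...      = |3D % intake error|
    Plates with zero true full volume are excluded with a warning.
    """
    rows = []
    for rec in records:
        if rec.truth_full_ml is None or rec.truth_intake_ml is None:
            raise ValueError("records must carry truth volumes")
        if rec.truth_full_ml <= 0:
            warnings.warn(f"plate {rec.plate_id!r} has zero full volume; excluded",
                          stacklevel=2)
            continue
        fv_err = rec.leftover_total_ml - rec.truth_leftover_ml
        in_err = rec.intake_total_ml - rec.truth_intake_ml
        rows.append((fv_err, abs(fv_err), in_err, abs(in_err),
                     100.0 * in_err / rec.truth_full_ml,
                     abs(100.0 * in_err / rec.truth_full_ml)))
    if not rows:
        raise ValueError("no usable plates")
    arr = np.asarray(rows, dtype=np.float64)
    names = ("food_volume_error_ml", "absolute_food_volume_error_ml",
             "intake_error_ml", "absolute_intake_error_ml",
             "pct_intake_error", "pct_absolute_intake_error")
    out = {"n_plates": int(arr.shape[0])}
    for j, name in enumerate(names):
        sd = float(arr[:, j].std(ddof=1)) if arr.shape[0] > 1 else 0.0
        out[name] = (float(arr[:, j].mean()), sd)
    return out
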