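"""Linking per-item intake fractions to intake of 13 nutrients.

The tracked panel is the one long-term-care stakeholders prioritise:
macronutrients calories, carbohydrates, fats, fiber, protein and
micronutrients calcium, iron, sodium, vitamins B6/C/D/K and zinc. Nutrition
is stored per full portion; intake of an item is its consumed fraction times
the full-portion vector, and plate totals are elementwise sums.

Missing nutrient values (common in nutrition databases, e.g. vitamin D) are
explicit ``None`` entries: they are excluded from totals and surfaced in
``missing``, never silently imputed as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .exceptions import MissingReferenceError

# nutrient key -> unit, in reporting order
NUTRIENT_UNITS = {
    "calories": "kcal",
    "carbohydrates": "g",
    "fats": "g",
    "fiber": "g",
    "protein": "g",
    "calcium": "mg",
    "iron": "mg",
    "sodium": "mg",
    "vitamin_b6": "mg",
    "vitamin_c": "mg",
    "vitamin_d": "ug",
    "vitamin_k": "ug",
    "zinc": "mg",
}
NUTRIENT_KEYS = tuple(NUTRIENT_UNITS)

# plausible per-full-portion ranges used by the synthetic food library
NUTRIENT_RANGES = {
    "calories": (80.0, 350.0),
    "carbohydrates": (0.0, 40.0),
    "fats": (0.0, 20.0),
    "fiber": (0.0, 8.0),
    "protein": (2.0, 25.0),
    "calcium": (20.0, 300.0),
    "iron": (0.5, 4.0),
    "sodium": (50.0, 600.0),
    "vitamin_b6": (0.05, 0.6),
    "vitamin_c": (0.0, 60.0),
    "vitamin_d": (0.0, 5.0),
    "vitamin_k": (1.0, 80.0),
    "zinc": (0.3, 3.0),
}

FRACTION_OUT_OF_RANGE = "fraction_out_of_range"


@dataclass(frozen=True)
class NutrientVector:
    """All 13 nutrients, each a float in its declared unit or None (missing).

    ``flags`` carries quality markers (e.g. an out-of-[0,1] intake fraction
    propagated from the volume pipeline); flagged vectors may hold negative
    values, unflagged ones may not.
    """

    values: dict
    flags: tuple = ()

    def __post_init__(self):
        missing_keys = set(NUTRIENT_KEYS) - set(self.values)
        extra = set(self.values) - set(NUTRIENT_KEYS)
        if missing_keys or extra:
            raise ValueError(f"nutrient keys must be exactly the 13-key panel; "
                             f"missing {sorted(missing_keys)}, extra {sorted(extra)}")
        if not self.flags and any(v is not None and v < 0 for v in self.values.values()):
            raise ValueError("unflagged nutrient values must be >= 0")

    def __getitem__(self, key):
        return self.values[key]

    @property
    def missing(self):
        return tuple(k for k in NUTRIENT_KEYS if self.values[k] is None)

    @classmethod
    def zeros(cls):
        return cls({k: 0.0 for k in NUTRIENT_KEYS})

    def scale(self, factor: float, extra_flags=()) -> "NutrientVector":
        vals = {k: (None if v is None else v * factor) for k, v in self.values.items()}
        return NutrientVector(vals, tuple(self.flags) + tuple(extra_flags))

    def to_dict(self):
        return dict(self.values)


@dataclass(frozen=True)
class PortionRecord:
    """One menu item's full-portion mass/volume/density and nutrition."""

    item: str
    full_portion_mass_g: float
    full_portion_volume_ml: float | None
    density_g_ml: float | None
    nutrients: NutrientVector
    dv_flags: dict = field(default_factory=dict)  # nutrient -> True if source was %DV

    def __post_init__(self):
        if self.full_portion_mass_g <= 0:
            raise ValueError("full portion mass must be > 0")
        if self.full_portion_volume_ml is not None and self.density_g_ml is not None:
            implied = self.full_portion_mass_g / self.full_portion_volume_ml
            if abs(implied - self.density_g_ml) > 1e-6 * max(implied, self.density_g_ml):
                raise ValueError("density inconsistent with mass/volume")


@dataclass(frozen=True)
class ReferenceValues:
    """Per-nutrient daily reference amounts used to convert %DV to absolute."""

    values: dict
    provenance: str = ""

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("reference amounts must be strictly positive")

    @classmethod
    def load_default(cls) -> "ReferenceValues":
        """Editable packaged defaults (data/reference_daily_values.csv).

        DRI-era amounts for adults >70 y, sex-averaged where requirements
        differ, macronutrients from the 2000-kcal label convention. These are
        documented stand-ins, not an authoritative regulatory table; replace
        the CSV for production use.
        """
        import pandas as pd

        path = Path(__file__).parent / "data" / "reference_daily_values.csv"
        df = pd.read_csv(path, comment="#")
        vals = dict(zip(df["nutrient"], df["amount"].astype(float)))
        return cls(vals, provenance=str(path))


def density(mass_g: float, volume_ml: float) -> float:
    """Food density (g/mL) from a full plate's weighed mass and true volume."""
    if volume_ml <= 0:
        raise ValueError("volume must be > 0")
    if mass_g < 0:
        raise ValueError("mass must be >= 0")
    return mass_g / volume_ml


def dv_to_absolute(percent_dv: float, nutrient: str, refs: ReferenceValues) -> float:
    """Convert a percent-daily-value figure to an absolute amount."""
    if nutrient not in refs.values:
        raise MissingReferenceError(nutrient)
    return percent_dv / 100.0 * refs.values[nutrient]


def item_nutrient_intake(fraction: float, portion: PortionRecord) -> NutrientVector:
    """Elementwise fraction x full-portion nutrients.

    Fractions outside [0, 1] (possible with noisy differential volumes) are
    propagated as-is and flagged, since signed errors are reported downstream.
    """
    flags = (FRACTION_OUT_OF_RANGE,) if not (0.0 <= fraction <= 1.0) else ()
    return portion.nutrients.scale(fraction, extra_flags=flags)


def plate_nutrient_totals(items) -> NutrientVector:
    """Sum item intake vectors across a plate (empty plate -> zero vector).

    A nutrient missing in an item is excluded from that nutrient's total; the
    partial total is flagged ``incomplete:<nutrient>`` (or None when every
    item missed it) so reports can surface the gap instead of hiding it.
    """
    totals = {k: 0.0 for k in NUTRIENT_KEYS}
    present = {k: 0 for k in NUTRIENT_KEYS}
    any_missing = set()
    flags = []
    n_items = 0
    for vec in items:
        n_items += 1
        for k in NUTRIENT_KEYS:
            v = vec.values[k]
            if v is None:
                any_missing.add(k)
            else:
                totals[k] += v
                present[k] += 1
        flags.extend(vec.flags)
    vals = {k: (None if (n_items and present[k] == 0 and k in any_missing) else totals[k])
            for k in NUTRIENT_KEYS}
    flags.extend(f"incomplete:{k}" for k in sorted(any_missing))
    return NutrientVector(vals, tuple(dict.fromkeys(flags)))


def unit_suffixed(key: str) -> str:
    return f"{key}_{NUTRIENT_UNITS[key]}"


def write_portion_table(records, path) -> None:
    """Nutrient table CSV: item, mass_g, volume_mL, 13 unit-suffixed nutrient
    columns, and per-nutrient value-kind columns (absolute | percent_dv)."""
    import pandas as pd

    rows = []
    for rec in records:
        row = {
            "item": rec.item,
            "mass_g": rec.full_portion_mass_g,
            "volume_mL": rec.full_portion_volume_ml,
        }
        for k in NUTRIENT_KEYS:
            row[unit_suffixed(k)] = rec.nutrients.values[k]
            row[f"{k}_kind"] = "percent_dv" if rec.dv_flags.get(k) else "absolute"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_portion_table(path, refs: ReferenceValues | None = None):
    """Read a nutrient table CSV; %DV-kind columns are converted to absolute
    amounts via `refs` (required when any column is percent_dv)."""
    import pandas as pd

    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        vals, dv_flags = {}, {}
        for k in NUTRIENT_KEYS:
            raw = row[unit_suffixed(k)]
            kind = row.get(f"{k}_kind", "absolute")
            if pd.isna(raw):
                vals[k] = None
                continue
            if kind == "percent_dv":
                if refs is None:
                    raise MissingReferenceError(k)
                vals[k] = dv_to_absolute(float(raw), k, refs)
                dv_flags[k] = True
            else:
                vals[k] = float(raw)
        volume = None if pd.isna(row["volume_mL"]) else float(row["volume_mL"])
        dens = (float(row["mass_g"]) / volume) if volume else None
        records.append(PortionRecord(
            item=str(row["item"]),
            full_portion_mass_g=float(row["mass_g"]),
            full_portion_volume_ml=volume,
            density_g_ml=dens,
            nutrients=NutrientVector(vals),
            dv_flags=dv_flags,
        ))
    return records


def portion_record_for(spec) -> PortionRecord:
    """PortionRecord for a synthetic FoodSpec (absolute-valued nutrients)."""
    return PortionRecord(
        item=spec.name,
        full_portion_mass_g=spec.full_portion_mass_g,
        full_portion_volume_ml=spec.full_portion_volume_ml,
        density_g_ml=spec.density_g_ml,
        nutrients=NutrientVector({k: spec.nutrients.get(k) for k in NUTRIENT_KEYS}),
    )
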