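"""Crop rotations, per-crop management plans and the yearly event scheduler.

Each farm type carries a 100-entry crop rotation (one entry per 1 % of
area). Every field starts at a seeded random position in its farm's
rotation and advances by one entry per simulation year, so over 100 years
a field grows every entry exactly once and the instantaneous crop shares
match the entry multiplicities on average.

Management plans are ordered event lists with day-of-year windows and
execution probabilities. Scheduling draws each event's day uniformly
inside its window, keeps soil-work/harvest ordering consistent (no harvest
before sowing), and pushes spray applications past rainy days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .landscape import FarmUnit, FieldParcel
from .weather import DAYS_PER_YEAR, WeatherSeries

logger = logging.getLogger(__name__)

ROTATION_LENGTH = 100

EVENT_TYPES = frozenset(
    {
        "plough",
        "harrow",
        "sow",
        "fertilize",
        "insecticide_spray",
        "fungicide_spray",
        "herbicide_spray",
        "harvest",
        "grass_cut",
    }
)
#: events whose within-season order must be non-decreasing in time
ORDERED_TYPES = ("plough", "harrow", "sow", "harvest")
SPRAY_TYPES = ("insecticide_spray", "fungicide_spray", "herbicide_spray")


@dataclass
class ManagementEvent:
    type: str
    window_start_day: int
    window_end_day: int
    probability: float
    product: str | None = None

    def __post_init__(self) -> None:
        if self.type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.type!r}")
        if not 1 <= self.window_start_day <= self.window_end_day <= DAYS_PER_YEAR:
            raise ValueError("event window must be ordered and within the year")
        if not 0 <= self.probability <= 1:
            raise ValueError("probability must be within [0, 1]")


@dataclass
class ManagementPlan:
    crop: str
    events: list[ManagementEvent]


@dataclass
class CropRotation:
    farm_type: str
    entries: list[str]

    def __post_init__(self) -> None:
        if len(self.entries) != ROTATION_LENGTH:
            raise ValueError(f"rotation must hold exactly {ROTATION_LENGTH} entries")

    @classmethod
    def from_shares(cls, farm_type: str, shares: dict[str, int]) -> "CropRotation":
        """Build a rotation from integer per-crop area shares summing to 100."""
        if sum(shares.values()) != ROTATION_LENGTH:
            raise ValueError("crop shares must sum to 100")
        entries: list[str] = []
        for crop, count in shares.items():
            entries.extend([crop] * count)
        return cls(farm_type, entries)

    def crop_at(self, index: int) -> str:
        return self.entries[index % ROTATION_LENGTH]


@dataclass
class ScheduledEvent:
    """A dated management event on one field."""

    field_id: int
    year: int
    day: int            # day-of-year, 1-based
    type: str
    product: str | None = None


@dataclass
class FarmingSystem:
    """Rotations per farm type plus management plans per crop."""

    rotations: dict[str, CropRotation]
    plans: dict[str, ManagementPlan]

    def rotation_for(self, farm_type: str) -> CropRotation:
        try:
            return self.rotations[farm_type]
        except KeyError:
            raise KeyError(f"no rotation configured for farm type {farm_type!r}") from None


def load_farming_system(path: str | None = None) -> FarmingSystem:
    """Load rotations and plans from YAML (packaged defaults if no path)."""
    if path is None:
        text = resources.files("carabsim.data").joinpath("farming_defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    plans = {}
    for crop, entry in raw["crops"].items():
        events = [
            ManagementEvent(
                type=e["type"],
                window_start_day=e["start"],
                window_end_day=e["end"],
                probability=e["probability"],
                product=e.get("product"),
            )
            for e in entry["events"]
        ]
        plans[crop] = ManagementPlan(crop=crop, events=events)
    rotations = {
        ftype: CropRotation.from_shares(ftype, shares)
        for ftype, shares in raw["rotations"].items()
    }
    for rot in rotations.values():
        for crop in set(rot.entries):
            if crop not in plans:
                raise ValueError(f"rotation references crop {crop!r} without a plan")
    return FarmingSystem(rotations=rotations, plans=plans)


def init_rotation_start(parcel: FieldParcel, rng: np.random.Generator) -> FieldParcel:
    """Assign a uniform random starting position in the farm's rotation."""
    parcel.rotation_index = int(rng.integers(0, ROTATION_LENGTH))
    return parcel


def advance_rotation(parcel: FieldParcel) -> FieldParcel:
    """Move to the next rotation entry (cyclic, called at the year end)."""
    parcel.rotation_index = (parcel.rotation_index + 1) % ROTATION_LENGTH
    return parcel


def current_crop(parcel: FieldParcel, farm: FarmUnit, system: FarmingSystem) -> str:
    return system.rotation_for(farm.farm_type).crop_at(parcel.rotation_index)


def schedule_year(
    plan: ManagementPlan,
    year: int,
    weather: WeatherSeries,
    rng: np.random.Generator,
    field_id: int = 0,
    spray_rain_threshold_mm: float = 2.0,
    shift_cap_days: int = 10,
) -> list[ScheduledEvent]:
    """Draw this year's dated events for one field growing ``plan.crop``.

    Each event fires with its probability on a uniform day inside its
    window. Ordered activities (plough/harrow/sow/harvest) never precede an
    earlier ordered activity; an event whose window closes before that
    constraint can be met is dropped (logged). Sprays are shifted forward
    past days with precipitation above the threshold, at most
    ``shift_cap_days`` days past the window end.
    """
    out: list[ScheduledEvent] = []
    min_ordered_day = 1
    precip = weather.precip_mm[weather.year_slice(year)] if year < weather.n_years else None
    for ev in plan.events:
        if rng.random() >= ev.probability:
            continue
        lo, hi = ev.window_start_day, ev.window_end_day
        if ev.type in ORDERED_TYPES:
            lo = max(lo, min_ordered_day)
            if lo > hi:
                logger.info(
                    "field %d year %d: %s window closed by ordering; dropped",
                    field_id, year, ev.type,
                )
                continue
        day = int(rng.integers(lo, hi + 1))
        if ev.type in SPRAY_TYPES and precip is not None:
            limit = min(DAYS_PER_YEAR, ev.window_end_day + shift_cap_days)
            while day <= limit and precip[day - 1] > spray_rain_threshold_mm:
                day += 1
            if day > limit:
                logger.info(
                    "field %d year %d: %s rained out beyond shift cap; dropped",
                    field_id, year, ev.type,
                )
                continue
        if ev.type in ORDERED_TYPES:
            min_ordered_day = day
        out.append(ScheduledEvent(field_id=field_id, year=year, day=day,
                                  type=ev.type, product=ev.product))
    return out


@dataclass
class VegetationParams:
    """Simplified degree-day growth curve parameters for one crop."""

    base_temperature_c: float = 5.0
    max_height_cm: float = 80.0
    half_saturation_dd: float = 300.0


def vegetation_state(
    crop: str,
    day: int,
    weather: WeatherSeries,
    sow_day: int,
    harvest_day: int | None = None,
    year: int = 0,
    params: VegetationParams | None = None,
) -> tuple[float, str]:
    """Vegetation height (cm) and cover class on ``day`` (day-of-year).

    Height is zero before sowing and after harvest, and otherwise follows a
    saturating curve of degree-days accumulated since sowing:
    ``h = h_max * dd / (dd + k)`` — monotone non-decreasing in accumulated
    degree-days up to the crop-specific maximum.
    """
    params = params or VegetationParams()
    if day < sow_day or (harvest_day is not None and day >= harvest_day):
        return 0.0, "bare"
    temps = weather.tmean_c[weather.year_slice(year)][sow_day - 1 : day]
    dd = float(np.maximum(0.0, temps - params.base_temperature_c).sum())
    height = params.max_height_cm * dd / (dd + params.half_saturation_dd) if dd > 0 else 0.0
    if height < 5:
        cover = "bare"
    elif height < 25:
        cover = "low"
    else:
        cover = "tall"
    return height, cover
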