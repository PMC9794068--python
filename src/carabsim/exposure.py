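"""Insecticide exposure and effects: lethality conversion, temperature-
adjusted degradation, toxic-unit treatment rates, spray-drift deposition,
gridded application, daily decay, and threshold-trigger mortality.

Concentrations are expressed in trigger-threshold units: the trigger — the
environmental concentration above which a beetle suffers a daily mortality
probability — is 1.0. There is no dose-response above the trigger.

The field-lethality classes LR90/LR50/LR25 denote the fraction of exposed
beetles dying over a 7-day field test. The overall mortality m over d days
relates to the daily probability p through (1 - m) = (1 - p)^d, so
p = 1 - (1 - m)^(1/d): 0.28/day for LR90, 0.09 for LR50, 0.04 for LR25.

Degradation is first-order with half-life DT50 at the 20 degC reference,
scaled to other temperatures by a Q10 rule (Q10 = 2.58). The toxic-unit
treatment rate 1/(0.5^(d / DT50)) deposits exactly enough that, decaying at
20 degC, the concentration stays above the trigger for the d-day effect
period: 41.78 trigger units for DT50 = 1.3 days.

Spray drift deposits A * dist^B percent of the application rate at
``dist`` metres from the sprayed area (A = 2.7705, B = -0.9787 for downward
field-crop spraying) up to a 12-m cutoff; drift-reducing technology scales
the curve by (1 - reduction).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .landscape import CROPPED_ELEMENTS, LandscapeGrid

Q10 = 2.58
REFERENCE_TEMP_C = 20.0
DELTA_T_C = 10.0

DRIFT_A_FIELD_CROPS = 2.7705
DRIFT_B_FIELD_CROPS = -0.9787
DRIFT_MAX_DIST_M = 12.0

TRIGGER_THRESHOLD = 1.0

#: overall 7-day field mortality per lethality-rate class
LR_CLASS_MORTALITY = {"LR90": 0.90, "LR50": 0.50, "LR25": 0.25}


def daily_mortality_prob(m: float, d: float) -> float:
    """Daily mortality probability p solving (1 - m) = (1 - p)^d.

    ``m`` is the overall mortality over the ``d``-day test period.
    """
    if not 0.0 <= m <= 1.0:
        raise ValueError("overall mortality m must lie in [0, 1]")
    if d < 1:
        raise ValueError("effect duration d must be at least 1 day")
    if m == 1.0:
        warnings.warn("m = 1 is degenerate: daily mortality is certain", stacklevel=2)
        return 1.0
    return 1.0 - (1.0 - m) ** (1.0 / d)


def temperature_adjusted_dt50(dt50_20: float, temp_c: float) -> float:
    """Half-life (days) at ``temp_c`` given the half-life at 20 degC.

    DT50(T) = DT50(20) * exp(ln(Q10) * (20 - T) / 10): colder soil degrades
    slower; one 10-degC step multiplies the half-life by Q10.
    """
    if dt50_20 <= 0:
        raise ValueError("DT50 must be positive")
    return dt50_20 * math.exp(
        math.log(Q10) * (REFERENCE_TEMP_C - temp_c) / DELTA_T_C
    )


def treatment_rate(dt50: float, duration: float = 7.0) -> float:
    """Toxic-unit application rate 1 / (0.5^(duration / DT50)).

    Calibrated so a deposit decaying first-order at 20 degC reaches the
    trigger threshold exactly after ``duration`` days.
    """
    if dt50 <= 0 or duration <= 0:
        raise ValueError("DT50 and duration must be positive")
    return 1.0 / (0.5 ** (duration / dt50))


@dataclass
class PesticideProduct:
    """One insecticide class used in a scenario.

    ``treatment_rate`` and ``daily_p`` are derived on construction from the
    lethality class, effect duration and half-life.
    """

    name: str
    lr_class: str
    dt50_20c: float
    effect_duration_d: float = 7.0
    overall_mortality: float = field(init=False)
    daily_p: float = field(init=False)
    treatment_rate: float = field(init=False)

    def __post_init__(self) -> None:
        if self.lr_class not in LR_CLASS_MORTALITY:
            raise ValueError(f"unknown lethality class {self.lr_class!r}")
        self.overall_mortality = LR_CLASS_MORTALITY[self.lr_class]
        self.daily_p = daily_mortality_prob(self.overall_mortality, self.effect_duration_d)
        self.treatment_rate = treatment_rate(self.dt50_20c, self.effect_duration_d)


@dataclass
class DriftCurve:
    """Power-law drift deposition curve with optional drift reduction.

    Reduction scales the whole curve by (1 - reduction), preserving the
    distance exponent.
    """

    A: float = DRIFT_A_FIELD_CROPS
    B: float = DRIFT_B_FIELD_CROPS
    max_dist_m: float = DRIFT_MAX_DIST_M
    reduction: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0 or self.B >= 0:
            raise ValueError("need A > 0 and B < 0")
        if not 0.0 <= self.reduction <= 1.0:
            raise ValueError("reduction must lie in [0, 1]")


def drift_fraction(dist_m, curve: DriftCurve):
    """Percent of the application rate deposited ``dist_m`` metres downwind.

    Zero beyond the curve's cutoff; distances must be positive (in-field
    cells receive the full rate, not drift).
    """
    dist = np.asarray(dist_m, dtype=float)
    if np.any(dist <= 0):
        raise ValueError("drift distance must be positive")
    out = np.where(
        dist <= curve.max_dist_m,
        (1.0 - curve.reduction) * curve.A * dist**curve.B,
        0.0,
    )
    return float(out) if np.isscalar(dist_m) else out


@dataclass
class ExposureGrid:
    """Per-cell environmental insecticide concentration (trigger units)."""

    cell_size_m: float
    concentration: np.ndarray

    @classmethod
    def zeros_like(cls, grid: LandscapeGrid) -> "ExposureGrid":
        return cls(grid.cell_size_m, np.zeros(grid.shape, dtype=np.float64))

    @property
    def max_concentration(self) -> float:
        return float(self.concentration.max()) if self.concentration.size else 0.0


def apply_application(
    exposure: ExposureGrid,
    grid: LandscapeGrid,
    field_id: int,
    product: PesticideProduct,
    curve: DriftCurve,
) -> ExposureGrid:
    """Spray one field: full treatment rate on its cropped cells, power-law
    drift on surrounding cells out to the 12-m cutoff.

    Margin and buffer cells of the parcel are not sprayed (they receive
    drift like any other off-crop cell). Drift distance is the Euclidean
    distance from the receiving cell centre to the nearest sprayed cell
    centre, so the first off-field ring at 1-m resolution sits at 1 m.
    Modifies ``exposure`` in place and returns it.
    """
    sprayed = (grid.field_id == field_id) & np.isin(grid.element, CROPPED_ELEMENTS)
    if not sprayed.any():
        if not (grid.field_id == field_id).any():
            raise ValueError(f"unknown field_id {field_id}")
        return exposure  # parcel exists but has no cropped cells left
    cell = grid.cell_size_m
    rate = product.treatment_rate
    pad = int(math.ceil(curve.max_dist_m / cell)) + 1
    rows, cols = np.nonzero(sprayed)
    r0, r1 = max(0, rows.min() - pad), min(grid.shape[0], rows.max() + pad + 1)
    c0, c1 = max(0, cols.min() - pad), min(grid.shape[1], cols.max() + pad + 1)
    local = sprayed[r0:r1, c0:c1]
    conc = exposure.concentration[r0:r1, c0:c1]
    conc[local] += rate
    # centre-to-centre distance to the nearest sprayed cell
    dist = ndimage.distance_transform_edt(~local, sampling=cell)
    recv = (~local) & (dist > 0) & (dist <= curve.max_dist_m)
    if recv.any():
        conc[recv] += rate * drift_fraction(dist[recv], curve) / 100.0
    return exposure


def daily_decay(exposure: ExposureGrid, temp_c: float, product: PesticideProduct) -> ExposureGrid:
    """One day of first-order decay at today's temperature (in place)."""
    dt50_today = temperature_adjusted_dt50(product.dt50_20c, temp_c)
    exposure.concentration *= 0.5 ** (1.0 / dt50_today)
    return exposure


def exposure_mortality_mask(
    concentrations: np.ndarray, product: PesticideProduct, rng: np.random.Generator
) -> np.ndarray:
    """Boolean death mask for agents at the given cell concentrations.

    An agent in a cell at or above the trigger dies with probability
    ``product.daily_p``; below the trigger it always survives. There is no
    dose-response: 10x the trigger kills no faster than 1.5x.
    """
    conc = np.asarray(concentrations, dtype=float)
    above = conc >= TRIGGER_THRESHOLD
    deaths = np.zeros(conc.shape, dtype=bool)
    n = int(above.sum())
    if n:
        deaths[above] = rng.random(n) < product.daily_p
    return deaths


def exposure_mortality(
    position: tuple[int, int],
    exposure: ExposureGrid,
    product: PesticideProduct,
    rng: np.random.Generator,
) -> bool:
    """Single-agent convenience wrapper: True if the agent dies today."""
    row, col = position
    conc = exposure.concentration[row, col]
    return bool(exposure_mortality_mask(np.array([conc]), product, rng)[0])
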