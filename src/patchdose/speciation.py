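"""Sulfide speciation and effective H2S dosimetry for NaHS donor solutions.

NaHS dissolves to Na+ and HS-; HS- protonates to H2S according to the
solution pH and the first dissociation constant K1 of the H2S/HS-/S2-
equilibrium.  Only the neutral H2S species is measured by an amperometric
sulfide sensor and only H2S crosses membranes readily, so converting a
nominal NaHS donor concentration into a dissolved — and, after evaporative
losses, *effective* — H2S concentration requires:

1. a temperature- and salinity-corrected pK1 (Millero equation),
2. the speciation equilibrium (full three-species or pH<9 simplified form),
3. a sensor calibration line (linear up to ~50 uM H2S),
4. an evaporation model for handling/perfusion losses, and
5. rescaling of any NaHS-denominated dose-response parameter (e.g. EC50)
   onto the effective-H2S axis.

All concentrations are micromolar, temperatures Kelvin, salinities g/L.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources
from typing import Sequence

import numpy as np
from scipy import stats as _sstats

__all__ = [
    "SulfideSolution",
    "DissociationConstants",
    "CalibrationCurve",
    "EvaporationModel",
    "DoseEstimate",
    "millero_pk1",
    "speciate",
    "fit_calibration",
    "current_to_h2s",
    "evaporation_loss",
    "effective_dose",
    "rescale_ec50",
    "round_half_up",
    "load_table1_calibration",
    "paper_evaporation_model",
    "PAPER_RETENTION_RANGE",
    "PAPER_FRACTION",
]

# Defaults of the experimental bath: pH 7.21, room temperature 20 C,
# physiological saline with 11.5 g total salts per liter.
DEFAULT_PH = 7.21
DEFAULT_TEMPERATURE_K = 293.15
DEFAULT_SALINITY = 11.5
DEFAULT_PK2 = 19.0

#: Retention range implied by a total evaporative loss of 40-50%.
PAPER_RETENTION_RANGE = (0.50, 0.60)

#: The printed speciation fraction of the source study's reporting chain
#: (exact evaluation at pH 7.21 / pK1 6.679 gives ~0.2275; see docs/methods.md).
PAPER_FRACTION = 0.223


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (reporting rule)."""
    q = Decimal(1).scaleb(-ndigits)
    v = float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
    return v


@dataclass(frozen=True)
class SulfideSolution:
    """Donor/solution chemistry state: total sulfide (uM), pH, T (K), salinity (g/L)."""

    total_sulfide: float
    ph: float = DEFAULT_PH
    temperature: float = DEFAULT_TEMPERATURE_K
    salinity: float = DEFAULT_SALINITY

    def __post_init__(self) -> None:
        if self.total_sulfide < 0:
            raise ValueError("total_sulfide must be >= 0")
        if not (0.0 < self.ph < 14.0):
            raise ValueError("pH must lie in (0, 14)")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if self.salinity < 0:
            raise ValueError("salinity must be >= 0")

    @property
    def proton_concentration(self) -> float:
        """[H+] in mol/L."""
        return 10.0 ** (-self.ph)


@dataclass(frozen=True)
class DissociationConstants:
    """pK1/pK2 of the sulfide system.  K2 is negligible below pH ~9."""

    pk1: float
    pk2: float = DEFAULT_PK2

    def __post_init__(self) -> None:
        if not self.pk2 > self.pk1:
            raise ValueError("pk2 must exceed pk1")

    @property
    def k1(self) -> float:
        return 10.0 ** (-self.pk1)

    @property
    def k2(self) -> float:
        return 10.0 ** (-self.pk2)

    @classmethod
    def from_conditions(
        cls, temperature: float = DEFAULT_TEMPERATURE_K, salinity: float = DEFAULT_SALINITY
    ) -> "DissociationConstants":
        return cls(pk1=millero_pk1(temperature, salinity))


def millero_pk1(temperature: float, salinity: float = 0.0) -> float:
    """First dissociation pK of H2S corrected for temperature and salinity.

    Empirical seawater-chemistry fit:
    pK1 = -98.08 + 5765.4/T + 15.04555 ln(T) - 0.157 sqrt(S) + 0.0135 S
    with T in Kelvin and S in g salts per liter.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (Kelvin)")
    if salinity < 0:
        raise ValueError("salinity must be >= 0")
    return (
        -98.08
        + 5765.4 / temperature
        + 15.04555 * math.log(temperature)
        - 0.157 * math.sqrt(salinity)
        + 0.0135 * salinity
    )


@dataclass
class DoseEstimate:
    """Dissolved and effective H2S derived from a donor solution."""

    dissolved_h2s: float
    fraction_dissolved: float
    effective_low: float = 0.0
    effective_high: float = 0.0
    retention_range: tuple[float, float] = (1.0, 1.0)
    #: effective concentration as a fraction of total sulfide (low, high)
    effective_fraction: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.effective_low <= self.effective_high + 1e-12):
            raise ValueError("effective_low must be in [0, effective_high]")


def speciate(
    solution: SulfideSolution,
    constants: DissociationConstants | None = None,
    simplified: bool = False,
) -> DoseEstimate:
    """Equilibrium [H2S] from total sulfide.

    Full form: [H2S] = S_tot / (1 + K1/[H+] + K1*K2/[H+]^2); the simplified
    form drops the K2 term, which is negligible for pH < 9.
    """
    if constants is None:
        constants = DissociationConstants.from_conditions(
            solution.temperature, solution.salinity
        )
    h = solution.proton_concentration
    denom = 1.0 + constants.k1 / h
    if not simplified:
        denom += constants.k1 * constants.k2 / (h * h)
    dissolved = solution.total_sulfide / denom
    fraction = 1.0 / denom
    return DoseEstimate(dissolved_h2s=dissolved, fraction_dissolved=fraction)


@dataclass
class CalibrationCurve:
    """OLS line mapping H2S concentration (uM) to sensor current (nA)."""

    slope: float
    intercept: float
    linear_max: float
    residual_sd: float
    n_used: int = 0
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if self.linear_max <= 0:
            raise ValueError("linear_max must be positive")

    def predict_current(self, h2s: float) -> float:
        return self.intercept + self.slope * h2s


def fit_calibration(
    points: Sequence[tuple[float, float]], linear_max: float
) -> CalibrationCurve:
    """Unweighted OLS over calibration points within the linear range.

    ``points`` are (h2s_uM, current_nA) pairs.  Points with h2s above
    ``linear_max`` are excluded from the fit and counted in ``n_excluded``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (h2s, current) pairs")
    inside = pts[:, 0] <= linear_max
    used = pts[inside]
    if len(used) < 2:
        raise ValueError("need at least 2 points within the linear range")
    if len(used) == 2 or np.ptp(used[:, 0]) == 0:
        # exact line through two points
        if used[1, 0] == used[0, 0]:
            raise ValueError("degenerate calibration points (equal h2s)")
        slope = (used[1, 1] - used[0, 1]) / (used[1, 0] - used[0, 0])
        intercept = used[0, 1] - slope * used[0, 0]
        resid_sd = 0.0
    else:
        res = _sstats.linregress(used[:, 0], used[:, 1])
        slope, intercept = res.slope, res.intercept
        resid = used[:, 1] - (intercept + slope * used[:, 0])
        dof = max(len(used) - 2, 1)
        resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        linear_max=float(linear_max),
        residual_sd=resid_sd,
        n_used=int(len(used)),
        n_excluded=int(len(pts) - len(used)),
    )


def current_to_h2s(current: float, curve: CalibrationCurve) -> tuple[float, bool]:
    """Invert the calibration line; flag results outside [0, linear_max]."""
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero")
    h2s = (current - curve.intercept) / curve.slope
    extrapolated = bool(h2s < 0 or h2s > curve.linear_max)
    return float(h2s), extrapolated


@dataclass
class EvaporationModel:
    """Cumulative H2S loss vs time as monotone piecewise-linear interpolation.

    Anchors are (time_min, cumulative_loss_fraction) pairs; loss is held
    constant after the last anchor.
    """

    anchors: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        anchors = sorted((float(t), float(l)) for t, l in self.anchors)
        if not anchors or anchors[0][0] != 0.0:
            anchors = [(0.0, 0.0)] + anchors
        if anchors[0][1] != 0.0:
            raise ValueError("loss at t=0 must be 0")
        losses = [l for _, l in anchors]
        if any(b < a for a, b in zip(losses, losses[1:])):
            raise ValueError("cumulative loss must be non-decreasing")
        if any(not (0.0 <= l < 1.0) for l in losses):
            raise ValueError("loss fractions must lie in [0, 1)")
        self.anchors = anchors

    def loss(self, time_min: float) -> float:
        return evaporation_loss(self, time_min)


def evaporation_loss(model: EvaporationModel, time_min: float) -> float:
    """Interpolated cumulative loss fraction at ``time_min`` (constant after last anchor)."""
    if time_min < 0:
        raise ValueError("time must be >= 0")
    t = np.array([a for a, _ in model.anchors])
    l = np.array([b for _, b in model.anchors])
    return float(np.interp(time_min, t, l))


#: Anchors reproducing the measured loss course: ~35% (30-40% band midpoint)
#: over the first 5 min of handling, ~7% more during the 5-min application,
#: and the measured 42% total by 20 min.
PAPER_EVAPORATION_ANCHORS = [(0.0, 0.0), (5.0, 0.35), (10.0, 0.42), (20.0, 0.42)]


def paper_evaporation_model() -> EvaporationModel:
    return EvaporationModel(anchors=list(PAPER_EVAPORATION_ANCHORS))


def effective_dose(
    solution: SulfideSolution,
    constants: DissociationConstants | None = None,
    retention_range: tuple[float, float] = PAPER_RETENTION_RANGE,
    paper_fraction: float | None = None,
) -> DoseEstimate:
    """Dissolved H2S reduced by evaporative losses.

    ``retention_range`` is the (low, high) fraction of dissolved H2S that
    survives handling and perfusion.  ``paper_fraction`` optionally overrides
    the exact speciation fraction used for the *percent-of-total* report so a
    rounded published chain can be reproduced while the exact equilibrium
    value remains available.
    """
    low, high = retention_range
    if not (0.0 < low <= high <= 1.0):
        raise ValueError("retention range must satisfy 0 < low <= high <= 1")
    est = speciate(solution, constants)
    est.retention_range = (low, high)
    est.effective_low = est.dissolved_h2s * low
    est.effective_high = est.dissolved_h2s * high
    frac = est.fraction_dissolved if paper_fraction is None else float(paper_fraction)
    est.effective_fraction = (frac * low, frac * high)
    return est


def rescale_ec50(
    ec50_nahs: float,
    fraction_dissolved: float,
    retention_range: tuple[float, float] = PAPER_RETENTION_RANGE,
) -> tuple[float, float]:
    """Rescale an NaHS-denominated EC50 onto the effective-H2S axis."""
    if ec50_nahs < 0:
        raise ValueError("EC50 must be >= 0")
    if not (0.0 <= fraction_dissolved <= 1.0):
        raise ValueError("fraction_dissolved must lie in [0, 1]")
    low, high = retention_range
    if not (0.0 < low <= high <= 1.0):
        raise ValueError("retention range must satisfy 0 < low <= high <= 1")
    return ec50_nahs * fraction_dissolved * low, ec50_nahs * fraction_dissolved * high


def load_table1_calibration() -> list[dict[str, float | None]]:
    """Packaged sensor calibration table (NaHS uM, current nA, sem, printed H2S uM)."""
    rows: list[dict[str, float | None]] = []
    with resources.files("patchdose.data").joinpath("table1_calibration.csv").open() as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                {
                    "nahs_uM": float(rec["nahs_uM"]),
                    "current_nA": float(rec["current_nA"]),
                    "sem_nA": float(rec["sem_nA"]) if rec.get("sem_nA") else None,
                    "h2s_uM": float(rec["h2s_uM"]) if rec.get("h2s_uM") else None,
                }
            )
    if not rows:
        warnings.warn("empty calibration table")
    return rows
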