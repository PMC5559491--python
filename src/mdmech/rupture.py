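"""Rupture-point detection and membrane rupture summaries.

Under monotonic membrane stretch the axial surface-averaged interaction
stress between an inclusion and its surrounding lipids rises with strain
until cohesion starts failing, then falls.  The strain at the first
prominent maximum of that curve is the rupture membrane strain and the
stress there the rupture stress; the membrane tension at rupture is the
axial interaction stress times the bilayer thickness (~5 nm), and the
areal strain at rupture is the in-plane area change of the surrounding
lipids over their initial area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .errors import ValidationError
from .units import MPA_NM_TO_MN_PER_M

#: default centered moving-average window (frames); odd for phase neutrality
DEFAULT_SMOOTHING_WINDOW = 11

#: default peak prominence as a fraction of the curve's range
DEFAULT_PROMINENCE_FRACTION = 0.1


@dataclass
class StressStrainCurve:
    """Paired (strain of the surrounding lipids, axial interaction stress)."""

    strain: np.ndarray
    stress_mpa: np.ndarray
    system: str = ""
    rate_label: float = float("nan")    # s^-1
    areal_strain: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress_mpa = np.asarray(self.stress_mpa, dtype=float)
        if self.strain.shape != self.stress_mpa.shape:
            raise ValidationError("strain and stress series must have equal length")
        order = np.argsort(self.strain, kind="stable")
        self.strain = self.strain[order]
        self.stress_mpa = self.stress_mpa[order]
        if self.areal_strain is not None:
            self.areal_strain = np.asarray(self.areal_strain, dtype=float)[order]


@dataclass(frozen=True)
class RuptureSummary:
    """Rupture signature of one complex at one loading rate."""

    detected: bool
    rupture_strain: float = float("nan")
    rupture_stress_mpa: float = float("nan")
    areal_strain_at_rupture: float = float("nan")
    rupture_tension_mn_per_m: float = float("nan")
    rupture_index: int = -1
    system: str = ""
    rate_label: float = float("nan")


def moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge truncation (window shrinks at ends)."""
    if window < 1:
        raise ValidationError("smoothing window must be >= 1")
    if window == 1:
        return np.asarray(y, dtype=float).copy()
    return pd.Series(y).rolling(window, center=True, min_periods=1).mean().to_numpy()


def detect_rupture(curve: StressStrainCurve,
                   smoothing_window: int = DEFAULT_SMOOTHING_WINDOW,
                   prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
                   thickness_nm: float = 5.0) -> RuptureSummary:
    """Locate the rupture point: the first prominent maximum of the curve.

    The stress series is smoothed with a centered moving average, then the
    first local maximum whose prominence exceeds
    ``prominence_fraction * (max - min)`` of the smoothed series is taken
    as rupture; the rupture index is then localized as the argmax of the
    *unsmoothed* series within one window of the smoothed peak (smoothing
    shifts and flattens sharp peaks), and the rupture values are read from
    the unsmoothed series at that index.  A monotonically rising curve
    returns ``detected=False`` (no rupture within the run), not an error.
    """
    if len(curve.strain) < 10:
        raise ValidationError("rupture detection needs >= 10 points")
    smooth = moving_average(curve.stress_mpa, smoothing_window)
    span = float(smooth.max() - smooth.min())
    if span <= 0:
        return RuptureSummary(detected=False, system=curve.system,
                              rate_label=curve.rate_label)
    peaks, _ = find_peaks(smooth, prominence=prominence_fraction * span)
    if len(peaks) == 0:
        return RuptureSummary(detected=False, system=curve.system,
                              rate_label=curve.rate_label)
    k = int(peaks[0])
    lo = max(0, k - smoothing_window)
    hi = min(len(curve.stress_mpa), k + smoothing_window + 1)
    k = lo + int(np.argmax(curve.stress_mpa[lo:hi]))
    strain = float(curve.strain[k])
    stress = float(curve.stress_mpa[k])
    areal = float(curve.areal_strain[k]) if curve.areal_strain is not None \
        else float("nan")
    return RuptureSummary(detected=True, rupture_strain=strain,
                          rupture_stress_mpa=stress,
                          areal_strain_at_rupture=areal,
                          rupture_tension_mn_per_m=membrane_tension(stress,
                                                                    thickness_nm),
                          rupture_index=k, system=curve.system,
                          rate_label=curve.rate_label)


def membrane_tension(axial_stress_mpa: float, thickness_nm: float = 5.0) -> float:
    """Membrane tension = axial interaction stress x bilayer thickness.

    1 MPa x 1 nm = 1 mN/m.  Linear in both arguments.
    """
    if thickness_nm <= 0:
        raise ValidationError("bilayer thickness must be positive")
    return float(axial_stress_mpa) * float(thickness_nm) * MPA_NM_TO_MN_PER_M


def summarize_runs(summaries: list[RuptureSummary]) -> pd.DataFrame:
    """Rate-vs-rupture table across runs, with the rate-insensitivity CV.

    Keys are (system, rate); duplicates are an error.  The coefficient of
    variation (std/mean, population definition) of the detected rupture
    strains within each system quantifies loading-rate insensitivity.
    """
    if not summaries:
        raise ValidationError("summarize_runs needs at least one run")
    rows = []
    seen = set()
    for s in summaries:
        key = (s.system, s.rate_label)
        if key in seen:
            raise ValidationError(f"duplicate (system, rate) key {key}")
        seen.add(key)
        rows.append({"system": s.system, "rate_per_s": s.rate_label,
                     "detected": s.detected, "rupture_strain": s.rupture_strain,
                     "rupture_stress_mpa": s.rupture_stress_mpa,
                     "areal_strain_at_rupture": s.areal_strain_at_rupture,
                     "rupture_tension_mn_per_m": s.rupture_tension_mn_per_m})
    table = pd.DataFrame(rows)
    cv = (table[table.detected]
          .groupby("system")["rupture_strain"]
          .agg(lambda x: float(np.std(x) / np.mean(x)) if np.mean(x) != 0 else np.nan)
          .rename("rupture_strain_cv"))
    return table.merge(cv, on="system", how="left")
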