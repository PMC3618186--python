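"""Circular-dichroism reductions for helix content and thermal stability.

Converts observed ellipticity to mean residue ellipticity (MRE), computes
the chain-length-corrected theoretical 222-nm signal for a fully helical
peptide, reduces measured 222-nm MRE to a percent helicity and a helical
residue count, and extracts the melting temperature of a two-state
transition from the first derivative of a 222-nm melt curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

logger = logging.getLogger("tetrafit")

__all__ = [
    "CDSpectrum",
    "MeltCurve",
    "MeltResult",
    "mean_residue_ellipticity",
    "theoretical_helix_mre",
    "percent_helicity",
    "helical_residue_count",
    "melt_tm",
]


def _ascending(x: np.ndarray, what: str) -> None:
    if x.ndim != 1 or len(x) < 2 or np.any(np.diff(x) <= 0):
        raise ValueError(f"{what} must be a strictly increasing 1-d array")


@dataclass
class CDSpectrum:
    """A far-UV CD spectrum with the optical metadata needed for MRE.

    ``theta_obs`` is the raw instrument ellipticity in degrees; ``mrw`` is
    the mean residue weight (molecular mass / residue count, Da).
    """

    wavelengths: np.ndarray
    theta_obs: np.ndarray
    pathlength_cm: float
    conc_mg_ml: float
    mrw: float
    n_residues: int

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.theta_obs = np.asarray(self.theta_obs, dtype=float)
        _ascending(self.wavelengths, "wavelengths")
        if len(self.theta_obs) != len(self.wavelengths):
            raise ValueError("wavelengths/theta_obs length mismatch")
        for name in ("pathlength_cm", "conc_mg_ml", "mrw"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_residues <= 0:
            raise ValueError("n_residues must be > 0")

    def mre(self) -> np.ndarray:
        """Mean residue ellipticity (deg·cm²·dmol⁻¹) at every wavelength."""
        return mean_residue_ellipticity(self.theta_obs, self.mrw,
                                        self.pathlength_cm, self.conc_mg_ml)

    def mre_at(self, wavelength: float) -> float:
        """MRE linearly interpolated at ``wavelength`` (nm)."""
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if not lo <= wavelength <= hi:
            raise ValueError(f"{wavelength} nm outside measured range "
                             f"[{lo}, {hi}]")
        return float(np.interp(wavelength, self.wavelengths, self.mre()))


@dataclass
class MeltCurve:
    """222-nm ellipticity versus temperature; units flagged by ``units``."""

    temperatures: np.ndarray
    theta222: np.ndarray
    units: str = "deg"  # "deg" (raw) or "mre"

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.theta222 = np.asarray(self.theta222, dtype=float)
        if len(self.temperatures) < 5:
            raise ValueError("melt curve needs at least 5 points")
        _ascending(self.temperatures, "temperatures")
        if len(self.theta222) != len(self.temperatures):
            raise ValueError("temperatures/theta222 length mismatch")


@dataclass
class MeltResult:
    tm: float | None
    transition_detected: bool
    derivative_extremum_magnitude: float
    smooth_window: int = field(default=5)

    def __post_init__(self) -> None:
        if self.tm is not None and not self.transition_detected:
            raise ValueError("tm set but no transition detected")


def mean_residue_ellipticity(theta_obs, mrw: float, pathlength_cm: float,
                             conc_mg_ml: float):
    """[θ] = θ_obs × MRW / (10 · l · c), in deg·cm²·dmol⁻¹.

    ``l`` in cm, ``c`` in mg/ml.  Accepts scalar or array θ_obs.
    """
    if pathlength_cm <= 0 or conc_mg_ml <= 0 or mrw <= 0:
        raise ValueError("pathlength, concentration and MRW must be > 0")
    return np.asarray(theta_obs, dtype=float) * mrw / (
        10.0 * pathlength_cm * conc_mg_ml)


def theoretical_helix_mre(n: int) -> float:
    """222-nm MRE of a 100% helical chain of ``n`` residues.

    Chain-length corrected value −40×10³·(1 − 4.6/n) deg·cm²·dmol⁻¹;
    negative because a helix has a 222-nm minimum.  Undefined (and
    rejected) for n ≤ 4 where the correction exceeds unity.
    """
    if n <= 4:
        raise ValueError("helix-length correction requires n > 4")
    return -40.0e3 * (1.0 - 4.6 / n)


def percent_helicity(mre222_exp: float, n: int) -> float:
    """Helical fraction: |measured 222-nm MRE| / |theoretical 100% value|.

    Clipped to [0, 1.05]; values above 1 are physically impossible under
    the two-state helix/coil picture and trigger a warning.
    """
    frac = abs(mre222_exp) / abs(theoretical_helix_mre(n))
    if frac > 1.0:
        logger.warning("percent helicity %.1f%% exceeds 100%%; clipping",
                       100 * frac)
        frac = min(frac, 1.05)
    return frac


def helical_residue_count(frac: float, n: int) -> int:
    """Number of helical residues, round-half-even of ``frac × n``."""
    if not 0.0 <= frac <= 1.0:
        raise ValueError("frac must lie in [0, 1]")
    return int(np.round(frac * n))


def melt_tm(curve: MeltCurve, smooth_window: int = 5) -> MeltResult:
    """Melting temperature from the first derivative of a melt curve.

    The curve is smoothed with a local quadratic (Savitzky–Golay, window
    ``smooth_window``), differentiated by central differences, and Tm taken
    at the derivative extremum.  A transition is declared only when the
    extremum magnitude exceeds 3× the median absolute derivative — a flat
    or purely linear curve (an unfolded chain with no cooperative
    transition) yields ``transition_detected=False`` and no Tm.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    n = len(curve.temperatures)
    if n < smooth_window + 2:
        raise ValueError(
            f"need at least {smooth_window + 2} points, got {n}")
    smoothed = savgol_filter(curve.theta222, smooth_window, polyorder=2)
    deriv = np.gradient(smoothed, curve.temperatures)
    mag = np.abs(deriv)
    idx = int(np.argmax(mag))
    extremum = float(mag[idx])
    median = float(np.median(mag))
    # floor below which a derivative extremum is numerical dust, not signal
    scale = max(float(np.ptp(curve.theta222)),
                1e-3 * float(np.max(np.abs(curve.theta222))), 1e-12)
    floor = 1e-9 * scale / float(np.ptp(curve.temperatures))
    detected = extremum > max(3.0 * median, floor)
    tm = float(curve.temperatures[idx]) if detected else None
    return MeltResult(tm=tm, transition_detected=detected,
                      derivative_extremum_magnitude=extremum,
                      smooth_window=smooth_window)
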