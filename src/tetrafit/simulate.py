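"""Synthetic data with the statistical structure the analysis assumes.

Three generators, all pure functions of (parameters, seed): multi-speed
sedimentation-equilibrium radial scans from the shared forward model plus
i.i.d. Gaussian absorbance noise; two-state van't Hoff thermal melts with
linear folded/unfolded baselines; and far-UV CD spectra built as linear
helix/coil mixtures whose 222-nm helix depth matches the theoretical
fully-helical value for the chain length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cd import CDSpectrum, MeltCurve, theoretical_helix_mre
from .sedeq import AssociationScheme, Buffer, RadialScan, radial_profile

__all__ = [
    "NoiseModel",
    "TwoStateMelt",
    "DEFAULT_RADII",
    "simulate_scans",
    "simulate_melt",
    "simulate_cd_spectrum",
]

R_KCAL = 1.987204e-3  # kcal·mol⁻¹·K⁻¹

#: Default radial grid: a typical 3-mm solution column, 6.85–7.15 cm
#: sampled every 0.001 cm.
DEFAULT_RADII = np.arange(6.85, 7.15 + 0.0005, 0.001)

#: Default absorbance noise, AU (typical XLI optics at moderate OD).
DEFAULT_SCAN_SD = 0.005


@dataclass(frozen=True)
class NoiseModel:
    """Additive i.i.d. Gaussian noise with a recorded seed."""

    sd: float
    seed: int = 0
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.kind != "gaussian":
            raise ValueError(f"unsupported noise kind {self.kind!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class TwoStateMelt:
    """Two-state van't Hoff unfolding with linear baselines.

    ``delta_h`` is the van't Hoff enthalpy (kcal/mol, > 0); baselines are
    ``intercept + slope·T(°C)`` for the folded and unfolded states.
    """

    tm: float            # °C
    delta_h: float       # kcal/mol
    folded_intercept: float = -30.0e3
    folded_slope: float = 0.0
    unfolded_intercept: float = -2.0e3
    unfolded_slope: float = 0.0

    def __post_init__(self) -> None:
        if self.delta_h <= 0:
            raise ValueError("delta_h must be > 0")

    def folded_fraction(self, temperatures_c) -> np.ndarray:
        t = np.asarray(temperatures_c, dtype=float) + 273.15
        tm = self.tm + 273.15
        k_unfold = np.exp(-self.delta_h / R_KCAL * (1.0 / t - 1.0 / tm))
        return 1.0 / (1.0 + k_unfold)


def simulate_scans(scheme: AssociationScheme, ref_concs, rpms,
                   buffer: Buffer, radii=None,
                   noise: NoiseModel | None = None,
                   pathlength: float = 1.2,
                   reference_radius: float | None = None,
                   baseline: float = 0.0) -> list[RadialScan]:
    """Noisy equilibrium scans at each rotor speed in ``rpms``.

    ``ref_concs`` are free base-species concentrations at the reference
    radius (defaults to the radial midpoint), applied identically at every
    speed.  With ``noise=None`` or sd=0 the output equals the forward
    model exactly.
    """
    radii = DEFAULT_RADII if radii is None else np.asarray(radii, float)
    if reference_radius is None:
        reference_radius = float(0.5 * (radii[0] + radii[-1]))
    rng = noise.rng() if noise is not None else None
    scans = []
    for rpm in rpms:
        scan = RadialScan(rpm=rpm, temperature=buffer.temperature,
                          radii=radii.copy(),
                          absorbance=np.zeros_like(radii),
                          reference_radius=reference_radius,
                          channel_id=f"{int(rpm)}rpm")
        signal = radial_profile(scheme, ref_concs, scan, buffer,
                                pathlength=pathlength, baseline=baseline)
        if rng is not None and noise.sd > 0:
            signal = signal + rng.normal(0.0, noise.sd, size=signal.shape)
        scan.absorbance = signal
        scans.append(scan)
    return scans


def simulate_melt(model: TwoStateMelt, temperatures_c=None,
                  noise: NoiseModel | None = None) -> MeltCurve:
    """A 222-nm melt curve from a two-state unfolding model.

    Signal = f·baseline_folded(T) + (1−f)·baseline_unfolded(T) with the
    folded fraction f from the van't Hoff equilibrium (f = 1/2 at Tm).
    """
    if temperatures_c is None:
        temperatures_c = np.arange(0.0, 80.0 + 0.5, 1.0)
    t = np.asarray(temperatures_c, dtype=float)
    f = model.folded_fraction(t)
    folded = model.folded_intercept + model.folded_slope * t
    unfolded = model.unfolded_intercept + model.unfolded_slope * t
    signal = f * folded + (1.0 - f) * unfolded
    if noise is not None and noise.sd > 0:
        signal = signal + noise.rng().normal(0.0, noise.sd, size=signal.shape)
    return MeltCurve(temperatures=t, theta222=signal, units="mre")


def _helix_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Helix basis, normalized to exactly 1 at 222 nm (double minimum)."""
    w = wavelengths
    shape = (np.exp(-((w - 222.0) ** 2) / (2 * 6.0 ** 2))
             + 0.95 * np.exp(-((w - 208.0) ** 2) / (2 * 5.5 ** 2))
             - 2.2 * np.exp(-((w - 192.0) ** 2) / (2 * 5.0 ** 2)))
    at222 = (1.0 + 0.95 * np.exp(-((222.0 - 208.0) ** 2) / (2 * 5.5 ** 2))
             - 2.2 * np.exp(-((222.0 - 192.0) ** 2) / (2 * 5.0 ** 2)))
    return shape / at222


def _coil_shape(wavelengths: np.ndarray) -> np.ndarray:
    """Coil basis (MRE units): small positive shoulder near 218 nm,
    near-zero at 222 nm, strong negative band below 200 nm.  A documented
    fixture shape, not a claim about real coil spectra."""
    w = wavelengths
    return (800.0 * np.exp(-((w - 218.0) ** 2) / (2 * 2.5 ** 2))
            - 15.0e3 * np.exp(-((w - 197.0) ** 2) / (2 * 4.0 ** 2)))


def simulate_cd_spectrum(frac_helix: float, n: int, pathlength_cm: float = 0.1,
                         conc_mg_ml: float = 0.1, mrw: float = 110.0,
                         wavelengths=None,
                         noise: NoiseModel | None = None) -> CDSpectrum:
    """A helix/coil mixture spectrum converted to observed ellipticity.

    The helix basis is scaled so its 222-nm MRE equals the theoretical
    fully-helical value for ``n`` residues; at ``frac_helix=1`` and zero
    noise the simulated 222-nm MRE therefore reproduces that value
    exactly.  Noise (deg) is added to θ_obs.
    """
    if not 0.0 <= frac_helix <= 1.0:
        raise ValueError("frac_helix must lie in [0, 1]")
    if wavelengths is None:
        wavelengths = np.arange(190.0, 260.0 + 0.5, 1.0)
    w = np.asarray(wavelengths, dtype=float)
    mre = (frac_helix * theoretical_helix_mre(n) * _helix_shape(w)
           + (1.0 - frac_helix) * _coil_shape(w))
    theta_obs = mre * 10.0 * pathlength_cm * conc_mg_ml / mrw
    if noise is not None and noise.sd > 0:
        theta_obs = theta_obs + noise.rng().normal(0.0, noise.sd,
                                                   size=theta_obs.shape)
    return CDSpectrum(wavelengths=w, theta_obs=theta_obs,
                      pathlength_cm=pathlength_cm, conc_mg_ml=conc_mg_ml,
                      mrw=mrw, n_residues=n)
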