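"""Forward physics of sedimentation equilibrium (SE-AUC).

At sedimentation equilibrium every ideal species i follows an exponential
radial concentration distribution

    c_i(r) = c_i(r0) · exp[ σ_i · (r² − r0²) / 2 ],

where the reduced buoyant exponent is

    σ_i = M_i (1 − v̄_i ρ) ω² / (R T)      [cm⁻²]

with M_i the molar mass (g/mol), v̄_i the partial specific volume (ml/g),
ρ the solvent density (g/ml), ω the rotor angular velocity (rad/s) and
R = 8.314×10⁷ erg·mol⁻¹·K⁻¹ (cgs units throughout, radii in cm).

Chemically coupled species stay in mass-action equilibrium at every
radius, not just at the reference radius, because the complex v̄ is the
mass-weighted mean of its components: buoyant masses are then additive,
σ_complex = Σ stoich_i σ_i, and the exponentials factor exactly.

Three association schemes are supported:

* ``SINGLE`` — one ideal species;
* ``MONOMER_DIMER`` — 2A ⇌ A₂ with Kd = [A]²/[A₂] (mol/l);
* ``HETERO_2_2`` — B₂ + 2A ⇌ B₂A₂, a bivalent homodimeric receptor B₂
  engaging two copies of a monomeric ligand A across its symmetry axis
  ("dimer of dimers"); Kd = [A]²[B₂]/[B₂A₂] in mol²/l² because the two
  ligand chains are treated as independent monomers.

The observed signal is Σ ε_i · l · c_i(r) plus a radially constant
baseline, with the complex extinction the sum of its components'.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "R_GAS_CGS",
    "Species",
    "Buffer",
    "RadialScan",
    "SchemeKind",
    "AssociationScheme",
    "reduced_exponent",
    "radial_profile",
    "free_concentrations_from_totals",
]

#: Gas constant in cgs units, erg·mol⁻¹·K⁻¹.
R_GAS_CGS = 8.314e7

#: Default admissible radial range of an analytical ultracentrifuge cell, cm.
RADIAL_RANGE = (5.8, 7.3)


@dataclass(frozen=True)
class Species:
    """One sedimenting species.

    ``epsilon`` is the molar signal increment at the detection wavelength,
    AU per (mol/l) per cm of optical path.  ``composition`` records the
    stoichiometry of base species for derived complexes (informational).
    """

    name: str
    monomer_mass: float  # Da (g/mol)
    vbar: float          # ml/g
    epsilon: float       # AU / (mol/l) / cm
    composition: dict[str, int] | None = None

    def __post_init__(self) -> None:
        if self.monomer_mass <= 0:
            raise ValueError(f"{self.name}: monomer_mass must be > 0")
        if not 0.5 < self.vbar < 0.9:
            raise ValueError(f"{self.name}: vbar {self.vbar} outside "
                             "(0.5, 0.9) ml/g")
        if self.epsilon < 0:
            raise ValueError(f"{self.name}: epsilon must be >= 0")


@dataclass(frozen=True)
class Buffer:
    """Solvent state: density (g/ml), temperature (K); NaCl and pH are
    descriptive condition labels, not physics inputs."""

    density: float
    temperature: float
    nacl: float = 0.15
    ph: float = 7.4

    def __post_init__(self) -> None:
        if not 0.9 < self.density < 1.2:
            raise ValueError(f"density {self.density} outside (0.9, 1.2)")
        if not 273.0 < self.temperature < 320.0:
            raise ValueError(
                f"temperature {self.temperature} K outside (273, 320)")


@dataclass
class RadialScan:
    """One equilibrium absorbance channel at a single rotor speed."""

    rpm: float
    temperature: float  # K, descriptive; physics uses Buffer.temperature
    radii: np.ndarray   # cm, strictly ascending
    absorbance: np.ndarray  # AU
    reference_radius: float  # cm, within the radial range
    channel_id: str = ""

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.radii.ndim != 1 or len(self.radii) < 2:
            raise ValueError("radii must be a 1-d array with >= 2 points")
        if np.any(np.diff(self.radii) <= 0):
            bad = int(np.argmax(np.diff(self.radii) <= 0))
            raise ValueError(
                f"radii must be strictly increasing (violation after row "
                f"{bad}, r={self.radii[bad]:.4f} cm)")
        lo, hi = RADIAL_RANGE
        if self.radii[0] < lo or self.radii[-1] > hi:
            raise ValueError(
                f"radii [{self.radii[0]:.3f}, {self.radii[-1]:.3f}] outside "
                f"the admissible cell range [{lo}, {hi}] cm")
        if len(self.absorbance) != len(self.radii):
            raise ValueError("radii/absorbance length mismatch")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance contains non-finite values")
        if not self.radii[0] <= self.reference_radius <= self.radii[-1]:
            raise ValueError("reference_radius outside the radial range")
        if self.rpm < 0:
            raise ValueError("rpm must be >= 0")


class SchemeKind(str, enum.Enum):
    SINGLE = "single"
    MONOMER_DIMER = "monomer_dimer"
    HETERO_2_2 = "hetero_2_2"


@dataclass
class AssociationScheme:
    """Declarative description of the species and their chemical coupling.

    ``species`` lists the free base species: ``[A]`` for SINGLE and
    MONOMER_DIMER, ``[B2, A]`` for HETERO_2_2 (the bivalent receptor dimer
    first, the monomeric ligand second).  ``kd`` is the dissociation
    constant — mol/l for MONOMER_DIMER, mol²/l² for HETERO_2_2.
    """

    kind: SchemeKind
    species: list[Species] = field(default_factory=list)
    kd: float | None = None

    def __post_init__(self) -> None:
        self.kind = SchemeKind(self.kind)
        n_expected = 2 if self.kind is SchemeKind.HETERO_2_2 else 1
        if len(self.species) != n_expected:
            raise ValueError(
                f"{self.kind.value} scheme needs exactly {n_expected} base "
                f"species, got {len(self.species)}")
        if self.kind is not SchemeKind.SINGLE:
            if self.kd is None or self.kd <= 0:
                raise ValueError("associating scheme requires kd > 0")

    @property
    def is_associating(self) -> bool:
        return self.kind is not SchemeKind.SINGLE

    def complex_species(self) -> Species | None:
        """The chemically coupled species implied by the scheme.

        Its v̄ is the mass-weighted mean of the components (which makes
        buoyant masses additive) and its ε the sum of the components'.
        """
        if self.kind is SchemeKind.SINGLE:
            return None
        if self.kind is SchemeKind.MONOMER_DIMER:
            a = self.species[0]
            return Species(name=f"{a.name}_dimer", monomer_mass=2 * a.monomer_mass,
                           vbar=a.vbar, epsilon=2 * a.epsilon,
                           composition={a.name: 2})
        b2, a = self.species
        mass = b2.monomer_mass + 2 * a.monomer_mass
        vbar = (b2.monomer_mass * b2.vbar + 2 * a.monomer_mass * a.vbar) / mass
        return Species(name=f"{b2.name}_{a.name}2", monomer_mass=mass,
                       vbar=vbar, epsilon=b2.epsilon + 2 * a.epsilon,
                       composition={b2.name: 1, a.name: 2})

    def complex_ref_conc(self, ref_concs: np.ndarray) -> float:
        """Complex concentration at the reference radius from mass action."""
        if self.kind is SchemeKind.MONOMER_DIMER:
            return float(ref_concs[0] ** 2 / self.kd)
        if self.kind is SchemeKind.HETERO_2_2:
            return float(ref_concs[1] ** 2 * ref_concs[0] / self.kd)
        return 0.0


def reduced_exponent(mass: float, vbar: float, buffer: Buffer,
                     rpm: float) -> float:
    """σ = M(1 − v̄ρ)ω²/(RT) in cm⁻²; ω = rpm·2π/60."""
    omega = rpm * 2.0 * np.pi / 60.0
    return mass * (1.0 - vbar * buffer.density) * omega ** 2 / (
        R_GAS_CGS * buffer.temperature)


def _species_terms(scheme: AssociationScheme, ref_concs,
                   buffer: Buffer, rpm: float):
    """(epsilon, sigma, c_ref) triples for all species incl. the complex."""
    ref_concs = np.atleast_1d(np.asarray(ref_concs, dtype=float))
    if len(ref_concs) != len(scheme.species):
        raise ValueError(
            f"expected {len(scheme.species)} reference concentrations, "
            f"got {len(ref_concs)}")
    if np.any(ref_concs < 0):
        raise ValueError("reference concentrations must be >= 0")
    terms = []
    for sp, c0 in zip(scheme.species, ref_concs):
        terms.append((sp.epsilon, reduced_exponent(sp.monomer_mass, sp.vbar,
                                                   buffer, rpm), float(c0)))
    cx = scheme.complex_species()
    if cx is not None:
        terms.append((cx.epsilon,
                      reduced_exponent(cx.monomer_mass, cx.vbar, buffer, rpm),
                      scheme.complex_ref_conc(ref_concs)))
    return terms


def radial_profile(scheme: AssociationScheme, ref_concs, scan: RadialScan,
                   buffer: Buffer, pathlength: float = 1.2,
                   baseline: float = 0.0) -> np.ndarray:
    """Model absorbance at every radius of ``scan``.

    ``ref_concs`` are the free base-species molar concentrations at the
    scan's reference radius, ordered as ``scheme.species``.
    """
    if pathlength <= 0:
        raise ValueError("pathlength must be > 0")
    r2 = scan.radii ** 2 - scan.reference_radius ** 2
    signal = np.full_like(scan.radii, float(baseline))
    for eps, sigma, c0 in _species_terms(scheme, ref_concs, buffer, scan.rpm):
        signal = signal + eps * pathlength * c0 * np.exp(sigma * r2 / 2.0)
    return signal


def free_concentrations_from_totals(scheme: AssociationScheme,
                                    totals) -> np.ndarray:
    """Free base-species concentrations given total loaded concentrations.

    Totals are in the same species order as the scheme: total monomer for
    MONOMER_DIMER (counting both chains of the dimer), total receptor
    dimer and total ligand monomer for HETERO_2_2.
    """
    totals = np.atleast_1d(np.asarray(totals, dtype=float))
    if np.any(totals < 0):
        raise ValueError("total concentrations must be >= 0")
    if scheme.kind is SchemeKind.SINGLE:
        return totals.copy()
    if scheme.kind is SchemeKind.MONOMER_DIMER:
        t = totals[0]
        if t == 0:
            return np.array([0.0])
        kd = scheme.kd
        # 2c²/kd + c − t = 0
        c = (-1.0 + np.sqrt(1.0 + 8.0 * t / kd)) * kd / 4.0
        return np.array([c])
    tb, ta = totals
    kd = scheme.kd
    if ta == 0 or tb == 0:
        return np.array([tb, ta])

    def residual(ca: float) -> float:
        cb = tb / (1.0 + ca ** 2 / kd)
        return ca + 2.0 * ca ** 2 * cb / kd - ta

    ca = brentq(residual, 0.0, ta, xtol=1e-18, rtol=1e-14)
    cb = tb / (1.0 + ca ** 2 / kd)
    return np.array([cb, ca])
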