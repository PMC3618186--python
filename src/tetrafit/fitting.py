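"""Global nonlinear least-squares fitting of sedimentation-equilibrium scans.

A single association scheme is fit jointly to scans collected at several
rotor speeds/channels: molar masses and the dissociation constant are
shared across channels, while reference-radius concentrations and optical
baselines are per channel.  The objective is the unweighted sum of squared
absorbance residuals.  Dissociation constants and concentrations are
optimized in log space; masses in linear space with bounds at
[0.2×, 5×] the initial value.  Kd fits use seeded multi-start
initialization (log-uniform over the Kd bounds) to avoid local minima.

Confidence bounds on Kd come from chi-square profiling: Kd is fixed on a
log-spaced grid, all nuisance parameters are re-fit at each grid point,
and the bounds are read off where the profile first exceeds the best-fit
chi-square plus a threshold (default Δχ² = 4).  A profile that rises on
only one side of the optimum yields a one-sided bound, mirroring the
"lower limit only" situation of very tight complexes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np

from .sedeq import (AssociationScheme, Buffer, RadialScan, SchemeKind,
                    Species, radial_profile, reduced_exponent)

logger = logging.getLogger("tetrafit")

__all__ = [
    "FitSpec",
    "SEFitResult",
    "ChiSquareProfile",
    "ConditionSeries",
    "NonIdentifiableError",
    "fit_global",
    "fit_molecular_weight",
    "fit_association",
    "profile_kd",
    "condition_series",
]

#: Default log10-Kd search bounds by scheme kind (dissociation direction).
DEFAULT_KD_BOUNDS = {
    SchemeKind.MONOMER_DIMER: (1e-12, 1e-3),   # mol/l
    SchemeKind.HETERO_2_2: (1e-18, 1e-6),      # mol²/l²
}

_LS_KWS = dict(ftol=1e-12, xtol=1e-12, gtol=1e-12)


class NonIdentifiableError(ValueError):
    """The requested fit has no information on its floated parameters."""


@dataclass
class FitSpec:
    """Which parameters are fixed and which float, with initial values."""

    scheme: AssociationScheme
    pathlength: float = 1.2
    float_masses: bool = False
    float_kd: bool = False
    float_concs: bool = True
    float_baselines: bool = False
    initial_kd: float | None = None
    kd_bounds: tuple[float, float] | None = None
    initial_concs: dict[str, np.ndarray] | None = None
    mass_bound_factors: tuple[float, float] = (0.2, 5.0)
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.float_masses or self.float_kd or self.float_concs
                or self.float_baselines):
            raise ValueError("at least one parameter must float")
        if self.float_kd and not self.scheme.is_associating:
            raise ValueError("kd can only float for an associating scheme")
        if self.kd_bounds is None and self.scheme.is_associating:
            self.kd_bounds = DEFAULT_KD_BOUNDS[self.scheme.kind]


@dataclass
class SEFitResult:
    """Best-fit parameters, their statuses, and goodness of fit."""

    parameters: dict[str, float]
    statuses: dict[str, str]  # "fixed" | "floated"
    chi_square: float
    reduced_chi_square: float
    residuals: dict[str, np.ndarray] = field(repr=False)
    converged: bool
    n_points: int
    n_floated: int
    seed: int
    n_starts: int
    kd_at_bound: bool = False
    scheme_kind: str = "single"

    def __post_init__(self) -> None:
        if self.chi_square < 0:
            raise ValueError("chi_square must be >= 0")

    @property
    def kd(self) -> float | None:
        return self.parameters.get("kd")

    def mass(self, index: int = 0) -> float:
        return self.parameters[f"mass_{index}"]


@dataclass
class ChiSquareProfile:
    """Chi-square versus fixed Kd with nuisance parameters re-fit."""

    kd_grid: np.ndarray
    chi_square: np.ndarray
    best_kd: float
    best_chi_square: float
    threshold: float
    lower: float | None
    upper: float | None

    def __post_init__(self) -> None:
        if (self.lower is not None and self.upper is not None
                and not self.lower <= self.best_kd <= self.upper):
            raise ValueError("profile bounds do not bracket best_kd")

    @property
    def lower_decade(self) -> float | None:
        """Lower bound rounded to the nearest decade, as −log10."""
        return None if self.lower is None else round(-np.log10(self.lower))

    @property
    def upper_decade(self) -> float | None:
        return None if self.upper is None else round(-np.log10(self.upper))


@dataclass
class ConditionSeries:
    """Per-condition fit results along a temperature/salt/pH axis."""

    conditions: tuple[float, ...]
    results: dict[float, SEFitResult | None]
    summary: dict[float, float | None]
    mode: str
    failed: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(b <= a for a, b in
               zip(self.conditions, self.conditions[1:])):
            raise ValueError("conditions must be strictly increasing")


# ---------------------------------------------------------------------------
# parameter bookkeeping

def _scan_key(i: int, scan: RadialScan) -> str:
    return scan.channel_id or f"scan{i}"


def _check_identifiable(spec: FitSpec, scans, buffer: Buffer) -> None:
    sigmas = [abs(reduced_exponent(sp.monomer_mass, sp.vbar, buffer, s.rpm))
              for s in scans for sp in spec.scheme.species]
    if max(sigmas) < 1e-10:
        raise NonIdentifiableError(
            "all reduced exponents are zero (no centrifugal field or "
            "neutral buoyancy); the radial profiles carry no information "
            "on mass or association")


def _initial_concs(spec: FitSpec, scans, scheme: AssociationScheme):
    """Crude per-channel starting concentrations from the signal at r0."""
    out = {}
    for i, scan in enumerate(scans):
        key = _scan_key(i, scan)
        if spec.initial_concs and key in spec.initial_concs:
            out[key] = np.asarray(spec.initial_concs[key], dtype=float)
            continue
        a_ref = float(np.interp(scan.reference_radius, scan.radii,
                                scan.absorbance))
        a_ref = max(a_ref, 1e-4)
        n = len(scheme.species)
        out[key] = np.array([a_ref / (n * sp.epsilon * spec.pathlength)
                             for sp in scheme.species])
    return out


def _build_params(spec: FitSpec, scans, conc0) -> lmfit.Parameters:
    params = lmfit.Parameters()
    scheme = spec.scheme
    for j, sp in enumerate(scheme.species):
        lo, hi = spec.mass_bound_factors
        params.add(f"mass_{j}", value=sp.monomer_mass,
                   min=lo * sp.monomer_mass, max=hi * sp.monomer_mass,
                   vary=spec.float_masses)
    if scheme.is_associating:
        kd0 = spec.initial_kd if spec.initial_kd is not None else scheme.kd
        lo, hi = spec.kd_bounds
        kd0 = min(max(kd0, lo), hi)
        params.add("log10_kd", value=np.log10(kd0), min=np.log10(lo),
                   max=np.log10(hi), vary=spec.float_kd)
    for i, scan in enumerate(scans):
        key = _scan_key(i, scan)
        for j in range(len(scheme.species)):
            c0 = max(conc0[key][j], 1e-15)
            params.add(f"logc_{i}_{j}", value=np.log10(c0), min=-15.0,
                       max=-2.0, vary=spec.float_concs)
        params.add(f"base_{i}", value=0.0, min=-0.5, max=0.5,
                   vary=spec.float_baselines)
    return params


def _eval_scheme(spec: FitSpec, params) -> AssociationScheme:
    base = spec.scheme
    species = [replace(sp, monomer_mass=params[f"mass_{j}"].value)
               for j, sp in enumerate(base.species)]
    kd = 10.0 ** params["log10_kd"].value if base.is_associating else None
    return AssociationScheme(kind=base.kind, species=species, kd=kd)


def _residual(params, spec: FitSpec, scans, buffer: Buffer) -> np.ndarray:
    scheme = _eval_scheme(spec, params)
    pieces = []
    for i, scan in enumerate(scans):
        concs = [10.0 ** params[f"logc_{i}_{j}"].value
                 for j in range(len(scheme.species))]
        model = radial_profile(scheme, concs, scan, buffer,
                               pathlength=spec.pathlength,
                               baseline=params[f"base_{i}"].value)
        pieces.append(model - scan.absorbance)
    return np.concatenate(pieces)


# ---------------------------------------------------------------------------
# fitting entry points

def fit_global(scans, spec: FitSpec, buffer: Buffer) -> SEFitResult:
    """Jointly fit all scans by unweighted least squares.

    Shared parameters (masses, Kd) are tied across channels; reference
    concentrations and baselines are per channel.  When Kd floats, the
    optimizer is restarted from ``spec.n_starts`` seeded log-uniform Kd
    values and the lowest-chi-square solution kept.
    """
    scans = list(scans)
    if not scans:
        raise ValueError("need at least one scan")
    _check_identifiable(spec, scans, buffer)
    conc0 = _initial_concs(spec, scans, spec.scheme)
    base_params = _build_params(spec, scans, conc0)

    rng = np.random.default_rng(spec.seed)
    n_starts = spec.n_starts if spec.float_kd else 1
    best = None
    for start in range(n_starts):
        params = base_params.copy()
        if start > 0 and spec.float_kd:
            p = params["log10_kd"]
            p.value = rng.uniform(p.min, p.max)
            if spec.float_concs:
                for name in params:
                    if name.startswith("logc_"):
                        params[name].value = float(np.clip(
                            params[name].value + rng.uniform(-0.3, 0.3),
                            params[name].min, params[name].max))
        out = lmfit.minimize(_residual, params, args=(spec, scans, buffer),
                             method="least_squares", **_LS_KWS)
        if best is None or out.chisqr < best.chisqr:
            best = out

    return _package_result(best, spec, scans, buffer)


def _package_result(out, spec: FitSpec, scans, buffer: Buffer) -> SEFitResult:
    params = out.params
    scheme = spec.scheme
    values: dict[str, float] = {}
    statuses: dict[str, str] = {}

    def record(name: str, value: float, vary: bool) -> None:
        values[name] = float(value)
        statuses[name] = "floated" if vary else "fixed"

    for j in range(len(scheme.species)):
        record(f"mass_{j}", params[f"mass_{j}"].value, spec.float_masses)
    kd_at_bound = False
    if scheme.is_associating:
        lg = params["log10_kd"]
        record("kd", 10.0 ** lg.value, spec.float_kd)
        if spec.float_kd and (lg.value - lg.min < 0.05
                              or lg.max - lg.value < 0.05):
            kd_at_bound = True
            logger.warning("fitted kd is at its search bound "
                           "(log10 kd = %.2f in [%.1f, %.1f])",
                           lg.value, lg.min, lg.max)
    residuals = {}
    resid_vec = _residual(params, spec, scans, buffer)
    offset = 0
    for i, scan in enumerate(scans):
        key = _scan_key(i, scan)
        n = len(scan.radii)
        residuals[key] = resid_vec[offset:offset + n]
        offset += n
        for j in range(len(scheme.species)):
            record(f"conc_{key}_{j}", 10.0 ** params[f"logc_{i}_{j}"].value,
                   spec.float_concs)
        record(f"baseline_{key}", params[f"base_{i}"].value,
               spec.float_baselines)

    chi = float(np.sum(resid_vec ** 2))
    n_points = len(resid_vec)
    n_floated = sum(1 for p in params.values() if p.vary)
    red = chi / max(n_points - n_floated, 1)
    return SEFitResult(parameters=values, statuses=statuses, chi_square=chi,
                       reduced_chi_square=red, residuals=residuals,
                       converged=bool(out.success), n_points=n_points,
                       n_floated=n_floated, seed=spec.seed,
                       n_starts=spec.n_starts, kd_at_bound=kd_at_bound,
                       scheme_kind=scheme.kind.value)


def fit_molecular_weight(scans, species: Species, buffer: Buffer,
                         pathlength: float = 1.2,
                         float_baselines: bool = False,
                         seed: int = 0) -> SEFitResult:
    """Single-species molar-mass determination.

    v̄, ρ and ε stay fixed; per-channel concentrations float and the
    molecular weight is calculated, as in conventional SE mass analysis.
    """
    scheme = AssociationScheme(kind=SchemeKind.SINGLE, species=[species])
    spec = FitSpec(scheme=scheme, pathlength=pathlength, float_masses=True,
                   float_concs=True, float_baselines=float_baselines,
                   seed=seed)
    return fit_global(scans, spec, buffer)


def fit_association(scans, scheme: AssociationScheme, buffer: Buffer,
                    pathlength: float = 1.2, float_concs: bool = True,
                    initial_kd: float | None = None,
                    kd_bounds: tuple[float, float] | None = None,
                    n_starts: int = 5, seed: int = 0) -> SEFitResult:
    """Association-constant determination with masses held fixed.

    Kd is fit in log space and reported in mol/l (monomer–dimer) or
    mol²/l² (2:2 hetero-complex).  Reference concentrations per channel
    float by default since the free concentration at the reference radius
    differs between speeds.
    """
    spec = FitSpec(scheme=scheme, pathlength=pathlength, float_masses=False,
                   float_kd=True, float_concs=float_concs,
                   initial_kd=initial_kd, kd_bounds=kd_bounds,
                   n_starts=n_starts, seed=seed)
    return fit_global(scans, spec, buffer)


def profile_kd(scans, spec: FitSpec, buffer: Buffer, grid=None,
               n_grid: int = 25, decades: float = 2.0,
               threshold: float = 4.0) -> ChiSquareProfile:
    """Chi-square profile of Kd with nuisance parameters re-fit.

    Kd is fixed at each grid value (default: log-spaced, ``decades``
    decades either side of the best fit) and everything else re-optimized.
    Confidence bounds are where the profile first crosses the best-fit
    chi-square plus ``threshold``; a side that never crosses yields a
    one-sided result with a warning.
    """
    if not spec.float_kd:
        raise ValueError("profiling requires a spec that floats kd")
    best = fit_global(scans, spec, buffer)
    best_kd = best.kd
    if grid is None:
        grid = np.logspace(np.log10(best_kd) - decades,
                           np.log10(best_kd) + decades, n_grid)
    grid = np.sort(np.asarray(grid, dtype=float))
    if np.log10(grid[-1] / grid[0]) < 2.0:
        raise ValueError("kd grid must span at least two decades")
    if not grid[0] <= best_kd <= grid[-1]:
        logger.warning("kd grid [%.3g, %.3g] does not bracket the best-fit "
                       "kd %.3g; profile will be one-sided",
                       grid[0], grid[-1], best_kd)

    chis = np.empty_like(grid)
    for i, kd in enumerate(grid):
        fixed_scheme = AssociationScheme(kind=spec.scheme.kind,
                                         species=spec.scheme.species, kd=kd)
        sub = replace(spec, scheme=fixed_scheme, float_kd=False,
                      initial_kd=None,
                      kd_bounds=(min(kd, spec.kd_bounds[0]),
                                 max(kd, spec.kd_bounds[1])),
                      n_starts=1)
        chis[i] = fit_global(scans, sub, buffer).chi_square

    limit = best.chi_square + threshold
    lower = upper = None
    # walk outward from the grid point nearest the best fit
    inear = int(np.argmin(np.abs(np.log10(grid / best_kd))))
    logg = np.log10(grid)
    for i in range(inear, 0, -1):
        if chis[i - 1] >= limit > chis[i]:
            frac = (limit - chis[i]) / (chis[i - 1] - chis[i])
            lower = 10.0 ** (logg[i] + frac * (logg[i - 1] - logg[i]))
            break
    for i in range(inear, len(grid) - 1):
        if chis[i + 1] >= limit > chis[i]:
            frac = (limit - chis[i]) / (chis[i + 1] - chis[i])
            upper = 10.0 ** (logg[i] + frac * (logg[i + 1] - logg[i]))
            break
    if lower is None or upper is None:
        logger.warning("chi-square profile crosses the Δχ²=%.1f limit on "
                       "%s side(s) only", threshold,
                       "one" if (lower or upper) else "neither")
    return ChiSquareProfile(kd_grid=grid, chi_square=chis, best_kd=best_kd,
                            best_chi_square=best.chi_square,
                            threshold=threshold, lower=lower, upper=upper)


def condition_series(entries: dict[float, tuple], spec: FitSpec,
                     mode: str = "apparent_mass") -> ConditionSeries:
    """Independent fits along a condition axis (temperature, salt or pH).

    ``entries`` maps each condition value to ``(scans, buffer)``.  In
    ``apparent_mass`` mode every condition is fit to a single effective
    species (the signature of weakening association is a falling apparent
    mass); in ``kd`` mode the association constant is fit per condition
    and summarized as −log10 Kd.  Failed conditions are flagged and the
    series continues.
    """
    if mode not in ("apparent_mass", "kd"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(entries) < 2:
        raise ValueError("need at least two conditions")
    conditions = tuple(sorted(entries))
    results: dict[float, SEFitResult | None] = {}
    summary: dict[float, float | None] = {}
    failed = []
    for cond in conditions:
        scans, buffer = entries[cond]
        try:
            if mode == "apparent_mass":
                res = fit_molecular_weight(scans, spec.scheme.species[0],
                                           buffer,
                                           pathlength=spec.pathlength,
                                           seed=spec.seed)
                metric = res.mass(0)
            else:
                res = fit_global(scans, replace(spec, float_kd=True), buffer)
                metric = float(-np.log10(res.kd))
        except Exception as exc:  # recorded, never silently dropped
            logger.error("condition %s failed: %s", cond, exc)
            res, metric = None, None
            failed.append(cond)
        results[cond] = res
        summary[cond] = metric
    return ConditionSeries(conditions=conditions, results=results,
                           summary=summary, mode=mode, failed=tuple(failed))
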