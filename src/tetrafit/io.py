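"""Readers, writers and run configuration.

Open text dialects throughout: CSV with a header row and unit-bearing
column names (``radius_cm``, ``temperature_C``), YAML sidecars/configs,
and JSON fit reports.  Native instrument exports are expected to be
converted to these dialects upstream.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from . import __version__
from .cd import CDSpectrum, MeltCurve
from .fitting import ChiSquareProfile, ConditionSeries, SEFitResult
from .sedeq import AssociationScheme, Buffer, RadialScan, SchemeKind, Species
from .seqprops import PKA_SETS, PIProfile, SequenceRecord, extinction_230

logger = logging.getLogger("tetrafit")

__all__ = [
    "read_fasta",
    "read_scan_csv",
    "write_scan_csv",
    "read_scan_dir",
    "write_scan_dir",
    "read_spectrum_csv",
    "read_melt_csv",
    "write_pi_profile_csv",
    "write_report",
    "RunConfig",
    "DEFAULT_SPECIES",
]

#: Nominal fragment table.  Partial specific volumes (ml/g) for the
#: dynactin p150 coiled-coil fragments and dynein IC N-terminal fragments;
#: 230-nm extinctions at 900 AU per residue; masses are theoretical
#: sequence masses (Da) where known, nominal otherwise.
DEFAULT_SPECIES = {
    "CC1": Species("CC1", monomer_mass=36000.0, vbar=0.721,
                   epsilon=extinction_230(327)),
    "CC1A": Species("CC1A", monomer_mass=16500.0, vbar=0.727,
                    epsilon=extinction_230(145)),
    "CC1B": Species("CC1B", monomer_mass=17000.0, vbar=0.726,
                    epsilon=extinction_230(149)),
    "IC1-44": Species("IC1-44", monomer_mass=5470.0, vbar=0.736,
                      epsilon=extinction_230(45)),
    "IC1-124": Species("IC1-124", monomer_mass=13880.0, vbar=0.731,
                       epsilon=extinction_230(124)),
}


def read_fasta(path) -> list[SequenceRecord]:
    """All records from a FASTA file, uppercase-normalized, in file order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        if seq != seq.upper():
            logger.warning("record %r contains lowercase residues; "
                           "normalizing to uppercase", rec.id)
            seq = seq.upper()
        records.append(SequenceRecord(id=rec.id, residues=seq))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}; "
                         f"found {list(df.columns)}")


def read_scan_csv(path, metadata: dict | None = None) -> RadialScan:
    """One radial scan from CSV (``radius_cm``, ``absorbance``).

    Channel metadata (rpm, temperature_C, reference_radius_cm, channel_id)
    comes from ``metadata`` or from a YAML sidecar ``<stem>.yaml`` next to
    the CSV.
    """
    path = Path(path)
    if metadata is None:
        sidecar = path.with_suffix(".yaml")
        if not sidecar.exists():
            raise FileNotFoundError(
                f"no metadata given and no sidecar {sidecar}")
        metadata = yaml.safe_load(sidecar.read_text())
    meta = _take(dict(metadata), {"rpm", "temperature_C",
                                  "reference_radius_cm", "channel_id"},
                 context=str(path))
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, ["radius_cm", "absorbance"], path)
    return RadialScan(rpm=float(meta["rpm"]),
                      temperature=float(meta["temperature_C"]) + 273.15,
                      radii=df["radius_cm"].to_numpy(),
                      absorbance=df["absorbance"].to_numpy(),
                      reference_radius=float(meta["reference_radius_cm"]),
                      channel_id=str(meta.get("channel_id", path.stem)))


def write_scan_csv(scan: RadialScan, path) -> None:
    path = Path(path)
    pd.DataFrame({"radius_cm": scan.radii,
                  "absorbance": scan.absorbance}).to_csv(path, index=False)
    sidecar = {"rpm": float(scan.rpm),
               "temperature_C": round(scan.temperature - 273.15, 6),
               "reference_radius_cm": float(scan.reference_radius),
               "channel_id": scan.channel_id}
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar))


def read_scan_dir(directory) -> list[RadialScan]:
    """Every ``*.csv`` scan (with YAML sidecar) in a directory, sorted."""
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise FileNotFoundError(f"no scan CSVs in {directory}")
    return [read_scan_csv(p) for p in paths]


def write_scan_dir(scans, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, scan in enumerate(scans):
        name = scan.channel_id or f"scan{i}"
        write_scan_csv(scan, directory / f"{name}.csv")


def read_spectrum_csv(path, metadata: dict) -> CDSpectrum:
    """CD spectrum from CSV (``wavelength_nm``, ``theta_deg``) plus optical
    metadata (pathlength_cm, conc_mg_ml, mrw, n_residues)."""
    meta = _take(dict(metadata), {"pathlength_cm", "conc_mg_ml", "mrw",
                                  "n_residues"}, context=str(path))
    df = pd.read_csv(path)
    _require_columns(df, ["wavelength_nm", "theta_deg"], path)
    return CDSpectrum(wavelengths=df["wavelength_nm"].to_numpy(),
                      theta_obs=df["theta_deg"].to_numpy(),
                      pathlength_cm=float(meta["pathlength_cm"]),
                      conc_mg_ml=float(meta["conc_mg_ml"]),
                      mrw=float(meta["mrw"]),
                      n_residues=int(meta["n_residues"]))


def read_melt_csv(path, units: str = "deg") -> MeltCurve:
    df = pd.read_csv(path)
    _require_columns(df, ["temperature_C", "theta222"], path)
    return MeltCurve(temperatures=df["temperature_C"].to_numpy(),
                     theta222=df["theta222"].to_numpy(), units=units)


def write_pi_profile_csv(profile: PIProfile, path) -> None:
    pd.DataFrame({"window_start": profile.starts,
                  "window_end": profile.ends,
                  "pI": profile.values}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _report_body(result):
    if isinstance(result, SEFitResult):
        return {"kind": "se_fit",
                "parameters": result.parameters,
                "statuses": result.statuses,
                "chi_square": result.chi_square,
                "reduced_chi_square": result.reduced_chi_square,
                "converged": result.converged,
                "n_points": result.n_points,
                "n_floated": result.n_floated,
                "seed": result.seed,
                "n_starts": result.n_starts,
                "kd_at_bound": result.kd_at_bound,
                "scheme": result.scheme_kind}
    if isinstance(result, ChiSquareProfile):
        neglog = {k: (None if v is None else float(-np.log10(v)))
                  for k, v in (("lower", result.lower),
                               ("upper", result.upper),
                               ("best_kd", result.best_kd))}
        return {"kind": "kd_profile",
                "kd_grid": result.kd_grid,
                "chi_square": result.chi_square,
                "best_kd": result.best_kd,
                "best_chi_square": result.best_chi_square,
                "threshold": result.threshold,
                "bounds_linear": {"lower": result.lower,
                                  "upper": result.upper},
                "bounds_neg_log10": neglog}
    if isinstance(result, ConditionSeries):
        return {"kind": "condition_series",
                "mode": result.mode,
                "conditions": list(result.conditions),
                "summary": {str(c): result.summary[c]
                            for c in result.conditions},
                "failed": list(result.failed)}
    if dataclasses.is_dataclass(result):
        return dataclasses.asdict(result)
    return result


def write_report(result, path) -> dict:
    """JSON fit report: parameters with statuses, χ², seeds, version."""
    doc = {"software": "tetrafit", "version": __version__,
           "report": _jsonable(_report_body(result))}
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return doc


# ---------------------------------------------------------------------------
# run configuration

def _take(d: dict, allowed: set, context: str, required: set = frozenset()):
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown key(s) {sorted(unknown)}; "
                         f"allowed: {sorted(allowed)}")
    missing = required - set(d)
    if missing:
        raise ValueError(f"{context}: missing required key(s) "
                         f"{sorted(missing)}")
    return d


@dataclasses.dataclass
class RunConfig:
    """Schema-validated analysis configuration (YAML)."""

    pka_set: str
    buffer: Buffer
    species: dict[str, Species]
    scheme: AssociationScheme | None
    fit: dict
    output_dir: str

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        _take(raw, {"pka_set", "buffer", "species", "scheme", "fit",
                    "output_dir"}, context=str(path))

        pka_set = raw.get("pka_set", "emboss")
        if pka_set not in PKA_SETS:
            raise ValueError(f"unknown pka_set {pka_set!r}; "
                             f"choose from {sorted(PKA_SETS)}")

        b = _take(dict(raw.get("buffer", {})),
                  {"density_g_ml", "temperature_C", "nacl_M", "pH"},
                  context=f"{path}:buffer",
                  required={"density_g_ml", "temperature_C"})
        buffer = Buffer(density=float(b["density_g_ml"]),
                        temperature=float(b["temperature_C"]) + 273.15,
                        nacl=float(b.get("nacl_M", 0.15)),
                        ph=float(b.get("pH", 7.4)))

        species = dict(DEFAULT_SPECIES)
        for entry in raw.get("species", []):
            e = _take(dict(entry), {"name", "mass_da", "vbar_ml_g",
                                    "epsilon"},
                      context=f"{path}:species",
                      required={"name", "mass_da", "vbar_ml_g", "epsilon"})
            species[e["name"]] = Species(name=e["name"],
                                         monomer_mass=float(e["mass_da"]),
                                         vbar=float(e["vbar_ml_g"]),
                                         epsilon=float(e["epsilon"]))

        scheme = None
        if "scheme" in raw:
            s = _take(dict(raw["scheme"]), {"kind", "species", "kd"},
                      context=f"{path}:scheme", required={"kind", "species"})
            members = []
            for name in s["species"]:
                if name not in species:
                    raise ValueError(f"{path}:scheme references unknown "
                                     f"species {name!r}")
                members.append(species[name])
            scheme = AssociationScheme(kind=SchemeKind(s["kind"]),
                                       species=members,
                                       kd=(float(s["kd"])
                                           if "kd" in s else None))

        fit = _take(dict(raw.get("fit", {})),
                    {"float_masses", "float_kd", "float_concs",
                     "float_baselines", "n_starts", "seed",
                     "pathlength_cm"}, context=f"{path}:fit")

        return cls(pka_set=pka_set, buffer=buffer, species=species,
                   scheme=scheme, fit=fit,
                   output_dir=str(raw.get("output_dir", ".")))
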