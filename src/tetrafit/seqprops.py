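"""Sequence-derived physical properties of polypeptides.

Net charge and isoelectric point (whole-sequence and in sliding windows),
average molecular mass, per-residue far-UV extinction, helix end-to-end
geometry and heptad-repeat counting.  All routines operate on validated
:class:`SequenceRecord` objects holding one-letter amino-acid codes.

Charge follows the Henderson–Hasselbalch treatment: each ionizable group
contributes its Boltzmann-weighted protonation fraction, positive groups
(N-terminus, His, Lys, Arg) as ``+1/(1+10^(pH−pKa))`` and negative groups
(C-terminus, Asp, Glu, Cys, Tyr) as ``−1/(1+10^(pKa−pH))``.  The pI is the
unique zero crossing of this strictly decreasing function of pH.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "STANDARD_AA",
    "SequenceRecord",
    "PKaSet",
    "PKA_SETS",
    "PIProfile",
    "net_charge",
    "isoelectric_point",
    "windowed_pi",
    "average_mass",
    "extinction_230",
    "helix_end_to_end",
    "heptad_count",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# IUPAC average residue masses (Da); a free chain adds one water.
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153

# Extinction at 230 nm: flat 900 AU per residue per unit molar
# concentration per cm of path.
EPSILON_230_PER_RESIDUE = 900.0

HELIX_RISE_PER_RESIDUE = 1.5  # Å per residue for an alpha helix


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence restricted to the 20 standard codes."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = sorted({c for c in self.residues if c not in STANDARD_AA})
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-standard residue codes "
                f"{''.join(bad)!r}; only the 20 standard one-letter codes "
                "are accepted (uppercase)"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class PKaSet:
    """pKa values (pH units) for termini and ionizable side chains."""

    n_term: float
    c_term: float
    asp: float
    glu: float
    cys: float
    tyr: float
    his: float
    lys: float
    arg: float

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if not 0.0 < value < 14.0:
                raise ValueError(f"pKa {name}={value} outside (0, 14)")


#: EMBOSS defaults (iep); the shipped default scale.
EMBOSS = PKaSet(n_term=8.6, c_term=3.6, asp=3.9, glu=4.1, cys=8.5,
                tyr=10.1, his=6.5, lys=10.8, arg=12.5)
#: Sillero & Ribeiro (1989) scale, selectable for sensitivity checks.
SILLERO = PKaSet(n_term=8.2, c_term=3.2, asp=4.0, glu=4.5, cys=9.0,
                 tyr=10.0, his=6.4, lys=10.4, arg=12.0)

PKA_SETS = {"emboss": EMBOSS, "sillero": SILLERO}

_POSITIVE = {"H": "his", "K": "lys", "R": "arg"}
_NEGATIVE = {"D": "asp", "E": "glu", "C": "cys", "Y": "tyr"}


@dataclass(frozen=True)
class PIProfile:
    """Per-window isoelectric points over a sliding window.

    ``starts`` are 1-based inclusive positions of each full window; trailing
    partial windows are dropped so every pI covers the same span.
    """

    starts: tuple[int, ...]
    window: int
    step: int
    values: tuple[float, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.starts) != len(self.values):
            raise ValueError("starts and values length mismatch")
        if any(b <= a for a, b in zip(self.starts, self.starts[1:])):
            raise ValueError("window starts must be strictly increasing")
        if any(not 0.0 < v < 14.0 for v in self.values):
            raise ValueError("pI values must lie in (0, 14)")

    @property
    def ends(self) -> tuple[int, ...]:
        return tuple(s + self.window - 1 for s in self.starts)


def net_charge(seq: SequenceRecord, ph: float, pkas: PKaSet = EMBOSS) -> float:
    """Net charge (elementary charges) at ``ph`` by Henderson–Hasselbalch."""
    charge = 1.0 / (1.0 + 10.0 ** (ph - pkas.n_term))
    charge -= 1.0 / (1.0 + 10.0 ** (pkas.c_term - ph))
    for res in seq.residues:
        if res in _POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - getattr(pkas, _POSITIVE[res])))
        elif res in _NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (getattr(pkas, _NEGATIVE[res]) - ph))
    return charge


def isoelectric_point(seq: SequenceRecord, pkas: PKaSet = EMBOSS,
                      xtol: float = 1e-4) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    With both termini present the charge is positive at pH 0 and negative
    at pH 14, so a sign change always exists; the function raises if it
    does not (degenerate pKa sets).
    """
    lo, hi = net_charge(seq, 0.0, pkas), net_charge(seq, 14.0, pkas)
    if not (lo > 0.0 > hi):
        raise ValueError(
            f"net charge does not change sign on [0, 14] for {seq.id!r} "
            f"(charge {lo:+.3g} at pH 0, {hi:+.3g} at pH 14)"
        )
    return float(bisect(lambda p: net_charge(seq, p, pkas), 0.0, 14.0,
                        xtol=xtol))


def windowed_pi(seq: SequenceRecord, window: int = 28, step: int = 7,
                pkas: PKaSet = EMBOSS) -> PIProfile:
    """pI of every full ``window``-residue stretch, advancing by ``step``."""
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    n = len(seq)
    if window > n:
        raise ValueError(
            f"window ({window}) exceeds sequence length ({n}) for {seq.id!r}"
        )
    starts, values = [], []
    for start in range(1, n - window + 2, step):
        sub = SequenceRecord(f"{seq.id}[{start}:{start + window - 1}]",
                             seq.residues[start - 1:start - 1 + window])
        starts.append(start)
        values.append(isoelectric_point(sub, pkas))
    return PIProfile(starts=tuple(starts), window=window, step=step,
                     values=tuple(values))


def average_mass(seq: SequenceRecord) -> float:
    """Average molecular mass (Da): residue masses plus one water."""
    return sum(RESIDUE_MASS[r] for r in seq.residues) + WATER_MASS


def extinction_230(n_residues: int) -> float:
    """230-nm extinction coefficient: 900 AU per residue (per M per cm)."""
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return EPSILON_230_PER_RESIDUE * n_residues


def helix_end_to_end(n_residues: int, frac_helix: float,
                     rise: float = HELIX_RISE_PER_RESIDUE) -> float:
    """End-to-end length (Å) of the helical fraction of a chain.

    An alpha helix rises 1.5 Å per residue, so a chain of ``n_residues``
    that is ``frac_helix`` helical spans ``n × frac × rise`` along the
    helix axis.
    """
    if not 0.0 <= frac_helix <= 1.0:
        raise ValueError("frac_helix must lie in [0, 1]")
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return n_residues * frac_helix * rise


def heptad_count(start: int, end: int) -> int:
    """Number of complete seven-residue (abcdefg) repeats in [start, end]."""
    if start > end:
        raise ValueError(f"inverted range {start}..{end}")
    return (end - start + 1) // 7
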