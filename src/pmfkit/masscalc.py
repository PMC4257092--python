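"""Mass and charge calculus: peptide/proteoform masses, [M+H]+, pI, gel coordinates.

The pI model is the composition-only Henderson–Hasselbalch charge balance with
the Bjellqvist pKa set (the ProtParam convention): net charge is the sum of
basic-group occupancies minus acidic-group occupancies, and the isoelectric
point is the bisection root of that monotone function on pH 0..14.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass
from functools import lru_cache
from importlib.resources import files

from .seqmodel import CANONICAL_AA, C_TERM, N_TERM, Modification, Proteoform

#: CODATA proton mass in Da.
PROTON = 1.007276

WATER_MONO = 18.010565
WATER_AVG = 18.0153


class MassKind(enum.Enum):
    MONO = "mono"
    AVG = "avg"


@dataclass(frozen=True)
class MassTables:
    """Residue-mass lookup tables plus the physical constants used throughout."""

    mono: dict[str, float]
    avg: dict[str, float]
    water_mono: float = WATER_MONO
    water_avg: float = WATER_AVG
    proton: float = PROTON

    def __post_init__(self) -> None:
        for table in (self.mono, self.avg):
            missing = CANONICAL_AA - set(table)
            if missing:
                raise ValueError(f"mass table missing residues {sorted(missing)}")
            if any(m <= 0 for m in table.values()):
                raise ValueError("residue masses must be positive")
        if abs(self.proton - 1.00728) > 1e-4:
            raise ValueError("proton mass implausible")

    def residue(self, aa: str, kind: MassKind) -> float:
        return (self.mono if kind is MassKind.MONO else self.avg)[aa]

    def water(self, kind: MassKind) -> float:
        return self.water_mono if kind is MassKind.MONO else self.water_avg


@lru_cache(maxsize=1)
def default_mass_tables() -> MassTables:
    """Load the shipped residue-mass TSV resource."""
    text = files("pmfkit.data").joinpath("residue_masses.tsv").read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    mono: dict[str, float] = {}
    avg: dict[str, float] = {}
    for row in csv.DictReader(rows, delimiter="\t"):
        mono[row["residue"]] = float(row["mono"])
        avg[row["residue"]] = float(row["avg"])
    return MassTables(mono=mono, avg=avg)


def peptide_mass(
    sequence: str,
    mods: list[tuple[Modification, int]] | None = None,
    kind: MassKind = MassKind.MONO,
    tables: MassTables | None = None,
) -> float:
    """Neutral mass of a peptide: residue masses + water + modification deltas.

    Raises ``ValueError`` for an empty peptide or a modification count that
    exceeds the number of placeable sites.
    """
    if not sequence:
        raise ValueError("empty peptide")
    tables = tables or default_mass_tables()
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise ValueError(f"non-canonical letters {sorted(bad)} in peptide")
    total = sum(tables.residue(aa, kind) for aa in sequence) + tables.water(kind)
    for mod, count in mods or ():
        if count < 0:
            raise ValueError(f"negative count for modification {mod.name!r}")
        if count > mod.n_sites(sequence):
            raise ValueError(
                f"modification {mod.name!r}: count {count} exceeds "
                f"{mod.n_sites(sequence)} placeable site(s)"
            )
        delta = mod.mono_delta if kind is MassKind.MONO else mod.avg_delta
        total += count * delta
    return total


def mz_mh(neutral_mass: float, tables: MassTables | None = None) -> float:
    """Singly protonated ion mass [M+H]+ of a neutral mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    tables = tables or default_mass_tables()
    return neutral_mass + tables.proton


def proteoform_mass(
    form: Proteoform,
    kind: MassKind = MassKind.AVG,
    tables: MassTables | None = None,
) -> float:
    """Mass of a proteoform: multimer x (chain mass with fixed modifications).

    Dimers are treated as non-covalent associations (exactly twice the
    monomer mass, no linker arithmetic).
    """
    monomer = peptide_mass(form.chain, list(form.fixed_mods), kind, tables)
    return form.multimer * monomer


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PkaSet:
    """Ionizable-group pKa values.

    ``side_chain`` maps residue letter -> (pKa, sign) where sign is +1 for
    basic groups and -1 for acidic ones.  ``n_term`` / ``c_term`` map residue
    letters to terminal pKa values with a ``DEFAULT`` fallback.
    """

    side_chain: dict[str, tuple[float, int]]
    n_term: dict[str, float]
    c_term: dict[str, float]

    def __post_init__(self) -> None:
        values = [p for p, _ in self.side_chain.values()]
        values += list(self.n_term.values()) + list(self.c_term.values())
        if any(not (0.0 < v < 14.0) for v in values):
            raise ValueError("pKa values must lie in (0, 14)")
        for name in ("n_term", "c_term"):
            if "DEFAULT" not in getattr(self, name):
                raise ValueError(f"{name} table requires a DEFAULT entry")

    def n_term_pka(self, first_residue: str) -> float:
        return self.n_term.get(first_residue, self.n_term["DEFAULT"])

    def c_term_pka(self, last_residue: str) -> float:
        return self.c_term.get(last_residue, self.c_term["DEFAULT"])


@lru_cache(maxsize=1)
def bjellqvist_pka() -> PkaSet:
    """Load the shipped Bjellqvist pKa TSV resource."""
    text = files("pmfkit.data").joinpath("pka_bjellqvist.tsv").read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    side: dict[str, tuple[float, int]] = {}
    n_term: dict[str, float] = {}
    c_term: dict[str, float] = {}
    for row in csv.DictReader(rows, delimiter="\t"):
        pka = float(row["pka"])
        sign = 1 if row["sign"] == "BASE" else -1
        if row["group"] == "SIDE_CHAIN":
            side[row["residue"]] = (pka, sign)
        elif row["group"] == "N_TERM":
            n_term[row["residue"]] = pka
        elif row["group"] == "C_TERM":
            c_term[row["residue"]] = pka
    return PkaSet(side_chain=side, n_term=n_term, c_term=c_term)


def net_charge(sequence: str, pH: float, pka: PkaSet | None = None) -> float:
    """Henderson–Hasselbalch net charge of a peptide at a given pH.

    charge = sum over basic groups of 1/(1+10^(pH-pKa))
           - sum over acidic groups of 1/(1+10^(pKa-pH)),
    termini included.  Continuous and strictly decreasing in pH.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if not (0.0 < pH < 14.0):
        raise ValueError("pH must lie in (0, 14)")
    pka = pka or bjellqvist_pka()
    charge = 0.0
    charge += 1.0 / (1.0 + 10.0 ** (pH - pka.n_term_pka(sequence[0])))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.c_term_pka(sequence[-1]) - pH))
    for aa, count in _composition(sequence).items():
        if aa in pka.side_chain:
            p, sign = pka.side_chain[aa]
            if sign > 0:
                charge += count / (1.0 + 10.0 ** (pH - p))
            else:
                charge -= count / (1.0 + 10.0 ** (p - pH))
    return charge


def _composition(sequence: str) -> dict[str, int]:
    out: dict[str, int] = {}
    for aa in sequence:
        out[aa] = out.get(aa, 0) + 1
    return out


def isoelectric_point(
    sequence: str, pka: PkaSet | None = None, tol: float = 1e-3
) -> float:
    """pH at which net charge is zero, found by bisection on [0, 14]."""
    if not sequence:
        raise ValueError("empty sequence")
    if tol <= 0:
        raise ValueError("tol must be positive")
    pka = pka or bjellqvist_pka()
    lo, hi = 1e-9, 14.0 - 1e-9
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid, pka) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# Gel coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GelCoordinate:
    """A 2-DE gel position: isoelectric point and apparent mass in kDa."""

    pI: float
    mw_kda: float

    def __post_init__(self) -> None:
        if not (0.0 < self.pI < 14.0):
            raise ValueError("pI out of range")
        if self.mw_kda <= 0:
            raise ValueError("mw_kda must be positive")


def predict_spot(
    form: Proteoform,
    pka: PkaSet | None = None,
    tables: MassTables | None = None,
) -> GelCoordinate:
    """Theoretical gel coordinate of a proteoform.

    pI comes from the monomeric chain composition (modification charge
    effects ignored); MW is the average proteoform mass in kDa, so dimers
    double MW but keep the monomer pI.
    """
    pi = isoelectric_point(form.chain, pka)
    mw = proteoform_mass(form, MassKind.AVG, tables) / 1000.0
    return GelCoordinate(pI=pi, mw_kda=mw)
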