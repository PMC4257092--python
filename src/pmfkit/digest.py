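"""In-silico trypsin digestion, modification-state enumeration, fingerprints.

Peptides with up to ``max_missed`` missed cleavages are the maximal runs of
consecutive zero-missed fragments; every placeable combination of variable
modifications yields a separate theoretical peptide with its own [M+H]+.
Spans are reported in mature coordinates of the *parent* protein, so
truncated proteoforms keep the parent numbering.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .masscalc import MassKind, MassTables, default_mass_tables, mz_mh, peptide_mass
from .seqmodel import Modification, Proteoform, load_modifications

logger = logging.getLogger(__name__)

TRYPSIN = "trypsin"

AMBIGUOUS = "AMBIGUOUS"
RESOLVED = "RESOLVED"


@dataclass(frozen=True)
class DigestParams:
    """Digestion and reporting parameters.

    ``no_p_rule`` suppresses cleavage when the residue after K/R is proline
    (Keil convention, the default).  ``mass_window`` bounds reported [M+H]+
    values, mirroring a reflector acquisition range.
    """

    enzyme: str = TRYPSIN
    no_p_rule: bool = True
    max_missed: int = 2
    min_len: int = 1
    max_len: int | None = None
    mass_window: tuple[float, float] = (500.0, 4000.0)
    max_states_per_peptide: int = 16

    def __post_init__(self) -> None:
        if self.enzyme != TRYPSIN:
            raise ValueError(f"unknown enzyme rule {self.enzyme!r}")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len is not None and self.max_len < self.min_len:
            raise ValueError("max_len < min_len")
        lo, hi = self.mass_window
        if not lo < hi:
            raise ValueError("mass_window min must be < max")


@dataclass(frozen=True)
class TheoreticalPeptide:
    """One tryptic peptide in one modification state."""

    span: tuple[int, int]
    sequence: str
    missed: int
    mod_state: tuple[tuple[Modification, int], ...]
    mh_mono: float

    def mod_label(self) -> str:
        parts = [f"{count}x{mod.name}" for mod, count in self.mod_state if count]
        return "+".join(parts) if parts else "unmodified"


@dataclass(frozen=True)
class TheoreticalFingerprint:
    """The set of theoretical tryptic peptides of one proteoform."""

    form: Proteoform
    peptides: tuple[TheoreticalPeptide, ...]
    params: DigestParams

    def spans(self) -> list[tuple[int, int]]:
        return sorted({p.span for p in self.peptides})


def default_variable_mods() -> list[Modification]:
    """The PMF search set: oxidation on Met, propionamide (acrylamide) on Cys."""
    mods = load_modifications()
    return [mods["oxidation"], mods["propionamide"]]


def cleavage_sites(chain: str, params: DigestParams | None = None) -> list[int]:
    """1-based positions after which trypsin cuts (K/R, optional no-P rule).

    The final residue is not reported as a site: cleavage after it is simply
    the chain end.
    """
    if not chain:
        raise ValueError("empty chain")
    params = params or DigestParams()
    sites = []
    for i in range(1, len(chain)):  # position i (1-based), next residue chain[i]
        if chain[i - 1] in "KR" and (not params.no_p_rule or chain[i] != "P"):
            sites.append(i)
    return sites


def fragments(chain: str, params: DigestParams | None = None) -> list[tuple[int, int]]:
    """Zero-missed-cleavage fragment spans (1-based, local to ``chain``)."""
    params = params or DigestParams()
    bounds = [0] + cleavage_sites(chain, params) + [len(chain)]
    return [(bounds[i] + 1, bounds[i + 1]) for i in range(len(bounds) - 1)]


def enumerate_mod_states(
    sequence: str,
    variable_mods: list[Modification],
    max_states: int = 16,
    oxidation_cap: int = 2,
) -> list[tuple[tuple[Modification, int], ...]]:
    """Enumerate variable-modification count combinations for one peptide.

    Policy: at most ``oxidation_cap`` oxidations; Cys adducts (propionamide
    or other all-Cys chemistry) are all-or-none per peptide; other variable
    modifications get a full 0..n_sites count range.  When the combination
    count exceeds ``max_states`` the lowest-total-count states are kept and a
    warning is logged (deterministic pruning).
    """
    per_mod: list[list[tuple[Modification, int]]] = []
    for mod in variable_mods:
        n = mod.n_sites(sequence)
        if n == 0:
            continue
        if mod.name == "oxidation":
            counts = list(range(0, min(n, oxidation_cap) + 1))
        elif "C" in mod.targets:
            counts = [0, n]  # all-or-none Cys chemistry
        else:
            counts = list(range(0, n + 1))
        per_mod.append([(mod, c) for c in counts])
    if not per_mod:
        return [()]
    states = [tuple(combo) for combo in itertools.product(*per_mod)]
    states.sort(key=lambda st: (sum(c for _, c in st), tuple(c for _, c in st)))
    if len(states) > max_states:
        logger.warning(
            "peptide %r: %d modification states exceed cap %d; pruning",
            sequence, len(states), max_states,
        )
        states = states[:max_states]
    return states


def digest(
    form: Proteoform,
    params: DigestParams | None = None,
    variable_mods: list[Modification] | None = None,
    tables: MassTables | None = None,
) -> TheoreticalFingerprint:
    """Build the theoretical fingerprint of a proteoform.

    Deterministic: equal inputs give identical fingerprints.  Peptides are
    filtered by the length bounds and the [M+H]+ mass window of ``params``.
    """
    params = params or DigestParams()
    if variable_mods is None:
        variable_mods = default_variable_mods()
    tables = tables or default_mass_tables()
    chain = form.chain
    offset = form.span[0] - 1  # local position 1 -> mature position offset+1
    frags = fragments(chain, params)
    fixed = list(form.fixed_mods)
    peptides: list[TheoreticalPeptide] = []
    seen: set[tuple[tuple[int, int], tuple[tuple[str, int], ...]]] = set()
    lo, hi = params.mass_window
    for i in range(len(frags)):
        for w in range(1, params.max_missed + 2):
            if i + w > len(frags):
                break
            start = frags[i][0]
            end = frags[i + w - 1][1]
            seq = chain[start - 1 : end]
            if len(seq) < params.min_len:
                continue
            if params.max_len is not None and len(seq) > params.max_len:
                continue
            span = (start + offset, end + offset)
            base = peptide_mass(seq, fixed, MassKind.MONO, tables)
            for state in enumerate_mod_states(
                seq, variable_mods, params.max_states_per_peptide
            ):
                key = (span, tuple((m.name, c) for m, c in state))
                if key in seen:
                    continue
                seen.add(key)
                delta = sum(c * m.mono_delta for m, c in state)
                mh = mz_mh(base + delta, tables)
                if not (lo <= mh <= hi):
                    continue
                peptides.append(
                    TheoreticalPeptide(
                        span=span,
                        sequence=seq,
                        missed=w - 1,
                        mod_state=state,
                        mh_mono=mh,
                    )
                )
    peptides.sort(key=lambda p: (p.span[0], p.span[1], p.mh_mono))
    return TheoreticalFingerprint(form=form, peptides=tuple(peptides), params=params)


def find_peptide(
    fp: TheoreticalFingerprint, span: tuple[int, int]
) -> list[TheoreticalPeptide]:
    """All modification states of the peptide with the given mature span."""
    return [p for p in fp.peptides if p.span == span]


def canonical_state(states: list[TheoreticalPeptide]) -> TheoreticalPeptide:
    """The modification state reported for a peptide in PMF summaries.

    Policy (fixed a priori): all cysteines carry the acrylamide adduct —
    in-gel digests of acrylamide gels yield propionamide-Cys as the dominant
    form — and methionines are unoxidised.  For Cys-free peptides this is
    simply the unmodified state.
    """
    if not states:
        raise ValueError("no states to choose from")

    def key(p: TheoreticalPeptide) -> tuple[int, int]:
        counts = {m.name: c for m, c in p.mod_state}
        n_cys = p.sequence.count("C")
        # exact-propionamide first, then fewest oxidations
        return (
            abs(counts.get("propionamide", 0) - n_cys),
            counts.get("oxidation", 0),
        )

    return min(states, key=key)


# ---------------------------------------------------------------------------
# Splice-variant diagnostics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiagnosticPeptide:
    """A peptide unique (by sequence) to one of two fingerprints."""

    owner: str  # "a" or "b"
    peptide: TheoreticalPeptide
    nearest_other: TheoreticalPeptide | None
    delta_da: float | None
    flag: str  # AMBIGUOUS or RESOLVED


@dataclass(frozen=True)
class DiagnosticReport:
    unique_a: tuple[DiagnosticPeptide, ...]
    unique_b: tuple[DiagnosticPeptide, ...]
    tolerance_da: float


def diagnostic_peptides(
    a: TheoreticalFingerprint,
    b: TheoreticalFingerprint,
    tolerance_da: float = 0.15,
) -> DiagnosticReport:
    """Find sequence-unique peptides of two fingerprints and near-isobaric risks.

    For each peptide sequence present in exactly one fingerprint, the
    nearest-mass peptide of the other fingerprint is reported; the pair is
    flagged AMBIGUOUS when |Δm| <= ``tolerance_da``, RESOLVED otherwise.
    """
    if a.params != b.params:
        raise ValueError("fingerprints were built with different params")

    def uniques(src: TheoreticalFingerprint, other: TheoreticalFingerprint, tag: str):
        other_seqs = {p.sequence for p in other.peptides}
        out = []
        for pep in src.peptides:
            if pep.sequence in other_seqs:
                continue
            nearest = min(
                other.peptides,
                key=lambda q: abs(q.mh_mono - pep.mh_mono),
                default=None,
            )
            dm = abs(nearest.mh_mono - pep.mh_mono) if nearest else None
            flag = AMBIGUOUS if dm is not None and dm <= tolerance_da else RESOLVED
            out.append(
                DiagnosticPeptide(
                    owner=tag, peptide=pep, nearest_other=nearest,
                    delta_da=dm, flag=flag,
                )
            )
        return tuple(out)

    return DiagnosticReport(
        unique_a=uniques(a, b, "a"),
        unique_b=uniques(b, a, "b"),
        tolerance_da=tolerance_da,
    )


def export_fingerprint_tsv(fp: TheoreticalFingerprint, path) -> None:
    """Write a fingerprint as TSV (span_start, span_end, sequence, missed, mods, mh_mono)."""
    with open(path, "w") as fh:
        fh.write("span_start\tspan_end\tsequence\tmissed\tmods\tmh_mono\n")
        for p in fp.peptides:
            fh.write(
                f"{p.span[0]}\t{p.span[1]}\t{p.sequence}\t{p.missed}\t"
                f"{p.mod_label()}\t{p.mh_mono:.4f}\n"
            )
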