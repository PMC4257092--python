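"""Domain types for proteins, proteoforms and modifications, plus FASTA I/O.

Coordinates are 1-based inclusive and always refer to the *mature* chain
(the precursor minus any annotated signal peptide).  Truncated proteoforms
keep the numbering of their parent mature chain, so a span such as (16, 158)
means "residues 16..158 of the mature protein".
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The 20 canonical amino-acid one-letter codes.
CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Ambiguity / non-standard letters rejected by default.
NON_CANONICAL_AA = frozenset("BJOUXZ")

N_TERM = "N-TERM"
C_TERM = "C-TERM"

FIXED = "FIXED"
VARIABLE = "VARIABLE"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class SequenceAlphabetError(ValueError):
    """Raised when a sequence contains letters outside the canonical 20."""


@dataclass(frozen=True)
class ProteinRecord:
    """A named amino-acid sequence with an optional mature-chain annotation.

    Parameters
    ----------
    id : str
        Short unique label (FASTA header token before the first whitespace).
    sequence : str
        Uppercase amino-acid string over the 20-letter alphabet.
    accession : str
        Free-text database identifier; may be empty for synthetic records.
    mature_span : tuple[int, int]
        1-based inclusive positions delimiting the mature chain within
        ``sequence``.  Defaults to ``(1, len(sequence))``.
    description : str
        Free text (remainder of the FASTA header).
    """

    id: str
    sequence: str
    accession: str = ""
    mature_span: tuple[int, int] | None = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ProteinRecord id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        bad = [(i + 1, c) for i, c in enumerate(self.sequence) if c not in CANONICAL_AA]
        if bad:
            pos, c = bad[0]
            raise SequenceAlphabetError(
                f"record {self.id!r}: non-canonical letter {c!r} at position {pos}"
            )
        if self.mature_span is None:
            object.__setattr__(self, "mature_span", (1, len(self.sequence)))
        start, end = self.mature_span
        if not (1 <= start <= end <= len(self.sequence)):
            raise ValueError(
                f"record {self.id!r}: mature_span {self.mature_span} outside "
                f"1..{len(self.sequence)}"
            )


def mature_chain(record: ProteinRecord) -> str:
    """Return the mature-chain slice of ``record.sequence``."""
    start, end = record.mature_span
    return record.sequence[start - 1 : end]


def mature_length(record: ProteinRecord) -> int:
    start, end = record.mature_span
    return end - start + 1


@dataclass(frozen=True)
class Modification:
    """A mass shift attached to specific residue letters or a terminus."""

    name: str
    targets: frozenset[str]
    mono_delta: float
    avg_delta: float
    mode: str = VARIABLE

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"modification {self.name!r}: targets must be non-empty")
        for t in self.targets:
            if t not in CANONICAL_AA and t not in (N_TERM, C_TERM):
                raise ValueError(f"modification {self.name!r}: bad target {t!r}")
        for d in (self.mono_delta, self.avg_delta):
            if d != d or d in (float("inf"), float("-inf")):
                raise ValueError(f"modification {self.name!r}: non-finite delta")
        if self.mode not in (FIXED, VARIABLE):
            raise ValueError(f"modification {self.name!r}: mode must be FIXED or VARIABLE")

    def n_sites(self, sequence: str) -> int:
        """Number of placeable sites for this modification in ``sequence``."""
        n = sum(sequence.count(t) for t in self.targets if len(t) == 1)
        if N_TERM in self.targets:
            n += 1
        if C_TERM in self.targets:
            n += 1
        return n


def load_modifications() -> dict[str, Modification]:
    """Load the shipped modification table keyed by name."""
    from importlib.resources import files

    out: dict[str, Modification] = {}
    text = files("pmfkit.data").joinpath("modifications.tsv").read_text()
    rows = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    reader = csv.DictReader(rows, delimiter="\t")
    for row in reader:
        mod = Modification(
            name=row["name"],
            targets=frozenset(row["targets"].split(",")),
            mono_delta=float(row["mono_delta"]),
            avg_delta=float(row["avg_delta"]),
            mode=row["mode"],
        )
        out[mod.name] = mod
    return out


@dataclass(frozen=True)
class Proteoform:
    """A contiguous sub-chain of a protein plus modification state and multimer count.

    ``span`` is expressed in mature-chain 1-based inclusive coordinates of the
    parent protein, so proteoforms keep parent numbering after truncation.
    """

    protein: ProteinRecord
    span: tuple[int, int] | None = None
    fixed_mods: tuple[tuple[Modification, int], ...] = ()
    multimer: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        n = mature_length(self.protein)
        if self.span is None:
            object.__setattr__(self, "span", (1, n))
        start, end = self.span
        if not (1 <= start <= end <= n):
            raise ValueError(
                f"proteoform span {self.span} outside mature chain 1..{n} "
                f"of {self.protein.id!r}"
            )
        if self.multimer < 1:
            raise ValueError("multimer must be >= 1")

    @property
    def chain(self) -> str:
        """The proteoform's amino-acid chain (mature-coordinate slice)."""
        start, end = self.span
        return mature_chain(self.protein)[start - 1 : end]

    def __len__(self) -> int:
        start, end = self.span
        return end - start + 1


def apply_truncation(form: Proteoform, new_span: tuple[int, int]) -> Proteoform:
    """Return a narrowed copy of ``form`` labelled with the removed intervals.

    Labels use mature coordinates, e.g. removing residues 1..15 from a
    (1, 158) span yields a label containing ``ΔN1–15``; dropping the final
    residue yields ``ΔC158``.
    """
    start, end = form.span
    ns, ne = new_span
    if not (start <= ns <= ne <= end):
        raise ValueError(f"new span {new_span} escapes parent span {form.span}")
    parts = []
    if ns > start:
        parts.append(f"ΔN{start}" if ns == start + 1 else f"ΔN{start}–{ns - 1}")
    if ne < end:
        parts.append(f"ΔC{end}" if ne == end - 1 else f"ΔC{ne + 1}–{end}")
    label = " ".join(parts)
    if form.label and label:
        label = f"{form.label} {label}"
    elif form.label:
        label = form.label
    return replace(form, span=new_span, label=label)


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def read_fasta(
    path: str | Path, permissive: bool = False
) -> list[ProteinRecord] | tuple[list[ProteinRecord], list[str]]:
    """Read protein records from a FASTA file.

    Sequences are uppercased, whitespace-stripped, and trailing ``*`` stop
    symbols removed.  Records containing non-canonical letters raise
    :class:`SequenceAlphabetError` unless ``permissive`` is true, in which
    case they are collected into a skip list and the function returns
    ``(records, skipped_ids)``.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    skipped: list[str] = []
    text = path.read_text()
    if text.strip() and not text.lstrip().startswith(">"):
        raise FastaFormatError(f"{path}: not FASTA (no '>' header before sequence data)")
    n_entries = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_entries += 1
        seq = "".join(str(rec.seq).split()).upper().rstrip("*")
        name = rec.id or f"entry_{n_entries}"
        if not seq:
            raise FastaFormatError(f"{path}: entry {name!r} has an empty sequence")
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        try:
            records.append(ProteinRecord(id=name, sequence=seq, description=desc))
        except SequenceAlphabetError:
            if permissive:
                skipped.append(name)
                continue
            raise
    if n_entries == 0:
        logger.warning("%s: empty FASTA file, no records read", path)
    if permissive:
        return records, skipped
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA, wrapped at 60 columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# Reference registry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegistryEntry:
    id: str
    accession: str
    fasta_path: Path
    mature_span: tuple[int, int] | None = None


def load_registry(path: str | Path) -> dict[str, RegistryEntry]:
    """Load a reference registry TSV.

    Columns: ``id``, ``accession``, ``fasta_path`` and optionally
    ``mature_start`` / ``mature_end`` (1-based, blank = full length).
    Relative FASTA paths resolve against the registry file's directory.
    """
    path = Path(path)
    out: dict[str, RegistryEntry] = {}
    with open(path) as fh:
        rows = [ln for ln in fh if ln.strip() and not ln.startswith("#")]
    for row in csv.DictReader(rows, delimiter="\t"):
        span = None
        if row.get("mature_start") and row.get("mature_end"):
            span = (int(row["mature_start"]), int(row["mature_end"]))
        fasta = Path(row["fasta_path"])
        if not fasta.is_absolute():
            fasta = path.parent / fasta
        entry = RegistryEntry(
            id=row["id"], accession=row["accession"], fasta_path=fasta, mature_span=span
        )
        out[entry.id] = entry
    return out


def load_reference(entry: RegistryEntry) -> ProteinRecord:
    """Load the first FASTA record for a registry entry, applying its annotations."""
    records = read_fasta(entry.fasta_path)
    rec = records[0]
    return replace(
        rec, accession=entry.accession, mature_span=entry.mature_span, id=entry.id
    )


# ---------------------------------------------------------------------------
# Nucleotide helper
# ---------------------------------------------------------------------------

def translate_orf(nucleotides: str) -> str:
    """Translate a cDNA from its first ATG to the first in-frame stop.

    Standard genetic code only; intended for single-ORF cDNA inputs.
    """
    nt = "".join(nucleotides.split()).upper().replace("U", "T")
    start = nt.find("ATG")
    if start < 0:
        raise ValueError("no ATG initiator codon found")
    coding = nt[start:]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate(to_stop=True))
    if not protein:
        raise ValueError("ORF is empty after translation")
    return protein
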