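"""Peak-list I/O, two-point calibration, tolerance matching, ranked identification."""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path

from .digest import TheoreticalFingerprint, TheoreticalPeptide
from .seqmodel import mature_length

logger = logging.getLogger(__name__)


class ToleranceUnit(enum.Enum):
    PPM = "ppm"
    DA = "da"


class PeakListFormatError(ValueError):
    pass


@dataclass(frozen=True)
class PeakList:
    """Measured m/z values (optionally with intensities) for one gel spot."""

    spot_id: str
    peaks: tuple[tuple[float, float | None], ...]
    calibrated: bool = False
    calibration_refs: tuple[tuple[float, float], tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        mzs = [mz for mz, _ in self.peaks]
        if any(mz <= 0 or math.isnan(mz) for mz in mzs):
            raise ValueError("m/z values must be positive and not NaN")
        if any(b <= a for a, b in zip(mzs, mzs[1:])):
            raise ValueError("m/z values must be strictly ascending")
        if any(i is not None and (i < 0 or math.isnan(i)) for _, i in self.peaks):
            raise ValueError("intensities must be non-negative")

    @property
    def mz(self) -> tuple[float, ...]:
        return tuple(mz for mz, _ in self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)


def _sorted_dedup(
    pairs: list[tuple[float, float | None]]
) -> tuple[tuple[float, float | None], ...]:
    """Sort ascending and collapse near-duplicates (|Δ| < 1e-6), keeping max intensity."""
    pairs = sorted(pairs, key=lambda p: p[0])
    out: list[tuple[float, float | None]] = []
    for mz, inten in pairs:
        if out and abs(mz - out[-1][0]) < 1e-6:
            prev_mz, prev_i = out[-1]
            best = max(
                (x for x in (prev_i, inten) if x is not None), default=None
            )
            out[-1] = (prev_mz, best)
        else:
            out.append((mz, inten))
    return tuple(out)


def read_peaklist(
    path: str | Path, dialect: str | None = None, spot_id: str | None = None
) -> PeakList:
    """Read a peak list from an MGF file or a 1-2 column numeric TSV.

    ``dialect`` is "mgf" or "tsv"; inferred from the extension when omitted.
    For MGF, only the first BEGIN IONS / END IONS block is read.
    """
    path = Path(path)
    if dialect is None:
        dialect = "mgf" if path.suffix.lower() == ".mgf" else "tsv"
    dialect = dialect.lower()
    if spot_id is None:
        spot_id = path.stem
    if dialect == "mgf":
        pairs, title = _read_mgf(path)
        if title:
            spot_id = title
    elif dialect == "tsv":
        pairs = _read_tsv(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if not pairs:
        logger.warning("%s: empty peak list", path)
    return PeakList(spot_id=spot_id, peaks=_sorted_dedup(pairs))


def _read_tsv(path: Path) -> list[tuple[float, float | None]]:
    pairs: list[tuple[float, float | None]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            try:
                mz = float(fields[0])
                inten = float(fields[1]) if len(fields) > 1 else None
            except ValueError as exc:
                raise PeakListFormatError(
                    f"{path}: non-numeric peak at line {lineno}: {line!r}"
                ) from exc
            pairs.append((mz, inten))
    return pairs


def _read_mgf(path: Path) -> tuple[list[tuple[float, float | None]], str | None]:
    pairs: list[tuple[float, float | None]] = []
    title = None
    in_block = False
    seen_block = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                seen_block = True
                continue
            if line == "END IONS":
                break
            if not in_block:
                continue
            if "=" in line:
                key, _, value = line.partition("=")
                if key.upper() == "TITLE":
                    title = value.strip()
                continue
            fields = line.split()
            try:
                mz = float(fields[0])
                inten = float(fields[1]) if len(fields) > 1 else None
            except ValueError as exc:
                raise PeakListFormatError(
                    f"{path}: non-numeric ion line {lineno}: {line!r}"
                ) from exc
            pairs.append((mz, inten))
    if not seen_block:
        raise PeakListFormatError(f"{path}: no BEGIN IONS block found")
    return pairs, title


def write_peaklist_tsv(pl: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for mz, inten in pl.peaks:
            if inten is None:
                fh.write(f"{mz:.6f}\n")
            else:
                fh.write(f"{mz:.6f}\t{inten:.6g}\n")


def write_peaklist_mgf(pl: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("BEGIN IONS\n")
        fh.write(f"TITLE={pl.spot_id}\n")
        for mz, inten in pl.peaks:
            if inten is None:
                fh.write(f"{mz:.6f}\n")
            else:
                fh.write(f"{mz:.6f} {inten:.6g}\n")
        fh.write("END IONS\n")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate(
    pl: PeakList, refs: tuple[tuple[float, float], tuple[float, float]]
) -> PeakList:
    """Apply the affine map fitted through two (observed, true) anchor pairs.

    Anchors map exactly onto their true values; all other m/z are transformed
    by the same line.
    """
    (obs1, true1), (obs2, true2) = refs
    if obs1 == obs2:
        raise ValueError("degenerate calibration: identical observed anchors")
    slope = (true2 - true1) / (obs2 - obs1)
    intercept = true1 - slope * obs1
    peaks = tuple((slope * mz + intercept, inten) for mz, inten in pl.peaks)
    return replace(pl, peaks=peaks, calibrated=True, calibration_refs=refs)


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MatchResult:
    """Assignment of measured peaks to one theoretical fingerprint."""

    fingerprint: TheoreticalFingerprint
    assignments: tuple[tuple[int, TheoreticalPeptide, float], ...]  # (peak idx, pep, ppm)
    matched_count: int
    coverage_pct: float
    score: float

    @property
    def coverage_display(self) -> int:
        """Coverage rounded to the nearest integer, as printed in reports."""
        return round(self.coverage_pct)

    def matched_spans(self) -> list[tuple[int, int]]:
        return sorted({pep.span for _, pep, _ in self.assignments})


def _error_da(tol: float, unit: ToleranceUnit, mz: float) -> float:
    return tol * mz * 1e-6 if unit is ToleranceUnit.PPM else tol


def span_union_size(spans: list[tuple[int, int]]) -> int:
    """Total number of residues covered by a union of 1-based inclusive spans."""
    covered = 0
    last_end = 0
    for start, end in sorted(spans):
        start = max(start, last_end + 1)
        if end >= start:
            covered += end - start + 1
            last_end = max(last_end, end)
    return covered


def match(
    pl: PeakList,
    fp: TheoreticalFingerprint,
    tol: float = 50.0,
    tol_unit: ToleranceUnit = ToleranceUnit.PPM,
    accept_uncalibrated: bool = False,
) -> MatchResult:
    """Greedy nearest-mass one-to-one assignment of peaks to theoretical peptides.

    Candidate (peak, peptide) pairs within tolerance are assigned in ascending
    order of absolute error; each peak and each (span, mod state) is used at
    most once.  Coverage is the matched-span union over the mature-chain
    length of the candidate's parent protein.  Score is the matched count.
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if not pl.calibrated and not accept_uncalibrated:
        raise ValueError(
            "peak list is not calibrated; pass accept_uncalibrated=True to match as-is"
        )
    import bisect

    by_mass = sorted(range(len(fp.peptides)), key=lambda i: fp.peptides[i].mh_mono)
    masses = [fp.peptides[i].mh_mono for i in by_mass]
    candidates = []
    for pi, (mz, _) in enumerate(pl.peaks):
        # widest possible error window at this m/z (ppm windows grow with mass)
        max_da = _error_da(tol, tol_unit, max(mz, masses[-1]) if masses else mz)
        lo = bisect.bisect_left(masses, mz - max_da)
        hi = bisect.bisect_right(masses, mz + max_da)
        for k in range(lo, hi):
            ti = by_mass[k]
            pep = fp.peptides[ti]
            err = mz - pep.mh_mono
            if abs(err) <= _error_da(tol, tol_unit, pep.mh_mono):
                ppm = err / pep.mh_mono * 1e6
                candidates.append((abs(err), pi, ti, ppm))
    candidates.sort()
    used_peaks: set[int] = set()
    used_peps: set[int] = set()
    assignments = []
    for _, pi, ti, ppm in candidates:
        if pi in used_peaks or ti in used_peps:
            continue
        used_peaks.add(pi)
        used_peps.add(ti)
        assignments.append((pi, fp.peptides[ti], ppm))
    assignments.sort(key=lambda a: a[0])
    spans = sorted({pep.span for _, pep, _ in assignments})
    denom = mature_length(fp.form.protein)
    coverage = 100.0 * span_union_size(spans) / denom
    return MatchResult(
        fingerprint=fp,
        assignments=tuple(assignments),
        matched_count=len(assignments),
        coverage_pct=coverage,
        score=float(len(assignments)),
    )


# ---------------------------------------------------------------------------
# Identification over candidates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Identification:
    """Ranked per-spot identification over a candidate fingerprint set."""

    spot_id: str
    ranked: tuple[MatchResult, ...]
    min_matched: int
    mixture_flag: bool

    @property
    def accepted(self) -> tuple[MatchResult, ...]:
        return tuple(r for r in self.ranked if r.matched_count >= self.min_matched)

    @property
    def top(self) -> MatchResult | None:
        return self.ranked[0] if self.ranked else None


def _rank_key(mr: MatchResult):
    prot = mr.fingerprint.form.protein
    # descending score / matched / coverage, ascending accession then id
    return (-mr.score, -mr.matched_count, -mr.coverage_pct, prot.accession, prot.id)


def identify(
    pl: PeakList,
    candidates: list[TheoreticalFingerprint],
    tol: float = 50.0,
    tol_unit: ToleranceUnit = ToleranceUnit.PPM,
    min_matched: int = 4,
    accept_uncalibrated: bool = False,
) -> Identification:
    """Run :func:`match` per candidate and rank deterministically.

    Candidates with ``matched_count >= min_matched`` are accepted; the
    mixture flag is raised when at least two are accepted.
    """
    if not candidates:
        raise ValueError("candidate set is empty")
    results = [
        match(pl, fp, tol, tol_unit, accept_uncalibrated=accept_uncalibrated)
        for fp in candidates
    ]
    results.sort(key=_rank_key)
    accepted = [r for r in results if r.matched_count >= min_matched]
    return Identification(
        spot_id=pl.spot_id,
        ranked=tuple(results),
        min_matched=min_matched,
        mixture_flag=len(accepted) >= 2,
    )


@dataclass(frozen=True)
class AmbiguityNote:
    """A matched peak with an alternative theoretical interpretation nearby."""

    peak_mz: float
    assigned: TheoreticalPeptide
    alternative: TheoreticalPeptide
    alternative_candidate: str
    delta_da: float


def ambiguity_scan(
    ident: Identification,
    tol: float = 0.15,
    tol_unit: ToleranceUnit = ToleranceUnit.DA,
) -> list[AmbiguityNote]:
    """For each matched peak, list alternative peptides (any candidate) within tol.

    Each (assigned, alternative) pair is reported once, regardless of how many
    candidate match results share the peak.
    """
    notes: list[AmbiguityNote] = []
    seen: set[frozenset] = set()
    for mr in ident.ranked:
        own = mr.fingerprint.form.protein.id
        for _, pep, _ in mr.assignments:
            for other in ident.ranked:
                other_id = other.fingerprint.form.protein.id
                for alt in other.fingerprint.peptides:
                    if other is mr and alt.span == pep.span and alt.mod_state == pep.mod_state:
                        continue  # the assignment itself
                    dm = abs(alt.mh_mono - pep.mh_mono)
                    if dm > _error_da(tol, tol_unit, pep.mh_mono):
                        continue
                    key = frozenset(
                        {
                            (own, pep.span, tuple((m.name, c) for m, c in pep.mod_state)),
                            (other_id, alt.span, tuple((m.name, c) for m, c in alt.mod_state)),
                        }
                    )
                    if key in seen:
                        continue
                    seen.add(key)
                    notes.append(
                        AmbiguityNote(
                            peak_mz=pep.mh_mono,
                            assigned=pep,
                            alternative=alt,
                            alternative_candidate=other_id,
                            delta_da=dm,
                        )
                    )
    return notes
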