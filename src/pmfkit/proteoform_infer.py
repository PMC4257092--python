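"""Proteoform inference from matched-peptide footprints.

Terminal status is only resolvable to tryptic-fragment granularity: a
terminus is called ABSENT when its terminal fragment was observable (inside
the mass window and length bounds, in at least one modification state) yet
no matched peptide touches it, and PRESENT when a matched peptide reaches
the terminal residue.  An unobservable terminal fragment can never support
an ABSENT call.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

from .digest import DigestParams, enumerate_mod_states, default_variable_mods, fragments, find_peptide
from .masscalc import (
    GelCoordinate,
    MassKind,
    MassTables,
    default_mass_tables,
    mz_mh,
    peptide_mass,
    predict_spot,
)
from .pmf_match import Identification, MatchResult, PeakList, ToleranceUnit, _error_da
from .seqmodel import ProteinRecord, Proteoform, mature_chain, mature_length

EXACT_BOUNDARY_UNKNOWN = "EXACT_BOUNDARY_UNKNOWN"


class TerminalStatus(enum.Enum):
    PRESENT = "PRESENT"
    ABSENT = "ABSENT"
    UNDETERMINED = "UNDETERMINED"


class CtermVariant(enum.Enum):
    FULL = "FULL"
    DES_K = "DES_K"
    BOTH = "BOTH"
    NEITHER = "NEITHER"


class GelFlag(enum.Enum):
    CONSISTENT = "CONSISTENT"
    TRUNCATED = "TRUNCATED"
    DIMER = "DIMER"


@dataclass(frozen=True)
class TerminalCall:
    """Per-candidate terminal status inferred from the matched footprint."""

    n_status: TerminalStatus
    c_status: TerminalStatus
    inferred_span: tuple[int, int] | None
    evidence: dict

    def __post_init__(self) -> None:
        if self.inferred_span is None and (
            self.n_status is not TerminalStatus.UNDETERMINED
            or self.c_status is not TerminalStatus.UNDETERMINED
        ):
            raise ValueError("inferred_span required unless both termini UNDETERMINED")


def call_terminals(mr: MatchResult, params: DigestParams | None = None) -> TerminalCall:
    """Infer N/C-terminal presence from a match against a full-length fingerprint."""
    fp = mr.fingerprint
    params = params or fp.params
    form = fp.form
    chain_len = mature_length(form.protein)
    if form.span != (1, chain_len):
        raise ValueError("call_terminals requires a match against the full-length form")
    chain = form.chain
    frags = fragments(chain, params)
    first_frag, last_frag = frags[0], frags[-1]
    matched = mr.matched_spans()
    evidence: dict = {
        "first_fragment": first_frag,
        "last_fragment": last_frag,
        "matched_spans": matched,
        "notes": [],
    }
    if not matched:
        evidence["notes"].append("no matched peptides")
        return TerminalCall(
            n_status=TerminalStatus.UNDETERMINED,
            c_status=TerminalStatus.UNDETERMINED,
            inferred_span=None,
            evidence=evidence,
        )
    # Observability: the fingerprint already applies the mass window and
    # length bounds, so a terminal fragment is observable iff present there.
    n_observable = bool(find_peptide(fp, first_frag))
    c_observable = bool(find_peptide(fp, last_frag))
    evidence["n_observable"] = n_observable
    evidence["c_observable"] = c_observable

    def overlaps(span: tuple[int, int], frag: tuple[int, int]) -> bool:
        return span[0] <= frag[1] and frag[0] <= span[1]

    if any(s[0] == 1 for s in matched):
        n_status = TerminalStatus.PRESENT
    elif n_observable and not any(overlaps(s, first_frag) for s in matched):
        n_status = TerminalStatus.ABSENT
        evidence["notes"].append(f"N:{EXACT_BOUNDARY_UNKNOWN}")
    else:
        n_status = TerminalStatus.UNDETERMINED

    if any(s[1] == chain_len for s in matched):
        c_status = TerminalStatus.PRESENT
    elif c_observable and not any(overlaps(s, last_frag) for s in matched):
        c_status = TerminalStatus.ABSENT
        evidence["notes"].append(f"C:{EXACT_BOUNDARY_UNKNOWN}")
    else:
        c_status = TerminalStatus.UNDETERMINED

    inferred = (min(s[0] for s in matched), max(s[1] for s in matched))
    return TerminalCall(
        n_status=n_status, c_status=c_status, inferred_span=inferred, evidence=evidence
    )


def call_cterm_variant(
    pl: PeakList,
    protein: ProteinRecord,
    params: DigestParams | None = None,
    tol: float = 50.0,
    tol_unit: ToleranceUnit = ToleranceUnit.PPM,
    tables: MassTables | None = None,
) -> CtermVariant:
    """Check peak support for the intact vs residue-clipped C-terminal peptide.

    When the mature chain ends in K or R, both the intact C-terminal tryptic
    peptide and its counterpart lacking the terminal residue (the "des"
    hypothesis) are built, in every modification state, and checked against
    the peak list.  Returns which hypotheses have support.
    """
    params = params or DigestParams()
    tables = tables or default_mass_tables()
    chain = mature_chain(protein)
    var_mods = default_variable_mods()

    def supported(peptide: str) -> bool:
        if not peptide:
            return False
        for state in enumerate_mod_states(peptide, var_mods, params.max_states_per_peptide):
            delta = sum(c * m.mono_delta for m, c in state)
            mh = mz_mh(peptide_mass(peptide, None, MassKind.MONO, tables) + delta, tables)
            for mz in pl.mz:
                if abs(mz - mh) <= _error_da(tol, tol_unit, mh):
                    return True
        return False

    full_pep = chain[fragments(chain, params)[-1][0] - 1 :]
    full_ok = supported(full_pep)
    if chain[-1] not in "KR":
        return CtermVariant.FULL if full_ok else CtermVariant.NEITHER
    clipped = chain[:-1]
    des_pep = clipped[fragments(clipped, params)[-1][0] - 1 :] if clipped else ""
    des_ok = supported(des_pep)
    if full_ok and des_ok:
        return CtermVariant.BOTH
    if full_ok:
        return CtermVariant.FULL
    if des_ok:
        return CtermVariant.DES_K
    return CtermVariant.NEITHER


# ---------------------------------------------------------------------------
# Spot annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GelCheck:
    predicted: GelCoordinate
    observed: GelCoordinate
    flag: GelFlag


@dataclass(frozen=True)
class SpotAnnotation:
    spot_id: str
    identification: Identification
    terminal_calls: dict[str, TerminalCall]
    gel_checks: dict[str, GelCheck]


def annotate_spot(
    ident: Identification,
    observed: GelCoordinate,
    dimer_band: tuple[float, float] = (1.8, 2.2),
    truncation_deficit: float = 0.15,
) -> SpotAnnotation:
    """Per accepted candidate: terminal calls plus gel-position consistency.

    Flags are mutually exclusive: DIMER when observed/predicted monomer MW
    falls in ``dimer_band``; TRUNCATED when the observed MW deficit exceeds
    ``truncation_deficit`` and the N-terminus is called ABSENT; CONSISTENT
    otherwise.
    """
    terminal_calls: dict[str, TerminalCall] = {}
    gel_checks: dict[str, GelCheck] = {}
    for mr in ident.accepted:
        pid = mr.fingerprint.form.protein.id
        call = call_terminals(mr)
        predicted = predict_spot(mr.fingerprint.form)
        ratio = observed.mw_kda / predicted.mw_kda
        if dimer_band[0] <= ratio <= dimer_band[1]:
            flag = GelFlag.DIMER
        elif (
            ratio < 1.0 - truncation_deficit
            and call.n_status is TerminalStatus.ABSENT
        ):
            flag = GelFlag.TRUNCATED
        else:
            flag = GelFlag.CONSISTENT
        terminal_calls[pid] = call
        gel_checks[pid] = GelCheck(predicted=predicted, observed=observed, flag=flag)
    return SpotAnnotation(
        spot_id=ident.spot_id,
        identification=ident,
        terminal_calls=terminal_calls,
        gel_checks=gel_checks,
    )


def write_annotations_tsv(annotations: list[SpotAnnotation], path: str | Path) -> None:
    """Spot-annotation report: one row per (spot, accepted candidate)."""
    with open(path, "w") as fh:
        fh.write(
            "spot_id\tcandidate\tn_status\tc_status\t"
            "inferred_start\tinferred_end\tgel_flag\n"
        )
        for ann in annotations:
            for pid, call in ann.terminal_calls.items():
                span = call.inferred_span or ("", "")
                flag = ann.gel_checks[pid].flag.value
                fh.write(
                    f"{ann.spot_id}\t{pid}\t{call.n_status.value}\t"
                    f"{call.c_status.value}\t{span[0]}\t{span[1]}\t{flag}\n"
                )
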