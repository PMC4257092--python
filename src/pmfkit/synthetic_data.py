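"""Seeded synthetic proteomes, gel spots and MALDI peak lists, plus recovery scoring.

The noise model: each theoretical peptide is dropped with probability
``dropout``; surviving masses are perturbed multiplicatively by a Gaussian of
``error_ppm_sd`` ppm; ``n_noise_peaks`` contaminants are drawn uniformly over
the mass window; an optional affine miscalibration is applied to the whole
spectrum together with the two reference ions, so two-point recalibration can
be exercised end to end.  Everything is deterministic under the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .digest import DigestParams, digest
from .masscalc import GelCoordinate, predict_spot
from .pmf_match import PeakList, _sorted_dedup, write_peaklist_mgf, write_peaklist_tsv
from .proteoform_infer import SpotAnnotation, TerminalStatus
from .seqmodel import CANONICAL_AA, ProteinRecord, Proteoform, mature_length, write_fasta

#: Trypsin autolysis reference ions ([M+H]+, Da) used for two-point calibration.
CALIBRANT_MZ = (842.5100, 2211.1046)

AA_ORDER = sorted(CANONICAL_AA)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; ``family_spec`` holds per-protein proteoform templates.

    Templates: ``FULL``, ``TRUNC_N:k`` (remove mature residues 1..k),
    ``DES_CTERM`` (remove the final residue), ``DIMER``, ``MIX_WITH:j``
    (two-protein spot with protein index ``j``).
    """

    seed: int = 0
    n_proteins: int = 6
    length_range: tuple[int, int] = (80, 200)
    family_spec: tuple[tuple[str, ...], ...] | None = None
    error_ppm_sd: float = 10.0
    dropout: float = 0.0
    n_noise_peaks: int = 0
    include_calibrants: bool = False
    miscalibration: tuple[float, float] = (1.0002, -0.3)
    kr_weight: float = 3.0
    gel_pi_sd: float = 0.05
    gel_mw_rel_sd: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout <= 1.0):
            raise ValueError("dropout must be in [0, 1]")
        if self.error_ppm_sd < 0:
            raise ValueError("error_ppm_sd must be >= 0")
        if self.n_proteins < 0:
            raise ValueError("n_proteins must be >= 0")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range must be (min, max) with min <= max")
        if self.n_proteins > 0 and lo < 10:
            raise ValueError(
                "length_range minimum below 10 cannot satisfy the cleavage-site floor"
            )


@dataclass
class GroundTruthSpot:
    spot_id: str
    forms: list[dict]
    true_gel: dict
    emitted: list[dict]
    dropped: list[dict]
    noise_mz: list[float]
    miscalibrated: bool


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery scoring."""

    seed: int
    proteins: dict[str, str] = field(default_factory=dict)  # id -> sequence
    spots: dict[str, GroundTruthSpot] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "proteins": self.proteins,
            "spots": {k: asdict(v) for k, v in self.spots.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        gt = cls(seed=d["seed"], proteins=dict(d["proteins"]))
        for sid, sd in d["spots"].items():
            gt.spots[sid] = GroundTruthSpot(**sd)
        return gt


def _random_chain(rng: np.random.Generator, length: int, kr_weight: float) -> str:
    weights = np.array([kr_weight if aa in "KR" else 1.0 for aa in AA_ORDER])
    weights /= weights.sum()
    return "".join(rng.choice(AA_ORDER, size=length, p=weights))


def simulate_proteome(cfg: SimConfig) -> tuple[list[ProteinRecord], GroundTruth]:
    """Draw a random proteome; every chain contains at least 3 cleavage sites."""
    rng = np.random.default_rng(cfg.seed)
    records: list[ProteinRecord] = []
    truth = GroundTruth(seed=cfg.seed)
    from .digest import cleavage_sites

    for i in range(cfg.n_proteins):
        length = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        for attempt in range(200):
            chain = _random_chain(rng, length, cfg.kr_weight)
            if len(cleavage_sites(chain)) >= 3:
                break
        else:  # pragma: no cover - kr_weight floor makes this unreachable
            raise ValueError("could not satisfy cleavage-site floor; check config")
        rec = ProteinRecord(
            id=f"syn{i:03d}", sequence=chain, accession=f"SYN:{i:03d}",
            description="synthetic protein",
        )
        records.append(rec)
        truth.proteins[rec.id] = chain
    return records, truth


def template_to_forms(
    template: str, record: ProteinRecord, proteome: list[ProteinRecord]
) -> list[Proteoform]:
    """Expand a family-spec template into the proteoform(s) of one spot."""
    n = mature_length(record)
    if template == "FULL":
        return [Proteoform(record, label="full")]
    if template == "DES_CTERM":
        return [Proteoform(record, span=(1, n - 1), label="des-Cterm")]
    if template == "DIMER":
        return [Proteoform(record, multimer=2, label="dimer")]
    if template.startswith("TRUNC_N:"):
        k = int(template.split(":", 1)[1])
        if not (1 <= k < n):
            raise ValueError(f"TRUNC_N:{k} out of range for {record.id} (len {n})")
        return [Proteoform(record, span=(k + 1, n), label=f"ΔN1–{k}")]
    if template.startswith("MIX_WITH:"):
        j = int(template.split(":", 1)[1])
        other = proteome[j]
        return [Proteoform(record, label="full"), Proteoform(other, label="full")]
    raise ValueError(f"unknown proteoform template {template!r}")


def simulate_spot(
    forms: list[Proteoform],
    cfg: SimConfig,
    spot_id: str = "spot",
    rng: np.random.Generator | None = None,
    params: DigestParams | None = None,
) -> tuple[PeakList, GelCoordinate, GroundTruthSpot]:
    """Generate one spot's peak list, observed gel coordinate and truth entry."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    params = params or DigestParams()
    emitted: list[dict] = []
    dropped: list[dict] = []
    pairs: list[tuple[float, float | None]] = []
    for form in forms:
        fp = digest(form, params)
        for pep in fp.peptides:
            desc = {
                "protein": form.protein.id,
                "span": list(pep.span),
                "mods": pep.mod_label(),
                "mh_true": pep.mh_mono,
            }
            if cfg.dropout > 0 and rng.random() < cfg.dropout:
                dropped.append(desc)
                continue
            mz = pep.mh_mono
            if cfg.error_ppm_sd > 0:
                mz *= 1.0 + rng.normal(0.0, cfg.error_ppm_sd) * 1e-6
            emitted.append({**desc, "mz": mz})
            pairs.append((mz, None))
    lo, hi = params.mass_window
    noise_mz = sorted(rng.uniform(lo, hi, size=cfg.n_noise_peaks).tolist())
    pairs.extend((mz, None) for mz in noise_mz)

    predicted = predict_spot(forms[0])
    observed = GelCoordinate(
        pI=float(np.clip(predicted.pI + rng.normal(0.0, cfg.gel_pi_sd), 0.01, 13.99)),
        mw_kda=float(
            max(predicted.mw_kda * (1.0 + rng.normal(0.0, cfg.gel_mw_rel_sd)), 1e-3)
        ),
    )

    if cfg.include_calibrants:
        pairs.extend((mz, None) for mz in CALIBRANT_MZ)
        a, b = cfg.miscalibration
        pairs = [(a * mz + b, inten) for mz, inten in pairs]
        calibrated = False
    else:
        calibrated = True
    pl = PeakList(spot_id=spot_id, peaks=_sorted_dedup(pairs), calibrated=calibrated)

    def form_dict(form: Proteoform) -> dict:
        n = mature_length(form.protein)
        return {
            "protein": form.protein.id,
            "span": list(form.span),
            "multimer": form.multimer,
            "label": form.label,
            "n_status": "PRESENT" if form.span[0] == 1 else "ABSENT",
            "c_status": "PRESENT" if form.span[1] == n else "ABSENT",
        }

    truth = GroundTruthSpot(
        spot_id=spot_id,
        forms=[form_dict(f) for f in forms],
        true_gel={"pI": observed.pI, "mw_kda": observed.mw_kda},
        emitted=emitted,
        dropped=dropped,
        noise_mz=noise_mz,
        miscalibrated=cfg.include_calibrants,
    )
    return pl, observed, truth


def simulate_bundle(
    cfg: SimConfig, outdir: str | Path | None = None, peak_format: str = "tsv"
) -> tuple[list[ProteinRecord], dict[str, PeakList], dict[str, GelCoordinate], GroundTruth]:
    """Full simulation: proteome, one spot per family-spec template, optional files."""
    records, truth = simulate_proteome(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    spec = cfg.family_spec
    if spec is None:
        spec = tuple(("FULL",) for _ in records)
    peaklists: dict[str, PeakList] = {}
    gels: dict[str, GelCoordinate] = {}
    counter = 0
    for i, templates in enumerate(spec):
        if i >= len(records):
            raise ValueError("family_spec longer than proteome")
        for template in templates:
            counter += 1
            spot_id = f"spot{counter:03d}"
            forms = template_to_forms(template, records[i], records)
            pl, gel, spot_truth = simulate_spot(forms, cfg, spot_id, rng)
            peaklists[spot_id] = pl
            gels[spot_id] = gel
            truth.spots[spot_id] = spot_truth
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "proteome.fasta")
        for spot_id, pl in peaklists.items():
            if peak_format == "mgf":
                write_peaklist_mgf(pl, outdir / f"{spot_id}.mgf")
            else:
                write_peaklist_tsv(pl, outdir / f"{spot_id}.tsv")
        with open(outdir / "spots.tsv", "w") as fh:
            fh.write("spot_id\tobserved_pi\tobserved_mw_kda\n")
            for spot_id, gel in gels.items():
                fh.write(f"{spot_id}\t{gel.pI:.3f}\t{gel.mw_kda:.3f}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
    return records, peaklists, gels, truth


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    n_spots: int
    top1_rate: float
    mixture_detection_rate: float
    false_mixture_rate: float
    n_confusion: dict[str, int]
    c_confusion: dict[str, int]
    truncation_start_accuracy: float
    counts: dict[str, int]

    def to_dict(self) -> dict:
        return asdict(self)


def score_recovery(truth: GroundTruth, results: list[SpotAnnotation]) -> RecoveryReport:
    """Compare pipeline output against generator ground truth.

    Reports top-1 identification rate, mixture detection, a terminal-call
    confusion matrix keyed ``"TRUE->CALLED"``, and the fraction of
    N-truncated spots whose inferred span starts at the true truncation
    start.
    """
    by_spot = {ann.spot_id: ann for ann in results}
    unmatched = [sid for sid in by_spot if sid not in truth.spots]
    if unmatched:
        raise ValueError(f"results contain unknown spot_ids: {unmatched}")

    n_spots = len(truth.spots)
    top1 = 0
    mixtures = mixtures_found = 0
    non_mixtures = false_mixtures = 0
    n_conf: dict[str, int] = {}
    c_conf: dict[str, int] = {}
    trunc_total = trunc_correct = 0

    for sid, spot in truth.spots.items():
        ann = by_spot.get(sid)
        true_ids = [f["protein"] for f in spot.forms]
        is_mixture = len(set(true_ids)) > 1
        if is_mixture:
            mixtures += 1
        else:
            non_mixtures += 1
        if ann is None:
            continue
        ident = ann.identification
        if ident.ranked and ident.ranked[0].fingerprint.form.protein.id in true_ids:
            top1 += 1
        if is_mixture and ident.mixture_flag:
            mixtures_found += 1
        if not is_mixture and ident.mixture_flag:
            false_mixtures += 1
        for form in spot.forms:
            call = ann.terminal_calls.get(form["protein"])
            if call is None:
                continue
            key_n = f"{form['n_status']}->{call.n_status.value}"
            key_c = f"{form['c_status']}->{call.c_status.value}"
            n_conf[key_n] = n_conf.get(key_n, 0) + 1
            c_conf[key_c] = c_conf.get(key_c, 0) + 1
            if form["n_status"] == "ABSENT":
                trunc_total += 1
                if (
                    call.n_status is TerminalStatus.ABSENT
                    and call.inferred_span is not None
                    and call.inferred_span[0] == form["span"][0]
                ):
                    trunc_correct += 1

    return RecoveryReport(
        n_spots=n_spots,
        top1_rate=top1 / n_spots if n_spots else 0.0,
        mixture_detection_rate=mixtures_found / mixtures if mixtures else 0.0,
        false_mixture_rate=false_mixtures / non_mixtures if non_mixtures else 0.0,
        n_confusion=n_conf,
        c_confusion=c_conf,
        truncation_start_accuracy=trunc_correct / trunc_total if trunc_total else 0.0,
        counts={
            "spots": n_spots,
            "mixtures": mixtures,
            "truncated_forms": trunc_total,
            "results": len(results),
        },
    )


# ---------------------------------------------------------------------------
# Seeded recovery experiments
# ---------------------------------------------------------------------------

def run_identification_experiment(
    seed: int,
    n_replicates: int = 200,
    error_ppm_sd: float = 10.0,
    dropout: float = 0.2,
    n_decoys: int = 5,
    tol_ppm: float = 50.0,
) -> float:
    """Top-1 identification rate over seeded replicates.

    Each replicate draws a fresh proteome of ``1 + n_decoys`` proteins,
    simulates a spot from the first protein's full-length form with the given
    mass error and dropout, and checks whether that protein ranks first among
    all candidates.
    """
    from .pmf_match import identify

    hits = 0
    for r in range(n_replicates):
        cfg = SimConfig(
            seed=seed + r,
            n_proteins=1 + n_decoys,
            error_ppm_sd=error_ppm_sd,
            dropout=dropout,
        )
        records, _ = simulate_proteome(cfg)
        rng = np.random.default_rng(cfg.seed + 10_000)
        pl, _, _ = simulate_spot(
            [Proteoform(records[0], label="full")], cfg, "spot", rng
        )
        candidates = [digest(Proteoform(rec)) for rec in records]
        ident = identify(pl, candidates, tol=tol_ppm)
        if (
            ident.ranked
            and ident.ranked[0].fingerprint.form.protein.id == records[0].id
        ):
            hits += 1
    return hits / n_replicates


def run_truncation_experiment(
    seed: int,
    n_replicates: int = 200,
    error_ppm_sd: float = 10.0,
    dropout: float = 0.2,
    n_noise_peaks: int = 10,
    tol_ppm: float = 50.0,
) -> dict[str, float]:
    """Terminal-call recovery at tryptic-boundary N-truncations.

    Per replicate: a protein is truncated at its second cleavage site, the
    spot is matched against the *full-length* fingerprint, and terminals are
    called.  Returns the ABSENT-call rate, the rate at which the inferred
    span starts at the true truncation start, and the false C-terminal
    ABSENT rate (the C-terminus is genuinely present in every replicate).
    """
    from .digest import cleavage_sites
    from .pmf_match import match
    from .proteoform_infer import call_terminals

    from .digest import find_peptide, fragments

    n_absent = n_start = n_false_c = 0
    for r in range(n_replicates):
        # redraw until the truncation is identifiable: the N-terminal fragment
        # must be observable in the mass window, and every peptide of the
        # removed region must be mass-isolated from the surviving region
        # (otherwise an isobaric surviving peptide fakes N-terminal evidence
        # and no PMF method could tell the difference)
        for sub in range(200):
            cfg = SimConfig(
                seed=seed + 50_000 + 211 * r + sub,
                n_proteins=1,
                error_ppm_sd=error_ppm_sd,
                dropout=dropout,
                n_noise_peaks=n_noise_peaks,
            )
            records, _ = simulate_proteome(cfg)
            rec = records[0]
            fp_probe = digest(Proteoform(rec))
            first_frag = fragments(rec.sequence, fp_probe.params)[0]
            if not find_peptide(fp_probe, first_frag):
                continue
            k = cleavage_sites(rec.sequence)[1]
            removed = [p.mh_mono for p in fp_probe.peptides if p.span[0] <= k]
            kept = [p.mh_mono for p in fp_probe.peptides if p.span[0] > k]
            margin = 2.0 * tol_ppm * 1e-6
            if all(
                abs(a - b) > margin * a for a in removed for b in kept
            ):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw an identifiable truncation instance")
        form = Proteoform(rec, span=(k + 1, mature_length(rec)), label=f"ΔN1–{k}")
        rng = np.random.default_rng(cfg.seed + 10_000)
        pl, _, _ = simulate_spot([form], cfg, "spot", rng)
        fp_full = digest(Proteoform(rec))
        mr = match(pl, fp_full, tol=tol_ppm)
        call = call_terminals(mr)
        if call.n_status is TerminalStatus.ABSENT:
            n_absent += 1
            if call.inferred_span and call.inferred_span[0] == k + 1:
                n_start += 1
        if call.c_status is TerminalStatus.ABSENT:
            n_false_c += 1  # C-terminus is present by construction
    return {
        "n_absent_rate": n_absent / n_replicates,
        "truncation_start_rate": n_start / n_replicates,
        "false_c_absent_rate": n_false_c / n_replicates,
    }
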