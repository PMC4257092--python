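# pmfkit

Peptide-mass-fingerprinting (PMF) toolkit for 2-DE proteomics: in-silico
tryptic digestion with missed cleavages and variable modifications,
monoisotopic/average mass calculus, Bjellqvist isoelectric-point
computation, MALDI peak-list calibration and tolerance matching,
coverage-based proteoform inference (N-terminal truncation, des-Lys
C-termini, dimer flags), gel-spot annotation, and a fully seeded synthetic
data generator for offline testing and parameter-recovery experiments.

## Test

```sh
python -m pytest tests/
```

The suite is self-contained except for `tests/test_acceptance.py`
criteria 1–4, which check sequence-derived published values and require the
reference sequences described below.

## Reference sequences

The acceptance harness works on real database records (odorant-binding
protein isoforms, salivary lipocalin, Von Ebner's gland protein, and an
EOGT cDNA). These are **not bundled**; fetch them once on a machine with
network access:

```sh
python scripts/fetch_references.py
```

This populates `src/pmfkit/data/reference/` (plain FASTA plus a
`registry.tsv` with mature-chain annotations). Until then the
reference-dependent acceptance tests fail with a `MissingReferenceError`
and the acceptance report omits the affected targets.

## CLI

Every pipeline stage is independently invokable:

```sh
pmfkit digest proteins.fasta -o fingerprint.tsv      # tryptic fingerprint
pmfkit pi proteins.fasta                             # theoretical pI / MW
pmfkit calibrate spot.tsv --refs 842.0:842.51,2211.0:2211.1046 -o cal.tsv
pmfkit match spot.tsv proteins.fasta --tol 50 --tol-unit ppm
pmfkit identify spot.tsv candidates.fasta -o spot.identification.json
pmfkit simulate --seed 7 -o simdir                   # synthetic bundle
pmfkit run --fasta candidates.fasta --peaks simdir \
           --spots simdir/spots.tsv -o report        # composite pipeline
```

`pmfkit run` writes per-spot identification JSON, a spot-annotation TSV
(terminal status, inferred span, gel flag) and a summary TSV; identical
inputs give byte-identical reports. Exit codes: 0 success, 2 malformed
input, 3 empty candidate set.

Configuration is a flat `key = value` file (see `pmfkit.cli.DEFAULTS` for
the knobs: matching tolerance/unit, acceptance threshold, digestion rules,
mass window, pI tolerance, gel-flag bands); unknown keys are rejected, and
the effective configuration is echoed into every report.

## Package layout

- `pmfkit.seqmodel` – protein records, proteoforms, modifications, FASTA I/O,
  truncation arithmetic, reference registry, one-ORF cDNA translation
- `pmfkit.masscalc` – residue-mass tables (TSV resources), peptide and
  proteoform masses, [M+H]+, Henderson–Hasselbalch net charge, pI bisection,
  gel-coordinate prediction
- `pmfkit.digest` – cleavage rules, missed-cleavage enumeration,
  modification-state enumeration, fingerprints, splice-variant diagnostics
- `pmfkit.pmf_match` – peak-list I/O (MGF/TSV), two-point calibration,
  greedy one-to-one tolerance matching, ranked identification, ambiguity scan
- `pmfkit.proteoform_infer` – terminal-status calls, des-C-terminal-residue
  variant check, gel-consistency spot annotation
- `pmfkit.synthetic_data` – seeded proteome/spot/peak-list simulator,
  ground truth, recovery scoring, seeded recovery experiments
- `pmfkit.cli` – `pmfkit` command-line entry point
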