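#!/usr/bin/env python
"""One-time fetch of the reference sequences used by the acceptance harness.

Requires network access (NCBI E-utilities, UniProt, Ensembl REST).  Not run
at test time: the test suite and acceptance script only read the files this
script writes into ``src/pmfkit/data/reference/``.

Usage:  python scripts/fetch_references.py
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request
from pathlib import Path

REFERENCE_DIR = Path(__file__).resolve().parents[1] / "src" / "pmfkit" / "data" / "reference"

NCBI = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
ENSEMBL = "https://rest.ensembl.org/sequence/id"

#: name -> (accession, source, db)
SOURCES = {
    "obp1": ("NP_998961", "ncbi", "protein"),
    "obp2": ("ENSSSCP00000028674", "ensembl", "protein"),
    "veg": ("S77587", "ncbi", "protein"),
    "veg_rm": ("AAO18367.1", "ncbi", "protein"),
    "veg_vno": ("AAB34720.1", "ncbi", "protein"),
    "sal": ("P81608", "uniprot", "protein"),
    "eogt_cdna": ("JX546149", "ncbi", "nuccore"),
}

#: Documented mature-chain lengths; the precursor's trailing window of this
#: size is annotated as the mature chain (signal peptide taken as annotation).
MATURE_LENGTHS = {"obp1": 158, "obp2": 156, "sal": 175}


def fetch(name: str, accession: str, source: str, db: str) -> str:
    if source == "ncbi":
        query = urllib.parse.urlencode(
            {"db": db, "id": accession, "rettype": "fasta", "retmode": "text"}
        )
        url = f"{NCBI}?{query}"
    elif source == "uniprot":
        url = f"https://rest.uniprot.org/uniprotkb/{accession}.fasta"
    elif source == "ensembl":
        url = f"{ENSEMBL}/{accession}?content-type=text/x-fasta;type=protein"
    else:
        raise ValueError(source)
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read().decode()


def main() -> int:
    REFERENCE_DIR.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, (accession, source, db) in SOURCES.items():
        out = REFERENCE_DIR / f"{name}.fasta"
        if out.exists():
            print(f"{name}: {out} already present, skipping fetch")
            text = out.read_text()
        else:
            print(f"{name}: fetching {accession} from {source} ...")
            text = fetch(name, accession, source, db)
            out.write_text(text)
        seq = "".join(
            ln.strip() for ln in text.splitlines() if ln and not ln.startswith(">")
        )
        span = ("", "")
        if name in MATURE_LENGTHS:
            n = MATURE_LENGTHS[name]
            if len(seq) < n:
                print(f"  WARNING: {name} sequence shorter than mature length {n}")
            else:
                span = (str(len(seq) - n + 1), str(len(seq)))
        rows.append((name, accession, f"{name}.fasta", *span))
        print(f"  {len(seq)} letters, mature span {span or 'full'}")

    registry = REFERENCE_DIR / "registry.tsv"
    with open(registry, "w") as fh:
        fh.write(
            "# Reference registry, rewritten by scripts/fetch_references.py.\n"
            "# mature_start/mature_end: 1-based precursor coordinates of the\n"
            "# mature chain (blank = full length).\n"
            "id\taccession\tfasta_path\tmature_start\tmature_end\n"
        )
        for row in rows:
            fh.write("\t".join(row) + "\n")
    print(f"wrote {registry}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
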