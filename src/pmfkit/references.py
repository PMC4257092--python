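"""Registry of reference sequences used by the acceptance harness.

The package does not bundle database sequences; the registry maps short
names to accessions and local FASTA files that the user fetches once with
``scripts/fetch_references.py`` (network required).  Until those files are
present, :func:`get` raises :class:`MissingReferenceError` and the
acceptance harness omits the affected targets.
"""

from __future__ import annotations

from importlib.resources import files
from pathlib import Path

from .seqmodel import ProteinRecord, RegistryEntry, load_reference, load_registry

#: Registered reference names -> database accessions.
ACCESSIONS = {
    "obp1": "NP_998961",
    "obp2": "ENSSSCP00000028674",
    "veg": "S77587",
    "veg_rm": "AAO18367.1",
    "veg_vno": "AAB34720.1",
    "sal": "P81608",
    "eogt_cdna": "JX546149",
}


class MissingReferenceError(FileNotFoundError):
    pass


def reference_dir() -> Path:
    return Path(str(files("pmfkit.data").joinpath("reference")))


def registry_path() -> Path:
    return reference_dir() / "registry.tsv"


def load_default_registry() -> dict[str, RegistryEntry]:
    path = registry_path()
    if not path.exists():
        return {}
    return load_registry(path)


def available() -> list[str]:
    """Names whose FASTA files are actually present."""
    return sorted(
        name
        for name, entry in load_default_registry().items()
        if entry.fasta_path.exists()
    )


def get(name: str) -> ProteinRecord:
    """Load a registered reference protein, with its mature-chain annotation."""
    registry = load_default_registry()
    entry = registry.get(name)
    if entry is None or not entry.fasta_path.exists():
        accession = ACCESSIONS.get(name, "?")
        raise MissingReferenceError(
            f"reference {name!r} (accession {accession}) is not available locally; "
            f"run scripts/fetch_references.py (network required) to populate "
            f"{reference_dir()}"
        )
    return load_reference(entry)


def get_nucleotide(name: str) -> str:
    """Load a registered nucleotide sequence (plain FASTA, first record)."""
    registry = load_default_registry()
    entry = registry.get(name)
    if entry is None or not entry.fasta_path.exists():
        accession = ACCESSIONS.get(name, "?")
        raise MissingReferenceError(
            f"reference {name!r} (accession {accession}) is not available locally; "
            f"run scripts/fetch_references.py to populate {reference_dir()}"
        )
    text = entry.fasta_path.read_text().splitlines()
    seq = "".join(ln.strip() for ln in text if not ln.startswith(">"))
    return seq.upper()
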