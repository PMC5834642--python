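"""File-format helpers: FASTA references/alleles, manifests, primer YAML."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pcr import dump_primer_sets, load_primer_sets
from .reference import REFERENCE, ReferenceAmplicon
from .simulate import Manifest

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_reference_fasta",
    "write_reference_fasta",
    "load_manifest",
    "load_primer_sets",
    "dump_primer_sets",
]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (ids verbatim)."""
    return {
        record.id: str(record.seq).upper()
        for record in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(path, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    """Write sequences as FASTA (60-column wrapping)."""
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in items
    ]
    SeqIO.write(records, str(path), "fasta")


def read_reference_fasta(
    path,
    target_window: tuple[int, int] | None = None,
    pam: tuple[int, int, str] | None = None,
) -> ReferenceAmplicon:
    """Load a reference amplicon from FASTA (first record).

    Window and PAM default to the packaged reference's when the sequence
    length matches, else to the full sequence and no PAM."""
    seqs = read_fasta(path)
    if not seqs:
        raise ValueError(f"no sequences in {path}")
    name, seq = next(iter(seqs.items()))
    if target_window is None:
        target_window = (
            REFERENCE.target_window if len(seq) == REFERENCE.length else (1, len(seq))
        )
    if pam is None and len(seq) == REFERENCE.length:
        pam = REFERENCE.pam
    return ReferenceAmplicon(id=name, sequence=seq, target_window=target_window, pam=pam)


def write_reference_fasta(path, ref: ReferenceAmplicon = REFERENCE) -> None:
    write_fasta(path, {ref.id: ref.sequence})


def load_manifest(path) -> Manifest:
    return Manifest.from_json(Path(path).read_text())
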