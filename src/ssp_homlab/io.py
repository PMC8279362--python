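"""Reading and writing sequence/label files.

Sequences travel as plain FASTA.  Per-residue secondary-structure labels
travel as a parallel FASTA-like file with the same ids in the same order and
the 8-state label string in place of the sequence.  The reader validates the
pairing (matching ids, matching lengths).
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .seq import LabeledSequence, SequenceDataset

PathLike = Union[str, Path]


def write_dataset(dataset: SequenceDataset, fasta_path: PathLike, labels_path: PathLike) -> None:
    """Write sequences as FASTA and ss8 labels as a parallel FASTA-like file."""
    seq_records = [
        SeqRecord(
            Seq(r.residues),
            id=r.id,
            description=f"family={r.family_id}"
            + (" ancestor=1" if r.is_ancestor else ""),
        )
        for r in dataset
    ]
    lab_records = [SeqRecord(Seq(r.ss8), id=r.id, description="ss8") for r in dataset]
    SeqIO.write(seq_records, str(fasta_path), "fasta")
    SeqIO.write(lab_records, str(labels_path), "fasta")


def read_dataset(
    fasta_path: PathLike,
    labels_path: PathLike,
    name: str = "",
    role: str = "universe",
) -> SequenceDataset:
    """Read a FASTA + label file pair, validating that they match."""
    seqs = list(SeqIO.parse(str(fasta_path), "fasta"))
    labs = list(SeqIO.parse(str(labels_path), "fasta"))
    if len(seqs) != len(labs):
        raise ValueError(
            f"sequence/label record count mismatch: {len(seqs)} vs {len(labs)}"
        )
    records = []
    for sr, lr in zip(seqs, labs):
        if sr.id != lr.id:
            raise ValueError(f"sequence/label id mismatch: {sr.id!r} vs {lr.id!r}")
        family = ""
        is_ancestor = False
        for token in sr.description.split():
            if token.startswith("family="):
                family = token[len("family="):]
            elif token == "ancestor=1":
                is_ancestor = True
        records.append(
            LabeledSequence(
                id=sr.id, residues=str(sr.seq), ss8=str(lr.seq),
                family_id=family, is_ancestor=is_ancestor,
            )
        )
    ds = SequenceDataset(name=name or Path(fasta_path).stem, role=role, records=records)
    ds.note(f"read from {fasta_path} + {labels_path}")
    return ds
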