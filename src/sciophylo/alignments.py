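"""Nucleotide alignments with a partition scheme (FASTA + RAxML-style
partition files)."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from io import StringIO
from typing import Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "AlignmentError", "read_fasta", "read_partitions",
           "write_fasta"]

NUCS = "ACGT"
#: IUPAC / gap symbols treated as fully missing
MISSING_SYMBOLS = set("-NnRYSWKMBDHV?X.")


class AlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """taxa × sites nucleotide matrix plus a column partition map.

    ``partitions`` maps partition name -> sorted column indices; the
    partitions must be disjoint and cover all columns.  When absent, a
    single partition ``"all"`` is assumed.
    """

    taxa: list[str]
    sequences: list[str]
    partitions: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise AlignmentError("taxa/sequence count mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon names")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        if not self.partitions:
            self.partitions = {"all": np.arange(self.length)}
        cover = np.concatenate(list(self.partitions.values())) if self.partitions else np.array([])
        if sorted(cover.tolist()) != list(range(self.length)):
            raise AlignmentError(
                "partitions must be disjoint and cover every column"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def encoded(self) -> np.ndarray:
        """(ntaxa, L) int8 matrix; A,C,G,T -> 0..3, anything else -> 4."""
        lut = np.full(256, 4, dtype=np.int8)
        for i, b in enumerate(NUCS):
            lut[ord(b)] = i
            lut[ord(b.lower())] = i
        arr = np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(len(self.taxa), self.length)
        return lut[arr]

    def columns(self, partition: str) -> np.ndarray:
        return self.partitions[partition]

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in keep]
        return Alignment(
            [self.taxa[i] for i in idx],
            [self.sequences[i] for i in idx],
            dict(self.partitions),
        )


def read_fasta(path, partitions: Mapping[str, np.ndarray] | None = None) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: no sequences")
    return Alignment(
        [r.id for r in records],
        [str(r.seq).upper() for r in records],
        dict(partitions) if partitions else {},
    )


def write_fasta(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(aln.taxa, aln.sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


_PART_RE = re.compile(
    r"^\s*DNA\s*,\s*(?P<name>\S+)\s*=\s*(?P<ranges>.+)$", re.IGNORECASE
)


def read_partitions(text_or_path) -> dict[str, np.ndarray]:
    """Parse a RAxML-style partition file.

    Lines like ``DNA, COI_pos1 = 1-658\\3`` (1-based, inclusive, optional
    codon stride) or comma-separated range lists.
    """
    try:
        text = open(text_or_path).read()
    except (OSError, TypeError):
        text = str(text_or_path)
    out: dict[str, np.ndarray] = {}
    for line in StringIO(text):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _PART_RE.match(line)
        if not m:
            raise AlignmentError(f"bad partition line: {line!r}")
        cols: list[int] = []
        for chunk in m.group("ranges").split(","):
            chunk = chunk.strip()
            stride = 1
            if "\\" in chunk:
                chunk, s = chunk.split("\\")
                stride = int(s)
            if "-" in chunk:
                a, b = chunk.split("-")
                cols.extend(range(int(a) - 1, int(b), stride))
            else:
                cols.append(int(chunk) - 1)
        out[m.group("name")] = np.array(sorted(cols), dtype=int)
    return out
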