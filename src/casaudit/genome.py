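"""Reference genome container and FASTA I/O.

A genome is an ordered mapping of chromosome name to an upper-case DNA
string over {A, C, G, T, N}.  The ``label`` field records provenance:
``"original"`` for a reference as loaded, ``"corrected"`` after cultivar
variants have been applied to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N maps to N."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Genome:
    """Named chromosome sequences with a provenance label."""

    chroms: dict[str, str] = field(default_factory=dict)
    label: str = "original"

    def __len__(self) -> int:
        return sum(len(s) for s in self.chroms.values())

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """0-based half-open slice of a chromosome."""
        return self.chroms[chrom][start:end]

    def base(self, chrom: str, pos: int) -> str:
        """Base at a 1-based position."""
        return self.chroms[chrom][pos - 1]

    @classmethod
    def from_fasta(cls, path, label: str = "original") -> "Genome":
        chroms = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        if not chroms:
            raise ValueError(f"no sequences found in {path}")
        return cls(chroms=chroms, label=label)

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.chroms.items()
        ]
        with open(path, "w") as fh:
            SeqIO.write(records, fh, "fasta")
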