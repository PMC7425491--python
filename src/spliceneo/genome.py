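"""Genome sequence access and translation primitives.

All coordinates in this package are 0-based half-open on the forward
strand. Minus-strand sequence is obtained by reverse-complementing
forward-strand extractions; exon lists are always stored in ascending
genomic order regardless of strand.
"""

from __future__ import annotations

from collections.abc import Sequence

from Bio.Seq import Seq
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeSequence:
    """Random-access nucleotide sequences for a genome.

    Backed either by an indexed FASTA file (pyfaidx) or by an in-memory
    chromosome dictionary (convenient for tests and tiny fixtures).
    Extraction of ``[a, b)`` always returns ``b - a`` uppercase bases.
    """

    def __init__(self, fasta_path: str | None = None, sequences: dict[str, str] | None = None):
        if (fasta_path is None) == (sequences is None):
            raise ValueError("provide exactly one of fasta_path or sequences")
        self._fasta = None
        self._seqs = None
        if fasta_path is not None:
            self._fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
        else:
            self._seqs = {c: s.upper() for c, s in sequences.items()}

    @classmethod
    def from_dict(cls, sequences: dict[str, str]) -> "GenomeSequence":
        return cls(sequences=sequences)

    def chroms(self) -> list[str]:
        if self._fasta is not None:
            return list(self._fasta.keys())
        return list(self._seqs)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand bases of ``chrom[start:end)``."""
        if start < 0 or end < start:
            raise ValueError(f"invalid interval [{start}, {end})")
        if self._fasta is not None:
            if chrom not in self._fasta:
                raise KeyError(chrom)
            return str(self._fasta[chrom][start:end])
        seq = self._seqs.get(chrom)
        if seq is None:
            raise KeyError(chrom)
        if end > len(seq):
            raise ValueError(f"interval [{start}, {end}) exceeds {chrom} length {len(seq)}")
        return seq[start:end]

    def fetch_spliced(self, chrom: str, exons: Sequence[tuple[int, int]], strand: str) -> str:
        """Spliced transcript sequence, 5'->3' on the transcript.

        ``exons`` are ascending genomic intervals; for strand '-' the
        concatenated forward sequence is reverse-complemented.
        """
        seq = "".join(self.fetch(chrom, s, e) for s, e in exons)
        return reverse_complement(seq) if strand == "-" else seq


def translate_to_stop(seq: str) -> tuple[str, bool]:
    """Translate ``seq`` in frame 0 up to the first stop codon.

    Returns ``(protein, stop_found)``. Only complete codons are read;
    a trailing partial codon is ignored. Codons containing N translate
    to 'X' (standard ambiguity handling).
    """
    n = (len(seq) // 3) * 3
    if n == 0:
        return "", False
    protein = str(Seq(seq[:n]).translate())
    stop = protein.find("*")
    if stop >= 0:
        return protein[:stop], True
    return protein, False
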