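"""The two "normal" filters: the normal-junction DB and normal-peptide index.

Junctions seen broadly across a panel of normal samples (GTEx-like),
plus every junction implied by the reference annotation, are treated as
immunologically tolerated and removed from consideration. Likewise any
8-11-mer that occurs in the normal proteome (reference proteins, plus
proteins produced by running the isoform machinery on normal junctions)
cannot be a neoantigen and is subtracted.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, NamedTuple

import pandas as pd

from .genome import GenomeSequence, translate_to_stop
from .models import TranscriptModel

log = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class JunctionKey(NamedTuple):
    """Canonical junction identity: the intron as a half-open interval."""

    chrom: str
    strand: str
    intron_start: int
    intron_end: int


class NormalJunctionDB:
    """Exact-key membership set of normal junctions with provenance.

    Provenance per key is a subset of {"annotation", "panel"}.
    Strand-unknown queries match a key on either strand.
    """

    FORMAT_HEADER = "#spliceneo-normal-junction-db\tv1"

    def __init__(self):
        self._prov: dict[JunctionKey, set[str]] = {}

    def __len__(self) -> int:
        return len(self._prov)

    def __contains__(self, key: JunctionKey) -> bool:
        if key.strand == ".":
            return (
                JunctionKey(key.chrom, "+", key.intron_start, key.intron_end) in self._prov
                or JunctionKey(key.chrom, "-", key.intron_start, key.intron_end) in self._prov
            )
        return key in self._prov

    def add(self, key: JunctionKey, provenance: str) -> None:
        self._prov.setdefault(key, set()).add(provenance)

    def keys(self) -> list[JunctionKey]:
        return sorted(self._prov)

    def provenance(self, key: JunctionKey) -> frozenset[str]:
        return frozenset(self._prov.get(key, ()))

    def panel_keys(self) -> list[JunctionKey]:
        return sorted(k for k, p in self._prov.items() if "panel" in p)

    @classmethod
    def from_annotation(cls, models: Iterable[TranscriptModel]) -> "NormalJunctionDB":
        db = cls()
        for m in models:
            for s, e in m.introns():
                db.add(JunctionKey(m.chrom, m.strand, s, e), "annotation")
        return db

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.FORMAT_HEADER + "\n")
            fh.write("chrom\tstrand\tintron_start\tintron_end\tprovenance\n")
            for k in self.keys():
                fh.write(
                    f"{k.chrom}\t{k.strand}\t{k.intron_start}\t{k.intron_end}\t"
                    f"{','.join(sorted(self._prov[k]))}\n"
                )

    @classmethod
    def read_tsv(cls, path) -> "NormalJunctionDB":
        db = cls()
        with open(path) as fh:
            first = fh.readline().rstrip("\n")
            if first != cls.FORMAT_HEADER:
                raise ValueError(f"unrecognized normal-junction DB header: {first!r}")
            fh.readline()  # column header
            for line in fh:
                chrom, strand, s, e, prov = line.rstrip("\n").split("\t")
                for p in prov.split(","):
                    db.add(JunctionKey(chrom, strand, int(s), int(e)), p)
        return db


def read_panel_tsv(path) -> pd.DataFrame:
    """Read a junction x sample count matrix.

    First four columns are chrom, strand, intron_start, intron_end
    (0-based half-open); each remaining column is one normal sample.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "strand", "intron_start", "intron_end"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"panel must start with columns {required}, got {list(df.columns[:4])}")
    return df


def build_normal_junction_db(
    panel: pd.DataFrame | None,
    annotation: Iterable[TranscriptModel],
    min_reads: int = 2,
    min_sample_frac: float = 0.01,
) -> NormalJunctionDB:
    """Combine a panel-of-normals with annotation-implied junctions.

    A panel junction is normal when it has >= ``min_reads`` reads in at
    least ``ceil(min_sample_frac * n_samples)`` samples. All junctions
    between consecutive exons of any annotated transcript are normal
    unconditionally.
    """
    if not 0 < min_sample_frac <= 1:
        raise ValueError("min_sample_frac must be in (0, 1]")
    db = NormalJunctionDB.from_annotation(annotation)
    if panel is None or panel.shape[1] <= 4 or len(panel) == 0:
        log.warning("empty normal panel: DB contains annotation junctions only")
        return db
    counts = panel.iloc[:, 4:].to_numpy()
    n_samples = counts.shape[1]
    need = math.ceil(min_sample_frac * n_samples)
    qualifying = (counts >= min_reads).sum(axis=1) >= need
    for row, ok in zip(panel.itertuples(index=False), qualifying):
        if ok:
            db.add(JunctionKey(row.chrom, row.strand, int(row.intron_start), int(row.intron_end)), "panel")
    return db


def extract_reference_proteome(
    models: Iterable[TranscriptModel], genome: GenomeSequence
) -> list[tuple[str, str]]:
    """Translate the spliced CDS of each coding transcript.

    Returns ``(transcript_id, protein)`` pairs; translation is
    strand-aware, starts at the annotated start codon and truncates at
    the first stop. A CDS length not divisible by 3 is translated over
    its complete codons with a warning.
    """
    proteome = []
    for m in models:
        if not m.is_coding:
            continue
        cds_seq = genome.fetch_spliced(m.chrom, m.cds_exons(), m.strand)
        if len(cds_seq) % 3 != 0:
            log.warning("%s: CDS length %d not divisible by 3", m.transcript_id, len(cds_seq))
        protein, _ = translate_to_stop(cds_seq)
        if protein:
            proteome.append((m.transcript_id, protein))
    return proteome


class NormalPeptideIndex:
    """k-mer membership over the normal proteome, k in {8..11}.

    Answers exact substring membership and supports nearest-peptide
    search (minimum Hamming distance over all equal-length windows of
    the stored proteins, lexicographic tie-break).
    """

    def __init__(self, proteins: Iterable[str], ks: Iterable[int] = (8, 9, 10, 11)):
        self.ks = tuple(sorted(set(ks)))
        self.proteins = tuple(p for p in proteins if p)
        if not self.proteins:
            raise ValueError("empty normal protein list")
        self._kmers: dict[int, set[str]] = {k: set() for k in self.ks}
        for p in self.proteins:
            for k in self.ks:
                for i in range(len(p) - k + 1):
                    self._kmers[k].add(p[i : i + k])

    def contains(self, kmer: str) -> bool:
        k = len(kmer)
        if k not in self._kmers:
            raise KeyError(f"index not built for k={k}")
        return kmer in self._kmers[k]

    __contains__ = contains

    def kmers(self, k: int) -> frozenset[str]:
        return frozenset(self._kmers[k])

    def nearest(self, candidate: str) -> tuple[str, int]:
        """Closest equal-length normal window and its Hamming distance.

        Ties on distance resolve to the lexicographically smallest
        window, so results are independent of protein order.
        """
        k = len(candidate)
        best_dist = k + 1
        best_pep: str | None = None
        for p in self.proteins:
            for i in range(len(p) - k + 1):
                window = p[i : i + k]
                d = 0
                for a, b in zip(candidate, window):
                    if a != b:
                        d += 1
                        if d > best_dist:
                            break
                if d < best_dist or (d == best_dist and (best_pep is None or window < best_pep)):
                    best_dist = d
                    best_pep = window
        if best_pep is None:
            raise ValueError(f"no normal protein of length >= {k}")
        return best_pep, best_dist


def build_normal_peptide_index(
    normal_proteins: Iterable[str], ks: Iterable[int] = (8, 9, 10, 11)
) -> NormalPeptideIndex:
    return NormalPeptideIndex(normal_proteins, ks)
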