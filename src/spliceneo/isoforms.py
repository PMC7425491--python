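"""Mapping junctions onto host isoforms and building novel isoforms.

Each surviving junction is placed on every reference isoform whose span
contains it (on a compatible strand) and classified by how its two
splice sites relate to the host's exon boundaries:

* tag 0 - the junction IS an intron of the host (annotated in context);
* tag 1 - both sites are annotated exon boundaries but the pair is not
  a host intron (e.g. an exon skip);
* tag 2 - exactly one site is an annotated boundary (alternative
  donor/acceptor);
* tag 3 - neither site is annotated (e.g. a novel exitron-like split).

Hosts are then filtered to the smallest tag present and an expression
gate (RPKM > 1), and the junction is spliced into each surviving host
under length constraints modeled on rMATS-style event bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from intervaltree import IntervalTree

from .junctions import Junction
from .models import TranscriptModel
from .normals import JunctionKey

log = logging.getLogger(__name__)


class Rejected(Exception):
    """A candidate event that fails a biological/length constraint.

    ``reason`` is a short machine-readable token (e.g. "exon-mod",
    "intron-length", "non-coding", "site-in-intron", "start-lost").
    """

    def __init__(self, reason: str, detail: str = ""):
        super().__init__(f"{reason}: {detail}" if detail else reason)
        self.reason = reason


@dataclass(frozen=True)
class JunctionPlacement:
    junction: Junction
    host: TranscriptModel
    tag: int
    donor_site_kind: str  # "annotated_boundary" | "novel"
    acceptor_site_kind: str


@dataclass(frozen=True)
class NovelIsoform:
    """A host isoform after one junction insertion."""

    isoform_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    source_transcript_id: str
    junction_key: JunctionKey
    tag: int
    cds_start: int  # inherited genomic CDS span of the host
    cds_end: int
    rpkm_of_host: float = 0.0

    def __post_init__(self):
        prev = None
        for s, e in self.exons:
            if e <= s or (prev is not None and s <= prev):
                raise ValueError(f"{self.isoform_id}: malformed exon chain {self.exons}")
            prev = e

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )


class TranscriptIndex:
    """Interval index over transcript genomic spans, per chromosome."""

    def __init__(self, models: Iterable[TranscriptModel]):
        self._trees: dict[str, IntervalTree] = {}
        for m in models:
            self._trees.setdefault(m.chrom, IntervalTree()).addi(m.tx_start, m.tx_end, m)

    def overlapping(self, chrom: str, start: int, end: int) -> list[TranscriptModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda m: m.transcript_id)


def classify_placement(j: Junction, host: TranscriptModel) -> JunctionPlacement:
    """Assign the 0-3 tag for a junction on one host isoform."""
    left_annot = j.intron_start in host.exon_ends()
    right_annot = j.intron_end in host.exon_starts()
    if (j.intron_start, j.intron_end) in host.introns():
        tag = 0
    elif left_annot and right_annot:
        tag = 1
    elif left_annot or right_annot:
        tag = 2
    else:
        tag = 3
    # biological donor is the genomic-left site on '+', right on '-'
    left_kind = "annotated_boundary" if left_annot else "novel"
    right_kind = "annotated_boundary" if right_annot else "novel"
    if host.strand == "-":
        donor_kind, acceptor_kind = right_kind, left_kind
    else:
        donor_kind, acceptor_kind = left_kind, right_kind
    return JunctionPlacement(j, host, tag, donor_kind, acceptor_kind)


def map_junction_to_isoforms(
    j: Junction, index: TranscriptIndex | Iterable[TranscriptModel]
) -> list[JunctionPlacement]:
    """All placements of a junction on strand-compatible spanning hosts.

    Strand-unknown junctions ('.') are tried against hosts on both
    strands. A host must genomically contain both junction endpoints.
    """
    if not isinstance(index, TranscriptIndex):
        index = TranscriptIndex(index)
    placements = []
    for host in index.overlapping(j.chrom, j.intron_start, j.intron_end):
        if j.strand != "." and j.strand != host.strand:
            continue
        if host.tx_start <= j.intron_start and j.intron_end <= host.tx_end:
            placements.append(classify_placement(j, host))
    return placements


def compute_rpkm(model: TranscriptModel, exon_read_count: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of exon model per million mapped reads."""
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    length = model.exonic_length
    if length == 0:
        raise ValueError(f"{model.transcript_id}: zero exonic length")
    return exon_read_count * 1e9 / (total_mapped_reads * length)


def select_hosts(
    placements: list[JunctionPlacement],
    rpkm: Mapping[str, float],
    min_rpkm: float = 1.0,
) -> list[JunctionPlacement]:
    """Keep smallest-tag hosts above the expression gate (RPKM > min).

    A tag-0 placement means the junction is annotated in context: no
    novel isoform is produced and an empty list is returned. Missing
    RPKM values count as 0.
    """
    if not placements:
        return []
    if any(p.tag == 0 for p in placements):
        log.debug("junction %s annotated in a host; dropped", placements[0].junction.key)
        return []
    min_tag = min(p.tag for p in placements)
    return [
        p
        for p in placements
        if p.tag == min_tag and rpkm.get(p.host.transcript_id, 0.0) > min_rpkm
    ]


def _exon_containing(exons, pos: int) -> tuple[int, int] | None:
    """The exon with ``start < pos < end`` (strictly interior), if any."""
    for s, e in exons:
        if s < pos < e:
            return (s, e)
    return None


def insert_junction(
    p: JunctionPlacement,
    min_exon_mod: int = 2,
    max_exon_mod: int = 250,
    min_intron: int = 50,
) -> NovelIsoform:
    """Splice the junction into the host, yielding a novel isoform.

    Constraints (raising :class:`Rejected` on violation):

    * the junction's intron span must intersect the host CDS span
      ("non-coding" otherwise);
    * tag 1: exons strictly inside the junction span are removed;
    * tag 2: the novel site must fall inside an exon; the modified
      exon's absolute length change d must satisfy
      ``min_exon_mod <= d <= max_exon_mod``;
    * tag 3: both sites must fall strictly inside the *same* exon,
      which is split; the novel intron must be longer than
      ``min_intron`` bp.
    """
    host, j = p.host, p.junction
    s, e = j.intron_start, j.intron_end
    if p.tag not in (1, 2, 3):
        raise ValueError(f"insert_junction requires tag 1-3, got {p.tag}")
    if not host.is_coding:
        raise Rejected("non-coding", f"host {host.transcript_id} has no CDS")
    if not (host.tx_start <= s and e <= host.tx_end):
        raise ValueError("placement inconsistent: junction outside host span")
    if not (s < host.cds_end and e > host.cds_start):
        raise Rejected("non-coding", "junction does not overlap the host CDS span")

    exons = list(host.exons)
    if p.tag == 1:
        new_exons = [ex for ex in exons if not (s <= ex[0] and ex[1] <= e)]
    elif p.tag == 2:
        left_annot = s in host.exon_ends()
        novel_pos = e if left_annot else s
        target = _exon_containing(exons, novel_pos)
        if target is None:
            raise Rejected("site-in-intron", f"novel site {novel_pos} not inside an exon")
        if left_annot:
            trimmed = (e, target[1])
            d = e - target[0]
        else:
            trimmed = (target[0], s)
            d = target[1] - s
        if not (min_exon_mod <= d <= max_exon_mod):
            raise Rejected("exon-mod", f"modified length {d} outside [{min_exon_mod},{max_exon_mod}]")
        new_exons = []
        for ex in exons:
            if ex == target:
                new_exons.append(trimmed)
            elif s <= ex[0] and ex[1] <= e:
                continue  # exon fully inside the novel intron: skipped
            else:
                new_exons.append(ex)
    else:  # tag 3
        left_exon = _exon_containing(exons, s)
        right_exon = _exon_containing(exons, e)
        if left_exon is None or right_exon is None:
            raise Rejected("site-in-intron", "a novel site falls in an intron")
        if left_exon != right_exon:
            raise Rejected("tag3-multi-exon", "novel sites fall in different exons")
        if not (e - s) > min_intron:
            raise Rejected("intron-length", f"novel intron {e - s} bp needs > {min_intron}")
        new_exons = []
        for ex in exons:
            if ex == left_exon:
                new_exons.extend([(ex[0], s), (e, ex[1])])
            else:
                new_exons.append(ex)

    iso_id = (
        f"{host.transcript_id}|{j.chrom}:{j.strand}:{s}-{e}|tag{p.tag}"
    )
    return NovelIsoform(
        isoform_id=iso_id,
        chrom=host.chrom,
        strand=host.strand,
        exons=tuple(new_exons),
        source_transcript_id=host.transcript_id,
        junction_key=j.key,
        tag=p.tag,
        cds_start=host.cds_start,
        cds_end=host.cds_end,
    )
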