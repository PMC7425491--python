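"""Transcript models and annotation parsing (refGene flat TSV and GTF).

A :class:`TranscriptModel` is one reference isoform: an ordered exon
chain plus an optional CDS span. Both supported dialects are normalized
to 0-based half-open genomic coordinates at parse time:

* refGene (UCSC Table Browser genePred): already 0-based starts,
  half-open ends;
* GTF 2.2: 1-based inclusive, converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Raised for malformed annotation input; carries the line number."""


@dataclass(frozen=True)
class TranscriptModel:
    """One reference isoform: exon chain plus optional CDS span.

    exons are ascending, non-overlapping ``(start, end)`` genomic
    intervals; ``cds_start``/``cds_end`` bound the coding span (None for
    non-coding transcripts).
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: no exons")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValueError(f"{self.transcript_id}: exons overlap or touch (intron < 1 bp)")
            prev_end = e
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"{self.transcript_id}: partial CDS bounds")
        if self.cds_start is not None:
            if self.cds_end <= self.cds_start:
                raise ValueError(f"{self.transcript_id}: empty CDS span")
            if not self._span_in_exons(self.cds_start, self.cds_end):
                raise ValueError(f"{self.transcript_id}: CDS outside exon union")

    def _span_in_exons(self, start: int, end: int) -> bool:
        if start < self.tx_start or end > self.tx_end:
            return False
        # every intron must lie outside [start, end) boundaries sanely:
        # the span may cross introns, but its endpoints must fall in exons
        return any(s <= start < e for s, e in self.exons) and any(
            s < end <= e for s, e in self.exons
        )

    @property
    def tx_start(self) -> int:
        return self.exons[0][0]

    @property
    def tx_end(self) -> int:
        return self.exons[-1][1]

    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)
        )

    def exon_starts(self) -> frozenset[int]:
        return frozenset(s for s, _ in self.exons)

    def exon_ends(self) -> frozenset[int]:
        return frozenset(e for _, e in self.exons)

    def cds_exons(self) -> tuple[tuple[int, int], ...]:
        """Exon intervals clipped to the CDS span (ascending)."""
        if not self.is_coding:
            return ()
        out = []
        for s, e in self.exons:
            a, b = max(s, self.cds_start), min(e, self.cds_end)
            if a < b:
                out.append((a, b))
        return tuple(out)


def _parse_refgene_line(fields: list[str], lineno: int) -> TranscriptModel | None:
    # genePred with optional leading bin column (UCSC table dump)
    if len(fields) >= 16 and fields[0].isdigit():
        fields = fields[1:]
    if len(fields) < 10:
        raise AnnotationError(f"line {lineno}: expected >=10 refGene columns, got {len(fields)}")
    try:
        name, chrom, strand = fields[0], fields[1], fields[2]
        cds_start, cds_end = int(fields[5]), int(fields[6])
        exon_count = int(fields[7])
        starts = [int(x) for x in fields[8].rstrip(",").split(",")]
        ends = [int(x) for x in fields[9].rstrip(",").split(",")]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: {exc}") from None
    if len(starts) != exon_count or len(ends) != exon_count:
        raise AnnotationError(f"line {lineno}: exon count mismatch")
    gene = fields[11] if len(fields) > 11 else name
    exons = tuple(zip(starts, ends))
    # refGene convention: cdsStart == cdsEnd marks a non-coding transcript
    cds = None if cds_start == cds_end else (cds_start, cds_end)
    try:
        return TranscriptModel(
            transcript_id=name,
            gene_id=gene,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds[0] if cds else None,
            cds_end=cds[1] if cds else None,
        )
    except ValueError as exc:
        if "CDS outside exon union" in str(exc):
            log.warning("skipping %s: %s", name, exc)
            return None
        raise AnnotationError(f"line {lineno}: {exc}") from None


def load_refgene(path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            m = _parse_refgene_line(line.split("\t"), lineno)
            if m is not None:
                models.append(m)
    return models


def load_gtf(path) -> list[TranscriptModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        force=True,
        keep_order=True,
    )
    exons: dict[str, list] = {}
    cds: dict[str, list] = {}
    meta: dict[str, tuple] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        tid = feat.attributes.get("transcript_id", [feat.id])[0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        meta[tid] = (gid, feat.seqid, feat.strand)
        # GTF is 1-based inclusive; convert to 0-based half-open
        iv = (feat.start - 1, feat.end)
        (exons if feat.featuretype == "exon" else cds).setdefault(tid, []).append(iv)
    models = []
    for tid, ivs in exons.items():
        gid, chrom, strand = meta[tid]
        ivs = tuple(sorted(ivs))
        c = cds.get(tid)
        cs, ce = (min(s for s, _ in c), max(e for _, e in c)) if c else (None, None)
        try:
            models.append(
                TranscriptModel(tid, gid, chrom, strand, ivs, cs, ce)
            )
        except ValueError as exc:
            log.warning("skipping %s: %s", tid, exc)
    return models


def load_annotation(path) -> list[TranscriptModel]:
    """Load transcripts from a refGene TSV or a GTF file (by extension)."""
    p = str(path)
    if p.endswith((".gtf", ".gff", ".gtf.gz")):
        return load_gtf(path)
    return load_refgene(path)


def write_refgene(models: list[TranscriptModel], path) -> None:
    """Write models in the refGene (genePred, no bin column) dialect."""
    with open(path, "w") as fh:
        for m in models:
            cs = m.cds_start if m.is_coding else m.tx_end
            ce = m.cds_end if m.is_coding else m.tx_end
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                "\t".join(
                    [
                        m.transcript_id,
                        m.chrom,
                        m.strand,
                        str(m.tx_start),
                        str(m.tx_end),
                        str(cs),
                        str(ce),
                        str(len(m.exons)),
                        starts,
                        ends,
                        "0",
                        m.gene_id,
                        "cmpl",
                        "cmpl",
                        ",".join("-1" for _ in m.exons) + ",",
                    ]
                )
                + "\n"
            )
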