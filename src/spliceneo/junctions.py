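"""Splice-junction parsing, percent-spliced-in (psi), and junction filters.

Junctions arrive as a STAR ``SJ.out.tab``-dialect table (or a BED-like
6-column table). psi5 answers "how often is this donor used with this
acceptor, relative to all acceptors sharing the donor"; psi3 is the
mirror question for the acceptor. Three filters then apply: unique-read
support, psi on both sides, and the normal-junction DB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace, field

from .normals import JunctionKey, NormalJunctionDB

log = logging.getLogger(__name__)

_STRAND_CODE = {"0": ".", "1": "+", "2": "-"}


@dataclass(frozen=True)
class Junction:
    """One splice junction, identified by its intron's genomic span."""

    chrom: str
    strand: str  # '+', '-' or '.' (unknown)
    intron_start: int  # 0-based half-open intron span
    intron_end: int
    unique_reads: int
    annotated_flag: bool = False
    psi5: float | None = None
    psi3: float | None = None

    def __post_init__(self):
        if self.intron_end <= self.intron_start:
            raise ValueError(f"intron_end must exceed intron_start: {self}")
        if self.unique_reads < 0:
            raise ValueError("unique_reads must be non-negative")
        for v in (self.psi5, self.psi3):
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"psi out of [0,1]: {v}")

    @property
    def key(self) -> JunctionKey:
        return JunctionKey(self.chrom, self.strand, self.intron_start, self.intron_end)

    @property
    def donor_pos(self) -> int:
        """Genomic coordinate of the donor (5') site.

        On '+' the donor is the intron start; on '-' the intron end.
        Strand-unknown junctions use the intron start as a grouping
        surrogate (they form their own strand group).
        """
        return self.intron_end if self.strand == "-" else self.intron_start

    @property
    def acceptor_pos(self) -> int:
        return self.intron_start if self.strand == "-" else self.intron_end


def parse_junction_table(path, fmt: str = "sj") -> list[Junction]:
    """Parse a junction table.

    ``fmt='sj'``: the 9-column STAR SJ.out.tab dialect (chrom, 1-based
    intron start, 1-based intron end, strand code 0/1/2, motif,
    annotated, unique reads, multi reads, max overhang). ``fmt='bed'``:
    a 6-column BED-like table (chrom, start, end, name, unique_reads,
    strand) already 0-based half-open.
    """
    if fmt not in ("sj", "bed"):
        raise ValueError(f"unknown junction format {fmt!r}")
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if fmt == "sj":
                    if len(fields) != 9:
                        raise ValueError(f"expected 9 columns, got {len(fields)}")
                    chrom = fields[0]
                    # SJ.out.tab introns are 1-based inclusive
                    start = int(fields[1]) - 1
                    end = int(fields[2])
                    strand = _STRAND_CODE.get(fields[3])
                    if strand is None:
                        raise ValueError(f"bad strand code {fields[3]!r}")
                    annotated = fields[5] not in ("0", "")
                    reads = int(fields[6])
                else:
                    if len(fields) < 6:
                        raise ValueError(f"expected 6 columns, got {len(fields)}")
                    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                    reads, strand = int(fields[4]), fields[5]
                    annotated = False
                    if strand not in ("+", "-", "."):
                        raise ValueError(f"bad strand {strand!r}")
                out.append(
                    Junction(chrom, strand, start, end, reads, annotated_flag=annotated)
                )
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from None
    return out


def compute_psi(junctions: list[Junction]) -> list[Junction]:
    """Set psi5/psi3 on every junction.

    psi is computed over the *full* table (before any filtering) so
    denominators reflect all observed junctions. A group whose total
    read count is zero gets psi = 0 for all members, with a warning.
    """
    donor_tot: dict[tuple, int] = {}
    accept_tot: dict[tuple, int] = {}
    for j in junctions:
        dk = (j.chrom, j.strand, j.donor_pos)
        ak = (j.chrom, j.strand, j.acceptor_pos)
        donor_tot[dk] = donor_tot.get(dk, 0) + j.unique_reads
        accept_tot[ak] = accept_tot.get(ak, 0) + j.unique_reads

    def _frac(reads: int, total: int, what: str) -> float:
        if total == 0:
            log.warning("zero total reads in a %s group; psi set to 0", what)
            return 0.0
        return reads / total

    return [
        replace(
            j,
            psi5=_frac(j.unique_reads, donor_tot[(j.chrom, j.strand, j.donor_pos)], "donor"),
            psi3=_frac(j.unique_reads, accept_tot[(j.chrom, j.strand, j.acceptor_pos)], "acceptor"),
        )
        for j in junctions
    ]


@dataclass
class FilterSummary:
    """Per-reason removal counts plus the reason assigned to each key.

    Reason precedence is reads -> psi -> normal: a junction failing
    several checks is counted once, under the first.
    """

    total: int = 0
    retained: int = 0
    removed_low_reads: int = 0
    removed_low_psi: int = 0
    removed_normal: int = 0
    reasons: dict[JunctionKey, str] = field(default_factory=dict)

    def consistent(self) -> bool:
        return (
            self.retained
            + self.removed_low_reads
            + self.removed_low_psi
            + self.removed_normal
            == self.total
        )


def filter_junctions(
    junctions: list[Junction],
    db: NormalJunctionDB,
    min_unique_reads: int = 10,
    min_psi: float = 0.1,
) -> tuple[list[Junction], FilterSummary]:
    """Apply the three junction filters; thresholds are strict (>).

    Retained iff unique_reads > min_unique_reads, psi5 > min_psi,
    psi3 > min_psi, and the junction key is absent from the normal DB.
    Input order is preserved.
    """
    summary = FilterSummary(total=len(junctions))
    kept = []
    for j in junctions:
        if j.psi5 is None or j.psi3 is None:
            raise ValueError("psi must be computed before filtering")
        if not j.unique_reads > min_unique_reads:
            summary.removed_low_reads += 1
            summary.reasons[j.key] = "low_reads"
        elif not (j.psi5 > min_psi and j.psi3 > min_psi):
            summary.removed_low_psi += 1
            summary.reasons[j.key] = "low_psi"
        elif j.key in db:
            summary.removed_normal += 1
            summary.reasons[j.key] = "normal"
        else:
            summary.retained += 1
            kept.append(j)
    return kept, summary
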