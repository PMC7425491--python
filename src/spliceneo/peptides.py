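"""Translation of novel isoforms and candidate peptide generation.

Novel isoforms are translated in one frame only: from the host's
annotated start codon, in its original frame, to the first stop codon.
Single-frame translation deliberately trades sensitivity for a lower
false-positive rate compared with three-/six-frame translation.
Retained proteins are chopped into 8-11-mers, exact matches to the
normal proteome are subtracted, and each survivor is paired with its
most similar normal peptide (minimum Hamming distance, equal length).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome import GenomeSequence, translate_to_stop
from .isoforms import NovelIsoform, Rejected
from .normals import JunctionKey, NormalPeptideIndex


@dataclass(frozen=True)
class ProteinRecord:
    """A translated novel protein (no stop character inside)."""

    sequence: str
    source_id: str  # novel isoform id
    frame_status: str  # "stop_found" | "ran_off_end"


@dataclass(frozen=True)
class PeptideCandidate:
    """A candidate neoantigen k-mer with merged provenance.

    ``sources`` lists every (novel isoform id, junction key) the
    sequence arose from. ``nearest_normal``/``mismatches`` are set by
    the nearest-normal search (mismatches >= 1 by construction, since
    exact normal matches were subtracted).
    """

    sequence: str
    sources: tuple[tuple[str, JunctionKey], ...]
    nearest_normal: str | None = None
    mismatches: int | None = None


def _start_codon_offset(iso: NovelIsoform) -> int:
    """Transcript-coordinate offset of the start codon's first base.

    Raises :class:`Rejected` ("start-lost") when the junction insertion
    excised the genomic position of the start codon.
    """
    g = iso.cds_start if iso.strand == "+" else iso.cds_end - 1
    offset = 0
    if iso.strand == "+":
        for s, e in iso.exons:
            if s <= g < e:
                return offset + (g - s)
            offset += e - s
    else:
        for s, e in reversed(iso.exons):
            if s <= g < e:
                return offset + (e - 1 - g)
            offset += e - s
    raise Rejected("start-lost", f"start codon position {g} excised from {iso.isoform_id}")


def translate_isoform(
    iso: NovelIsoform, genome: GenomeSequence, min_protein_len: int = 30
) -> ProteinRecord:
    """One-frame translation of a novel isoform.

    The spliced transcript is assembled 5'->3' (strand-aware) and
    translated from the inherited start codon to the first stop
    (``stop_found``) or the transcript end (``ran_off_end``). Proteins
    of length <= ``min_protein_len`` are rejected ("short-protein").
    """
    offset = _start_codon_offset(iso)
    transcript = genome.fetch_spliced(iso.chrom, iso.exons, iso.strand)
    protein, stop = translate_to_stop(transcript[offset:])
    if not len(protein) > min_protein_len:
        raise Rejected("short-protein", f"length {len(protein)} needs > {min_protein_len}")
    return ProteinRecord(
        sequence=protein,
        source_id=iso.isoform_id,
        frame_status="stop_found" if stop else "ran_off_end",
    )


def chop_peptides(
    protein: ProteinRecord | str, ks: tuple[int, ...] = (8, 9, 10, 11)
) -> list[tuple[str, int, int]]:
    """All k-mers of the protein, as ``(sequence, start, k)`` tuples."""
    seq = protein.sequence if isinstance(protein, ProteinRecord) else protein
    out = []
    for k in sorted(set(ks)):
        for i in range(len(seq) - k + 1):
            out.append((seq[i : i + k], i, k))
    return out


def filter_normal_peptides(
    kmers: list[tuple[str, str, JunctionKey]],
    index: NormalPeptideIndex,
) -> list[PeptideCandidate]:
    """Subtract normal-proteome k-mers; deduplicate survivors.

    ``kmers`` are ``(sequence, isoform_id, junction_key)`` triples.
    Peptides containing non-canonical residues ('X' from ambiguous
    codons) are dropped: binding predictors cannot score them. Output
    is sorted by sequence with provenance merged and deduplicated.
    """
    merged: dict[str, list[tuple[str, JunctionKey]]] = {}
    for seq, iso_id, jkey in kmers:
        if "X" in seq or "*" in seq:
            continue
        if index.contains(seq):
            continue
        merged.setdefault(seq, [])
        if (iso_id, jkey) not in merged[seq]:
            merged[seq].append((iso_id, jkey))
    return [
        PeptideCandidate(sequence=s, sources=tuple(sorted(merged[s])))
        for s in sorted(merged)
    ]


def nearest_normal_peptide(candidate: str, index: NormalPeptideIndex) -> tuple[str, int]:
    """Most similar equal-length normal peptide and its mismatch count.

    Precondition: the candidate was already subtracted (it must not be
    an exact member of the index).
    """
    if index.contains(candidate):
        raise ValueError(f"{candidate} is itself a normal peptide")
    return index.nearest(candidate)


def annotate_nearest_normal(
    candidates: list[PeptideCandidate], index: NormalPeptideIndex
) -> list[PeptideCandidate]:
    out = []
    for c in candidates:
        pep, m = nearest_normal_peptide(c.sequence, index)
        out.append(replace(c, nearest_normal=pep, mismatches=m))
    return out
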