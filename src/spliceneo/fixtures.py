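"""Synthetic fixture generation: a miniature genome with planted junctions.

The generator emits everything one pipeline run consumes — genome
FASTA, refGene-dialect annotation, an SJ.out.tab junction table, a
panel-of-normals count matrix, per-transcript read counts and an
epitope FASTA — plus a manifest recording the expected fate of every
planted junction. Five four-exon genes host twelve junctions, each
engineered to exercise exactly one decision of the pipeline:

========================  =======================================
planted class             expected fate
========================  =======================================
tag1_pass                 retained (exon skip, in frame)
tag2_pass                 retained (alternative 3' site, -30 bp)
tag3_pass                 retained (exitron-like split, -60 bp)
low_reads                 rejected:low_reads   (10 reads, needs >10)
low_psi                   rejected:low_psi     (psi3 = 0.1, needs >0.1)
normal                    rejected:normal      (annotated + panel)
exon_mod                  rejected:exon-mod    (1 bp shift, needs >=2)
intron_length             rejected:intron-length (50 bp, needs >50)
non_coding                rejected:non-coding  (junction in 3' UTR)
start_lost                rejected:start-lost  (skip excises ATG)
low_rpkm                  rejected:low_rpkm    (host RPKM exactly 1.0)
short_protein             rejected:short-protein (6 aa after shift)
========================  =======================================

Gene CDSs are random sense codons (no internal stops) so reference
proteins translate cleanly; the short-protein gene carries an
engineered in-frame-silent motif that becomes a stop codon in the
shifted reading frame created by its planted junction. Candidate
peptides for the three "retained" junctions are guaranteed to include
at least one surrogate binder (%rank < 2 at the fixture seed) by
resampling that gene's codons until one exists — emulating the fact
that real tumors present some of their splice-derived peptides.

Fixed seed => byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import reverse_complement, translate_to_stop
from .models import TranscriptModel, write_refgene
from .predictors import SurrogateBindingPredictor

EXON_LENS = (120, 150, 90, 150)
INTRON_LEN = 300
GENE_SPAN = sum(EXON_LENS) + 3 * INTRON_LEN  # 1410
DEFAULT_ALLELES = ("HLA-A*02:01", "HLA-B*07:02")
TOTAL_MAPPED_READS = 100_000_000

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class _Gene:
    name: str
    chrom: str
    offset: int
    strand: str
    cds_tx: tuple[int, int]  # CDS span in transcript coordinates
    # bases forced at fixed exon offsets AFTER random codon fill
    # (offset within the gene, genomic orientation) -> base
    pattern: tuple[tuple[int, str], ...] = ()

    @property
    def exons(self) -> tuple[tuple[int, int], ...]:
        out, pos = [], self.offset
        for length in EXON_LENS:
            out.append((pos, pos + length))
            pos += length + INTRON_LEN
        return tuple(out)

    def model(self) -> TranscriptModel:
        txpos = self.tx_positions()
        lo, hi = self.cds_tx
        cds_pos = txpos[lo:hi]
        return TranscriptModel(
            transcript_id=f"TX_{self.name}",
            gene_id=f"GENE_{self.name}",
            chrom=self.chrom,
            strand=self.strand,
            exons=self.exons,
            cds_start=min(cds_pos),
            cds_end=max(cds_pos) + 1,
        )

    def tx_positions(self) -> list[int]:
        """Genomic position of each transcript coordinate, 5'->3'."""
        fwd = [p for s, e in self.exons for p in range(s, e)]
        return fwd if self.strand == "+" else fwd[::-1]


# Gene layout. The short-protein motif in gene C (exon-1 offsets
# 105-113, in-frame codons GCC CTA AAA) reads as ...CCC TAA... in the
# +1-shifted frame entered through the planted 61-bp exitron split.
_GENES = {
    "A": _Gene("A", "chr1", 500, "+", (30, 450)),
    "B": _Gene("B", "chr2", 500, "-", (30, 450)),
    "C": _Gene(
        "C", "chr1", 3500, "+", (30, 450),
        pattern=tuple((105 + i, b) for i, b in enumerate("GCCCTAAAA")),
    ),
    "D": _Gene("D", "chr2", 3500, "+", (150, 450)),
    "E": _Gene("E", "chr1", 6500, "+", (30, 450)),
}

_CHROM_LENS = {"chr1": 8500, "chr2": 5500}


def _e(gene: str, i: int, side: str) -> int:
    ex = _GENES[gene].exons[i]
    return ex[0] if side == "s" else ex[1]


# name -> (gene, intron_start, intron_end, unique_reads, annotated, fate)
def _junction_plan() -> list[dict]:
    g = _GENES
    plan = [
        ("tag1_pass", "A", _e("A", 1, "e"), _e("A", 3, "s"), 150, 0, "retained"),
        ("low_reads", "A", _e("A", 0, "e"), _e("A", 2, "s"), 10, 0, "rejected:low_reads"),
        ("tag2_pass", "B", _e("B", 1, "e"), _e("B", 2, "s") + 30, 120, 0, "retained"),
        ("low_psi", "B", _e("B", 0, "e"), _e("B", 1, "s") + 45, 20, 0, "rejected:low_psi"),
        ("normal", "B", _e("B", 0, "e"), _e("B", 1, "s"), 180, 1, "rejected:normal"),
        ("tag3_pass", "C", _e("C", 1, "s") + 30, _e("C", 1, "s") + 90, 200, 0, "retained"),
        ("intron_length", "C", _e("C", 2, "s") + 20, _e("C", 2, "s") + 70, 90, 0, "rejected:intron-length"),
        ("exon_mod", "C", _e("C", 0, "e"), _e("C", 1, "s") + 1, 80, 0, "rejected:exon-mod"),
        ("short_protein", "C", g["C"].offset + 45, g["C"].offset + 106, 60, 0, "rejected:short-protein"),
        ("start_lost", "D", _e("D", 0, "e"), _e("D", 2, "s"), 100, 0, "rejected:start-lost"),
        ("non_coding", "D", g["D"].offset + 1352, g["D"].offset + 1405, 70, 0, "rejected:non-coding"),
        ("low_rpkm", "E", _e("E", 1, "e"), _e("E", 3, "s"), 130, 0, "rejected:low_rpkm"),
    ]
    return [
        dict(
            name=n, gene=gn, chrom=g[gn].chrom, strand=g[gn].strand,
            intron_start=s, intron_end=e, unique_reads=r,
            annotated=a, expected_fate=f, host_transcript=f"TX_{gn}",
        )
        for n, gn, s, e, r, a, f in plan
    ]


def _novel_exons(name: str) -> tuple[tuple[int, int], ...] | None:
    """Expected exon chain of each retained junction's novel isoform."""
    g = _GENES
    if name == "tag1_pass":
        ex = g["A"].exons
        return (ex[0], ex[1], ex[3])
    if name == "tag2_pass":
        ex = g["B"].exons
        return (ex[0], ex[1], (ex[2][0] + 30, ex[2][1]), ex[3])
    if name == "tag3_pass":
        ex = g["C"].exons
        s, e = ex[1][0] + 30, ex[1][0] + 90
        return (ex[0], (ex[1][0], s), (e, ex[1][1]), ex[2], ex[3])
    return None


def _fill_gene_cds(chrom_seq: list[str], gene: _Gene, rng: np.random.Generator) -> None:
    """Overwrite the gene's CDS with random sense codons (ATG ... TAA)."""
    lo, hi = gene.cds_tx
    n_codons = (hi - lo) // 3
    codons = ["ATG"] + [
        _SENSE_CODONS[i] for i in rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    ] + ["TAA"]
    cds = "".join(codons)
    txpos = gene.tx_positions()
    for i, base in enumerate(cds):
        p = txpos[lo + i]
        chrom_seq[p] = base if gene.strand == "+" else _COMP[base]
    for off, base in gene.pattern:
        chrom_seq[gene.offset + off] = base


def _spliced(chrom_seq: list[str], exons, strand: str) -> str:
    seq = "".join("".join(chrom_seq[s:e]) for s, e in exons)
    return reverse_complement(seq) if strand == "-" else seq


def _protein(chrom_seq, exons, cds_start: int, cds_end: int, strand: str) -> str:
    """One-frame translation from the (genomic) start codon position."""
    tx = _spliced(chrom_seq, exons, strand)
    start_g = cds_start if strand == "+" else cds_end - 1
    offset = 0
    for s, e in exons if strand == "+" else reversed(exons):
        if s <= start_g < e:
            offset += (start_g - s) if strand == "+" else (e - 1 - start_g)
            break
        offset += e - s
    prot, _ = translate_to_stop(tx[offset:])
    return prot


def _kmers(seq: str, ks=(8, 9, 10, 11)) -> set[str]:
    return {seq[i : i + k] for k in ks for i in range(len(seq) - k + 1)}


def generate_fixture(
    out_dir,
    seed: int,
    alleles: tuple[str, ...] = DEFAULT_ALLELES,
    panel_samples: int = 100,
) -> dict:
    """Write the fixture bundle into ``out_dir``; return the manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([int(seed), 0xF1C5])
    binder = SurrogateBindingPredictor(seed=int(seed))

    chrom_seq = {
        c: list("".join(np.array(list("ACGT"))[rng.integers(0, 4, n)]))
        for c, n in _CHROM_LENS.items()
    }
    plan = _junction_plan()
    by_name = {j["name"]: j for j in plan}

    pass_junction = {"A": "tag1_pass", "B": "tag2_pass", "C": "tag3_pass"}
    for gname, gene in _GENES.items():
        model = gene.model()
        target = pass_junction.get(gname)
        for attempt in range(200):
            gene_rng = np.random.default_rng([int(seed), ord(gname), attempt])
            _fill_gene_cds(chrom_seq[gene.chrom], gene, gene_rng)
            if target is None:
                break
            ref = _protein(
                chrom_seq[gene.chrom], gene.exons,
                model.cds_start, model.cds_end, gene.strand,
            )
            novel = _protein(
                chrom_seq[gene.chrom], _novel_exons(target),
                model.cds_start, model.cds_end, gene.strand,
            )
            candidates = sorted(_kmers(novel) - _kmers(ref))
            if any(
                binder.percent_rank(p, a) < 2.0 for p in candidates for a in alleles
            ):
                break
        else:
            raise RuntimeError(f"could not plant a surrogate binder in gene {gname}")

    models = [g.model() for g in _GENES.values()]

    genome_path = out / "genome.fa"
    with open(genome_path, "w") as fh:
        for chrom in sorted(chrom_seq):
            fh.write(f">{chrom}\n")
            s = "".join(chrom_seq[chrom])
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")

    annot_path = out / "annotation.refgene.txt"
    write_refgene(models, annot_path)

    strand_code = {"+": "1", "-": "2"}
    sj_path = out / "junctions.sj.tab"
    with open(sj_path, "w") as fh:
        for j in plan:
            fh.write(
                "\t".join(
                    [
                        j["chrom"],
                        str(j["intron_start"] + 1),  # SJ.out.tab is 1-based inclusive
                        str(j["intron_end"]),
                        strand_code[j["strand"]],
                        "0",
                        str(j["annotated"]),
                        str(j["unique_reads"]),
                        "0",
                        "30",
                    ]
                )
                + "\n"
            )

    # panel of normals: the 'normal' junction qualifies (2 reads in half
    # the samples); decoys fall below either boundary of the rule
    panel_path = out / "panel.tsv"
    nj = by_name["normal"]
    with open(panel_path, "w") as fh:
        header = ["chrom", "strand", "intron_start", "intron_end"] + [
            f"N{i:03d}" for i in range(panel_samples)
        ]
        fh.write("\t".join(header) + "\n")
        rows = [
            (nj["chrom"], nj["strand"], nj["intron_start"], nj["intron_end"],
             [2] * (panel_samples // 2) + [0] * (panel_samples - panel_samples // 2)),
            ("chr1", "+", 100, 260, [1] * panel_samples),  # below min_reads everywhere
            ("chr2", "+", 100, 260, [0] * panel_samples),  # absent
        ]
        for chrom, strand, s, e, counts in rows:
            fh.write("\t".join([chrom, strand, str(s), str(e)] + [str(c) for c in counts]) + "\n")

    # per-transcript read counts: RPKM = 100 everywhere except gene E,
    # whose RPKM is exactly 1.0 (fails the strict > 1 gate)
    counts_path = out / "counts.tsv"
    with open(counts_path, "w") as fh:
        for g in _GENES.values():
            count = 51 if g.name == "E" else 5100
            fh.write(f"TX_{g.name}\t{count}\n")

    # epitope library: windows of the reference proteome plus unrelated
    # random peptides, so recognition probabilities span a range
    genome_ref = {
        m.transcript_id: _protein(
            chrom_seq[m.chrom], m.exons, m.cds_start, m.cds_end, m.strand
        )
        for m in models
    }
    epi_path = out / "epitopes.fa"
    with open(epi_path, "w") as fh:
        i = 0
        for tid in sorted(genome_ref):
            prot = genome_ref[tid]
            for _ in range(2):
                start = int(rng.integers(0, len(prot) - 9))
                fh.write(f">EPI{i:02d}\n{prot[start : start + 9]}\n")
                i += 1
        aas = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(5):
            pep = "".join(aas[k] for k in rng.integers(0, 20, 9))
            fh.write(f">EPI{i:02d}\n{pep}\n")
            i += 1

    manifest = {
        "seed": int(seed),
        "alleles": list(alleles),
        "total_mapped_reads": TOTAL_MAPPED_READS,
        "panel_samples": panel_samples,
        "files": {
            "genome": genome_path.name,
            "annotation": annot_path.name,
            "junctions": sj_path.name,
            "panel": panel_path.name,
            "counts": counts_path.name,
            "epitopes": epi_path.name,
        },
        "genes": [
            {
                "transcript_id": m.transcript_id,
                "chrom": m.chrom,
                "strand": m.strand,
                "exons": [list(e) for e in m.exons],
                "cds_start": m.cds_start,
                "cds_end": m.cds_end,
            }
            for m in models
        ],
        "junctions": [
            {
                **{k: v for k, v in j.items() if k != "gene"},
                "novel_exons": (
                    [list(e) for e in _novel_exons(j["name"])]
                    if _novel_exons(j["name"])
                    else None
                ),
            }
            for j in plan
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
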