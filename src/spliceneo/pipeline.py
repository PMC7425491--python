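"""End-to-end orchestration: junction table in, scored neoantigen table out.

Stage order: junction filtering (reads, psi, normal DB) -> isoform
placement and host selection -> junction insertion -> one-frame
translation -> k-mer chopping and normal-proteome subtraction ->
binding prediction (%rank < 2) -> immune scoring and HIN labeling.
Every junction is accounted for exactly once, either as retained or as
rejected with a reason; work is partitioned by junction and results are
canonically sorted before writing, so the thread count never changes
the output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .genome import GenomeSequence
from .isoforms import (
    NovelIsoform,
    Rejected,
    TranscriptIndex,
    compute_rpkm,
    insert_junction,
    map_junction_to_isoforms,
    select_hosts,
)
from .junctions import Junction, compute_psi, filter_junctions, parse_junction_table
from .models import TranscriptModel, load_annotation
from .normals import (
    NormalJunctionDB,
    NormalPeptideIndex,
    build_normal_junction_db,
    build_normal_peptide_index,
    extract_reference_proteome,
    read_panel_tsv,
)
from .peptides import (
    ProteinRecord,
    annotate_nearest_normal,
    chop_peptides,
    filter_normal_peptides,
    translate_isoform,
)
from .predictors import SurrogateBindingPredictor, SurrogateProcessingPredictor
from .scoring import (
    EpitopeLibrary,
    ScoreComponents,
    ScoredPeptide,
    hydrophobicity_score_H,
    label_hin,
    predict_binding,
    recognition_probability_R,
)

log = logging.getLogger(__name__)

SCORE_COLUMNS = [
    "peptide", "allele", "Rm", "normal_peptide", "Rn", "M",
    "C", "H", "R", "S", "HIN", "junctions", "isoforms", "tags",
]


@dataclass
class PipelineConfig:
    """All inputs and thresholds of one pipeline run."""

    genome: str
    annotation: str
    junctions: str
    epitope_library: str
    hla_alleles: tuple[str, ...]
    normal_db: str | None = None
    panel: str | None = None
    counts: str | None = None
    total_mapped_reads: int | None = None
    junction_format: str = "sj"
    min_unique_reads: int = 10
    min_psi: float = 0.1
    min_rpkm: float = 1.0
    min_exon_mod: int = 2
    max_exon_mod: int = 250
    min_intron: int = 50
    min_protein_len: int = 30
    lengths: tuple[int, ...] = (8, 9, 10, 11)
    rank_threshold: float = 2.0
    hin_cutoff: float = 1e-8
    panel_min_reads: int = 2
    panel_min_sample_frac: float = 0.01
    include_normal_junction_proteins: bool = True
    predictor: str = "surrogate"
    seed: int = 1
    threads: int = 1
    out_dir: str | None = None

    def validate(self) -> None:
        for name in ("genome", "annotation", "junctions", "epitope_library"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.normal_db is None and self.panel is None:
            raise ValueError("provide a prebuilt normal_db or a panel matrix")
        if not set(self.lengths) <= {8, 9, 10, 11}:
            raise ValueError("lengths must be a subset of {8, 9, 10, 11}")
        for name in ("min_psi", "min_rpkm", "rank_threshold", "hin_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.hla_alleles:
            raise ValueError("at least one HLA allele required")


@dataclass
class RunSummary:
    """Stage counts, per-junction fates and output paths of one run."""

    counts: dict[str, int] = field(default_factory=dict)
    junction_fates: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    records: list[ScoredPeptide] = field(default_factory=list)
    candidate_sequences: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "counts": self.counts,
                "junction_fates": dict(sorted(self.junction_fates.items())),
                "outputs": self.outputs,
                "config": self.config,
            },
            indent=2,
            sort_keys=False,
        )


def _key_str(key) -> str:
    return f"{key.chrom}:{key.strand}:{key.intron_start}-{key.intron_end}"


def _load_rpkm(config: PipelineConfig, models: list[TranscriptModel]) -> dict[str, float]:
    if config.counts is None:
        return {}
    counts = pd.read_csv(
        config.counts, sep="\t", header=None, names=["transcript_id", "count"]
    )
    count_map = dict(zip(counts.transcript_id, counts["count"].astype(int)))
    total = config.total_mapped_reads or int(counts["count"].sum())
    by_id = {m.transcript_id: m for m in models}
    return {
        tid: compute_rpkm(by_id[tid], c, total)
        for tid, c in count_map.items()
        if tid in by_id
    }


def _process_junction(
    j: Junction,
    index: TranscriptIndex,
    genome: GenomeSequence,
    rpkm: dict[str, float],
    config: PipelineConfig,
) -> tuple[str, list[NovelIsoform], list[ProteinRecord]]:
    """Fate, novel isoforms and proteins for one filtered junction."""
    placements = map_junction_to_isoforms(j, index)
    if not placements:
        return "rejected:unmapped", [], []
    if any(p.tag == 0 for p in placements):
        return "rejected:annotated", [], []
    selected = select_hosts(placements, rpkm, config.min_rpkm)
    if not selected:
        return "rejected:low_rpkm", [], []
    isoforms, proteins, reasons = [], [], []
    for p in selected:
        try:
            iso = insert_junction(
                p,
                min_exon_mod=config.min_exon_mod,
                max_exon_mod=config.max_exon_mod,
                min_intron=config.min_intron,
            )
            iso = replace(iso, rpkm_of_host=rpkm.get(p.host.transcript_id, 0.0))
            prot = translate_isoform(iso, genome, config.min_protein_len)
        except Rejected as exc:
            reasons.append(exc.reason)
            continue
        isoforms.append(iso)
        proteins.append(prot)
    if proteins:
        return "retained", isoforms, proteins
    return f"rejected:{reasons[0]}", [], []


def _normal_junction_proteins(
    db: NormalJunctionDB,
    index: TranscriptIndex,
    genome: GenomeSequence,
    config: PipelineConfig,
) -> list[str]:
    """Proteins the isoform machinery produces from panel-normal junctions.

    These extend the normal proteome: peptides reachable through a
    tolerated junction are not tumor-specific. Expression gating does
    not apply here (tolerance, not abundance, is the question).
    """
    proteins = []
    for key in db.panel_keys():
        j = Junction(key.chrom, key.strand, key.intron_start, key.intron_end, unique_reads=0)
        placements = [p for p in map_junction_to_isoforms(j, index) if p.tag > 0]
        if not placements:
            continue
        min_tag = min(p.tag for p in placements)
        for p in placements:
            if p.tag != min_tag:
                continue
            try:
                iso = insert_junction(
                    p,
                    min_exon_mod=config.min_exon_mod,
                    max_exon_mod=config.max_exon_mod,
                    min_intron=config.min_intron,
                )
                prot = translate_isoform(iso, genome, config.min_protein_len)
            except Rejected:
                continue
            proteins.append(prot.sequence)
    return proteins


def run_pipeline(config: PipelineConfig) -> RunSummary:
    config.validate()
    summary = RunSummary(config={
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
    })

    genome = GenomeSequence(config.genome)
    models = load_annotation(config.annotation)
    index = TranscriptIndex(models)
    rpkm = _load_rpkm(config, models)

    if config.normal_db is not None:
        db = NormalJunctionDB.read_tsv(config.normal_db)
    else:
        db = build_normal_junction_db(
            read_panel_tsv(config.panel),
            models,
            min_reads=config.panel_min_reads,
            min_sample_frac=config.panel_min_sample_frac,
        )

    proteome = [seq for _, seq in extract_reference_proteome(models, genome)]
    normal_proteins = list(proteome)
    if config.include_normal_junction_proteins:
        normal_proteins += _normal_junction_proteins(db, index, genome, config)
    peptide_index = build_normal_peptide_index(normal_proteins, ks=config.lengths)

    junctions = parse_junction_table(config.junctions, fmt=config.junction_format)
    junctions = compute_psi(junctions)
    filtered, filt = filter_junctions(
        junctions, db, min_unique_reads=config.min_unique_reads, min_psi=config.min_psi
    )
    for key, reason in filt.reasons.items():
        summary.junction_fates[_key_str(key)] = f"rejected:{reason}"

    def worker(j):
        return j, _process_junction(j, index, genome, rpkm, config)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(worker, filtered))
    else:
        results = [worker(j) for j in filtered]
    # canonical order regardless of executor scheduling
    results.sort(key=lambda item: item[0].key)

    all_isoforms: list[NovelIsoform] = []
    kmer_triples = []
    for j, (fate, isoforms, proteins) in results:
        summary.junction_fates[_key_str(j.key)] = fate
        all_isoforms.extend(isoforms)
        for iso, prot in zip(isoforms, proteins):
            for seq, _, _ in chop_peptides(prot, ks=config.lengths):
                kmer_triples.append((seq, iso.isoform_id, iso.junction_key))

    candidates = filter_normal_peptides(kmer_triples, peptide_index)
    candidates = annotate_nearest_normal(candidates, peptide_index)
    summary.candidate_sequences = [c.sequence for c in candidates]

    binder = SurrogateBindingPredictor(seed=config.seed)
    processing = SurrogateProcessingPredictor(binder)
    peptide_seqs = [c.sequence for c in candidates]
    all_results, retained_pairs = predict_binding(
        peptide_seqs, list(config.hla_alleles), binder, config.rank_threshold
    )
    library = EpitopeLibrary.from_fasta(config.epitope_library)

    by_seq = {c.sequence: c for c in candidates}
    records: list[ScoredPeptide] = []
    for br in retained_pairs:
        cand = by_seq[br.peptide]
        rn = binder.percent_rank(cand.nearest_normal, br.hla_allele)
        comp = ScoreComponents(
            Rm=br.percent_rank,
            Rn=rn,
            M=cand.mismatches,
            C=processing.combined_score(br.peptide, br.hla_allele),
            H=hydrophobicity_score_H(br.peptide),
            R=recognition_probability_R(br.peptide, library),
        )
        records.append(
            ScoredPeptide(
                peptide=br.peptide,
                allele=br.hla_allele,
                components=comp,
                nearest_normal=cand.nearest_normal,
                sources=cand.sources,
            )
        )
    records = label_hin(records, config.hin_cutoff)
    records.sort(key=lambda r: (-r.S, r.peptide, r.allele))
    summary.records = records

    summary.counts = {
        "junctions_input": filt.total,
        "junctions_removed_low_reads": filt.removed_low_reads,
        "junctions_removed_low_psi": filt.removed_low_psi,
        "junctions_removed_normal": filt.removed_normal,
        "junctions_after_filters": filt.retained,
        "junctions_retained": sum(
            1 for _, (fate, _, _) in results if fate == "retained"
        ),
        "novel_isoforms": len(all_isoforms),
        "novel_proteins": len(all_isoforms),
        "kmers_total": len(kmer_triples),
        "candidate_peptides": len(candidates),
        "binding_pairs_tested": len(all_results),
        "putative_pairs": len(retained_pairs),
        "putative_peptides": len({r.peptide for r in records}),
        "hin_pairs": sum(1 for r in records if r.hin),
    }

    if config.out_dir is not None:
        write_outputs(records, summary, config.out_dir)
    return summary


def records_to_frame(records: list[ScoredPeptide]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.components
        rows.append(
            {
                "peptide": r.peptide,
                "allele": r.allele,
                "Rm": c.Rm,
                "normal_peptide": r.nearest_normal,
                "Rn": c.Rn,
                "M": c.M,
                "C": c.C,
                "H": c.H,
                "R": c.R,
                "S": c.S,
                "HIN": int(bool(r.hin)),
                "junctions": ";".join(sorted({_key_str(k) for _, k in r.sources})),
                "isoforms": ";".join(sorted({iso for iso, _ in r.sources})),
                "tags": ";".join(
                    sorted({iso.rsplit("tag", 1)[-1] for iso, _ in r.sources})
                ),
            }
        )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def write_outputs(records: list[ScoredPeptide], summary: RunSummary, out_dir) -> None:
    """Score table (TSV, S-descending), peptide FASTA, JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records)
    score_path = out / "neoantigens.tsv"
    df.to_csv(score_path, sep="\t", index=False)
    fasta_path = out / "neoantigens.fa"
    with open(fasta_path, "w") as fh:
        for pep in sorted({r.peptide for r in records}):
            fh.write(f">{pep}\n{pep}\n")
    summary.outputs = {"score_table": str(score_path), "peptides": str(fasta_path)}
    summary_path = out / "summary.json"
    summary_path.write_text(summary.to_json() + "\n")
    summary.outputs["summary"] = str(summary_path)
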