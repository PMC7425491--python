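# spliceneo

Tumors mis-splice. Splice junctions seen in tumor RNA-seq but absent
from normal tissue can create novel protein sequence, and fragments of
that sequence — 8–11-mer peptides presented on MHC class I — are
candidate neoantigens for immunotherapy and vaccine design. `spliceneo`
is a pipeline for calling and prioritizing such splice-derived MHC-I
neoantigen candidates from aligner-reported junction tables. It is
aimed at computational immunologists and cancer-genomics analysts who
already have STAR junction output (`SJ.out.tab`), patient HLA-I types,
and a reference genome/annotation.

## What it computes

Starting from a junction table, the pipeline:

1. **filters junctions** — unique reads > 10, percent-spliced-in
   psi5 > 0.1 and psi3 > 0.1 (psi5: how often this donor is used with
   this acceptor relative to all acceptors sharing the donor; psi3 the
   mirror), and removal of *normal junctions* (junctions with ≥ 2 reads
   in ≥ 1% of a panel of normal samples, plus every annotated intron);
2. **builds novel isoforms** — each junction is placed on every
   spanning reference isoform and tagged: 0 = annotated intron, 1 =
   both sites are known exon boundaries (exon skip), 2 = one novel site
   (alternative donor/acceptor), 3 = both sites novel. Smallest-tag
   hosts with RPKM > 1 are kept; insertion requires the junction to hit
   the CDS, a 2–250 bp exon modification for tag 2, and a > 50 bp novel
   intron for tag 3;
3. **translates in one frame** — from the host's annotated start codon
   to the first stop; proteins of length ≤ 30 are dropped (single-frame
   translation keeps the false-positive rate low);
4. **subtracts the normal proteome** — novel proteins are chopped into
   8–11-mers and any k-mer occurring in the normal proteome (reference
   proteins plus proteins derived from normal junctions) is removed;
5. **predicts binding** — every surviving (peptide, HLA allele) pair is
   scored for binding percentile rank; pairs with %rank < 2 are the
   putative neopeptides;
6. **scores immunogenicity** — each putative neopeptide gets

   ```
   S = C · L(Rm) · (1 − L(Rn)/2^M) · H · R,   L(x) = 1/(1 + e^{5(x−2)})
   ```

   with Rm/Rn the binding %ranks of the candidate and of its most
   similar normal peptide, M their Hamming mismatch count, C a combined
   processing score (binding + proteasomal C-terminal cleavage + TAP
   transport), H a hydrophobicity score over TCR-contact residues and R
   a recognition probability from gapless BLOSUM62 similarity to a
   known-epitope library. Candidates with S > 1e-8 are flagged
   high-immunogenicity neopeptides (HIN).

Binding and processing predictors are pluggable: adapters parse
NetMHCpan-4.0 / NetCTLpan text output when you have those tools, and
deterministic seeded surrogates run everywhere else, so the entire
pipeline works offline.

## Worked example

`examples/03_junction_filters.py` builds a four-junction table by hand
and applies the junction filters:

```
psi on the full table (denominators use every observed junction):
  1000-2000: reads= 150 psi5=0.909 psi3=1.000
  1000-3000: reads=  15 psi5=0.091 psi3=1.000
  5000-6000: reads=  10 psi5=1.000 psi3=1.000
  7000-8000: reads=  90 psi5=1.000 psi3=1.000

retained: [(1000, 2000)]
removed: 1 low-reads, 1 low-psi, 1 normal
```

Only the first junction survives: 10 reads is not *greater than* 10,
the junction sharing the donor at 1000 has psi5 = 15/165 = 0.091 ≤ 0.1,
and the last one is in the normal-junction DB.

`examples/01_run_pipeline.py` runs end to end on a generated synthetic
bundle (five genes, twelve planted junctions, each engineered to
trigger one specific filter) and prints the stage accounting:

```
junctions_input                  12
junctions_after_filters          9
junctions_retained               3
novel_proteins                   3
candidate_peptides               102
putative_pairs                   5
```

followed by every planted junction's fate (`retained`,
`rejected:low_reads`, `rejected:exon-mod`, `rejected:start-lost`, ...)
and the score table sorted by S. `examples/02_score_components.py`
walks through the score term by term and shows why a candidate whose
nearest normal peptide is a near-identical strong binder is discounted
(central tolerance).

The same run is available from the shell:

```bash
spliceneo fixture --seed 1 --out bundle/
spliceneo run --junctions bundle/junctions.sj.tab --genome bundle/genome.fa \
    --annotation bundle/annotation.refgene.txt --panel bundle/panel.tsv \
    --epitopes bundle/epitopes.fa --counts bundle/counts.tsv \
    --total-mapped-reads 100000000 \
    --hla "HLA-A*02:01,HLA-B*07:02" --seed 1 --out out/
```

Outputs: `neoantigens.tsv` (one row per scored peptide–allele pair with
all score components), `neoantigens.fa`, and `summary.json` with stage
counts and per-junction fates.

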