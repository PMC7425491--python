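# Methods

## Coordinate and identity conventions

All genomic intervals are 0-based half-open on the forward strand; exon
chains are stored in ascending genomic order regardless of strand. A
junction is identified by its intron's span: `(chrom, strand,
intron_start, intron_end)`. STAR `SJ.out.tab` rows (1-based inclusive
introns, strand codes 0/1/2) and GTF features (1-based inclusive) are
converted at parse time; refGene rows are already half-open. A single
internal convention removes the main source of off-by-one drift in
junction tools. Exon-boundary matching during placement is exact
(0 bp tolerance): junction coordinates from an aligner are base-exact.

## Junction filtering

psi5 of a junction is its unique-read count divided by the summed
unique reads of all junctions sharing its donor site (same chrom,
strand, donor coordinate); psi3 is the analogue over the acceptor. On
'+' the donor is the intron start, on '−' the intron end.
Strand-unknown junctions (SJ strand code 0) form their own strand group
for psi — merging them into either strand would corrupt denominators —
and are tested against hosts on both strands during placement. psi is
computed on the **full** input table before any filtering, so
denominators reflect all observed junctions; filtering first would
inflate psi. A group with zero total reads yields psi 0 with a warning.

All junction thresholds are strict inequalities, matching their
"greater than" definitions: unique reads > 10, psi5 and psi3 > 0.1,
host RPKM > 1, novel intron > 50 bp, protein length > 30, binding
%rank < 2, HIN score > 1e-8. The panel-of-normals rule is ≥ on both of
its boundaries ("at least 2 reads", "at least 1% of samples"), with the
sample cutoff `ceil(min_sample_frac · n_samples)`; with 100 panel
samples a junction qualifying in a single sample is already normal.
Removal reasons are assigned with precedence reads → psi → normal
(cheap to expensive); this affects only bookkeeping, and the per-reason
counts always sum to the input size.

## Isoform construction

Placements are classified by how the junction's two sites relate to the
host's exon boundaries (tags 0–3, see README). Only smallest-tag hosts
produce novel isoforms; a tag-0 placement anywhere means the junction
is annotated in context and yields nothing. The expression gate uses
the host's reference RPKM (`reads · 1e9 / (total_mapped · exonic_len)`)
— the only expression quantity available before the novel isoform
exists.

Insertion rules: the junction's intron span must intersect the host's
genomic CDS span (the most permissive reading of "in the protein coding
region" that still guarantees the translation is perturbed); tag-1
junctions remove the exons strictly between their sites; tag-2
junctions move the affected exon boundary to the novel site, and the
absolute exon-length change must be within 2–250 bp (the alternative
splice-site bounds used by rMATS-style event callers); tag-3 junctions
must fall strictly inside a single exon, which is split around a novel
intron of > 50 bp. Tag-2/3 sites inside an intron of the host are
rejected (`site-in-intron`): the exon-modification constraint is only
defined for exonic sites, so intron retention is deliberately out of
scope. Tag-3 sites in two different exons are rejected with a distinct
reason (`tag3-multi-exon`) rather than guessed at. One novel isoform is
produced per surviving host; downstream peptides are deduplicated by
sequence with provenance merged.

## Translation and peptide generation

Novel isoforms are translated in **one frame only**: the spliced
transcript is assembled 5'→3' and read from the host's start codon, in
its original frame, to the first stop (or transcript end, recorded as
`ran_off_end`). Single-frame translation trades sensitivity for a much
lower false-positive rate than three-/six-frame translation. If the
insertion excised the start codon the isoform is rejected
(`start-lost`). Codons containing N translate to 'X'; peptides
containing 'X' are dropped before membership testing since binding
models cannot score them.

The normal proteome is the reference proteome plus, by default, the
proteins produced by running the same insertion/translation machinery
on every panel-derived normal junction — peptides reachable through a
tolerated junction are not tumor-specific. Surviving 8–11-mers are
checked by exact k-mer membership; each survivor's nearest normal
peptide is the equal-length window of any normal protein minimizing
Hamming distance (ungapped, matching the positional definition of the
mismatch count M), with ties broken by lexicographically smallest
window so results are independent of protein order and platform. The
scan uses an early-exit bound; at desk scale (proteomes of a few
thousand residues) this is exact and fast.

## Predictors and the immune score

The four external prediction tasks (binding %rank, processing,
hydrophobicity, recognition) sit behind small, swappable interfaces.
Adapters parse NetMHCpan-4.0/NetCTLpan text output by column name; the
defaults are pure deterministic surrogates:

* **Binding**: an allele-keyed position-weight profile (anchor
  positions 2 and the C terminus weighted 3.0, others 0.3, weights
  drawn from a seeded RNG keyed by a stable allele hash) scores the
  peptide; the score is converted to a percentile rank against 999
  seeded random background peptides of the same length. Ranks lie in
  (0, 100], are reproducible for a fixed seed, and exercise the strict
  %rank < 2 threshold.
* **Processing**: `C = (w_b·b + w_c·cleavage + w_t·tap) / Σw` with
  `b = 1 − min(Rm, 10)/10`, residue-propensity tables for proteasomal
  C-terminal cleavage and TAP transport (bulky hydrophobic/basic
  favored, acidic/proline disfavored), and default weights
  (1.0, 0.225, 0.025) following the conventional emphasis of combined
  processing predictors.
* **Hydrophobicity**: a logistic of the mean Kyte–Doolittle hydropathy
  over TCR-contact positions 3..k−1 (1-based), slope 0.5 per hydropathy
  unit, intercept calibrated so poly-alanine scores 0.73. This is a
  documented surrogate for a learned hydrophobicity model, swappable
  behind the same signature.
* **Recognition**: the fitness-model form
  `R = Z/(1+Z), Z = Σ_e exp(k·(|s,e| − a))` over a known-epitope
  library, with `|s,e|` the best gapless BLOSUM62 alignment (the
  shorter sequence slides along the longer with full overlap) and
  defaults a = 26, k = 4.87 from the model's source publication.
  Computed via log-sum-exp for numerical stability.

The immune score multiplies the terms:
`S = C · L(Rm) · (1 − L(Rn)/2^M) · H · R` with
`L(x) = 1/(1 + e^{5(x−2)})`, evaluated as a numerically stable
sigmoid. Rn is computed for the candidate's own allele (the
tolerance argument the factor encodes is per-allele). With all
components in [0, 1] the score satisfies 0 ≤ S < 1, and the
self-dissimilarity factor `(1 − L(Rn)/2^M)` lies in (0, 1], rising to 1
as M grows. Scoring is deterministic to full float precision.

## The synthetic bundle: what it emulates, what it does not

`generate_fixture` writes five four-exon genes (one on the minus
strand) on two chromosomes, with random stop-free CDS codons and
twelve planted junctions — three that survive everything (an in-frame
exon skip, a −30 bp alternative acceptor, a −60 bp exitron-like split)
and nine that each fail exactly one filter (see the module docstring
table). RPKM for the low-expression gene is exactly 1.0, probing the
strict gate; the psi-failure junction shares an acceptor with an
annotated junction at a 20:180 read ratio, landing exactly on
psi = 0.1; the short-protein gene carries an engineered motif that is
silent in frame but becomes a stop codon in the shifted frame of its
planted junction, yielding a 6-aa product. Read counts (10–200 unique
reads), a 100-sample panel, two HLA alleles and a 15-entry epitope
library are desk-scale stand-ins for a tumor junction table, a
GTEx-scale panel, a patient HLA type and an IEDB-scale library. Each
"retained" gene's codons are deterministically resampled until at least
one junction-spanning peptide is a surrogate binder at the fixture
seed, emulating the observation that tumors present some of their
splice-derived peptides; the bundle is byte-identical for a fixed seed.

What passing on this bundle does **not** show: performance on real
data. Real junction tables have thousands of junctions with sequencing
noise, real binding motifs differ from the surrogate's, and a real
epitope library is orders of magnitude larger. In particular, with the
small synthetic library the recognition term R — and therefore S — is
very small, so fixture runs report zero HIN peptides; the HIN labeling
logic and representative score magnitudes are exercised in unit tests
with constructed components. The fixture validates the *decision
logic* (filters, tags, insertion constraints, frames, subtraction,
thresholds, determinism), which is exactly the part of the pipeline
that is hard to get right and easy to verify exhaustively at small
scale.

## Numerical and concurrency choices

Work is partitioned by junction; results are gathered and canonically
sorted (by junction key, then by score and peptide at write time), so
the thread count never changes any output byte. Score tables are
written with full-precision float repr and round-trip exactly. The
acceptance script and test suite run the complete pipeline at the
5-gene/12-junction scale (seconds on one CPU), the scale at which the
brute-force oracles (full window scans, exhaustive enumerations) remain
exact.

## Known limitations

Intron retention and multi-junction combinatorial isoforms are not
modeled (one junction per novel isoform). The surrogate predictors are
structurally faithful but numerically unrelated to NetMHCpan/NetCTLpan;
absolute score magnitudes on synthetic data are not comparable to runs
with the licensed tools. HLA typing, read alignment and junction
discovery are upstream of this package, and MHC class II is out of
scope.
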