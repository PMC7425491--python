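"""The immune score: composition of binding, processing, self-dissimilarity,
hydrophobicity and T-cell recognition terms.

For a candidate neoantigen with binding percentile rank ``Rm``, nearest
normal peptide rank ``Rn`` and mismatch count ``M``, combined
processing score ``C``, hydrophobicity score ``H`` and recognition
probability ``R``, the immune score is

    S = C * L(Rm) * (1 - L(Rn) / 2**M) * H * R

with the logistic ``L(x) = 1 / (1 + exp(5 * (x - 2)))`` centred on the
conventional 2% binder threshold. ``L(Rm)`` rewards strong binders; the
``(1 - L(Rn)/2**M)`` factor penalizes candidates whose nearest normal
peptide is both a strong binder and nearly identical (small M), i.e.
likely subject to central tolerance. Candidates with score above 1e-8
are flagged as high-immunogenicity neopeptides (HIN).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.special import expit, logsumexp

# Kyte-Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}

# Logistic calibration of the hydrophobicity surrogate: slope 0.5 per
# hydropathy unit, intercept set so that an all-alanine peptide (mean
# hydropathy 1.8) scores ~0.73.
H_SLOPE = 0.5
H_INTERCEPT = float(np.log(0.73 / 0.27) - H_SLOPE * 1.8)

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def logistic(x: float) -> float:
    """L(x) = 1 / (1 + exp(5 (x - 2))); strictly decreasing, L(2)=0.5."""
    return float(expit(-5.0 * (x - 2.0)))


@dataclass(frozen=True)
class BindingResult:
    peptide: str
    hla_allele: str
    percent_rank: float

    def __post_init__(self):
        if self.percent_rank < 0:
            raise ValueError("percent_rank must be >= 0")


@dataclass(frozen=True)
class ScoreComponents:
    """The seven score components of one scored (peptide, allele) pair."""

    Rm: float
    Rn: float
    M: int
    C: float
    H: float
    R: float

    @property
    def S(self) -> float:
        return immune_score(self)


def immune_score(c: ScoreComponents) -> float:
    """S = C * L(Rm) * (1 - L(Rn)/2**M) * H * R."""
    return c.C * logistic(c.Rm) * (1.0 - logistic(c.Rn) / 2.0**c.M) * c.H * c.R


def predict_binding(
    peptides: Sequence[str],
    alleles: Sequence[str],
    predictor,
    rank_threshold: float = 2.0,
) -> tuple[list[BindingResult], list[BindingResult]]:
    """Score every (peptide, allele) pair; retain strict %rank < threshold.

    Returns ``(all_results, retained)``; a peptide is retained
    per-allele (one record per passing pair).
    """
    for a in alleles:
        if not a.startswith("HLA-"):
            raise ValueError(f"allele {a!r} is not a syntactically valid HLA-I allele")
    ranks = predictor.percent_ranks(list(peptides), list(alleles))
    results = [
        BindingResult(p, a, ranks[(p, a)]) for p in peptides for a in alleles
    ]
    retained = [r for r in results if r.percent_rank < rank_threshold]
    return results, retained


def hydrophobicity_score_H(peptide: str) -> float:
    """Hydrophobicity score in [0, 1] from TCR-contact residues.

    A logistic of the mean Kyte-Doolittle hydropathy over the
    TCR-facing positions 3..k-1 (1-based; the two N-terminal residues
    and the C-terminal anchor are excluded as MHC-facing). This is a
    documented surrogate for a learned hydrophobicity model and can be
    swapped for one behind the same signature.
    """
    contact = peptide[2:-1]
    if not contact:
        raise ValueError(f"peptide too short for contact positions: {peptide!r}")
    try:
        mean_kd = sum(KYTE_DOOLITTLE[a] for a in contact) / len(contact)
    except KeyError as exc:
        raise ValueError(f"non-canonical residue {exc} in {peptide!r}") from None
    return float(expit(H_INTERCEPT + H_SLOPE * mean_kd))


class EpitopeLibrary:
    """Known immunogenic epitopes used by the recognition term."""

    def __init__(self, records: Iterable[tuple[str, str]]):
        self.records = tuple(records)
        if not self.records:
            raise ValueError("epitope library is empty")
        self.sequences = tuple(seq for _, seq in self.records)

    @classmethod
    def from_fasta(cls, path) -> "EpitopeLibrary":
        return cls([(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")])


def gapless_alignment_score(s: str, e: str) -> float:
    """Best gapless alignment score of ``s`` against ``e`` (BLOSUM62).

    The shorter sequence slides along the longer with full overlap; the
    maximum summed substitution score over offsets is returned. With
    equal lengths this is the single positional alignment.
    """
    short, long_ = (s, e) if len(s) <= len(e) else (e, s)
    best = -np.inf
    for off in range(len(long_) - len(short) + 1):
        total = 0.0
        for a, b in zip(short, long_[off : off + len(short)]):
            total += _BLOSUM62[a][b]
        best = max(best, total)
    return float(best)


def recognition_probability_R(
    peptide: str,
    library: EpitopeLibrary,
    a: float = 26.0,
    k_steep: float = 4.87,
) -> float:
    """T-cell recognition probability from epitope similarity.

    Per the fitness-model form: with alignment scores ``|s,e|`` against
    each library epitope, ``R = Z / (1 + Z)`` where
    ``Z = sum_e exp(k_steep * (|s,e| - a))``. ``a`` is the horizontal
    displacement (alignment score of a borderline recognizable
    epitope) and ``k_steep`` the steepness; both are configurable.
    """
    if not library.sequences:
        raise ValueError("epitope library is empty")
    terms = np.array(
        [k_steep * (gapless_alignment_score(peptide, e) - a) for e in library.sequences]
    )
    log_z = float(logsumexp(terms))
    return float(expit(log_z))


def processing_score_C(peptide: str, allele: str, predictor) -> float:
    """Combined processing score from a processing predictor.

    The predictor is either the built-in surrogate (binding + cleavage
    + TAP weighted combination) or an adapter over recorded
    NetCTLpan-style output.
    """
    return float(predictor.combined_score(peptide, allele))


@dataclass(frozen=True)
class ScoredPeptide:
    """One scored (peptide, allele) record, with HIN flag once labeled."""

    peptide: str
    allele: str
    components: ScoreComponents
    nearest_normal: str
    sources: tuple = ()
    hin: bool | None = None

    @property
    def S(self) -> float:
        return self.components.S


def label_hin(records: list[ScoredPeptide], hin_cutoff: float = 1e-8) -> list[ScoredPeptide]:
    """Flag high-immunogenicity neopeptides: S strictly above the cutoff."""
    return [replace(r, hin=bool(r.S > hin_cutoff)) for r in records]
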