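"""Binding/processing predictor interfaces with deterministic surrogates.

The pipeline composes several per-peptide predictions: an MHC-I binding
percentile rank, a combined antigen-processing score (binding +
proteasomal C-terminal cleavage + TAP transport), a hydrophobicity
score and an epitope-similarity recognition probability. The licensed
external tools usually used for the first two (NetMHCpan-4.0,
NetCTLpan) are wrapped behind small adapters that parse their text
output; the built-in surrogates below are pure, seeded functions so the
whole pipeline runs (and is testable) without them.

The surrogate binding predictor scores a peptide against an
allele-specific position-weight profile (anchor positions 2 and the C
terminus weighted most, as in class-I binding motifs) and converts the
score to a percentile rank against a fixed random-peptide background
generated from the seed. Ranks are therefore reproducible, span
(0, 100], and exercise the strict %rank < 2 retention threshold.
"""

from __future__ import annotations

import hashlib
import re
import subprocess
from typing import Protocol, runtime_checkable

import numpy as np

from .normals import AMINO_ACIDS

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


@runtime_checkable
class BindingPredictor(Protocol):
    """Maps (peptide, allele) pairs to %rank; deterministic and total."""

    name: str
    version: str

    def percent_rank(self, peptide: str, allele: str) -> float: ...

    def percent_ranks(
        self, peptides: list[str], alleles: list[str]
    ) -> dict[tuple[str, str], float]: ...


def _stable_hash(*parts: str) -> int:
    h = hashlib.blake2b("|".join(parts).encode(), digest_size=4)
    return int.from_bytes(h.digest(), "big") % (2**31)


class SurrogateBindingPredictor:
    """Seeded position-weight surrogate for MHC-I %rank prediction."""

    name = "surrogate-binding"
    version = "1"

    ANCHOR_WEIGHT = 3.0
    OTHER_WEIGHT = 0.3

    def __init__(self, seed: int = 0, background_size: int = 999):
        self.seed = int(seed)
        self.background_size = int(background_size)
        self._profiles: dict[str, np.ndarray] = {}
        self._backgrounds: dict[tuple[str, int], np.ndarray] = {}

    def _profile(self, allele: str) -> np.ndarray:
        prof = self._profiles.get(allele)
        if prof is None:
            rng = np.random.default_rng([self.seed, _stable_hash("profile", allele)])
            prof = rng.normal(size=(2, 20))  # row 0: anchor prefs, row 1: generic
            self._profiles[allele] = prof
        return prof

    def _score(self, peptide: str, allele: str) -> float:
        prof = self._profile(allele)
        k = len(peptide)
        total = 0.0
        for pos, aa in enumerate(peptide):
            idx = _AA_INDEX.get(aa)
            if idx is None:
                raise ValueError(f"non-canonical residue {aa!r} in {peptide}")
            if pos == 1 or pos == k - 1:  # class-I anchor positions
                total += self.ANCHOR_WEIGHT * prof[0, idx]
            else:
                total += self.OTHER_WEIGHT * prof[1, idx]
        return total

    def _background(self, allele: str, k: int) -> np.ndarray:
        key = (allele, k)
        bg = self._backgrounds.get(key)
        if bg is None:
            rng = np.random.default_rng(
                [self.seed, _stable_hash("background", allele), k]
            )
            peps = rng.integers(0, 20, size=(self.background_size, k))
            prof = self._profile(allele)
            w = np.full(k, self.OTHER_WEIGHT)
            w[1] = w[k - 1] = self.ANCHOR_WEIGHT
            rows = np.where(
                (np.arange(k) == 1) | (np.arange(k) == k - 1), 0, 1
            )
            scores = (prof[rows[None, :], peps] * w[None, :]).sum(axis=1)
            bg = np.sort(scores)
            self._backgrounds[key] = bg
        return bg

    def percent_rank(self, peptide: str, allele: str) -> float:
        """Percentile of background peptides scoring >= this peptide.

        Lower is a stronger binder; values lie in (0, 100].
        """
        score = self._score(peptide, allele)
        bg = self._background(allele, len(peptide))
        n_better = len(bg) - np.searchsorted(bg, score, side="right")
        return 100.0 * (int(n_better) + 1) / (len(bg) + 1)

    def percent_ranks(self, peptides, alleles):
        return {
            (p, a): self.percent_rank(p, a) for p in peptides for a in alleles
        }


# Residue propensities for the processing surrogate, scaled to [0, 1].
# Proteasomal C-terminal cleavage favors bulky hydrophobic and basic
# residues at P1; TAP transport favors hydrophobic/basic C termini and
# disfavors acidic ones (also weakly sensitive to N-terminal residues).
CLEAVAGE_PROPENSITY = {
    "A": 0.50, "C": 0.40, "D": 0.10, "E": 0.10, "F": 0.95, "G": 0.30,
    "H": 0.45, "I": 0.80, "K": 0.70, "L": 1.00, "M": 0.75, "N": 0.35,
    "P": 0.05, "Q": 0.40, "R": 0.75, "S": 0.35, "T": 0.40, "V": 0.80,
    "W": 0.90, "Y": 0.90,
}
TAP_PROPENSITY = {
    "A": 0.55, "C": 0.50, "D": 0.05, "E": 0.05, "F": 0.95, "G": 0.25,
    "H": 0.50, "I": 0.85, "K": 0.60, "L": 0.95, "M": 0.80, "N": 0.40,
    "P": 0.10, "Q": 0.45, "R": 0.90, "S": 0.40, "T": 0.45, "V": 0.85,
    "W": 0.85, "Y": 0.95,
}


class SurrogateProcessingPredictor:
    """Combined processing score: binding + cleavage + TAP, in [0, 1].

    ``C = (w_b * b + w_c * cleavage + w_t * tap) / (w_b + w_c + w_t)``
    where ``b = 1 - min(Rm, 10)/10`` maps the binding %rank into [0, 1]
    and the default weights follow the conventional emphasis of
    combined processing predictors (binding dominates, cleavage next,
    TAP least).
    """

    name = "surrogate-processing"
    version = "1"

    def __init__(
        self,
        binding: BindingPredictor,
        w_binding: float = 1.0,
        w_cleavage: float = 0.225,
        w_tap: float = 0.025,
    ):
        self.binding = binding
        self.weights = (w_binding, w_cleavage, w_tap)

    @staticmethod
    def cleavage_score(peptide: str) -> float:
        tail = peptide[-3:]
        return 0.8 * CLEAVAGE_PROPENSITY[peptide[-1]] + 0.2 * (
            sum(CLEAVAGE_PROPENSITY[a] for a in tail) / len(tail)
        )

    @staticmethod
    def tap_score(peptide: str) -> float:
        head = peptide[:3]
        return 0.7 * TAP_PROPENSITY[peptide[-1]] + 0.3 * (
            sum(TAP_PROPENSITY[a] for a in head) / len(head)
        )

    def combined_score(self, peptide: str, allele: str) -> float:
        rm = self.binding.percent_rank(peptide, allele)
        b = 1.0 - min(rm, 10.0) / 10.0
        wb, wc, wt = self.weights
        return (wb * b + wc * self.cleavage_score(peptide) + wt * self.tap_score(peptide)) / (
            wb + wc + wt
        )


def _parse_columned_output(text: str, rank_col_pattern: str) -> dict[tuple[str, str], float]:
    """Parse whitespace-columned predictor text output by header name."""
    results: dict[tuple[str, str], float] = {}
    header_idx: dict[str, int] = {}
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "-")):
            continue
        fields = stripped.split()
        if "Peptide" in fields:
            header_idx = {name: i for i, name in enumerate(fields)}
            continue
        if not header_idx or len(fields) < len(header_idx):
            continue
        try:
            pep = fields[header_idx["Peptide"]]
            allele_col = "HLA" if "HLA" in header_idx else "MHC"
            allele = fields[header_idx[allele_col]]
            col = next(
                i for name, i in header_idx.items() if re.fullmatch(rank_col_pattern, name)
            )
            results[(pep, allele)] = float(fields[col])
        except (KeyError, StopIteration, ValueError):
            continue
    return results


def parse_netmhcpan_ranks(text: str) -> dict[tuple[str, str], float]:
    """Extract (peptide, allele) -> %Rank from NetMHCpan-4.0 text output."""
    return _parse_columned_output(text, r"%Rank.*|Rank")


def parse_netctlpan_scores(text: str) -> dict[tuple[str, str], float]:
    """Extract (peptide, allele) -> combined score from NetCTLpan output."""
    return _parse_columned_output(text, r"Comb(_score)?|COMB")


class RecordedOutputPredictor:
    """Adapter over a recorded external-tool output (or a live binary).

    ``table`` maps (peptide, allele) to the tool's reported value.
    Useful both for NetMHCpan-style %ranks and NetCTLpan-style combined
    scores; the pipeline treats it as total over requested pairs and
    raises for missing ones.
    """

    def __init__(self, table: dict[tuple[str, str], float], name: str = "recorded", version: str = "0"):
        self.table = dict(table)
        self.name = name
        self.version = version

    @classmethod
    def from_netmhcpan_output(cls, text: str) -> "RecordedOutputPredictor":
        return cls(parse_netmhcpan_ranks(text), name="netmhcpan-4.0")

    @classmethod
    def from_netctlpan_output(cls, text: str) -> "RecordedOutputPredictor":
        return cls(parse_netctlpan_scores(text), name="netctlpan")

    def percent_rank(self, peptide: str, allele: str) -> float:
        try:
            return self.table[(peptide, allele)]
        except KeyError:
            raise RuntimeError(
                f"external predictor output lacks ({peptide}, {allele})"
            ) from None

    def percent_ranks(self, peptides, alleles):
        return {(p, a): self.percent_rank(p, a) for p in peptides for a in alleles}

    combined_score = percent_rank


def run_external_predictor(cmd: list[str]) -> str:
    """Run an external predictor binary, surfacing stderr on failure."""
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"{cmd[0]} failed (exit {proc.returncode}): {proc.stderr}")
    return proc.stdout
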