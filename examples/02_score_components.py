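"""The immune score, term by term, for one hand-constructed candidate.

Shows how binding rank, self-dissimilarity, processing, hydrophobicity
and epitope similarity combine multiplicatively, and why a candidate
nearly identical to a strongly binding self peptide scores low.
"""

from spliceneo import (
    EpitopeLibrary,
    ScoreComponents,
    hydrophobicity_score_H,
    immune_score,
    logistic,
    recognition_probability_R,
)

peptide = "SIINFEKLM"
library = EpitopeLibrary([("known1", "SIINFEKLV"), ("known2", "GILGFVFTL")])

H = hydrophobicity_score_H(peptide)
R = recognition_probability_R(peptide, library)
print(f"candidate {peptide}")
print(f"  L(Rm=0.5) = {logistic(0.5):.6f}   (strong binder, near-maximal reward)")
print(f"  H         = {H:.6f}   (TCR-contact hydrophobicity, positions 3..8)")
print(f"  R         = {R:.6f}   (similarity to the known-epitope library)")

far = ScoreComponents(Rm=0.5, Rn=20.0, M=5, C=0.8, H=H, R=R)
near_self = ScoreComponents(Rm=0.5, Rn=0.3, M=1, C=0.8, H=H, R=R)
print(f"\n  S (nearest normal dissimilar, M=5, Rn=20): {immune_score(far):.3e}")
print(f"  S (nearest normal near-identical binder, M=1, Rn=0.3): {immune_score(near_self):.3e}")
print(
    "\nThe (1 - L(Rn)/2^M) factor discounts candidates whose closest normal"
    "\npeptide both binds the same allele and differs at few positions:"
    "\nT cells against such peptides are likely deleted by central tolerance."
)
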