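"""Junction-level filtering in isolation: psi and the panel of normals.

Builds a small junction table by hand, computes percent-spliced-in on
the full table, and shows which junctions the three filters remove and
why.
"""

from spliceneo import (
    Junction,
    JunctionKey,
    NormalJunctionDB,
    compute_psi,
    filter_junctions,
)

junctions = [
    Junction("chr1", "+", 1000, 2000, unique_reads=150),  # healthy novel junction
    Junction("chr1", "+", 1000, 3000, unique_reads=15),   # shares the donor at 1000
    Junction("chr1", "+", 5000, 6000, unique_reads=10),   # at the read threshold
    Junction("chr1", "+", 7000, 8000, unique_reads=90),   # known normal junction
]

db = NormalJunctionDB()
db.add(JunctionKey("chr1", "+", 7000, 8000), "annotation")

with_psi = compute_psi(junctions)
print("psi on the full table (denominators use every observed junction):")
for j in with_psi:
    print(f"  {j.intron_start}-{j.intron_end}: reads={j.unique_reads:4d} psi5={j.psi5:.3f} psi3={j.psi3:.3f}")

kept, summary = filter_junctions(with_psi, db, min_unique_reads=10, min_psi=0.1)
print(f"\nretained: {[(j.intron_start, j.intron_end) for j in kept]}")
print(
    f"removed: {summary.removed_low_reads} low-reads, "
    f"{summary.removed_low_psi} low-psi, {summary.removed_normal} normal"
)
print(
    "\nNote the strict thresholds: 10 reads is NOT > 10, and the junction"
    "\nsharing the 1000 donor keeps psi5 = 15/165 = 0.091, below 0.1."
)
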