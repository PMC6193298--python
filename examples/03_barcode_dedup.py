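"""Degenerate-barcode deduplication and the collision model.

Simulates a 10-cycle barcoded PCR library, deduplicates reads by distinct
barcode per mapped position, and compares the recovered molecule counts with
the planted truth; prints the analytic per-position collision probability.
"""

from holoseq.quant import (
    BarcodeModel,
    barcode_collision_probability,
    dedup_barcoded,
    max_distinct_barcoded_reads,
)
from holoseq.synthetic import simulate_barcoded_library

reads, truth = simulate_barcoded_library(
    n_positions=200, templates_per_position=10, cycles=10, reads_sampled=100_000, seed=3
)
counts, _ = dedup_barcoded(reads)
exact = sum(
    counts.get(pos, 0) == m for pos, m in truth.molecules_per_position.items()
)
print(f"{exact}/{len(truth.molecules_per_position)} positions recover the true "
      f"molecule count (10) exactly after deduplication")

p = barcode_collision_probability(10, 65_536)
print(f"per-position collision probability for 10 molecules, 65,536 barcodes: {p:.2e}")
print(f"amplification ceiling (10 templates, 10 cycles): "
      f"{max_distinct_barcoded_reads(BarcodeModel())} distinct barcoded reads")
print("positions that miss the exact count drew a barcode twice; the collision "
      "probability above says that should affect well under 1% of positions.")
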