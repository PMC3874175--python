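"""Assign ChIP peak midpoints to gene fragments and summarize binding.

Each peak is reduced to its midpoint and assigned to every fragment
containing it; per fragment the number of distinct TFs is counted.  The
generator plants peaks in first introns at 1.43x the rate of other
introns, and the per-region summary recovers that ratio.
"""

from intronreg.chip import (
    assign_peaks,
    promoter_intron_overlap,
    region_binding_summary,
)
from intronreg.genome import define_promoter, extract_fragments
from intronreg.simulate import SimConfig, simulate_chip_peaks, simulate_genome_pair

pair = simulate_genome_pair(SimConfig(seed=4, n_genes=400))
peaks, _ = simulate_chip_peaks(pair)
fragments = []
for pg in pair.species_a.placed:
    fragments.extend(extract_fragments(pg.model, pair.species_a.genome))
    fragments.append(define_promoter(pg.model, pair.species_a.genes,
                                     pair.species_a.genome))
assignments = assign_peaks(peaks, fragments)
summary = region_binding_summary(assignments, fragments)
for cls, stats in sorted(summary.per_class.items()):
    print(f"{cls:13s} mean TFs = {stats['mean']:.3f} +- {stats['sem']:.3f} "
          f"(n={stats['n']})")
print(f"first/other intron binding ratio: "
      f"{summary.first_over_other_ratio:.3f} (planted 1.43)")

ois = []
for pg in pair.species_a.placed:
    gid = pg.model.gene_id
    oi = promoter_intron_overlap(
        assignments.get((gid, "promoter", 1), set()),
        assignments.get((gid, "intron", 1), set()),
    )
    if oi is not None:
        ois.append(oi)
print(f"mean overlap/intron (O/I) fraction over {len(ois)} genes: "
      f"{sum(ois) / len(ois):.3f}")
print("\nO/I is the fraction of a gene's first-intron TFs that also bind "
      "its promoter; low values mean the two regions bind different TFs.")
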