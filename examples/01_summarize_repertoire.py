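"""Compute summary distributions for one synthetic AIRR repertoire.

Generates a 500-sequence IGH-like repertoire with known parameters, then
prints a handful of summary statistics: per-sequence distributions are
reported by their mean, categorical summaries by their top categories.
"""

from repsum import SUMMARY_REGISTRY, default_spec, generate_repertoire
from repsum.summaries import (
    cdr3_length_distribution,
    gc_content_distribution,
    gene_usage_counts,
    germline_distance_distribution,
    hill_diversity,
    in_frame_percentage,
    cluster_size_distribution,
    CategoricalCounts,
)

table = generate_repertoire(default_spec(seed=42, n_sequences=500))
print(f"{table!r}\n")

gc = gc_content_distribution(table)
print(f"GC content          mean {gc.values.mean():.3f} over {len(gc)} sequences")
cdr3 = cdr3_length_distribution(table, "nt")
print(f"CDR3 length (nt)    mean {cdr3.values.mean():.1f}, range "
      f"{int(cdr3.values.min())}-{int(cdr3.values.max())}")
mut = germline_distance_distribution(table)
print(f"Germline distance   mean {mut.values.mean():.1f} substitutions/sequence")
print(f"In-frame junctions  {in_frame_percentage(table):.1f}%")

usage = gene_usage_counts(table, ("V",))
top = sorted(usage.frequencies().items(), key=lambda kv: -kv[1])[:3]
print("Top V genes        ", ", ".join(f"{g} {f:.2f}" for g, f in top))

clusters = cluster_size_distribution(table)
cc = CategoricalCounts(
    {i: int(v) for i, v in enumerate(clusters.values)}, "clusters"
)
print(f"Clonal diversity    richness {hill_diversity(cc, 0):.0f}, "
      f"exp-Shannon {hill_diversity(cc, 1):.1f}, inv-Simpson {hill_diversity(cc, 2):.1f}")
print(f"\n({len(SUMMARY_REGISTRY)} summaries available in SUMMARY_REGISTRY)")
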