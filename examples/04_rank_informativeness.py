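"""Rank sequence-level summaries by how well they separate datasets.

Three synthetic repertoires differ only in mutation rate, so the
mutation-linked covariates (germline distance, hotspot counts) should
branch off the multinomial lasso path first and receive the best ranks,
while rearrangement covariates shared across datasets rank behind them.
"""

from repsum import build_design_matrix, default_spec, generate_repertoire, rank_summaries

tables = [
    generate_repertoire(default_spec(seed=10 + i, n_sequences=300, mutation_rate=r))
    for i, r in enumerate([0.005, 0.03, 0.09])
]
design = build_design_matrix(tables)
result = rank_summaries(design, seed=0)

print(f"{'rank':>4}  {'summary':<28} median per-class rank")
for name, rank in sorted(result.ranks.items(), key=lambda kv: kv[1]):
    print(f"{rank:>4}  {name:<28} {result.median_ranks[name]:.1f}")
print("\nRank 1 = branches off the regularization path earliest = most "
      "discriminative between the three datasets.")
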