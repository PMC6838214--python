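"""Compare two repertoires summary-by-summary.

The second repertoire is generated with a higher somatic mutation rate, so
mutation-linked summaries (germline distance, hotspot counts) should show
larger divergences than rearrangement summaries (gene usage, deletion
lengths), which share the same generative parameters.  Scalar distributions
are compared by Jensen-Shannon divergence (<= ln 2 ~ 0.693), categorical
counts by normalized l1 (<= 2).
"""

from repsum import compare_repertoires, default_spec, generate_repertoire, results_to_frame

low = generate_repertoire(default_spec(seed=1, n_sequences=400, mutation_rate=0.01))
high = generate_repertoire(default_spec(seed=2, n_sequences=400, mutation_rate=0.08))

results = results_to_frame(compare_repertoires(low, high))
computed = results[~results.skipped].sort_values("value", ascending=False)
print(computed[["summary", "method", "value"]].to_string(index=False))
print(
    "\nLargest divergences should sit on mutation-linked summaries "
    "(germline_distance, positional_mutation_distances); gene usage stays low."
)
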