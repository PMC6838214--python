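# Methods

## Data model and capability levels

The unit of analysis is a `RepertoireTable`: one annotated rearrangement per
row with AIRR Rearrangement schema field names. Summaries are grouped by the
post-processing they assume, encoded as an ordered `CapabilityLevel`:

1. `alignment_only` — needs `sequence_alignment` (and, for mutation
   summaries, `germline_alignment` of equal length);
2. `annotated` — gene calls, junction fields, deletion/insertion statistics;
3. `clustered` — `clone_id` clonal family labels;
4. `phylogenetic` — a rooted tree per clonal family (Newick, or a
   two-column `clone_id → newick` TSV).

Each level implies the ones below it. `compare_repertoires` computes every
registry summary at or below the two tables' shared level and reports the
rest as skipped rather than failing. The package performs no annotation,
clustering, or tree inference itself; it assumes those metadata are present.

Normalization conventions, applied on read/construction:

- sequences are uppercased; empty strings become missing values;
- gene calls that are comma-separated ambiguity lists keep only the first
  entry, and the `*NN` allele suffix is stripped before usage counting
  (disable with `collapse_allele=False`); this makes usage distributions
  comparable across annotation tools;
- IMGT gap characters (`.`, `-`) are stripped pairwise-consistently from
  `sequence_alignment`/`germline_alignment` (a position gapped in either is
  dropped from both) before any distance or mutation computation, preserving
  positional correspondence while keeping distances over nucleotides only.
  Whether upstream tools store gapped or degapped alignments varies, so the
  paired-degap convention is a deliberate, configurable-at-the-helper-level
  choice;
- summaries labelled "CDR3" operate on the `junction`/`junction_aa` fields
  as provided (the junction includes the conserved anchor residues);
  no CDR3 re-extraction is attempted;
- no implicit productivity filtering; the CLI offers `--productive-only`.

## Summary statistics

Most summaries yield one scalar per record (a `SummaryDistribution`);
gene usage and k-mer summaries yield category counts; insertion transition
summaries yield a 4×4 row-stochastic matrix with its raw transition counts.
Choices that were genuinely open:

- **String metric.** Levenshtein edit distance (via edlib global alignment)
  is the default for pairwise, nearest-neighbor, and germline distances;
  Hamming is available for equal-length inputs.
- **Hot/coldspot motifs.** Defaults are the canonical AID targeting motifs —
  hotspots {WRC, GYW, WA, TW}, coldspots {SYC, GRS} — counted with overlap
  on the given strand only; both the motif sets and the counting are
  configurable arguments. Ambiguous bases in the sequence match nothing, and
  are likewise excluded from the GC denominator and from mutation calling.
- **Positional mutation distances** are gaps between *consecutive* mutated
  positions (not all pairs); records with fewer than two mutations
  contribute nothing.
- **In-frame percentage** uses the tool-independent criterion: junction
  length divisible by 3.
- **Physicochemical scales.** GRAVY uses Kyte–Doolittle hydropathy;
  polarity Grantham (1974); bulkiness Zimmerman (1968); net charge is
  Henderson–Hasselbalch at pH 7.4 over side chains with the EMBOSS pKa set
  (termini excluded); aromaticity is the F/W/Y fraction; the aliphatic index
  is Ikai's mole-percent formula with coefficients 2.9 and 3.9; Atchley
  (five) and Kidera (ten) factors are aggregated as the arithmetic mean per
  factor, one scalar per sequence per factor. Two scales have no single
  canonical literature table: here **basicity** is per-residue gas-phase
  basicity (kJ/mol) and **acidity** is the D/E (carboxylate side chain)
  fraction. These are deliberate choices and may differ numerically from
  other packages' constants; all tables live in `aa_properties.py`.
  Sequences containing non-standard letters (X, stop, gaps) are skipped.
- **Hill numbers** over clonal abundances: richness at q = 0,
  exp-Shannon at q = 1 (the continuous limit), `(Σ pᵢ^q)^(1/(1−q))`
  otherwise.
- **Tree imbalance.** Sackin = sum of leaf depths in edge counts;
  cophenetic = sum over unordered leaf pairs of their MRCA's depth
  (computed in one postorder pass via per-node leaf-pair counts);
  Colless-like follows the Mir–Rosselló–Rotger construction with
  f(n) = ln(n + e) and mean-deviation-from-the-mean dissimilarity — both
  configurable. Trees with fewer than two leaves are skipped.

## Divergences

Scalar distributions are compared by Jensen–Shannon divergence in natural
log (bound ln 2). Samples are discretized on shared equal-width bins,
`B = max(min(m, n), 2)` where m and n are the two samples' counts of
distinct values, spanning the pooled range (left-closed/right-open bins,
last bin closed — numpy histogram semantics). Bins where exactly one
density is zero are discarded from both and the retained masses
renormalized; if *every* bin is discarded the samples are reported as
maximally divergent (ln 2) with a warning, the natural limit for totally
disjoint distributions. Note the bin rule means two large *continuous*
samples from one distribution do not drive JSD to zero (support size = n);
the summaries this package compares are integer- or few-valued, where
convergence holds and is tested.

Categorical counts use the ℓ1 divergence over the union of categories
(missing categories count 0), optionally on relative frequencies —
`compare_repertoires` normalizes by default since dataset sizes commonly
differ. Transition matrices are compared by ℓ1 over their 16 row-normalized
cells. Scalar summaries (in-frame percentage) use the absolute difference.

## Subsampled approximation

For summaries whose exact cost is quadratic, the rolling approximation
draws record subsamples of batch size m (default 30, without replacement;
with replacement only if m exceeds the table), applies the summary to each
batch, concatenates values, and stops when the JSD between successive
concatenations drops below ε (default 10⁻³); at least two batches are
always drawn, a safety cap (default 10⁴ iterations) bounds the loop, and a
fixed seed makes the output reproducible. Appending batches is the
distributional analogue of a rolling average.

Nearest-neighbor distances violate the subsampling premise: restricting the
reference set can only keep or increase each minimum, so a subsample-only
estimate is biased upward. The dedicated variant therefore computes each
sampled sequence's exact nearest neighbor against the full repertoire —
every emitted value is a member of the true nearest-neighbor multiset — and
uses a tighter default tolerance of 10⁻⁴. Distances are memoized per call
so repeated sampling of an index costs one scan.

Tables no larger than twice the batch size are summarized exactly, with the
mode recorded in the result metadata. Approximation is applied by default
(in the CLI) only to the pairwise-distance, nearest-neighbor, and CDR3
pairwise-distance summaries; everything else is exact.

## Informativeness ranking

Per-sequence summary values are pooled over datasets into a design matrix
(rows with any missing value dropped; zero-variance columns dropped with a
warning; columns standardized), with dataset identity as the response.
Kidera and Atchley factor components are excluded by default — they are
orthogonal-by-construction descriptor sets — and re-includable by flag.
Only sequence-level summaries are valid covariates; a pairwise-distance
distribution has no per-row representation and is rejected explicitly.

The ℓ1-penalized multinomial path is fitted by warm-started SAGA
(scikit-learn) on a 100-point log-spaced grid from λ_max (the KKT threshold
`max_{d,s} |X_sᵀ(1{y=d} − π_d)|/n`, above which all coefficients are zero)
down to 10⁻³ λ_max. For each class d and summary s, the branch-off point
t_{d,s} is the largest grid λ at which the coefficient is nonzero
(|β| > 10⁻⁸, absorbing solver noise) *and stays nonzero* at every smaller
grid λ, which enforces monotonicity of the activation order. Within each
class, summaries are ranked by descending t (earlier branch-off = more
informative); a coefficient that never activates ranks strictly last — the
natural reading of "branches off latest". Final scores are the ranks of the
per-summary medians across classes. All ties are broken by seeded
randomization to avoid alphabetization artifacts, so duplicated columns
receive each rank with roughly equal frequency across seeds.

## Simulator scoring and embedding

For k observed/simulated pairs, LRAD-data(s) is the log of the mean
cross-pair divergence among observed repertoires over the mean within-pair
(observed vs own simulation) divergence; LRAD-sim replaces the numerator
with simulated–simulated pairs and shares the identical denominator.
Because the divergences are symmetric, the ordered double sum with its
2/(k(k−1)) weight equals the unordered-pair mean, which is how it is
computed. Degenerate cases are reported explicitly: zero denominator with
positive numerator → +∞ (perfectly replicated summary), zero numerator with
positive denominator → −∞, both zero → NaN flagged undefined.

Divergence matrices over repertoire collections are computed once per
unordered pair and mirrored (exactly symmetric, zero diagonal); all registry
summaries are deterministic, so the matrices are reproducible without
seeding. Embedding uses classical (Torgerson) MDS — double-centering of the
squared dissimilarities, eigendecomposition, top eigenvectors scaled by
root-eigenvalues, eigenvalues below 10⁻¹² of the largest treated as zero —
which is deterministic and reproduces any Euclidean-realizable matrix
exactly at sufficient dimension.

## Synthetic repertoire generator

The generator emulates V(D)J recombination with fully specified parameters:

- gene pools: 10 V (~300 nt), 5 D (20 nt), 4 J (50 nt) synthetic random
  germlines with usage probabilities proportional to 1/rank (mildly skewed,
  as in real repertoires); real germlines can be supplied via `GenePool`;
- deletions: capped geometric (p = 0.3, cap 10 nt) at the V 3′, D 5′/3′,
  and J 5′ ends;
- np1/np2 insertions: capped-geometric lengths (p = 0.25, cap 15) with
  content from a first-order Markov chain (specified initial distribution
  and 4×4 transition matrix);
- junction: fixed anchor offsets — the last 6 nt of the trimmed V through
  the first 9 nt of the trimmed J — so junction fields are exactly
  consistent with the alignment coordinates; `junction_aa` is the
  translation when the junction is in frame;
- clonal structure: geometric clone sizes (p = 0.5), one naive ancestor per
  clone, members receiving i.i.d. per-site substitutions at rate 0.02
  (star genealogy; tree-structured lineages are out of scope);
- germline realism: the junction-proximal windows of the pools (V 3′ 18 nt,
  all of D, J 5′ 12 nt) are drawn from {A, C, G}. No stop codon can form
  without a T, so junctions translate cleanly in any frame — mimicking the
  stop-codon depletion of productive repertoires — *without conditioning
  any sampled quantity*, which keeps deletion, insertion, and usage
  distributions exactly at their nominal parameters for recovery tests.
  About a third of junctions are in frame (no frame selection is applied).

What the generator does **not** emulate: SHM hotspot targeting (mutations
are uniform), selection, indels within SHM, allelic variation beyond a
`*01` suffix, sequencing error, or realistic germline sequence content.
Tests passing on generated data therefore demonstrate correctness of the
statistics and algorithms under a known model, not biological realism of
any particular dataset.

`perturb_repertoire` applies summary-targeted modifications for validation
scenarios: `junction_length` (insert N random nt mid-junction, junction_aa
re-derived; alignments and gene calls untouched), `gene_shuffle`
(independent column permutations over a fraction of rows — marginal usage
exactly preserved, joint usage scrambled), `mutation_rate` (extra i.i.d.
substitutions on `sequence_alignment`). Magnitude 0 is always the identity.

## Problem sizes and numerical choices

The test suite and acceptance script use: 50-record fixtures (with
short-germline pools so brute-force DP oracles stay cheap) for bit-exact
oracle equivalence; 200 sequences for nearest-neighbor unbiasedness;
1,000 sequences for rolling-approximation convergence; 10⁴ records
(degenerate clone sizes, so draws are independent) for parameter recovery,
giving ~4×10⁴ pooled insertion transitions; 3 × 200-record paired sets for
LRAD signs; and 120×5 designs over 20–50 seeds for ranking recovery.
Tolerances in the recovery tests come from sampling theory at those sizes
(e.g., expected ℓ1 error of a 10-category usage estimate at n = 10⁴ is
≈ 0.02, tested against 0.03). Floating-point equality is asserted at 10⁻¹²
where exact arithmetic is expected; JSD values are clipped to [0, ln 2] to
absorb float round-off.

## Known limitations

- The per-gene-per-position substitution rate is indexed by the (possibly
  gapped) alignment coordinate of each record's own alignment; records of
  unequal alignment length are pooled up to the longest.
- The lasso path depends on SAGA convergence at each grid point; the active
  set settles well before full coefficient convergence, but extremely
  correlated designs may still show solver-order effects that the seeded
  tie-breaking masks only partially.
- LRAD with approximated (stochastic) summaries would require a fixed seed
  per matrix; the built-in registry computes all summaries exactly, so this
  arises only for user-supplied stochastic summaries.
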