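# Methods

## Problem and model

A specificity-determining position (SDP) is an alignment column that is
conserved *within* groups of proteins sharing a binding specificity and
differs *between* such groups.  Given a multiple sequence alignment
(MSA) of N sequences and a (possibly partial) partition of the
sequences into k specificity groups, column p is scored by the mutual
information between its amino-acid distribution and the grouping,

    MI_p = (1/N) Σ_α Σ_j i_αj · ln( i_αj · N / (i_α · n_j) ),

where i_αj counts amino acid α of group j at column p, i_α = Σ_j i_αj,
and n_j is the group size.  Gapped cells and sequences in the *virtual
group* (no confident specificity) are excluded, so N here is the
per-column count of assigned, non-gap residues.  All logarithms in the
package are natural; any fixed base only rescales every score by the
same constant.

## The null model and its moments

Whether an observed MI is large can only be judged against the null in
which group labels carry no information.  Two analytic ingredients
replace shuffling simulations:

* **Exact null mean.**  Under random assignment of labels (equivalently
  a random permutation of the sequences within the column), the count
  of an amino acid present i_α times inside a group of size n_j is
  hypergeometric, and E[i·ln(i·N/(i_α·n_j))] has a short closed form.
  Summing over amino acids and groups gives the exact expected MI of
  the column under the shuffle null — no approximation.  Values are
  memoised per (i_α, n_j, N) triple, so scoring an alignment touches a
  few hundred distinct triples at most.

* **Approximate null variance.**  The variance uses the classical
  independent-multinomial approximation: amino acids are assumed to be
  distributed independently over k equiprobable groups, which turns the
  per-amino-acid variance into a binomial/trinomial expression that is
  pre-tabulated over (count ≤ c_max, k ≤ k_max) by `build_moment_table`
  (cache on disk, deterministic rebuild; lookups outside the table are
  computed on demand).  Cross-amino-acid covariances vanish under this
  approximation, so a column's null variance is the sum of per-amino-
  acid variances divided by N².

The Z-score of a column is (MI − exact mean) / sqrt(approximate
variance).  Using the exact mean matters: at the small training sets of
the stochastic pipeline (15 assigned sequences in groups of 3) the
approximation's mean bias reaches a full standard deviation, which
uniformly shifts all Z-scores and breaks any selection rule downstream.
The variance approximation only sets the scale; a modest global
mis-scale does not reorder columns.  Columns with fewer than two
residue kinds, fewer than two non-empty groups, or (near-)zero null
variance are flagged degenerate and get Z = 0; columns with more than
50 % gaps (configurable) are excluded from SDP candidacy.

For equal group sizes and small counts (i_α ≤ 12, k ≤ 4) the tabulated
mean and variance agree with exhaustive multinomial enumeration to
1e-9; this is enforced by the test suite and pins down the otherwise
ambiguous inner summation bounds of the trinomial cross term.

## Selecting the SDP set

Eligible columns are ranked by Z (ties broken by lower column index).
For a prefix of size m whose weakest member has upper-tail normal
probability p_m, the chance that m or more of the C eligible columns
reach that level by luck is the binomial tail P(Bin(C, p_m) ≥ m),
evaluated in log space so that Z ≈ 40 still yields strictly ordered
probabilities.  Two refinements make this statistic usable:

* Prefixes are limited to columns with Z > 0 — a column at or below its
  null mean can never be part of the least probable set.  Without this
  the statistic degenerates near m = C ("all columns exceed their own
  minimum").
* The reported prefix is the smallest *local minimum* of the curve
  reaching at least γ = 0.5 of the global minimum log-probability.  The
  global minimum alone keeps absorbing every individually significant
  column (each adds a small negative increment), e.g. on a synthetic
  family it reports 68 columns where the ten implanted SDPs form a
  −2051-nat dip followed by a sharp cliff.  The γ-rule returns the
  coherent extreme block when one exists and the broad set otherwise.

A final prediction must clear a set-probability ceiling (α = 0.05);
during the stochastic exploration (below) the refinement instead always
works with the current least-probable set, because early training
groupings are deliberately weak and a hard gate would stall the
bootstrap.

## Profiles and classification

Each real group is summarised by a positional weight matrix over the
selected SDP columns only: weight(α) = ln[(count + c·b_α)/(n + c)] −
ln b_α with background-proportional pseudocounts of mass c = 1 and
background b_α estimated from the whole alignment.  A sequence is
assigned to the best-scoring group iff the score is positive and beats
the runner-up by θ = ln 2 per scored (non-gap) column; otherwise it
joins the virtual group.  After refinement converges, one
*consolidation* sweep re-tests every membership at 3 nats per column
(≈ twentyfold per-column preference): groups held together by many
weakly informative columns (in practice, phylogenetic rather than
specificity structure; measured margins 0.9–2.6 per column) dissolve,
while groups backed by genuinely discriminating columns (margins
≥ 5 per column on the synthetic benchmark) are untouched.

## Iterative refinement and the stochastic wrapper

`refine_groups` alternates SDP selection, profile construction and a
synchronous reassignment of *every* sequence until the grouping stops
changing, a previous grouping recurs (cycle; the most significant
visited state is returned), or an iteration cap (default 100) is hit.
Groups emptied by reassignment are dropped, so k never increases.

Without prior groups, `run_sdpclust` repeats (default R = 10000 times;
benchmarks here use R = 1000): draw random disjoint training groups
(default max(2, round(N/10)) groups of 3), refine, and count, for every
pair of sequences, how often they land in the same final group.  Each
run actually refines several independent random seeds (default 6
restarts) and keeps the state whose SDP set is most significant *per
column* (lowest mean log set-probability per selected position).  This
steering matters on families whose specificity contradicts the
phylogeny: a random training set is roughly twice as likely to drift
into a phylogenetic (subfamily) grouping as into the specificity
grouping, but the specificity states are far more significant per
column, so preferring them across restarts (plus the consolidation
sweep) keeps the co-assignment signal dominated by specificity.

Pair frequencies become distances d = −ln(count/R), with zero counts
capped at −ln(1/(R+1)) to stay finite.  A UPGMA tree (average linkage,
heights = half the merge distance, ties broken by the lexicographically
smallest pair of minimal leaf indices) is cut by a dynamic programme
over the per-clade quality Q(X) = min external distance − diameter:
Q_max(X) = max(Q(X), min(Q_max(left), Q_max(right))), backtracking
emits the shallowest node with Q = Q_max.  The resulting partition
maximises the ascending-sorted quality vector lexicographically over
all tree-consistent partitions (verified against exhaustive enumeration
on trees of ≤ 8 leaves; vectors of different lengths compare as if
padded with +∞).  Q of a singleton uses diameter 0; Q of the full leaf
set is −∞ so the trivial one-cluster answer is never preferred over its
children.  The clusters then serve as specificity groups for one final,
α-gated SDP pass.

Determinism: one master seed; per-run child seeds derived via
`numpy.random.SeedSequence.spawn`, so runs are independent and the
whole pipeline is bit-reproducible for a given seed.

## Synthetic benchmark generator

`generate_family` emulates a naive random evolutionary model: a
190-residue root drawn i.i.d. from SwissProt amino-acid composition
(vendored table), five subfamily seeds at 30 random point mutations
from the root, ten leaves per seed at 50 further mutations (each
mutation picks a uniform position and one of the 19 other residues, so
step counts bound Hamming distances).  Specificity is implanted by
appending ten columns in which each of the five classes carries its own
fixed residue, residues distinct within a column — total alignment
length 200, gold SDP set and gold grouping known by construction.  In
concordant mode classes coincide with subfamilies; in random mode a
balanced uniform permutation scatters them.  The generator produces no
gaps, no indels, no realistic substitution-matrix structure and no rate
heterogeneity, and its implanted SDPs are perfectly conserved — pipeline
recovery on these families demonstrates the machinery end to end, not
performance on real alignments, where SDP conservation is partial and
gaps are common.

## Evaluation metrics

Sensitivity TP/(TP+FN) and false-positive rate FP/(FP+TN) over
alignment columns with the implanted set (or a structure-derived set)
as gold; the normalised mutual-information distance between partitions
D = 1 − MI/H(joint) (0 for identical up to relabelling, 1 for
independent; a metric — symmetry and the triangle inequality are
property-tested); a one-sided Mann–Whitney test that predicted SDPs lie
closer to the ligand than residues in general (exact enumeration for
tie-free combined samples ≤ 20, otherwise normal approximation with
continuity and tie correction); and the structure rules: residues
strictly closer than 10 Å to the ligand count as true SDPs, atoms
strictly closer than 5 Å as contacts.

## Problem sizes and defaults used in the shipped benchmarks

The test suite and the acceptance script run the pipeline at R = 1000
resampling runs (≈ 1–2 minutes per family on one core) on the default
family geometry (50 sequences × 200 columns); this recovers the
implanted SDPs and the gold grouping exactly in both specificity
patterns.  The production default remains R = 10000.  Moment tables are
built per alignment (k_max = number of training groups, c_max = N);
the full 200 × 500 table is only needed for very large alignments and
is a one-off costing minutes.

## Known limitations

* The null variance keeps the equal-group-size independence
  approximation; Z-scores are centred but not exactly unit-scale, and
  the selection thresholds (α, γ) absorb this.
* Training-group size (3) and count (≈ N/10), restart count (6) and the
  consolidation margin (3 nats/column) are heuristics chosen on the
  synthetic benchmark geometry; highly gapped or very small real
  alignments may need adjustment via the exposed parameters.
* Refinement cannot create groups, so a single run covers only the
  specificities nucleated by its random training set; coverage comes
  from aggregation over runs.
* The guided mode reassigns training sequences too; a training label is
  a hint, not a constraint.
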