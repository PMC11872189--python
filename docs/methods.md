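# Methods

This note records the models, conventions and numerical choices behind
ethonet, and what the synthetic-data tests do and do not establish.

## Data model

Coded video is a long-format event table: community, subject, video id,
mound id, mound type (aerial | underground), onset time on a 0.25 s grid,
element label, optional body position and hand. Elements are mutually
exclusive in time — an onset ends the previous element — so onsets fully
describe a bout, and onsets within a (subject, video) group must be
strictly increasing. Unknown labels map to the catch-all `Other` code with
a warning rather than failing, mirroring coding practice.

Widening produces one line per `bin_s`-second time frame (default 5 s in
`to_presence_matrix`; `per_event` gives one line per coded action), keyed
by unit = subject and conversation = (subject, video). Imported wide
matrices may carry not-applicable cells: `apply_na_policy` drops element
columns that are NA in more than 90% of lines (the drop list is reported on
the result) and recodes every remaining NA as absence, because the network
accumulator cannot carry missing values. The operation is idempotent.
Aerial and underground data are always handled as separate matrices and
separate models, since the two contexts draw on different element
inventories.

Interrater agreement is Cohen's kappa computed from the coders' confusion
matrix, reported together with observed and expected agreement; the package
reports the statistic and imposes no acceptance threshold. Kappa is
undefined (raised, not NaN) when both coders use a single identical label.

## Bundled ethograms

Two inventories ship as editable fixtures: 16 elements for fishing at
aerial mounds and 21 for underground nests. Each element carries a
functional role — probe, extract, tool_making, posture, ingestion, other —
assigned from the inventories' published grouping (general / tool making /
tool use / non-tool use) refined by element semantics: insertion elements
are probes, withdrawal/harvest-assist elements are extracts, stick
selection and modification are tool making, body orientations postures,
mouth-directed elements ingestion. The role map is a fixture, not a claim
about nature; users with their own coding schemes supply an ethogram CSV
(`label,role,description`).

## Technique mining

"Sequential combinations" are read as contiguous n-grams: behavioral
elements strung together in direct succession. Candidates of length 2–7
are functional techniques when some probe-role element precedes some
extract-role element within the window. Occurrence counting is overlapping
and nested by default — an occurrence of a long technique also increments
its catalogued sub-runs — because occurrence segmentation is genuinely
ambiguous in continuous fishing bouts and the nested convention makes short
prototype techniques ("basic fish": probe then extract) visible alongside
their elaborations. `maximal_only=True` counts only occurrences not
contained in a longer catalogued occurrence at the same position.
Sequences never span videos: the motion-triggered clip is the observation
unit, and a technique interrupted by a clip boundary is simply truncated.
Catalog ids are assigned in (length, lexicographic) order, so the catalog
is invariant under video order.

## Repertoire statistics

Rarefaction resamples at the video level: each bootstrap replicate (1000 by
default) permutes a subject's videos uniformly and accumulates distinct
elements. The terminal value is therefore always the observed inventory;
what the curve adds is the expected discovery trajectory and its spread.
Plateau detection is made explicit rather than visual: a curve is
saturated when the mean slope over the final 20% of observations falls
below 0.05 new elements per observation (both parameters exposed).
Community-level curves pool all of a community's videos.

Fisher's exact test contrasts, for one technique and two subjects, uses of
that technique against uses of all other techniques, so table margins equal
the subjects' usage totals; two-sided p follows the probability-ordering
convention (scipy's implementation, verified in the tests against
exhaustive hypergeometric enumeration for all margins ≤ 12). Across the
full technique × pair family, raw and Benjamini–Hochberg adjusted p-values
are reported side by side; subjects with zero usage are excluded with a
warning rather than producing degenerate tables.

Clustering defaults to the heatmap convention: the usage matrix is divided
by its single largest cell (maximum exactly 1), subjects agglomerated with
Euclidean distance and average linkage. Distance, linkage and
normalization are arguments, and the kinship-recovery analyses in the test
suite use cosine distance with complete linkage: observation volume (how
often a chimp was filmed and how productively it fished) is not the
heritable quantity, usage *profile* is, and with count vectors the volume
and its sampling noise dominate Euclidean distances. This was measured
directly: with identical-propensity twins the Euclidean kin/non-kin
distance ratio stays near 0.6 (noise floor), while the angle between count
vectors separates cleanly.

## Sørensen similarity

Repertoires are element sets (technique-level similarity exists as an
option but element presence is the cross-community currency). S is
symmetric, 1 for identical nonempty sets, 0 for disjoint sets, undefined
(raised) when both sets are empty, and only computed within a mound-type
stratum. The per-individual community profile computes, for each subject
of one community, the mean S against every subject of the reference
community; `pool_reference=True` instead compares against the reference
community's union repertoire. Box summaries report mean, median,
quartiles, and 2.5%/97.5% quantiles.

## Epistemic network analysis

Units are individual chimpanzees, groups are communities, conversations
are (subject, video) — the entities plotted as circles, squares and
bounded sequences respectively. For each line ℓ and unordered element
pair (i, j), the unit's weight grows by 1 when i is present on ℓ and j is
present anywhere in the stanza window {ℓ−w+1 … ℓ}, or vice versa, at most
once per line (binary accumulation; a summed variant is a flag). Windows
truncate at conversation starts and never cross them. The default window
is w = 4 lines, configurable from 1 to the whole conversation; no
published value exists for this analysis context, so the planted-structure
tests run the recovery property across window settings.

Each unit's pair vector is divided by its L2 norm (units seen in more
clips accumulate more counts; the sphere keeps relative pattern), all-zero
units are excluded with a warning, vectors are mean-centered and the first
two right-singular directions give SVD1/SVD2. Variance explained is the
squared-singular-value fraction. Axis sign is fixed by making the
largest-magnitude loading positive, so repeated runs are bit-identical;
published figures have arbitrary sign. With two groups some ENA variants
rotate the first axis through the group means; that rotation is not
implemented — all models here are plain SVD, which is what multi-group
models use.

Node (element) positions solve a least-squares co-registration: each
unit's network centroid — its edge midpoints weighted by normalized edge
weight — should land on the unit's projected point. Goodness of fit is the
Pearson and Spearman correlation, per axis, between points and centroids.
When elements outnumber what the unit set constrains, the minimum-norm
solution is used with a warning; centroids (and hence fit) are unaffected
by that choice within the solution space.

Group means get axis-aligned t confidence intervals (95% default;
singleton groups are flagged without an interval). Group comparisons use
the Mann–Whitney U of the first group's coordinates, two-sided, with
rank-biserial effect size r = 1 − 2U/(n₁n₂): complete separation gives
|r| = 1 regardless of sample sizes, which is the convention-independent
endpoint the tests pin. All-tied coordinates return p = 1, r = 0 with a
warning instead of failing.

## Synthetic corpus generator

The generator emulates the data-collection process, not any fitted model
of real chimpanzees. Structure and defaults:

- **Sampling frame.** 2 communities × 8 subjects (field studies span
  5–31 per community), 22 motion-triggered clips per subject (published
  corpora average ~22 usable clips per fishing subject), clip length 20 s
  (infrared low-light mode) or 60 s (full light), one element about every
  2.5 s on the quarter-second grid, presence lines of 2.5 s (about one
  coded action per line). Clips truncate bouts mid-sequence.
- **Element propensities.** A role-budgeted base (probing dominates clips;
  extraction arrives mostly through the grammar below) with geometric skew
  within non-functional roles and a flat split across probe/extract
  variants. Community profiles drift from the base by a lognormal factor
  (`profile_divergence`, 0.3; 0 restores exchangeability). Subjects draw
  stable role totals but sparse within-role variant preferences
  (Dirichlet, `subject_concentration` 0.6): which grip a chimp favors is
  strongly individual, how much it probes is not.
- **Grammar.** First-order Markov chain; after a probe-role element the
  chain moves to an extract-role element with probability `p_functional`
  (0.9), so bouts contain catalogued techniques at a known rate. The
  chain's stationary distribution is stored as each subject's realized
  propensity (the drawn vectors are kept separately).
- **Community habits.** Each community gets a planted pair of common
  non-functional elements whose mutual transition probability is
  multiplied by `affinity_strength` (6) and whose propensities get a
  modest boost (2.5): a habit is frequent elements used together. With
  `distinct_affinities=False` plus zero divergence, communities are
  exchangeable — the null condition.
- **Kinship.** Offspring propensity = κ·mother + (1−κ)·community exposure
  with κ = 0.8; the non-maternal share defaults to the community-average
  profile (horizontal transmission pulls toward the community norm), with
  a fresh individual draw available via `kinship_fresh="draw"`. The
  family configuration (`default_family_config`) models the well-observed
  subjects that repertoire analyses retain after rarefaction screening:
  three dyads, 60 full-light clips each.

What the generator does **not** emulate: real temporal bout structure
(pauses, tool replacement, multi-mound visits), age- or sex-structured
behavior, coding error, camera placement bias, or any parameter fitted to
real corpora. Passing tests therefore show that the pipeline recovers the
structure this process plants at realistic sizes — not that real
communities would separate this cleanly.

## Calibration and recovery properties (as tested)

With generator defaults, the test suite checks: type-I error of the ENA
community comparison within 2–9% over 200 seeded null replicates; power
≥ 90% over 100 replicates with the planted difference; 93–97% empirical
coverage of the 95% group-mean intervals over simulated Gaussian groups;
all three κ = 0.8 dyads co-clustered in ≥ 80% of 50 replicates (chance
level at κ = 0); the planted habit pair as the top mean-network edge of
its community in ≥ 95% of replicates; pooled community rarefaction
terminating at the planted inventory in every replicate; and bit-level
determinism of corpora, catalogs and projections under a fixed seed.

## Numerical conventions and degenerate inputs

Pair order is the upper triangle in ethogram column order; projections are
invariant to that choice. Quarter-second grid membership is checked to
1e-6. Empty event tables, all-zero matrices, empty repertoire pairs and
single-subject clustering raise typed errors rather than returning NaN.
Problem sizes throughout the suite (8 subjects per community, tens of
clips, 16-element inventory) were chosen as the smallest sizes at which
the planted effects are identifiable with comfortable margins; rarefaction
uses 1000 bootstrap replicates in analyses and smaller counts in tests
where only the mean curve matters.

## Known limitations

- The stanza window, binary accumulation and unit-sphere normalization are
  one ENA convention set; web-tool implementations differ in detail
  (e.g., means rotation for two groups), so coordinates are comparable
  within ethonet runs, not across tools.
- Nested occurrence counting inflates long-technique counts in highly
  repetitive sequences; use `maximal_only` when comparing against
  segmentation-based counts.
- The Fisher family reports per-technique × pair tests without modeling
  the dependence among overlapping techniques.
- Rank-biserial sign follows group argument order; only |r| is
  convention-free.
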