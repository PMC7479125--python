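# Methods

This note documents the models, numerical choices and open design
decisions behind `hemirc`, in the order the pipeline applies them. It
states no empirical result that the test suite does not itself compute.

## Network construction

**Edge adoption.** A connection between two regions enters the network
only when its streamline count strictly exceeds the threshold
(`fn_threshold`, default 3, dimensionless count). The inequality is
strict: FN = 3 is rejected. The rule suppresses spurious connections
from noisy deterministic tractography; it is idempotent and monotone in
the threshold (raising the threshold can only remove edges), and both
properties are under test.

**Hemisphere split.** The whole-brain 90-node network is reduced to two
45-node within-hemisphere principal submatrices; inter-hemispheric edges
are discarded, not redistributed. The packaged node table orders all 45
left regions first, then their right homologues in matching order, so
the right submatrix is homologue-aligned to the left by construction —
row *i* of each hemispheric matrix refers to mirror regions. Edge
weights are copied exactly, never rescaled.

**Group average.** The average network used for hub selection pools all
subjects, both groups, and both hemispheres (after homologue alignment),
with absent edges entering the mean as true zeros
(`average_mode="include_zeros"`). Zero-inclusive averaging preserves
density differences between cohorts; averaging only over subjects that
possess an edge (`"nonzero_only"`) is available for sensitivity
analysis. Pooling both groups yields a single hub set for the whole
study, so group comparisons of class measures are not confounded by
group-specific hub definitions.

## Rich-club measurement

**Weighted coefficient.** For each degree level *k* (node degree is the
binary count of nonzero weights), let S be the set of nodes with degree
strictly greater than *k*, W the total weight among S and E the number
of edges among S. Then φʷ(k) = W divided by the sum of the E largest
edge weights in the whole network. φʷ(k) ∈ [0, 1] wherever defined.
Levels where |S| < 2 or E = 0 are carried as masked values — never
imputed as zero, because a zero would masquerade as "no rich club"
where the statistic is simply undefined. The implementation reduces the
per-level totals to suffix sums over min(deg_i, deg_j) per edge (an edge
survives level k iff both endpoint degrees exceed k), which is O(m) per
curve and is checked against an explicit subgraph-enumeration oracle on
hundreds of small graphs at machine precision. The club cut is strict
(degree > k, the van den Heuvel–Sporns convention) by default; a
``degree_cut="greater_equal"`` option gives the ≥ k reading, which is
the strict curve shifted by one level.

**Null model.** Surrogates come from weighted double-edge swaps: two
edges (a,b), (c,d) are replaced by (a,d), (c,b) when this creates
neither self-loops nor duplicate edges, and each edge keeps its weight
through the swap. This preserves the degree sequence and the multiset of
edge weights (hence total strength) *exactly* — the two properties the
procedure is defined by. Per-node strength is only approximately
preserved; `phi_null_std` in the curve object quantifies the ensemble
spread. Default intensity is 10 accepted swaps per edge, with an attempt
cap of 50× the target so swap-free topologies (stars) terminate with a
warning rather than hang. `n_swap_per_edge=0` returns the input
unchanged.

**Normalization.** φ_norm(k) = φ(k) / mean over `n_null` surrogate
curves (study default 1000; tests and the acceptance script use 50–200,
which is Monte-Carlo consistent — verified by comparing ensemble sizes
within propagated error). Because rewiring preserves every node's
degree, the club membership S is identical across surrogates and all
curves live on one k-grid; levels where any surrogate φ is undefined are
masked in the normalized curve. A graph that is itself a draw from the
ensemble has φ_norm = 1 up to the ensemble SD of a single draw (not
SD/√n_null — the single-draw variance dominates), which is the
calibration test's tolerance.

**Hubs and edge classes.** Hubs are the top ⌊fraction × n⌋ nodes by
degree of the pooled average network (0.16 × 45 = 7.2 → 7 hubs, 38
peripheral). Ties at the cut are broken by higher nodal strength, then
by node order — deterministic and documented, exercised by a dedicated
tie test. Every existing edge is rich-club (two hub endpoints), feeder
(one), or local (none). Class connectivity density divides the class's
edge count by *all* n(n−1)/2 possible hemispheric edges (990 for
n = 45), so the three class densities sum to the overall network
density; class strength sums FA over the class's edges, once per
undirected edge. Both additivity identities hold at machine precision
and are under test. A per-class possible-edge denominator is a
defensible alternative reading; the whole-network denominator is the
implemented contract.

**Degree range for group comparison.** Curves report only defined
levels; cross-subject analyses should restrict to levels defined for
every subject, which the long-format curve table makes a simple
group-by.

## Statistics

**Asymmetry score.** AS(X) = 100·(X_R − X_L)/(X_R + X_L), in percent,
bounded in [−100, 100] (clipped against floating-point overshoot at the
boundary), antisymmetric under hemisphere swap, zero iff the sides are
equal, and undefined (NaN with a warning) when both sides are zero.
Negative values mean a left-hemisphere advantage.

**Mixed ANOVA.** With two within-subject levels the repeated-measures
design decomposes exactly into orthogonal strata: subject means
m = (L+R)/2 carry the between-subject information and contrasts
d = R − L carry the within-subject information. The group effect is the
ANCOVA partial F for group on m with covariates in the model, giving
denominator df N − 2 − c (the study's df pattern: N = 104, c = 3 →
df = 99). The hemisphere main effect tests the unweighted mean of the
two group means of d (SPSS Type-III convention for unbalanced groups),
and the interaction tests the group difference in d; both use the pooled
within-group variance of d on N − 2 df. Covariates enter the
between-subject stratum only — the declared contract, since the source
SPSS parameterization is undocumented. The implementation is plain
numpy/scipy least squares for speed; it is cross-checked against
`pingouin.mixed_anova` on balanced designs (where the conventions
coincide, agreement to 1e-10) and calibrated to nominal type-I error
over 2000 null replicates. For degenerate inputs with zero residual
variance, F is 0 when the effect estimate is also 0 (p = 1) and +inf
otherwise, rather than NaN.

**Post hoc and asymmetry tests.** Gated on omnibus p < 0.05. Paired
t-tests (hemisphere, within group) act on d with covariates residualized
out (the mean of d is restored so only the covariate trend is removed);
independent t-tests (group, within hemisphere) act on residualized
values; both reduce the df by the number of covariates. One-sample
asymmetry tests use df = n − 1 per group. If covariate adjustment leaves
no residual df, the test returns NaN with a warning instead of a fake
statistic.

**Bonferroni.** p_adj = min(1, m·p); applied to nodal-degree tests with
m = number of regions (45), per the convention of correcting nodal maps
but not the six connectivity measures.

**Partial Spearman.** Rank-transform x and y, residualize both rank
vectors on [1, covariates], Pearson-correlate the residuals; two-sided p
from the t distribution on n − 2 − c df. Reduces exactly to plain
Spearman with no or constant covariates, is invariant to strictly
monotone transforms of either variable, and matches a step-by-step
brute-force oracle to 1e-12.

**Edge-wise census.** Over homologue-aligned hemispheric edge values
(absent edges are true zeros, not missing): per edge, an independent t
on the subject-wise hemisphere-mean FA (group effect), a paired t of L
vs R (hemisphere effect), and an independent t on the per-edge AS (group
asymmetry effect), each at uncorrected α = 0.05 in keeping with the
exploratory framing (a Benjamini–Hochberg option exists but is off by
default); counts and percentages are reported per edge class.
Edges with no variance yield p = 1, never a rejection.

## Synthetic cohorts

The generator states a world and the tests measure whether the pipeline
recovers it; its parameters were fixed before the calibration tests were
run and are not tuned to outcomes.

**Template.** 90 nodes, 7 planted hubs per hemisphere at the positions
of the packaged table's PreCG, INS, MOG, PoCG, PCUN, PUT, TPOsup
regions. Hub–hub pairs connect with probability 0.95; feeder pairs at
2.5× and local pairs at 1× a base rate solved so the hemisphere hits
`base_density` (default 0.30, typical of FN-thresholded deterministic-
tractography FA networks; infeasible combinations raise). FA-like
weights are a clipped normal (mean 0.45, SD 0.10 — a plausible
white-matter FA range), with hub–hub weights multiplied by
`core_weight_boost` = 1.3, so φ_norm > 1 at high k by construction
(verified through the pipeline's own rich-club code). The right
hemisphere mirrors the left exactly, in weights and fiber counts;
homotopic plus sparse heterotopic inter-hemispheric edges are added and
later discarded by the split. A configurable fraction (0.10) of
candidate edges receives fiber counts in {1, 2, 3} and is dropped by the
FN > 3 rule.

**Subjects.** Each subject multiplies template weights by lognormal
noise (σ = 0.10) and draws fiber counts as Poisson jitter around the
template counts, so near-threshold edges flicker through the FN filter
and connectivity *density* varies across subjects — without this the
density metrics are constant within group and the within-subject F
statistics degenerate. Patients additionally get multiplicative FA
deficits on feeder (0.10) and local (0.15) edges, and a per-subject
severity u ~ U(0,1) that deletes up to 25% of right-hemisphere local
edges, driving a leftward peripheral-degree asymmetry whose magnitude
the clinical scores track (negative-binomial YMRS/HAMD with a logistic
mean link, clipped to the scales' 0–41 / 0–32 ranges), giving the
partial Spearman stage recoverable signal.

**Asymmetry injection.** Hemispheric asymmetry targets (defaults |AS| =
5: controls rightward in local connections, patients leftward in feeder
connections) are implemented by deleting a seeded random fraction
f = 2·AS/(100 + AS) of the disadvantaged hemisphere's class edges. A
multiplicative weight scale was considered and rejected: it moves
strength but cannot move density, and the asymmetry phenomenon under
study spans both measures. Deletion shifts both to the same AS target —
density exactly in expectation, strength in expectation under
edge-exchangeable weights — with a closed form, so no bisection
calibration is needed.

**What a green test does not establish.** The generator has no
tractography geometry, no distance-dependent connection probability, no
realistic regional FA profile, and no subject-level variance estimates
from the real cohort (none are published); effect sizes are chosen for
testability. Power and direction-recovery results on this world say the
pipeline detects what was injected — not that the study's subject-level
F/t/p values are reproduced, which is impossible without the original
cohort.

**Seeding.** One master seed; every template, subject, phenotype and
null-ensemble draw derives a sub-seed by CRC-hashing a stable label
(e.g. subject id + hemisphere) against the master, all below 2³¹, so
runs are reproducible end to end and independent of iteration order.

## Pipeline

Stages run in a fixed order (threshold → split → pooled average → hubs →
classify → per-subject measures → curves → AS → ANOVA/post hoc → AS
tests → nodal tests → Spearman → census), each logged with timing; every
output table carries the config hash and master seed in its `attrs` and
in a header comment when written to TSV. Two runs with the same
configuration are byte-identical (tested). Rich-club curve computation
can be disabled (`compute_rich_club_curves=False`) for analyses that do
not consume the curves, e.g. large calibration sweeps.

## Known limitations

- Handedness enters as an opaque covariate; the published construction
  formula is internally inconsistent and is not reimplemented.
- The hemisphere main effect follows the unweighted-means (Type III)
  convention; packages using weighted grand means will differ on
  unbalanced designs.
- The census's per-edge model (hemisphere-mean group test, paired
  hemisphere test, AS group test) is one reasonable reading of an
  underdocumented procedure; its class-level proportions, not its exact
  counts, are the meaningful output.
- The Maslov surrogate's swap count and acceptance rules are not
  published for the original toolchain; any scheme preserving degrees
  and the weight multiset is admissible, and ensembles differing in
  swap intensity agree within Monte-Carlo error.
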