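# Methods

## Scope and data model

The package screens binary species-by-category trait tables on rooted
phylogenies with branch lengths, propagating phylogenetic uncertainty by
recomputing every statistic on each tree of an ensemble (e.g. a Bayesian
posterior sample) and reporting the median and range. Trees are treated as
rooted as written; any outgroup rooting is assumed done upstream, and
outgroup taxa are pruned with `prune_to_taxa` before trait analyses (all
statistics here — D, rooted PD, descendant counts — are rooted
quantities). Tip labels are joined to use-record species names through a
shared normalizer: whitespace collapsing, underscore-to-space, list-driven
authority stripping, and genus capitalization. Authority stripping is
deliberately list-driven rather than heuristic so epithets are never
mangled; the default list covers only common authority abbreviations and
should be extended per dataset.

Category membership is set-valued: a species belongs to a category if at
least one of its records maps there, so duplicate records and record order
never matter. Prevalence is N divided by the number of tips of the
analysis tree (after outgroup pruning). Toxicity records (EBDCS level-1
*vertebrate poisons*) participate in the biological-response classes —
toxicity and medicinality differ mainly by dosage — but never in the
medicines level-2 categories.

## D statistic

For a binary trait x on a bifurcating tree, each internal node receives a
nodal value from its two daughters and contributes |x₁ − x₂| to ΣD. The
default nodal estimator is branch-length-weighted averaging with
Felsenstein's adjustment: daughter weights ∝ 1/v where v is the daughter's
adjusted edge length, and the merged node's edge is extended by
v₁v₂/(v₁+v₂). Zero-length edges are legal: a zero-length daughter carries
full weight (the limit of 1/v weighting), and two zero-length daughters
average plainly. An `unweighted` switch (plain means, branch lengths
ignored) is provided for cross-checking against other implementations;
both variants calibrate identically because the observed trait and both
nulls pass through the same ΣD operator. Polytomies are resolved randomly
(seeded) with zero-length inserted edges before ΣD; this leaves all
patristic distances unchanged.

The two nulls are: (i) uniform permutations of the tip-state vector
(prevalence preserved exactly) and (ii) the Brownian-threshold model — a
continuous trait accumulating independent N(0, branch length) increments
from root to tips, thresholded so the k top-ranked tips (k = observed
count) are state 1, ties broken at random. The Brownian variance scale is
fixed at 1 per unit branch length; it cancels under rank thresholding.
D = (ΣD_obs − mean ΣD_b)/(mean ΣD_r − mean ΣD_b). Monte Carlo p-values use
"≤"/"≥" comparisons with a plus-one correction, p = (#extreme + 1)/(n + 1),
so p ∈ [1/(n+1), 1] and never 0. Categories with fewer than 2 members (or
fewer than 2 non-members) raise an "insufficient variation" error, which
the ensemble driver records as an NA row with its reason.

Implementation note: ΣD is evaluated on a flat postorder array encoding of
the tree with precomputed (trait-independent) daughter weights, so null
batches are vectorized; Brownian tip values are drawn as Z·M where M is
the √(branch-length)-scaled root-to-tip edge incidence matrix.

## PD and MNTD

Faith's PD is the branch-length sum of the union of root-to-tip paths over
the category's species; `include_root=True` (default) keeps the connection
to the root, `False` drops edges above the set's MRCA. The same flag is
applied to numerator and denominator of PD percent. The default follows
the common rooted-PD convention; the flag exists because published
analyses do not always state the choice.

MNTD between sets A and B averages, over members of each set, the
patristic distance to the nearest member of the other set. Shared species
count at distance zero by default (`include_zero`, the plain definition);
the `exclude` policy skips self-matches and drops a term entirely when a
species has no non-self counterpart, erroring only when no terms remain.
Both policies are exposed because overlap handling is a genuine freedom in
published MNTD comparisons between overlapping categories.

The MNTD null draws random categories of the tested category's size
uniformly from a stated species pool (for the screening use case: the
union of the focal response-category species and the medicines species)
and uses the one-sided small-is-similar p-value with the plus-one rule. A
pool exactly equal to the tested category makes every draw identical; this
degenerate case warns and returns p = 1. Under generic (non-ultrametric)
branch lengths the p-value is uniform on its attainable grid when the
tested category really is a random draw; on exactly ultrametric trees the
many tied through-root distances make it discrete and conservative — the
uniformity property (and its test) applies to the generic case.

Patristic distances are computed in one postorder sweep as
d(i,j) = depth(i) + depth(j) − 2·depth(mrca); dendropy's distance matrix
and the R package picante serve as independent cross-checks in the test
suite, not as the implementation.

## Hot nodes

Each null replicate shuffles the K member labels uniformly over all N tips
of the analysis tree (configurable to a restricted pool); per internal
node the observed member count k is compared with the empirical alpha and
1−alpha quantiles of its null counts, with strict inequalities, flagging
hot and cold tails separately. Because the shuffle is a uniform draw
without replacement the per-node null is exactly Hypergeometric(N, K, nᵢ),
which the suite uses as the analytic oracle (3-binomial-SE agreement of
tail probabilities and ≥95% flag agreement at n_rand = 10,000). The test
runs on the majority-rule consensus tree; an exact quantile/tie convention
is not standardized across randomization tools, so the strict-inequality
rule here is fixed and validated against the hypergeometric law rather
than against any particular binary.

The consensus itself is built from rooted clades (descendant tip sets):
clades with frequency > min_freq (default 0.5) are kept — above one half
they are automatically compatible — and each consensus edge carries the
mean branch length over the trees containing its clade, plus the support
frequency. Node identifiers in reports are "(smallest descendant
label)|(clade size)", which is unique within a tree.

## Ensemble aggregation

Per-tree seeds derive from CRC32 of "(master seed):(tree index):(category)",
so adding a category or tree never perturbs another's random stream, and
every derived seed is below 2³¹. Significance bands implement exactly two
levels: `*` when ≥ 95% of trees give p(D < 1) < 0.05 and `***` when all
trees give p < 0.005 (no intermediate level; boundary reads: "95%" is
inclusive, "all" means fraction exactly 1, "<90%" strict). Strength labels
use the fraction f of trees with p(D > 0) > 0.05: weak f < 0.90, moderate
0.90 ≤ f < 0.95, strong 0.95 ≤ f < 1, very strong f = 1. These rules are
pure functions of the stored fractions and are tested at the boundary
values. Medians and ranges are computed over non-NA trees, with the
effective tree count reported. Report tables print to two decimals with an
en-dash range, EBDCS categories alphabetized and response-class rows
appended last.

## Synthetic data

The generator emulates the shape of a posterior tree set and a use-record
table, not any particular dataset: Yule or birth–death trees (forward
Gillespie simulation conditioned on the tip count, with a final
exponential waiting time so terminal branches are strictly positive);
pseudo-posterior ensembles as NNI-perturbed, branch-jittered copies of a
base tree (defaults: 2 NNI moves and log-normal jitter σ = 0.1, a mild
spread comparable to a well-resolved credible set); and traits in three
regimes — uniform random (D ≈ 1), Brownian-threshold (D ≈ 0, sharing the
simulator of the D statistic's null so there is a single implementation to
test), and single-clade clumping (D < 0, the hot-node ground truth).
Default study conditions used by the tests and the acceptance script:
200-tip trees, prevalence 0.25, 500-draw nulls for calibration; 20-tip
planted clades with 1,000-shuffle enrichment tests for recovery; 50-tip
trees with 10,000 shuffles for null-law agreement; ensembles of 8–50
trees for pipeline checks.

What passing these tests does *not* show: real posterior ensembles have
correlated topologies and heterogeneous branch-length uncertainty that NNI
jitter only caricatures; real use records carry name-matching noise,
sampling bias toward well-studied species, and non-independent categories.
Synthetic recovery rates are therefore upper bounds on real-data power,
and the calibration results validate the statistics' internal consistency,
not any empirical claim.

## Known limitations

* The D statistic requires ≥ 2 species in each state; very small
  categories are reported as NA rather than computed.
* Abundance-weighted MNTD and standardized effect sizes (NRI/NTI) are out
  of scope, as are continuous-trait signal statistics.
* The consensus branch-length rule (mean over supporting trees) is one
  reasonable convention among several; support values are stored but not
  used downstream.
* Ensemble MNTD p-value aggregation uses the ≥95%-of-trees rule only;
  no multiple-testing correction is applied across categories.
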