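# Methods

## The AMD statistic and its sampling null

A CpG dyad measured on both strands gives two methylation levels; the
absolute methylation difference (AMD) is their absolute difference in
percentage points, at a single dyad or between the per-strand means over a
gene's TSS window (−1500 … +2000 bases around the TSS along the gene's
orientation; both strand means are unweighted over the window's dyads, and
the window convention is frozen so that a plus-strand gene at TSS 10000
covers 8500–12000 inclusive).  Dyads enter the analysis only when both
strands carry at least `min_depth` reads (default 5, applied per strand:
the AMD compares two independent measurements, each of which must be
adequately sampled); zero-depth calls carry no defined level and are
dropped before pairing.

Two finite binomial measurements of the same underlying level `p` disagree
by chance, so the observed AMD is referenced to the exact expectation
`100·E|X/n1 − Y/n2|` with `X ~ Bin(n1, p)`, `Y ~ Bin(n2, p)` independent,
computed by enumerating all `(n1+1)(n2+1)` outcome pairs weighted by the
product of binomial pmfs.  The pmfs are evaluated through log-gamma terms,
which stays finite for `p` arbitrarily close to (but not at) 0 or 1; the
point cases `p ∈ {0, 1}` are handled exactly and give expectation 0.  A
normal approximation is deliberately never used — approximation error at
low depth is exactly the kind of bias the statistic is meant to detect.
Results are cached by `(n1, n2, p)` with the depth pair in canonical order
(the expectation is symmetric under depth swap and under `p ↔ 1−p`).

For a whole sample the null aggregates over a 102-bin methylation scheme:
the point bins {0} and {100} plus the open-closed percent bins (0,1] …
(99,100).  Every dyad contributes its pooled level (mean of the two strand
levels) to the bin weights and its per-strand depth pair to the
expectation, evaluated at the bin midpoint (0.5, 1.5, …, 99.5; exactly 0
and 1 in the point bins).  The aggregate null is the weight-summed
expectation; the *AMD excess* is the observed mean AMD minus the aggregate.

### The depth-10 worked example

The published worked example for this null quotes an expectation of 14.82%
for the 19–20% bin at depth 10.  An independent brute-force oracle (pure
enumeration, written before the production routine) shows that no
convention in the candidate family reproduces that figure: with depth read
as 10 per strand the expectation spans 13.59–13.88% as `p` scans 0.19–0.20,
and with 10 total reads split 5+5 it spans 18.58–19.02%.  Wider sweeps
(unequal depths, depths 2–30, deviation-from-truth readings, the normal
approximation ≈ 14.14%) also miss it.  The package therefore pins the
midpoint convention — `p = 0.195`, `n1 = n2 = 10`, expectation
**13.7377%** — and records the +1.08-point residual against the quoted
figure in the test suite instead of adjusting the computation toward it.

### Gene-level null

A gene's window is treated as one pooled site: its methylation is the mean
over window dyads and its depth the summed depth, split evenly between two
virtual strands (rounded, at least 1 per strand).  An even split is chosen
because the strand-wise depth split is not recoverable from the pooled
description; CpG sites are weighted equally (not by depth) when averaging,
matching the observed gene-AMD definition.

### Permutation test

The natural-sounding null device — swapping strand labels within a dyad —
leaves `|m+ − m−|` unchanged and tests nothing.  The exchangeable null of
"two interchangeable measurements of one site" is instead realised by
re-splitting each dyad's pooled reads between the strands with a
hypergeometric draw conditional on the total methylated count, which is
exactly the conditional distribution of one strand's count under the
no-hemi null.  The test statistic is the sample mean AMD; the one-sided
empirical p-value is `(1 + #{permuted mean ≥ observed}) / (n_perm + 1)`
(999 permutations by default, 199 in the replicated calibration runs).
Because the binning of the null table uses observed (noisy) pooled levels,
the aggregate null carries a small positive plug-in bias (≈ +0.15 points at
depth 30 on a uniform level spectrum); the permutation test is unaffected
since it never consults the table.

## Condition comparisons

Demethylation is `level(control) − level(perturbed)` in percentage points
over entities measured in both conditions (pairwise deletion, no
imputation).  "Demethylated by X" means strictly above the mean
demethylation of all measured entities — a deliberate relative criterion; an
absolute-threshold mode exists but is not the default.  The mean is taken
over all measured entities, not only those with positive delta.
Overlap between target sets reports directional fractions, Jaccard, and a
one-sided hypergeometric enrichment p (the fractions are
universe-invariant; the p-value is not).  Correlations default to Pearson,
with Spearman by flag.  AMD-response curves sort entities by (AMD, id) —
the id tie-break makes runs reproducible — into equal-count groups (14 for
sites, 20 for genes by default; remainder spread over the first groups).

## Zones, mimic groups and selections

* **Zone I**: 42–83 CpG dyads in the TSS window; **Zone II**: additionally
  40–60% gene methylation.  All printed band endpoints in these analyses are
  treated as inclusive (the sources print closed bands without specifying
  open/closed; inclusive is chosen once and frozen in tests).
* **Mimic groups**: bands 0–10 / 30–40 / 60–70 / 90–100% with
  AMD/methylation ratio < 0.02 (strand-symmetric groups I, II, IV, VI) or
  > 0.1 (hemi-rich groups III, V); both thresholds strict, so genes between
  them join no group and the groups are pairwise disjoint.  Groups at or
  below `min_size` (default 100) are flagged under-powered, not dropped.
* **High/low enrichment split**: within each 102-scheme methylation bin,
  genes at or above the bin's median AMD are "high" (ties, including a bin
  of identical AMDs, go to high); bins with fewer than two genes stay
  unassigned.
* **Matched-demethylation filter**: control methylation 20–60% (inclusive);
  both perturbations drop methylation by more than 20 points (strict;
  "20%" is read in the data's percentage-point units throughout, and the
  both-arms reading is the default because the third clause presupposes
  both arms moved — an any-arm escape hatch exists); the two perturbed
  levels differ by less than 5 points AND by no more than 10% of their
  average.  The worked fixtures pin the case where only the relative clause
  binds (levels 25/28 after a 50% control: diff 3 < 5 but 3 > 2.65).
* **Vitamin-C response selection**: Tet1 demethylation strictly larger in
  the Vc+ system than the Vc− system, and Tet1-vs-control log2 fold change
  strictly positive (no fold-change threshold beyond sign, as none is
  stated).

## The simulator

Each dyad is a population state vector over {uu, mu, um, mm}.  The plus
level is `f_mm + f_mu`, the minus level `f_mm + f_um`, and the true AMD
`100·|f_mu − f_um|`: hemi-methylation is visible to the AMD only through an
orientation imbalance.  The generator therefore draws one preferred
orientation per gene (replication is locally coherent; the sign is random,
so orientations are balanced across the genome) and places class-level hemi
mass on that strand with concordance `orientation_skew` (default 1).  The
background's small replication-transient hemi (3%) is modelled as
incoherent across cells — it contributes reads but no true AMD — because a
cell population's transient hemi at a locus has no preferred strand.

Gene classes (defaults): 85% background, 10% pluripotency-like, 5%
EMT-like.  Pluripotency-like promoters have 42–83 CpGs spaced 45–83 bp
apart (inside the 45–90 bp spacing band where hemi-methylation
concentrates), methylation 40–60% and a coherent 30% hemi fraction.
EMT-like promoters sit at 88–98% methylation with ~1% hemi.  Background
promoters are mostly CpG-island-like (70% Beta(1.2, 6)-shaped low
methylation) with a uniform minority spanning the full range — the uniform
component is a simulation convenience that keeps every methylation band
populated at modest gene counts rather than a claim about genome
composition — and a 15% hemi-rich subset (15% coherent hemi) stands in for
hemi-rich non-pluripotency promoters.  Per-dyad levels jitter around the
gene level (SD 5 points).

Perturbations act on state vectors, one round by default (`generations`
raises it):

* **Tet1** (active): hemi dyads lose their methylated strand with
  probability `r_hemi = 0.40`; fully methylated dyads lose each strand
  independently with `r_full = 0.16`.  The defaults encode the observed
  preferential activity on hemi-methylated substrate (a pure-hemi pool
  drops ~40% of its methylation in one round, a fully methylated pool
  ~16%).  Vitamin C multiplies `r_full` by 2.0 and `r_hemi` by 1.3
  (clipped at 1), encoding its stronger boost on fully methylated
  substrate.
* **sh-Dnmt1** (passive): one replication generation in which a fraction
  `maintenance_failure = 0.30` of fully methylated dyads fail maintenance
  on the daughter strand and become hemi (oriented by the gene's preferred
  orientation); hemi dyads are left intact.  No quantitative failure rate
  is published; 0.30 is chosen once as a strong-knockdown value that
  separates the passive arm's AMD clearly from control at depth 30.

Reads are sampled per strand: depth ~ Poisson(mean 30) (or fixed) and
methylated count ~ Binomial(depth, strand level), emitted in the Bismark
cytosine-report dialect; a fixed seed reproduces output byte-for-byte.
Depth 30 is deep enough that sampling AMD (≈ 10 points at 50% methylation)
sits well below the coherent-hemi AMD (30 points), keeping recovery tests
sharp.  Expression changes are `κ·(Δmethylation/100) + N(0, 0.3)` with
`κ_active = 2.0` for Tet1 arms and `κ_passive = 0.5` for sh-Dnmt1 arms —
chosen so active-arm demethylation explains a modest share of expression
variance (r ≈ 0.3), consistent with methylation being one regulator among
many, while the passive arm's coupling is clearly weaker.  Accessibility is
`(100 − level)/100 − hemi + N(0, 0.1)`: openness falls with methylation and
with hemi content.

What the simulator does **not** emulate: read-level errors and bisulfite
conversion failure, 5hmC/5fC/5caC chemistry (bisulfite cannot resolve
them), linked methylation along reads, genomic CpG landscape composition,
overlapping genes, and gene-specific perturbation sensitivity.  The last
omission matters for one analysis: with uniform single-round kinetics the
active route demethylates almost every gene more than the passive route, so
the matched-demethylation filter — which demands near-equal drops by both
arms — selects essentially nothing from simulated studies.  The filter's
behaviour is therefore pinned by hand-built fixtures; passing tests show
the filter logic and boundaries are exact, not that matched genes arise
under these kinetics.

## Test and calibration problem sizes

All statistical checks run at desk scale, chosen to keep the full suite
around a minute while leaving clear margins: null calibration uses 10,000
dyads at fixed depth 30 (single dataset for the ±0.3-point excess bound;
100 replicates at 199 permutations for the 5% type-I bound); power uses 100
replicates of 2,000 dyads at a 30% hemi fraction; the hemi-recovery
regression uses 5,000 dyads with hemi fractions uniform on [0, 0.5]; the
perturbation-direction check uses 50 default studies (1,000 genes,
~27,000 dyads each); response-curve monotonicity uses three default
studies with 14 site groups; Monte Carlo cross-validation of the exact
expectation uses 10⁶ draws per (depth, level) cell on a 4×4 grid with a
0.1-point tolerance.

## Known limitations

* The aggregate null's plug-in bias (binning by noisy observed levels)
  is small at depth ≥ 30 but grows at very low depth; the permutation test
  should be preferred for inference there.
* Gene windows use the plus-strand cytosine as the dyad coordinate; a dyad
  whose plus C sits exactly on a window edge is included, which can differ
  by one base from a minus-strand-anchored convention (immaterial at 3.5 kb
  windows, but frozen for reproducibility).
* Asymmetric strand coverage is dropped, not imputed.
* The 14/20-group response curves assume equal-count grouping; equal-width
  grouping is not offered.
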