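# Methods

This note documents the models behind each pipeline stage, the defaults
and why they were chosen, what the synthetic-data generators do and do
not emulate, and the numerical conventions that matter for reproducing
results.

## Preprocessing

A feature table is a samples × taxa matrix of non-negative integer
counts. The low-prevalence filter removes any ASV whose total count is 1
(a singleton) or that is non-zero in at most one sample; the filter is
idempotent and never changes the sample set. Filtering is applied
*before* rarefaction by default — the order is configurable because the
two operations do not commute, and conventions differ across pipelines.

Rarefaction draws each sample down to a common depth **without
replacement** (a multivariate hypergeometric draw from the row's count
multiset), in a single draw rather than an average over repeats;
averaging is offered only in the rarefaction-curve routine, whose mean
observed-richness values converge on the closed-form hypergeometric
expectation `E[S] = Σ_i (1 − C(N−n_i, d)/C(N, d))`. The default depth is
the minimum sample total. Newick trees must carry branch lengths;
missing lengths are rejected rather than silently defaulted, because
phylogenetic dissimilarities scale linearly with them.

BIOM 2.x input is read directly from its HDF5 layout (sample-major CSR)
via h5py.

## Alpha and beta diversity

Shannon entropy uses log base 2 (values in bits; a config switch gives
nats), Pielou evenness is H/log2(S) and is reported missing below two
observed taxa. Faith's PD sums the branch lengths of the minimal
subtree spanning the observed tips *including the stem path to the
root*; the crown-only variant is available. The include-root choice
matches the convention of the common amplicon toolchain and is
cross-checked in the tests against an independent implementation.

Jaccard dissimilarity is computed on presence/absence, Bray-Curtis on
counts; after rarefaction all rows share one total, so counts and
relative abundances give identical Bray-Curtis values. Diversity–factor
association uses Spearman rank correlation (trajectories of temperature,
sugar, pH etc. are monotone but not linear) with Benjamini–Hochberg
adjustment across the whole index × factor table.

## Turnover / nestedness partition

The incidence-based pairwise decomposition splits total Jaccard
dissimilarity into a turnover (replacement) component and a
nestedness-resultant component:

    β_jac = (b+c)/(a+b+c)
    β_jtu = 2·min(b,c)/(a + 2·min(b,c))
    β_jne = β_jac − β_jtu

The additive identity holds to machine precision and is enforced by a
1,000-pair property test. Only the pairwise incidence family is
implemented; multi-site measures and abundance-based decompositions are
out of scope.

"How much of each component is related to sampling time" is
operationalised as the R² of a one-way PERMANOVA of the component
distance matrix against time-point labels. This is a design decision —
the quantity is not otherwise pinned down — and is therefore prominent
here: other variance decompositions would give different percentages.

PERMANOVA uses Anderson's pseudo-F on squared distances with
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` (999 permutations by
default) and an exhaustive-enumeration mode for small n, where
p = #{F ≥ F_obs}/n! including the identity. Non-Euclidean component
matrices (the nestedness component in particular) can yield marginally
negative among-group sums of squares; reported F and R² are floored at
zero while the permutation test compares raw statistics. Type-I error
is calibrated: 500 exchangeable null simulations reject at 0.05 ± 0.02.

## Assembly null models

βMNTD is the abundance-weighted mean distance from each taxon of one
community to its nearest relative in the other (weights are within-
sample relative abundances; an unweighted switch uses 1/richness). The
null model shuffles taxon labels across **all** tree tips — equivalently
permutes rows and columns of the patristic matrix — holding both
compositions fixed, 999 draws by default; βNTI is the z-score using the
sample (n−1) standard deviation of the null draws. Exhaustive
tip-permutation enumeration (population SD) serves as the test oracle on
trees of ≤ 6 tips; sampled and enumerated z agree within 0.05 at 10,000
draws. A degenerate null (SD = 0, e.g. a star tree) yields a missing
βNTI and the label `undetermined`.

At matrix level one permutation per replicate scores **all** pairs via a
taxon-to-community minimum-distance matrix, making each replicate
O(taxa × samples) instead of O(taxa² × pairs).

RC_bray builds null community pairs that preserve each sample's observed
richness and total: taxa are drawn without replacement with probability
proportional to pool occurrence frequency (Gumbel-top-k, identical in
distribution to sequential weighted draws), each drawn taxon receives
one individual, and the rest are assigned multinomially by pool mean
relative abundance. `RC = 2·[(#{null<obs} + ½·#{null=obs})/n_null] − 1`.
The pool defaults to all samples sharing group and stage — the pairing
is within time points, but a single time point's replicates are too few
and too self-similar to define occurrence frequencies; the scope is
configurable and is logged. For synthetic-scenario recovery the
generating regional pool is passed explicitly.

Classification follows strict thresholds: βNTI > 2 variable selection,
βNTI < −2 homogeneous selection; otherwise RC_bray > 0.95 dispersal
limitation, RC_bray < −0.95 homogenizing dispersal, remaining pairs
drift. Boundary ties fall to the stochastic/drift side. Pairs are
scored only within (group, stage, time point) — never across times.

The βNTI–factor regression is ordinary least squares with a Gaussian
identity link (the only family consistent with straight-line fits); the
pair-level predictor is the mean of the factor over the two samples
(option: absolute difference), log-transformed on request. Simulated
data with slope −1.5 and noise SD 0.5 show nominal 95% CI coverage.

## Source attribution

A collapsed Gibbs sampler assigns each sink individual to one of V known
sources or an Unknown source. Known profiles are fixed and Dirichlet-
smoothed with α_src = 0.001 per taxon; the assignment prior adds
α_sink = 0.1 pseudo-counts per source; the Unknown profile is learned
from currently unassigned mass under a flat smoothing of β = 10
pseudo-counts **per taxon**. The heavy flattening matters: a freely
adapting Unknown source can reproduce any sink exactly and absorbs all
mass whenever real sinks deviate from source profiles by sampling or
batch noise. With the flat prior it wins only for taxa no known source
explains. Sinks are rarefied to 1,000 individuals by default (the
sampler is per-individual; this bounds cost), 50 burn-in + 100 recorded
sweeps, averaged over 4 independent restarts, with a warning when
restart-to-restart spread exceeds 0.05. Proportions are posterior means
of n_v/N; credible intervals are percentile intervals of the pooled
draws. The inner sweep is a numba kernel; results are bit-reproducible
for a fixed seed.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
verified; their defaults are fixed and are not tuning knobs.

**Trees.** Besides birth-death and Kingman coalescent models, a
"radiation" model produces the clumpy shape typical of marker-gene ASV
trees: two deep lineages, each an ancient radiation of ~4-tip clades on
long, nearly equal spokes with short within-clade branches. This shape
is what gives nearest-taxon statistics their contrast: a community's
close relatives are a few clade-mates, while a random tip is far away.
On generic birth-death or coalescent trees the contrast largely
vanishes — random tips already have close neighbours — and βNTI cannot
separate selection from noise at any plausible effect size; this is a
property of the statistic, not of the implementation.

**Pools.** Traits evolve by Brownian motion along branches (so clades
share environmental optima), mean abundances are lognormal, and
occurrence frequency decreases with abundance rank.

**Assembly scenarios** (canonical conditions: 128 taxa, 20 communities,
richness 16, depth 2,000, pool abundance lognormal σ = 0.25 — flat
enough that abundance weighting does not collapse the effective number
of informative taxa):

- *Homogeneous selection*: membership drawn by a Gaussian trait filter
  around one shared optimum placed at the upper trait decile (trait
  extremes are clade-coherent; the centre of the trait distribution is
  crossed by many unrelated clades). σ adapts so the niche holds about
  2× richness candidates, keeping community overlap partial.
- *Variable selection*: same filter, optima alternating between the two
  trait extremes.
- *Drift*: membership by occurrence frequency, abundances by pool means
  — exactly the Raup-Crick null, so RC is calibrated near zero.
- *Dispersal limitation*: each community confined to its own uniform
  random sub-pool with independently drifted (Dirichlet) abundances, at
  doubled richness so the pool-based null expects sharing the isolated
  communities fail to show.
- *Homogenizing dispersal*: multinomial resamples of one strongly uneven
  (lognormal σ = 2) mother community at doubled richness, so rare
  members flicker across samples and the phylogenetic null is
  non-degenerate.

Under these conditions each scenario's generating process is the modal
inferred label across seeds. The homogeneous-selection fraction of
pairs with βNTI < −2 is typically 0.75–0.97 (median ≈ 0.87) across
tree/pool realizations; individual realizations below 0.80 occur and
are reported as measured.

**Two-stage scenario.** 2 groups × 3 batches × (5 SAC + 6 FER) time
points = 66 samples per lineage; distinct starter pools per group
("P…"/"T…" taxon prefixes), one shared environment pool ("E…" prefix,
auditable identifiability). A replacement-mode lineage substitutes
starter taxa with environment taxa during fermentation at roughly
constant richness; a loss-mode lineage deletes starter taxa without
substitution (nested subsets, shrinking richness) while three
environment taxa come to dominate. Saccharification samples carry an 8%
environmental admixture; the fermentation environment share ramps from
0.3 to 0.9. Physicochemical trajectories are monotone-with-noise curves
in plausible units (moisture %, temperature °C, sugar and ethanol
g/100 g, acidity in 0.1 M NaOH titration units, pH). Per-sample true
source-mass fractions and per-lineage modes are recorded and suffice to
score every downstream stage.

What the generators do **not** emulate: sequencing error and chimeras,
taxonomy, compositional correlations between lineages, non-monotone
factor excursions, overlap between starter and environment pools
(injectable, off by default), or real ecological dynamics beyond the
stylised mechanisms above. Passing recovery tests therefore demonstrates
the statistics' correctness and sensitivity under known ground truth,
not performance guarantees on field data.

## Numerical conventions and limitations

- All randomness flows through `numpy.random.default_rng(seed)` (the
  Gibbs kernel seeds numba's internal generator); fixed seeds give
  bit-identical outputs.
- RC_bray tie counting uses an absolute tolerance of 1e-12 on
  Bray-Curtis values; relabelling taxa changes which null draws are
  realised, so RC is invariant in distribution, not bit-for-bit.
- βNTI uses the sample SD of null draws; the exhaustive oracle uses the
  population SD — comparisons are made with tolerance, never bit-exact.
- Problem sizes in the tests and the acceptance script (128-taxon pools,
  999 null draws, 199–9,999 permutations, 500 calibration simulations,
  depth-1,000 Gibbs sinks) were chosen as the package's own verification
  scale: large enough for stable estimates at the stated tolerances,
  small enough to run comfortably on a single CPU.
- Scores whose null is degenerate propagate as `undetermined` rather
  than being silently dropped; downstream tallies include them.
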