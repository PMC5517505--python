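# Methods

This note documents the statistical model behind each pipeline stage, the
synthetic-data generator that stands in for real sequencing data, the
numerical choices, and what the tests do and do not demonstrate.

## Study design assumptions

The pipeline targets a time-course design with **one sequencing library per
condition**: a control culture, an oxygen-glucose-deprivation (OGD)
condition, and several reperfusion time points. Default comparisons are
OGD vs control, then each reperfusion point vs OGD. One library per
condition has two hard consequences that shape everything below:

- no per-condition biological dispersion can be estimated, so the per-gene
  test must assume a counting-noise-only null;
- correlation across conditions is estimated from very few points (5 by
  default), so co-expression edges need a high correlation floor, and any
  quantitative validation of correlation recovery needs more conditions.

## Differential expression

Expression is quantified as RPKM, `1e9 * C / (N * L)`, with `N` the
per-library total mapped reads (which may exceed the column sum of the
quantified genes — totals include reads mapped outside the gene set).

The per-gene test is the exact Poisson-ratio (Audic–Claverie) test, the
standard replicate-free choice: under equal underlying rates and
conditional on the observed count `x` in the first library, the second
count follows the predictive law `NB(x + 1, n1/(n1+n2))`. The two-sided
p-value doubles the smaller of the two conditional tails and caps at 1,
and is evaluated through the regularized incomplete beta function (the
negative-binomial CDF/SF), which the test suite verifies against exact
rational tail summation to 1e-10 relative. Note the test is
orientation-dependent: `p(x, y, n1, n2)` and `p(y, x, n2, n1)` agree only
asymptotically, because the predictive law conditions on the first
argument. The pipeline always conditions on the reference library.

FDR control is Benjamini–Hochberg over all testable genes of a comparison;
genes with zero counts in both libraries are untestable and excluded from
the BH denominator. A DEG must pass both `|log2 ratio| >= 1` (fold change
at least 2; the boundary is admitted) and `FDR <= 0.001`. Fold changes are
computed on RPKM with each value floored at 0.01 first, keeping ratios
finite when one library has no reads; the floor is visible in the output
tables (a drop to zero appears as a large but finite negative ratio).

## Enrichment

Upper-tail hypergeometric over-representation with the annotated-expressed
universe convention: `N` counts genes that are both quantified (testable
in the comparison) and annotated to at least one term of the namespace.
Both Bonferroni (`min(1, p*T)`) and BH columns are reported because both
corrections are conventional in this literature; the significance gate is
BH `p <= 0.05` (boundary admitted), configurable. Terms whose universe
overlap with the DEG list is empty are still tested (p = 1) and counted in
`T`. Namespaces (GO vs KEGG vs custom) are corrected independently. Gene
sets are used exactly as given in the GMT file — no ontology-DAG ancestor
propagation — so GO results are only as complete as the annotation file.

The tail probability is computed with exact integer arithmetic
(`math.comb` and one rational-to-float rounding), which is exact to double
precision at any universe size this pipeline meets; the suite cross-checks
it against draw-by-draw enumeration and against Fisher's exact test.

## Co-expression network

Profiles are `log2(RPKM + 1)` across all samples of the experiment (the
pseudo-count avoids log 0; the log tames the heavy right tail). A pair
becomes an edge when `|r| >= 0.9` **and** the two-sided correlation-test
p-value (`t = r * sqrt((L-2)/(1-r^2))`, L−2 df) is `<= 0.05`. With only 5
samples the t-test alone is far too weak, hence the correlation floor —
the usual co-expression convention; both thresholds are configurable.
Negative correlations form edges, with the sign kept as an edge attribute.
Constant-profile genes cannot form edges and are retained as isolated
nodes. Degree centrality and k-core numbers (peeling decomposition; core
numbers are order-independent) annotate every node; hub ranking sorts by
(core number, degree, gene id).

The pipeline builds each comparison's network from the DEGs that belong to
at least one significantly enriched term; when no term is significant it
falls back to all DEGs of the comparison so the stage remains informative.

## Key-gene screen

Three criteria per DEG: magnitude (`|log2 ratio| > 1.5`, strictly —
exactly 1.5 fails), membership in a significant term of any namespace, and
membership in a curated known-mechanism list. `strict` mode (default)
requires all three, matching the conjunctive reading of the screening
procedure; `any_two` keeps magnitude mandatory and requires one of the
other two, for settings where the mechanism curation is unavailable or
partial (passing `mech=None` disables criterion 3 entirely). Network
degree and core number are annotations and tie-breakers, not gates — no
defensible numeric centrality cutoff exists for 5-sample networks.

## Synthetic data generator

The generator emulates the five-condition design: log-normal gene lengths
(median ≈ 1.5 kb, floored at 200 bp), log-normal baseline expression
(median ≈ 12 RPKM, ln-sd 1.0), per-library totals ≈ 5 million mapped reads
(2% log-normal jitter). Planted DE genes multiply their expected
expression by `2^lfc` (|lfc| uniform in [2, 4], random sign) in one
perturbed condition — the OGD condition by default — and the truth object
derives the planted signed fold change for *every* ordered condition pair,
so reversed comparisons are scored correctly. Planted co-expression
modules add a shared latent log2 profile: gene offset =
`sqrt(rho)*u_module + sqrt(1-rho)*eps_gene` with sd 2.0 per condition,
giving pairwise correlation ≈ rho. Module genes are drawn disjointly from
DE genes.

**Noise model.** `dispersion` is the usual negative-binomial alpha
(`Var = mu + alpha*mu^2`, 0.05 by default; 0 = Poisson). It is realised as
a per-gene gamma factor with mean 1 and variance alpha that is **shared
across libraries** (a gene-specific capture-efficiency effect), on top of
independent per-library Poisson shot noise. Marginally every count is
exactly NB(mu, alpha); between libraries the gene factor cancels. This is
a deliberate design: independent per-library overdispersion is
statistically indistinguishable from differential expression in a
replicate-free design (no test conditioned on two single counts can
separate them), so a generator meant to validate this pipeline must put
the overdispersion where a single-library design can carry it. The flip
side is stated plainly under Limitations.

Gene sets: 50 sets with sizes uniform in [10, 40]; 5 are constructed so
that 80% of their members are planted DE genes, the rest are uniform
draws. The synthetic mechanism list samples 30 planted DE genes plus 20
background genes. All draws flow through one seeded generator per artifact
(`numpy` PCG64 seeded with `(seed, stream)`), so identical configs give
bit-identical outputs.

## Benchmarks and what they show

`ogdrseq.benchmarks` holds the standing recovery experiments (reused by
the acceptance script):

- **DEG recovery** (2000 genes, 100 planted DE at 4–16 fold, depth 5e6,
  dispersion 0.05, no modules): sensitivity ≥ 0.9 with ≤ 5 false calls
  among the 1900 nulls. Modules are omitted because module latent profiles
  are genuine condition-dependence that would contaminate the false-positive
  count.
- **Enrichment recovery** (same data plus generated gene sets, 10 seeds):
  all 5 planted terms BH-significant and no spurious term in ≥ 9/10 runs.
  With 5 strong true terms and BH at 0.05, roughly 0.1–0.3 spurious terms
  per run are expected in the continuous-p limit; the discreteness of the
  hypergeometric null is what keeps realized runs clean.
- **Network recovery** (300 genes, 20 conditions, three 30-gene modules at
  rho = 0.95, no planted DE): ≥ 90% of edges intra-module. Twenty
  conditions exist purely to give correlation estimates power; the default
  5-condition design cannot support this measurement.
- **Null control** (nothing planted, dispersion 0, 20 seeds): average DEG
  calls ≤ 1 per 2000 genes. Dispersion 0 because that is the regime in
  which the exact test's calibration claim applies (see Limitations).

Problem sizes (2000 genes, 10 seeds, 20 extended conditions) were chosen
so each experiment carries clear statistical signal while the whole
benchmark battery runs in seconds.

Passing these benchmarks shows the machinery recovers structure that the
generator's assumptions encode. It does **not** show the pipeline is
calibrated on real RNA-seq with biological replicates-worth of variability
— see next section.

## Limitations

- The exact Poisson-ratio test is calibrated only under Poisson
  library-level noise. On data with genuine independent per-library
  overdispersion (e.g. biological replicates treated as conditions) it is
  strongly anticonservative: at alpha = 0.05-level dispersion the null
  log2-ratio sd is about `sqrt(2*alpha)/ln 2 ≈ 0.46`, so a few percent of
  null genes exceed the two-fold gate with overwhelming significance. This
  is a property of every replicate-free pipeline of this design, not an
  implementation artifact; conclusions from single-library designs rest on
  downstream validation (qPCR, perturbation), not on the FDR alone.
- The generator does not simulate reads, alignment, multi-mapping,
  isoforms, GC/length bias trends, or condition-correlated library
  composition effects.
- GO/KEGG semantics (DAG propagation, directional enrichment) are out of
  scope; gene sets are flat lists.
- The two-sided AC p-value is orientation-dependent (documented above);
  swapping treatment and reference can change borderline calls.
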