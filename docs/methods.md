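# Methods

## The analysis model

The package treats a reprogramming (or transdifferentiation) experiment as
an ordered, branching sample sheet: a shared unsorted prefix (day 0, day 3),
a successful branch (Thy-1⁻ at days 6/9, SSEA-1⁺ at days 12/16, iPSC
endpoint at day 18 in the default design) and an unsuccessful branch
(Thy-1⁺, SSEA-1⁻).  The *successful route* is the shared prefix followed by
the successful branch in day order; the *unsuccessful route* contains only
the sorted unsuccessful samples.  All genomic coordinates are BED-style
0-based half-open.

### Region annotation

The promoter of a gene is the `promoter_bp` (default 3000) bases strictly
upstream of its TSS, strand-aware and clamped at coordinate 0; the genebody
is the gene interval itself.  A peak overlapping ≥ 1 bp of a promoter is a
promoter peak regardless of genebody overlap (promoter > genebody >
intergenic precedence, mirroring the common annotation convention); ties
across genes break by smallest peak-to-TSS distance, then lexicographic
gene id — the gene-level tie-break is a declared choice, configurable in
the sense that the assignment function takes the catalog and window
explicitly.  Peaks on chromosomes absent from the catalog degrade to
intergenic with a logged warning so that partial catalogs remain usable.

### Quantification

Tag counts are scaled to a common library size (default 10⁷ tags, the usual
ChIP tag-directory convention; the constant is configurable).  FPKM is
`counts / ((length/10³)·(library/10⁶))`.  A gene/sample is *present* when
`(IP + 1)/(input + 1) ≥ 2` on library-normalized values **and** the IP
density is ≥ 0.5 normalized tags per kb of genebody.  The pseudocount
guards empty input bins; the density floor suppresses 2-vs-1-type calls on
near-empty genes and can be set to 0 for a pure fold rule.  Per-row
min–max normalization maps each row to [0, 1]; constant rows map to all
zeros (a declared degenerate-case decision — such rows carry no shape).

### Onset classification

For a boolean presence trajectory `p₀…p_T` along the successful route
(`p₀` = day 0):

* *onset at t* — `p` is false at 0…t−1 and true at t…T;
* *constitutive* — `p₀` true;
* *never* — all false;
* *unsustained* — anything else (gained-then-lost or gapped).

The four statuses partition pattern space; onset can never be called at
day 0.  Expression onset applies an FPKM > 1 gate and requires day-0 FPKM
≤ 1.  Because "above threshold at any time-point after day 0 till the end"
admits two readings, both are implemented: the existential default takes
the first crossing after day 0; the *sustained* variant takes the earliest
time-point from which expression stays above threshold through the end,
ignoring earlier transient crossings (this is deliberately weaker than the
deposition rule, which disqualifies any pre-onset enrichment).  Chromatin
accessibility uses the same machinery as expression.

Route exclusivity is true iff enrichment is absent at **every** sorted
unsuccessful-route time-point; the shared day-0/day-3 samples are excluded
because they precede sorting and cannot discriminate routes — an empty
unsuccessful vector therefore yields *undefined*, never *true*.

Precedence per gene is `lead = index(expression onset) − index(H3.3
onset)` in time-point steps along the successful route; positive lead means
deposition precedes transcription; the relation is undefined unless both
modalities have an onset.

### Clusters and differential expression

Differential expression is an endpoint log2 fold change with pseudocount 1:
`log2((end+1)/(D0+1))`, gated at |log2FC| ≥ 1 on the successful route.
Replicate-based testing is intentionally absent: the cluster semantics
depend only on direction of change.  With `down/flat/up` defined by the
same ±1 threshold on each route: Cluster I = down/down, II = down on the
successful route only (unsuccessful flat **or up**), III = up/up, IV = up
on the successful route only.  Genes without an unsuccessful-route
measurement stay unassigned.  Heatmap row order is cluster label first,
then average-linkage (Euclidean) leaf order within each cluster, with rows
pre-sorted by gene id so the ordering is permutation-invariant and fully
tied groups fall back to id order.

### Discovery

* **Loss ranking** — the loss score is the maximum decrease between
  consecutive successful-route time-points, floored at 0; ties break by
  total loss (sum of all positive consecutive decreases), then gene id.
  The metric operationalizes "depleted at any time-point" with a single
  sharp-drop statistic; the default table size is 250.
* **Activators** — H3.3 onset within {D6T−, D9T−, D12S+}, route-exclusive,
  expression rising on the successful route (log2FC ≥ 1) and flat on the
  unsuccessful one (|log2FC| < 1).
* **Marker enrichment** — upper-tail hypergeometric p per marker set
  (`scipy.stats.hypergeom.sf`), Benjamini–Hochberg across sets
  (`statsmodels`), score = −log10(adjusted p), significant at score ≥ 2.
  Marker sets travel as GMT text; the curated tissue panels of dedicated
  cell-type enrichment services are out of scope — sets are user-supplied.

## The synthetic generator

The generator plants a known answer for every stage.  Gene classes and
their piecewise-constant templates (transitions exactly at planted onsets,
which keeps the ground truth unambiguous):

| class | H3.3 (successful) | H3.3 (unsucc.) | FPKM (successful) | planted cluster |
|---|---|---|---|---|
| fibroblast / mesenchymal | present until loss point (D3–D9), then lost | retained | 20 → 4.25 at loss point | I or II (50/50) |
| pluripotency | absent until onset (D3–D12S+), then present | none (50%) or all | 0.8 → 6.2 at expression onset | IV if route-exclusive else III |
| epithelial | as pluripotency | always retained | as pluripotency | III |
| housekeeping | always present | always present | 50 throughout | none |
| neutral | never | never | 0.5 throughout | none |

Default class fractions: 0.15 / 0.10 / 0.20 / 0.10 / 0.15 / 0.30.  The
template levels are chosen so that the planted endpoint effect size is
|log2FC| = 2 under the pipeline's own pseudocounted metric
(`log2(6.2+1)−log2(0.8+1) = 2`, `log2(4.25+1)−log2(20+1) = −2`) and so that
up-gene baselines sit below the FPKM > 1 onset gate.  Expression onset
follows H3.3 onset by one time-point for a configurable fraction of onset
genes (default 0.9, reflecting that deposition almost always leads
transcription); the fraction is allocated **exactly** (a random subset of
the required size, not per-gene Bernoulli draws) so recovered precedence
fractions are comparable to the configuration without sampling slack.
Activator flags are restricted to route-exclusive pluripotency-class genes
with onsets in the D6–D12 window; epithelial genes always retain
unsuccessful-route enrichment, which makes the planted flag coincide with
the recovery predicate.

Noise model: IP/input tag counts are negative-binomial around their
expectations (`var = μ + d·μ²`, dispersion `d` default 0.05; `d = 0` yields
the expectation exactly), chosen because ChIP tag counts are overdispersed;
FPKM and accessibility carry multiplicative lognormal noise (natural-log sd
default 0.25); planted presence states can be flipped independently with
probability ε before count generation (default 0).  Input expectations are
20 tags/kb of genebody; enriched IP expectations are 6× input.  Library
sizes are reported as a constant 10⁷ mapped tags per sample — the
depth-equalized-library idealization, under which per-library normalization
preserves the planted fold exactly.  Without it, the enrichment-mass
difference between IP libraries would deflate recovered folds toward the
calling threshold in a composition-dependent way; depth equalization is
standard practice and keeps the planted truth exact.  All sampling is
driven by `numpy.random.default_rng` seeded from `(seed, stream)` pairs in
a fixed order, so bundles are byte-identical across runs and platforms.

What the generator does **not** emulate: read-level artifacts (fragment
size, GC bias, mappability), replicate structure, gradual (non-step)
trajectories, peak-calling uncertainty, and correlated noise across
samples.  Passing recovery tests therefore demonstrates the correctness of
the decision rules and their composition, not robustness to every mode of
real ChIP noise.

## Profiles

Meta-profiles average per-bp stepwise coverage in `n_bins` equal bins over
`[anchor − flank, anchor + flank)`; minus-strand windows are reversed so
upstream plots left.  The declared normalization is mean per-bp signal per
bin (coverage itself is expected on the normalized-tags scale).  Windows
running past a chromosome start are clamped and averaged over their covered
bases, with a logged count of clamped anchors — anchors are never silently
dropped.  Binned totals conserve the brute-force per-base mass exactly for
stepwise coverage.  Gene-set trajectories report mean ± standard error per
time-point along a route; plotting is left to the caller (tables are TSV).

## Numerical and interface choices

* TSV matrices are written with `repr`-precision floats, so
  read(write(M)) = M exactly; boolean/integer matrices are written as 0/1.
* Sample labels use ASCII `+`/`-` suffixes (`D6T-`, `D12S+`); iPSC is
  assigned day 18 and iHP day 8 to keep days integer and ordered.
* The manifest records tool version, config hash and effective parameter
  values, but no timestamps or timings (those go to the stderr log), so
  identical configs produce byte-identical bundles.
* Thresholds and their defaults: promoter 3000 bp, fold 2, density floor
  0.5 tags/kb, FPKM gate 1, |log2FC| gate 1, top-N 250, enrichment score 2,
  profile flank 2000 bp / 40 bins, library scale 10⁷.

## Known limitations

* The DE gate uses endpoints only; genes with non-monotone expression that
  return to baseline at the endpoint are unassigned even if transiently
  regulated.
* `min_density` interacts with gene length: very long genes with diffuse
  enrichment can drop below the floor despite a passing fold.
* The brute-force onset rule is O(T²) per gene in the worst case — fine for
  course lengths in the tens, not intended for hundreds of time-points.
* Marker-set enrichment assumes a closed universe supplied by the caller;
  results are sensitive to that choice, as with any hypergeometric test.
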