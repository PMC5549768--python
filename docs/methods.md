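# Methods

This note documents the models, conventions and numerical choices behind
`regland`, what the synthetic-data generator does and does not emulate,
and the package's known limitations.

## Coordinate and format conventions

All coordinates are 0-based, half-open, matching BED/bedGraph. Reads and
fragments are attributed to containers (restriction fragments, regions,
counting windows, genomic bins) by fixed rules stated per operation: reads
go to the restriction fragment containing their 5′ coordinate; fragments
and restriction fragments go to regions/bins by midpoint; a fragment
counts toward a summit window when it overlaps `[summit − h, summit + h)`
by at least one base. An interval ending exactly at a window start does
not overlap it. These boundary rules are load-bearing: the tests pin them.

## 4C-seq viewpoint processing

**Digestion.** Cut positions are `occurrence_start + cut_offset` for every
(possibly overlapping) forward-strand occurrence of the enzyme motif;
DpnII is modelled as `^GATC` (offset 0) and NlaIII as `CATG^` (offset 4).
Fragments are the intervals between consecutive cuts plus both flanks;
empty fragments from cuts at position 0 or the sequence end are dropped.
The fragment coordinate system is built from the primary enzyme only —
the secondary enzyme belongs to library construction, not to the
coordinate system.

**Smoothing.** An 11-fragment centered running mean. At chromosome ends
the window shrinks to the available fragments rather than NA-padding, so
output length equals input length. The implementation accumulates window
terms left-to-right so it is bitwise identical to a naive per-position
recomputation — this makes the oracle test exact rather than
tolerance-based.

**Viewpoint exclusion.** The viewpoint fragment and one fragment on each
side are zeroed before smoothing and excluded from all downstream sums.
This is standard handling of self-ligation/undigested artifacts; the
exclusion half-width is a parameter (`exclude_flank`).

**Normalization.** The smoothed signal is divided by its sum over the
fragments whose midpoints lie in a reference region (for the locus
analysis: the span of the five TADs around it, at real scale
chr10:62,880,000–70,720,000). Signal is therefore expressed as fractions
summing to 1 over the region; the operation is scale invariant and
idempotent, and a region containing no signal is an error rather than a
silent division by zero. A read-count-preserving constant was deliberately
not used: all downstream statistics (per-region distributions, TAD
ratios) are ratios of fractions and do not depend on one.

**Distributions and TAD ratio.** Per-region fractions are sums of
normalized signal over fragments with midpoints in each region; the
regions must cover all non-excluded signal (uncovered fraction reported
in the error otherwise). The TAD ratio is the arithmetic mean over
replicates of fraction(a)/fraction(b). For a viewpoint inside a TAD with
intra-TAD contact enrichment, the neighbour/own ratio sits well below 1;
moving the shared boundary toward the viewpoint monotonically reallocates
fraction from the viewpoint's region to the neighbour, which is the
mechanism behind boundary-repositioning analyses.

## Directionality index and boundaries

DI follows the signed chi-square form: per bin, `A` and `B` are contact
sums to bins within the window up/downstream (windows truncate at matrix
edges), `E = (A+B)/2`, and `DI = sign(B−A)·((A−E)²/E + (B−E)²/E)`, with
`DI = 0` when `A = B` or `E = 0`. DI is antisymmetric under coordinate
reversal and its magnitude scales with sequencing depth — only its sign
is scale free, and the tests assert exactly that. The window defaults to
2 Mb at real scale; on the 1:4 toy locus the proportional 500 kb
(12 bins of 40 kb) is used.

Boundary suggestion is deliberately simple: a boundary is emitted where
the track passes from a bin at or below −threshold to a bin at or above
+threshold with at most `max_zone_bins` low-|DI| bins between, and the
low-DI run is reported as the transition zone (the boundary lands at the
bin edge midway through it). This replaces HMM-based TAD calling, which
is out of scope; on synthetic block matrices with enrichment 4 it
recovers all block edges within 2 bins in ≥ 18/20 seeds (the acceptance
script measures this each run). CTCF sites are clustered by
single-linkage chaining (gap ≤ 10 kb, ≥ 3 sites by default, both
configurable); repositioning moves a named boundary to the midpoint of
the nearest qualifying cluster within a search radius, ties broken toward
the lower coordinate, adjacent TADs resized with no gap or overlap. The
midpoint (rather than a cluster edge) is a declared convention.

## ATAC-seq differential accessibility

**Fragment filter.** Fragments with length strictly below 100 bp are
kept — the strict inequality is intentional and tested at the boundary.

**Summit calling.** A simplified caller standing in for MACS2-scale
machinery: fragment midpoints are counted in a 200-bp window evaluated
every 5 bp; the local background rate is the maximum of the
chromosome-wide rate and 1-kb/10-kb local rates (so broad enrichment is
not itself a peak); one-sided Poisson p-values are BH-corrected over all
tested positions and positions with q ≤ 0.01 form enriched regions, each
contributing its count-maximal position (leftmost on ties) as a summit.
The 5-bp evaluation grid trades sub-summit precision (irrelevant under
50-bp merging) for an order-of-magnitude smaller working set. Positions
whose count falls below a conservative normal-approximation bound on the
achievable p-value are skipped (their p is set to 1); since BH-adjusted
q ≥ p, no discovery can be lost to this shortcut.

**Merging.** Summits of all samples closer than 50 bp chain transitively
into one group (single linkage — the only order-independent reading);
summits exactly 50 bp apart stay separate. Each group is represented by
its lowest-q summit, ties to the left. Representatives of adjacent groups
are automatically ≥ 50 bp apart, so the operation is idempotent.

**Counting and size factors.** Fragments overlapping
`[summit − 250, summit + 250)` are counted per sample (the 250-bp
half-width covers a nucleosome-free region and is configurable). Size
factors are median-of-ratios over 10-kb bin counts; bins with a zero in
any sample are excluded because the geometric mean is undefined there.

**Dispersion.** NB2 (`var = μ + αμ²`). The per-summit method-of-moments
estimator matches moments within each condition and sums over conditions,

    α̂ = Σ_g (n_g−1)(s²_g − m_g) / Σ_g (n_g−1)(m_g² − s²_g/n_g),

which stays unbiased when condition means differ by orders of magnitude
(a deleted element) — dividing pooled variance by the squared grand mean
would roughly double α̂ there. The denominator subtracts `s²/n` so that
`E[m²]`-bias is removed; with very few summits the fallback trend is the
mean (not the median, which sits low for chi-square-distributed
estimates) of the clipped raw values. A trend `α(μ) = a₀ + a₁/μ` is fit
by least squares across summits when at least 10 are available, and every
raw estimate is shrunk toward the trend with weight 0.7 — with duplicate
experiments a per-summit estimate alone is hopelessly unstable. Estimates
are floored at 1e-8. In the pipeline, dispersions are estimated once from
all samples (variance pooled within each genotype×region condition,
9 residual df for the default design) and reused by every contrast.

**Wald test.** Per summit, an NB log-link GLM with intercept + condition
indicator and log size factors as offsets, fitted by IRLS (Fisher weights
`μ/(1+αμ)`, linear predictor clipped at ±30 natural-log units, 50
iterations, tolerance 1e-10; the fit is cross-checked against an
independent GLM implementation in the tests). The reported log2
fold-change is log2(test/ref); the Wald statistic is log2FC/SE with a
two-sided standard-normal p-value, BH adjustment across testable summits
reported alongside. Summits with zero counts in every sample are marked
untestable, not dropped. The significance flag uses raw p < 0.05,
matching the convention of starring per-element barplots; adjusted values
are in the output for any stricter use.

## Synthetic-data generator

The generator emulates the study design, not raw sequencing: no reads,
base-call errors, PCR duplicates, alignment or mappability are modelled,
and trans-chromosomal signal does not exist on a one-chromosome locus.

* **Locus**: 2 Mb, five 400-kb TADs (−2, −1, Krox20, +1, +2); promoter at
  1.1 Mb with elements A/B/C ~54/41/36 kb upstream and NE ~27 kb
  downstream — the real inter-element distances at 1:4 scale. A CTCF
  cluster sits between the Nrbf2-side viewpoint and element A, where the
  repositioned boundary belongs.
* **ATAC**: background fragment midpoints uniform at 0.01 fragments/bp
  (Poisson); each element adds an NB-distributed fragment total with mean
  `multiplier × 200` and normal midpoints (sd = element width/4). The
  multiplier table encodes the design: promoter open everywhere; A open
  in r3/r5; B in r5/posterior; C in r3/r5; NE mostly r3. ΔC deletes C and
  halves A in r3 and B in r5 (the potentiation effect); ΔA deletes A and
  changes nothing else. Between-replicate dispersion α = 0.05 matches the
  downstream NB model; fragment lengths are truncated normal
  (mean 60, sd 15 bp), so ~0.4% of fragments exceed the 100-bp filter —
  the filter is exercised with a real, nonzero rejection rate. The
  200-fragments-per-unit depth makes counting noise small relative to
  biological noise, which is where a real experiment with a few thousand
  cells per dissection sits.
* **4C**: per-fragment multinomial with probability ∝
  `max(distance, 2 kb)^(−1)`, times 5 for fragments in the viewpoint's
  TAD; counts sum exactly to the library size (500,000 by default).
* **Hi-C**: expected count `200 · (|i−j|+1)^(−1)`, times 4 within a TAD,
  Poisson noise, symmetric by construction; 40-kb bins.
* **Reproducibility**: each sample's stream is seeded by hashing
  (seed, stage, genotype, region, replicate) with SHA-256, so samples are
  mutually independent but the whole experiment is a pure function of one
  integer. Identical inputs give byte-identical outputs.

Passing tests on these data show that the pipeline recovers the
statistical structure it assumes (NB counts around design means, power-law
contacts with block enrichment); they do not show robustness to
mappability artifacts, copy-number differences, fragment-length biases or
cross-contamination between dissections, none of which are generated.

## Power of the headline contrast, and other limitations

With duplicate samples, between-replicate dispersion α = 0.05 and a true
2-fold reduction, the asymptotic standard error of the log2 fold-change is
`√(α + 1/(2μ₁) + 1/(2μ₂))/ln 2 ≈ 0.33`, giving a Wald noncentrality of
~3.1 and a two-sided detection rate at p < 0.05 of ~86% even when the true
dispersion is known exactly; plug-in dispersion estimation costs a few
more points. The end-to-end detection rate of the halved element-A signal
reported by `scripts/acceptance.py` (~0.82–0.86) sits at this statistical
ceiling — it is a property of the 2-replicate design at this effect size
and noise level, not an implementation loss. Unaffected elements are
flagged at ~6–8% per contrast, close to the nominal 5% with the residual
excess coming from small-sample Wald anticonservatism, which is shared by
any plug-in NB Wald procedure at n = 2.

Other limitations: the summit caller is not MACS2 (no fragment-model
estimation, no paired-end pileup modes); Hi-C matrices are used as given
(no ICE/balancing, no loop calling); TAD calling is threshold-based, not
HMM-based; 4C normalization is fraction-based rather than the original
pipeline's (unpublished) constant; per-dissection cell-number differences
are not modelled. Problem sizes in the test-suite and acceptance script
(2-Mb locus, 100-seed Monte Carlo, 1000-summit calibrations) were chosen
as the smallest at which the Monte Carlo bounds are meaningful.
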