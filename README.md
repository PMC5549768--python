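# regland

Regulatory-landscape analysis of a multi-enhancer developmental locus,
modelled on the mouse *Krox20*/*Egr2* hindbrain locus: a promoter under the
control of several distant enhancers (the autoregulatory element A, the
r5 initiator B, the potentiator C, and a newly found element NE) inside a
topologically associating domain (TAD). The package implements the three
computational analyses used to characterise such a locus, plus a
synthetic-locus generator that emulates the experimental design so every
stage can be exercised and validated without sequencing data.

**Who it is for:** computational biologists analysing viewpoint-based
chromosome-conformation (4C-seq) data, binned Hi-C matrices, and ATAC-seq
chromatin-accessibility experiments on a single locus, who want a small,
fully-tested, reproducible pipeline rather than a genome-scale framework.

## What it computes

**4C-seq viewpoint processing** (`regland.fourc`). The chromosome is
digested in silico with the primary restriction enzyme (DpnII, `GATC`;
NlaIII `CATG` supported as secondary). Reads are translated to restriction
fragments by their 5′ coordinate, smoothed with an 11-fragment centered
running mean, and normalized to a reference region (e.g. the five TADs
around the locus) so that the signal there sums to 1. Per-region signal
fractions and TAD signal ratios — mean over replicates of
fraction(region&nbsp;a)/fraction(region&nbsp;b) — quantify how strongly a
viewpoint's contacts are confined to its own TAD.

**Directionality index and TAD boundaries** (`regland.tads`). For bin *i*
of a binned contact matrix, with *A* the contact sum to bins within a
window upstream, *B* downstream and *E* = (*A*+*B*)/2,

```
DI(i) = sign(B − A) · ((A−E)²/E + (B−E)²/E)
```

Candidate boundaries are thresholded −/+ sign changes of the DI track;
a boundary in a fuzzy transition zone can be repositioned onto the
midpoint of a nearby cluster of CTCF binding sites (single-linkage
clustering with a maximum gap).

**ATAC-seq differential accessibility** (`regland.atac`). Sub-100-bp
fragments (transcription-factor-protected DNA) are kept; accessibility
summits are called per sample against a Poisson local background,
merged across all samples at 50 bp keeping the lowest-q summit per group;
fragments are counted in a window around each merged summit; library size
factors come from median-of-ratios on 10-kb genomic bins; and each summit
is tested for a genotype effect with a negative-binomial Wald test
(log-link GLM fitted by IRLS, NB2 variance μ + αμ², per-summit dispersion
by method of moments shrunk toward a mean–dispersion trend; statistic =
log2FC/SE, two-sided normal p, BH-adjusted p reported alongside).

**Synthetic locus** (`regland.simulate`). A 2-Mb toy chromosome (1:4 scale
of the real locus) with five TADs (−2, −1, Krox20, +1, +2) and elements
A/B/C/NE/promoter. It generates ATAC fragment sets for a genotype
(WT, ΔC, ΔA) × dissected region (r3, r5, posterior) × replicate design
with per-element accessibility multipliers, 4C contact counts with
power-law distance decay and intra-TAD enrichment, and Poisson Hi-C
matrices with TAD block structure — all driven by a single integer seed.

## Worked example

Simulate the accessibility experiment, run the ΔC-vs-WT contrast on the
r3 dissection, and print the per-element results:

```python
import regland
from regland import simulate, workflows

model = regland.default_locus()
samples = simulate.simulate_atac_experiment(model, simulate.AccessibilitySpec(seed=1))
result = workflows.differential_accessibility(
    samples, model.chrom_length, [("dC_r3", "WT_r3")], model=model)
t = result.tests
print(t.loc[t.element != "", ["element", "summit", "log2FoldChange",
                              "lfcSE", "pvalue", "significant"]].to_string(index=False))
```

```
 element  summit  log2FoldChange    lfcSE       pvalue  significant
       A 1045750       -1.428567 0.284237 5.008831e-07         True
       B 1059235       -0.064823 0.380592 8.647573e-01        False
       C 1064250       -7.113487 0.457813 1.919902e-54         True
promoter 1100015       -0.183529 0.318419 5.643611e-01        False
      NE 1126755       -0.216023 0.295009 4.640101e-01        False
```

Element C (deleted in ΔC) collapses to background (log2FC ≈ −7); element A,
whose simulated intensity is halved in ΔC-r3 through the loss of its
potentiator, is significantly reduced (log2FC ≈ −1.4, p ≈ 5×10⁻⁷); the
promoter and the untouched elements are not.

The 4C side of the analysis, for the promoter viewpoint:

```python
from regland import fourc
seq = simulate.random_chromosome(model.chrom_length, seed=7)
fragmap = fourc.digest(seq, chrom=model.chrom_name)
regions = fourc.RegionSet.from_pairs([(t.label, t.start, t.end) for t in model.tads])
vp = model.viewpoints["promoter"]
counts = {rep: simulate.simulate_4c_counts(
              model, fragmap, simulate.FourCSpec(viewpoint=vp, seed=rep))
          for rep in (1, 2)}
dists = workflows.fourc_viewpoint_analysis(fragmap, counts, "promoter", vp, regions)
print({k: round(v, 3) for k, v in dists[0].fractions.items()})
print("ratio -1/Krox20:", round(fourc.tad_ratio(dists, "-1", "Krox20"), 4))
```

```
{'-2': 0.008, '-1': 0.016, 'Krox20': 0.934, '+1': 0.03, '+2': 0.011}
ratio -1/Krox20: 0.0173
```

93% of the promoter's normalized 4C signal stays in its own TAD; the
−1/Krox20 ratio far below 1 is the signature of TAD confinement.

The same analyses are available from the shell via the `regland` CLI
(`simulate`, `digest`, `fourc`, `hic-di`, `atac`, `report` subcommands);
every run writes a `run_manifest.json` with output checksums so
deterministic stages are reproducible byte for byte.

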