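"""End-to-end analysis workflows tying the modules together.

These functions are the library-level equivalents of the CLI subcommands:
a 4C distribution/ratio analysis for one viewpoint over a region set, and
the full ATAC differential-accessibility pipeline (filter -> summits ->
merge -> count -> size factors -> dispersion -> NB Wald contrasts) with
element annotation of the resulting summits.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import atac, fourc
from .locus import LocusModel


# ---------------------------------------------------------------------------
# 4C
# ---------------------------------------------------------------------------
def fourc_viewpoint_analysis(
    fragmap: fourc.RestrictionFragmentMap,
    counts_per_replicate: dict,
    viewpoint_name: str,
    viewpoint_position: int,
    regions: fourc.RegionSet,
    window: int = fourc.DEFAULT_WINDOW,
    exclude_flank: int = 1,
) -> list[fourc.SignalDistribution]:
    """Smooth, normalize and region-distribute one viewpoint's replicates.

    ``counts_per_replicate`` maps replicate id -> per-fragment raw counts.
    Profiles are normalized over the span of ``regions`` (the analysis
    region), so per-region fractions sum to 1.
    """
    distributions = []
    span = regions.span
    for rep, counts in counts_per_replicate.items():
        profile = fourc.viewpoint_profile(
            viewpoint_name, fragmap, counts, viewpoint_position,
            exclude_flank=exclude_flank, window=window,
        )
        profile = fourc.normalize_to_region(profile, span)
        distributions.append(fourc.region_distribution(profile, regions, replicate=rep))
    return distributions


def distribution_table(distributions: list[fourc.SignalDistribution]) -> pd.DataFrame:
    rows = [
        {
            "viewpoint": d.viewpoint_name,
            "replicate": d.replicate,
            "region": label,
            "fraction": frac,
        }
        for d in distributions
        for label, frac in d.fractions.items()
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ATAC
# ---------------------------------------------------------------------------
@dataclass
class ATACResult:
    catalog: atac.SummitCatalog
    counts: atac.CountTable
    size_factors: pd.Series
    dispersions: np.ndarray
    tests: pd.DataFrame  # concatenated Wald results, one block per contrast
    annotation: pd.DataFrame  # summit -> element map


def annotate_summits(
    catalog: atac.SummitCatalog, model: LocusModel, radius: int = 500
) -> pd.DataFrame:
    """Map each element of the locus to its nearest catalog summit.

    Elements without a summit within ``radius`` bp get a null row; each
    summit row carries the element name (or '' for unannotated summits).
    """
    element_of = np.full(len(catalog), "", dtype=object)
    for el in model.elements:
        if len(catalog) == 0:
            continue
        dist = np.abs(catalog.positions - el.center)
        best = int(np.argmin(dist))
        if dist[best] <= radius:
            element_of[best] = el.name
    return pd.DataFrame(
        {"summit": catalog.positions, "element": element_of}
    )


def differential_accessibility(
    samples: list[atac.FragmentSet],
    chrom_length: int,
    contrasts: list[tuple[str, str]],
    model: LocusModel | None = None,
    max_fragment_len: int = atac.MAX_FRAGMENT_LEN,
    q_threshold: float = 0.01,
    half_width: int = atac.DEFAULT_HALF_WIDTH,
    annotation_radius: int = 500,
) -> ATACResult:
    """Run the full differential-accessibility pipeline.

    ``contrasts`` are (condition_test, condition_ref) pairs over the
    ``condition`` labels of the samples; each needs two replicates per
    condition.  Summits are called per sample after the sub-100-bp
    filter, merged at 50 bp into one catalog, counted in every sample,
    normalized with 10-kb-bin size factors, and tested per contrast with
    the NB Wald test (dispersions estimated on the samples of that
    contrast).
    """
    filtered = [filter_fragments_checked(fs, max_fragment_len) for fs in samples]
    all_summits: list[atac.Summit] = []
    for fs in filtered:
        all_summits.extend(atac.call_summits(fs, chrom_length, q_threshold=q_threshold))
    catalog = atac.merge_summits(all_summits)
    table = atac.count_at_summits(catalog, filtered, half_width=half_width)
    factors = atac.size_factors(filtered, chrom_length)

    # Dispersions are estimated once across all samples (variance pooled
    # within every condition) -- per-contrast estimates from 2 vs 2
    # replicates alone are far too unstable.
    dispersions = atac.estimate_dispersion(table, factors)
    blocks = []
    for contrast in contrasts:
        sel = table.conditions.isin(contrast)
        sub = atac.CountTable(
            counts=table.counts.loc[:, sel.to_numpy()],
            conditions=table.conditions[sel],
            half_width=table.half_width,
        )
        res = atac.wald_test(sub, factors, dispersions, contrast)
        blocks.append(res)
    tests = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame()
    annotation = (
        annotate_summits(catalog, model, radius=annotation_radius)
        if model is not None
        else pd.DataFrame({"summit": catalog.positions, "element": ""})
    )
    if not tests.empty:
        tests = tests.merge(annotation, on="summit", how="left")
    return ATACResult(
        catalog=catalog,
        counts=table,
        size_factors=factors,
        dispersions=dispersions,
        tests=tests,
        annotation=annotation,
    )


def filter_fragments_checked(fs: atac.FragmentSet, max_len: int) -> atac.FragmentSet:
    out = atac.filter_fragments(fs, max_len)
    if len(out) == 0:
        raise ValueError(f"sample {fs.sample_id!r}: no fragments pass the length filter")
    return out


def element_count_table(result: ATACResult) -> pd.DataFrame:
    """Normalized fragment counts per annotated element per sample.

    The per-element barplot data: size-factor-normalized counts at the
    summit annotated to each element, one row per element x sample.
    """
    ann = result.annotation
    ann = ann[ann["element"] != ""]
    norm = result.counts.counts / result.size_factors
    rows = []
    for _, r in ann.iterrows():
        for sample in norm.columns:
            rows.append(
                {
                    "element": r["element"],
                    "summit": r["summit"],
                    "sample": sample,
                    "condition": result.counts.conditions[sample],
                    "normalized_count": float(norm.loc[r["summit"], sample]),
                }
            )
    return pd.DataFrame(rows)
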