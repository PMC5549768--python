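"""Synthetic data for the toy regulatory locus.

Generates, with the statistical structure the downstream analyses assume:

* paired-end ATAC fragment sets for a genotype x dissected-region x
  replicate design, with per-element accessibility multipliers and
  negative-binomial between-replicate noise;
* per-restriction-fragment 4C contact counts from a viewpoint with
  power-law distance decay and intra-TAD enrichment;
* a binned Hi-C contact matrix with TAD block structure and Poisson noise;
* a random chromosome sequence for in-silico digestion.

Reproducibility: every sample derives its own random stream by hashing
the global seed together with the sample coordinates (genotype, region,
replicate), so samples are independent but the whole experiment is a pure
function of one integer seed.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .atac import FragmentSet
from .fourc import RestrictionFragmentMap
from .locus import LocusModel
from .tads import ContactMatrix

GENOTYPES = ("WT", "dC", "dA")
REGIONS = ("r3", "r5", "post")


def derive_rng(seed: int, *keys) -> np.random.Generator:
    """Independent random stream for (seed, *keys), stable across runs."""
    tag = ":".join([str(seed), *map(str, keys)])
    digest = hashlib.sha256(tag.encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


# ---------------------------------------------------------------------------
# ATAC fragments
# ---------------------------------------------------------------------------
def default_element_intensity() -> dict[tuple[str, str, str], float]:
    """Accessibility multipliers (element, genotype, region) of the design.

    Wild-type pattern: the promoter is open everywhere; A is open in r3/r5
    (autoregulatory element); B in r5/posterior; C in r3/r5 (potentiator);
    NE mostly in r3.  The dC genotype removes C and halves A in r3 and B
    in r5 (the potentiation effect); dA removes A and changes nothing
    else (the null result for elements B and C).
    """
    wt = {
        "promoter": {"r3": 4.0, "r5": 4.0, "post": 4.0},
        "A": {"r3": 6.0, "r5": 6.0, "post": 0.3},
        "B": {"r3": 0.5, "r5": 6.0, "post": 6.0},
        "C": {"r3": 6.0, "r5": 6.0, "post": 0.5},
        "NE": {"r3": 6.0, "r5": 2.0, "post": 2.0},
        "ctcf_cluster": {"r3": 2.0, "r5": 2.0, "post": 2.0},
    }
    table: dict[tuple[str, str, str], float] = {}
    for element, per_region in wt.items():
        for region, value in per_region.items():
            table[(element, "WT", region)] = value
            table[(element, "dC", region)] = value
            table[(element, "dA", region)] = value
    for region in REGIONS:
        table[("C", "dC", region)] = 0.0  # element C deleted
        table[("A", "dA", region)] = 0.0  # element A deleted
    table[("A", "dC", "r3")] = wt["A"]["r3"] / 2.0  # potentiation lost
    table[("B", "dC", "r5")] = wt["B"]["r5"] / 2.0
    return table


@dataclass
class AccessibilitySpec:
    """Parameters of the synthetic ATAC experiment.

    ``background_rate`` is in fragments per bp; ``unit_fragments`` is the
    expected fragment count of an element at intensity multiplier 1;
    per-element totals are NB distributed with ``var = mu + dispersion *
    mu**2``.  Fragment lengths are truncated normal (mean 60, sd 15 bp by
    default) so most, but not all, pass the < 100 bp filter.
    """

    background_rate: float = 0.01
    unit_fragments: float = 200.0
    element_intensity: dict[tuple[str, str, str], float] = field(
        default_factory=default_element_intensity
    )
    fragment_length_mean: float = 60.0
    fragment_length_sd: float = 15.0
    dispersion: float = 0.05
    replicates: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for key, v in self.element_intensity.items():
            if v < 0:
                raise ValueError(f"negative intensity multiplier for {key}")


def _nb_total(rng: np.random.Generator, mean: float, alpha: float) -> int:
    if mean <= 0:
        return 0
    if alpha <= 0:
        return int(rng.poisson(mean))
    # gamma-Poisson mixture: shape 1/alpha, scale alpha*mean
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    return int(rng.poisson(lam))


def simulate_atac_fragments(
    model: LocusModel,
    spec: AccessibilitySpec,
    genotype: str,
    region: str,
    replicate: int,
) -> FragmentSet:
    """Simulate one sample's ATAC fragments.

    Background fragment midpoints are uniform over the chromosome at
    ``background_rate`` per bp (Poisson total).  Each element adds an
    NB-distributed number of fragments with mean ``multiplier *
    unit_fragments`` and midpoints normal around the element center
    (sd = width / 4).  A deleted element (multiplier 0) emits background
    only.  Fully deterministic given (spec.seed, genotype, region,
    replicate).
    """
    known = {g for (_e, g, _r) in spec.element_intensity}
    known_regions = {r for (_e, _g, r) in spec.element_intensity}
    if genotype not in known:
        raise KeyError(f"unknown genotype {genotype!r} (have {sorted(known)})")
    if region not in known_regions:
        raise KeyError(f"unknown region {region!r} (have {sorted(known_regions)})")
    rng = derive_rng(spec.seed, "atac", genotype, region, replicate)

    mids = []
    n_bg = rng.poisson(spec.background_rate * model.chrom_length)
    mids.append(rng.integers(0, model.chrom_length, size=n_bg))
    for el in model.elements:
        mult = spec.element_intensity.get((el.name, genotype, region), 0.0)
        n_el = _nb_total(rng, mult * spec.unit_fragments, spec.dispersion)
        if n_el:
            pos = rng.normal(el.center, max(el.width / 4.0, 1.0), size=n_el)
            mids.append(np.clip(np.rint(pos), 0, model.chrom_length - 1).astype(np.int64))
    mid = np.concatenate(mids).astype(np.int64)

    lengths = rng.normal(spec.fragment_length_mean, spec.fragment_length_sd, size=mid.size)
    lengths = np.clip(np.rint(lengths), 10, None).astype(np.int64)
    starts = np.clip(mid - lengths // 2, 0, None)
    ends = np.minimum(starts + lengths, model.chrom_length)
    starts = np.minimum(starts, ends - 1)
    return FragmentSet(
        sample_id=f"{genotype}_{region}_rep{replicate}",
        chrom=model.chrom_name,
        starts=starts,
        ends=ends,
        condition=f"{genotype}_{region}",
        metadata={"genotype": genotype, "region": region, "replicate": replicate},
    )


def simulate_atac_experiment(
    model: LocusModel,
    spec: AccessibilitySpec,
    genotypes: tuple[str, ...] = GENOTYPES,
    regions: tuple[str, ...] = REGIONS,
) -> list[FragmentSet]:
    """All genotype x region x replicate samples of the design."""
    return [
        simulate_atac_fragments(model, spec, g, r, k)
        for g in genotypes
        for r in regions
        for k in range(1, spec.replicates + 1)
    ]


# ---------------------------------------------------------------------------
# 4C contact counts
# ---------------------------------------------------------------------------
@dataclass
class FourCSpec:
    """Parameters of the synthetic 4C library for one viewpoint."""

    viewpoint: int
    decay_exponent: float = 1.0
    intra_tad_factor: float = 5.0
    total_reads: int = 500_000
    min_distance: float = 2_000.0  # decay clamp near the viewpoint
    seed: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError("total_reads must be positive")
        if self.decay_exponent <= 0:
            raise ValueError("decay_exponent must be positive")
        if self.intra_tad_factor < 1:
            raise ValueError("intra_tad_factor must be >= 1")


def simulate_4c_counts(
    model: LocusModel, fragmap: RestrictionFragmentMap, spec: FourCSpec
) -> np.ndarray:
    """Multinomial per-fragment 4C counts from one viewpoint.

    Fragment probabilities are proportional to ``max(distance,
    min_distance) ** -decay_exponent``, multiplied by ``intra_tad_factor``
    for fragments in the viewpoint's TAD.  Counts sum to ``total_reads``.
    """
    if not (0 <= spec.viewpoint < fragmap.span_end):
        raise ValueError(
            f"viewpoint {spec.viewpoint} outside fragment map span "
            f"[0, {fragmap.span_end})"
        )
    rng = derive_rng(spec.seed, "4c", spec.viewpoint)
    mids = fragmap.midpoints
    dist = np.maximum(np.abs(mids - spec.viewpoint), spec.min_distance)
    weights = dist.astype(float) ** (-spec.decay_exponent)
    vp_tad = model.tad_of(spec.viewpoint)
    if vp_tad is not None:
        tad = model.tad(vp_tad)
        weights[(mids >= tad.start) & (mids < tad.end)] *= spec.intra_tad_factor
    return rng.multinomial(spec.total_reads, weights / weights.sum())


def random_chromosome(length: int, seed: int = 0, gc: float = 0.42) -> str:
    """Random chromosome sequence (for in-silico digestion of the toy locus)."""
    rng = derive_rng(seed, "sequence", length)
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=probs))


# ---------------------------------------------------------------------------
# Hi-C matrices
# ---------------------------------------------------------------------------
@dataclass
class HiCSpec:
    """Parameters of the synthetic binned Hi-C matrix."""

    bin_size: int = 40_000
    decay_exponent: float = 1.0
    tad_enrichment: float = 4.0
    mean_depth: float = 200.0  # expected reads at distance 0, outside TADs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.tad_enrichment < 1:
            raise ValueError("tad_enrichment must be >= 1")


def simulate_hic(model: LocusModel, spec: HiCSpec) -> ContactMatrix:
    """Symmetric Poisson contact matrix with distance decay and TAD blocks.

    The expected count of bin pair (i, j) is ``mean_depth * (|i-j|+1) **
    -decay_exponent``, multiplied by ``tad_enrichment`` when both bin
    midpoints fall in the same TAD.
    """
    if model.chrom_length < 2 * spec.bin_size:
        raise ValueError("chromosome must span at least two Hi-C bins")
    rng = derive_rng(spec.seed, "hic")
    n = model.chrom_length // spec.bin_size
    centers = (np.arange(n) + 0.5) * spec.bin_size
    tad_labels = np.array(
        [model.tad_of(int(c)) or "" for c in centers], dtype=object
    )
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mean = spec.mean_depth * (np.abs(i - j) + 1.0) ** (-spec.decay_exponent)
    same = (tad_labels[i] == tad_labels[j]) & (tad_labels[i] != "")
    mean = np.where(same, mean * spec.tad_enrichment, mean)
    upper = rng.poisson(np.triu(mean))
    mat = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
    return ContactMatrix(
        chrom=model.chrom_name, bin_size=spec.bin_size, matrix=mat.astype(float)
    )
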