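"""4C-seq viewpoint signal processing.

Circular chromosome conformation capture (4C-seq) measures the contact
frequency of one anchored restriction fragment (the viewpoint) with every
other restriction fragment of the chromosome.  The processing chain
implemented here follows the standard viewpoint pipeline:

1. in-silico digestion of the chromosome with the primary restriction
   enzyme (DpnII/GATC by default) into a :class:`RestrictionFragmentMap`;
2. translation of aligned reads/intervals to restriction fragments
   (assignment by 5' coordinate);
3. smoothing with an 11-fragment centered running mean;
4. normalization of the smoothed signal to a reference region (e.g. the
   five TADs surrounding the locus), expressed as fractions summing to 1;
5. per-region signal-distribution statistics and TAD signal ratios
   (e.g. the "-1" over "Krox20" TAD ratio averaged over replicates).

Coordinates are 0-based half-open throughout; the fragment containing a
read's 5' coordinate receives the read.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_MOTIF = "GATC"  # DpnII, cuts at motif start (^GATC)
SECONDARY_MOTIF = "CATG"  # NlaIII, cuts after the motif (CATG^)
DEFAULT_WINDOW = 11

_SEQ_ALPHABET = frozenset("ACGTN")
_MOTIF_ALPHABET = frozenset("ACGT")


# ---------------------------------------------------------------------------
# restriction fragment map
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RestrictionFragmentMap:
    """Ordered tiling of a chromosome into restriction fragments.

    ``starts``/``ends`` tile ``[0, span_end)`` without gaps or overlaps;
    every internal boundary is a cut position of ``enzyme_motif`` at
    ``cut_offset`` bases into the motif.
    """

    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    enzyme_motif: str
    cut_offset: int

    @property
    def n_fragments(self) -> int:
        return len(self.starts)

    @property
    def span_end(self) -> int:
        return int(self.ends[-1])

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2

    def fragment_containing(self, position: int) -> int:
        """Index of the fragment whose half-open interval contains ``position``."""
        if not (0 <= position < self.span_end):
            raise ValueError(
                f"position {position} outside fragment map span [0, {self.span_end})"
            )
        return int(np.searchsorted(self.starts, position, side="right") - 1)


def digest(
    sequence: str, motif: str = DEFAULT_MOTIF, cut_offset: int = 0, chrom: str = "chr"
) -> RestrictionFragmentMap:
    """In-silico restriction digestion of ``sequence``.

    Cut positions are ``occurrence_start + cut_offset`` for every (possibly
    overlapping) occurrence of ``motif`` on the forward strand.  Fragments
    are the intervals between consecutive cuts plus the two flanks;
    zero-length fragments (a cut at position 0 or at the sequence end) are
    dropped.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if not motif:
        raise ValueError("motif must be non-empty")
    if not (0 <= cut_offset <= len(motif)):
        raise ValueError(f"cut_offset {cut_offset} outside [0, {len(motif)}]")
    seq = sequence.upper()
    bad = set(seq) - _SEQ_ALPHABET
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
    mot = motif.upper()
    if set(mot) - _MOTIF_ALPHABET:
        raise ValueError("ambiguity codes in restriction motifs are unsupported")

    cuts = []
    pos = seq.find(mot)
    while pos != -1:
        cuts.append(pos + cut_offset)
        pos = seq.find(mot, pos + 1)  # overlapping occurrences count

    boundaries = [0] + sorted(set(cuts)) + [len(seq)]
    starts, ends = [], []
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        if b > a:  # empty flank/fragment dropped
            starts.append(a)
            ends.append(b)
    return RestrictionFragmentMap(
        chrom=chrom,
        starts=np.asarray(starts, dtype=np.int64),
        ends=np.asarray(ends, dtype=np.int64),
        enzyme_motif=mot,
        cut_offset=cut_offset,
    )


def assign_to_fragments(
    positions: np.ndarray, fragmap: RestrictionFragmentMap
) -> tuple[np.ndarray, int]:
    """Translate read 5' coordinates to per-fragment raw counts.

    Each position is assigned to the fragment containing it under the
    half-open convention (a read starting exactly at a fragment boundary
    belongs to the fragment that starts there).  Returns ``(counts,
    n_unassigned)``; positions outside the fragment-map span are tallied
    in ``n_unassigned``, never silently dropped.
    """
    pos = np.asarray(positions, dtype=np.int64)
    counts = np.zeros(fragmap.n_fragments, dtype=np.int64)
    if pos.size == 0:
        return counts, 0
    inside = (pos >= 0) & (pos < fragmap.span_end)
    idx = np.searchsorted(fragmap.starts, pos[inside], side="right") - 1
    np.add.at(counts, idx, 1)
    return counts, int((~inside).sum())


def running_mean(values: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centered running mean over ``window`` fragments.

    At the chromosome ends the window truncates to the available fragments
    (a shrinking window, not NA padding), so the output has the same length
    as the input.  ``window`` must be odd.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("values must be non-empty")
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    half = window // 2
    n = v.size
    # shifted-slice accumulation: terms enter left-to-right, so the result
    # is bitwise identical to a naive per-position sum
    acc = np.zeros(n)
    cnt = np.zeros(n)
    for k in range(-half, half + 1):
        lo = max(-k, 0)
        hi = min(n - k, n)
        if hi > lo:
            acc[lo:hi] += v[lo + k : hi + k]
            cnt[lo:hi] += 1.0
    return acc / cnt


# ---------------------------------------------------------------------------
# viewpoint profiles
# ---------------------------------------------------------------------------
@dataclass
class ViewpointProfile:
    """Raw, smoothed and (optionally) normalized signal for one viewpoint.

    ``excluded`` holds the indices of the viewpoint fragment and its
    immediate neighbours, which are removed before smoothing and carry no
    signal afterwards (standard handling of self-ligation artifacts).
    ``normalization`` records the region and scale constant of the last
    :func:`normalize_to_region` call; after normalization the smoothed
    signal sums to 1 over that region.
    """

    viewpoint_name: str
    fragmap: RestrictionFragmentMap
    viewpoint_fragment_index: int
    raw_counts: np.ndarray
    smoothed: np.ndarray
    excluded: frozenset[int] = field(default_factory=frozenset)
    normalization: tuple[tuple[int, int], float] | None = None

    def _active_mask(self) -> np.ndarray:
        mask = np.ones(self.fragmap.n_fragments, dtype=bool)
        if self.excluded:
            mask[list(self.excluded)] = False
        return mask


def viewpoint_profile(
    name: str,
    fragmap: RestrictionFragmentMap,
    raw_counts: np.ndarray,
    viewpoint_position: int,
    exclude_flank: int = 1,
    window: int = DEFAULT_WINDOW,
) -> ViewpointProfile:
    """Build a smoothed viewpoint profile from per-fragment raw counts.

    The viewpoint fragment and ``exclude_flank`` fragments on each side are
    zeroed before smoothing and flagged as excluded.
    """
    raw = np.asarray(raw_counts, dtype=float)
    if raw.size != fragmap.n_fragments:
        raise ValueError("raw_counts length does not match fragment map")
    if np.any(raw < 0):
        raise ValueError("raw counts must be nonnegative")
    vp_idx = fragmap.fragment_containing(viewpoint_position)
    excluded = frozenset(
        i
        for i in range(vp_idx - exclude_flank, vp_idx + exclude_flank + 1)
        if 0 <= i < fragmap.n_fragments
    )
    work = raw.copy()
    work[list(excluded)] = 0.0
    smoothed = running_mean(work, window)
    smoothed[list(excluded)] = 0.0
    return ViewpointProfile(
        viewpoint_name=name,
        fragmap=fragmap,
        viewpoint_fragment_index=vp_idx,
        raw_counts=raw,
        smoothed=smoothed,
        excluded=excluded,
    )


def normalize_to_region(
    profile: ViewpointProfile, region: tuple[int, int]
) -> ViewpointProfile:
    """Scale the smoothed signal so it sums to 1 over ``region``.

    A fragment belongs to the region when its midpoint does.  Scale
    invariant and idempotent; raises if the region carries no signal.
    """
    start, end = int(region[0]), int(region[1])
    if end <= start:
        raise ValueError("region end must exceed region start")
    mids = profile.fragmap.midpoints
    in_region = (mids >= start) & (mids < end) & profile._active_mask()
    total = float(profile.smoothed[in_region].sum())
    if total <= 0:
        raise ValueError(
            f"no signal in normalization region [{start}, {end}) "
            f"({int(in_region.sum())} fragments)"
        )
    return replace(
        profile,
        smoothed=profile.smoothed / total,
        normalization=((start, end), total),
    )


# ---------------------------------------------------------------------------
# region distributions
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class RegionSet:
    """Named, non-overlapping genomic regions (e.g. the TADs of the locus)."""

    labels: tuple[str, ...]
    intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.intervals):
            raise ValueError("labels and intervals length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        order = sorted(range(len(self.intervals)), key=lambda i: self.intervals[i])
        for a, b in zip(order[:-1], order[1:]):
            if self.intervals[b][0] < self.intervals[a][1]:
                raise ValueError(
                    f"regions {self.labels[a]!r} and {self.labels[b]!r} overlap"
                )

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, int, int]]) -> "RegionSet":
        return cls(
            labels=tuple(p[0] for p in pairs),
            intervals=tuple((int(p[1]), int(p[2])) for p in pairs),
        )

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(s for s, _ in self.intervals),
            max(e for _, e in self.intervals),
        )


@dataclass
class SignalDistribution:
    """Per-region fraction of normalized 4C signal for one replicate."""

    viewpoint_name: str
    replicate: str | int
    fractions: dict[str, float]


def region_distribution(
    profile: ViewpointProfile,
    regions: RegionSet,
    replicate: str | int = 0,
    coverage_tol: float = 1e-6,
) -> SignalDistribution:
    """Distribute the normalized signal of ``profile`` over ``regions``.

    The profile must be normalized over the union of the regions; every
    non-excluded fragment with signal must fall in some region (fragments
    are attributed by midpoint).  Fractions are nonnegative and sum to 1.
    """
    if profile.normalization is None:
        raise ValueError("profile must be normalized before region_distribution")
    mids = profile.fragmap.midpoints
    active = profile._active_mask()
    total = float(profile.smoothed[active].sum())
    fractions: dict[str, float] = {}
    covered = 0.0
    for label, (start, end) in zip(regions.labels, regions.intervals):
        sel = (mids >= start) & (mids < end) & active
        frac = float(profile.smoothed[sel].sum())
        fractions[label] = frac
        covered += frac
    uncovered = total - covered
    if abs(total - 1.0) > coverage_tol or uncovered > coverage_tol:
        raise ValueError(
            f"regions do not cover all normalized signal: uncovered fraction "
            f"{uncovered:.3e} (profile total {total:.6f})"
        )
    return SignalDistribution(
        viewpoint_name=profile.viewpoint_name,
        replicate=replicate,
        fractions=fractions,
    )


def tad_ratio(
    distributions: list[SignalDistribution], region_a: str, region_b: str
) -> float:
    """Mean over replicates of fraction(region_a) / fraction(region_b)."""
    if not distributions:
        raise ValueError("no distributions given")
    ratios = []
    for dist in distributions:
        if region_a not in dist.fractions or region_b not in dist.fractions:
            raise KeyError(
                f"regions {region_a!r}/{region_b!r} missing in replicate "
                f"{dist.replicate!r}"
            )
        denom = dist.fractions[region_b]
        if denom <= 0:
            raise ZeroDivisionError(
                f"zero signal in region {region_b!r} (replicate {dist.replicate!r})"
            )
        ratios.append(dist.fractions[region_a] / denom)
    return float(np.mean(ratios))
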