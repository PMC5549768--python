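"""Directionality index and CTCF-guided TAD boundary repositioning.

The directionality index (DI) quantifies the up/downstream bias of Hi-C
contacts of each genomic bin.  For bin *i*, with A the sum of contacts to
bins within a window upstream, B the sum downstream and E = (A+B)/2 the
expected value under no bias,

    DI(i) = sign(B - A) * ((A-E)^2/E + (B-E)^2/E)

DI is strongly positive at the left edge of a TAD (downstream bias),
strongly negative at the right edge, and crosses zero inside TADs and in
boundary transition zones.  Boundary candidates are taken at thresholded
sign changes of the DI track (a deliberately simple stand-in for HMM-based
callers); boundaries can then be repositioned onto nearby clusters of CTCF
binding sites, the way a transition-zone boundary is resolved manually.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ContactMatrix:
    """Symmetric binned contact matrix for one chromosome."""

    chrom: str
    bin_size: int
    matrix: np.ndarray
    offset: int = 0  # bp coordinate of the left edge of bin 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("matrix must be square")
        if np.any(self.matrix < 0):
            raise ValueError("matrix must be nonnegative")

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[0]

    def bin_start(self, i: int) -> int:
        return self.offset + i * self.bin_size


@dataclass
class DirectionalityTrack:
    """Per-bin DI values with the upstream/downstream sums behind them."""

    chrom: str
    bin_size: int
    offset: int
    window_bp: int
    di: np.ndarray
    upstream: np.ndarray  # A
    downstream: np.ndarray  # B


@dataclass(frozen=True)
class Boundary:
    """A candidate TAD boundary with its DI transition zone (bin indices)."""

    bin_index: int
    position: int
    zone_start_bin: int
    zone_end_bin: int


@dataclass(frozen=True)
class CtcfCluster:
    start: int
    end: int
    site_count: int

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class CtcfClusterSet:
    clusters: tuple[CtcfCluster, ...]
    min_sites: int
    max_gap: int


@dataclass
class TADSet:
    """Ordered, non-overlapping labelled TAD intervals."""

    tads: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.tads = sorted(self.tads, key=lambda t: t[1])
        for (la, sa, ea), (lb, sb, eb) in zip(self.tads[:-1], self.tads[1:]):
            if ea > sb:
                raise ValueError(f"TADs {la!r} and {lb!r} overlap")
        for label, s, e in self.tads:
            if e <= s:
                raise ValueError(f"TAD {label!r} has non-positive length")

    @property
    def span(self) -> tuple[int, int]:
        return self.tads[0][1], self.tads[-1][2]

    def boundary_after(self, label: str) -> int:
        """Boundary position at the right edge of the TAD named ``label``."""
        for i, (lab, _s, e) in enumerate(self.tads):
            if lab == label:
                if i + 1 >= len(self.tads):
                    raise ValueError(f"TAD {label!r} is last; no internal boundary")
                return e
        raise KeyError(label)


def directionality_index(
    cm: ContactMatrix, window_bp: int, sym_tol: float = 1e-8
) -> DirectionalityTrack:
    """Compute the Dixon-style directionality index of a contact matrix.

    ``window_bp`` is converted to whole bins (floor); windows truncate at
    the matrix edges.  DI is 0 wherever A = B or A + B = 0.  Raises on an
    asymmetric matrix (relative infinity-norm of M - M^T above ``sym_tol``).
    """
    m = cm.matrix
    scale = max(float(np.abs(m).max()), 1.0)
    if float(np.abs(m - m.T).max()) > sym_tol * scale:
        raise ValueError("contact matrix is not symmetric")
    if window_bp < cm.bin_size:
        raise ValueError("window must be at least one bin")
    w = window_bp // cm.bin_size
    n = cm.n_bins
    a = np.empty(n)
    b = np.empty(n)
    for i in range(n):
        a[i] = m[i, max(i - w, 0) : i].sum()
        b[i] = m[i, i + 1 : min(i + w + 1, n)].sum()
    e = (a + b) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        chi = (a - e) ** 2 / e + (b - e) ** 2 / e
    di = np.sign(b - a) * chi
    di[(a == b) | (e == 0)] = 0.0
    return DirectionalityTrack(
        chrom=cm.chrom,
        bin_size=cm.bin_size,
        offset=cm.offset,
        window_bp=window_bp,
        di=di,
        upstream=a,
        downstream=b,
    )


def suggest_boundaries(
    track: DirectionalityTrack, threshold: float, max_zone_bins: int = 15
) -> list[Boundary]:
    """Candidate TAD boundaries from thresholded DI sign changes.

    A boundary is emitted where the DI track passes from a bin with
    DI <= -threshold to a bin with DI >= +threshold with at most
    ``max_zone_bins`` low-|DI| bins between them; that low-DI run is the
    reported transition zone.  The boundary is placed at the bin edge
    midway through the transition.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    di = track.di
    boundaries: list[Boundary] = []
    last_neg: int | None = None
    gap = 0
    for i, d in enumerate(di):
        if d <= -threshold:
            last_neg = i
            gap = 0
        elif d >= threshold:
            if last_neg is not None and gap <= max_zone_bins:
                edge = (last_neg + i + 1) // 2
                boundaries.append(
                    Boundary(
                        bin_index=edge,
                        position=track.offset + edge * track.bin_size,
                        zone_start_bin=last_neg + 1,
                        zone_end_bin=i,
                    )
                )
            last_neg = None
            gap = 0
        else:
            if last_neg is not None:
                gap += 1
                if gap > max_zone_bins:
                    last_neg = None
                    gap = 0
    return boundaries


def cluster_ctcf(
    positions: np.ndarray, min_sites: int = 3, max_gap: int = 10_000
) -> CtcfClusterSet:
    """Single-linkage clustering of CTCF site positions.

    Consecutive sites at most ``max_gap`` bp apart chain into one cluster;
    clusters with fewer than ``min_sites`` sites are discarded.
    """
    pos = np.sort(np.asarray(positions, dtype=np.int64))
    clusters: list[CtcfCluster] = []
    if pos.size:
        breaks = np.where(np.diff(pos) > max_gap)[0]
        for chunk in np.split(pos, breaks + 1):
            if chunk.size >= min_sites:
                clusters.append(
                    CtcfCluster(int(chunk[0]), int(chunk[-1]), int(chunk.size))
                )
    return CtcfClusterSet(tuple(clusters), min_sites=min_sites, max_gap=max_gap)


def reposition_boundary(
    tads: TADSet,
    boundary_label: str,
    clusters: CtcfClusterSet,
    search_radius: int = 200_000,
) -> TADSet:
    """Move a TAD boundary onto the nearest qualifying CTCF cluster.

    ``boundary_label`` names the TAD whose right edge is the boundary to
    move.  The boundary goes to the midpoint of the nearest cluster within
    ``search_radius``; ties break toward the lower coordinate.  The two
    adjacent TADs are resized consistently (no gap, no overlap) and the
    total span of the TAD set is preserved.
    """
    current = tads.boundary_after(boundary_label)
    candidates = [
        c
        for c in clusters.clusters
        if abs(c.midpoint - current) <= search_radius
    ]
    if not candidates:
        raise ValueError(
            f"no CTCF cluster within {search_radius} bp of boundary at {current}"
        )
    candidates.sort(key=lambda c: (abs(c.midpoint - current), c.midpoint))
    new_pos = candidates[0].midpoint
    new_tads = []
    for i, (label, s, e) in enumerate(tads.tads):
        if label == boundary_label:
            left = (label, s, new_pos)
            right_label, _rs, re_ = tads.tads[i + 1]
            if not (s < new_pos < re_):
                raise ValueError(
                    f"cluster midpoint {new_pos} would empty TAD "
                    f"{label!r} or {right_label!r}"
                )
            new_tads.append(left)
            new_tads.append((right_label, new_pos, re_))
            new_tads.extend(tads.tads[i + 2 :])
            break
        new_tads.append((label, s, e))
    return TADSet(new_tads)
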