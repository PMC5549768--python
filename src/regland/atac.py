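"""ATAC-seq differential accessibility.

The analysis chain mirrors the standard count-based workflow for
accessibility of regulatory elements:

* keep only sub-100-bp fragments (transcription-factor-protected DNA,
  strict ``length < 100``);
* call accessibility summits per sample against a Poisson local
  background (a simplified caller: sliding-window midpoint counts tested
  against the max of window-, 1 kb- and 10 kb-scale local rates, with
  Benjamini-Hochberg q-values and one summit per enriched region);
* merge summits of all samples/replicates that lie closer than 50 bp
  (transitive single linkage), keeping the lowest-q summit per group;
* count fragments overlapping a fixed window around each merged summit;
* compute median-of-ratios library size factors on 10-kb genomic bins;
* estimate a per-summit negative-binomial dispersion (method of moments
  shrunk toward a fitted mean-dispersion trend);
* test each summit for a genotype effect with a negative-binomial Wald
  test (log-link GLM fitted by IRLS; statistic = log2FC / SE, two-sided
  normal p, BH-adjusted p reported alongside).

The NB model is ``var = mu + alpha * mu**2`` (NB2).  All coordinates are
0-based half-open.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

MAX_FRAGMENT_LEN = 100
SUMMIT_GROUPING_BP = 50
SIZE_FACTOR_BIN_BP = 10_000
DEFAULT_HALF_WIDTH = 250
DISPERSION_FLOOR = 1e-8
TREND_SHRINKAGE = 0.7
LN2 = float(np.log(2.0))


# ---------------------------------------------------------------------------
# fragments and summits
# ---------------------------------------------------------------------------
@dataclass
class FragmentSet:
    """Paired-end fragments of one sample (0-based half-open intervals)."""

    sample_id: str
    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    condition: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if self.starts.shape != self.ends.shape:
            raise ValueError("starts/ends length mismatch")
        if np.any(self.ends <= self.starts):
            raise ValueError("fragment intervals must satisfy end > start")

    def __len__(self) -> int:
        return len(self.starts)

    @property
    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def midpoints(self) -> np.ndarray:
        return (self.starts + self.ends) // 2


@dataclass(frozen=True)
class Summit:
    position: int
    q_value: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError("q_value must be in [0, 1]")


@dataclass
class SummitCatalog:
    """Non-redundant merged summits (pairwise >= grouping_distance apart)."""

    positions: np.ndarray
    q_values: np.ndarray
    member_counts: np.ndarray
    grouping_distance: int = SUMMIT_GROUPING_BP

    def __len__(self) -> int:
        return len(self.positions)


def filter_fragments(fragments: FragmentSet, max_len: int = MAX_FRAGMENT_LEN) -> FragmentSet:
    """Keep fragments strictly shorter than ``max_len`` bp."""
    keep = fragments.lengths < max_len
    return FragmentSet(
        sample_id=fragments.sample_id,
        chrom=fragments.chrom,
        starts=fragments.starts[keep],
        ends=fragments.ends[keep],
        condition=fragments.condition,
        metadata=dict(fragments.metadata),
    )


def _windowed_counts(per_bp: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered window sums [i - w/2, i + w/2) and effective (truncated) widths."""
    n = per_bp.size
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(per_bp, dtype=float)))
    if n <= 2 * half:  # window spans the whole array
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half, n)
        return csum[hi] - csum[lo], (hi - lo).astype(float)
    hi_vals = np.concatenate([csum[half:n], np.full(half, csum[n])])
    lo_vals = np.concatenate([np.zeros(half), csum[: n - half]])
    widths = np.concatenate(
        [
            np.arange(half, 2 * half, dtype=float),
            np.full(n - 2 * half, 2.0 * half),
            np.arange(2 * half, half, -1, dtype=float),
        ]
    )
    return hi_vals - lo_vals, widths


def _stepped_window_sums(
    csum: np.ndarray, positions: np.ndarray, half: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sums of per-bp counts over [p - half, p + half), truncated at the ends."""
    n = csum.size - 1
    lo = np.maximum(positions - half, 0)
    hi = np.minimum(positions + half, n)
    return csum[hi] - csum[lo], (hi - lo).astype(float)


def call_summits(
    fragments: FragmentSet,
    chrom_length: int | None = None,
    q_threshold: float = 0.01,
    window: int = 200,
    step: int = 5,
) -> list[Summit]:
    """Call accessibility summits against a Poisson local background.

    Fragment midpoints are counted in a centered ``window`` evaluated
    every ``step`` bases.  The background rate at each position is the
    maximum of the chromosome-wide rate and local rates estimated at 1-kb
    and 10-kb scales, so broad enrichment cannot masquerade as a peak.
    One-sided Poisson p-values are BH-corrected over all tested positions;
    contiguous runs of positions with q <= ``q_threshold`` form enriched
    regions, and the position of maximal windowed count in each run
    (leftmost on ties) is reported as the region's summit with the
    q-value at that position.
    """
    if len(fragments) == 0:
        raise ValueError("cannot call summits on an empty fragment set")
    mids = fragments.midpoints
    length = int(chrom_length) if chrom_length is not None else int(mids.max()) + 1
    if mids.max() >= length or mids.min() < 0:
        raise ValueError("fragment midpoints outside [0, chrom_length)")
    per_bp = np.bincount(mids, minlength=length)
    csum = np.concatenate(([0.0], np.cumsum(per_bp, dtype=float)))
    pos = np.arange(0, length, step)

    win_counts, win_width = _stepped_window_sums(csum, pos, window // 2)
    c1k, w1k = _stepped_window_sums(csum, pos, 500)
    c10k, w10k = _stepped_window_sums(csum, pos, 5_000)
    lam_global = len(fragments) / length
    lam = np.maximum(np.maximum(c1k / w1k, c10k / w10k), lam_global) * win_width

    # Poisson sf only where the count could conceivably reach p <= q_threshold;
    # positions below a normal-approximation bound (with a 1-sigma safety
    # margin, so the bound is conservative) keep p = 1.  Since BH q >= p,
    # such positions can never be discoveries.
    k_sigma = max(stats.norm.isf(min(q_threshold, 0.5)) - 1.0, 0.0)
    pvals = np.ones(pos.size)
    cand = win_counts > lam + k_sigma * np.sqrt(lam)
    if cand.any():
        pvals[cand] = stats.poisson.sf(win_counts[cand] - 1, lam[cand])

    qvals = _bh_adjust_sparse(pvals, m=pos.size)
    sig = qvals <= q_threshold
    summits: list[Summit] = []
    if sig.any():
        sig_idx = np.flatnonzero(sig)
        run_breaks = np.where(np.diff(sig_idx) > 1)[0]
        for run in np.split(sig_idx, run_breaks + 1):
            best = run[np.argmax(win_counts[run])]  # argmax is leftmost on ties
            summits.append(
                Summit(
                    position=int(pos[best]),
                    q_value=float(qvals[best]),
                    sample_id=fragments.sample_id,
                )
            )
    return summits


def _bh_adjust_sparse(pvals: np.ndarray, m: int) -> np.ndarray:
    """BH q-values with total test count ``m``; entries equal to 1 stay 1."""
    q = np.ones_like(pvals)
    tested = np.flatnonzero(pvals < 1.0)
    if tested.size == 0:
        return q
    p = pvals[tested]
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, p.size + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    q[tested] = out
    return q


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Standard Benjamini-Hochberg adjustment."""
    p = np.asarray(pvals, dtype=float)
    return _bh_adjust_sparse(np.minimum(p, 1.0 - 1e-300), m=p.size)


def merge_summits(
    summits: list[Summit], grouping_distance: int = SUMMIT_GROUPING_BP
) -> SummitCatalog:
    """Merge summits of all samples/replicates into a non-redundant catalog.

    Summits strictly closer than ``grouping_distance`` chain into one group
    (transitive single linkage; summits exactly ``grouping_distance`` apart
    stay separate).  Each group is represented by its lowest-q summit,
    ties broken toward the leftmost position.
    """
    if not summits:
        return SummitCatalog(
            positions=np.empty(0, dtype=np.int64),
            q_values=np.empty(0),
            member_counts=np.empty(0, dtype=np.int64),
            grouping_distance=grouping_distance,
        )
    order = sorted(summits, key=lambda s: (s.position, s.q_value))
    groups: list[list[Summit]] = [[order[0]]]
    for s in order[1:]:
        if s.position - groups[-1][-1].position < grouping_distance:
            groups[-1].append(s)
        else:
            groups.append([s])
    reps = [min(g, key=lambda s: (s.q_value, s.position)) for g in groups]
    return SummitCatalog(
        positions=np.array([r.position for r in reps], dtype=np.int64),
        q_values=np.array([r.q_value for r in reps]),
        member_counts=np.array([len(g) for g in groups], dtype=np.int64),
        grouping_distance=grouping_distance,
    )


# ---------------------------------------------------------------------------
# counting and normalization
# ---------------------------------------------------------------------------
@dataclass
class CountTable:
    """Fragment counts per merged summit (rows) per sample (columns)."""

    counts: pd.DataFrame
    conditions: pd.Series  # sample id -> condition label
    half_width: int

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.conditions.index):
            raise ValueError("count columns and condition index mismatch")


def count_at_summits(
    catalog: SummitCatalog,
    samples: list[FragmentSet],
    half_width: int = DEFAULT_HALF_WIDTH,
) -> CountTable:
    """Count fragments overlapping ``[summit - hw, summit + hw)`` per sample.

    A fragment counts when it overlaps the window by at least one base
    (half-open on both sides: a fragment ending exactly at the window
    start does not count).
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    data = {}
    conditions = {}
    lo = catalog.positions - half_width
    hi = catalog.positions + half_width
    for fs in samples:
        starts = np.sort(fs.starts)
        ends = np.sort(fs.ends)
        # overlap iff start < hi and end > lo
        n_start_ok = np.searchsorted(starts, hi, side="left")
        n_end_bad = np.searchsorted(ends, lo, side="right")
        data[fs.sample_id] = (n_start_ok - n_end_bad).astype(np.int64)
        conditions[fs.sample_id] = fs.condition
    counts = pd.DataFrame(data, index=catalog.positions.copy())
    return CountTable(
        counts=counts,
        conditions=pd.Series(conditions).loc[counts.columns],
        half_width=half_width,
    )


def size_factors(
    samples: list[FragmentSet],
    chrom_length: int,
    bin_size: int = SIZE_FACTOR_BIN_BP,
) -> pd.Series:
    """Median-of-ratios library size factors on genomic bin counts.

    Fragment midpoints are counted in ``bin_size`` bins; bins with a zero
    count in any sample are excluded (the geometric mean is undefined
    there).  Each sample's factor is the median over bins of its count
    divided by the bin's geometric mean across samples.
    """
    if len(samples) < 2:
        raise ValueError("size factors need at least two samples")
    n_bins = int(np.ceil(chrom_length / bin_size))
    mat = np.empty((n_bins, len(samples)))
    for j, fs in enumerate(samples):
        mat[:, j] = np.bincount(fs.midpoints // bin_size, minlength=n_bins)[:n_bins]
    keep = (mat > 0).all(axis=1)
    if not keep.any():
        raise ValueError("every genomic bin has a zero count in some sample")
    logm = np.log(mat[keep])
    log_geo = logm.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logm - log_geo, axis=0))
    return pd.Series(factors, index=[fs.sample_id for fs in samples], name="size_factor")


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------
def estimate_dispersion(
    table: CountTable, factors: pd.Series, conditions: pd.Series | None = None
) -> np.ndarray:
    """Per-summit NB dispersion alpha, shrunk toward a mean-dispersion trend.

    For each summit a method-of-moments estimate is taken from size-factor
    normalized counts, matching the NB2 relation ``E[ss_g] = (n_g - 1) *
    (mu_g + alpha * mu_g^2)`` within each condition g:

        alpha = sum_g (ss_g - (n_g - 1) mean_g) / sum_g (n_g - 1) mean_g^2

    so conditions with very different means (e.g. a deleted element) do
    not bias the estimate.  A trend ``alpha(mu) = a0 + a1 / mu`` is fit
    across summits by least squares and each raw estimate is shrunk toward
    it with weight ``TREND_SHRINKAGE`` (per-summit estimates from two
    replicates are too unstable to use alone).  Result floored at 1e-8.
    """
    conds = table.conditions if conditions is None else conditions
    counts = table.counts.to_numpy(dtype=float)
    sf = factors.loc[table.counts.columns].to_numpy(dtype=float)
    norm = counts / sf
    mu = norm.mean(axis=1)

    groups = [np.flatnonzero(conds.to_numpy() == c) for c in conds.unique()]
    n_samples = norm.shape[1]
    n_groups = len(groups)
    if n_samples - n_groups < 1:
        raise ValueError("dispersion estimation needs replicates within conditions")
    num = np.zeros(norm.shape[0])
    den = np.zeros(norm.shape[0])
    for idx in groups:
        if idx.size < 2:
            continue
        gm = norm[:, idx].mean(axis=1)
        s2 = ((norm[:, idx] - gm[:, None]) ** 2).sum(axis=1) / (idx.size - 1)
        num += (idx.size - 1) * (s2 - gm)
        # E[gm^2] = mu^2 + var/n: subtract s2/n so the denominator is an
        # unbiased estimate of (n-1) mu^2
        den += (idx.size - 1) * np.maximum(gm**2 - s2 / idx.size, gm**2 * 0.5)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_raw = num / den
    alpha_raw[~np.isfinite(alpha_raw)] = 0.0

    ok = mu > 0
    if ok.sum() >= 10:
        x = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
        coef, *_ = np.linalg.lstsq(x, alpha_raw[ok], rcond=None)
        a0, a1 = max(coef[0], 0.0), max(coef[1], 0.0)
    else:
        # means are unbiased for chi-square-distributed raw estimates where
        # a median would sit systematically low
        a0 = float(np.mean(np.maximum(alpha_raw[ok], 0.0))) if ok.any() else 0.0
        a1 = 0.0
    with np.errstate(divide="ignore"):
        trend = np.where(ok, a0 + a1 / np.where(ok, mu, 1.0), a0)
    alpha = (1.0 - TREND_SHRINKAGE) * np.maximum(alpha_raw, 0.0) + TREND_SHRINKAGE * trend
    return np.maximum(alpha, DISPERSION_FLOOR)


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------
_MAX_ETA = 30.0  # natural-log cap on the linear predictor


def _nb_irls(
    y: np.ndarray, x: np.ndarray, offset: np.ndarray, alpha: float,
    max_iter: int = 50, tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit an NB2 log-link GLM by iteratively reweighted least squares.

    Returns (beta, covariance).  Working weights are mu / (1 + alpha*mu),
    the Fisher information weights of the NB2 family with known alpha.
    """
    beta = np.zeros(x.shape[1])
    beta[0] = np.log(max(y.sum() / np.exp(offset).sum(), 1e-8))
    for _ in range(max_iter):
        eta = np.clip(x @ beta + offset, -_MAX_ETA, _MAX_ETA)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = x.T * w
        try:
            beta_new = np.linalg.solve(xtw @ x, xtw @ z)
        except np.linalg.LinAlgError:
            break
        beta_new = np.clip(beta_new, -_MAX_ETA, _MAX_ETA)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = np.clip(x @ beta + offset, -_MAX_ETA, _MAX_ETA)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha * mu)
    fisher = (x.T * w) @ x
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        cov = np.full((x.shape[1], x.shape[1]), np.nan)
    return beta, cov


def wald_test(
    table: CountTable,
    factors: pd.Series,
    dispersions: np.ndarray,
    contrast: tuple[str, str],
    alpha_level: float = 0.05,
) -> pd.DataFrame:
    """Negative-binomial Wald contrast between two conditions.

    ``contrast = (condition_test, condition_ref)``: the reported log2
    fold-change is log2(test / ref), so a reduction in the test condition
    gives a negative value.  Each summit is fitted with an NB log-link GLM
    (intercept + condition indicator, log size factors as offsets) at its
    plug-in dispersion; the Wald statistic is log2FC / SE with a two-sided
    standard-normal p-value.  Rows where every sample has zero counts are
    marked untestable (NaN statistics) rather than dropped.  BH-adjusted
    p-values and a significance flag at raw p < ``alpha_level`` are
    reported alongside.
    """
    cond_test, cond_ref = contrast
    conds = table.conditions
    sel = conds.isin([cond_test, cond_ref])
    for c in contrast:
        n = int((conds == c).sum())
        if n < 2:
            raise ValueError(f"condition {c!r} needs >= 2 replicates, has {n}")
    cols = table.counts.columns[sel.to_numpy()]
    y_all = table.counts[cols].to_numpy(dtype=float)
    sf = factors.loc[cols].to_numpy(dtype=float)
    offset = np.log(sf)
    ind = (conds.loc[cols] == cond_test).to_numpy(dtype=float)
    x = np.column_stack([np.ones_like(ind), ind])

    n_summits = y_all.shape[0]
    base_mean = (y_all / sf).mean(axis=1)
    lfc = np.full(n_summits, np.nan)
    se = np.full(n_summits, np.nan)
    stat = np.full(n_summits, np.nan)
    pval = np.full(n_summits, np.nan)
    untestable = np.zeros(n_summits, dtype=bool)

    for i in range(n_summits):
        y = y_all[i]
        if y.sum() == 0:
            untestable[i] = True
            continue
        beta, cov = _nb_irls(y, x, offset, float(dispersions[i]))
        if not np.isfinite(cov[1, 1]) or cov[1, 1] <= 0:
            untestable[i] = True
            continue
        lfc[i] = beta[1] / LN2
        se[i] = float(np.sqrt(cov[1, 1])) / LN2
        stat[i] = lfc[i] / se[i]
        pval[i] = max(2.0 * stats.norm.sf(abs(stat[i])), np.finfo(float).tiny)

    padj = np.full(n_summits, np.nan)
    testable = ~untestable
    if testable.any():
        padj[testable] = bh_adjust(pval[testable])
    return pd.DataFrame(
        {
            "summit": table.counts.index.to_numpy(),
            "baseMean": base_mean,
            "log2FoldChange": lfc,
            "lfcSE": se,
            "stat": stat,
            "pvalue": pval,
            "padj": padj,
            "alpha": np.asarray(dispersions, dtype=float),
            "significant": testable & (pval < alpha_level),
            "untestable": untestable,
            "contrast": f"{cond_test}_vs_{cond_ref}",
        }
    )
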