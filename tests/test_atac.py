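"""Fragment filtering, summit calling/merging, counting, size factors, NB Wald."""
import numpy as np
import pandas as pd
import pytest

from regland import atac

COLS = ["a1", "a2", "b1", "b2"]
CONDS = pd.Series(["A", "A", "B", "B"], index=COLS)
UNIT_FACTORS = pd.Series(1.0, index=COLS)


def _fragset(rng, n, length, sample="s", lo=0, hi=100_000, condition=""):
    starts = rng.integers(lo, hi - length, size=n)
    return atac.FragmentSet(sample, "c", starts, starts + length, condition=condition)


def _nb(rng, mean, alpha, size):
    nv = 1.0 / alpha
    return rng.negative_binomial(nv, nv / (nv + mean), size=size)


def _table(counts):
    return atac.CountTable(pd.DataFrame(counts, columns=COLS), CONDS, half_width=250)


# ---------------------------------------------------------------------------
# fragment filter
# ---------------------------------------------------------------------------
def test_filter_is_strictly_below_100():
    fs = atac.FragmentSet("s", "c", np.array([0, 0, 0]), np.array([99, 100, 101]))
    out = atac.filter_fragments(fs)
    assert list(out.lengths) == [99]


def test_filter_empty_input():
    fs = atac.FragmentSet("s", "c", np.array([], dtype=int), np.array([], dtype=int))
    assert len(atac.filter_fragments(fs)) == 0


def test_filter_matches_brute_force(rng):
    starts = rng.integers(0, 10_000, size=500)
    lengths = rng.integers(1, 200, size=500)
    fs = atac.FragmentSet("s", "c", starts, starts + lengths)
    out = atac.filter_fragments(fs)
    expected = [(s, e) for s, e in zip(starts, starts + lengths) if e - s < 100]
    assert sorted(zip(out.starts, out.ends)) == sorted(expected)


def test_fragmentset_rejects_empty_intervals():
    with pytest.raises(ValueError):
        atac.FragmentSet("s", "c", np.array([5]), np.array([5]))


# ---------------------------------------------------------------------------
# summit calling
# ---------------------------------------------------------------------------
def test_no_summits_on_uniform_background():
    misses = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        fs = _fragset(rng, 2_000, 60, hi=200_000)
        if atac.call_summits(fs, 200_000):
            misses += 1
    assert misses <= 5


def test_single_spike_gives_one_summit_near_center(rng):
    center = 50_000
    bg = _fragset(rng, 2_000, 60, hi=200_000)
    spike_starts = rng.integers(center - 100, center + 100 - 60, size=200)
    fs = atac.FragmentSet(
        "s", "c",
        np.concatenate([bg.starts, spike_starts]),
        np.concatenate([bg.ends, spike_starts + 60]),
    )
    summits = atac.call_summits(fs, 200_000)
    assert len(summits) == 1
    assert abs(summits[0].position - center) <= 50
    assert summits[0].q_value <= 0.01


def test_two_spikes_give_two_summits(rng):
    bg = _fragset(rng, 2_000, 60, hi=200_000)
    s1 = rng.integers(49_900, 50_040, size=150)
    s2 = rng.integers(59_900, 60_040, size=150)
    fs = atac.FragmentSet(
        "s", "c",
        np.concatenate([bg.starts, s1, s2]),
        np.concatenate([bg.ends, s1 + 60, s2 + 60]),
    )
    positions = sorted(s.position for s in atac.call_summits(fs, 200_000))
    assert len(positions) == 2
    assert abs(positions[0] - 50_000) <= 100 and abs(positions[1] - 60_000) <= 100


def test_call_summits_empty_input_errors():
    fs = atac.FragmentSet("s", "c", np.array([], dtype=int), np.array([], dtype=int))
    with pytest.raises(ValueError, match="empty"):
        atac.call_summits(fs, 1000)


# ---------------------------------------------------------------------------
# summit merging
# ---------------------------------------------------------------------------
def exhaustive_single_linkage(summits, dist):
    """Independent oracle: grow groups until no pair < dist links them."""
    groups = [[s] for s in summits]
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    abs(a.position - b.position) < dist
                    for a in groups[i]
                    for b in groups[j]
                ):
                    groups[i] += groups.pop(j)
                    merged = True
                    break
            if merged:
                break
    return sorted(
        min(g, key=lambda s: (s.q_value, s.position)).position for g in groups
    )


def test_merge_keeps_lowest_q_within_50bp():
    s = [atac.Summit(100, 0.01), atac.Summit(149, 0.001)]
    cat = atac.merge_summits(s)
    assert list(cat.positions) == [149]
    assert list(cat.q_values) == [0.001]


def test_merge_distance_exactly_50_keeps_both():
    s = [atac.Summit(100, 0.01), atac.Summit(150, 0.001)]
    assert list(atac.merge_summits(s).positions) == [100, 150]


def test_merge_transitive_chain():
    s = [atac.Summit(100, 0.5), atac.Summit(140, 0.9), atac.Summit(180, 0.2)]
    cat = atac.merge_summits(s)
    assert list(cat.positions) == [180]
    assert list(cat.member_counts) == [3]


def test_merge_matches_exhaustive_oracle(rng):
    for _ in range(100):
        n = int(rng.integers(0, 200))
        summits = [
            atac.Summit(int(p), float(q))
            for p, q in zip(
                rng.integers(0, 5_000, size=n), rng.uniform(0, 1, size=n)
            )
        ]
        cat = atac.merge_summits(summits)
        assert sorted(cat.positions) == exhaustive_single_linkage(summits, 50)
        if len(cat) > 1:
            assert np.diff(cat.positions).min() >= 50


def test_merge_idempotent(rng):
    summits = [
        atac.Summit(int(p), float(q))
        for p, q in zip(rng.integers(0, 3_000, size=80), rng.uniform(0, 1, 80))
    ]
    cat = atac.merge_summits(summits)
    again = atac.merge_summits(
        [atac.Summit(int(p), float(q)) for p, q in zip(cat.positions, cat.q_values)]
    )
    assert np.array_equal(again.positions, cat.positions)
    assert np.array_equal(again.q_values, cat.q_values)


# ---------------------------------------------------------------------------
# counting
# ---------------------------------------------------------------------------
def _catalog(*positions):
    positions = np.array(positions, dtype=np.int64)
    return atac.SummitCatalog(
        positions=positions,
        q_values=np.zeros(len(positions)),
        member_counts=np.ones(len(positions), dtype=np.int64),
    )


def test_count_no_fragments_gives_zeros():
    fs = atac.FragmentSet("s", "c", np.array([], dtype=int), np.array([], dtype=int))
    table = atac.count_at_summits(_catalog(1000, 2000), [fs], half_width=250)
    assert table.counts.to_numpy().sum() == 0


def test_count_half_open_window_boundaries():
    # window [750, 1250): fragment ending at 750 out, starting at 1249 in
    fs = atac.FragmentSet(
        "s", "c",
        np.array([700, 1249, 1250]),
        np.array([750, 1300, 1300]),
    )
    table = atac.count_at_summits(_catalog(1000), [fs], half_width=250)
    assert table.counts.iloc[0, 0] == 1


def test_count_matches_brute_force(rng):
    fs = _fragset(rng, 800, 60, hi=50_000)
    cat = _catalog(*sorted(rng.integers(500, 49_500, size=30)))
    table = atac.count_at_summits(cat, [fs], half_width=250)
    for k, pos in enumerate(cat.positions):
        lo, hi = pos - 250, pos + 250
        brute = int(np.sum((fs.starts < hi) & (fs.ends > lo)))
        assert table.counts.iloc[k, 0] == brute


# ---------------------------------------------------------------------------
# size factors
# ---------------------------------------------------------------------------
def test_size_factors_identical_samples_are_one(rng):
    fs = _fragset(rng, 5_000, 60)
    twin = atac.FragmentSet("s2", "c", fs.starts.copy(), fs.ends.copy())
    sf = atac.size_factors([fs, twin], 100_000)
    assert np.allclose(sf, 1.0)


def test_size_factors_doubled_sample_closed_form(rng):
    fs = _fragset(rng, 5_000, 60)
    doubled = atac.FragmentSet(
        "s2", "c", np.repeat(fs.starts, 2), np.repeat(fs.ends, 2)
    )
    sf = atac.size_factors([fs, doubled], 100_000)
    assert sf.iloc[0] == pytest.approx(1 / np.sqrt(2), abs=1e-9)
    assert sf.iloc[1] == pytest.approx(np.sqrt(2), abs=1e-9)


def test_size_factors_scaling_property(rng):
    # triplicating sample 2 multiplies its factor by 3 / 3**(1/2) and divides
    # the other's by 3**(1/2) (shared geometric-mean rescaling)
    fs1 = _fragset(rng, 5_000, 60, sample="s1")
    fs2 = _fragset(rng, 5_000, 60, sample="s2")
    base = atac.size_factors([fs1, fs2], 100_000)
    fs2x3 = atac.FragmentSet("s2", "c", np.repeat(fs2.starts, 3), np.repeat(fs2.ends, 3))
    scaled = atac.size_factors([fs1, fs2x3], 100_000)
    assert scaled.iloc[1] / base.iloc[1] == pytest.approx(3 / np.sqrt(3), rel=1e-9)
    assert scaled.iloc[0] / base.iloc[0] == pytest.approx(1 / np.sqrt(3), rel=1e-9)


def test_size_factors_need_two_samples(rng):
    with pytest.raises(ValueError):
        atac.size_factors([_fragset(rng, 100, 60)], 100_000)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------
def test_dispersion_poisson_counts_near_zero(rng):
    mu = np.exp(rng.uniform(np.log(50), np.log(2000), 1000))
    counts = rng.poisson(mu[:, None], (1000, 4))
    disp = atac.estimate_dispersion(_table(counts), UNIT_FACTORS)
    assert np.median(disp) <= 0.01


def test_dispersion_recovers_alpha(rng):
    mu = np.exp(rng.uniform(np.log(200), np.log(2000), 1000))
    counts = _nb(rng, mu[:, None], 0.2, (1000, 4))
    disp = atac.estimate_dispersion(_table(counts), UNIT_FACTORS)
    assert 0.1 <= np.median(disp) <= 0.4


def test_dispersion_equal_replicates_floored():
    disp = atac.estimate_dispersion(_table([[5, 5, 5, 5]]), UNIT_FACTORS)
    assert disp[0] == pytest.approx(atac.DISPERSION_FLOOR)


def test_dispersion_unbiased_for_unequal_condition_means(rng):
    # a 20x difference between conditions must not inflate alpha
    mu = np.exp(rng.uniform(np.log(200), np.log(1000), 800))
    ca = _nb(rng, mu[:, None], 0.05, (800, 2))
    cb = _nb(rng, 20 * mu[:, None], 0.05, (800, 2))
    disp = atac.estimate_dispersion(_table(np.hstack([ca, cb])), UNIT_FACTORS)
    assert 0.02 <= np.median(disp) <= 0.09


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------
def test_wald_type_one_error_calibrated(rng):
    mu = np.exp(rng.uniform(np.log(50), np.log(2000), 1000))
    counts = _nb(rng, mu[:, None], 0.05, (1000, 4))
    table = _table(counts)
    disp = atac.estimate_dispersion(table, UNIT_FACTORS)
    res = atac.wald_test(table, UNIT_FACTORS, disp, ("B", "A"))
    fpr = float((res["pvalue"] < 0.05).mean())
    assert 0.03 <= fpr <= 0.08


def test_wald_recovers_twofold_effect(rng):
    mu = np.exp(rng.uniform(np.log(100), np.log(1000), 1000))
    ca = _nb(rng, mu[:, None], 0.05, (1000, 2))
    cb = _nb(rng, 2 * mu[:, None], 0.05, (1000, 2))
    table = _table(np.hstack([ca, cb]))
    disp = atac.estimate_dispersion(table, UNIT_FACTORS)
    res = atac.wald_test(table, UNIT_FACTORS, disp, ("B", "A"))
    assert 0.7 <= float(np.median(res["log2FoldChange"])) <= 1.3


def test_wald_depth_confound_removed_by_size_factors(rng):
    mu = np.exp(rng.uniform(np.log(100), np.log(1000), 500))
    ca = _nb(rng, mu[:, None], 0.05, (500, 2))
    cb = _nb(rng, 2 * mu[:, None], 0.05, (500, 2))  # doubled depth, same biology
    table = _table(np.hstack([ca, cb]))
    factors = pd.Series([1.0, 1.0, 2.0, 2.0], index=COLS)
    disp = atac.estimate_dispersion(table, factors)
    res = atac.wald_test(table, factors, disp, ("B", "A"))
    assert abs(float(np.median(res["log2FoldChange"]))) < 0.1


def test_wald_all_zero_row_marked_untestable():
    table = _table([[0, 0, 0, 0], [10, 12, 30, 28]])
    res = atac.wald_test(table, UNIT_FACTORS, np.array([0.05, 0.05]), ("B", "A"))
    assert bool(res["untestable"].iloc[0])
    assert np.isnan(res["pvalue"].iloc[0])
    assert not bool(res["untestable"].iloc[1])


def test_wald_statistic_is_lfc_over_se():
    rng = np.random.default_rng(3)
    counts = _nb(rng, 500.0, 0.05, (50, 4))
    table = _table(counts)
    res = atac.wald_test(table, UNIT_FACTORS, np.full(50, 0.05), ("B", "A"))
    ok = ~res["untestable"]
    assert np.allclose(
        res.loc[ok, "stat"], res.loc[ok, "log2FoldChange"] / res.loc[ok, "lfcSE"]
    )
    assert ((res.loc[ok, "pvalue"] > 0) & (res.loc[ok, "pvalue"] <= 1)).all()


def test_wald_requires_two_replicates():
    cols = ["a1", "b1", "b2"]
    table = atac.CountTable(
        pd.DataFrame([[5, 6, 7]], columns=cols),
        pd.Series(["A", "B", "B"], index=cols),
        half_width=250,
    )
    with pytest.raises(ValueError, match="replicates"):
        atac.wald_test(table, pd.Series(1.0, index=cols), np.array([0.05]), ("B", "A"))


def test_nb_glm_matches_statsmodels_oracle():
    """Cross-check the IRLS fit against an independent NB GLM implementation."""
    sm = pytest.importorskip("statsmodels.api")
    rng = np.random.default_rng(11)
    y = _nb(rng, np.array([200.0, 200, 200, 400, 400, 400]), 0.1, 6).astype(float)
    x = np.column_stack([np.ones(6), np.array([0, 0, 0, 1, 1, 1.0])])
    offset = np.log(np.array([1.0, 1.1, 0.9, 1.0, 1.2, 0.8]))
    alpha = 0.1
    beta, cov = atac._nb_irls(y, x, offset, alpha)
    model = sm.GLM(
        y, x, family=sm.families.NegativeBinomial(alpha=alpha), offset=offset
    ).fit()
    assert beta == pytest.approx(model.params, rel=1e-5)
    assert np.sqrt(cov[1, 1]) == pytest.approx(model.bse[1], rel=1e-4)
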