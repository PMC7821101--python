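"""Counts-to-hits statistics: epsilon, Mann-Whitney, eta, eFDR."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import mannwhitneyu, rankdata

from optenrich.scoring import (
    CountTable,
    average_runs,
    efdr_at,
    efdr_curve,
    eta,
    group_scores,
    hit_rate,
    mannwhitney_batch,
    phenotypic_scores,
    simulated_negatives,
    tss_pvalue,
)

# ---------------------------------------------------------------------------
# phenotypic scores


def test_epsilon_toy_table(toy_count_table):
    """Hand arithmetic: 8v2 with pc=1 gives log2(9/3) = 1.585 after the
    nontargeting centering cancels the depth factor."""
    eps = phenotypic_scores(toy_count_table, "sample", "reference")
    assert eps["A"] == pytest.approx(math.log2(3), abs=1e-12)
    assert eps["NT1"] == pytest.approx(0.0, abs=1e-12)


def test_epsilon_identical_columns_is_zero(toy_count_table):
    t = toy_count_table
    t.frame["sample2"] = t.frame["reference"]
    eps = phenotypic_scores(t, "sample2", "reference")
    assert np.allclose(eps.to_numpy(), 0.0)


def test_epsilon_depth_invariance(toy_count_table):
    eps1 = phenotypic_scores(toy_count_table, "sample", "reference")
    doubled = CountTable(
        toy_count_table.frame.assign(
            sample=toy_count_table.frame["sample"] * 2,
            reference=toy_count_table.frame["reference"] * 2,
        )
    )
    eps2 = phenotypic_scores(doubled, "sample", "reference")
    # doubling all counts only moves the pseudocount weight slightly; with
    # pc scaled off (pc=0 is not allowed with zeros, so compare pc ratios)
    assert eps2["NT1"] == pytest.approx(0.0, abs=1e-12)
    assert eps2["A"] == pytest.approx(math.log2(17 / 5), abs=1e-12)
    # depth normalization proper: multiplying ONE column's depth cancels
    tripled_ref = CountTable(
        toy_count_table.frame.assign(reference=toy_count_table.frame["reference"] * 3)
    )
    eps3 = phenotypic_scores(tripled_ref, "sample", "reference")
    assert eps3["A"] == pytest.approx(eps1["A"], abs=0.3)


def test_epsilon_nontargeting_median_exactly_zero(rng):
    n = 200
    frame = pd.DataFrame(
        {
            "gene": ["NONTARGETING" if i % 5 == 0 else f"G{i}" for i in range(n)],
            "tss": ["" if i % 5 == 0 else f"G{i}_T1" for i in range(n)],
            "s": rng.integers(0, 500, n),
            "r": rng.integers(0, 500, n),
        },
        index=pd.Index([f"sg{i}" for i in range(n)], name="sgrna_id"),
    )
    t = CountTable(frame)
    eps = phenotypic_scores(t, "s", "r")
    assert np.median(eps[t.nontargeting_ids]) == pytest.approx(0.0, abs=1e-12)


def test_epsilon_errors(toy_count_table):
    with pytest.raises(ValueError):
        phenotypic_scores(toy_count_table, "sample", "sample")
    zero = CountTable(toy_count_table.frame.assign(z=[0, 0, 0]))
    with pytest.raises(ValueError):
        phenotypic_scores(zero, "sample", "z")
    with pytest.raises(ValueError):
        phenotypic_scores(toy_count_table, "sample", "reference",
                          nontargeting_ids=[])


# ---------------------------------------------------------------------------
# run averaging and grouping


def test_average_runs():
    idx = pd.Index(list("abc"), name="sgrna_id")
    runs = [pd.Series([1.0, 2.0, 0.0], index=idx),
            pd.Series([1.0, 0.0, 0.0], index=idx)]
    avg = average_runs(runs)
    assert avg.tolist() == [1.0, 1.0, 0.0]
    assert average_runs([runs[0]]).equals(runs[0].rename("epsilon"))
    with pytest.raises(ValueError):
        average_runs([runs[0], runs[1].iloc[:2]])
    with pytest.raises(ValueError):
        average_runs([])


def test_run_averaging_reduces_variance(rng):
    """Averaging four independent count draws of the same population shrinks
    the per-sgRNA epsilon spread."""
    n = 300
    idx = pd.Index([f"sg{i}" for i in range(n)], name="sgrna_id")
    gene = ["NONTARGETING" if i < 30 else f"G{i}" for i in range(n)]
    p = np.full(n, 1 / n)
    ref = rng.multinomial(200_000, p)
    per_run = []
    for _ in range(4):
        frame = pd.DataFrame(
            {"gene": gene, "tss": gene, "s": rng.multinomial(50_000, p), "r": ref},
            index=idx,
        )
        per_run.append(phenotypic_scores(CountTable(frame), "s", "r"))
    avg = average_runs(per_run)
    assert avg.var() < per_run[0].var()


def test_group_scores_modes(rng):
    scores = pd.Series(rng.normal(size=6), index=[f"sg{i}" for i in range(6)])
    g1 = group_scores(scores, 1, seed=0)
    assert sorted(g1.to_numpy()) == pytest.approx(sorted(scores.to_numpy()))
    g2 = group_scores(scores, 2, seed=3)
    assert len(g2) == 3
    assert g2.to_numpy().sum() * 2 == pytest.approx(scores.sum())
    # leftover dropped
    g4 = group_scores(scores, 4, seed=3)
    assert len(g4) == 1
    with pytest.raises(ValueError):
        group_scores(scores, 7)
    # deterministic per seed
    assert group_scores(scores, 2, seed=5).equals(group_scores(scores, 2, seed=5))


# ---------------------------------------------------------------------------
# Mann-Whitney


def _enumeration_oracle(x, y):
    """Independent brute-force two-sided permutation p for the U statistic,
    computed from pairwise comparisons (no rank machinery)."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_of(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = 0.0
        for xi in a:
            for yi in b:
                u += (xi > yi) + 0.5 * (xi == yi)
        return u

    mu = n1 * (len(pooled) - n1) / 2.0
    obs = abs(u_of(range(n1)) - mu)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        total += 1
        hits += abs(u_of(idx) - mu) >= obs - 1e-9
    return hits / total


def test_mannwhitney_exact_example():
    """(3,4,5) vs (0,1,2): the 2 extreme arrangements out of C(6,3)=20."""
    assert tss_pvalue([3, 4, 5], [0, 1, 2]) == pytest.approx(0.1)


def test_mannwhitney_equal_multisets_p_one():
    assert tss_pvalue([1.0, 2.0, 3.0], [3.0, 1.0, 2.0]) == pytest.approx(1.0)
    assert tss_pvalue([5.0] * 3, [5.0] * 7) == 1.0


@pytest.mark.parametrize("n1, n2", [(2, 3), (3, 5), (4, 7), (5, 8)])
def test_mannwhitney_matches_enumeration_oracle(n1, n2, rng):
    """Exact small-sample path agrees with the independent enumeration
    oracle, with and without ties."""
    for tied in (False, True):
        for _ in range(5):
            if tied:
                x = rng.integers(0, 4, n1).astype(float)
                y = rng.integers(0, 4, n2).astype(float)
                if np.all(np.concatenate([x, y]) == x[0]):
                    continue
            else:
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
            assert tss_pvalue(x, y) == pytest.approx(
                _enumeration_oracle(x, y), abs=1e-12
            )


def test_mannwhitney_batch_matches_scipy(rng):
    """Vectorized batch path reproduces scipy's tie-corrected asymptotic
    two-sided p row by row."""
    controls = rng.normal(size=22)
    members = rng.normal(size=(50, 10))
    members[::3] = np.round(members[::3])  # inject ties
    controls_t = np.round(controls)
    for ctrl in (controls, controls_t):
        ps = mannwhitney_batch(members, ctrl)
        for row, p in zip(members, ps):
            ref = mannwhitneyu(row, ctrl, alternative="two-sided",
                               method="asymptotic").pvalue
            assert p == pytest.approx(ref, abs=1e-12)


def test_mannwhitney_large_sample_uses_asymptotic(rng):
    x = rng.normal(1.0, 1.0, size=10)
    y = rng.normal(size=22)
    ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
    assert tss_pvalue(x, y) == pytest.approx(ref, abs=1e-12)


def test_mannwhitney_empty_errors():
    with pytest.raises(ValueError):
        tss_pvalue([], [1.0])


# ---------------------------------------------------------------------------
# eta


def test_eta_closed_form():
    assert eta(2.0, math.exp(-3)) == pytest.approx(6.0)
    assert eta(1.5, 1.0) == 0.0
    assert eta(0.0, 0.01) == 0.0
    with pytest.raises(ValueError):
        eta(1.0, 0.0)
    with pytest.raises(ValueError):
        eta(1.0, 1.5)


@settings(derandomize=True, max_examples=60)
@given(
    e1=st.floats(0.01, 50), e2=st.floats(0.01, 50),
    p1=st.floats(1e-12, 1.0, exclude_min=False), p2=st.floats(1e-12, 1.0),
)
def test_eta_monotone(e1, e2, p1, p2):
    """eta increases with |epsilon| at fixed p and with -ln p at fixed eps."""
    lo_e, hi_e = sorted([e1, e2])
    assert eta(lo_e, p1) <= eta(hi_e, p1)
    lo_p, hi_p = sorted([p1, p2])
    assert eta(e1, hi_p) <= eta(e1, lo_p)


# ---------------------------------------------------------------------------
# simulated negatives


def test_simulated_negatives_null_library():
    idx = pd.Index([f"sg{i}" for i in range(60)], name="sgrna_id")
    scores = pd.Series(np.zeros(60), index=idx)
    sim = simulated_negatives(scores, np.zeros(22), group_size=10, seed=1)
    assert len(sim) == 6
    assert np.allclose(sim["epsilon"], 0.0)
    assert np.allclose(sim["p_value"], 1.0)
    assert np.allclose(sim["eta"], 0.0)


def test_simulated_negatives_group_count(rng):
    idx = pd.Index([f"sg{i}" for i in range(6092)], name="sgrna_id")
    scores = pd.Series(rng.normal(size=6092), index=idx)
    sim = simulated_negatives(scores, rng.normal(size=22), group_size=10, seed=2)
    assert len(sim) == 609  # floor(6092 / 10) per regrouping
    # deterministic per seed
    sim2 = simulated_negatives(scores, rng.normal(size=22), group_size=10, seed=2)
    assert np.allclose(sim["epsilon"], sim2["epsilon"])
    with pytest.raises(ValueError):
        simulated_negatives(scores.iloc[:5], np.zeros(3), group_size=10)


def test_simulated_negatives_null_calibration(rng):
    """On a fully null score set, real-gene and simulated-negative etas are
    indistinguishable (KS p > 0.01)."""
    from scipy.stats import ks_2samp

    from optenrich.scoring import score_genes

    n_genes = 200
    idx = pd.Index([f"g{i}_sg{j}" for i in range(n_genes) for j in range(10)]
                   + [f"nt{j}" for j in range(22)], name="sgrna_id")
    gene = [f"G{i}" for i in range(n_genes) for _ in range(10)] + [
        "NONTARGETING"] * 22
    tss = [f"G{i}_T1" for i in range(n_genes) for _ in range(10)] + [""] * 22
    eps = pd.Series(rng.normal(size=len(idx)), index=idx)
    ann = pd.DataFrame({"gene": gene, "tss": tss}, index=idx)
    genes = score_genes(eps, ann)
    sim = simulated_negatives(eps, eps[ann["gene"] == "NONTARGETING"].to_numpy(),
                              group_size=10, n_groups=2000, seed=3)
    assert ks_2samp(genes["eta"], sim["eta"]).pvalue > 0.01


# ---------------------------------------------------------------------------
# eFDR


def test_efdr_hand_count():
    """genes (5,4,1), simnegs (2,0.5), cutoff 1.5: one simneg and two genes
    above, so eFDR = 1/3."""
    assert efdr_at([5, 4, 1], [2, 0.5], 1.5) == pytest.approx(1 / 3)


def test_efdr_zero_above_max_simneg():
    assert efdr_at([5, 4, 1], [2, 0.5], 3.0) == 0.0
    assert efdr_at([], [2.0], 3.0) == 0.0  # 0/0 := 0


def test_efdr_curve_cutoff_and_hits():
    curve, hits = efdr_curve([5, 4, 1], [2, 0.5], target=0.001)
    # smallest observed eta with eFDR <= target is the max simneg (2.0):
    # above it no simneg remains and two genes do
    assert curve.chosen_cutoff == 2.0
    assert hits.tolist() == [True, True, False]
    with pytest.raises(ValueError):
        efdr_curve([], [1.0])


@settings(derandomize=True, max_examples=50)
@given(
    g=st.lists(st.floats(0, 100), min_size=1, max_size=30),
    s=st.lists(st.floats(0, 100), min_size=1, max_size=30),
    c=st.floats(0, 100),
)
def test_efdr_matches_brute_force(g, s, c):
    n_s = sum(1 for v in s if v > c)
    n_g = sum(1 for v in g if v > c)
    expected = n_s / (n_g + n_s) if (n_g + n_s) else 0.0
    assert efdr_at(g, s, c) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# hit rate and subsetting


def test_hit_rate_worked_example():
    """15 of 544 screened genes reproduce the printed 2.76% hit rate."""
    assert round(hit_rate(15, 544), 2) == 2.76
    with pytest.raises(ValueError):
        hit_rate(5, 0)


def test_top5_subset(screen_library):
    table = CountTable.from_library(screen_library.annotations())
    sub = table.top5_subset()
    ranks = sub.frame["sg_rank"]
    assert ranks.max() == 5
    # nontargeting rows are retained for centering/testing
    assert len(sub.nontargeting_ids) == 22
    assert len(sub.frame) == 607 * 5 + 22  # 544 + 63 extra TSSs, 5 sgRNAs each
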