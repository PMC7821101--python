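"""Counts-to-hits statistics for pooled screens.

The scoring stack follows the enrichment-screen convention: a per-sgRNA
phenotypic score epsilon is the depth-normalized log2 read-count ratio of
a sorted sample over a reference sample, centered so that the median
epsilon of the nontargeting control sgRNAs is exactly zero.  sgRNAs are
grouped by the transcription start site (TSS) they target; each TSS is
scored by the mean epsilon of its sgRNAs and by a two-sided Mann-Whitney U
test of those epsilons against the nontargeting controls.  The combined
score is

    eta = |epsilon_gene| * (-ln p)

so eta grows with both the severity of the phenotype and its statistical
trustworthiness.  Because only a couple dozen nontargeting sgRNAs exist,
significance is calibrated against simulated negative controls built by
randomly regrouping all library sgRNAs into pseudo-genes of the same size
and scoring them identically; an empirical FDR over eta then sets the hit
cutoff (default target 0.1%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import comb, ndtr

__all__ = [
    "CountTable",
    "phenotypic_scores",
    "average_runs",
    "group_scores",
    "tss_pvalue",
    "mannwhitney_batch",
    "simulated_negatives",
    "eta",
    "score_genes",
    "collapse_gene",
    "EFDRCurve",
    "efdr_curve",
    "hit_rate",
]

EXACT_ENUMERATION_LIMIT = 100_000  # max C(n1+n2, n1) for the exact MW path


class CountTable:
    """sgRNA x sample read-count table with gene/TSS annotations.

    Thin wrapper around a DataFrame indexed by sgrna_id with annotation
    columns (``gene``, ``tss``, optionally ``sg_rank``) and one integer
    column per sample.
    """

    ANNOT = ("gene", "tss", "sg_rank")

    def __init__(self, frame: pd.DataFrame):
        if frame.index.name != "sgrna_id":
            raise ValueError("CountTable frame must be indexed by sgrna_id")
        if not frame.index.is_unique:
            raise ValueError("duplicate sgrna_id rows")
        self.frame = frame
        for s in self.samples:
            if (frame[s] < 0).any():
                raise ValueError(f"negative counts in sample {s!r}")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.frame.columns if c not in self.ANNOT]

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.frame.index

    @property
    def nontargeting_ids(self) -> pd.Index:
        return self.frame.index[self.frame["gene"] == "NONTARGETING"]

    def counts(self, sample: str) -> pd.Series:
        if sample not in self.samples:
            raise KeyError(f"unknown sample {sample!r}")
        return self.frame[sample]

    def add_sample(self, name: str, counts: pd.Series) -> None:
        if name in self.frame.columns:
            raise ValueError(f"sample {name!r} already present")
        self.frame[name] = counts.reindex(self.frame.index, fill_value=0).astype(np.int64)

    def subset_rows(self, mask) -> "CountTable":
        return CountTable(self.frame.loc[mask].copy())

    def top5_subset(self) -> "CountTable":
        """Rows restricted to the high-efficacy ("Top5") sgRNA class.

        Keeps nontargeting rows (sg_rank 0) so control-based centering and
        testing still work on the subset.
        """
        if "sg_rank" not in self.frame.columns:
            raise ValueError("count table lacks sg_rank annotation")
        rank = self.frame["sg_rank"]
        half = math.ceil(rank.max() / 2)
        return self.subset_rows((rank == 0) | (rank <= half))

    @classmethod
    def from_library(cls, annotations: pd.DataFrame) -> "CountTable":
        frame = annotations.copy()
        if frame.index.name != "sgrna_id":
            frame = frame.set_index("sgrna_id")
        return cls(frame)

    def write_tsv(self, path, header_lines: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.frame.to_csv(fh, sep="\t")

    @classmethod
    def read_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                         na_values=[])
        return cls(df.set_index("sgrna_id"))


def phenotypic_scores(
    table: CountTable,
    sample: str,
    reference: str,
    nontargeting_ids: Iterable[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-sgRNA phenotypic score epsilon (log2 units).

    epsilon_i = log2[ (c_s,i + pc)/N_s  /  (c_r,i + pc)/N_r ]
                - median over nontargeting sgRNAs of the same quantity,

    where N is the raw total of each column.  The nontargeting median is
    exactly zero after centering, which makes the control null exact and
    cancels the depth-normalization factor.
    """
    if sample == reference:
        raise ValueError("sample and reference must differ")
    cs = table.counts(sample).to_numpy(dtype=float)
    cr = table.counts(reference).to_numpy(dtype=float)
    ns, nr = cs.sum(), cr.sum()
    if ns == 0 or nr == 0:
        raise ValueError("zero total reads in a count column")
    if nontargeting_ids is None:
        nontargeting_ids = table.nontargeting_ids
    nt = pd.Index(nontargeting_ids)
    if len(nt) == 0:
        raise ValueError("nontargeting_ids must be non-empty")
    if not nt.isin(table.sgrna_ids).all():
        raise KeyError("nontargeting ids absent from count table")

    raw = np.log2((cs + pseudocount) / ns) - np.log2((cr + pseudocount) / nr)
    eps = pd.Series(raw, index=table.sgrna_ids, name="epsilon")
    return eps - eps.loc[nt].median()


def average_runs(per_run_scores: Sequence[pd.Series]) -> pd.Series:
    """Arithmetic mean of per-run epsilons; a single run is the identity."""
    if len(per_run_scores) == 0:
        raise ValueError("need at least one run")
    first = per_run_scores[0].index
    for s in per_run_scores[1:]:
        if not s.index.equals(first):
            raise ValueError("mismatched sgRNA sets across runs")
    out = pd.concat(per_run_scores, axis=1).mean(axis=1)
    out.name = "epsilon"
    return out


def group_scores(
    scores: pd.Series,
    group_size: int,
    mode: str = "random",
    seed: int = 0,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.Series:
    """Mean epsilon per group of sgRNAs.

    mode="random" partitions the sgRNAs into disjoint groups of
    ``group_size`` without replacement (leftover sgRNAs are dropped);
    mode="by_group" uses the provided group -> member-ids mapping.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if mode == "by_group":
        if groups is None:
            raise ValueError("mode='by_group' requires a groups mapping")
        return pd.Series(
            {g: scores.loc[list(members)].mean() for g, members in groups.items()},
            name="epsilon",
        )
    if mode != "random":
        raise ValueError(f"unknown mode {mode!r}")
    n = len(scores)
    if group_size > n:
        raise ValueError("group_size exceeds number of sgRNAs")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 31]))
    perm = rng.permutation(n)
    n_groups = n // group_size
    vals = scores.to_numpy()[perm[: n_groups * group_size]]
    means = vals.reshape(n_groups, group_size).mean(axis=1)
    return pd.Series(means, index=[f"group{i + 1}" for i in range(n_groups)],
                     name="epsilon")


def _exact_mw_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact Mann-Whitney p by enumeration over label assignments.

    Handles ties: p = P(|U - n1 n2 / 2| >= |U_obs - n1 n2 / 2|) under the
    permutation distribution (which is symmetric about n1 n2 / 2).
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n1 * n2 / 2.0
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - mu)
    total = 0
    extreme = 0
    for idx in combinations(range(n1 + n2), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        total += 1
        if abs(u - mu) >= dev_obs - 1e-9:
            extreme += 1
    return extreme / total


def tss_pvalue(member_eps: Sequence[float], nontargeting_eps: Sequence[float]) -> float:
    """Two-sided Mann-Whitney p of a TSS's sgRNA epsilons vs controls.

    Uses the exact permutation distribution when C(n1+n2, n1) is small
    enough to enumerate, otherwise the tie-corrected normal approximation
    with continuity correction.  Degenerate input (all values identical in
    both lists) returns p = 1.
    """
    x = np.asarray(member_eps, dtype=float)
    y = np.asarray(nontargeting_eps, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    if comb(len(x) + len(y), len(x)) <= EXACT_ENUMERATION_LIMIT:
        return _exact_mw_pvalue(x, y)
    return float(mannwhitney_batch(x[None, :], y)[0])


def mannwhitney_batch(members: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Vectorized two-sided tie-corrected normal-approximation Mann-Whitney.

    ``members`` is (k, n1); every row is tested against the same 1-D
    ``controls`` (n2,).  Matches scipy.stats.mannwhitneyu
    (method="asymptotic", use_continuity=True) row by row.
    """
    members = np.atleast_2d(np.asarray(members, dtype=float))
    controls = np.asarray(controls, dtype=float)
    k, n1 = members.shape
    n2 = len(controls)
    n = n1 + n2
    pooled = np.concatenate(
        [members, np.broadcast_to(controls, (k, n2))], axis=1
    )
    ranks = sps.rankdata(pooled, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0

    # Tie correction: sum(t^3 - t) over tied groups, per row.
    srt = np.sort(pooled, axis=1)
    tie_term = np.zeros(k)
    same = np.hstack([np.zeros((k, 1), bool), srt[:, 1:] == srt[:, :-1]])
    if same.any():
        for i in np.nonzero(same.any(axis=1))[0]:
            _, counts = np.unique(srt[i], return_counts=True)
            tie_term[i] = float((counts.astype(float) ** 3 - counts).sum())
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(sigma2)

    dev = u1 - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(dev) - 0.5) / sigma
    p = np.where(sigma > 0, 2.0 * (1.0 - ndtr(z)), 1.0)
    return np.clip(p, 0.0, 1.0)


def eta(epsilon_gene: float, p: float) -> float:
    """Combined score: eta = |epsilon| * (-ln p); zero iff eps=0 or p=1."""
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    return abs(epsilon_gene) * (-math.log(p))


def score_genes(
    eps: pd.Series,
    annotations: pd.DataFrame,
    nontargeting_eps: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Score every TSS: mean epsilon, Mann-Whitney p vs controls, eta.

    ``annotations`` maps sgrna_id -> (gene, tss); nontargeting rows define
    the control epsilons when ``nontargeting_eps`` is not given.  Returns a
    frame with one row per TSS (columns gene, tss, epsilon, p_value, eta).
    """
    ann = annotations.loc[eps.index]
    if nontargeting_eps is None:
        nontargeting_eps = eps[ann["gene"] == "NONTARGETING"].to_numpy()
    nontargeting_eps = np.asarray(nontargeting_eps, dtype=float)
    if len(nontargeting_eps) == 0:
        raise ValueError("no nontargeting control epsilons")

    targeting = ann["gene"] != "NONTARGETING"
    grouped = eps[targeting].groupby(ann.loc[targeting, "tss"], sort=True)
    tss_ids, genes, means, member_rows = [], [], [], []
    sizes = set()
    for tss, vals in grouped:
        tss_ids.append(tss)
        genes.append(ann.loc[vals.index[0], "gene"])
        means.append(vals.mean())
        member_rows.append(vals.to_numpy())
        sizes.add(len(vals))

    if len(sizes) == 1:
        pvals = mannwhitney_batch(np.vstack(member_rows), nontargeting_eps)
    else:  # ragged TSS sizes (e.g. after subsetting): score row by row
        pvals = np.array(
            [mannwhitney_batch(r[None, :], nontargeting_eps)[0] for r in member_rows]
        )
    means = np.asarray(means)
    etas = np.abs(means) * (-np.log(np.clip(pvals, 1e-300, 1.0)))
    return pd.DataFrame(
        {"gene": genes, "tss": tss_ids, "epsilon": means,
         "p_value": pvals, "eta": etas}
    )


def collapse_gene(tss_scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse multi-TSS genes to the TSS with maximal eta."""
    idx = tss_scores.groupby("gene")["eta"].idxmax()
    return tss_scores.loc[idx].set_index("gene").sort_index()


def simulated_negatives(
    scores: pd.Series,
    nontargeting_eps: Sequence[float],
    group_size: int = 10,
    n_groups: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score simulated negative controls by random sgRNA regrouping.

    All sgRNAs in ``scores`` (targeting and nontargeting alike) are
    randomly partitioned into pseudo-genes of ``group_size`` sgRNAs; each
    pseudo-gene is scored exactly like a real gene (mean epsilon,
    Mann-Whitney p vs the nontargeting controls, eta).  One regrouping
    yields floor(n / group_size) negatives; ``n_groups`` larger than that
    draws additional independent regroupings until satisfied (default: one
    regrouping).
    """
    n = len(scores)
    if n < group_size:
        raise ValueError("library smaller than group_size")
    per_draw = n // group_size
    if n_groups is None:
        n_groups = per_draw
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 47]))
    vals = scores.to_numpy(dtype=float)
    rows = []
    while sum(r.shape[0] for r in rows) < n_groups:
        perm = rng.permutation(n)
        take = vals[perm[: per_draw * group_size]].reshape(per_draw, group_size)
        rows.append(take)
    members = np.vstack(rows)[:n_groups]
    pvals = mannwhitney_batch(members, np.asarray(nontargeting_eps, dtype=float))
    means = members.mean(axis=1)
    etas = np.abs(means) * (-np.log(np.clip(pvals, 1e-300, 1.0)))
    return pd.DataFrame(
        {
            "gene": [f"simneg{i + 1}" for i in range(n_groups)],
            "epsilon": means,
            "p_value": pvals,
            "eta": etas,
            "is_simulated_negative": True,
        }
    )


@dataclass
class EFDRCurve:
    """Empirical-FDR curve over eta cutoffs.

    ``efdr[i]`` is the raw empirical FDR at ``cutoffs[i]``:
    #{simulated negatives with eta > c} / #{genes or negatives with eta > c}
    (0/0 := 0).  ``chosen_cutoff`` is the smallest observed eta value whose
    eFDR is at or below ``target`` (+inf when none qualifies).
    """

    cutoffs: np.ndarray
    efdr: np.ndarray
    chosen_cutoff: float
    target: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.cutoffs, "efdr": self.efdr})


def efdr_curve(
    gene_etas: Sequence[float],
    simneg_etas: Sequence[float],
    target: float = 0.001,
) -> tuple[EFDRCurve, np.ndarray]:
    """Empirical-FDR thresholding of gene etas against simulated negatives.

    Returns the curve and a boolean hit mask over ``gene_etas`` (hits are
    genes with eta strictly above the chosen cutoff).
    """
    g = np.asarray(gene_etas, dtype=float)
    s = np.asarray(simneg_etas, dtype=float)
    if len(g) == 0 or len(s) == 0:
        raise ValueError("gene and simulated-negative eta lists must be non-empty")
    cutoffs = np.unique(np.concatenate([g, s]))
    g_sorted = np.sort(g)
    s_sorted = np.sort(s)
    # strict inequality: count of values > c
    n_g = len(g) - np.searchsorted(g_sorted, cutoffs, side="right")
    n_s = len(s) - np.searchsorted(s_sorted, cutoffs, side="right")
    denom = n_g + n_s
    with np.errstate(invalid="ignore", divide="ignore"):
        efdr = np.where(denom > 0, n_s / np.maximum(denom, 1), 0.0)
    ok = efdr <= target
    chosen = float(cutoffs[ok][0]) if ok.any() else math.inf
    hits = g > chosen
    return EFDRCurve(cutoffs=cutoffs, efdr=efdr, chosen_cutoff=chosen,
                     target=target), hits


def efdr_at(gene_etas, simneg_etas, cutoff: float) -> float:
    """Raw empirical FDR at a single cutoff (strict inequality, 0/0 := 0)."""
    g = np.asarray(gene_etas, dtype=float)
    s = np.asarray(simneg_etas, dtype=float)
    n_g = int((g > cutoff).sum())
    n_s = int((s > cutoff).sum())
    return n_s / (n_g + n_s) if (n_g + n_s) > 0 else 0.0


def hit_rate(n_hits: int, n_genes_screened: int) -> float:
    """Screen hit rate as a percentage of genes screened."""
    if n_genes_screened <= 0:
        raise ValueError("n_genes_screened must be positive")
    if not 0 <= n_hits <= n_genes_screened:
        raise ValueError("n_hits out of range")
    return 100.0 * n_hits / n_genes_screened
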