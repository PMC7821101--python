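"""End-to-end screen orchestration from a JSON run configuration.

Three screen flavors are provided, mirroring the experimental designs an
optical-enrichment screen is run in:

* :func:`run_mock_screen` — the proof-of-principle screen: a 9:1 mixture
  of marker-negative and marker-positive cells carrying two separate
  barcode libraries; the marker (mIFP) is the phenotype, detected cells
  are photoactivated long (2,000 ms), true negatives short (100 ms), and
  group-level phenotypic scores separate the two libraries.
* :func:`run_size_screen` — the imaging screen proper: cells carry a
  CRISPRi library with planted hit genes that enlarge nuclei; cells with
  measured nuclear area above the screening threshold are photoactivated
  and sorted; runs are averaged and replicates intersected; hits are
  called at an empirical FDR over the combined score eta.
* :func:`run_sort_only_screen` — FACS-only comparison screens: the top
  10% of cells by forward scatter (cell size) or total H2B-GFP (DNA
  content proxy) are sorted directly, with the same count statistics.

Screen-scale simulations run analytically on the population frame
(measured area = true ellipse area x lognormal measurement noise) rather
than rendering and segmenting every field of view; the imaging modules
are exercised on rendered fields by their own operations and the
``render``/``segment`` CLI paths.  Everything is deterministic given
(config, seed), and every output file header carries the seed and a
config hash.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, ValidationError

from optenrich import library as lib_mod
from optenrich import scoring as sc
from optenrich.activation import ActivationResponse, photoactivate
from optenrich.flow import GateSet, apply_recovery, gate_events, precision, sort_to_counts
from optenrich.library import (
    DEFAULT_BASELINE_AREA,
    EffectModel,
    LibraryDesign,
    build_library,
    default_efficacies,
    simulate_population_frame,
)


class ConfigError(ValueError):
    """Configuration could not be resolved (bad JSON, bad field values)."""


# ---------------------------------------------------------------------------
# configuration models


class LibrarySpec(BaseModel):
    n_single_tss_genes: int = 481
    n_double_tss_genes: int = 63
    sgrnas_per_tss: int = 10
    n_nontargeting: int = 22


class EffectSpec(BaseModel):
    n_hit_genes: int = 0
    hit_genes: list[str] | None = None
    effect_size: float = 2.0
    penetrance: float = 0.6


class PopulationSpec(BaseModel):
    n_cells_per_run: int = 50_000
    infected_fraction: float = 0.95  # post-puromycin-selection population
    baseline_area_mean: float = DEFAULT_BASELINE_AREA[0]
    baseline_area_sd: float = DEFAULT_BASELINE_AREA[1]
    measurement_cv: float = 0.03  # lognormal area-measurement noise


class FilterSpec(BaseModel):
    min_area: float = 40.0
    max_area: float = 6000.0
    bfp_ln_threshold: float = 7.6
    size_threshold: float = 1000.0


class ActivationSpec(BaseModel):
    pos_ms: float = 2000.0
    neg_ms: float = 200.0
    i_max: float = 30000.0
    tau_ms: float = 1000.0
    background: float = 100.0
    noise_cv: float = 0.10

    def response(self) -> ActivationResponse:
        return ActivationResponse(
            i_max=self.i_max, tau_ms=self.tau_ms,
            background=self.background, noise_cv=self.noise_cv,
        )


class FlowSpec(BaseModel):
    recovery: float = 0.8
    depth: int = 1_000_000
    # reference material (true negatives, unanalyzed cells) is orders of
    # magnitude more abundant than photoactivated positives; cap high so
    # the reference never becomes the per-sgRNA coverage bottleneck
    n_sorted_negative: int = 50_000
    n_unanalyzed: int = 50_000


class AnalysisSpec(BaseModel):
    reference: str = "neg"  # "neg" (sorted true negatives) or "ctrl" (unanalyzed)
    pseudocount: float = 1.0
    group_size: int = 2  # mock-screen grouping
    simneg_group_size: int = 10
    simneg_draws: int = 50
    efdr_target: float = 0.001
    n_runs: int = 4
    n_replicates: int = 2


class MockSpec(BaseModel):
    n_cells: int = 150_000
    positive_fraction: float = 0.1  # 9:1 negative:positive mixture
    positive_barcodes: int = 860
    control_barcodes: int = 6100
    unanalyzed_fraction: float = 0.15
    detection_tp: float = 0.9
    detection_fp: float = 0.005
    neg_ms: float = 100.0
    n_sorted_negative: int = 30_000
    n_unanalyzed: int = 30_000


class SortScreenSpec(BaseModel):
    # sized so the top-10% sorted sample keeps several cells per sgRNA;
    # at lower coverage count discreteness swamps the per-sgRNA signal
    n_cells: int = 400_000
    top_fraction: float = 0.10
    fsc_noise_cv: float = 0.20
    gfp_facs_mean: float = 5000.0
    gfp_facs_cv: float = 0.25
    # the pre-FACS "unsorted" sample is bulk material, not cell-limited
    n_unsorted: int = 100_000


class RunConfig(BaseModel):
    seed: int = 0
    library: LibrarySpec = Field(default_factory=LibrarySpec)
    effects: EffectSpec = Field(default_factory=EffectSpec)
    population: PopulationSpec = Field(default_factory=PopulationSpec)
    filters: FilterSpec = Field(default_factory=FilterSpec)
    activation: ActivationSpec = Field(default_factory=ActivationSpec)
    flow: FlowSpec = Field(default_factory=FlowSpec)
    analysis: AnalysisSpec = Field(default_factory=AnalysisSpec)
    mock: MockSpec = Field(default_factory=MockSpec)
    sort_screen: SortScreenSpec = Field(default_factory=SortScreenSpec)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        try:
            with open(path) as fh:
                data = json.load(fh)
            return cls.model_validate(data)
        except (OSError, json.JSONDecodeError, ValidationError) as exc:
            raise ConfigError(str(exc)) from exc

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def header_lines(self, kind: str) -> list[str]:
        return [f"optenrich {kind} seed={self.seed} config={self.config_hash()}"]


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, tags)]))


# ---------------------------------------------------------------------------
# shared pieces


def _build_screen_library(cfg: RunConfig) -> tuple[LibraryDesign, EffectModel]:
    lib = build_library(
        cfg.library.n_single_tss_genes,
        cfg.library.n_double_tss_genes,
        cfg.library.sgrnas_per_tss,
        cfg.library.n_nontargeting,
        seed=cfg.seed,
    )
    if cfg.effects.hit_genes is not None:
        hits = frozenset(cfg.effects.hit_genes)
        unknown = hits - set(lib.genes)
        if unknown:
            raise ConfigError(f"hit genes not in library: {sorted(unknown)}")
    elif cfg.effects.n_hit_genes > 0:
        rng = _rng(cfg.seed, 3)
        hits = frozenset(
            str(g) for g in
            rng.choice(lib.genes, size=cfg.effects.n_hit_genes, replace=False)
        )
    else:
        hits = frozenset()
    effects = EffectModel(
        hit_genes=hits,
        effect_size=cfg.effects.effect_size,
        penetrance=cfg.effects.penetrance,
        sgrna_efficacy=default_efficacies(lib, seed=cfg.seed),
    )
    return lib, effects


def _score_averaged_screen(
    table: sc.CountTable,
    run_samples: Sequence[tuple[str, str]],
    analysis: AnalysisSpec,
    seed: int,
) -> dict:
    """Per-run epsilons -> run average -> TSS scores -> gene collapse ->
    simulated negatives -> eFDR hit calls.  Returns a result dict."""
    per_run = [
        sc.phenotypic_scores(table, s, r, pseudocount=analysis.pseudocount)
        for s, r in run_samples
    ]
    eps = sc.average_runs(per_run)
    ann = table.frame[["gene", "tss"]]
    tss_scores = sc.score_genes(eps, ann)
    gene_scores = sc.collapse_gene(tss_scores)
    nt_eps = eps[table.nontargeting_ids].to_numpy()
    per_draw = len(eps) // analysis.simneg_group_size
    simneg = sc.simulated_negatives(
        eps,
        nt_eps,
        group_size=analysis.simneg_group_size,
        n_groups=analysis.simneg_draws * per_draw,
        seed=seed,
    )
    curve, hit_mask = sc.efdr_curve(
        gene_scores["eta"].to_numpy(), simneg["eta"].to_numpy(),
        target=analysis.efdr_target,
    )
    gene_scores = gene_scores.copy()
    gene_scores["hit"] = hit_mask
    return {
        "epsilon": eps,
        "per_run_epsilon": per_run,
        "tss_scores": tss_scores,
        "gene_scores": gene_scores,
        "simneg": simneg,
        "efdr_curve": curve,
        "hits": sorted(gene_scores.index[hit_mask]),
    }


# ---------------------------------------------------------------------------
# nuclear size screen


@dataclass
class SizeScreenResult:
    table: sc.CountTable
    replicates: list[dict]
    hits_per_replicate: list[list[str]]
    intersection_hits: list[str]
    planted_hits: list[str]
    diagnostics: pd.DataFrame


def _simulate_size_run(
    cfg: RunConfig,
    lib: LibraryDesign,
    effects: EffectModel,
    rep: int,
    run: int,
) -> tuple[dict[str, list[str]], dict]:
    """One imaging run at the cell level: simulate, measure, filter,
    photoactivate, gate, recover.  Returns sgRNA lists per sample and a
    diagnostics dict."""
    seed = cfg.seed
    pop = simulate_population_frame(
        lib,
        effects,
        cfg.population.n_cells_per_run,
        cfg.population.infected_fraction,
        (cfg.population.baseline_area_mean, cfg.population.baseline_area_sd),
        seed=int(_rng(seed, 100, rep, run).integers(2**31)),
    )
    rng = _rng(seed, 101, rep, run)
    mcv = cfg.population.measurement_cv
    sigma = math.sqrt(math.log1p(mcv**2)) if mcv > 0 else 0.0
    measured = pop["area_um2"].to_numpy() * (
        np.exp(rng.normal(-sigma**2 / 2.0, sigma, len(pop))) if sigma else 1.0
    )

    bfp_pass = pop["bfp_ln"].to_numpy() > cfg.filters.bfp_ln_threshold
    in_bounds = (measured >= cfg.filters.min_area) & (measured <= cfg.filters.max_area)
    analyzed = bfp_pass & in_bounds
    positive = analyzed & (measured > cfg.filters.size_threshold)
    negative = analyzed & ~positive

    # dual activation: positives long, a sortable subset of true negatives short
    exposure = np.zeros(len(pop))
    exposure[positive] = cfg.activation.pos_ms
    neg_idx = np.flatnonzero(negative)
    n_neg = min(len(neg_idx), cfg.flow.n_sorted_negative)
    neg_take = rng.choice(neg_idx, size=n_neg, replace=False) if n_neg else neg_idx
    exposure[neg_take] = cfg.activation.neg_ms

    response = cfg.activation.response()
    mcherry = photoactivate(
        exposure, response, seed=int(rng.integers(2**31))
    )
    gates = GateSet.from_activation_classes(
        np.full(2000, response.background),
        {"neg": cfg.activation.neg_ms, "pos": cfg.activation.pos_ms},
        response,
    )
    events = pd.DataFrame({"cell_id": pop["cell_id"], "mcherry": mcherry})
    assignment = gate_events(events, gates)

    samples: dict[str, list[str]] = {}
    for name in ("pos", "neg"):
        ids = events.loc[assignment == name, "cell_id"].to_numpy()
        kept = apply_recovery(ids, cfg.flow.recovery, seed=int(rng.integers(2**31)))
        sgrnas = pop.loc[pop["cell_id"].isin(kept), "sgrna_id"]
        samples[name] = [s for s in sgrnas if s]
    # unanalyzed control: BFP-passing cells sampled without image analysis
    pool = np.flatnonzero(bfp_pass & (pop["sgrna_id"] != "").to_numpy())
    take = rng.choice(pool, size=min(len(pool), cfg.flow.n_unanalyzed), replace=False)
    samples["ctrl"] = list(pop.loc[take, "sgrna_id"])

    diag = {
        "replicate": rep,
        "run": run,
        "cells": len(pop),
        "analyzed": int(analyzed.sum()),
        "selected_positive": int(positive.sum()),
        "sorted_positive": len(samples["pos"]),
        "sorted_negative": len(samples["neg"]),
        "unanalyzed": len(samples["ctrl"]),
    }
    return samples, diag


def run_size_screen(cfg: RunConfig, outdir=None) -> SizeScreenResult:
    """Nuclear size screen: runs x replicates, run-averaged scoring,
    eFDR hit calling per replicate, and the replicate intersection."""
    lib, effects = _build_screen_library(cfg)
    table = sc.CountTable.from_library(lib.annotations())
    diags = []
    for rep in range(cfg.analysis.n_replicates):
        for run in range(cfg.analysis.n_runs):
            samples, diag = _simulate_size_run(cfg, lib, effects, rep, run)
            diags.append(diag)
            for name, sgrnas in samples.items():
                counts = sort_to_counts(
                    sgrnas, lib.sgrna_ids, cfg.flow.depth,
                    seed=int(_rng(cfg.seed, 102, rep, run, hash(name) % 1000).integers(2**31)),
                )
                table.add_sample(f"rep{rep + 1}_run{run + 1}_{name}", counts)

    ref = cfg.analysis.reference
    replicates = []
    hits_per_rep = []
    for rep in range(cfg.analysis.n_replicates):
        run_samples = [
            (f"rep{rep + 1}_run{r + 1}_pos", f"rep{rep + 1}_run{r + 1}_{ref}")
            for r in range(cfg.analysis.n_runs)
        ]
        res = _score_averaged_screen(
            table, run_samples, cfg.analysis,
            seed=int(_rng(cfg.seed, 103, rep).integers(2**31)),
        )
        replicates.append(res)
        hits_per_rep.append(res["hits"])

    intersection = sorted(set(hits_per_rep[0]).intersection(*hits_per_rep[1:]))
    result = SizeScreenResult(
        table=table,
        replicates=replicates,
        hits_per_replicate=hits_per_rep,
        intersection_hits=intersection,
        planted_hits=sorted(effects.hit_genes),
        diagnostics=pd.DataFrame(diags),
    )
    if outdir is not None:
        _write_size_screen(result, cfg, outdir)
    return result


def _write_tsv(df: pd.DataFrame, path: Path, header: list[str], index: bool) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_size_screen(result: SizeScreenResult, cfg: RunConfig, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = cfg.header_lines("size-screen")
    result.table.write_tsv(outdir / "counts.tsv", header)
    _write_tsv(result.diagnostics, outdir / "diagnostics.tsv", header, index=False)
    for i, res in enumerate(result.replicates, start=1):
        gene = res["gene_scores"].copy()
        gene["neg_ln_p"] = -np.log(gene["p_value"])
        _write_tsv(gene, outdir / f"replicate{i}_genes.tsv", header, index=True)
        _write_tsv(res["efdr_curve"].to_frame(), outdir / f"replicate{i}_efdr.tsv",
                   header, index=False)
        _write_tsv(res["simneg"], outdir / f"replicate{i}_simneg.tsv", header,
                   index=False)
    hits = pd.DataFrame(
        {"gene": result.intersection_hits,
         "planted": [g in result.planted_hits for g in result.intersection_hits]}
    )
    _write_tsv(hits, outdir / "hits_intersection.tsv", header, index=False)


# ---------------------------------------------------------------------------
# mock (proof-of-principle) screen


@dataclass
class MockScreenResult:
    table: sc.CountTable
    precision: float
    group_scores: dict[str, dict[str, pd.Series]]  # reference -> {pos, ctrl}
    auc: dict[str, float]
    gap: dict[str, float]
    diagnostics: dict


def _rank_auc(pos: np.ndarray, ctrl: np.ndarray) -> float:
    """AUC separating two score samples (Mann-Whitney U / n1 n2)."""
    from scipy.stats import rankdata

    pooled = np.concatenate([pos, ctrl])
    ranks = rankdata(pooled)
    u = ranks[: len(pos)].sum() - len(pos) * (len(pos) + 1) / 2.0
    return float(u / (len(pos) * len(ctrl)))


def run_mock_screen(cfg: RunConfig, outdir=None) -> MockScreenResult:
    """Marker-based mock screen: detect the marker-positive subpopulation,
    photoactivate, sort, count, and score barcode groups."""
    m = cfg.mock
    lib_pos = build_library(m.positive_barcodes, 0, 1, 0, gene_prefix="P")
    lib_ctrl = build_library(m.control_barcodes, 0, 1, 0, gene_prefix="C")
    rng = _rng(cfg.seed, 200)

    n = m.n_cells
    n_pos = int(round(n * m.positive_fraction))
    is_pos = np.zeros(n, dtype=bool)
    is_pos[:n_pos] = True
    pos_ids = np.array(lib_pos.sgrna_ids, dtype=object)
    ctrl_ids = np.array(lib_ctrl.sgrna_ids, dtype=object)
    sgrna = np.where(
        is_pos,
        pos_ids[rng.integers(0, len(pos_ids), n)],
        ctrl_ids[rng.integers(0, len(ctrl_ids), n)],
    )

    unanalyzed = rng.random(n) < m.unanalyzed_fraction
    analyzed = ~unanalyzed
    detected = analyzed & np.where(
        is_pos, rng.random(n) < m.detection_tp, rng.random(n) < m.detection_fp
    )
    exposure = np.zeros(n)
    exposure[detected] = cfg.activation.pos_ms
    exposure[analyzed & ~detected] = m.neg_ms

    response = cfg.activation.response()
    mcherry = photoactivate(exposure, response, seed=int(rng.integers(2**31)))
    gates = GateSet.from_activation_classes(
        np.full(2000, response.background),
        {"neg": m.neg_ms, "pos": cfg.activation.pos_ms},
        response,
    )
    events = pd.DataFrame({"cell_id": np.arange(n), "mcherry": mcherry})
    assignment = gate_events(events, gates)

    called = np.flatnonzero((assignment == "pos").to_numpy())
    prec = precision(called, dict(enumerate(is_pos)))

    all_ids = list(lib_pos.sgrna_ids) + list(lib_ctrl.sgrna_ids)
    samples: dict[str, np.ndarray] = {}
    for name, pool, cap in (
        ("pos", called, None),
        ("neg", np.flatnonzero((assignment == "neg").to_numpy()), m.n_sorted_negative),
        ("ctrl", np.flatnonzero(unanalyzed), m.n_unanalyzed),
    ):
        if cap is not None and len(pool) > cap:
            pool = rng.choice(pool, size=cap, replace=False)
        kept = apply_recovery(pool, cfg.flow.recovery, seed=int(rng.integers(2**31)))
        samples[name] = sgrna[np.asarray(kept, dtype=int)]

    ann = pd.concat([lib_pos.annotations(), lib_ctrl.annotations()])
    table = sc.CountTable.from_library(ann)
    for name, sgrnas in samples.items():
        counts = sort_to_counts(
            list(sgrnas), all_ids, cfg.flow.depth, seed=int(rng.integers(2**31))
        )
        table.add_sample(name, counts)

    # score against both references; centering uses the control library
    group_scores: dict[str, dict[str, pd.Series]] = {}
    auc: dict[str, float] = {}
    gap: dict[str, float] = {}
    pos_set = pd.Index(lib_pos.sgrna_ids)
    ctrl_set = pd.Index(lib_ctrl.sgrna_ids)
    for ref_name, ref_col in (("sorted_negative", "neg"), ("unanalyzed", "ctrl")):
        eps = sc.phenotypic_scores(
            table, "pos", ref_col,
            nontargeting_ids=ctrl_set, pseudocount=cfg.analysis.pseudocount,
        )
        g_pos = sc.group_scores(
            eps.loc[pos_set], cfg.analysis.group_size, mode="random",
            seed=int(_rng(cfg.seed, 201).integers(2**31)),
        )
        g_ctrl = sc.group_scores(
            eps.loc[ctrl_set], cfg.analysis.group_size, mode="random",
            seed=int(_rng(cfg.seed, 202).integers(2**31)),
        )
        group_scores[ref_name] = {"pos": g_pos, "ctrl": g_ctrl}
        auc[ref_name] = _rank_auc(g_pos.to_numpy(), g_ctrl.to_numpy())
        gap[ref_name] = float(g_pos.mean() - g_ctrl.mean())

    result = MockScreenResult(
        table=table,
        precision=prec,
        group_scores=group_scores,
        auc=auc,
        gap=gap,
        diagnostics={
            "cells": n,
            "positive_cells": int(is_pos.sum()),
            "detected": int(detected.sum()),
            "sorted_positive": len(samples["pos"]),
            "sorted_negative": len(samples["neg"]),
            "unanalyzed": len(samples["ctrl"]),
        },
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = cfg.header_lines("mock-screen")
        table.write_tsv(outdir / "counts.tsv", header)
        for ref_name, gs in group_scores.items():
            df = pd.concat(
                [gs["pos"].rename("epsilon").to_frame().assign(population="positive"),
                 gs["ctrl"].rename("epsilon").to_frame().assign(population="control")]
            )
            _write_tsv(df, outdir / f"groups_{ref_name}.tsv", header, index=True)
        summary = pd.DataFrame(
            {"reference": list(auc), "auc": list(auc.values()),
             "gap": [gap[r] for r in auc], "precision": prec}
        )
        _write_tsv(summary, outdir / "summary.tsv", header, index=False)
    return result


# ---------------------------------------------------------------------------
# FACS-only screens (FSC / H2B-GFP)


@dataclass
class SortScreenResult:
    table: sc.CountTable
    gene_scores: pd.DataFrame
    hits: list[str]
    planted_hits: list[str]
    epsilon: pd.Series
    diagnostics: dict


def run_sort_only_screen(
    cfg: RunConfig, channel: str = "fsc", top_fraction: float | None = None
) -> SortScreenResult:
    """Sort the top fraction of cells by a FACS channel and score counts.

    ``channel`` is ``fsc`` (forward scatter, tracks cell size and hence
    the planted nuclear-size effects) or ``gfp`` (total H2B-GFP, a DNA
    content proxy unaffected by the planted effects).
    """
    if channel not in ("fsc", "gfp"):
        raise ConfigError(f"unknown sort channel {channel!r}")
    s = cfg.sort_screen
    top = s.top_fraction if top_fraction is None else top_fraction
    lib, effects = _build_screen_library(cfg)
    pop = simulate_population_frame(
        lib,
        effects,
        s.n_cells,
        cfg.population.infected_fraction,
        (cfg.population.baseline_area_mean, cfg.population.baseline_area_sd),
        seed=int(_rng(cfg.seed, 300).integers(2**31)),
    )
    rng = _rng(cfg.seed, 301)
    sig_f = math.sqrt(math.log1p(s.fsc_noise_cv**2))
    fsc = pop["area_um2"].to_numpy() * np.exp(
        rng.normal(-sig_f**2 / 2.0, sig_f, len(pop))
    )
    sig_g = math.sqrt(math.log1p(s.gfp_facs_cv**2))
    gfp_total = s.gfp_facs_mean * np.exp(rng.normal(-sig_g**2 / 2.0, sig_g, len(pop)))
    events = pd.DataFrame(
        {"cell_id": pop["cell_id"], "fsc": fsc, "gfp": gfp_total}
    )
    gates = GateSet.top_fraction(channel, top, name="sorted")
    assignment = gate_events(events, gates)
    sorted_idx = np.flatnonzero((assignment == "sorted").to_numpy())
    kept = apply_recovery(sorted_idx, cfg.flow.recovery,
                          seed=int(rng.integers(2**31)))
    sg = pop["sgrna_id"].to_numpy()
    sorted_sgrnas = [x for x in sg[np.asarray(kept, dtype=int)] if x]
    infected = np.flatnonzero(sg != "")
    unsorted_take = rng.choice(
        infected, size=min(len(infected), s.n_unsorted), replace=False
    )

    table = sc.CountTable.from_library(lib.annotations())
    table.add_sample(
        "sorted",
        sort_to_counts(sorted_sgrnas, lib.sgrna_ids, cfg.flow.depth,
                       seed=int(rng.integers(2**31))),
    )
    table.add_sample(
        "unsorted",
        sort_to_counts(list(sg[unsorted_take]), lib.sgrna_ids, cfg.flow.depth,
                       seed=int(rng.integers(2**31))),
    )

    res = _score_averaged_screen(
        table, [("sorted", "unsorted")], cfg.analysis,
        seed=int(_rng(cfg.seed, 302).integers(2**31)),
    )
    return SortScreenResult(
        table=table,
        gene_scores=res["gene_scores"],
        hits=res["hits"],
        planted_hits=sorted(effects.hit_genes),
        epsilon=res["epsilon"],
        diagnostics={"cells": s.n_cells, "sorted": len(sorted_sgrnas),
                     "unsorted": len(unsorted_take)},
    )


# ---------------------------------------------------------------------------
# null calibration screen (counts only)


def run_null_count_screen(
    n_genes: int = 544,
    sgrnas_per_gene: int = 10,
    n_nontargeting: int = 22,
    depth: int = 1_000_000,
    analysis: AnalysisSpec | None = None,
    seed: int = 0,
) -> tuple[int, dict]:
    """Fully null count-level screen for eFDR calibration.

    Both the sorted sample and the reference are independent multinomial
    draws from the same uniform sgRNA composition; returns the number of
    hits called at the eFDR target and the full scoring result.
    """
    analysis = analysis or AnalysisSpec(n_runs=1)
    lib = build_library(n_genes, 0, sgrnas_per_gene, n_nontargeting)
    rng = _rng(seed, 400)
    p = np.full(lib.n_sgrnas, 1.0 / lib.n_sgrnas)
    table = sc.CountTable.from_library(lib.annotations())
    table.add_sample("sample", pd.Series(rng.multinomial(depth, p),
                                         index=pd.Index(lib.sgrna_ids, name="sgrna_id")))
    table.add_sample("reference", pd.Series(rng.multinomial(depth, p),
                                            index=pd.Index(lib.sgrna_ids, name="sgrna_id")))
    res = _score_averaged_screen(
        table, [("sample", "reference")], analysis,
        seed=int(rng.integers(2**31)),
    )
    return len(res["hits"]), res
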