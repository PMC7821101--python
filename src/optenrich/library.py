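"""sgRNA library construction and synthetic cell populations.

The library emulates a CRISPRi screening library: genes with one or two
transcription start sites (TSSs), a fixed number of sgRNAs per TSS, plus a
small set of nontargeting control sgRNAs that have no genomic target and
define the null phenotype distribution.  sgRNA identifiers are opaque
barcodes; no protospacer sequences are modeled.

Cell populations are simulated under the single-sgRNA-per-cell contract of
low-MOI lentiviral transduction: each infected cell carries exactly one
sgRNA drawn uniformly from the library.  Cells carrying an sgRNA against a
planted hit gene express the phenotype (here: enlarged nuclei) with
probability penetrance x per-sgRNA efficacy, in which case the nucleus area
is drawn from a multiplicatively shifted copy of the baseline lognormal
distribution.  Infection is tracked through a BFP reporter whose
log-intensity separates infected from uninfected cells around the
ln(mean BFP) = 7.6 gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NONTARGETING = "NONTARGETING"

#: Baseline nucleus-area distribution (mean, sd) in um^2.  Lognormal with
#: these moments puts the 99.5th percentile at ~1,000 um^2, so the
#: top-0.5%-of-controls screening gate lands at the canonical 1,000 um^2.
DEFAULT_BASELINE_AREA = (450.0, 152.0)

#: Default pixel size, um/px (20x objective on an sCMOS with 6.5 um pixels).
DEFAULT_PIXEL_SIZE = 0.325

# ln(mean BFP) distributions on either side of the 7.6 infection gate.
BFP_LN_INFECTED = (8.6, 0.5)
BFP_LN_UNINFECTED = (6.6, 0.5)

# Efficacy mixture: the first half of each TSS's sgRNAs behave like a
# curated "Top5" set (high knockdown efficacy), the rest like the weaker
# "Supp5" complement.
TOP5_EFFICACY_RANGE = (0.8, 1.0)
SUPP5_EFFICACY_RANGE = (0.4, 0.7)


@dataclass(frozen=True)
class LibraryDesign:
    """An sgRNA library: genes, their TSSs, and barcode-level sgRNAs.

    ``sgrnas`` holds ``(sgrna_id, gene_or_NONTARGETING, tss_id)`` triples;
    nontargeting sgRNAs carry ``tss_id = ""``.
    """

    genes: tuple[str, ...]
    tss_map: Mapping[str, tuple[str, ...]]
    sgrnas: tuple[tuple[str, str, str], ...]
    sgrnas_per_tss: int
    n_nontargeting: int

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.sgrnas]
        if len(set(ids)) != len(ids):
            raise ValueError("sgRNA ids must be unique")
        n_tss = sum(len(v) for v in self.tss_map.values())
        expected = n_tss * self.sgrnas_per_tss + self.n_nontargeting
        if len(self.sgrnas) != expected:
            raise ValueError(
                f"library has {len(self.sgrnas)} sgRNAs, expected {expected}"
            )
        for _, gene, tss in self.sgrnas:
            if gene != NONTARGETING and tss not in self.tss_map.get(gene, ()):
                raise ValueError(f"sgRNA targets unknown TSS {tss!r} of {gene!r}")

    @property
    def n_sgrnas(self) -> int:
        return len(self.sgrnas)

    @property
    def sgrna_ids(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.sgrnas)

    @property
    def nontargeting_ids(self) -> tuple[str, ...]:
        return tuple(s[0] for s in self.sgrnas if s[1] == NONTARGETING)

    def annotations(self) -> pd.DataFrame:
        """Per-sgRNA annotation frame: gene, tss, and within-TSS rank.

        Rank is 1-based in library order; ranks <= ceil(m/2) form the
        "Top5-like" efficacy class for a 10-sgRNA TSS.
        """
        df = pd.DataFrame(self.sgrnas, columns=["sgrna_id", "gene", "tss"])
        rank = df.groupby("tss", sort=False).cumcount() + 1
        rank[df["gene"] == NONTARGETING] = 0
        df["sg_rank"] = rank
        return df.set_index("sgrna_id")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sgrnas, columns=["sgrna_id", "gene", "tss"])


@dataclass(frozen=True)
class EffectModel:
    """Planted phenotypic effects for a simulated screen.

    effect_size is the multiplicative shift applied to the phenotype
    (nucleus area) distribution of cells expressing the phenotype; 1 means
    no effect.  penetrance is the fraction of cells carrying a hit sgRNA
    that express the phenotype at all; per-sgRNA efficacy multiplies it.
    """

    hit_genes: frozenset[str] = frozenset()
    effect_size: float = 2.0
    penetrance: float = 0.8
    sgrna_efficacy: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance <= 1.0:
            raise ValueError("penetrance must be in [0, 1]")
        for sg, e in self.sgrna_efficacy.items():
            if not 0.0 <= e <= 1.0:
                raise ValueError(f"efficacy of {sg!r} outside [0, 1]")


@dataclass(frozen=True)
class Ellipse:
    """Nucleus footprint: center (px), semi-axes (px), orientation (rad)."""

    cx: float
    cy: float
    a: float
    b: float
    theta: float = 0.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError("ellipse semi-axes must be positive")

    def area_px(self) -> float:
        return math.pi * self.a * self.b


@dataclass
class CellRecord:
    """One simulated cell with its ground truth."""

    cell_id: int
    sgrna_id: str | None
    true_phenotype: bool
    nucleus: Ellipse
    base_intensities: dict[str, float]
    bfp_ln_mean: float


def build_library(
    n_single_tss_genes: int,
    n_double_tss_genes: int,
    sgrnas_per_tss: int,
    n_nontargeting: int,
    seed: int = 0,
    gene_prefix: str = "G",
) -> LibraryDesign:
    """Build a deterministic sgRNA library.

    The canonical screening library is ``build_library(481, 63, 10, 22)``:
    544 genes, 6,070 targeting sgRNAs (10 per TSS, 63 genes with two TSSs)
    plus 22 nontargeting controls = 6,092 sgRNAs.  ``gene_prefix`` keeps
    ids distinct when several libraries are mixed in one experiment.
    """
    for name, v in (
        ("n_single_tss_genes", n_single_tss_genes),
        ("n_double_tss_genes", n_double_tss_genes),
        ("sgrnas_per_tss", sgrnas_per_tss),
        ("n_nontargeting", n_nontargeting),
    ):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")

    genes: list[str] = []
    tss_map: dict[str, tuple[str, ...]] = {}
    sgrnas: list[tuple[str, str, str]] = []
    n_genes = n_single_tss_genes + n_double_tss_genes
    width = max(4, len(str(max(n_genes, 1))))
    for g in range(n_genes):
        gene = f"{gene_prefix}{g + 1:0{width}d}"
        genes.append(gene)
        n_tss = 1 if g < n_single_tss_genes else 2
        tss_ids = tuple(f"{gene}_T{t + 1}" for t in range(n_tss))
        tss_map[gene] = tss_ids
        for tss in tss_ids:
            for j in range(sgrnas_per_tss):
                sgrnas.append((f"{tss}_sg{j + 1:02d}", gene, tss))
    for j in range(n_nontargeting):
        sgrnas.append((f"{gene_prefix}NT_sg{j + 1:02d}", NONTARGETING, ""))

    return LibraryDesign(
        genes=tuple(genes),
        tss_map=tss_map,
        sgrnas=tuple(sgrnas),
        sgrnas_per_tss=sgrnas_per_tss,
        n_nontargeting=n_nontargeting,
    )


def default_efficacies(library: LibraryDesign, seed: int = 0) -> dict[str, float]:
    """Draw per-sgRNA efficacies from the Top5/Supp5 mixture.

    Within each TSS, the first ceil(m/2) sgRNAs draw from the high
    ("Top5-like") range and the rest from the lower ("Supp5-like") range;
    nontargeting sgRNAs get efficacy 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))
    half = math.ceil(library.sgrnas_per_tss / 2)
    out: dict[str, float] = {}
    ann = library.annotations()
    for sgrna_id, row in ann.iterrows():
        if row["gene"] == NONTARGETING:
            out[sgrna_id] = 0.0
        elif row["sg_rank"] <= half:
            out[sgrna_id] = float(rng.uniform(*TOP5_EFFICACY_RANGE))
        else:
            out[sgrna_id] = float(rng.uniform(*SUPP5_EFFICACY_RANGE))
    return out


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and sd."""
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be > 0 and sd >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def simulate_population_frame(
    library: LibraryDesign,
    effects: EffectModel,
    n_cells: int,
    infected_fraction: float,
    baseline_area_dist: tuple[float, float] = DEFAULT_BASELINE_AREA,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> pd.DataFrame:
    """Vectorized population simulation; one row per cell.

    Columns: cell_id, sgrna_id (empty string = uninfected), gene,
    true_phenotype, area_um2, a_px, b_px, theta, bfp_ln, gfp.
    """
    if not 0.0 <= infected_fraction <= 1.0:
        raise ValueError("infected_fraction must be in [0, 1]")
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if library.n_sgrnas == 0 and infected_fraction > 0:
        raise ValueError("cannot infect cells from an empty library")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 23]))
    infected = rng.random(n_cells) < infected_fraction

    ids = np.array(library.sgrna_ids, dtype=object)
    gene_of = {s[0]: s[1] for s in library.sgrnas}
    sg_idx = rng.integers(0, max(library.n_sgrnas, 1), size=n_cells)
    sgrna = np.where(infected, ids[sg_idx] if len(ids) else "", "")
    gene = np.array([gene_of.get(s, "") for s in sgrna], dtype=object)

    # Phenotype: Bernoulli(penetrance * efficacy) for hit-sgRNA cells.
    eff = np.zeros(n_cells)
    if effects.hit_genes:
        is_hit = np.array([g in effects.hit_genes for g in gene])
        eff_map = effects.sgrna_efficacy
        eff[is_hit] = [eff_map.get(s, 1.0) for s in sgrna[is_hit]]
    phenotype = rng.random(n_cells) < effects.penetrance * eff

    mu, sigma = lognormal_params(*baseline_area_dist)
    area = np.exp(rng.normal(mu, sigma, size=n_cells))
    area[phenotype] *= effects.effect_size

    # Ellipse geometry consistent with the sampled area.
    aspect = rng.uniform(1.0, 1.5, size=n_cells)
    area_px = area / pixel_size**2
    a_px = np.sqrt(area_px * aspect / math.pi)
    b_px = a_px / aspect
    theta = rng.uniform(0.0, math.pi, size=n_cells)

    bfp = np.where(
        infected,
        rng.normal(*BFP_LN_INFECTED, size=n_cells),
        rng.normal(*BFP_LN_UNINFECTED, size=n_cells),
    )
    gfp = np.clip(rng.normal(3000.0, 300.0, size=n_cells), 100.0, None)

    return pd.DataFrame(
        {
            "cell_id": np.arange(n_cells),
            "sgrna_id": sgrna,
            "gene": gene,
            "true_phenotype": phenotype,
            "area_um2": area,
            "a_px": a_px,
            "b_px": b_px,
            "theta": theta,
            "bfp_ln": bfp,
            "gfp": gfp,
        }
    )


def simulate_population(
    library: LibraryDesign,
    effects: EffectModel,
    n_cells: int,
    infected_fraction: float,
    baseline_area_dist: tuple[float, float] = DEFAULT_BASELINE_AREA,
    seed: int = 0,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
) -> list[CellRecord]:
    """Simulate a cell population; record-level view of the same draw as
    :func:`simulate_population_frame` (identical seed gives identical cells).
    """
    df = simulate_population_frame(
        library, effects, n_cells, infected_fraction, baseline_area_dist,
        seed=seed, pixel_size=pixel_size,
    )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CellRecord(
                cell_id=int(row.cell_id),
                sgrna_id=row.sgrna_id or None,
                true_phenotype=bool(row.true_phenotype),
                nucleus=Ellipse(0.0, 0.0, float(row.a_px), float(row.b_px),
                                float(row.theta)),
                base_intensities={"gfp": float(row.gfp)},
                bfp_ln_mean=float(row.bfp_ln),
            )
        )
    return records


def write_library_tsv(library: LibraryDesign, path) -> None:
    library.to_frame().to_csv(path, sep="\t", index=False)


def read_library_tsv(path) -> pd.DataFrame:
    """Read a library TSV (columns sgrna_id, gene, tss)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sgrna_id", "gene", "tss"}
    if not required.issubset(df.columns):
        raise ValueError(f"library TSV must have columns {sorted(required)}")
    return df


def write_population_tsv(frame: pd.DataFrame, path, header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=False)
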