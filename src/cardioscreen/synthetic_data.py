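"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study conditions of a paired dropout screen in
cardiomyocytes: a barcoded shRNA library (4625 genes, 1-18 shRNAs per gene
with a median of 6, ~27,500 shRNAs in total, sequenced to a fixed depth and
normalized to 20 million reads), a 384-well drug-repurposing viability screen
(four concentrations per drug, DMSO controls, ~22% viability drop in treated
controls), random protein-protein interaction graphs with pathway
collections, and zebrafish-embryo cohorts with ejection fraction, heart rate,
survival and ventricle areas.

Counts are negative-binomially distributed around plasmid-proportional means:
per-shRNA intensities are gamma-distributed (shape 1/dispersion) and a single
multinomial draw at fixed depth converts them to reads, so each sample sums
exactly to the requested depth while marginals keep the NB mean-variance
relation var = mu + dispersion * mu^2.  All randomness flows from a single
seed; identical configurations give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .screen_io import CONDITIONS, DMSO

DEFAULT_CONCENTRATIONS = (40.0, 200.0, 1000.0, 5000.0)

# Interaction-type vocabularies used when simulating drug->target annotations.
_AGONIST_TERMS = ("agonist", "activator", "inducer", "partial agonist", "stimulator")
_ANTAGONIST_TERMS = ("antagonist", "inhibitor", "blocker", "inverse agonist", "suppressor")
_UNKNOWN_TERMS = ("cofactor", "binder", "other/unknown")


@dataclass(frozen=True)
class EffectSpec:
    """A spiked treatment effect on one gene's shRNAs.

    fold_change multiplies the gene's expected representation in the treated
    sample; > 1 is enrichment (the gene suppresses survival), < 1 depletion.
    """

    gene: str
    direction: str
    fold_change: float

    def __post_init__(self) -> None:
        if self.direction not in ("enriched", "depleted"):
            raise ValueError(f"direction must be 'enriched' or 'depleted', got {self.direction!r}")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be positive")
        if self.direction == "enriched" and self.fold_change <= 1:
            raise ValueError("enriched effects need fold_change > 1")
        if self.direction == "depleted" and self.fold_change >= 1:
            raise ValueError("depleted effects need fold_change < 1")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screens; the seed fixes all randomness."""

    seed: int = 0
    depth: int = 20_000_000
    dispersion: float = 0.1
    n_genes: int = 4625
    effects: list[EffectSpec] = field(default_factory=list)
    n_drugs: int = 689
    concentrations: tuple[float, ...] = DEFAULT_CONCENTRATIONS
    # ~8 384-well plates per condition at full scale, two control columns each
    dmso_wells: int = 256
    treated_control_viability_ratio: float = 0.78
    rlu_cv: float = 0.10
    base_rlu: float = 1.0e6

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass
class LibraryDesign:
    """Barcoded shRNA library: one row per shRNA with its gene and expected plasmid reads."""

    table: pd.DataFrame  # columns: shrna_id, gene, plasmid_expected

    @property
    def genes(self) -> list[str]:
        return list(pd.unique(self.table["gene"]))

    @property
    def n_shrnas(self) -> int:
        return len(self.table)


def default_shrna_count_sampler(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    """Per-gene shRNA counts on [1, 18] with median 6 and mean ~5.95.

    A shifted binomial (Bin(17, 0.291) + 1) matches the published range and
    median; the exact per-gene distribution of the commercial library is not
    public, so this is a modeling choice.
    """
    counts = rng.binomial(17, 0.291, size=n_genes) + 1
    return np.clip(counts, 1, 18)


def generate_library(
    n_genes: int,
    shrna_count_sampler: int | Callable[[np.random.Generator, int], np.ndarray] | None = None,
    seed: int = 0,
    target_depth: float = 20e6,
    plasmid_cv: float = 0.25,
) -> LibraryDesign:
    """Draw a library design: gene symbols, shRNAs per gene, expected plasmid reads.

    plasmid_expected is lognormal around an even split of ``target_depth``
    reads across all shRNAs, mimicking uneven plasmid representation.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if shrna_count_sampler is None:
        per_gene = default_shrna_count_sampler(rng, n_genes)
    elif isinstance(shrna_count_sampler, int):
        if not 1 <= shrna_count_sampler <= 18:
            raise ValueError("fixed shRNA count must be in [1, 18]")
        per_gene = np.full(n_genes, shrna_count_sampler, dtype=int)
    else:
        per_gene = np.asarray(shrna_count_sampler(rng, n_genes), dtype=int)
        if per_gene.min() < 1 or per_gene.max() > 18:
            raise ValueError("sampler produced shRNA counts outside [1, 18]")
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    gene_col = np.repeat(genes, per_gene)
    shrna_ids = [f"{g}_sh{k + 1}" for g, n in zip(genes, per_gene) for k in range(n)]
    n_total = len(shrna_ids)
    jitter = rng.lognormal(mean=-0.5 * plasmid_cv**2, sigma=plasmid_cv, size=n_total)
    plasmid = target_depth / n_total * jitter
    table = pd.DataFrame({"shrna_id": shrna_ids, "gene": gene_col, "plasmid_expected": plasmid})
    return LibraryDesign(table=table)


def simulate_shrna_counts(
    design: LibraryDesign,
    effects: Sequence[EffectSpec],
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate paired control/treatment counts for a library.

    Control means are proportional to plasmid_expected; treated means are
    additionally scaled by each effect's fold_change.  Gamma intensities plus
    one multinomial draw per sample give NB marginals that sum exactly to
    ``config.depth``.
    """
    known = set(design.table["gene"])
    for eff in effects:
        if eff.gene not in known:
            raise ValueError(f"effect references unknown gene {eff.gene!r}")
    rng = np.random.default_rng(config.seed)
    base = design.table["plasmid_expected"].to_numpy(float)
    fold_by_gene = {eff.gene: eff.fold_change for eff in effects}
    gene_fold = design.table["gene"].map(fold_by_gene).fillna(1.0).to_numpy(float)

    shape = 1.0 / config.dispersion
    counts = {}
    for cond, mean in (("control", base), ("treatment", base * gene_fold)):
        lam = rng.gamma(shape=shape, scale=mean / shape)
        lam = np.clip(lam, 1e-300, None)
        counts[cond] = rng.multinomial(config.depth, lam / lam.sum())
    out = design.table.copy()
    out["count_control"] = counts["control"].astype(float)
    out["count_treatment"] = counts["treatment"].astype(float)
    return out[["shrna_id", "gene", "count_control", "count_treatment", "plasmid_expected"]]


def simulate_drug_plates(
    config: SimulationConfig,
    protective: Mapping[str, float] | None = None,
    normoxia_toxic: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate a plate-format viability screen.

    Every drug gets one well per (concentration, condition); DMSO controls get
    ``config.dmso_wells`` wells per condition.  Treated wells are centred at
    ``treated_control_viability_ratio`` times the normoxic level (default
    0.78, i.e. a 22% viability drop).  ``protective`` maps drug names to a
    multiplicative viability boost applied in the treated condition;
    ``normoxia_toxic`` maps drug names to a factor < 1 applied in normoxia.
    RLU noise is lognormal (multiplicative, CV ``rlu_cv``), keeping
    luminescence strictly positive.
    """
    if config.dmso_wells < 1:
        raise ValueError("need at least one DMSO well per condition")
    protective = dict(protective or {})
    normoxia_toxic = dict(normoxia_toxic or {})
    rng = np.random.default_rng(config.seed + 1)
    sigma = np.sqrt(np.log1p(config.rlu_cv**2))
    cond_level = {"normoxia": 1.0, "hypoxia_reoxygenation": config.treated_control_viability_ratio}

    rows: list[tuple[str, float, str, float]] = []

    def noisy(mean: float) -> float:
        return float(mean * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    for cond in CONDITIONS:
        for _ in range(config.dmso_wells):
            rows.append((DMSO, 0.0, cond, noisy(config.base_rlu * cond_level[cond])))
    for i in range(config.n_drugs):
        drug = f"drug{i:04d}"
        for conc in config.concentrations:
            for cond in CONDITIONS:
                level = config.base_rlu * cond_level[cond]
                if cond == "hypoxia_reoxygenation" and drug in protective:
                    level *= protective[drug]
                if cond == "normoxia" and drug in normoxia_toxic:
                    level *= normoxia_toxic[drug]
                rows.append((drug, float(conc), cond, noisy(level)))
    return pd.DataFrame(rows, columns=["drug", "concentration_nM", "condition", "rlu"])


def generate_ppi_and_pathways(
    n_proteins: int,
    edge_density: float,
    n_pathways: int,
    sizes: Sequence[int] | tuple[int, int],
    seed: int = 0,
    proteins: Sequence[str] | None = None,
) -> tuple[list[tuple[str, str]], dict[str, list[str]]]:
    """Random simple PPI graph (Erdos-Renyi) plus random pathway collections.

    ``sizes`` is either one size per pathway or a (low, high) range sampled
    uniformly.  Pathway members are drawn without replacement from the protein
    universe.  Outputs round-trip through the PSI-MITAB and GMT writers.
    """
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    if proteins is None:
        proteins = [f"P{i:04d}" for i in range(n_proteins)]
    else:
        proteins = [str(p).upper() for p in proteins]
        if len(proteins) != n_proteins:
            raise ValueError("len(proteins) must equal n_proteins")
    rng = np.random.default_rng(seed)
    graph = nx.gnp_random_graph(n_proteins, edge_density, seed=int(rng.integers(2**31 - 1)))
    edges = sorted(tuple(sorted((proteins[a], proteins[b]))) for a, b in graph.edges())

    if isinstance(sizes, tuple) and len(sizes) == 2:
        low, high = int(sizes[0]), int(sizes[1])
        size_list = rng.integers(low, high + 1, size=n_pathways)
    else:
        size_list = np.asarray(sizes, dtype=int)
        if len(size_list) != n_pathways:
            raise ValueError("sizes must match n_pathways or be a (low, high) range")
    if (size_list > n_proteins).any():
        raise ValueError("pathway size exceeds protein universe")
    if (size_list < 1).any():
        raise ValueError("pathway sizes must be >= 1")
    pathways = {
        f"PATHWAY_{j:03d}": sorted(rng.choice(proteins, size=int(size_list[j]), replace=False))
        for j in range(n_pathways)
    }
    return edges, pathways


def simulate_drug_annotations(
    drugs: Sequence[str],
    genes: Sequence[str],
    seed: int = 0,
    targets_per_drug: tuple[int, int] = (1, 3),
    term_weights: tuple[float, float, float] = (0.4, 0.4, 0.2),
) -> pd.DataFrame:
    """Random drug->target annotations with agonist/antagonist/unknown terms."""
    rng = np.random.default_rng(seed)
    genes = [str(g).upper() for g in genes]
    rows = []
    terms_by_class = (_AGONIST_TERMS, _ANTAGONIST_TERMS, _UNKNOWN_TERMS)
    for drug in drugs:
        k = int(rng.integers(targets_per_drug[0], targets_per_drug[1] + 1))
        k = min(k, len(genes))
        targets = rng.choice(genes, size=k, replace=False)
        cls = int(rng.choice(3, p=term_weights))
        for t in targets:
            term = str(rng.choice(terms_by_class[cls]))
            rows.append((drug, t, term))
    return pd.DataFrame(rows, columns=["drug", "target", "interaction_term"])


def simulate_embryo_cohort(
    group_means: Mapping[str, float],
    group_sds: Mapping[str, float] | float,
    n_per_group: Mapping[str, int] | int,
    death_probs: Mapping[str, float] | float = 0.0,
    seed: int = 0,
    heart_rate_mean: float = 160.0,
    heart_rate_sd: float = 15.0,
    inner_radius_mean: float = 50.0,
    thickness_means: Mapping[str, float] | float = 15.0,
) -> pd.DataFrame:
    """Per-embryo EF/HR/survival/ventricle-area records for named groups.

    EF (%) is normal per group (clipped at 0); deaths are Bernoulli and dead
    embryos carry EF = 0 and HR = 0, mirroring cohorts where mortality is
    folded into the contractility readout.  Ventricle areas come from a
    circular cross-section: a_in = pi r^2, a_out = pi (r + thickness)^2, in
    squared micrometres.
    """
    if not group_means:
        raise ValueError("need at least one group")

    def per_group(spec, group):
        return spec[group] if isinstance(spec, Mapping) else spec

    rng = np.random.default_rng(seed)
    rows = []
    for group, ef_mean in group_means.items():
        n = int(per_group(n_per_group, group))
        if n < 0:
            raise ValueError(f"negative n for group {group!r}")
        sd = float(per_group(group_sds, group))
        dp = float(per_group(death_probs, group))
        thick = float(per_group(thickness_means, group))
        ef = np.clip(rng.normal(ef_mean, sd, size=n), 0.0, None)
        hr = np.clip(rng.normal(heart_rate_mean, heart_rate_sd, size=n), 0.0, None)
        dead = rng.random(n) < dp
        ef[dead] = 0.0
        hr[dead] = 0.0
        r_in = np.clip(rng.normal(inner_radius_mean, inner_radius_mean * 0.1, size=n), 1.0, None)
        t = np.clip(rng.normal(thick, thick * 0.2, size=n), 0.1, None)
        a_in = np.pi * r_in**2
        a_out = np.pi * (r_in + t) ** 2
        for i in range(n):
            rows.append((group, float(ef[i]), float(hr[i]), bool(~dead[i]), float(a_out[i]), float(a_in[i])))
    return pd.DataFrame(rows, columns=["group", "ef_percent", "heart_rate_bpm", "alive", "a_out", "a_in"])
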