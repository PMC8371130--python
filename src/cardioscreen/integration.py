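"""Cross-screen concordance and the end-to-end synthetic pipeline.

A protein is nominated for inhibition when its shRNAs were significantly
enriched under treatment (losing it helps survival) AND it is the target of a
protective antagonist drug; for activation when its shRNAs were significantly
depleted AND it is the target of a protective agonist drug.  The overlap
universe is the intersection of the shRNA gene universe with the annotated
drug-target universe.  ``run_all`` wires every stage together on synthetic
data from a single seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drug_screen, interaction_network, pathway_analysis, screen_io, shrna_screen
from . import synthetic_data as synth

logger = logging.getLogger(__name__)


@dataclass
class ConcordantTargets:
    overlap_universe: set[str]
    inhibition_candidates: set[str]
    activation_candidates: set[str]
    provenance: dict[str, list[str]] = field(default_factory=dict)  # target -> nominating drugs

    def to_frame(self) -> pd.DataFrame:
        rows = [("inhibition", t, ";".join(sorted(self.provenance.get(t, []))))
                for t in sorted(self.inhibition_candidates)]
        rows += [("activation", t, ";".join(sorted(self.provenance.get(t, []))))
                 for t in sorted(self.activation_candidates)]
        return pd.DataFrame(rows, columns=["mode", "target", "drugs"])


def concordant_targets(shrna_results: pd.DataFrame, drug_scores: pd.DataFrame,
                       annotations: pd.DataFrame) -> ConcordantTargets:
    """Intersect shRNA directions with protective drug-target action categories.

    A drug with multiple annotated targets contributes all of them; drugs
    whose interaction term resolves to neither category contribute none.
    """
    cat = interaction_network.categorize_annotations(annotations)
    protective = set(drug_scores.loc[drug_scores["protective"], "drug"])
    sig = shrna_results[shrna_results["significant"]]
    enriched = set(sig.loc[sig["direction"] == "enriched", "gene"])
    depleted = set(sig.loc[sig["direction"] == "depleted", "gene"])
    prot_cat = cat[cat["drug"].isin(protective)]
    antagonist_targets = set(prot_cat.loc[prot_cat["category"] == "antagonist", "target"])
    agonist_targets = set(prot_cat.loc[prot_cat["category"] == "agonist", "target"])
    universe = set(shrna_results["gene"]) & set(annotations["target"])
    if not universe:
        logger.warning("concordant_targets: empty overlap universe")
    inhibition = enriched & antagonist_targets
    activation = depleted & agonist_targets
    provenance: dict[str, list[str]] = {}
    for t in inhibition | activation:
        provenance[t] = sorted(prot_cat.loc[prot_cat["target"] == t, "drug"].unique())
    return ConcordantTargets(universe, inhibition, activation, provenance)


@dataclass
class PipelineConfig:
    """Scales and effect sizes for the end-to-end synthetic run."""

    n_genes: int = 300
    depth: int = 2_000_000
    dispersion: float = 0.1
    n_enriched: int = 20
    n_depleted: int = 20
    fold_change: float = 4.0
    cutoff: float = 50.0
    n_drugs: int = 60
    n_protective: int = 10
    protective_boost: float = 1.3
    ppi_density: float = 0.02
    n_pathways: int = 40
    pathway_sizes: tuple[int, int] = (5, 30)
    n_perm: int = 500
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "pathway_sizes" in raw:
            raw["pathway_sizes"] = tuple(raw["pathway_sizes"])
        return cls(**raw)


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Synthetic generation -> both screens -> networks -> pathways -> concordance.

    Every stage writes its table under ``outdir`` and is re-read through the
    IO layer, so the run also exercises the file formats; all randomness
    derives from ``config.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    child = np.random.SeedSequence(config.seed).generate_state(8)
    seeds = [int(s % 2**31) for s in child]

    # --- shRNA screen -----------------------------------------------------
    library = synth.generate_library(config.n_genes, seed=seeds[0])
    genes = library.genes
    rng = np.random.default_rng(seeds[1])
    spiked = rng.choice(genes, size=config.n_enriched + config.n_depleted, replace=False)
    effects = [synth.EffectSpec(g, "enriched", config.fold_change) for g in spiked[: config.n_enriched]]
    effects += [synth.EffectSpec(g, "depleted", 1.0 / config.fold_change)
                for g in spiked[config.n_enriched:]]
    sim_cfg = synth.SimulationConfig(seed=seeds[2], depth=config.depth,
                                     dispersion=config.dispersion, n_genes=config.n_genes,
                                     n_drugs=config.n_drugs)
    counts = synth.simulate_shrna_counts(library, effects, sim_cfg)
    screen_io.write_shrna_counts(counts, outdir / "shrna_counts.tsv")
    counts = screen_io.read_shrna_counts(outdir / "shrna_counts.tsv")
    logger.info("run_all: analyzing %d shRNAs / %d genes", len(counts), config.n_genes)
    ranks = shrna_screen.analyze_shrna_screen(counts, cutoff=config.cutoff)
    ranks.to_csv(outdir / "ranks.tsv", sep="\t", index=False)

    # --- drug screen ------------------------------------------------------
    drug_names = [f"drug{i:04d}" for i in range(config.n_drugs)]
    prot_drugs = {d: config.protective_boost
                  for d in rng.choice(drug_names, size=config.n_protective, replace=False)}
    plates = synth.simulate_drug_plates(sim_cfg, protective=prot_drugs)
    screen_io.write_drug_plates(plates, outdir / "plates.tsv")
    plates = screen_io.read_drug_plates(outdir / "plates.tsv")
    drug_scores = drug_screen.score_drugs(plates)
    drug_scores.to_csv(outdir / "drug_scores.tsv", sep="\t", index=False)

    annotations = synth.simulate_drug_annotations(drug_names, genes, seed=seeds[3])
    screen_io.write_drug_targets(annotations, outdir / "drug_targets.tsv")
    annotations = screen_io.read_drug_targets(outdir / "drug_targets.tsv")

    # --- PPI network + pathways -------------------------------------------
    edges, pathways = synth.generate_ppi_and_pathways(
        len(genes), config.ppi_density, config.n_pathways, config.pathway_sizes,
        seed=seeds[4], proteins=genes,
    )
    screen_io.write_mitab(edges, outdir / "ppi.mitab")
    screen_io.write_gmt(pathways, outdir / "pathways.gmt")
    edges = screen_io.read_mitab(outdir / "ppi.mitab")
    pathways = screen_io.read_gmt(outdir / "pathways.gmt")

    networks = interaction_network.hit_set_networks(ranks, drug_scores, annotations, edges)
    for name, table in networks.items():
        table.to_csv(outdir / f"degrees_{name}.tsv", sep="\t", index=False)

    # --- pathway analysis (both screens) ----------------------------------
    shrna_values = pathway_analysis.filter_shrna_targets(counts)
    shrna_included = set(shrna_values.loc[shrna_values["included"], "gene"])
    shrna_pathway_scores = pathway_analysis.analyze_pathways(
        shrna_values, shrna_included, pathways, screen="shrna",
        n_perm=config.n_perm, seed=seeds[5],
    )
    shrna_table = pathway_analysis.rank_pathways(shrna_pathway_scores)
    shrna_table.to_csv(outdir / "pathways_shrna.tsv", sep="\t", index=False)
    shrna_pathway_scores.to_csv(outdir / "pathway_scores_shrna.tsv", sep="\t", index=False)

    drug_values = pathway_analysis.select_drug_targets(drug_scores, annotations)
    drug_tables_written = False
    if not drug_values.empty:
        drug_included = set(drug_values["gene"])
        try:
            drug_pathway_scores = pathway_analysis.analyze_pathways(
                drug_values, drug_included, pathways, screen="drug",
                n_perm=config.n_perm, fitness_universe=sorted(set(annotations["target"])),
                seed=seeds[6],
            )
            drug_table = pathway_analysis.rank_pathways(drug_pathway_scores)
            drug_table.to_csv(outdir / "pathways_drug.tsv", sep="\t", index=False)
            drug_pathway_scores.to_csv(outdir / "pathway_scores_drug.tsv", sep="\t", index=False)
            drug_tables_written = True
        except ValueError:
            logger.warning("run_all: drug-screen pathway analysis skipped (too few valued hits)")
    if not drug_tables_written:
        empty = pd.DataFrame(columns=["pathway", "genes_found", "pathway_length", "p_value", "p_fitness"])
        empty.to_csv(outdir / "pathways_drug.tsv", sep="\t", index=False)

    # --- concordance ------------------------------------------------------
    concordant = concordant_targets(ranks, drug_scores, annotations)
    concordant.to_frame().to_csv(outdir / "concordant.tsv", sep="\t", index=False)

    return {
        "counts": counts,
        "ranks": ranks,
        "drug_scores": drug_scores,
        "annotations": annotations,
        "networks": networks,
        "pathways_shrna": shrna_table,
        "concordant": concordant.to_frame(),
    }
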