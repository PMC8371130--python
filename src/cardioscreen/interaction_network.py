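"""Drug-action categorization and PPI degree ranking of screen hits.

Drug-target interaction terms are classified as agonist or antagonist by
exact, case-insensitive match against fixed vocabularies; protein-protein
interactions are superimposed on a hit set as an induced subgraph (only
mutual interactions among hits count) and hits are ranked by their degree in
that subgraph, the most connected nodes being treated as central regulators.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

AGONIST_TERMS = frozenset(
    t.lower() for t in (
        "potentiator", "activator", "agonist", "inducer", "ligand",
        "partial agonist", "positive allosteric modulator", "stimulator",
    )
)
ANTAGONIST_TERMS = frozenset(
    t.lower() for t in (
        "antagonist", "antisense", "antisense oligonucleotide", "blocker",
        "competitive", "inhibitor", "inhibitory allosteric modulator",
        "inverse agonist", "negative modulator", "partial antagonist",
        "suppressor", "vaccine",
    )
)


def categorize_term(interaction_term: str | None) -> str:
    """Classify a drug-target interaction term as agonist, antagonist or unknown.

    Matching is exact (whole term, case-insensitive, whitespace-normalized),
    so multi-word terms like 'partial agonist' match their own list rather
    than via a substring.
    """
    if interaction_term is None:
        return "unknown"
    term = " ".join(str(interaction_term).lower().split())
    if term in AGONIST_TERMS:
        return "agonist"
    if term in ANTAGONIST_TERMS:
        return "antagonist"
    return "unknown"


def categorize_annotations(annotations: pd.DataFrame) -> pd.DataFrame:
    """Add a ``category`` column to a drug->target annotation table."""
    out = annotations.copy()
    out["category"] = out["interaction_term"].map(categorize_term)
    return out


def build_subnetwork(hit_set: Iterable[str], edge_list: Sequence[tuple[str, str]]) -> nx.Graph:
    """Induced simple subgraph of the PPI network on a hit set.

    Hits without any mutual interaction remain as isolated nodes; edges with
    an endpoint outside the hit set are discarded, as are self-loops.
    """
    hits = {str(h).upper() for h in hit_set}
    graph = nx.Graph()
    graph.add_nodes_from(sorted(hits))
    for a, b in edge_list:
        a, b = str(a).upper(), str(b).upper()
        if a != b and a in hits and b in hits:
            graph.add_edge(a, b)
    return graph


def degree_ranking(graph: nx.Graph) -> pd.DataFrame:
    """Rank nodes by induced-subgraph degree, descending; ties alphabetical.

    Returns columns node, degree, rank (1 = most connected; ties share the
    minimum rank of the block after the deterministic alphabetical sort).
    """
    items = sorted(graph.degree(), key=lambda kv: (-kv[1], kv[0]))
    df = pd.DataFrame(items, columns=["node", "degree"])
    df["rank"] = df["degree"].rank(method="min", ascending=False).astype(int) if len(df) else []
    return df


def hit_set_networks(
    shrna_results: pd.DataFrame,
    drug_scores: pd.DataFrame,
    annotations: pd.DataFrame,
    edge_list: Sequence[tuple[str, str]],
) -> dict[str, pd.DataFrame]:
    """Degree rankings for the four hit sets analyzed separately.

    The sets are: significantly shRNA-enriched genes, significantly
    shRNA-depleted genes, targets of protective antagonist drugs and targets
    of protective agonist drugs.  Drugs with an unknown category contribute
    to neither target set.
    """
    cat = categorize_annotations(annotations)
    protective = set(drug_scores.loc[drug_scores["protective"], "drug"])
    sig = shrna_results[shrna_results["significant"]]
    sets = {
        "shrna_enriched": set(sig.loc[sig["direction"] == "enriched", "gene"]),
        "shrna_depleted": set(sig.loc[sig["direction"] == "depleted", "gene"]),
        "antagonist_targets": set(
            cat.loc[cat["drug"].isin(protective) & (cat["category"] == "antagonist"), "target"]
        ),
        "agonist_targets": set(
            cat.loc[cat["drug"].isin(protective) & (cat["category"] == "agonist"), "target"]
        ),
    }
    return {name: degree_ranking(build_subnetwork(hits, edge_list)) for name, hits in sets.items()}
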