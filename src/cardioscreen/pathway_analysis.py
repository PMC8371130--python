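"""Pathway scoring by metric-learning dimensionality reduction with permutation nulls.

Each screen supplies one value per protein per condition (median
depth-normalized shRNA counts, or normalized representative drug viabilities).
For a pathway, the member values of the two conditions are treated as two
labeled point clouds and reduced with maximally collapsing metric learning
(MCML): a positive-semidefinite metric is learned that collapses same-
condition points together, the data are projected onto the metric's leading
eigenvector, and the reduced value of a condition is the centroid of its
projected points.  The pathway score is the treated minus the control reduced
value; high scores are significant for the shRNA screen (enrichment under
treatment) and low scores for the drug screen.

Significance comes from permutation nulls: random same-size protein sets are
drawn from the data, their scores are smoothed with an Epanechnikov kernel
density (K(u) = 3/4 (1 - u^2) on |u| <= 1, Silverman bandwidth), and the p
value is read off the fitted cumulative distribution.  A second 'category
fitness' test checks whether the pathway annotation is unusually well
represented in the hit set, comparing the observed occupancy (members found /
annotation size) with the occupancy of random protein sets.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EPS = 1e-12


# ---------------------------------------------------------------------------
# input selection
# ---------------------------------------------------------------------------

def filter_shrna_targets(counts: pd.DataFrame, threshold: float = 1.3,
                         target: float = 20e6) -> pd.DataFrame:
    """Per-gene median normalized counts and the >= 30%-enriched subset.

    The gene value per condition is the median depth-normalized count over
    its shRNAs; a gene is included when its treated median is at least
    ``threshold`` (default 1.3, i.e. 30% enrichment, boundary inclusive)
    times its control median.  Genes whose control median is zero while the
    treated median is positive are included and flagged.
    """
    from .shrna_screen import normalize_to_depth

    df = counts[["gene"]].copy()
    df["norm_control"] = normalize_to_depth(counts["count_control"], target)
    df["norm_treatment"] = normalize_to_depth(counts["count_treatment"], target)
    med = df.groupby("gene", sort=True).median()
    c = med["norm_control"].to_numpy()
    t = med["norm_treatment"].to_numpy()
    flagged = (c == 0) & (t > 0)
    included = flagged | (t >= threshold * c) & (t > 0)
    return pd.DataFrame({
        "gene": med.index,
        "value_control": c,
        "value_treatment": t,
        "included": included,
        "flagged": flagged,
    })


def select_drug_targets(drug_scores: pd.DataFrame, annotations: pd.DataFrame) -> pd.DataFrame:
    """Per-target values from protective drugs (union of their targets).

    The treated value of a target is the mean normalized representative
    viability of the protective drugs annotated to it; the control value is
    the mean normoxic relative viability at the representative concentration.
    """
    protective = drug_scores[drug_scores["protective"]]
    merged = annotations.merge(protective, on="drug", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=["gene", "value_control", "value_treatment"])
    agg = merged.groupby("target", sort=True).agg(
        value_control=("normoxic_at_representative", "mean"),
        value_treatment=("representative_value", "mean"),
    )
    agg.index.name = "gene"
    return agg.reset_index()


# ---------------------------------------------------------------------------
# MCML reduction
# ---------------------------------------------------------------------------

def _mcml_metric(X: np.ndarray, labels: np.ndarray, n_iter: int = 100,
                 lr: float = 0.1) -> np.ndarray:
    """Learn a PSD metric collapsing same-label points (convex MCML relaxation).

    Projected gradient descent on the KL objective between the metric-induced
    soft-neighbour distribution and the ideal collapsed one; deterministic
    (identity initialization, fixed iteration count).
    """
    n, d = X.shape
    A = np.eye(d)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    diffs = X[:, None, :] - X[None, :, :]  # n x n x d
    outer = np.einsum("ijk,ijl->ijkl", diffs, diffs)
    n_pairs = max(same.sum(), 1)
    scale = max(np.mean(np.sum(diffs**2, axis=-1)), EPS)
    for _ in range(n_iter):
        d2 = np.einsum("ijk,kl,ijl->ij", diffs, A, diffs)
        logits = -d2
        np.fill_diagonal(logits, -np.inf)
        logits -= logits.max(axis=1, keepdims=True)
        w = np.exp(logits)
        w /= w.sum(axis=1, keepdims=True)
        # gradient of sum_{same} [d_ij + log Z_i]
        p_weight = same.sum(axis=1)[:, None] * w
        grad = np.einsum("ij,ijkl->kl", same.astype(float) - p_weight, outer) / n_pairs
        A = A - lr / scale * grad
        # PSD projection
        vals, vecs = np.linalg.eigh((A + A.T) / 2.0)
        A = (vecs * np.clip(vals, 0.0, None)) @ vecs.T
    return A


def mcml_reduce(values_control: np.ndarray, values_treatment: np.ndarray,
                n_iter: int = 100) -> tuple[float, float]:
    """Reduce two labeled point clouds to one value per condition.

    Points are the member values of each condition; the learned metric's
    leading eigenvector defines a 1-D projection and each condition's reduced
    value is the centroid of its projected points.  For 1-D input the metric
    is a non-negative scalar, the unit projection is the identity and the
    reduced values are exactly the raw condition centroids (a 1-D metric
    cannot change relative separations).  A singleton member set falls back
    to the raw values.
    """
    Xc = np.asarray(values_control, float)
    Xt = np.asarray(values_treatment, float)
    if Xc.ndim == 1:
        Xc = Xc[:, None]
    if Xt.ndim == 1:
        Xt = Xt[:, None]
    if Xc.shape[1] != Xt.shape[1]:
        raise ValueError("condition point clouds must share dimensionality")
    if Xc.shape[0] == 0 or Xt.shape[0] == 0:
        raise ValueError("need at least one member per condition")
    d = Xc.shape[1]
    if d == 1:
        return float(Xc.mean()), float(Xt.mean())
    X = np.vstack([Xc, Xt])
    labels = np.concatenate([np.zeros(len(Xc), int), np.ones(len(Xt), int)])
    A = _mcml_metric(X, labels, n_iter=n_iter)
    vals, vecs = np.linalg.eigh(A)
    v = vecs[:, -1]
    # deterministic sign: largest-magnitude component positive
    imax = int(np.argmax(np.abs(v)))
    if v[imax] < 0:
        v = -v
    return float((Xc @ v).mean()), float((Xt @ v).mean())


def pathway_score(reduced_control: float, reduced_treatment: float) -> float:
    """Signed pathway score: treated minus control reduced value.

    Upper tail is significant for the shRNA screen, lower tail for the drug
    screen.
    """
    return float(reduced_treatment) - float(reduced_control)


# ---------------------------------------------------------------------------
# Epanechnikov KDE p-values
# ---------------------------------------------------------------------------

def silverman_bandwidth(samples: np.ndarray) -> float:
    x = np.asarray(samples, float)
    n = len(x)
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = max(abs(float(np.mean(x))) * 1e-3, EPS)
    return 0.9 * spread * n ** (-1 / 5)


def epanechnikov_cdf(x, samples, bandwidth: float | None = None) -> np.ndarray:
    """CDF of an Epanechnikov KDE fitted to ``samples``, evaluated at ``x``.

    The kernel CDF is W(u) = 0.5 + 3/4 (u - u^3/3) on |u| <= 1; the fitted
    density integrates to 1 and its CDF is monotone from 0 to 1.
    """
    s = np.asarray(samples, float)
    if bandwidth is None:
        bandwidth = silverman_bandwidth(s)
    u = (np.atleast_1d(np.asarray(x, float))[:, None] - s[None, :]) / bandwidth
    w = np.where(u <= -1, 0.0, np.where(u >= 1, 1.0, 0.5 + 0.75 * (u - u**3 / 3.0)))
    return w.mean(axis=1)


def kde_tail_p(observed: float, null_scores: np.ndarray, tail: str,
               bandwidth: float | None = None) -> float:
    """Tail p-value from the Epanechnikov-KDE CDF of a permutation null.

    Clamped to [1/(n+1), 1] so smooth tails never report a zero p.  A
    degenerate null (all scores equal) falls back to direct comparison.
    """
    null_scores = np.asarray(null_scores, float)
    n = len(null_scores)
    if n == 0:
        raise ValueError("empty null distribution")
    lo = 1.0 / (n + 1.0)
    if np.allclose(null_scores, null_scores[0]):
        if tail == "upper":
            p = 1.0 if observed <= null_scores[0] else lo
        else:
            p = 1.0 if observed >= null_scores[0] else lo
        return float(p)
    cdf = float(epanechnikov_cdf(observed, null_scores, bandwidth)[0])
    p = 1.0 - cdf if tail == "upper" else cdf
    return float(np.clip(p, lo, 1.0))


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _tail_for_screen(screen: str) -> str:
    if screen == "shrna":
        return "upper"
    if screen == "drug":
        return "lower"
    raise ValueError("screen must be 'shrna' or 'drug'")


def score_null_p(observed: float, universe_values: pd.DataFrame, set_length: int,
                 n_perm: int, screen: str, seed: int) -> float:
    """Permutation p for a pathway score.

    ``n_perm`` random protein sets of ``set_length`` are drawn without
    replacement from the data universe (a frame with value_control /
    value_treatment per gene); each set is reduced exactly like the pathway
    and the observed score is referred to the Epanechnikov-KDE CDF of the
    null scores, upper tail for the shRNA screen and lower tail for the drug
    screen.
    """
    if set_length < 1:
        raise ValueError("set_length must be >= 1")
    if len(universe_values) < set_length:
        raise ValueError("universe smaller than set_length")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    tail = _tail_for_screen(screen)
    null = null_score_distribution(universe_values, set_length, n_perm, seed)
    return kde_tail_p(observed, null, tail)


def null_score_distribution(universe_values: pd.DataFrame, set_length: int,
                            n_perm: int, seed: int) -> np.ndarray:
    """Null pathway scores from random same-length sets (vectorized over sets)."""
    rng = np.random.default_rng(seed)
    vc = universe_values["value_control"].to_numpy(float)
    vt = universe_values["value_treatment"].to_numpy(float)
    n = len(vc)
    scores = np.empty(n_perm)
    for i in range(n_perm):
        idx = rng.choice(n, size=set_length, replace=False)
        # 1-D MCML reduction of a random set = centroid difference
        scores[i] = vt[idx].mean() - vc[idx].mean()
    return scores


def fitness_p(pathway_members: Iterable[str], included_set: Iterable[str],
              universe: Sequence[str], n_sets: int, seed: int) -> tuple[float, int, int]:
    """Category-fitness p: is the annotation unusually occupied by the hit set?

    Observed occupancy = |members found in the hit set| / annotation size.
    Null occupancies come from ``n_sets`` random sets the size of the hit
    set, drawn from ``universe`` (all drug targets for the drug screen; all
    proteins in the pathway annotations for the shRNA screen), smoothed with
    the Epanechnikov KDE; upper-tail p.  Returns (p, genes_found,
    pathway_length).
    """
    members = {str(m).upper() for m in pathway_members}
    if not members:
        raise ValueError("pathway has no members")
    if n_sets < 10:
        raise ValueError("n_sets must be >= 10")
    hit = {str(h).upper() for h in included_set}
    uni = np.asarray([str(u).upper() for u in universe])
    length = len(members)
    found = len(members & hit)
    observed = found / length
    k = min(len(hit), len(uni))
    rng = np.random.default_rng(seed)
    member_mask = np.isin(uni, sorted(members))
    occ = np.empty(n_sets)
    for i in range(n_sets):
        idx = rng.choice(len(uni), size=k, replace=False)
        occ[i] = member_mask[idx].sum() / length
    return kde_tail_p(observed, occ, "upper"), found, length


# ---------------------------------------------------------------------------
# the reported table
# ---------------------------------------------------------------------------

def analyze_pathways(values: pd.DataFrame, included: Iterable[str],
                     pathways: Mapping[str, Sequence[str]], screen: str,
                     n_perm: int = 10_000, n_fitness_sets: int | None = None,
                     fitness_universe: Sequence[str] | None = None,
                     seed: int = 0, min_genes_found: int = 2) -> pd.DataFrame:
    """Score every pathway against one screen's values.

    ``values`` has one row per gene with value_control / value_treatment;
    ``included`` is the screen's hit set (enriched shRNA targets or targets
    of protective drugs) whose values feed the reduction; ``pathways`` maps
    names to member lists.  Pathways with fewer than ``min_genes_found``
    members in the data are skipped.  Defaults for the fitness null follow
    the screen convention: 100 random sets for the drug screen, 10 for the
    shRNA screen; the fitness universe defaults to the union of all pathway
    annotations.
    """
    tail_screen = screen
    _tail_for_screen(screen)  # validate
    if n_fitness_sets is None:
        n_fitness_sets = 10 if screen == "shrna" else 100
    included = {str(g).upper() for g in included}
    data = values[values["gene"].isin(included)].reset_index(drop=True)
    if data.empty:
        raise ValueError("no included genes carry values")
    by_gene = data.set_index("gene")
    if fitness_universe is None:
        fitness_universe = sorted({m for mem in pathways.values() for m in mem})
    null_cache: dict[int, np.ndarray] = {}
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(2 * len(pathways) + 2)
    records = []
    for j, (name, members) in enumerate(pathways.items()):
        mem = {str(m).upper() for m in members}
        present = sorted(mem & set(by_gene.index))
        if len(present) < min_genes_found:
            continue
        vc = by_gene.loc[present, "value_control"].to_numpy(float)
        vt = by_gene.loc[present, "value_treatment"].to_numpy(float)
        rc, rt = mcml_reduce(vc[:, None], vt[:, None])
        score = pathway_score(rc, rt)
        k = len(present)
        if k not in null_cache:
            null_cache[k] = null_score_distribution(data, k, n_perm, int(seeds[2 * j] % 2**31))
        p = kde_tail_p(score, null_cache[k], _tail_for_screen(tail_screen))
        pf, found, length = fitness_p(mem, included, fitness_universe, n_fitness_sets,
                                      int(seeds[2 * j + 1] % 2**31))
        records.append((name, found, length, rc, rt, score, p, pf))
    return pd.DataFrame(
        records,
        columns=["pathway", "genes_found", "pathway_length", "reduced_control",
                 "reduced_treatment", "score", "p_value", "p_fitness"],
    )


def rank_pathways(scores: pd.DataFrame, alpha: float = 0.05, fitness_alpha: float = 0.1,
                  adjust: bool = False) -> pd.DataFrame:
    """Reported pathway table: rounded p <= alpha and rounded fitness p <= fitness_alpha.

    p-values are rounded to three decimals before comparison (so 0.0504
    passes at alpha = 0.05 but 0.101 fails at 0.1), and the table is sorted
    ascending by p.  ``adjust=True`` applies Benjamini-Hochberg to the score
    p-values first; off by default since the KDE-derived p is reported as is.
    """
    out_cols = ["pathway", "genes_found", "pathway_length", "p_value", "p_fitness"]
    if scores.empty:
        return pd.DataFrame(columns=out_cols)
    df = scores.copy()
    if adjust and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    keep = (df["p_value"].round(3) <= alpha) & (df["p_fitness"].round(3) <= fitness_alpha)
    out = df.loc[keep].sort_values(["p_value", "pathway"], kind="mergesort")
    return out[out_cols].reset_index(drop=True)
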