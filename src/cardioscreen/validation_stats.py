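"""Statistics for the validation experiments.

Covers: average myocardium thickness from ventricle cross-section areas,
Fisher's exact test for embryo lethality, affine rescaling of viability
between the two control medians, and group comparisons (Kruskal-Wallis +
pairwise Mann-Whitney U, or one-way ANOVA + pairwise t tests) with
Benjamini-Hochberg FDR adjustment of each family of pairwise p-values.
Dead embryos carry ejection fraction 0 and heart rate 0 and are kept in the
comparisons, so mortality folds into the contractility readout.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def myocardium_thickness(a_out: float, a_in: float) -> float:
    """Average myocardium thickness from outer/inner ventricle areas.

    Treats both outlines as circles of equal area: thickness =
    sqrt(a_out / pi) - sqrt(a_in / pi).  Homogeneous of degree 1/2 in the
    areas.
    """
    if a_in < 0 or a_out < 0:
        raise ValueError("areas must be non-negative")
    if a_in > a_out:
        raise ValueError("inner area exceeds outer area")
    return float(np.sqrt(a_out / np.pi) - np.sqrt(a_in / np.pi))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 contingency table.

    Sums the hypergeometric probabilities of all tables (at fixed margins) no
    more probable than the observed one.  An empty margin gives p = 1.
    """
    arr = np.asarray(table, dtype=int)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("need a 2x2 table of non-negative integers")
    if arr.sum() == 0 or (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


def rescale_viability(values, normoxic_control_values, treated_control_values) -> np.ndarray:
    """Affine rescaling sending the treated-control median to 0 and the normoxic to 1."""
    hi = float(np.median(np.asarray(normoxic_control_values, float)))
    lo = float(np.median(np.asarray(treated_control_values, float)))
    if hi == lo:
        raise ValueError("control medians coincide; rescaling undefined")
    return (np.asarray(values, float) - lo) / (hi - lo)


def _mannwhitney_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else normal with tie correction."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (max(len(x), len(y)) <= 20 and not ties) else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)


def _grouped_values(records: pd.DataFrame, value_field: str, group_field: str):
    groups = {}
    for name, sub in records.groupby(group_field, sort=True):
        vals = sub[value_field].to_numpy(float)
        if len(vals) < 2:
            warnings.warn(f"group {name!r} has n < 2 and is excluded", stacklevel=3)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")
    return groups


def group_compare_nonparametric(records: pd.DataFrame, value_field: str,
                                group_field: str = "group") -> dict:
    """Kruskal-Wallis omnibus + all pairwise Mann-Whitney U with BH adjustment.

    Returns {'omnibus_p': float, 'pairwise': DataFrame(group1, group2, p, p_adj)}.
    """
    groups = _grouped_values(records, value_field, group_field)
    omnibus = float(stats.kruskal(*groups.values()).pvalue)
    rows = [(a, b, _mannwhitney_p(groups[a], groups[b])) for a, b in combinations(groups, 2)]
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "p"])
    pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"omnibus_p": omnibus, "pairwise": pairwise}


def group_compare_parametric(records: pd.DataFrame, value_field: str,
                             group_field: str = "group", paired: bool = False,
                             replicate_field: str | None = None) -> dict:
    """One-way ANOVA omnibus + pairwise two-tailed t tests with BH adjustment.

    With ``paired=True`` the pairwise tests are paired t tests; observations
    are matched on ``replicate_field`` when given, else on within-group
    order (groups must then be equal-sized).
    """
    if paired and replicate_field is not None:
        groups = {}
        for name, sub in records.groupby(group_field, sort=True):
            groups[name] = sub.sort_values(replicate_field)[value_field].to_numpy(float)
        if len(groups) < 2:
            raise ValueError("need at least two groups")
    else:
        groups = _grouped_values(records, value_field, group_field)
    omnibus = float(stats.f_oneway(*groups.values()).pvalue)
    rows = []
    for a, b in combinations(groups, 2):
        x, y = groups[a], groups[b]
        if paired:
            if len(x) != len(y):
                raise ValueError(f"paired test needs equal n for {a!r} and {b!r}")
            if np.allclose(x, y):
                p = 1.0
            else:
                p = float(stats.ttest_rel(x, y).pvalue)
        else:
            p = float(stats.ttest_ind(x, y).pvalue)
        rows.append((a, b, p))
    pairwise = pd.DataFrame(rows, columns=["group1", "group2", "p"])
    pairwise["p_adj"] = multipletests(pairwise["p"], method="fdr_bh")[1]
    return {"omnibus_p": omnibus, "pairwise": pairwise}
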