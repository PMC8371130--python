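"""Differential-abundance analysis of the pooled shRNA dropout screen.

Counts are first normalized to a fixed sequencing depth (20 million reads per
sample) and then to the expected plasmid representation of each shRNA in the
original library, giving a per-shRNA representation ratio.  Separate shRNAs
against the same gene act as internal replicates.  Three independent
per-gene tests are run:

* a median (tau = 0.5) quantile-regression rank-score test of the gene's
  shRNA log-ratios against the library-wide level,
* a negative-binomial GLM Wald test with shRNA-identity covariates and
  gene-wise Cox-Reid-adjusted ML dispersion,
* an NB exact-style test with dispersion taken from a mean-dispersion
  power-law fitted across all shRNAs.

Per-gene significance is the arithmetic mean of the gene's ranks (ascending
p, average ties) in the three tests; genes with mean rank below a cutoff
(default 500) are called significant, with the direction (enriched/depleted)
taken from the pooled log2 fold change of representation.  The original
analyses used R packages; these tests are statistically equivalent
re-implementations validated by calibration and power simulation rather than
bit-compatibility.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from scipy.optimize import minimize_scalar

logger = logging.getLogger(__name__)

PSEUDOCOUNT = 0.5  # added to depth-normalized counts before log-ratios (true zeros occur)
DISPERSION_FLOOR = 1e-8
DISPERSION_CEIL = 10.0


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_to_depth(raw_counts, target: float = 20e6) -> np.ndarray:
    """Rescale a sample's counts so they sum to ``target`` reads."""
    raw = np.asarray(raw_counts, dtype=float)
    total = raw.sum()
    if total <= 0:
        raise ValueError("cannot depth-normalize an all-zero sample")
    return raw * (target / total)


def plasmid_normalize(normalized, plasmid_expected) -> np.ndarray:
    """Per-shRNA representation ratio: depth-normalized count / expected plasmid count."""
    norm = np.asarray(normalized, dtype=float)
    expected = np.asarray(plasmid_expected, dtype=float)
    if np.any(expected <= 0):
        raise ValueError("plasmid_expected must be positive")
    return norm / expected


def representation_table(counts: pd.DataFrame, target: float = 20e6) -> pd.DataFrame:
    """Add depth-normalized counts, representation ratios and per-shRNA log2 ratios."""
    df = counts.copy()
    for cond in ("control", "treatment"):
        df[f"norm_{cond}"] = normalize_to_depth(df[f"count_{cond}"], target)
        df[f"repr_{cond}"] = plasmid_normalize(df[f"norm_{cond}"], df["plasmid_expected"])
    # plasmid expectation cancels in the treatment/control ratio
    df["log2_ratio"] = np.log2(
        (df["norm_treatment"] + PSEUDOCOUNT) / (df["norm_control"] + PSEUDOCOUNT)
    )
    return df


# ---------------------------------------------------------------------------
# test 1: quantile-regression rank-score test
# ---------------------------------------------------------------------------

def test_quantile(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-shift rank-score test of each gene's shRNA log-ratios vs the library.

    For median regression with a gene-indicator covariate the rank-score test
    statistic reduces to a standardized rank-sum of the gene's shRNAs among
    all shRNAs, which is what is computed here (tie-corrected normal
    reference).  Returns columns gene, stat, p.
    """
    df = representation_table(counts)
    y = df["log2_ratio"].to_numpy(float)
    n_all = len(y)
    if n_all == 0:
        raise ValueError("empty count table")
    if np.allclose(y, y[0]):
        out = pd.DataFrame({"gene": pd.unique(df["gene"])})
        out["stat"] = 0.0
        out["p"] = 1.0
        return out
    ranks = stats.rankdata(y)
    scores = ranks / (n_all + 1.0) - np.mean(ranks / (n_all + 1.0))
    a2 = np.mean(scores**2)
    score_sum = pd.Series(scores).groupby(df["gene"].to_numpy()).sum()
    gene_n = df.groupby("gene").size().reindex(score_sum.index)
    n = gene_n.to_numpy(float)
    var = n * (n_all - n) / (n_all - 1.0) * a2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, score_sum.to_numpy() / np.sqrt(var), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"gene": score_sum.index, "stat": z, "p": np.clip(p, 0.0, 1.0)})


# ---------------------------------------------------------------------------
# test 2: NB GLM Wald test (shRNA-identity covariates)
# ---------------------------------------------------------------------------

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> float:
    r = 1.0 / alpha
    mu = np.clip(mu, 1e-12, None)
    return float(
        np.sum(
            gammaln(y + r) - gammaln(r) - gammaln(y + 1)
            + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu) + 1e-300)
        )
    )


def _irls_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray, alpha: float,
             max_iter: int = 25, tol: float = 1e-8):
    """IRLS fit of an NB log-link GLM; returns (beta, mu, XtWX)."""
    mu = np.clip(y + 0.5, 0.5, None)
    eta = np.log(mu)
    beta = None
    for _ in range(max_iter):
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset) + (y - mu) / mu
        xtw = X.T * w
        xtwx = xtw @ X
        try:
            new_beta = np.linalg.solve(xtwx, xtw @ z)
        except np.linalg.LinAlgError:
            new_beta = np.linalg.lstsq(xtwx, xtw @ z, rcond=None)[0]
        eta = np.clip(X @ new_beta + offset, -30.0, 30.0)
        mu = np.exp(eta)
        if beta is not None and np.max(np.abs(new_beta - beta)) < tol:
            beta = new_beta
            break
        beta = new_beta
    w = mu / (1.0 + alpha * mu)
    xtwx = (X.T * w) @ X
    return beta, mu, xtwx


def _fit_gene_nb(y: np.ndarray, X: np.ndarray, offset: np.ndarray):
    """Profile out the NB dispersion with a Cox-Reid adjusted likelihood."""

    def negloglik(log_alpha: float) -> float:
        alpha = float(np.exp(log_alpha))
        beta, mu, xtwx = _irls_nb(y, X, offset, alpha, max_iter=10)
        sign, logdet = np.linalg.slogdet(xtwx)
        if sign <= 0:
            logdet = 0.0
        return -(_nb_loglik(y, mu, alpha) - 0.5 * logdet)

    res = minimize_scalar(
        negloglik,
        bounds=(np.log(DISPERSION_FLOOR), np.log(DISPERSION_CEIL)),
        method="bounded",
        options={"xatol": 0.05, "maxiter": 30},
    )
    alpha = float(np.exp(res.x)) if res.success else _moments_dispersion(y)
    beta, mu, xtwx = _irls_nb(y, X, offset, alpha)
    return beta, mu, xtwx, alpha


def _moments_dispersion(y: np.ndarray) -> float:
    """Method-of-moments fallback: var = mu + alpha mu^2 on the pooled sample."""
    m = float(np.mean(y))
    v = float(np.var(y, ddof=1)) if len(y) > 1 else 0.0
    if m <= 0:
        return DISPERSION_FLOOR
    return float(np.clip((v - m) / m**2, DISPERSION_FLOOR, DISPERSION_CEIL))


_DESIGN_CACHE: dict[int, np.ndarray] = {}


def _design_matrix(n_shrnas: int) -> np.ndarray:
    """Design for 2 x n observations: intercept, condition, shRNA-identity dummies."""
    if n_shrnas not in _DESIGN_CACHE:
        n = n_shrnas
        X = np.zeros((2 * n, n + 1))
        X[:, 0] = 1.0
        X[n:, 1] = 1.0
        for k in range(1, n):
            X[k, 1 + k] = 1.0
            X[n + k, 1 + k] = 1.0
        _DESIGN_CACHE[n_shrnas] = X
    return _DESIGN_CACHE[n_shrnas]


def test_nb_wald(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of the condition effect.

    Response = raw counts (control then treatment rows per shRNA); design =
    intercept + condition + shRNA-identity covariates; offset = log library
    size so the condition coefficient is a log representation ratio.  The
    Wald statistic is referred to a t distribution on the residual degrees of
    freedom (n_shRNA - 1), which protects calibration at small replicate
    numbers.  Non-estimable genes get p = 1 with a logged flag.
    """
    total_c = float(counts["count_control"].sum())
    total_t = float(counts["count_treatment"].sum())
    if total_c <= 0 or total_t <= 0:
        raise ValueError("cannot test: a condition has zero total counts")
    log_ratio = np.log(total_t / total_c)
    records = []
    n_flagged = 0
    for gene, sub in counts.groupby("gene", sort=True):
        yc = sub["count_control"].to_numpy(float)
        yt = sub["count_treatment"].to_numpy(float)
        n = len(yc)
        y = np.concatenate([yc, yt])
        if n < 2 or y.sum() == 0 or np.all(yc == 0) or np.all(yt == 0):
            # one-shRNA genes and degenerate all-zero sides carry no replicate
            # information for a gene-wise dispersion; flagged, not fatal
            records.append((gene, 0.0, 1.0, np.nan))
            n_flagged += 1
            continue
        X = _design_matrix(n)
        offset = np.concatenate([np.zeros(n), np.full(n, log_ratio)])
        try:
            beta, mu, xtwx, alpha = _fit_gene_nb(y, X, offset)
            cov = np.linalg.inv(xtwx)
            se = float(np.sqrt(max(cov[1, 1], 0.0)))
            if not np.isfinite(se) or se == 0:
                raise np.linalg.LinAlgError
            tstat = float(beta[1]) / se
            df = max(n - 1, 1)
            p = float(2.0 * stats.t.sf(abs(tstat), df))
            records.append((gene, tstat, min(p, 1.0), alpha))
        except (np.linalg.LinAlgError, FloatingPointError, ValueError):
            records.append((gene, 0.0, 1.0, np.nan))
            n_flagged += 1
    if n_flagged:
        logger.warning("test_nb_wald: %d gene(s) not estimable, assigned p = 1", n_flagged)
    return pd.DataFrame(records, columns=["gene", "stat", "p", "dispersion"])


# ---------------------------------------------------------------------------
# test 3: NB exact-style test with power-law dispersion
# ---------------------------------------------------------------------------

def fit_dispersion_power_law(norm_control: np.ndarray, norm_treatment: np.ndarray,
                             n_bins: int = 20) -> tuple[float, float]:
    """Fit var = mu + phi * mu^kappa across all shRNAs from paired samples.

    With one pair per shRNA, (c - t)^2 / 2 is an unbiased single-pair variance
    estimate under the null of equal means; binned means of its excess over
    the Poisson level are regressed on log mean.  Returns (phi, kappa); falls
    back to a near-Poisson model when the fit is degenerate.
    """
    c = np.asarray(norm_control, float)
    t = np.asarray(norm_treatment, float)
    m = (c + t) / 2.0
    keep = m > 0
    m, c, t = m[keep], c[keep], t[keep]
    excess = (c - t) ** 2 / 2.0 - m
    if len(m) < 20:
        return DISPERSION_FLOOR, 2.0
    order = np.argsort(m)
    bins = np.array_split(order, n_bins)
    xs, ys = [], []
    for idx in bins:
        if len(idx) == 0:
            continue
        mb = float(np.mean(m[idx]))
        eb = float(np.mean(excess[idx]))
        if mb > 0 and eb > 0:
            xs.append(np.log(mb))
            ys.append(np.log(eb))
    if len(xs) < 3:
        return DISPERSION_FLOOR, 2.0
    kappa, logphi = np.polyfit(xs, ys, 1)
    phi = float(np.exp(logphi))
    return float(np.clip(phi, 1e-12, None)), float(kappa)


def _nb_exact_two_sided(c: int, t: int, mu: float, var: float) -> float:
    """Exact-style two-sided NB test of a balanced split of ``c + t``.

    Both sides are modeled NB(mu, var); p sums the probabilities of all
    splits no more likely than the observed one, over a window wide enough
    that the truncated mass is negligible.
    """
    total = c + t
    if total == 0:
        return 1.0
    var = max(var, mu + 1e-9)
    r = min(mu**2 / (var - mu), 1e8)
    pr = r / (r + mu)
    sd = np.sqrt(var)
    lo = max(0, int(np.floor(min(mu - 15 * sd, c, t))))
    hi = min(total, int(np.ceil(max(mu + 15 * sd, c, t))))
    x = np.arange(lo, hi + 1)
    logf = stats.nbinom.logpmf(x, r, pr) + stats.nbinom.logpmf(total - x, r, pr)
    logf -= logf.max()
    f = np.exp(logf)
    f_obs = f[t - lo]
    p = f[f <= f_obs * (1.0 + 1e-12)].sum() / f.sum()
    return float(min(p, 1.0))


def test_nbp(counts: pd.DataFrame, target: float = 20e6) -> pd.DataFrame:
    """Per-gene NB exact-style test pooling each gene's shRNAs.

    Counts are depth-normalized so the two libraries are balanced, the
    mean-dispersion power law supplies the variance of each gene's pooled
    count, and a two-sided exact-style NB test is applied to the pooled
    control/treatment split.
    """
    c_norm = normalize_to_depth(counts["count_control"], target)
    t_norm = normalize_to_depth(counts["count_treatment"], target)
    phi, kappa = fit_dispersion_power_law(c_norm, t_norm)
    df = counts[["gene"]].copy()
    df["c"] = c_norm
    df["t"] = t_norm
    df["m"] = (c_norm + t_norm) / 2.0
    df["vshr"] = df["m"] + phi * df["m"] ** kappa
    agg = df.groupby("gene", sort=True).agg(c=("c", "sum"), t=("t", "sum"), v=("vshr", "sum"))
    records = []
    for gene, row in agg.iterrows():
        c_i = int(round(row["c"]))
        t_i = int(round(row["t"]))
        mu = (c_i + t_i) / 2.0
        if mu == 0:
            records.append((gene, 1.0))
            continue
        records.append((gene, _nb_exact_two_sided(c_i, t_i, mu, float(row["v"]))))
    return pd.DataFrame(records, columns=["gene", "p"])


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def classify_direction(counts: pd.DataFrame, target: float = 20e6) -> pd.DataFrame:
    """Pooled per-gene log2 fold change of representation and its direction.

    Enriched if the gene's pooled treatment representation exceeds control,
    depleted if below; exact ties are 'unchanged' and flagged.
    """
    df = representation_table(counts, target)
    agg = df.groupby("gene", sort=True).agg(
        c=("norm_control", "sum"), t=("norm_treatment", "sum")
    )
    log2fc = np.log2((agg["t"] + PSEUDOCOUNT) / (agg["c"] + PSEUDOCOUNT))
    direction = np.where(log2fc > 0, "enriched", np.where(log2fc < 0, "depleted", "unchanged"))
    return pd.DataFrame({"gene": agg.index, "log2_fold_change": log2fc.to_numpy(),
                         "direction": direction})


def mean_rank_consensus(p_tables: Mapping[str, pd.Series], cutoff: float = 500) -> pd.DataFrame:
    """Aggregate per-test p-values into the mean-rank consensus.

    Each test's genes are ranked ascending by p (average ranks on ties); the
    arithmetic mean of a gene's ranks across tests is its consensus score and
    genes with mean rank strictly below ``cutoff`` are significant.  All
    tables must cover the same gene universe.  Invariant to any monotone
    transform of each test's p-values.
    """
    names = list(p_tables)
    if len(names) < 2:
        raise ValueError("need at least two tests to aggregate")
    universe = None
    ranks = {}
    for name in names:
        s = p_tables[name]
        genes = set(s.index)
        if universe is None:
            universe = genes
        elif genes != universe:
            raise ValueError(f"test {name!r} covers a different gene universe")
        ranks[f"rank_{name}"] = s.rank(method="average", ascending=True)
    out = pd.DataFrame(ranks)
    out.index.name = "gene"
    out["mean_rank"] = out.mean(axis=1)
    out["significant"] = out["mean_rank"] < cutoff
    return out.reset_index().sort_values("mean_rank", kind="mergesort").reset_index(drop=True)


def analyze_shrna_screen(counts: pd.DataFrame, cutoff: float = 500,
                         target: float = 20e6) -> pd.DataFrame:
    """Run all three tests and the mean-rank consensus on a count table.

    Returns one row per gene: per-test p-values and ranks, mean rank,
    significance at the cutoff, pooled log2 fold change and direction.
    """
    q = test_quantile(counts).set_index("gene")["p"]
    w = test_nb_wald(counts).set_index("gene")["p"]
    e = test_nbp(counts).set_index("gene")["p"]
    consensus = mean_rank_consensus({"quantile": q, "nb_wald": w, "nbp": e}, cutoff=cutoff)
    direction = classify_direction(counts, target).set_index("gene")
    out = consensus.set_index("gene")
    out["p_quantile"] = q
    out["p_nb_wald"] = w
    out["p_nbp"] = e
    out["log2_fold_change"] = direction["log2_fold_change"]
    out["direction"] = direction["direction"]
    return out.reset_index()
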