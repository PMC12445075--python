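"""Shared statistical primitives.

Normalization (median-of-ratios size factors / CPM), Welch-t differential
expression on the log scale, Holm / Benjamini-Hochberg adjustment, all-pairs
Pearson correlation with Holm correction, an exact-or-asymptotic Mann-Whitney
U test, 2^-ddCT relative quantification, and z-scoring.

The differential-expression stage deliberately replaces a negative-binomial
GLM with a Welch t-test on log2 size-factor-normalized counts: the DE call is
a gate feeding the bespoke signature-selection steps, and a dependency-free,
fully documented test keeps the pipeline self-contained. The gate thresholds
(|log2FC| > 1, FDR < 0.05) are unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# ---------------------------------------------------------------------------
# normalization

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (genes x samples count matrix).

    The reference profile is the per-gene geometric mean across samples; genes
    with a zero count in any sample (geometric mean 0) are excluded from the
    median. Raises if a sample is all zeros.
    """
    mat = counts.to_numpy(dtype=float)
    zero_samples = np.flatnonzero(mat.sum(axis=0) == 0)
    if len(zero_samples):
        raise ValueError(
            f"all-zero sample(s): {list(counts.columns[zero_samples])}"
        )
    with np.errstate(divide="ignore"):
        log_mat = np.log(mat)
    ref = log_mat.mean(axis=1)  # -inf where any zero
    usable = np.isfinite(ref)
    if not usable.any():
        raise ValueError("no gene has nonzero counts in every sample")
    ratios = np.exp(log_mat[usable] - ref[usable, None])
    return pd.Series(np.median(ratios, axis=0), index=counts.columns)


def normalize_counts(
    counts: pd.DataFrame, method: str = "size_factors", log2: bool = False
) -> pd.DataFrame:
    """Normalize a genes x samples count matrix.

    method 'size_factors': divide each sample by its median-of-ratios factor;
    method 'cpm': scale each sample to 1e6 total. With ``log2=True`` the
    result is log2(x + 1), the variance-stabilizing transform used throughout
    the signature pipeline.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    if method == "size_factors":
        out = counts / size_factors(counts)
    elif method == "cpm":
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValueError(
                f"all-zero sample(s): {list(counts.columns[totals == 0])}"
            )
        out = counts * 1e6 / totals
    else:
        raise ValueError(f"unknown method {method!r}")
    if log2:
        out = np.log2(out + 1.0)
    return out


# ---------------------------------------------------------------------------
# multiple testing

def adjust_pvalues(p, method: str = "holm") -> np.ndarray:
    """Holm step-down or Benjamini-Hochberg step-up adjustment.

    Input order is preserved; monotonicity is enforced by the underlying
    step procedures. Values outside [0, 1] raise.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    if method not in ("holm", "bh"):
        raise ValueError(f"unknown method {method!r}")
    sm_method = "holm" if method == "holm" else "fdr_bh"
    return multipletests(p, method=sm_method)[1]


# ---------------------------------------------------------------------------
# differential expression

@dataclass
class DifferentialResult:
    feature: str
    log2fc: float
    p: float
    p_adj: float
    significant: bool


def differential_expression(
    counts: pd.DataFrame,
    group_a: list[str],
    group_b: list[str],
    fc_gate: float = 1.0,
    fdr_gate: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Welch t-test between two sample groups.

    Counts are size-factor normalized and log2(x+1) transformed; log2FC is
    mean(group_a) - mean(group_b) on that scale, so positive values are
    up in *group_a*. p values are BH-adjusted; the ``significant`` flag is
    |log2FC| > fc_gate AND p_adj < fdr_gate. Genes with zero variance in both
    groups get p = 1 when the means are equal (p = 0 otherwise) and are marked
    in the ``degenerate`` column rather than raising.
    """
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need >= 2 samples per group")
    log = normalize_counts(counts, "size_factors", log2=True)
    xa = log[group_a].to_numpy()
    xb = log[group_b].to_numpy()
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(xa, xb, axis=1, equal_var=False)
    degenerate = ~np.isfinite(p)
    p = np.where(degenerate, np.where(np.isclose(log2fc, 0.0), 1.0, 0.0), p)
    p_adj = adjust_pvalues(p, "bh")
    sig = (np.abs(log2fc) > fc_gate) & (p_adj < fdr_gate)
    return pd.DataFrame(
        {
            "feature": counts.index,
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "significant": sig,
            "degenerate": degenerate,
        }
    ).set_index("feature", drop=False)


# ---------------------------------------------------------------------------
# correlation

def pearson_pairs(expr: pd.DataFrame, genes: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation for every unordered gene pair, Holm-adjusted.

    *expr* is genes x samples on any (already normalized) scale. p values come
    from the t transform t = r * sqrt((n-2)/(1-r^2)) with n-2 degrees of
    freedom, two-sided, then Holm adjustment across all pairs. Pairs involving
    a zero-variance gene are reported with r = NaN, p = 1 and flagged.
    """
    if genes is None:
        genes = list(expr.index)
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:5]}")
    sub = expr.loc[genes]
    n = sub.shape[1]
    if n < 3:
        raise ValueError("need >= 3 samples")
    mat = sub.to_numpy(dtype=float)
    sd = mat.std(axis=1, ddof=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r_full = np.corrcoef(mat)
    rows = []
    for i, j in combinations(range(len(genes)), 2):
        if constant[i] or constant[j]:
            rows.append((genes[i], genes[j], np.nan, 1.0, True))
            continue
        r = float(np.clip(r_full[i, j], -1.0, 1.0))
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * sps.t.sf(abs(t), df=n - 2)
        rows.append((genes[i], genes[j], r, p, False))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "degenerate"])
    out["p_adj"] = adjust_pvalues(out["p"].to_numpy(), "holm")
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney U

@dataclass
class RankTestResult:
    U: float
    p: float
    exact: bool


def _mw_u_and_ties(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    return u1, tie_counts


def mann_whitney(x, y, exact_limit: int = 64) -> RankTestResult:
    """Two-sided Mann-Whitney U test (U reported for *x*).

    Midrank tie handling throughout. When n1*n2 <= *exact_limit* the p value
    is computed by exhaustive enumeration of all C(n1+n2, n1) assignments of
    the pooled values (valid under ties); otherwise by normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs, tie_counts = _mw_u_and_ties(x, y)
    mu = n1 * n2 / 2.0
    if n1 * n2 <= exact_limit:
        pooled = np.concatenate([x, y])
        ranks = sps.rankdata(pooled)
        dev_obs = abs(u_obs - mu)
        total = comb(n1 + n2, n1)
        hits = 0
        offset = n1 * (n1 + 1) / 2.0
        for idx in combinations(range(n1 + n2), n1):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return RankTestResult(U=u_obs, p=hits / total, exact=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return RankTestResult(U=u_obs, p=1.0, exact=False)
    # continuity correction toward the mean
    z = (u_obs - mu - np.sign(u_obs - mu) * 0.5) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankTestResult(U=u_obs, p=p, exact=False)


def mann_whitney_matrix(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized asymptotic Mann-Whitney across features.

    *xa*, *xb* are features x observations arrays sharing the feature axis.
    Returns (U for group a, two-sided p) per feature using the same normal
    approximation (tie + continuity corrections) as :func:`mann_whitney`.
    Used by the single-cell differential stage where per-gene exact
    enumeration is unnecessary at thousands of cells.
    """
    n1, n2 = xa.shape[1], xb.shape[1]
    n = n1 + n2
    pooled = np.concatenate([xa, xb], axis=1)
    ranks = sps.rankdata(pooled, axis=1)
    u1 = ranks[:, :n1].sum(axis=1) - n1 * (n1 + 1) / 2.0
    # per-feature tie correction
    srt = np.sort(pooled, axis=1)
    tie_term = np.empty(pooled.shape[0])
    for i in range(pooled.shape[0]):
        _, counts = np.unique(srt[i], return_counts=True)
        tie_term[i] = (counts.astype(float) ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (u1 - mu - np.sign(u1 - mu) * 0.5) / np.sqrt(var)
    p = np.where(var > 0, np.minimum(1.0, 2.0 * sps.norm.sf(np.abs(z))), 1.0)
    return u1, p


# ---------------------------------------------------------------------------
# qPCR relative quantification

@dataclass
class DdctResult:
    delta_ct_exp: float
    delta_ct_ctrl: float
    delta_delta_ct: float
    fold_change: float


def ddct_fold_change(
    ct_target_exp: float,
    ct_housekeeping_exp: float,
    ct_target_ctrl: float,
    ct_housekeeping_ctrl: float,
) -> DdctResult:
    """2^-ddCT relative quantification against a housekeeping gene.

    dCT = CT(target) - CT(housekeeping) per condition; ddCT is the
    experimental minus control dCT; fold change is 2^(-ddCT).
    """
    cts = (ct_target_exp, ct_housekeeping_exp, ct_target_ctrl, ct_housekeeping_ctrl)
    if not all(np.isfinite(cts)):
        raise ValueError("CT values must be finite")
    d_exp = ct_target_exp - ct_housekeeping_exp
    d_ctrl = ct_target_ctrl - ct_housekeeping_ctrl
    ddct = d_exp - d_ctrl
    return DdctResult(d_exp, d_ctrl, ddct, 2.0 ** (-ddct))


# ---------------------------------------------------------------------------
# z-scores

def zscore(values, axis: int | None = None) -> np.ndarray:
    """Standardize with sample SD (ddof=1); zero-SD slices return zeros + warning."""
    x = np.asarray(values, dtype=float)
    mean = x.mean(axis=axis, keepdims=axis is not None)
    sd = x.std(axis=axis, ddof=1, keepdims=axis is not None)
    if np.any(sd == 0):
        warnings.warn("zero standard deviation; returning zeros for constant slices")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mean) / sd
    return np.where(np.broadcast_to(sd, z.shape) == 0, 0.0, z)
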