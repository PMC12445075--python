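"""Signature scoring.

Four scoring schemes cover the pipeline's needs:

* :func:`rank_score` — rank-based per-sample scores in the singscore style:
  each sample's genes are midranked, the mean rank of the up set is min-max
  normalized by its theoretical extremes given the set size, the down set
  analogously with its sense inverted, and the two are combined. Scores are
  invariant to any strictly monotone per-sample transform of expression.
* :func:`mean_signature_score` — the mean-expression score (down genes
  inverted) fed to survival stratification, matching the "mean expression of
  selected genes / invert feature for downregulated genes" convention of the
  KM web tool being emulated.
* :func:`subtype_zscore` — per-gene z-scores of log2FC averaged over subtype
  gene sets.
* :func:`cell_set_score` — per-cell set score against expression-bin-matched
  control genes (25 bins, 50 controls per set gene by default, seeded).

Rank-normalization constants: for a set of size k among G ranked genes the
mean rank lies in [(k+1)/2, G-(k-1)/2], so the normalized score is
(mean_rank - (k+1)/2) / (G - k).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .signatures import GeneSignature
from .stats import zscore


def _check_coverage(sig_genes: list[str], index: pd.Index, what: str) -> list[str]:
    present = [g for g in sig_genes if g in index]
    if not sig_genes:
        return present
    if len(present) < 0.5 * len(sig_genes):
        missing = sorted(set(sig_genes) - set(present))
        raise KeyError(
            f"{what}: only {len(present)}/{len(sig_genes)} signature genes present; "
            f"missing {missing[:10]}"
        )
    return present


def rank_score(expr: pd.DataFrame, signature: GeneSignature) -> pd.DataFrame:
    """Rank-based signature score per sample.

    *expr* is genes x samples on any monotone scale. Requires >= 50% of the
    signature's genes in the matrix. Returns a table with raw (mean-rank),
    normalized (in [0, 1] for up-only signatures, [-1, 1] with a down set)
    and z-standardized scores. A constant sample scores exactly the midpoint
    and is flagged.
    """
    up = _check_coverage(signature.up_genes, expr.index, "up genes")
    down = _check_coverage(signature.down_genes, expr.index, "down genes")
    if not up and not down:
        raise ValueError("signature has no genes in the matrix")
    mat = expr.to_numpy(dtype=float)
    g = mat.shape[0]
    ranks = sps.rankdata(mat, axis=0)  # midranks, 1..G per sample

    def norm_mean_rank(gene_list: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = expr.index.get_indexer(gene_list)
        k = len(gene_list)
        mean_rank = ranks[idx].mean(axis=0)
        lo, hi = (k + 1) / 2.0, g - (k - 1) / 2.0
        return mean_rank, (mean_rank - lo) / (hi - lo)

    if up:
        raw_up, norm_up = norm_mean_rank(up)
    else:
        raw_up, norm_up = np.zeros(mat.shape[1]), np.zeros(mat.shape[1])
    if down:
        raw_dn, norm_dn = norm_mean_rank(down)
        raw = raw_up - raw_dn
        normalized = norm_up - norm_dn
    else:
        raw, normalized = raw_up, norm_up

    constant = mat.std(axis=0) == 0
    if constant.any():
        warnings.warn("constant sample(s) score the theoretical midpoint")
    return pd.DataFrame(
        {
            "sample": expr.columns,
            "raw_score": raw,
            "normalized_score": normalized,
            "z": zscore(normalized) if len(normalized) > 1 else np.zeros_like(normalized),
            "constant_sample": constant,
        }
    ).set_index("sample", drop=False)


def classify_inducibility(scores: pd.DataFrame, z_band: float = 0.5) -> pd.DataFrame:
    """Three-way inducibility call from standardized signature scores.

    z >= +z_band → inducible; z <= -z_band → non-inducible; otherwise
    intermediate. Output is ranked by descending score. Zero score variance
    makes every call intermediate (with a warning).
    """
    if len(scores) < 3:
        raise ValueError("need >= 3 samples to standardize scores")
    out = scores.copy()
    vals = out["normalized_score"].to_numpy(dtype=float)
    scale = max(1.0, float(np.abs(vals).max()))
    if vals.std(ddof=1) <= 1e-12 * scale:
        warnings.warn("zero score variance; all samples classified intermediate")
        out["z"] = 0.0
    else:
        out["z"] = zscore(out["normalized_score"].to_numpy())
    out["class"] = np.select(
        [out["z"] >= z_band, out["z"] <= -z_band],
        ["inducible", "non-inducible"],
        default="intermediate",
    )
    return out.sort_values("z", ascending=False, kind="mergesort")


def mean_signature_score(
    expr: pd.DataFrame, signature: GeneSignature, invert_down: bool = True
) -> pd.Series:
    """Mean expression over up genes, minus the down-gene mean when inverting.

    This is the score fed to best-cutoff survival stratification; *expr*
    should be on the log scale. Swapping the up and down lists negates it.
    """
    up = _check_coverage(signature.up_genes, expr.index, "up genes")
    down = _check_coverage(signature.down_genes, expr.index, "down genes")
    if not up and not down:
        raise ValueError("signature has no genes in the matrix")
    score = pd.Series(0.0, index=expr.columns)
    if up:
        score = score + expr.loc[up].mean(axis=0)
    if down and invert_down:
        score = score - expr.loc[down].mean(axis=0)
    elif down and not invert_down:
        score = score + expr.loc[down].mean(axis=0)
    score.name = f"{signature.name}_score"
    return score


def subtype_zscore(log2fc: pd.DataFrame, gene_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Mean per-set z-score of log2FC, per sample.

    Each gene's log2FC is z-scored across samples, then averaged over each
    set's genes. Missing genes are dropped with a warning; a set needs >= 2
    present genes... single-gene sets are allowed but reported as-is.
    """
    rows = {}
    z = pd.DataFrame(
        zscore(log2fc.to_numpy(), axis=1), index=log2fc.index, columns=log2fc.columns
    )
    for set_name, genes in gene_sets.items():
        present = [g for g in genes if g in log2fc.index]
        if len(present) < len(genes):
            warnings.warn(f"set {set_name!r}: {len(genes) - len(present)} genes missing")
        if not present:
            rows[set_name] = pd.Series(np.nan, index=log2fc.columns)
            continue
        rows[set_name] = z.loc[present].mean(axis=0)
    return pd.DataFrame(rows).T


def cell_set_score(
    log_expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 25,
    n_ctrl: int = 50,
    seed: int = 0,
) -> pd.Series:
    """Per-cell gene-set score against expression-matched controls.

    *log_expr* is cells x genes on the log scale. Genes are ordered by mean
    expression across cells and cut into ``n_bins`` equal-size bins; for each
    set gene, ``n_ctrl`` control genes are sampled (seeded, without
    replacement, capped at bin size) from its bin; the score is the mean over
    set genes minus the mean over the pooled controls, per cell.
    """
    present = [g for g in gene_set if g in log_expr.columns]
    if not present:
        raise ValueError("gene set entirely absent from the matrix")
    rng = np.random.default_rng(seed)
    gene_means = log_expr.mean(axis=0)
    order = gene_means.rank(method="first")
    bins = pd.cut(order, bins=n_bins, labels=False)
    by_bin = {b: list(idx) for b, idx in log_expr.columns.groupby(bins).items()}

    controls: set[str] = set()
    for gene in present:
        pool = by_bin[bins[gene]]
        k = min(n_ctrl, len(pool))
        controls.update(rng.choice(pool, size=k, replace=False))
    ctrl = sorted(controls)
    score = log_expr[present].mean(axis=1) - log_expr[ctrl].mean(axis=1)
    score.name = "set_score"
    return score
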