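"""Single-cell stage: QC, normalization, extreme-decile stratification,
extreme-group differential expression, treatment enrichment, and a windowed
CNV score.

The heavy external machinery of a full single-cell pipeline (variational
batch correction, doublet removal, automated cell typing, graph clustering,
HMM-based CNV inference) is out of scope here: cell-type and patient labels
arrive as input metadata, and copy-number signal is summarized by a windowed
relative-expression score that keeps the 250-gene sliding-window principle
without the HMM. What this module does own is the analysis proper:
deterministic QC gates, pooled top/bottom-decile stratification by a single
gene's expression, rank-test differential expression between the extremes,
and the treated-vs-naive enrichment fold of the high-expression state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from . import stats


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)


@dataclass
class QCReport:
    n_input_cells: int
    n_input_genes: int
    removed_low_genes: int        # cells under the min-genes gate
    removed_rare_genes: int       # genes under the min-cells gate
    removed_high_mt: int
    removed_high_ribo: int
    removed_high_count: int       # cells above the gene-count percentile
    n_cells: int
    n_genes: int


def qc_filter(
    adata: ad.AnnData,
    min_genes: int = 200,
    min_cells: int = 10,
    max_mt: float = 0.15,
    max_ribo: float = 0.15,
    gene_pct: float = 98.0,
) -> tuple[ad.AnnData, QCReport]:
    """Sequential QC gates, in a fixed order.

    (1) drop cells expressing fewer than ``min_genes`` genes; (2) drop genes
    detected in fewer than ``min_cells`` of the remaining cells; (3) drop
    cells whose mitochondrial or ribosomal count fraction exceeds the 15%
    gates (separate thresholds — the two gene families are gated
    independently); (4) drop cells whose detected-gene count exceeds the
    ``gene_pct`` percentile of the remaining cells. Metrics for each gate are
    computed on the matrix as it stands when the gate runs. Raises if nothing
    survives; the report counts removals per gate.
    """
    if "is_mt" not in adata.var or "is_ribo" not in adata.var:
        raise ValueError("var must carry is_mt and is_ribo flags")
    X = _dense(adata.X)
    n_in_cells, n_in_genes = X.shape

    n_genes_per_cell = (X > 0).sum(axis=1)
    keep_cells = n_genes_per_cell >= min_genes
    removed_low = int((~keep_cells).sum())
    X = X[keep_cells]
    obs = adata.obs[keep_cells].copy()

    detected_in = (X > 0).sum(axis=0)
    keep_genes = detected_in >= min_cells
    removed_rare = int((~keep_genes).sum())
    X = X[:, keep_genes]
    var = adata.var[keep_genes].copy()

    totals = X.sum(axis=1).astype(float)
    totals[totals == 0] = 1.0
    mt_frac = X[:, var["is_mt"].to_numpy(bool)].sum(axis=1) / totals
    ribo_frac = X[:, var["is_ribo"].to_numpy(bool)].sum(axis=1) / totals
    high_mt = mt_frac > max_mt
    high_ribo = ribo_frac > max_ribo
    removed_mt = int(high_mt.sum())
    removed_ribo = int((high_ribo & ~high_mt).sum())
    keep = ~(high_mt | high_ribo)
    X = X[keep]
    obs = obs[keep]
    mt_frac, ribo_frac = mt_frac[keep], ribo_frac[keep]

    n_genes_now = (X > 0).sum(axis=1)
    if len(n_genes_now) == 0:
        raise ValueError(
            f"no cells survive QC (low-gene {removed_low}, MT {removed_mt}, "
            f"ribo {removed_ribo})"
        )
    cutoff = np.percentile(n_genes_now, gene_pct)
    high_count = n_genes_now > cutoff
    removed_high = int(high_count.sum())
    X = X[~high_count]
    obs = obs[~high_count].copy()

    if X.shape[0] == 0 or X.shape[1] == 0:
        raise ValueError("empty matrix after QC")
    obs["n_genes"] = (X > 0).sum(axis=1)
    obs["total_counts"] = X.sum(axis=1)
    obs["mt_frac"] = mt_frac[~high_count]
    obs["ribo_frac"] = ribo_frac[~high_count]
    report = QCReport(
        n_input_cells=n_in_cells, n_input_genes=n_in_genes,
        removed_low_genes=removed_low, removed_rare_genes=removed_rare,
        removed_high_mt=removed_mt, removed_high_ribo=removed_ribo,
        removed_high_count=removed_high,
        n_cells=X.shape[0], n_genes=X.shape[1],
    )
    out = ad.AnnData(X=X, obs=obs, var=var)
    out.uns = dict(adata.uns)
    return out, report


def normalize_cells(adata: ad.AnnData) -> ad.AnnData:
    """Library-size normalization to the median total count, then log1p.

    Stores the result in ``layers['lognorm']`` and returns the same object.
    """
    X = _dense(adata.X).astype(float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("cells with zero total counts; run qc_filter first")
    target = np.median(totals)
    adata.layers["lognorm"] = np.log1p(X * (target / totals)[:, None])
    return adata


def stratify_extremes(
    adata: ad.AnnData, gene: str, q: float = 0.10, layer: str = "lognorm"
) -> pd.Series:
    """Label the top and bottom q-fraction of cells by one gene's expression.

    Stratification is over the pooled population given (the malignant pool,
    across treatment arms). Exactly floor(q*N) cells get 'High' and as many
    'Low'; boundary ties are broken by total counts descending, then cell id
    ascending, so the split is deterministic. Errors when groups would have
    fewer than 10 cells.
    """
    if gene not in adata.var_names:
        raise KeyError(f"gene {gene!r} not in matrix")
    n = adata.n_obs
    k = int(np.floor(q * n))
    if k < 10:
        raise ValueError(f"q*N = {k} < 10: groups too small")
    expr = np.asarray(adata.layers[layer][:, adata.var_names.get_loc(gene)]).ravel()
    totals = _dense(adata.X).sum(axis=1)
    order_df = pd.DataFrame(
        {"expr": expr, "totals": totals, "cell": adata.obs_names}
    )
    # High: largest expression; ties -> larger library first, then cell id
    high_order = order_df.sort_values(
        ["expr", "totals", "cell"], ascending=[False, False, True], kind="mergesort"
    ).index[:k]
    low_order = order_df.sort_values(
        ["expr", "totals", "cell"], ascending=[True, False, True], kind="mergesort"
    ).index[:k]
    strata = pd.Series("neither", index=adata.obs_names, name="strata")
    strata.iloc[high_order] = "High"
    strata.iloc[low_order] = "Low"
    return strata


def extreme_de(
    adata: ad.AnnData, strata: pd.Series, layer: str = "lognorm"
) -> pd.DataFrame:
    """Differential expression between the High and Low strata.

    Per-gene Mann-Whitney (asymptotic, tie-corrected — see
    :func:`stressig.stats.mann_whitney_matrix`), BH-adjusted. The
    significance score is -log10 of the adjusted probability and the
    enrichment score the High-minus-Low difference in mean log expression.
    """
    X = np.asarray(adata.layers[layer])
    hi = X[(strata == "High").to_numpy()]
    lo = X[(strata == "Low").to_numpy()]
    if hi.shape[0] == 0 or lo.shape[0] == 0:
        raise ValueError("both strata must be non-empty")
    u, p = stats.mann_whitney_matrix(hi.T, lo.T)
    p_adj = stats.adjust_pvalues(p, "bh")
    enrich = hi.mean(axis=0) - lo.mean(axis=0)
    with np.errstate(divide="ignore"):
        sig_score = -np.log10(p_adj)
    return pd.DataFrame(
        {
            "feature": adata.var_names, "U": u, "p": p, "p_adj": p_adj,
            "significance_score": sig_score, "enrichment": enrich,
            "significant": (p_adj < 0.05) & (np.abs(enrich) > 0),
        }
    ).set_index("feature", drop=False)


def enrichment_fold(
    strata: pd.Series, treatment: pd.Series, odds_ratio: bool = False
) -> tuple[float, pd.DataFrame, bool]:
    """Treated-vs-naive enrichment of the High state.

    Default definition is the proportion ratio
    ``[n(High, treated) / n(treated)] / [n(High, naive) / n(naive)]`` with
    denominators counting all cells of each arm in the stratified population;
    ``odds_ratio=True`` switches to the odds ratio of the High/Low 2x2 table.
    A Haldane correction (+0.5 on every cell of the table) is applied only
    when a zero cell occurs, in which case the result is flagged. Returns
    (fold, 2x2 table High/Low x treated/naive, corrected_flag).
    """
    treatment = treatment.reindex(strata.index)
    for arm in ("treated", "naive"):
        if (treatment == arm).sum() == 0:
            raise ValueError(f"no cells in treatment arm {arm!r}")
    table = pd.DataFrame(
        {
            arm: [
                int(((strata == s) & (treatment == arm)).sum()) for s in ("High", "Low")
            ]
            for arm in ("treated", "naive")
        },
        index=["High", "Low"],
    )
    corrected = (table.to_numpy() == 0).any()
    t = table.astype(float) + (0.5 if corrected else 0.0)
    if corrected:
        warnings.warn("zero cell in contingency table; Haldane correction applied")
    if odds_ratio:
        fold = (t.loc["High", "treated"] / t.loc["Low", "treated"]) / (
            t.loc["High", "naive"] / t.loc["Low", "naive"]
        )
    else:
        n_treated = float((treatment == "treated").sum()) + (0.5 if corrected else 0.0)
        n_naive = float((treatment == "naive").sum()) + (0.5 if corrected else 0.0)
        fold = (t.loc["High", "treated"] / n_treated) / (t.loc["High", "naive"] / n_naive)
    return float(fold), table, bool(corrected)


def cnv_window_score(
    adata: ad.AnnData,
    reference_cells: list[str] | np.ndarray,
    window: int = 250,
    layer: str = "lognorm",
    clip_sd: float = 3.0,
) -> tuple[np.ndarray, pd.Series]:
    """Windowed relative-expression CNV profile and per-cell burden.

    Genes must carry a ``position`` column in ``var`` (genomic order). Each
    cell's log expression minus the reference-cell mean, clipped to
    ±``clip_sd`` reference SDs per gene, is smoothed by a centered moving
    average over ``window`` consecutive genes (truncated at the ends);
    burden is the mean squared profile per cell. Identifying and removing
    the lowest-burden cluster (normal-adjacent tissue) is left to the
    caller. ``window=1`` returns the clipped relative expression itself.
    """
    if window > adata.n_vars:
        raise ValueError("window exceeds gene count")
    if "position" not in adata.var:
        raise ValueError("var must carry genomic 'position' for ordering")
    order = np.argsort(adata.var["position"].to_numpy(), kind="mergesort")
    X = np.asarray(adata.layers[layer])[:, order]
    ref_mask = adata.obs_names.isin(reference_cells)
    if ref_mask.sum() == 0:
        raise ValueError("no reference cells found")
    ref_mean = X[ref_mask].mean(axis=0)
    ref_sd = X[ref_mask].std(axis=0, ddof=1)
    fallback = ref_sd[ref_sd > 0].mean() if (ref_sd > 0).any() else 1.0
    ref_sd = np.where(ref_sd > 0, ref_sd, fallback)
    rel = np.clip(X - ref_mean, -clip_sd * ref_sd, clip_sd * ref_sd)
    profile = (
        pd.DataFrame(rel).T.rolling(window, center=True, min_periods=1).mean().T.to_numpy()
    )
    # undo gene reordering so columns match var_names
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    profile = profile[:, inv]
    burden = pd.Series(np.mean(profile**2, axis=1), index=adata.obs_names, name="cnv_burden")
    return profile, burden
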