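"""Signature derivation: the inducibility signature and the STRESS signature.

Two bespoke procedures sit here. The inducibility signature separates cell
lines that can vs. cannot upregulate the integrin-beta3 analog: differential
expression between the two known groups, gated at |log2FC| > 1 and FDR < 0.05,
then a robustness filter dropping genes whose within-group SD on the
log-normalized scale exceeds 2 in either group; the upregulated survivors form
the signature.

The STRESS signature starts from STAT-open regions (STAT3-bound, accessible
only in inducible lines), catalogs their enhancer-linked candidate genes,
computes all pairwise Pearson correlations across a tumor cohort
(Holm-adjusted), ranks genes by how often they appear in significantly
correlated pairs, keeps the top half of the distinct ranks (zero-count genes
excluded — both behaviors are explicit gates), and finally splits the
selection by survival direction: genes whose high expression worsens outcome
(hazard ratio > 1 at the best-cutoff split) go to the up list, protective
genes to the down list. Every stage's input/output sizes are recorded in the
signature's provenance so the reduction is auditable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd

from . import intervals, stats
from .survival import best_cutoff


@dataclass
class GeneSignature:
    name: str
    up_genes: list[str]
    down_genes: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down gene lists overlap")
        if not self.up_genes and not self.down_genes:
            warnings.warn(f"signature {self.name!r} is empty")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)

    def to_gmt(self, path) -> None:
        """One line per direction: NAME_UP and (if present) NAME_DN."""
        with open(path, "w") as fh:
            fh.write("\t".join([f"{self.name}_UP", "na"] + list(self.up_genes)) + "\n")
            if self.down_genes:
                fh.write("\t".join([f"{self.name}_DN", "na"] + list(self.down_genes)) + "\n")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"name": self.name, "up_genes": self.up_genes,
                 "down_genes": self.down_genes, "provenance": self.provenance},
                fh, indent=2, default=str,
            )


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file into {set name: gene list}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def signature_from_gmt(path, name: str) -> GeneSignature:
    sets = read_gmt(path)
    return GeneSignature(
        name=name,
        up_genes=sets.get(f"{name}_UP", []),
        down_genes=sets.get(f"{name}_DN", []),
    )


# ---------------------------------------------------------------------------
# inducibility signature

def derive_inducible_signature(
    counts: pd.DataFrame,
    inducible_samples: list[str],
    noninducible_samples: list[str],
    fc_gate: float = 1.0,
    fdr_gate: float = 0.05,
    sd_gate: float = 2.0,
    name: str = "B3_INDUCIBLE",
) -> GeneSignature:
    """Differential expression plus within-group SD filter, up-genes only.

    Pipeline: size-factor normalization; Welch-t DE between the groups;
    keep |log2FC| > fc_gate and FDR < fdr_gate; on the log2-normalized scale
    drop surviving DEGs whose SD exceeds sd_gate within EITHER group (a gene
    must behave consistently across all lines of a group to be part of a
    robust signature); the upregulated survivors are the signature.
    """
    de = stats.differential_expression(
        counts, inducible_samples, noninducible_samples, fc_gate, fdr_gate
    )
    degs = de[de["significant"]]
    log = stats.normalize_counts(counts, "size_factors", log2=True)
    sd_ind = log.loc[degs.index, inducible_samples].std(axis=1, ddof=1)
    sd_non = log.loc[degs.index, noninducible_samples].std(axis=1, ddof=1)
    stable = degs.index[(sd_ind <= sd_gate) & (sd_non <= sd_gate)]
    up = sorted(g for g in stable if de.loc[g, "log2fc"] > 0)
    provenance = {
        "n_genes": int(len(counts)),
        "n_de": int(len(degs)),
        "n_after_sd_filter": int(len(stable)),
        "n_up": len(up),
        "fc_gate": fc_gate, "fdr_gate": fdr_gate, "sd_gate": sd_gate,
        "n_inducible": len(inducible_samples),
        "n_noninducible": len(noninducible_samples),
    }
    return GeneSignature(name=name, up_genes=up, provenance=provenance)


# ---------------------------------------------------------------------------
# correlation-frequency selection

def rank_by_pair_frequency(
    pairs: pd.DataFrame, alpha: float = 0.05, use_adjusted: bool = True
) -> pd.DataFrame:
    """Per-gene count of significant correlated pairs, competition-ranked.

    A pair is significant when its (Holm-adjusted, unless ``use_adjusted`` is
    False) p value is below *alpha*. Rank 1 is the most connected gene; tied
    counts share the better rank (competition ranking) and the output is
    sorted by (rank, gene) so tie order is stable alphabetically.
    """
    universe = sorted(set(pairs["gene_a"]) | set(pairs["gene_b"]))
    col = "p_adj" if use_adjusted else "p"
    sig = pairs[pairs[col] < alpha]
    counts = pd.Series(0, index=universe, dtype=int)
    for side in ("gene_a", "gene_b"):
        vc = sig[side].value_counts()
        counts = counts.add(vc, fill_value=0).astype(int)
    rank = counts.apply(lambda c: int((counts > c).sum()) + 1)
    out = pd.DataFrame(
        {"gene": counts.index, "n_significant_pairs": counts.values, "rank": rank.values}
    )
    return out.sort_values(["rank", "gene"], kind="mergesort").reset_index(drop=True)


def select_top_half(ranking: pd.DataFrame, min_count: int = 1) -> list[str]:
    """Genes in the top half of the distinct ranks, zero-count genes excluded.

    Among genes with at least ``min_count`` significant pairs, the distinct
    competition ranks are enumerated and genes at the best
    ceil(n_distinct / 2) ranks are selected. Both gates (the count floor and
    the half-of-distinct-ranks threshold) are explicit parameters of the
    selection, and the caller can audit them via the returned provenance of
    :func:`derive_stress_signature`.
    """
    if ranking.empty:
        raise ValueError("empty ranking")
    eligible = ranking[ranking["n_significant_pairs"] >= min_count]
    if eligible.empty:
        return []
    distinct = sorted(eligible["rank"].unique())
    threshold = distinct[ceil(len(distinct) / 2) - 1]
    return sorted(eligible.loc[eligible["rank"] <= threshold, "gene"])


# ---------------------------------------------------------------------------
# survival direction

@dataclass
class DirectionResult:
    gene: str
    direction: str | None  # 'hazardous' | 'protective' | None when undefined
    hr: float
    p: float
    flagged: bool


def survival_direction(
    expr_row: pd.Series, time, event,
    lower_q: float = 0.25, upper_q: float = 0.75,
) -> DirectionResult:
    """Call a gene hazardous or protective from a best-cutoff Cox fit.

    The gene's per-sample expression is dichotomized at the log-rank-optimal
    cutoff; HR > 1 for the high group means hazardous, HR < 1 protective.
    With no events the direction is undefined; calls with p > 0.5 are flagged
    as unstable.
    """
    ev = np.asarray(event, dtype=int)
    if ev.sum() == 0:
        return DirectionResult(str(expr_row.name), None, float("nan"), 1.0, True)
    res = best_cutoff(expr_row.to_numpy(dtype=float), time, event,
                      lower_q=lower_q, upper_q=upper_q)
    direction = "hazardous" if res.cox.hr > 1 else "protective"
    flagged = res.cox.p > 0.5 or res.cox.flagged
    return DirectionResult(str(expr_row.name), direction, res.cox.hr, res.cox.p, flagged)


# ---------------------------------------------------------------------------
# STRESS signature (end-to-end derivation)

def catalog_candidate_genes(
    regions: pd.DataFrame,
    enhancer_map: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> list[str]:
    """Genes associated with a region set via enhancer links.

    The catalog is the union of target genes of every enhancer a region
    overlaps; a region overlapping no enhancer contributes its nearest-TSS
    gene when a gene table is available.
    """
    if regions.empty:
        return []
    ann = intervals.annotate_peaks(regions, enhancer_map, genes)
    out: set[str] = set()
    for rec in ann.itertuples(index=False):
        if rec.enhancer_genes:
            out.update(rec.enhancer_genes)
        elif rec.nearest_gene:
            out.add(rec.nearest_gene)
    return sorted(out)


def derive_stress_signature(
    chip_shared: pd.DataFrame,
    atac_inducible: pd.DataFrame,
    atac_noninducible: pd.DataFrame,
    enhancer_map: pd.DataFrame,
    tumor_counts: pd.DataFrame,
    survival_table: pd.DataFrame,
    genes: pd.DataFrame | None = None,
    alpha: float = 0.05,
    use_adjusted: bool = True,
    min_count: int = 1,
    name: str = "STRESS",
) -> GeneSignature:
    """Full STRESS derivation: regions → catalog → co-expression → direction.

    ``tumor_counts`` is a genes x samples count matrix and ``survival_table``
    a DataFrame with sample/time/event columns aligned to its columns. The
    returned signature's up list holds the hazardous genes and its down list
    the protective ones; provenance records every stage's cardinality.
    """
    regions = intervals.stat_open_regions(chip_shared, atac_inducible, atac_noninducible)
    provenance: dict = {
        "n_chip_shared": int(len(chip_shared)),
        "n_stat_open_regions": int(len(regions)),
        "alpha": alpha, "use_adjusted": use_adjusted, "min_count": min_count,
    }
    if regions.empty:
        warnings.warn("no STAT-open regions; returning empty signature")
        return GeneSignature(name=name, up_genes=[], provenance=provenance)

    catalog = catalog_candidate_genes(regions, enhancer_map, genes)
    provenance["n_candidate_genes"] = len(catalog)
    present = [g for g in catalog if g in tumor_counts.index]
    if len(present) < len(catalog):
        warnings.warn(f"{len(catalog) - len(present)} catalog genes absent from cohort matrix")
    provenance["n_candidates_in_cohort"] = len(present)
    if len(present) < 2:
        warnings.warn("fewer than 2 candidate genes in cohort; empty signature")
        return GeneSignature(name=name, up_genes=[], provenance=provenance)

    log = stats.normalize_counts(tumor_counts, "size_factors", log2=True)
    pairs = stats.pearson_pairs(log, present)
    provenance["n_pairs"] = int(len(pairs))
    col = "p_adj" if use_adjusted else "p"
    provenance["n_significant_pairs"] = int((pairs[col] < alpha).sum())

    ranking = rank_by_pair_frequency(pairs, alpha=alpha, use_adjusted=use_adjusted)
    selected = select_top_half(ranking, min_count=min_count)
    provenance["n_selected"] = len(selected)

    surv = survival_table.set_index("sample").loc[list(tumor_counts.columns)]
    up, down, flagged = [], [], []
    for gene in selected:
        call = survival_direction(log.loc[gene], surv["time"], surv["event"])
        if call.direction == "hazardous":
            up.append(gene)
        elif call.direction == "protective":
            down.append(gene)
        if call.flagged:
            flagged.append(gene)
    provenance["n_up"] = len(up)
    provenance["n_down"] = len(down)
    provenance["flagged_direction_calls"] = flagged
    return GeneSignature(name=name, up_genes=sorted(up), down_genes=sorted(down),
                         provenance=provenance)
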