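"""Genomic-interval algebra, BED / enhancer-map I/O, peak ranking and annotation.

All coordinates are 0-based half-open, matching BED. Peak sets are plain
:class:`pandas.DataFrame` objects with the columns in :data:`PEAK_COLUMNS`;
the ``log2fc`` and ``p_adj`` columns carry the differential-binding (or
differential-accessibility) statistics that upstream peak callers would have
produced. Strand is ignored for overlap computations (peaks are unstranded);
distances to transcription start sites are signed by gene strand, negative
meaning upstream of the TSS.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column layout of a peak set ("BED6+2": BED6 plus log2FC and adjusted p).
PEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand", "log2fc", "p_adj"]

#: Column layout of an enhancer map (one row per enhancer-gene link).
ENHANCER_COLUMNS = ["enhancer_id", "chrom", "start", "end", "gene", "link_score"]

#: Column layout of a gene annotation table.
GENE_COLUMNS = ["gene", "chrom", "start", "end", "strand", "tss"]

_DIALECT_NCOLS = {"bed3": 3, "bed6": 6, "bed6+2": 8}


class BedParseError(ValueError):
    """Raised for malformed BED input; the message names offending lines."""


def _sort_key(df: pd.DataFrame) -> pd.DataFrame:
    """Deterministic peak ordering: (chrom, start, end, name)."""
    cols = [c for c in ("chrom", "start", "end", "name") if c in df.columns]
    return df.sort_values(cols, kind="mergesort").reset_index(drop=True)


def make_peaks(records: Iterable[tuple] | pd.DataFrame) -> pd.DataFrame:
    """Build a validated peak table from records or a DataFrame.

    Records may supply 3, 6 or 8 of the :data:`PEAK_COLUMNS` in order;
    missing columns are filled with defaults (name ``peak_<i>``, score 0,
    strand ``.``, log2fc 0, p_adj 1).
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = list(records)
        ncol = len(rows[0]) if rows else 8
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS[:ncol])
    for col, default in (
        ("name", None), ("score", 0.0), ("strand", "."),
        ("log2fc", 0.0), ("p_adj", 1.0),
    ):
        if col not in df.columns:
            if col == "name":
                df[col] = [f"peak_{i}" for i in range(len(df))]
            else:
                df[col] = default
    df = df[PEAK_COLUMNS]
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["score"] = df["score"].astype(float)
    df["log2fc"] = df["log2fc"].astype(float)
    df["p_adj"] = df["p_adj"].astype(float)
    bad = df.index[df["start"] >= df["end"]]
    if len(bad):
        raise BedParseError(f"start >= end for peaks at rows {list(bad[:5])}")
    if ((df["p_adj"] < 0) | (df["p_adj"] > 1)).any():
        raise BedParseError("p_adj outside [0, 1]")
    return _sort_key(df)


def read_bed(path, dialect: str = "bed6+2") -> pd.DataFrame:
    """Read a BED file into a peak table.

    Malformed lines (wrong column count, non-numeric coordinates or scores,
    ``start >= end``) raise :class:`BedParseError` naming the 1-based line
    number of the first few offenders.
    """
    if dialect not in _DIALECT_NCOLS:
        raise ValueError(f"unknown dialect {dialect!r}")
    ncols = _DIALECT_NCOLS[dialect]
    rows, errors = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < ncols:
                errors.append(f"line {lineno}: expected {ncols} columns, got {len(fields)}")
                continue
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                if start >= end:
                    raise ValueError("start >= end")
                rec = [chrom, start, end]
                if ncols >= 6:
                    rec += [fields[3], float(fields[4]), fields[5]]
                if ncols == 8:
                    rec += [float(fields[6]), float(fields[7])]
                rows.append(tuple(rec))
            except ValueError as exc:
                errors.append(f"line {lineno}: {exc}")
    if errors:
        raise BedParseError("; ".join(errors[:10]))
    return make_peaks(rows)


def write_bed(peaks: pd.DataFrame, path, dialect: str = "bed6+2") -> None:
    """Write a peak table as BED (tab-separated, no header)."""
    ncols = _DIALECT_NCOLS[dialect]
    out = peaks[PEAK_COLUMNS[:ncols]]
    out.to_csv(path, sep="\t", header=False, index=False)


def read_enhancer_map(path) -> pd.DataFrame:
    """Read a GeneHancer-style enhancer→gene map TSV (with header)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(ENHANCER_COLUMNS) - set(df.columns)
    if missing:
        raise BedParseError(f"enhancer map missing columns: {sorted(missing)}")
    return df[ENHANCER_COLUMNS]


def write_enhancer_map(enhancers: pd.DataFrame, path) -> None:
    enhancers[ENHANCER_COLUMNS].to_csv(path, sep="\t", index=False)


def intersect_peaks(a: pd.DataFrame, b: pd.DataFrame, min_overlap_bp: int = 1) -> pd.DataFrame:
    """All pairs of intervals from *a* and *b* overlapping by >= min_overlap_bp.

    Chromosome-sweep over both sets sorted by (start, end, name); returns one
    row per overlapping pair with the shared interval
    ``[max(starts), min(ends))``. Output ordering is deterministic: *a*
    coordinate order, then *b* coordinate order within each *a* interval.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    a = _sort_key(a)
    b = _sort_key(b)
    out_rows = []
    for chrom, a_chr in a.groupby("chrom", sort=True):
        if chrom not in set(b["chrom"]):
            continue
        b_chr = b[b["chrom"] == chrom].reset_index(drop=True)
        b_start = b_chr["start"].to_numpy()
        b_end = b_chr["end"].to_numpy()
        b_name = b_chr["name"].to_numpy()
        bi = 0
        cache: list[int] = []
        for a_start, a_end, a_name in zip(
            a_chr["start"].to_numpy(), a_chr["end"].to_numpy(), a_chr["name"].to_numpy()
        ):
            while bi < len(b_chr) and b_start[bi] < a_end:
                cache.append(bi)
                bi += 1
            kept = []
            for j in cache:
                if b_end[j] <= a_start:
                    # b ends before every remaining a starts: drop for good
                    continue
                kept.append(j)
                lo = max(a_start, b_start[j])
                hi = min(a_end, b_end[j])
                if hi - lo >= min_overlap_bp:
                    out_rows.append((a_name, b_name[j], chrom, lo, hi))
            cache = kept
    return pd.DataFrame(out_rows, columns=["name_a", "name_b", "chrom", "start", "end"])


def select_top_peaks(peaks: pd.DataFrame, n: int, key: str = "score") -> pd.DataFrame:
    """Top *n* peaks by descending score or ascending adjusted p.

    Ties are broken by (chrom, start, end, name) so the selection is
    deterministic; if fewer than *n* peaks exist all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if key not in ("score", "p_adj"):
        raise ValueError("key must be 'score' or 'p_adj'")
    if peaks.empty:
        return peaks.copy()
    ascending = key == "p_adj"
    ordered = peaks.sort_values(
        [key, "chrom", "start", "end", "name"],
        ascending=[ascending, True, True, True, True],
        kind="mergesort",
    )
    return _sort_key(ordered.head(n))


def merge_intervals(peaks: pd.DataFrame) -> pd.DataFrame:
    """Union of overlapping/adjacent intervals per chromosome.

    Provenance: the ``name`` of a merged interval concatenates contributing
    names with ``;``; score is the max and p_adj the min of the contributors.
    """
    if peaks.empty:
        return make_peaks(peaks)
    peaks = _sort_key(peaks)
    rows = []
    for chrom, grp in peaks.groupby("chrom", sort=True):
        cur = None
        for rec in grp.itertuples(index=False):
            if cur is None or rec.start > cur["end"]:
                if cur is not None:
                    rows.append(cur)
                cur = {
                    "chrom": chrom, "start": rec.start, "end": rec.end,
                    "names": [rec.name], "score": rec.score,
                    "log2fc": rec.log2fc, "p_adj": rec.p_adj,
                }
            else:
                cur["end"] = max(cur["end"], rec.end)
                cur["names"].append(rec.name)
                cur["score"] = max(cur["score"], rec.score)
                cur["p_adj"] = min(cur["p_adj"], rec.p_adj)
        if cur is not None:
            rows.append(cur)
    return make_peaks(
        [
            (r["chrom"], r["start"], r["end"], ";".join(r["names"]),
             r["score"], ".", r["log2fc"], r["p_adj"])
            for r in rows
        ]
    )


def nearest_tss(peaks: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Nearest TSS (by peak-midpoint distance) per peak, with signed distance.

    Distance is (peak midpoint - TSS) for + strand genes and (TSS - midpoint)
    for - strand genes, so negative always means upstream of the gene. Ties in
    absolute distance are broken by gene name for determinism.
    """
    out = []
    gene_by_chrom = {c: g.sort_values(["tss", "gene"]).reset_index(drop=True)
                     for c, g in genes.groupby("chrom")}
    for rec in _sort_key(peaks).itertuples(index=False):
        g = gene_by_chrom.get(rec.chrom)
        if g is None or g.empty:
            out.append((rec.name, None, np.nan))
            continue
        mid = (rec.start + rec.end) // 2
        dist = np.abs(g["tss"].to_numpy() - mid)
        best = np.flatnonzero(dist == dist.min())
        idx = best[np.argsort(g["gene"].to_numpy()[best])[0]] if len(best) > 1 else best[0]
        row = g.iloc[idx]
        signed = mid - row["tss"] if row["strand"] != "-" else row["tss"] - mid
        out.append((rec.name, row["gene"], int(signed)))
    return pd.DataFrame(out, columns=["name", "nearest_gene", "tss_distance"])


def annotate_peaks(
    peaks: pd.DataFrame,
    enhancer_map: pd.DataFrame,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate each peak with overlapping enhancer records and the nearest TSS.

    For each peak, every enhancer it overlaps by >= 1 bp contributes its id and
    target genes; when a gene table is supplied the nearest-TSS gene is added.
    The ``genes`` column is the union of enhancer target genes and the
    nearest-TSS gene (matching the dual HOMER/GeneHancer annotation style).
    Peaks on chromosomes absent from both indexes are annotated with empty
    hits and a warning is logged.
    """
    peaks = _sort_key(peaks)
    enh_intervals = enhancer_map.drop_duplicates("enhancer_id")[
        ["enhancer_id", "chrom", "start", "end"]
    ].rename(columns={"enhancer_id": "name"})
    enh_intervals = make_peaks(enh_intervals)
    hits = intersect_peaks(peaks, enh_intervals)
    targets = enhancer_map.groupby("enhancer_id")["gene"].apply(list).to_dict()

    known_chroms = set(enhancer_map["chrom"])
    if genes is not None:
        known_chroms |= set(genes["chrom"])
        tss = nearest_tss(peaks, genes).set_index("name")
    else:
        tss = None

    rows = []
    hit_by_peak = hits.groupby("name_a")["name_b"].apply(list).to_dict() if not hits.empty else {}
    for rec in peaks.itertuples(index=False):
        if rec.chrom not in known_chroms:
            logger.warning("peak %s on chromosome %s absent from annotation index",
                           rec.name, rec.chrom)
        enh_ids = sorted(hit_by_peak.get(rec.name, []))
        enh_genes: list[str] = []
        for eid in enh_ids:
            enh_genes.extend(targets.get(eid, []))
        enh_genes = sorted(set(enh_genes))
        if tss is not None and rec.name in tss.index:
            ng = tss.loc[rec.name, "nearest_gene"]
            dist = tss.loc[rec.name, "tss_distance"]
        else:
            ng, dist = None, np.nan
        union = sorted(set(enh_genes) | ({ng} if ng else set()))
        rows.append((rec.name, enh_ids, enh_genes, ng, dist, union))
    return pd.DataFrame(
        rows,
        columns=["name", "enhancer_ids", "enhancer_genes", "nearest_gene",
                 "tss_distance", "genes"],
    )


def shared_differential_peaks(
    cond1: pd.DataFrame,
    cond2: pd.DataFrame,
    alpha: float = 0.05,
    top_n: int | None = 200,
    min_overlap_bp: int = 1,
) -> pd.DataFrame:
    """Merged regions differential in BOTH conditions.

    Each set is filtered to ``p_adj <= alpha``, reduced to its ``top_n`` peaks
    by score (both gates mirror the two peak pipelines the analysis exposes:
    a ranked top-N list and an adjusted-p threshold; pass ``top_n=None`` to
    disable ranking), then intersected. Overlapping shared intervals are
    merged; merged names carry the contributing peak names from both
    conditions as provenance.
    """
    def gate(df: pd.DataFrame) -> pd.DataFrame:
        kept = df[df["p_adj"] <= alpha]
        if top_n is not None and not kept.empty:
            kept = select_top_peaks(kept, top_n, key="score")
        return kept

    g1, g2 = gate(cond1), gate(cond2)
    if g1.empty or g2.empty:
        return make_peaks(pd.DataFrame(columns=PEAK_COLUMNS))
    pairs = intersect_peaks(g1, g2, min_overlap_bp=min_overlap_bp)
    if pairs.empty:
        return make_peaks(pd.DataFrame(columns=PEAK_COLUMNS))
    shared = make_peaks(
        [
            (r.chrom, r.start, r.end, f"{r.name_a}|{r.name_b}", 0.0, ".", 0.0, 0.0)
            for r in pairs.itertuples(index=False)
        ]
    )
    return merge_intervals(shared)


def stat_open_regions(
    chip_shared: pd.DataFrame,
    atac_inducible: pd.DataFrame,
    atac_noninducible: pd.DataFrame,
) -> pd.DataFrame:
    """STAT-open regions: STAT3-bound, accessible only in inducible lines.

    Keeps the shared ChIP regions that overlap at least one inducible-line
    accessibility peak and no non-inducible-line accessibility peak.
    """
    chip_shared = _sort_key(chip_shared)
    if chip_shared.empty:
        return chip_shared.copy()
    ind_hits = intersect_peaks(chip_shared, atac_inducible) if not atac_inducible.empty \
        else pd.DataFrame(columns=["name_a"])
    non_hits = intersect_peaks(chip_shared, atac_noninducible) if not atac_noninducible.empty \
        else pd.DataFrame(columns=["name_a"])
    accessible = set(ind_hits["name_a"])
    closed_ok = set(chip_shared["name"]) - set(non_hits["name_a"])
    keep = accessible & closed_ok
    return chip_shared[chip_shared["name"].isin(keep)].reset_index(drop=True)
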