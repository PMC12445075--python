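"""End-to-end orchestration on synthetic data.

:func:`full_synthetic` runs the complete discovery pipeline against one
simulated dataset — differential ChIP peaks for both stress conditions,
shared-region intersection, STAT-open filtering against the accessibility
sets, candidate cataloging, co-expression-frequency selection, survival
direction calls, signature scoring, and best-cutoff stratification — and
reports how much of the planted truth was recovered. It is the library
surface behind the ``stressig full-synthetic`` command.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import intervals, signatures, scoring, stats, survival, synthdata


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def region_recovery(regions: pd.DataFrame, ref: synthdata.Reference) -> dict:
    """Compare derived STAT-open regions with the planted shared enhancers."""
    planted = ref.truth.shared_enhancer_ids
    enh = ref.enhancers.drop_duplicates("enhancer_id")
    enh_peaks = intervals.make_peaks(
        enh.rename(columns={"enhancer_id": "name"})[["chrom", "start", "end", "name"]]
    )
    if regions.empty:
        recovered: set[str] = set()
        spurious = 0
    else:
        hits = intervals.intersect_peaks(regions, enh_peaks)
        recovered = set(hits["name_b"]) & set(planted)
        spurious = int((~regions["name"].isin(set(hits["name_a"]))).sum())
        # regions overlapping only non-planted enhancers are spurious too
        off_target = set(hits.loc[~hits["name_b"].isin(planted), "name_a"])
        on_target = set(hits.loc[hits["name_b"].isin(planted), "name_a"])
        spurious += len(off_target - on_target)
    return {
        "n_regions_planted": len(planted),
        "n_regions_derived": int(len(regions)),
        "n_regions_recovered": len(recovered),
        "n_regions_spurious": spurious,
        "regions_exact": len(recovered) == len(planted) and spurious == 0
        and len(regions) == len(planted),
    }


def gene_recovery(sig: signatures.GeneSignature, truth: synthdata.GroundTruth) -> dict:
    """Compare the derived signature with the planted 18-gene module."""
    up, down = set(sig.up_genes), set(sig.down_genes)
    haz, prot = set(truth.hazardous_genes), set(truth.protective_genes)
    correct = len(up & haz) + len(down & prot)
    selected = up | down
    return {
        "n_module_genes": len(haz | prot),
        "n_selected": len(selected),
        "n_recovered": len(selected & (haz | prot)),
        "n_recovered_correct_direction": correct,
        "n_intruders": len(selected - (haz | prot)),
        "n_up": len(up),
        "n_down": len(down),
    }


def full_synthetic(
    config: synthdata.SimConfig,
    outdir: str | Path | None = None,
    alpha: float = 0.05,
    top_n: int | None = 200,
) -> dict:
    """Simulate, derive the STRESS signature, stratify survival, report truth recovery.

    Returns a JSON-serializable report; when *outdir* is given, every primary
    artifact (peak BEDs, enhancer map, expression and survival TSVs, the
    signature GMT/JSON, score table, stratification result, truth, manifest)
    is written there deterministically.
    """
    ref = synthdata.simulate_reference(config)
    chip = {c: synthdata.simulate_chip(config, ref, c) for c in synthdata.CONDITIONS}
    atac_ind = synthdata.simulate_atac(config, ref, "inducible")
    atac_non = synthdata.simulate_atac(config, ref, "non-inducible")
    shared = intervals.shared_differential_peaks(
        chip["OSM"], chip["hypoxia"], alpha=alpha, top_n=top_n
    )
    counts, surv = synthdata.simulate_bulk_cohort(config, ref)

    sig = signatures.derive_stress_signature(
        shared, atac_ind, atac_non, ref.enhancers, counts, surv, genes=ref.genes,
        alpha=alpha,
    )
    regions = intervals.stat_open_regions(shared, atac_ind, atac_non)

    report: dict = {"config": dataclasses.asdict(config)}
    report.update(region_recovery(regions, ref))
    report.update(gene_recovery(sig, ref.truth))
    report["provenance"] = sig.provenance

    log = stats.normalize_counts(counts, "size_factors", log2=True)
    if sig.genes:
        score = scoring.mean_signature_score(log, sig)
        cut = survival.best_cutoff(score.to_numpy(), surv["time"], surv["event"])
        report["signature_score_cutoff"] = cut.cutoff
        report["signature_hr"] = cut.cox.hr
        report["signature_hr_ci95"] = list(cut.cox.ci95)
        report["logrank_p"] = cut.logrank_p
        report["n_high"] = cut.n_high
        report["n_low"] = cut.n_low
    else:
        score = None

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cond, peaks in chip.items():
            intervals.write_bed(peaks, outdir / f"chip_{cond}.bed")
        intervals.write_bed(atac_ind, outdir / "atac_inducible.bed")
        intervals.write_bed(atac_non, outdir / "atac_noninducible.bed")
        intervals.write_bed(shared, outdir / "chip_shared.bed")
        intervals.write_bed(regions, outdir / "stat_open_regions.bed")
        intervals.write_enhancer_map(ref.enhancers, outdir / "enhancer_map.tsv")
        synthdata.write_expression(counts, outdir / "tumor_expression.tsv")
        survival_cols = surv[["sample", "time", "event"]]
        survival_cols.to_csv(outdir / "survival.tsv", sep="\t", index=False)
        synthdata.write_truth(ref.truth, outdir / "truth.json")
        sig.to_gmt(outdir / "stress_signature.gmt")
        sig.to_json(outdir / "stress_signature.json")
        if score is not None:
            score.rename("score").to_frame().to_csv(outdir / "signature_scores.tsv", sep="\t")
        with open(outdir / "truth_recovery.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=str)
        manifest = {
            "parameters": {"alpha": alpha, "top_n": top_n,
                           "config": dataclasses.asdict(config)},
            "outputs": {
                p.name: _sha256(p) for p in sorted(outdir.iterdir())
                if p.name not in ("manifest.json",)
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return report


def recovery_over_seeds(
    base_config: synthdata.SimConfig, seeds: list[int],
    min_correct: int = 16,
) -> dict:
    """Run full_synthetic over several seeds; summarize planted-truth recovery."""
    results = []
    for s in seeds:
        cfg = dataclasses.replace(base_config, seed=int(s))
        rep = full_synthetic(cfg)
        results.append(
            {
                "seed": int(s),
                "regions_exact": rep["regions_exact"],
                "n_recovered_correct_direction": rep["n_recovered_correct_direction"],
                "signature_hr": rep.get("signature_hr"),
            }
        )
    n_pass = sum(
        r["regions_exact"] and r["n_recovered_correct_direction"] >= min_correct
        for r in results
    )
    return {"per_seed": results, "n_seeds": len(seeds), "n_pass": n_pass}
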