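"""Synthetic multi-omic data with planted ground truth.

Every input the pipeline consumes — differential ChIP peak sets for two
stress conditions (cytokine and hypoxia), accessibility peak sets for
inducible and non-inducible cell lines, a cell-line expression panel, a bulk
tumor cohort with survival, and a single-cell count matrix — is generated on
one synthetic chromosome with a known answer key, so every downstream stage
can be tested for exact or statistical recovery without external downloads.

Defaults encode the structure the analysis assumes: 14 shared stress-responsive
enhancers whose GeneHancer-style links fan out to 54 candidate genes; an
18-gene co-expressed module (10 hazard-associated, 8 protective) hidden among
the candidates; a 93-gene inducibility program separating 5 inducible from 5
non-inducible lines at 2 log2 units; a 177-tumor cohort whose hazard ratio
between activation groups is 6 with 40% censoring; and a single-cell pool in
which a high-ITGB3-analog program is 62-fold enriched in treated patients.

Counts are negative binomial with log-normal gene means; coordinates are
0-based half-open on a single chromosome; one global seed fans out to
per-stage child seeds by fixed offsets so each stage is independently
reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
from scipy import sparse, io as spio, optimize

from .intervals import make_peaks

CHROM = "chr1"
GENE_SPACING = 40_000
GENE_BODY = 2_000
ENHANCER_WIDTH = 1_200
_MIN_ENH_OFFSET, _MAX_ENH_OFFSET = 5_000, 18_000

# fixed child-seed offsets, one per generator stage
_SEED_REFERENCE = 11
_SEED_CHIP = {"OSM": 21, "hypoxia": 22}
_SEED_ATAC = {"inducible": 31, "non-inducible": 32}
_SEED_PANEL = 41
_SEED_COHORT = 51
_SEED_SCRNA = 61

CONDITIONS = ("OSM", "hypoxia")


@dataclass
class SimConfig:
    """Generator parameters; defaults are the study conditions."""

    seed: int = 0
    n_genes: int = 2000
    n_enhancers: int = 300
    n_shared_responsive: int = 14
    n_condition_private: int = 50
    n_lines_inducible: int = 5
    n_lines_noninducible: int = 5
    n_tumors: int = 177
    n_cells: int = 5000
    signature_size: int = 54          # candidate genes reachable from shared enhancers
    module_size: int = 18             # planted co-expressed module among candidates
    n_hazardous: int = 10             # module genes that worsen survival when active
    n_inducible_signature: int = 93   # genes separating inducible from non-inducible lines
    effect_log2fc: float = 2.0
    true_hr: float = 6.0
    censor_frac: float = 0.4
    nb_dispersion: float = 0.02
    treated_enrichment: float = 62.0
    program_frac: float = 0.12        # overall fraction of high-program malignant cells
    n_background_peaks: int = 500
    n_sd_inflated: int = 0            # panel DEGs given inflated within-group SD
    baseline_median_survival: float = 24.0  # months, activation-low group

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes, n_enhancers=self.n_enhancers,
            n_shared_responsive=self.n_shared_responsive,
            n_lines_inducible=self.n_lines_inducible,
            n_lines_noninducible=self.n_lines_noninducible,
            n_tumors=self.n_tumors, n_cells=self.n_cells,
            signature_size=self.signature_size, module_size=self.module_size,
            n_hazardous=self.n_hazardous,
            n_inducible_signature=self.n_inducible_signature,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.n_shared_responsive > self.n_enhancers:
            raise ValueError("n_shared_responsive cannot exceed n_enhancers")
        if self.n_enhancers > self.n_genes:
            raise ValueError("n_enhancers cannot exceed n_genes (one anchor gene each)")
        if self.n_shared_responsive + 2 * self.n_condition_private > self.n_enhancers:
            raise ValueError("not enough enhancers for shared + private sets")
        if self.signature_size > 5 * self.n_shared_responsive:
            raise ValueError("signature_size exceeds 5 genes per shared enhancer")
        if self.module_size > self.signature_size or self.n_hazardous > self.module_size:
            raise ValueError("module sizes inconsistent")
        if self.signature_size + self.n_inducible_signature > self.n_genes:
            raise ValueError("gene universe too small for planted gene sets")
        if not 0 <= self.censor_frac < 1:
            raise ValueError("censor_frac must be in [0, 1)")
        if self.true_hr <= 0:
            raise ValueError("true_hr must be positive")
        if self.treated_enrichment <= 0:
            raise ValueError("treated_enrichment must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 < self.program_frac < 0.5:
            raise ValueError("program_frac must be in (0, 0.5)")


@dataclass
class GroundTruth:
    """Answer key for the planted structures."""

    shared_enhancer_ids: list[str]
    condition_private_ids: dict[str, list[str]]
    accessible_in_inducible_ids: list[str]
    candidate_genes: list[str]
    hazardous_genes: list[str]
    protective_genes: list[str]
    inducible_up_genes: list[str]
    itgb3_gene: str
    line_inducibility_labels: dict[str, str] = field(default_factory=dict)
    cell_program_labels: list[bool] = field(default_factory=list)

    @property
    def module_genes(self) -> list[str]:
        return self.hazardous_genes + self.protective_genes

    def validate(self) -> None:
        shared = set(self.shared_enhancer_ids)
        for cond, ids in self.condition_private_ids.items():
            if shared & set(ids):
                raise ValueError(f"shared and {cond}-private enhancers overlap")
        if set(self.hazardous_genes) & set(self.protective_genes):
            raise ValueError("hazardous and protective gene lists overlap")
        if not set(self.module_genes) <= set(self.candidate_genes):
            raise ValueError("module genes must be a subset of candidate genes")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class Reference:
    """Synthetic genome annotation: genes, enhancer map, and the answer key."""

    genes: pd.DataFrame       # gene, chrom, start, end, strand, tss
    enhancers: pd.DataFrame   # enhancer_id, chrom, start, end, gene, link_score
    truth: GroundTruth


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization (var = m + d m^2)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_reference(config: SimConfig) -> Reference:
    """Build the synthetic chromosome, gene TSSs and enhancer→gene map.

    Each enhancer is anchored to a distinct gene and placed 5-18 kb from its
    TSS (enhancers are therefore mutually disjoint given the 40 kb gene
    spacing). The shared-responsive enhancers partition the candidate gene
    catalog among themselves (3-5 targets each), guaranteeing that every
    candidate gene is reachable from at least one shared enhancer; all other
    enhancers link their anchor gene plus up to four neighbors.
    """
    rng = np.random.default_rng([config.seed, _SEED_REFERENCE])
    n = config.n_genes
    names = np.array([f"G{i:05d}" for i in range(n)])
    tss = 100_000 + np.arange(n, dtype=np.int64) * GENE_SPACING
    strand = rng.choice(["+", "-"], size=n)
    start = np.where(strand == "+", tss, tss - GENE_BODY)
    genes = pd.DataFrame(
        {"gene": names, "chrom": CHROM, "start": start, "end": start + GENE_BODY,
         "strand": strand, "tss": tss}
    )

    perm = rng.permutation(n)
    candidates = list(names[perm[: config.signature_size]])
    hazardous = candidates[: config.n_hazardous]
    protective = candidates[config.n_hazardous: config.module_size]
    inducible_up = list(
        names[perm[config.signature_size: config.signature_size + config.n_inducible_signature]]
    )

    # shared enhancers partition the candidate catalog round-robin
    n_shared = config.n_shared_responsive
    groups = [candidates[j::n_shared] for j in range(n_shared)]
    anchor_used = set()
    enh_rows = []

    def place_enhancer(anchor_gene: str, targets: list[str]) -> str:
        gi = int(np.flatnonzero(names == anchor_gene)[0])
        offset = int(rng.integers(_MIN_ENH_OFFSET, _MAX_ENH_OFFSET))
        sign = int(rng.choice([-1, 1]))
        mid = int(tss[gi] + sign * offset)
        e_start, e_end = mid - ENHANCER_WIDTH // 2, mid + ENHANCER_WIDTH // 2
        eid = f"GH01J{e_start:08d}"
        for g in targets:
            enh_rows.append((eid, CHROM, e_start, e_end, g,
                             float(np.round(rng.uniform(5, 30), 2))))
        return eid

    shared_ids = []
    for grp in groups:
        shared_ids.append(place_enhancer(grp[0], grp))
        anchor_used.add(grp[0])

    other_anchors = [g for g in names if g not in anchor_used]
    rng.shuffle(other_anchors)
    n_other = config.n_enhancers - n_shared
    other_ids = []
    for k in range(n_other):
        anchor = other_anchors[k]
        extra = rng.integers(0, 5)
        neighbors = list(rng.choice(names, size=extra, replace=False)) if extra else []
        other_ids.append(place_enhancer(anchor, [anchor] + neighbors))

    private: dict[str, list[str]] = {}
    pos = 0
    for cond in CONDITIONS:
        private[cond] = other_ids[pos: pos + config.n_condition_private]
        pos += config.n_condition_private

    truth = GroundTruth(
        shared_enhancer_ids=shared_ids,
        condition_private_ids=private,
        accessible_in_inducible_ids=list(shared_ids),
        candidate_genes=candidates,
        hazardous_genes=hazardous,
        protective_genes=protective,
        inducible_up_genes=inducible_up,
        itgb3_gene=hazardous[0],
    )
    truth.validate()
    enhancers = pd.DataFrame(
        enh_rows, columns=["enhancer_id", "chrom", "start", "end", "gene", "link_score"]
    )
    return Reference(genes=genes, enhancers=enhancers, truth=truth)


def _enhancer_intervals(ref: Reference, ids: list[str]) -> pd.DataFrame:
    enh = ref.enhancers.drop_duplicates("enhancer_id").set_index("enhancer_id")
    return enh.loc[ids]


def simulate_chip(config: SimConfig, ref: Reference, condition: str) -> pd.DataFrame:
    """Differential STAT3-binding peaks for one stress condition.

    Peaks at shared-responsive and condition-private enhancers carry high
    scores and adjusted p sampled log-uniformly below 0.05 (the 0.05 gate
    recovers every planted peak: power 1 by construction); background peaks
    sit at random loci with adjusted p uniform on (0.05, 1], so the gate also
    rejects every background peak.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    rng = np.random.default_rng([config.seed, _SEED_CHIP[condition]])
    planted_ids = ref.truth.shared_enhancer_ids + ref.truth.condition_private_ids[condition]
    enh = _enhancer_intervals(ref, planted_ids)
    rows = []
    for eid, rec in enh.iterrows():
        p_adj = 10.0 ** rng.uniform(-30, -1.5)
        score = float(rng.uniform(50, 150))
        rows.append((CHROM, rec["start"] + 100, rec["end"] - 100,
                     f"{condition}_{eid}", score, ".",
                     float(rng.uniform(2, 5)), p_adj))
    chrom_len = 200_000 + config.n_genes * GENE_SPACING
    for i in range(config.n_background_peaks):
        s = int(rng.integers(0, chrom_len - 500))
        rows.append((CHROM, s, s + 400, f"{condition}_bg_{i:04d}",
                     float(rng.uniform(1, 40)), ".",
                     float(rng.normal(0, 0.5)), float(rng.uniform(0.051, 1.0))))
    return make_peaks(rows)


def simulate_atac(config: SimConfig, ref: Reference, line_label: str) -> pd.DataFrame:
    """Accessibility peaks for a pooled inducible or non-inducible line set.

    Both labels share a housekeeping-promoter background (first 100 gene
    promoters); inducible lines additionally carry accessibility peaks
    covering every shared-responsive enhancer, which non-inducible lines lack
    entirely (closed chromatin at the receptive enhancers).
    """
    if line_label not in ("inducible", "non-inducible"):
        raise ValueError(f"unknown line label {line_label!r}")
    rng = np.random.default_rng([config.seed, _SEED_ATAC[line_label]])
    rows = []
    n_hk = min(100, config.n_genes)
    for _, rec in ref.genes.head(n_hk).iterrows():
        rows.append((CHROM, rec["tss"] - 500, rec["tss"] + 500,
                     f"{line_label}_hk_{rec['gene']}", float(rng.uniform(20, 80)),
                     ".", 0.0, float(rng.uniform(0.1, 1.0))))
    if line_label == "inducible":
        enh = _enhancer_intervals(ref, ref.truth.accessible_in_inducible_ids)
        for eid, rec in enh.iterrows():
            rows.append((CHROM, rec["start"], rec["end"], f"{line_label}_{eid}",
                         float(rng.uniform(60, 140)), ".",
                         float(rng.uniform(2, 5)), 10.0 ** rng.uniform(-20, -2)))
    return make_peaks(rows)


def _gene_means(rng: np.random.Generator, n: int, floor_idx: np.ndarray | None = None,
                floor: float = 150.0) -> np.ndarray:
    means = np.exp(rng.normal(np.log(200.0), 0.8, size=n))
    if floor_idx is not None:
        means[floor_idx] = np.maximum(means[floor_idx], floor)
    return means


def simulate_cellline_panel(config: SimConfig, ref: Reference) -> tuple[pd.DataFrame, pd.Series]:
    """Negative-binomial expression panel of inducible vs non-inducible lines.

    The planted inducibility-program genes are shifted up by
    ``effect_log2fc`` in inducible lines; their base means are floored so
    the differential-expression gate, not count sparsity, is what downstream
    recovery exercises. ``n_sd_inflated`` of the planted genes additionally
    receive alternating large multipliers within the inducible group, so they
    stay differentially expressed while their within-group SD exceeds the
    robustness gate — the gene class the SD filter exists to remove.
    Per-sample library-size factors vary to exercise normalization.
    """
    rng = np.random.default_rng([config.seed, _SEED_PANEL])
    gene_names = ref.genes["gene"].to_numpy()
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    planted = np.array([gene_idx[g] for g in ref.truth.inducible_up_genes])
    means = _gene_means(rng, config.n_genes, floor_idx=planted)

    samples = [f"IND{i + 1:02d}" for i in range(config.n_lines_inducible)] + \
              [f"NON{i + 1:02d}" for i in range(config.n_lines_noninducible)]
    labels = pd.Series(
        ["inducible"] * config.n_lines_inducible +
        ["non-inducible"] * config.n_lines_noninducible,
        index=samples, name="inducibility",
    )
    mean_mat = np.tile(means[:, None], (1, len(samples)))
    ind_cols = np.arange(config.n_lines_inducible)
    mean_mat[np.ix_(planted, ind_cols)] *= 2.0 ** config.effect_log2fc
    if config.n_sd_inflated:
        # alternating large multipliers within the inducible group: the mean
        # shift keeps these genes DE-significant while their within-group SD
        # on the log scale exceeds the robustness gate
        wobble_genes = planted[: config.n_sd_inflated]
        alt = np.where(np.arange(len(ind_cols)) % 2 == 0, 2.0**10, 2.0**5)
        mean_mat[np.ix_(wobble_genes, ind_cols)] *= alt[None, :]
    lib = rng.uniform(0.7, 1.4, size=len(samples))
    counts = _nb_draw(rng, mean_mat * lib, config.nb_dispersion)
    ref.truth.line_inducibility_labels = labels.to_dict()
    return pd.DataFrame(counts, index=gene_names, columns=samples), labels


def _censor_tau(rates: np.ndarray, censor_frac: float) -> float:
    """Upper bound of the uniform censoring window giving the target fraction."""
    def frac(tau: float) -> float:
        lt = rates * tau
        return float(np.mean((1.0 - np.exp(-lt)) / lt)) - censor_frac
    # frac is decreasing in tau from 1 to 0
    lo, hi = 1e-6, 1e3 / rates.min()
    return optimize.brentq(frac, lo, hi)


def simulate_bulk_cohort(config: SimConfig, ref: Reference) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bulk tumor cohort: expression with a latent activation factor + survival.

    Each tumor carries a latent activation state a in {0, 1} (p = 0.5).
    Hazardous module genes are shifted up and protective genes down by
    ``effect_log2fc`` when a = 1, which induces the planted co-expression
    block the pairwise-correlation stage must find. Event times are
    exponential with rate lambda0 * true_hr^a (lambda0 set by the baseline
    median survival); censoring is independent uniform on (0, tau] with tau
    solved so the expected censored fraction equals ``censor_frac``.
    Returns (counts genes x samples, survival table with the latent
    ``activation`` column retained as ground truth).
    """
    rng = np.random.default_rng([config.seed, _SEED_COHORT])
    gene_names = ref.genes["gene"].to_numpy()
    gene_idx = {g: i for i, g in enumerate(gene_names)}
    cand = np.array([gene_idx[g] for g in ref.truth.candidate_genes])
    haz = np.array([gene_idx[g] for g in ref.truth.hazardous_genes])
    prot = np.array([gene_idx[g] for g in ref.truth.protective_genes])
    means = _gene_means(rng, config.n_genes, floor_idx=cand)

    n = config.n_tumors
    samples = [f"T{i + 1:03d}" for i in range(n)]
    activation = rng.integers(0, 2, size=n)
    mean_mat = np.tile(means[:, None], (1, n))
    act_cols = np.flatnonzero(activation == 1)
    mean_mat[np.ix_(haz, act_cols)] *= 2.0 ** config.effect_log2fc
    mean_mat[np.ix_(prot, act_cols)] /= 2.0 ** config.effect_log2fc
    lib = rng.uniform(0.7, 1.4, size=n)
    counts = _nb_draw(rng, mean_mat * lib, config.nb_dispersion)

    lam0 = np.log(2.0) / config.baseline_median_survival
    rates = lam0 * config.true_hr ** activation
    t_event = rng.exponential(1.0 / rates)
    if config.censor_frac == 0:
        time, event = t_event, np.ones(n, dtype=int)
    else:
        tau = _censor_tau(rates, config.censor_frac)
        c = rng.uniform(0, tau, size=n)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)
    surv = pd.DataFrame(
        {"sample": samples, "time": np.maximum(time, 1e-6), "event": event,
         "activation": activation}
    )
    return pd.DataFrame(counts, index=gene_names, columns=samples), surv


_N_MT, _N_RIBO = 13, 20


def simulate_scrna(config: SimConfig, ref: Reference) -> ad.AnnData:
    """Single-cell NB counts with a planted high-program cell state.

    Cells belong to 12 patients (6 naive, 6 chemotherapy-treated). Malignant
    epithelial cells enter a high-program state — strongly elevated
    ITGB3-analog plus elevated hazardous-module program genes — with
    per-treatment probabilities whose ratio is ``treated_enrichment`` and
    whose pooled mean is ``program_frac`` (slightly above the default
    stratification decile, so the top decile samples from within the program
    state rather than straddling its boundary). Dedicated MT- and ribosomal-tagged
    genes give per-cell fractions well below the 15% QC gate except for a
    forced 2% of cells whose MT load is inflated above it. Malignant (non
    normal-adjacent) epithelial cells additionally carry a contiguous
    amplified gene block as CNV signal; immune cells serve as the CNV
    reference. Returns an AnnData with counts in X, cell metadata in ``obs``
    (patient, treatment, cell_type, normal_adjacent, program, forced_high_mt)
    and gene metadata in ``var`` (is_mt, is_ribo, position).
    """
    rng = np.random.default_rng([config.seed, _SEED_SCRNA])
    n_cells = config.n_cells
    base_genes = list(ref.genes["gene"])
    mt_genes = [f"MT-SYN{i + 1}" for i in range(_N_MT)]
    ribo_genes = [f"RPSYN{i + 1}" for i in range(_N_RIBO)]
    genes = base_genes + mt_genes + ribo_genes
    n_genes = len(genes)
    gene_idx = {g: i for i, g in enumerate(genes)}

    nu = np.exp(rng.normal(np.log(0.5), 1.0, size=n_genes))
    total_base = nu[: len(base_genes)].sum()
    nu[len(base_genes): len(base_genes) + _N_MT] = 0.065 * total_base / _N_MT
    nu[len(base_genes) + _N_MT:] = 0.08 * total_base / _N_RIBO

    itgb3 = gene_idx[ref.truth.itgb3_gene]
    program_genes = np.array([gene_idx[g] for g in ref.truth.hazardous_genes])
    nu[itgb3] = 0.1

    treatment = np.where(np.arange(n_cells) % 2 == 0, "naive", "treated")
    patient_slot = rng.integers(0, 6, size=n_cells)
    patient = np.where(treatment == "naive",
                       np.char.add("P0", (patient_slot + 1).astype(str)),
                       np.char.add("P", (patient_slot + 7).astype(str)))
    cell_type = np.where(rng.random(n_cells) < 0.85, "epithelial", "immune")
    normal_adj = (cell_type == "epithelial") & (rng.random(n_cells) < 0.05)
    malignant = (cell_type == "epithelial") & ~normal_adj

    e = config.treated_enrichment
    p_naive = 2.0 * config.program_frac / (1.0 + e)
    p_prog = np.where(treatment == "treated", e * p_naive, p_naive)
    program = malignant & (rng.random(n_cells) < p_prog)

    forced_mt = rng.random(n_cells) < 0.02

    mean_mat = np.tile(nu[None, :], (n_cells, 1))
    mean_mat[program, itgb3] *= 2.0 ** 7
    mean_mat[np.ix_(program, program_genes)] *= 2.0 ** 1.5
    # CNV: contiguous amplified block in malignant cells
    lo = min(600, max(0, len(base_genes) - 500))
    amp_block = np.arange(lo, min(lo + 500, len(base_genes)))
    mean_mat[np.ix_(malignant, amp_block)] *= 2.0 ** 0.5
    mt_cols = np.arange(len(base_genes), len(base_genes) + _N_MT)
    mean_mat[np.ix_(forced_mt, mt_cols)] *= 6.0

    lib = np.exp(rng.normal(0.0, 0.25, size=n_cells))
    counts = _nb_draw(rng, mean_mat * lib[:, None], config.nb_dispersion)

    obs = pd.DataFrame(
        {
            "patient": patient, "treatment": treatment, "cell_type": cell_type,
            "normal_adjacent": normal_adj, "program": program,
            "forced_high_mt": forced_mt,
        },
        index=[f"CELL{i:06d}" for i in range(n_cells)],
    )
    var = pd.DataFrame(
        {
            "is_mt": [g in set(mt_genes) for g in genes],
            "is_ribo": [g in set(ribo_genes) for g in genes],
            "position": np.arange(n_genes),
        },
        index=genes,
    )
    ref.truth.cell_program_labels = [bool(b) for b in program]
    adata = ad.AnnData(X=counts.astype(np.int64), obs=obs, var=var)
    adata.uns["amplified_block"] = [int(amp_block[0]), int(amp_block[-1]) + 1]
    return adata


# ---------------------------------------------------------------------------
# I/O of generated artifacts (all plain-text formats)

def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")


def write_truth(truth: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())


def write_mtx(adata: ad.AnnData, outdir) -> None:
    """Write counts as an MTX triplet (genes x cells) plus a metadata TSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.csr_matrix(np.asarray(adata.X).T)  # genes x cells
    spio.mmwrite(str(outdir / "matrix.mtx"), mat)
    adata.var.reset_index(names="gene").to_csv(outdir / "genes.tsv", sep="\t", index=False)
    pd.Series(adata.obs_names, name="barcode").to_csv(
        outdir / "barcodes.tsv", sep="\t", index=False)
    adata.obs.reset_index(names="cell").to_csv(outdir / "metadata.tsv", sep="\t", index=False)


def read_mtx(outdir) -> ad.AnnData:
    from pathlib import Path

    outdir = Path(outdir)
    mat = spio.mmread(str(outdir / "matrix.mtx")).tocsr().T  # cells x genes
    var = pd.read_csv(outdir / "genes.tsv", sep="\t").set_index("gene")
    obs = pd.read_csv(outdir / "metadata.tsv", sep="\t").set_index("cell")
    return ad.AnnData(X=np.asarray(mat.todense()), obs=obs, var=var)
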