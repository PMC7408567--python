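"""Synthetic multi-omics cohort and single-cell generator with ground truth.

The generator implements a latent-variable model of the data structure the
pipeline assumes: each tumor carries a latent glycolysis activity ``g`` and a
latent hypoxia activity ``h`` drawn from a bivariate normal with correlation
``rho``.  Glycolysis-signature genes load on ``g``, hypoxia-signature genes
on ``h``, and the six shared genes on both, on the log2(TPM+1) scale.  Driver
alterations shift carriers' ``g``; survival hazard, tumor stage, aneuploidy
and genome doubling are all linked to ``g`` through configurable effect
sizes.  Every bundle ships with its :class:`SimTruth` so parameter-recovery
tests can compare any downstream estimate with the planted value.

Defaults emulate a small TCGA-like study: 4 cancer types, 300 tumors + 50
normals each, 400 genes, latent correlation 0.8 (the strongly coupled
hypoxia–glycolysis regime), one planted gained oncogene, one lost
suppressor, and one mutated driver per cohort.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from . import signatures as sigmod
from .io_formats import (
    CellMatrix,
    CNAMatrix,
    ExpressionMatrix,
    write_cells,
    write_clinical,
    write_matrix,
    write_mutations,
)

REGIONS = ("core", "edge", "middle")


@dataclass(frozen=True)
class DriverSpec:
    gene: str
    alteration: str  # 'gain' | 'loss' | 'mutation'
    carrier_fraction: float
    score_shift: float  # shift of latent g in carriers, latent-SD units

    def __post_init__(self) -> None:
        if self.alteration not in ("gain", "loss", "mutation"):
            raise ValueError(f"unknown alteration {self.alteration!r}")
        if not 0 < self.carrier_fraction < 1:
            raise ValueError("carrier_fraction must lie in (0, 1)")


def default_drivers() -> list[DriverSpec]:
    return [
        DriverSpec("DRV_ONC1", "gain", 0.30, 0.4),
        DriverSpec("DRV_SUP1", "loss", 0.30, -0.4),
        DriverSpec("DRV_MUT1", "mutation", 0.20, 0.5),
    ]


@dataclass
class SimConfig:
    seed: int  # mandatory; every bundle is reproducible from it
    n_cancer_types: int = 4
    n_tumor: int = 300
    n_normal: int = 50
    n_genes: int = 400
    rho: float = 0.8  # latent glycolysis-hypoxia correlation
    sig_effect: float = 1.0  # log2 units of expression per latent SD
    noise_sd: float = 0.4  # residual log2 expression SD on signature genes
    tumor_shift: float = 1.0  # tumor latent mean above the normal baseline
    drivers: list[DriverSpec] = field(default_factory=default_drivers)
    background_cna_rate: float = 0.05  # per-gene null gain/loss rate
    background_mut_rate: float = 0.01  # per-gene-sample null nonsyn mutation rate
    hazard_beta: float = float(np.log(2))  # log-hazard per latent SD of g
    baseline_hazard: float = 1 / 1000.0  # events per day at g = 0
    censor_hazard: float = 1 / 1500.0  # independent exponential censoring
    stage_beta: float = 0.5
    aneuploidy_rho: float = 0.4
    doubling_beta: float = 0.3
    # single cell
    n_patients: int = 8
    cells_per_patient: int = 90
    n_genes_sc: int = 400
    rho_cells: float = 0.8
    region_shift: float = 0.3  # hypoxia latent elevation: core > middle > edge
    cell_loading: float = 0.8  # ln-mean units per latent SD
    nb_dispersion: float = 0.5
    qc_fail_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not -1 <= self.rho <= 1:
            raise ValueError("|rho| must be <= 1")


@dataclass
class SimTruth:
    latent_g: pd.Series
    latent_h: pd.Series
    driver_carriers: dict[str, list[str]]
    config: SimConfig
    cell_latent_g: pd.Series | None = None
    cell_latent_h: pd.Series | None = None
    qc_fail_cells: list[str] = field(default_factory=list)


@dataclass
class CohortBundle:
    expr: ExpressionMatrix
    cna: CNAMatrix
    mutations: pd.DataFrame
    clinical: pd.DataFrame
    truth: SimTruth


def _gene_universe(cfg: SimConfig) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Gene list and per-gene (loading_on_g, loading_on_h)."""
    gly = set(sigmod.builtin_signature("glycolysis22").genes)
    hyp = set(sigmod.builtin_signature("hypoxia14").genes)
    overlap = gly & hyp
    loadings: dict[str, tuple[float, float]] = {}
    genes: list[str] = []
    for g in sorted(gly | hyp):
        if g in overlap:
            loadings[g] = (cfg.sig_effect / 2, cfg.sig_effect / 2)
        elif g in gly:
            loadings[g] = (cfg.sig_effect, 0.0)
        else:
            loadings[g] = (0.0, cfg.sig_effect)
        genes.append(g)
    # a planted glycolysis-coupled candidate regulator outside both signatures
    genes.append("HSPA8")
    loadings["HSPA8"] = (0.8 * cfg.sig_effect, 0.0)
    for spec in cfg.drivers:
        if spec.gene not in loadings:
            genes.append(spec.gene)
            loadings[spec.gene] = (0.0, 0.0)
    i = 1
    while len(genes) < cfg.n_genes:
        name = f"BG{i:04d}"
        if name not in loadings:
            genes.append(name)
            loadings[name] = (0.0, 0.0)
        i += 1
    return genes[: cfg.n_genes], loadings


def _bvn(rng, n, rho):
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    return z[:, 0], z[:, 1]


def simulate_cohort(cfg: SimConfig) -> CohortBundle:
    """Generate a multi-cancer bulk cohort with planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    genes, loadings = _gene_universe(cfg)
    baseline = rng.uniform(2.0, 8.0, size=len(genes))

    sample_ids: list[str] = []
    cancer_types: list[str] = []
    sample_types: list[str] = []
    g_list: list[np.ndarray] = []
    h_list: list[np.ndarray] = []
    type_names = [f"SYN{i+1:02d}" for i in range(cfg.n_cancer_types)]
    type_shift = rng.normal(0.0, 0.3, size=cfg.n_cancer_types)

    carriers: dict[str, list[str]] = {spec.gene: [] for spec in cfg.drivers}

    for t, ct in enumerate(type_names):
        tum = [f"{ct}-T{i+1:04d}" for i in range(cfg.n_tumor)]
        nor = [f"{ct}-N{i+1:04d}" for i in range(cfg.n_normal)]
        g_t, h_t = _bvn(rng, cfg.n_tumor, cfg.rho)
        g_t = g_t + cfg.tumor_shift + type_shift[t]
        h_t = h_t + cfg.tumor_shift + type_shift[t]
        # driver alterations shift carriers' glycolysis latent
        for spec in cfg.drivers:
            mask = rng.random(cfg.n_tumor) < spec.carrier_fraction
            g_t = g_t + np.where(mask, spec.score_shift, 0.0)
            carriers[spec.gene].extend([s for s, m in zip(tum, mask) if m])
        g_n = np.zeros(cfg.n_normal)
        h_n = np.zeros(cfg.n_normal)
        sample_ids += tum + nor
        cancer_types += [ct] * (cfg.n_tumor + cfg.n_normal)
        sample_types += ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal
        g_list += [g_t, g_n]
        h_list += [h_t, h_n]

    g = np.concatenate(g_list)
    h = np.concatenate(h_list)
    n = len(sample_ids)

    load_g = np.array([loadings[x][0] for x in genes])
    load_h = np.array([loadings[x][1] for x in genes])
    expr = (
        baseline[:, None]
        + load_g[:, None] * g[None, :]
        + load_h[:, None] * h[None, :]
        + rng.normal(0.0, cfg.noise_sd, size=(len(genes), n))
    )
    expr = np.maximum(expr, 0.0)  # log2(TPM+1) is nonnegative
    expr_mat = ExpressionMatrix(genes, sample_ids, expr)

    # --- CNA matrix: planted driver calls + null background alterations ---
    calls = np.zeros((len(genes), n), dtype=int)
    is_tumor = np.array([st == "tumor" for st in sample_types])
    u = rng.random((len(genes), n))
    calls[(u < cfg.background_cna_rate)] = 1
    calls[(u > 1 - cfg.background_cna_rate)] = -1
    calls[:, ~is_tumor] = 0
    gidx = {x: i for i, x in enumerate(genes)}
    sidx = {s: i for i, s in enumerate(sample_ids)}
    for spec in cfg.drivers:
        if spec.alteration not in ("gain", "loss"):
            continue
        row = gidx[spec.gene]
        calls[row, :] = 0
        code = 1 if spec.alteration == "gain" else -1
        for s in carriers[spec.gene]:
            calls[row, sidx[s]] = code
    cna = CNAMatrix(genes, sample_ids, calls)

    # --- mutations: planted driver + null background, plus synonymous noise ---
    mut_rows = []
    for spec in cfg.drivers:
        if spec.alteration != "mutation":
            continue
        for s in carriers[spec.gene]:
            mut_rows.append((s, spec.gene, True))
    bg = rng.random((len(genes), n))
    driver_mut_genes = {sp.gene for sp in cfg.drivers if sp.alteration == "mutation"}
    for i, gname in enumerate(genes):
        if gname in driver_mut_genes:
            continue
        hit = np.where((bg[i] < cfg.background_mut_rate) & is_tumor)[0]
        for j in hit:
            mut_rows.append((sample_ids[j], gname, True))
    # synonymous records exercise the nonsynonymous filter downstream
    syn_idx = rng.choice(n, size=max(1, n // 20), replace=False)
    for j in syn_idx:
        if is_tumor[j]:
            mut_rows.append((sample_ids[j], genes[int(rng.integers(len(genes)))], False))
    mutations = pd.DataFrame(mut_rows, columns=["sample_id", "gene_id", "nonsynonymous"])
    mutations = mutations.sort_values(["sample_id", "gene_id", "nonsynonymous"]).reset_index(drop=True)

    # --- clinical ---
    hazard = cfg.baseline_hazard * np.exp(cfg.hazard_beta * (g - cfg.tumor_shift))
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.exponential(1.0 / cfg.censor_hazard, size=n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)
    stage_latent = cfg.stage_beta * (g - cfg.tumor_shift) + rng.logistic(0.0, 1.0, size=n)
    cuts = np.quantile(stage_latent[is_tumor], [0.25, 0.5, 0.75])
    stage_num = np.digitize(stage_latent, cuts)  # 0..3
    stage = np.array(["I", "II", "III", "IV"])[stage_num]
    aneu_latent = cfg.aneuploidy_rho * (g - cfg.tumor_shift) + np.sqrt(
        max(1 - cfg.aneuploidy_rho**2, 0.0)
    ) * rng.normal(size=n)
    aneuploidy = np.clip(np.round(8 + 5 * aneu_latent), 0, 39).astype(int)
    dbl_latent = cfg.doubling_beta * (g - cfg.tumor_shift) + rng.normal(size=n)
    doublings = np.digitize(dbl_latent, np.quantile(dbl_latent[is_tumor], [0.5, 0.85]))
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "cancer_type": cancer_types,
            "sample_type": sample_types,
            "stage": np.where(is_tumor, stage, None),
            "os_time": np.round(os_time, 1),
            "os_event": os_event,
            "aneuploidy_score": np.where(is_tumor, aneuploidy, np.nan),
            "genome_doublings": np.where(is_tumor, doublings, np.nan),
        }
    ).set_index("sample_id", drop=False)

    truth = SimTruth(
        latent_g=pd.Series(g, index=sample_ids, name="g"),
        latent_h=pd.Series(h, index=sample_ids, name="h"),
        driver_carriers=carriers,
        config=cfg,
    )
    return CohortBundle(expr_mat, cna, mutations, clinical, truth)


# ---------------------------------------------------------------------------
# single cell
# ---------------------------------------------------------------------------


def _sc_gene_universe(cfg: SimConfig) -> tuple[list[str], np.ndarray, np.ndarray]:
    genes, loadings = _gene_universe(
        SimConfig(seed=cfg.seed, n_genes=cfg.n_genes_sc - 5, sig_effect=1.0,
                  drivers=cfg.drivers)
    )
    mito = [f"MT-SIM{i}" for i in range(1, 6)]
    all_genes = genes + mito
    load_g = np.array([loadings.get(x, (0.0, 0.0))[0] for x in all_genes]) * cfg.cell_loading
    load_h = np.array([loadings.get(x, (0.0, 0.0))[1] for x in all_genes]) * cfg.cell_loading
    return all_genes, load_g, load_h


def simulate_cells(cfg: SimConfig) -> tuple[CellMatrix, SimTruth]:
    """Generate NB single-cell counts with patient and region structure.

    Hypoxia latent means rank core > middle > edge by ``region_shift``; the
    glycolysis latent tracks hypoxia with correlation ``rho_cells``.  A
    ``qc_fail_fraction`` of cells is deliberately corrupted (count-thinned or
    mitochondria-boosted) so QC filtering is exercised with known truth.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes, load_g, load_h = _sc_gene_universe(cfg)
    is_mito = np.array([x.startswith("MT-") for x in genes])
    base_ln = rng.normal(np.log(2.0), 0.6, size=len(genes))
    base_ln[is_mito] = np.log(1.0)

    region_mean = {"core": cfg.region_shift, "middle": cfg.region_shift / 2, "edge": 0.0}
    cell_ids, patients, regions = [], [], []
    g_all, h_all = [], []
    counts_cols = []
    alpha = cfg.nb_dispersion
    for p in range(cfg.n_patients):
        pid = f"PT{p+1:02d}"
        per_region = cfg.cells_per_patient // len(REGIONS)
        for region in REGIONS:
            gl, hl = _bvn(rng, per_region, cfg.rho_cells)
            hl = hl + region_mean[region]
            gl = gl + region_mean[region] * cfg.rho_cells
            for c in range(per_region):
                cell_ids.append(f"{pid}-{region}-{c+1:03d}")
                patients.append(pid)
                regions.append(region)
            g_all.append(gl)
            h_all.append(hl)
            ln_mu = (
                base_ln[:, None]
                + load_g[:, None] * gl[None, :]
                + load_h[:, None] * hl[None, :]
            )
            mu = np.exp(ln_mu)
            if alpha > 0:
                nb_n = 1.0 / alpha
                nb_p = nb_n / (nb_n + mu)
                block = rng.negative_binomial(nb_n, nb_p)
            else:
                block = rng.poisson(mu)
            counts_cols.append(block)
    counts = np.concatenate(counts_cols, axis=1)
    g = np.concatenate(g_all)
    h = np.concatenate(h_all)

    # inject deliberate QC failures with known identity
    n_cells = counts.shape[1]
    n_fail = int(round(cfg.qc_fail_fraction * n_cells))
    fail_idx = rng.choice(n_cells, size=n_fail, replace=False)
    fail_cells = []
    for k, j in enumerate(sorted(fail_idx)):
        if k % 2 == 0:  # thin to < 200 total counts
            total = counts[:, j].sum()
            keep_p = min(100.0 / max(total, 1), 1.0)
            counts[:, j] = rng.binomial(counts[:, j], keep_p)
        else:  # boost mitochondrial fraction past 10%
            counts[is_mito, j] = counts[is_mito, j] * 50 + 50
        fail_cells.append(cell_ids[j])

    meta = pd.DataFrame(
        {"cell_id": cell_ids, "patient_id": patients, "region": regions}
    ).set_index("cell_id", drop=False)
    cells = CellMatrix(
        gene_ids=genes,
        cell_ids=cell_ids,
        counts=sparse.csr_matrix(counts),
        cell_meta=meta[["patient_id", "region"]],
    )
    truth = SimTruth(
        latent_g=pd.Series(dtype=float),
        latent_h=pd.Series(dtype=float),
        driver_carriers={},
        config=cfg,
        cell_latent_g=pd.Series(g, index=cell_ids),
        cell_latent_h=pd.Series(h, index=cell_ids),
        qc_fail_cells=fail_cells,
    )
    return cells, truth


# ---------------------------------------------------------------------------
# fixture bundles on disk
# ---------------------------------------------------------------------------


def write_fixture_bundle(out_dir, cfg: SimConfig, force: bool = False) -> dict[str, str]:
    """Write a full cohort + single-cell bundle; returns file SHA-256 digests."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} exists and is not empty (use force=True)")
    out.mkdir(parents=True, exist_ok=True)
    bundle = simulate_cohort(cfg)
    cells, sc_truth = simulate_cells(cfg)
    write_matrix(bundle.expr, out / "expr.tsv")
    write_matrix(bundle.cna, out / "cna.tsv")
    write_mutations(bundle.mutations, out / "mutations.tsv")
    write_clinical(bundle.clinical, out / "clinical.tsv")
    write_cells(cells, out / "counts.mtx", out / "genes.tsv", out / "cells.tsv")
    drivers = pd.DataFrame(
        [
            {"gene_id": d.gene,
             "role": "oncogene" if d.alteration == "gain" else "suppressor"}
            for d in cfg.drivers
            if d.alteration in ("gain", "loss")
        ]
    )
    drivers.to_csv(out / "drivers.tsv", sep="\t", index=False)
    truth = {
        "latent_g": bundle.truth.latent_g.round(6).to_dict(),
        "latent_h": bundle.truth.latent_h.round(6).to_dict(),
        "driver_carriers": bundle.truth.driver_carriers,
        "qc_fail_cells": sc_truth.qc_fail_cells,
        "seed": cfg.seed,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=0, sort_keys=True)
    digests = {}
    for f in sorted(out.iterdir()):
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    return digests
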