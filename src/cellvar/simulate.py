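"""Synthetic datasets with known ground truth for every pipeline stage.

Counts follow a gamma-Poisson model because its CV is analytically
controllable (CV^2 = phi + 1/mu). The high-variability (HV) population is
encoded by inflating per-gene dispersion, not means, so population-level
means stay matched. Morphology uses correlated log-normal size parameters;
allele frequencies drift along a given clone tree; knockdown fold-changes
are planted with a configurable overlap with the inflated gene set.

All generators are pure functions of (config, seed): identical inputs
produce bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skbio import TreeNode

from .scvar import ExpressionMatrix

__all__ = [
    "SimConfig",
    "SimGroundTruth",
    "gen_sc_dataset",
    "gen_morphology_dataset",
    "gen_vaf_dataset",
    "gen_perturbation_dataset",
    "MORPHOLOGY_PARAMS",
]

MORPHOLOGY_PARAMS = (
    "cell_area",
    "cytoplasmic_area",
    "nuclear_area",
    "perimeter",
    "major_axis_length",
    "minor_axis_length",
)

# pixel-scale log-normal location parameters for the six size measures
_MORPH_MEANS = {
    "cell_area": 5000.0,
    "cytoplasmic_area": 3200.0,
    "nuclear_area": 1500.0,
    "perimeter": 320.0,
    "major_axis_length": 130.0,
    "minor_axis_length": 60.0,
}


@dataclass
class SimConfig:
    """Parameters for all synthetic generators. Counts must be >= 1."""

    # single-cell expression
    n_genes: int = 500
    n_cells: int = 10  # per population
    mean_log: float = 3.5  # log-normal location of per-gene means
    sd_log: float = 1.0
    dispersion: float = 0.5  # baseline gamma-Poisson phi
    inflation_factor: float = 2.0  # k; 1 = null
    inflated_fraction: float = 0.5
    # sd (natural log) of a per-gene HV-dispersion tilt shared across
    # comparisons that reuse the same ground truth; models gene-specific
    # variability differences that replicate between related cell lines
    hv_tilt_sd: float = 0.0
    spikein_fraction: float = 0.05
    # intron / junction layers
    n_introns: int = 300
    intron_depth: float = 40.0  # expected flanking-exon reads per side
    intron_retention_mean: float = 0.3
    intron_retention_cv: float = 0.4  # cell-to-cell CV of the retention rate
    junction_fraction: float = 0.5  # genes carrying junction layers
    # morphology
    n_clones: int = 100
    n_cells_per_clone: int = 100
    morph_cv: float = 0.2
    morph_corr: float = 0.8
    hv_fraction: float = 0.03
    morph_inflation: float = 2.0
    # perturbation / gene sets
    kd_effect: float = 2.0
    kd_noise_sd: float = 0.5
    kd_overlap_jaccard: float = 0.5
    kd_set_size: int | None = None  # default: size of the inflated gene set
    planted_set_size: int = 150
    planted_purity: float = 0.8  # fraction of the planted set from inflated genes
    n_decoy_sets: int = 50
    decoy_set_size: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cells", "n_introns", "n_clones",
                     "n_cells_per_clone", "planted_set_size", "n_decoy_sets",
                     "decoy_set_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("spikein_fraction", "inflated_fraction", "hv_fraction",
                     "junction_fraction", "kd_overlap_jaccard"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.inflation_factor < 1:
            raise ValueError("inflation_factor must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class SimGroundTruth:
    """What the generator actually planted, for recovery tests."""

    baseline_mean: pd.Series  # per-gene mu
    dispersion: pd.Series  # per-gene phi
    inflated_genes: set
    inflation_factor: float
    hv_tilt: pd.Series | None = None  # per-gene HV dispersion multiplier
    spikein_genes: set = field(default_factory=set)
    hv_clones: set = field(default_factory=set)
    tree_newick: str = ""
    seed: int = 0


def _gamma_poisson(rng, mu, phi, size):
    """Counts with mean mu and CV^2 = phi + 1/mu (phi=0 -> Poisson)."""
    mu = np.broadcast_to(mu, size)
    phi = np.broadcast_to(phi, size)
    rate = np.where(
        phi > 0,
        rng.gamma(np.where(phi > 0, 1.0 / np.maximum(phi, 1e-12), 1.0),
                  mu * np.maximum(phi, 1e-12)),
        mu,
    )
    return rng.poisson(rate)


def gen_sc_dataset(
    config: SimConfig,
    truth: SimGroundTruth | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SimGroundTruth]:
    """Two-population (LV/HV) expression, intron, and junction layers.

    Passing an existing ``truth`` reuses its per-gene means, dispersions
    and inflated set (new noise from ``config.seed``), which lets two
    "cell line" comparisons share the same planted variable genes.

    Returns (expression, intron_table, junction_table, ground_truth);
    the intron table is long-format with columns gene_id, intron_index,
    cell_id, intron_reads, up_exon_reads, down_exon_reads; the junction
    table has gene_id, donor, acceptor, cell_id, reads.
    """
    if config.n_cells < 5:
        raise ValueError("need at least 5 cells per population")
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    n_spike = int(round(config.spikein_fraction * g))
    gene_ids = [f"gene_{i:05d}" for i in range(g - n_spike)]
    spike_ids = [f"spikein_{i:03d}" for i in range(n_spike)]
    all_ids = gene_ids + spike_ids

    if truth is None:
        mu = rng.lognormal(config.mean_log, config.sd_log, size=g)
        phi = config.dispersion * rng.uniform(0.5, 1.5, size=g)
        n_inflated = int(round(config.inflated_fraction * len(gene_ids)))
        inflated = set(rng.choice(gene_ids, size=n_inflated, replace=False))
        tilt = np.exp(rng.normal(0.0, config.hv_tilt_sd, size=g))
        tilt[len(gene_ids):] = 1.0  # spike-ins stay identical in both pops
        truth = SimGroundTruth(
            baseline_mean=pd.Series(mu, index=all_ids),
            dispersion=pd.Series(phi, index=all_ids),
            inflated_genes=inflated,
            inflation_factor=config.inflation_factor,
            hv_tilt=pd.Series(tilt, index=all_ids),
            spikein_genes=set(spike_ids),
            seed=config.seed,
        )
    else:
        mu = truth.baseline_mean.loc[all_ids].to_numpy()
        phi = truth.dispersion.loc[all_ids].to_numpy()
        inflated = truth.inflated_genes
        truth = replace(truth, seed=config.seed)
    tilt = (truth.hv_tilt.loc[all_ids].to_numpy()
            if truth.hv_tilt is not None else np.ones(g))

    k = config.inflation_factor
    inflate_mask = np.array([fid in inflated for fid in all_ids])
    n = config.n_cells
    counts = {}
    for pop, pop_k in (("LV", 1.0), ("HV", k)):
        phi_pop = np.where(inflate_mask, phi * pop_k, phi)
        if pop == "HV":
            phi_pop = phi_pop * tilt
        counts[pop] = _gamma_poisson(
            rng, mu[:, None], phi_pop[:, None], (g, n)
        )
    values = pd.DataFrame(
        np.hstack([counts["LV"], counts["HV"]]),
        index=all_ids,
        columns=[f"LV_c{i:03d}" for i in range(n)] + [f"HV_c{i:03d}" for i in range(n)],
        dtype=float,
    )
    mapped = values.sum(axis=0)
    spike_reads = values.loc[spike_ids].sum(axis=0) if n_spike else mapped * 0
    cells = pd.DataFrame(
        {
            "population": ["LV"] * n + ["HV"] * n,
            "total_reads": np.ceil(mapped * 1.1).astype(int),
            "mapped_reads": mapped.astype(int),
            "spikein_reads": spike_reads.astype(int),
        },
        index=values.columns,
    )
    features = pd.DataFrame(
        {"is_spikein": [fid in truth.spikein_genes for fid in all_ids]},
        index=all_ids,
    )
    matrix = ExpressionMatrix(values=values, cells=cells, features=features)

    intron_table = _gen_intron_layer(rng, config, gene_ids, inflated, k, values.columns, cells)
    junction_table = _gen_junction_layer(rng, config, gene_ids, values)
    return matrix, intron_table, junction_table, truth


def _gen_intron_layer(rng, config, gene_ids, inflated, k, cell_ids, cells):
    """Per-cell intron/flanking-exon counts with inflatable retention variance."""
    host_genes = rng.choice(gene_ids, size=config.n_introns, replace=True)
    idx_within = {}
    records = []
    n_cells_total = len(cell_ids)
    is_hv = (cells["population"] == "HV").to_numpy()
    phi_r = config.intron_retention_cv**2
    for gene in host_genes:
        idx_within[gene] = idx_within.get(gene, 0) + 1
        intron_index = idx_within[gene]
        depth = rng.lognormal(np.log(config.intron_depth), 0.3)
        rho = rng.uniform(0.5, 1.5) * config.intron_retention_mean
        phi_here = np.where(is_hv & (gene in inflated), phi_r * k, phi_r)
        # cell-to-cell retention rate with CV^2 = phi_here
        rate = rng.gamma(1.0 / phi_here, rho * phi_here, size=n_cells_total)
        up = rng.poisson(depth, size=n_cells_total)
        down = rng.poisson(depth, size=n_cells_total)
        intron = rng.poisson((up + down) * rate)
        for j, cell in enumerate(cell_ids):
            records.append((gene, intron_index, cell, intron[j], up[j], down[j]))
    return pd.DataFrame(
        records,
        columns=["gene_id", "intron_index", "cell_id",
                 "intron_reads", "up_exon_reads", "down_exon_reads"],
    )


def _gen_junction_layer(rng, config, gene_ids, values):
    """Two junctions per selected gene; counts are a multinomial split of
    the gene's counts, so junction variability tracks gene variability."""
    n_j_genes = int(round(config.junction_fraction * len(gene_ids)))
    j_genes = list(rng.choice(gene_ids, size=n_j_genes, replace=False))
    share = rng.uniform(0.3, 0.7, size=n_j_genes)
    sub = values.loc[j_genes].to_numpy().astype(int)
    j1 = rng.binomial(sub, share[:, None])
    j2 = sub - j1
    frames = []
    for jnum, jcounts, donors in ((1, j1, ("e1", "e2")), (2, j2, ("e2", "e3"))):
        df = pd.DataFrame(jcounts, index=j_genes, columns=values.columns)
        long = df.stack().reset_index()
        long.columns = ["gene_id", "cell_id", "reads"]
        long.insert(1, "donor", donors[0])
        long.insert(2, "acceptor", donors[1])
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["gene_id", "donor", "acceptor", "cell_id"]).reset_index(
        drop=True
    )


def gen_morphology_dataset(config: SimConfig) -> tuple[pd.DataFrame, SimGroundTruth]:
    """Per-cell six-parameter morphology table with planted HV clones.

    Size parameters are correlated log-normals; HV clones have every
    parameter's CV multiplied by ``morph_inflation`` with the log-normal
    location adjusted so the arithmetic means are unchanged.
    """
    if config.n_clones < 10:
        raise ValueError("need at least 10 clones")
    if not 0 < config.hv_fraction < 1:
        raise ValueError("hv_fraction must be in (0, 1)")
    rng = np.random.default_rng(config.seed)
    p = len(MORPHOLOGY_PARAMS)
    cv = config.morph_cv
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    mu_log = np.array(
        [np.log(_MORPH_MEANS[name]) - sigma2 / 2 for name in MORPHOLOGY_PARAMS]
    )
    corr = np.full((p, p), config.morph_corr)
    np.fill_diagonal(corr, 1.0)

    f = config.morph_inflation
    sigma2_hv = np.log1p(f**2 * cv**2)
    sigma_hv = np.sqrt(sigma2_hv)
    mu_log_hv = mu_log + (sigma2 - sigma2_hv) / 2  # keep arithmetic means fixed

    n_hv = max(1, int(round(config.hv_fraction * config.n_clones)))
    clone_ids = [f"clone_{i:03d}" for i in range(config.n_clones)]
    hv_clones = set(rng.choice(clone_ids, size=n_hv, replace=False))

    frames = []
    for clone in clone_ids:
        hv = clone in hv_clones
        s = sigma_hv if hv else sigma
        m = mu_log_hv if hv else mu_log
        cov = corr * np.outer(s, s)
        logs = rng.multivariate_normal(m, cov, size=config.n_cells_per_clone)
        df = pd.DataFrame(np.exp(logs), columns=list(MORPHOLOGY_PARAMS))
        df.insert(0, "clone_id", clone)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    truth = SimGroundTruth(
        baseline_mean=pd.Series(
            {name: _MORPH_MEANS[name] for name in MORPHOLOGY_PARAMS}
        ),
        dispersion=pd.Series(cv, index=list(MORPHOLOGY_PARAMS)),
        inflated_genes=set(),
        inflation_factor=config.morph_inflation,
        hv_clones=hv_clones,
        seed=config.seed,
    )
    return table, truth


def gen_vaf_dataset(
    tree: TreeNode, n_variants: int, drift_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Variant allele frequencies drifting along a clone tree.

    Root frequencies are Uniform(0.05, 0.95); each child adds
    Normal(0, drift_sd * branch_length) noise, clipped to [0, 1]. Leaves
    become population columns of the returned frequency table.
    """
    if drift_sd < 0:
        raise ValueError("drift_sd must be >= 0")
    leaves = list(tree.tips())
    if len(leaves) < 3:
        raise ValueError("tree must have at least 3 leaves")
    if any(lf.name is None for lf in leaves):
        raise ValueError("all leaves must be named")
    rng = np.random.default_rng(seed)
    freqs: dict[int, np.ndarray] = {
        id(tree): rng.uniform(0.05, 0.95, size=n_variants)
    }
    columns = {}
    for node in tree.preorder(include_self=False):
        parent_f = freqs[id(node.parent)]
        length = node.length if node.length is not None else 1.0
        f = np.clip(
            parent_f + rng.normal(0.0, drift_sd * length, size=n_variants), 0.0, 1.0
        )
        freqs[id(node)] = f
        if node.is_tip():
            columns[node.name] = f
    out = pd.DataFrame(columns)
    out.index = [f"var_{i:06d}" for i in range(n_variants)]
    out.index.name = "variant_id"
    return out


def gen_perturbation_dataset(
    config: SimConfig, truth: SimGroundTruth
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Knockdown log2 fold-changes plus gene sets with a planted signal.

    A "dependent" gene set of size ``kd_set_size`` overlaps the planted
    variable genes at the configured Jaccard index; dependent genes get a
    +/- ``kd_effect`` shift on top of Normal(0, kd_noise_sd) replicate
    noise. Gene sets comprise one planted set concentrated among inflated
    genes (capped at 200 members) and random decoy sets.
    """
    rng = np.random.default_rng(config.seed)
    genes = [g for g in truth.baseline_mean.index if g not in truth.spikein_genes]
    inflated = sorted(truth.inflated_genes)
    non_inflated = sorted(set(genes) - set(inflated))
    s = config.kd_set_size if config.kd_set_size else max(len(inflated), 1)
    j = config.kd_overlap_jaccard
    if j == 0:
        # null: membership independent of the inflated set
        dependent = set(rng.choice(genes, size=min(s, len(genes)), replace=False))
    else:
        # |D & I| = j * (|D| + |I| - |D & I|)  =>  o = j (s + |I|) / (1 + j)
        o = int(round(j * (s + len(inflated)) / (1.0 + j)))
        if o > min(s, len(inflated)) or (s - o) > len(non_inflated):
            raise ValueError(
                "requested overlap is infeasible for this gene universe"
            )
        dep_in = list(rng.choice(inflated, size=o, replace=False)) if o else []
        dep_out = list(rng.choice(non_inflated, size=s - o, replace=False))
        dependent = set(dep_in + dep_out)

    effect = np.zeros(len(genes))
    dep_mask = np.array([g in dependent for g in genes])
    signs = rng.choice([-1.0, 1.0], size=len(genes))
    effect[dep_mask] = (signs * config.kd_effect)[dep_mask]
    rep1 = effect + rng.normal(0.0, config.kd_noise_sd, size=len(genes))
    rep2 = effect + rng.normal(0.0, config.kd_noise_sd, size=len(genes))
    fc = pd.DataFrame(
        {
            "log2fc_rep1": rep1,
            "log2fc_rep2": rep2,
            "mean_log2fc": (rep1 + rep2) / 2.0,
        },
        index=pd.Index(genes, name="transcript_id"),
    )

    planted_size = min(config.planted_set_size, 200)
    n_from_inflated = min(int(round(config.planted_purity * planted_size)),
                          len(inflated))
    planted = list(rng.choice(inflated, size=n_from_inflated, replace=False))
    planted += list(
        rng.choice(non_inflated, size=planted_size - n_from_inflated, replace=False)
    )
    gene_sets = {"planted_variable_set": sorted(planted)}
    for i in range(config.n_decoy_sets):
        members = rng.choice(genes, size=config.decoy_set_size, replace=False)
        gene_sets[f"decoy_{i:03d}"] = sorted(members)
    return fc, gene_sets
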