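"""Synthetic paired transcriptome/proteome study generator.

Emulates the statistical structure of a multi-condition microbial study:
several conditions with replicated mRNA counts and protein abundances,
an orthogroup map with a core of orthogroups shared by all bacterial
conditions (and a smaller core shared with the archaeal condition),
per-orthogroup conserved protein-to-mRNA (ptr) offsets that are partly
conserved across conditions, a left-skewed injected-outlier mixture,
essential-gene subsets with higher abundance / lower replicate variance /
tighter mRNA-protein coupling, and logistic protein dropout.

Everything is generated on the log2 scale:

    mrna_latent[g, r]    = mu[g] + eta[g, r]
    protein_latent[g, r] = mu[g] + offset[g] + eps[g, r]

where for an orthologous gene ``offset = c_j + d_ij`` (conserved
per-orthogroup offset plus per-condition deviation) and for a private
gene the offset is its own independent draw. mRNA is emitted as Poisson
counts at a configurable library depth (``library_depth=None`` emits
linear abundances directly, which makes noise-free identities exact).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.special import expit

from .errors import ConfigError, UnknownConditionError
from .io_tables import (
    AbundanceTable,
    OrthologMap,
    write_abundance_table,
    write_gene_list,
    write_orthogroups,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "default_config",
    "generate_study",
    "truth_rtp",
    "write_study",
]


@dataclass(frozen=True)
class SyntheticConfig:
    n_conditions: int = 9
    genes_per_condition: int = 2500
    n_orthogroups: int = 600
    ortholog_coverage: float = 0.55
    n_replicates: int = 4
    mrna_mean: float = 8.0
    mrna_sd: float = 1.9  # SD of the shared per-orthogroup latent mean
    condition_mrna_sd: float = 0.9  # per-condition deviation around the shared mean
    conserved_ptr_sd: float = 1.5
    species_ptr_sd: float = 0.5
    private_ptr_sd: float | None = None  # non-orthologous genes; default hypot of the two above
    replicate_noise_sd: float = 0.25
    measurement_noise_sd: float = 0.5
    outlier_fraction: float = 0.11
    outlier_magnitude: float = 5.0
    outlier_sign_bias: float = 0.95  # probability an injected outlier is low-ptr
    outlier_mrna_shift: float = 3.0  # extra mRNA for low-ptr outliers (keeps them detectable)
    essential_fraction: float = 0.12
    essential_mean_shift: float = 2.0
    essential_sd_scale: float = 0.5
    essential_noise_scale: float = 0.5
    protein_dropout_midpoint: float = 4.5
    protein_dropout_slope: float = 1.15  # 0 disables dropout
    library_depth: int | None = 2_000_000  # None: emit linear mRNA abundances
    n_core_bacterial: int = 140  # orthogroups covering the first 8 conditions
    n_core_all: int = 58  # orthogroups covering every condition
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_conditions", "genes_per_condition", "n_orthogroups", "n_replicates"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool) or v <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {v!r}")
        if self.n_replicates < 2:
            raise ConfigError("n_replicates must be >= 2")
        if self.library_depth is not None and (
            not isinstance(self.library_depth, (int, np.integer)) or self.library_depth <= 0
        ):
            raise ConfigError(f"library_depth must be a positive integer or None")
        for name in ("mrna_sd", "condition_mrna_sd", "conserved_ptr_sd", "species_ptr_sd",
                     "replicate_noise_sd", "measurement_noise_sd",
                     "outlier_magnitude", "outlier_mrna_shift", "protein_dropout_slope"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.private_ptr_sd is not None and self.private_ptr_sd < 0:
            raise ConfigError("private_ptr_sd must be >= 0")
        for name in ("ortholog_coverage", "outlier_fraction", "outlier_sign_bias",
                     "essential_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        for name in ("essential_sd_scale", "essential_noise_scale"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        if self.n_core_all > self.n_core_bacterial:
            raise ConfigError("n_core_all cannot exceed n_core_bacterial")
        if self.n_core_bacterial > self.n_orthogroups:
            raise ConfigError("core orthogroup counts cannot exceed n_orthogroups")


def default_config(**overrides) -> SyntheticConfig:
    """The default study-shaped preset (9 conditions, 2,500 genes)."""
    cfg = SyntheticConfig(**overrides) if overrides else SyntheticConfig()
    cfg.validate()
    return cfg


@dataclass
class SyntheticTruth:
    """Generative ground truth recorded alongside a synthetic study."""

    conserved_offset: dict[str, float]  # orthogroup -> c_j
    condition_deviation: dict[str, dict[str, float]]  # condition -> orthogroup -> d_ij
    essential: dict[str, set[str]]  # condition -> essential gene IDs
    outlier_orthogroups: dict[str, int]  # orthogroup -> sign (+1 high ptr, -1 low ptr)
    outlier_private: dict[str, dict[str, int]]  # condition -> gene -> sign
    latent_mrna_mean: dict[str, dict[str, float]]  # condition -> gene -> mu


@dataclass
class SyntheticStudy:
    config: SyntheticConfig
    mrna: dict[str, AbundanceTable]
    protein: dict[str, AbundanceTable]
    orthomap: OrthologMap
    essential: dict[str, set[str]]
    truth: SyntheticTruth

    @property
    def condition_ids(self) -> list[str]:
        return list(self.mrna)


def _coverage_matrix(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n_orthogroups, n_conditions) presence matrix."""
    n_og, n_cond = cfg.n_orthogroups, cfg.n_conditions
    cov = np.zeros((n_og, n_cond), dtype=bool)
    n_bact = min(8, n_cond)
    cov[: cfg.n_core_all, :] = True
    cov[cfg.n_core_all: cfg.n_core_bacterial, :n_bact] = True
    rest = slice(cfg.n_core_bacterial, n_og)
    cov[rest] = rng.random((n_og - cfg.n_core_bacterial, n_cond)) < cfg.ortholog_coverage
    empty = np.flatnonzero(~cov.any(axis=1))
    if empty.size:
        cov[empty, rng.integers(0, n_cond, size=empty.size)] = True
    return cov


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    """Generate a full paired study; deterministic given ``config.seed``."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_cond = cfg.n_conditions
    cond_ids = [f"c{i + 1}" for i in range(n_cond)]
    og_ids = [f"OG{j:04d}" for j in range(cfg.n_orthogroups)]

    cov = _coverage_matrix(cfg, rng)

    # conserved per-orthogroup offsets with injected outlier mixture
    c = rng.normal(0.0, cfg.conserved_ptr_sd, size=cfg.n_orthogroups)
    is_outlier = rng.random(cfg.n_orthogroups) < cfg.outlier_fraction
    signs = np.where(rng.random(cfg.n_orthogroups) < cfg.outlier_sign_bias, -1.0, 1.0)
    c = np.where(is_outlier, signs * cfg.outlier_magnitude, c)

    outlier_ogs = {og_ids[j]: int(signs[j]) for j in np.flatnonzero(is_outlier)}
    conserved_offset = {og_ids[j]: float(c[j]) for j in range(cfg.n_orthogroups)}

    # shared per-orthogroup latent mRNA mean: orthologs keep correlated
    # abundance (and hence detection) across conditions; low-ptr outliers
    # get extra mRNA so their (low) protein stays above the detection floor
    og_mean = rng.normal(cfg.mrna_mean, cfg.mrna_sd, size=cfg.n_orthogroups)
    og_mean[is_outlier & (signs < 0)] += cfg.outlier_mrna_shift
    private_sd = math.hypot(cfg.mrna_sd, cfg.condition_mrna_sd)

    groups: dict[str, dict[str, list[str]]] = {og: {} for og in og_ids}
    condition_deviation: dict[str, dict[str, float]] = {}
    essential: dict[str, set[str]] = {}
    outlier_private: dict[str, dict[str, int]] = {}
    latent_mrna_mean: dict[str, dict[str, float]] = {}
    mrna_tables: dict[str, AbundanceTable] = {}
    protein_tables: dict[str, AbundanceTable] = {}
    rep_ids = [f"r{k + 1}" for k in range(cfg.n_replicates)]

    for i, cond in enumerate(cond_ids):
        og_here = np.flatnonzero(cov[:, i])
        n_orth = og_here.size
        n_private = cfg.genes_per_condition - n_orth
        if n_private < 0:
            raise ConfigError(
                f"condition {cond}: {n_orth} orthologous genes exceed "
                f"genes_per_condition={cfg.genes_per_condition}"
            )
        orth_genes = [f"{cond}_{og_ids[j]}" for j in og_here]
        private_genes = [f"{cond}_p{k:04d}" for k in range(n_private)]
        gene_ids = orth_genes + private_genes
        n_genes = len(gene_ids)
        for j, gid in zip(og_here, orth_genes):
            groups[og_ids[j]][cond] = [gid]

        # essential genes: drawn among private genes only, so orthogroup-level
        # ground truth (c_j, d_ij) stays untouched by essential rescaling
        n_ess = int(round(cfg.essential_fraction * cfg.genes_per_condition))
        if n_ess > n_private:
            raise ConfigError(
                f"condition {cond}: essential_fraction asks for {n_ess} essential genes "
                f"but only {n_private} private genes exist"
            )
        ess_local = rng.choice(n_private, size=n_ess, replace=False)
        ess_mask_priv = np.zeros(n_private, dtype=bool)
        ess_mask_priv[ess_local] = True
        essential[cond] = {private_genes[k] for k in ess_local}

        # latent log2 mRNA means; private genes match the ortholog marginal SD
        mu = np.empty(n_genes)
        mu[:n_orth] = og_mean[og_here] + rng.normal(0.0, cfg.condition_mrna_sd, size=n_orth)
        mu_priv = rng.normal(cfg.mrna_mean, private_sd, size=n_private)
        mu_priv[ess_mask_priv] = rng.normal(
            cfg.mrna_mean + cfg.essential_mean_shift,
            private_sd * cfg.essential_sd_scale,
            size=n_ess,
        )
        mu[n_orth:] = mu_priv

        # ptr offsets
        d = rng.normal(0.0, cfg.species_ptr_sd, size=n_orth)
        condition_deviation[cond] = {og_ids[j]: float(dv) for j, dv in zip(og_here, d)}
        offset = np.empty(n_genes)
        offset[:n_orth] = c[og_here] + d

        priv_sd = (cfg.private_ptr_sd if cfg.private_ptr_sd is not None
                   else math.hypot(cfg.conserved_ptr_sd, cfg.species_ptr_sd))
        off_priv = rng.normal(0.0, priv_sd, size=n_private)
        # outlier mixture among non-essential private genes
        inj_priv = (rng.random(n_private) < cfg.outlier_fraction) & ~ess_mask_priv
        sign_priv = np.where(rng.random(n_private) < cfg.outlier_sign_bias, -1.0, 1.0)
        off_priv = np.where(inj_priv, sign_priv * cfg.outlier_magnitude, off_priv)
        off_priv[ess_mask_priv] *= cfg.essential_noise_scale
        offset[n_orth:] = off_priv
        outlier_private[cond] = {
            private_genes[k]: int(sign_priv[k]) for k in np.flatnonzero(inj_priv)
        }

        # private low-ptr outliers get the same mRNA boost as orthologous ones
        mu[n_orth:][inj_priv & (sign_priv < 0)] += cfg.outlier_mrna_shift

        latent_mrna_mean[cond] = {g: float(m) for g, m in zip(gene_ids, mu)}

        # per-replicate noise; essential genes get tighter replicate noise
        noise_scale = np.ones(n_genes)
        noise_scale[n_orth:][ess_mask_priv] = cfg.essential_noise_scale
        eta = rng.normal(0.0, 1.0, size=(n_genes, cfg.n_replicates))
        eta *= cfg.replicate_noise_sd * noise_scale[:, None]
        eps = rng.normal(0.0, 1.0, size=(n_genes, cfg.n_replicates))
        eps *= cfg.measurement_noise_sd * noise_scale[:, None]

        mrna_latent = mu[:, None] + eta
        protein_latent = mu[:, None] + offset[:, None] + eps

        if cfg.library_depth is None:
            mrna_values = np.exp2(mrna_latent)
        else:
            linear = np.exp2(mrna_latent)
            proportions = linear / linear.sum(axis=0, keepdims=True)
            mrna_values = rng.poisson(cfg.library_depth * proportions).astype(float)

        protein_values = np.exp2(protein_latent)
        if cfg.protein_dropout_slope > 0:
            p_detect = expit(cfg.protein_dropout_slope
                             * (protein_latent - cfg.protein_dropout_midpoint))
            detected = rng.random(protein_values.shape) < p_detect
            protein_values = protein_values * detected

        mrna_tables[cond] = AbundanceTable(cond, "mrna", list(gene_ids), mrna_values, list(rep_ids))
        protein_tables[cond] = AbundanceTable(cond, "protein", list(gene_ids), protein_values,
                                              list(rep_ids))

    groups = {og: members for og, members in groups.items() if members}
    truth = SyntheticTruth(
        conserved_offset=conserved_offset,
        condition_deviation=condition_deviation,
        essential=essential,
        outlier_orthogroups=outlier_ogs,
        outlier_private=outlier_private,
        latent_mrna_mean=latent_mrna_mean,
    )
    omap = OrthologMap(groups, condition_ids=cond_ids)
    return SyntheticStudy(cfg, mrna_tables, protein_tables, omap, essential, truth)


def truth_rtp(truth: SyntheticTruth, condition_subset: Iterable[str]) -> dict[str, float]:
    """Expected conversion factor c_j + mean(d_ij) over a condition subset.

    Only orthogroups covered by every condition in the subset are returned.
    """
    conds = list(condition_subset)
    if not conds:
        raise ValueError("condition subset must be non-empty")
    for cond in conds:
        if cond not in truth.condition_deviation:
            raise UnknownConditionError(cond)
    out: dict[str, float] = {}
    for og, c_j in truth.conserved_offset.items():
        devs = []
        for cond in conds:
            d = truth.condition_deviation[cond].get(og)
            if d is None:
                break
            devs.append(d)
        else:
            out[og] = c_j + float(np.mean(devs))
    return out


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, list[str]]:
    """Write the study as plain-text files; returns written paths per kind."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, list[str]] = {"mrna": [], "protein": [], "orthogroups": [],
                                     "essential": [], "truth": []}
    for cond, table in study.mrna.items():
        p = outdir / f"{cond}_mrna.tsv"
        write_abundance_table(table, p)
        written["mrna"].append(str(p))
    for cond, table in study.protein.items():
        p = outdir / f"{cond}_protein.tsv"
        write_abundance_table(table, p)
        written["protein"].append(str(p))
    p = outdir / "Orthogroups.tsv"
    write_orthogroups(study.orthomap, p)
    written["orthogroups"].append(str(p))
    for cond, ids in study.essential.items():
        p = outdir / f"{cond}_essential.txt"
        write_gene_list(ids, p)
        written["essential"].append(str(p))
    p = outdir / "truth_conserved_offset.tsv"
    with open(p, "w") as fh:
        fh.write("orthogroup\tconserved_offset\toutlier_sign\n")
        for og in sorted(study.truth.conserved_offset):
            sign = study.truth.outlier_orthogroups.get(og, 0)
            fh.write(f"{og}\t{study.truth.conserved_offset[og]!r}\t{sign}\n")
    written["truth"].append(str(p))
    return written
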