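"""End-to-end pipeline orchestration.

Stages run in order preprocess -> correlation -> essential -> outliers ->
rtp (leave-one-out + randomized null); stages whose inputs are absent are
skipped and noted in the manifest. Every stage writes a TSV; the summary
JSON is assembled from those TSVs without recomputation. A single global
seed fans out to per-stage seeds derived by hashing the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (
    compare_protein_vs_mrna_conservation,
    fit_r_squared,
    pairwise_ortholog_matrix,
    spearman,
)
from .errors import ConfigError, UndefinedCorrelationError
from .essential import abundance_and_sd_contrast, partition_by_essentiality
from .io_tables import (
    OrthologMap,
    read_abundance_table,
    read_gene_list,
    read_orthogroups,
)
from .outliers import (
    conserved_ranking,
    fit_ptr_regression,
    outlier_count_table,
    standardized_residuals,
)
from .preprocess import preprocess_condition, protein_scale
from .rtp import leave_one_out, randomized_rtp, shared_ortholog_scope
from .synthetic import SyntheticConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    input_checksums: dict[str, str]
    outputs: dict[str, str]
    skipped: list[str]
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def derive_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    if ("synthetic" in cfg) == ("data" in cfg):
        raise ConfigError(f"{path}: exactly one of 'synthetic' or 'data' is required")
    if "data" in cfg:
        data = cfg["data"]
        if "conditions" not in data or not data["conditions"]:
            raise ConfigError(f"{path}: data.conditions must be a non-empty list")
        for entry in data["conditions"]:
            for key in ("id", "mrna", "protein"):
                if key not in entry:
                    raise ConfigError(f"{path}: data.conditions entry missing {key!r}")
        if "orthogroups" not in data:
            raise ConfigError(f"{path}: data.orthogroups is required")
    return cfg


def _load_inputs(cfg: dict, seed: int):
    """Returns (mrna tables, protein tables, orthomap, essential lists, checksums)."""
    checksums: dict[str, str] = {}
    if "synthetic" in cfg:
        params = dict(cfg["synthetic"] or {})
        params.setdefault("seed", derive_seed(seed, "synthetic"))
        study = generate_study(SyntheticConfig(**params))
        return study.mrna, study.protein, study.orthomap, study.essential, checksums
    data = cfg["data"]
    conds = [str(e["id"]) for e in data["conditions"]]
    mrna, protein, essential = {}, {}, {}
    for entry in data["conditions"]:
        cond = str(entry["id"])
        for key, store, modality in (("mrna", mrna, "mrna"), ("protein", protein, "protein")):
            p = Path(entry[key])
            if not p.exists():
                raise ConfigError(f"missing input file {p}")
            checksums[str(p)] = _sha256(p)
            store[cond] = read_abundance_table(p, cond, modality)
        if "essential" in entry:
            p = Path(entry["essential"])
            if not p.exists():
                raise ConfigError(f"missing input file {p}")
            checksums[str(p)] = _sha256(p)
            essential[cond] = read_gene_list(p)
    og_path = Path(data["orthogroups"])
    if not og_path.exists():
        raise ConfigError(f"missing input file {og_path}")
    checksums[str(og_path)] = _sha256(og_path)
    omap = read_orthogroups(og_path, conds)
    return mrna, protein, omap, essential, checksums


def run_pipeline(config: dict | str | Path, outdir: str | Path, seed: int = 0) -> RunManifest:
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()
    stage_seeds = {s: derive_seed(seed, s) for s in
                   ("synthetic", "essential", "null")}
    outputs: dict[str, str] = {}
    skipped: list[str] = []
    summary: dict = {"seed": seed, "version": __version__}

    mrna_raw, protein_raw, omap, essential_lists, checksums = _load_inputs(config, seed)
    conds = list(mrna_raw)
    opts = config.get("options", {}) or {}

    # ---- preprocess ----
    scaled = dict(zip(protein_raw, protein_scale(list(protein_raw.values()))))
    pairs = {}
    detection_rows = []
    for cond in conds:
        _, _, pair, removed = preprocess_condition(
            mrna_raw[cond], scaled[cond],
            hotspot_threshold=float(opts.get("hotspot_threshold", 1e5)),
            min_protein_replicates=opts.get("min_protein_replicates"),
        )
        pairs[cond] = pair
        detection_rows.append({
            "condition": cond,
            "n_genes": mrna_raw[cond].n_genes,
            "n_paired": pair.n_genes,
            "paired_fraction": pair.n_genes / mrna_raw[cond].n_genes,
            "hotspots_removed": len(removed),
        })
    detection = pd.DataFrame(detection_rows)
    path = outdir / "detection.tsv"
    detection.to_csv(path, sep="\t", index=False)
    outputs["detection"] = str(path)

    # ---- per-condition correlation ----
    corr_rows = []
    for cond, pair in pairs.items():
        try:
            rho = spearman(pair.mrna, pair.protein).rho
            r2 = fit_r_squared(pair.mrna, pair.protein).r_squared
        except UndefinedCorrelationError:
            rho, r2 = float("nan"), float("nan")
        corr_rows.append({"condition": cond, "n": pair.n_genes,
                          "spearman_rho": rho, "r_squared": r2})
    corr = pd.DataFrame(corr_rows)
    path = outdir / "correlations.tsv"
    corr.to_csv(path, sep="\t", index=False)
    outputs["correlations"] = str(path)

    # ---- pairwise ortholog matrices ----
    if len(conds) >= 2:
        counts_m, rho_m = pairwise_ortholog_matrix(pairs, omap, "mrna")
        _, rho_p = pairwise_ortholog_matrix(pairs, omap, "protein")
        counts_m.values.to_csv(outdir / "pair_counts.tsv", sep="\t")
        rho_m.values.to_csv(outdir / "pair_rho_mrna.tsv", sep="\t")
        rho_p.values.to_csv(outdir / "pair_rho_protein.tsv", sep="\t")
        outputs["pair_counts"] = str(outdir / "pair_counts.tsv")
        outputs["pair_rho_mrna"] = str(outdir / "pair_rho_mrna.tsv")
        outputs["pair_rho_protein"] = str(outdir / "pair_rho_protein.tsv")
        wins, test = compare_protein_vs_mrna_conservation(rho_m, rho_p)
        conservation = pd.DataFrame([{
            "wins": wins,
            "n_pairs": len(rho_m.off_diagonal_pairs()),
            "signed_rank_p": test.p_value,
        }])
        path = outdir / "conservation_test.tsv"
        conservation.to_csv(path, sep="\t", index=False)
        outputs["conservation_test"] = str(path)
    else:
        skipped.append("pairwise")

    # ---- essential contrasts ----
    if essential_lists:
        ess_rows = []
        for cond, ids in essential_lists.items():
            part = partition_by_essentiality(pairs[cond], ids)
            if part.n_essential < 3 or part.n_non_essential < 3:
                continue
            contrast = abundance_and_sd_contrast(pairs[cond], part)
            ess_rows.append({
                "condition": cond,
                "n_essential": contrast.n_essential,
                "n_non_essential": contrast.n_non_essential,
                "rho_essential": contrast.rho_essential,
                "rho_non_essential": contrast.rho_non_essential,
                "mrna_abundance_p": contrast.abundance_p["mrna"],
                "protein_abundance_p": contrast.abundance_p["protein"],
                "mrna_sd_p": contrast.sd_p["mrna"],
                "protein_sd_p": contrast.sd_p["protein"],
            })
        if ess_rows:
            path = outdir / "essential_contrast.tsv"
            pd.DataFrame(ess_rows).to_csv(path, sep="\t", index=False)
            outputs["essential_contrast"] = str(path)
        else:
            skipped.append("essential")
    else:
        skipped.append("essential")

    # ---- outliers ----
    records = {}
    for cond, pair in pairs.items():
        model = fit_ptr_regression(pair)
        records[cond] = standardized_residuals(model, pair, omap)
        rows = pd.DataFrame(
            [{"gene_id": r.gene_id, "ptr": r.ptr, "z": r.z, "class": r.klass,
              "orthogroup": r.orthogroup or ""} for r in records[cond]]
        )
        rows.to_csv(outdir / f"outliers_{cond}.tsv", sep="\t", index=False)
    counts = outlier_count_table(records)
    path = outdir / "outlier_counts.tsv"
    counts.to_csv(path, sep="\t", index_label="condition")
    outputs["outlier_counts"] = str(path)

    # conserved ranking: the archaeal (last, 9th) condition is excluded by default
    ranking_conds = conds[:8] if len(conds) == 9 else conds
    if len(ranking_conds) >= 2:
        ranking = conserved_ranking(records, omap, conditions=ranking_conds)
        ranking.z_matrix.to_csv(outdir / "conserved_z.tsv", sep="\t", index_label="orthogroup")
        ranking.ptr_matrix.to_csv(outdir / "conserved_ptr.tsv", sep="\t",
                                  index_label="orthogroup")
        outputs["conserved_z"] = str(outdir / "conserved_z.tsv")
        outputs["conserved_ptr"] = str(outdir / "conserved_ptr.tsv")
        top_bottom = pd.DataFrame({
            "rank": list(range(1, len(ranking.top) + 1)),
            "top": ranking.top,
            "bottom": ranking.bottom + [""] * (len(ranking.top) - len(ranking.bottom)),
        })
        path = outdir / "conserved_top_bottom.tsv"
        top_bottom.to_csv(path, sep="\t", index=False)
        outputs["conserved_top_bottom"] = str(path)
    else:
        skipped.append("conserved_ranking")

    # ---- rtp: leave-one-out + randomized null ----
    loo_conds = ranking_conds
    if len(loo_conds) >= 2:
        scope = shared_ortholog_scope(pairs, omap, loo_conds)
        loo_pairs = {c: pairs[c] for c in loo_conds}
        results, test = leave_one_out(loo_pairs, omap, gene_scope=scope)
        loo_df = pd.DataFrame([{
            "condition": r.condition_id, "n": r.n,
            "rho_before": r.rho_before, "rho_after": r.rho_after, "delta": r.delta,
        } for r in results])
        path = outdir / "loo.tsv"
        loo_df.to_csv(path, sep="\t", index=False)
        outputs["loo"] = str(path)
        loo_test = pd.DataFrame([{"signed_rank_p": test.p_value, "n": test.n}])
        path = outdir / "loo_test.tsv"
        loo_test.to_csv(path, sep="\t", index=False)
        outputs["loo_test"] = str(path)

        n_draws = int(opts.get("null_draws", 200))
        if n_draws > 0 and scope:
            target = loo_conds[0]
            null_results = randomized_rtp(
                loo_pairs, omap, scope, target,
                n_draws=n_draws, seed=stage_seeds["null"],
            )
            null_df = pd.DataFrame([{
                "draw": i, "rho_before": r.rho_before,
                "rho_after": r.rho_after, "delta": r.delta,
            } for i, r in enumerate(null_results)])
            path = outdir / "null_deltas.tsv"
            null_df.to_csv(path, sep="\t", index=False)
            outputs["null_deltas"] = str(path)
    else:
        skipped.append("rtp")

    # ---- summary assembled from stage TSVs only ----
    summary["conditions"] = conds
    summary["correlations"] = pd.read_csv(outputs["correlations"], sep="\t").to_dict("records")
    summary["detection"] = pd.read_csv(outputs["detection"], sep="\t").to_dict("records")
    summary["outlier_counts"] = (
        pd.read_csv(outputs["outlier_counts"], sep="\t").to_dict("records")
    )
    if "conservation_test" in outputs:
        summary["conservation_test"] = (
            pd.read_csv(outputs["conservation_test"], sep="\t").to_dict("records")[0]
        )
    if "loo" in outputs:
        summary["loo"] = pd.read_csv(outputs["loo"], sep="\t").to_dict("records")
        summary["loo_signed_rank_p"] = float(
            pd.read_csv(outputs["loo_test"], sep="\t")["signed_rank_p"][0]
        )
    if "essential_contrast" in outputs:
        summary["essential_contrast"] = (
            pd.read_csv(outputs["essential_contrast"], sep="\t").to_dict("records")
        )
    summary["skipped"] = skipped
    path = outdir / "summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    outputs["summary"] = str(path)

    manifest = RunManifest(config_hash, seed, stage_seeds, checksums, outputs, skipped)
    (outdir / "manifest.json").write_text(manifest.to_json())
    return manifest
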