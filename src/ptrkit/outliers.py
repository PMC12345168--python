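"""Genome-wide log2 protein ~ mRNA regression and ptr-outlier detection.

A per-condition OLS fit of protein on mRNA (both log2) yields
standardized residuals z = residual / s with s^2 = SSE/(n-2); genes with
z >= 2 are "high ptr" (more protein than the genome-wide trend predicts)
and z <= -2 are "low ptr". Cross-condition conserved outliers are ranked
by the mean of per-condition z values clipped at +/-2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FitError
from .io_tables import OrthologMap
from .preprocess import ProfilePair

HIGH_THRESHOLD = 2.0
LOW_THRESHOLD = -2.0


@dataclass
class PtrRegression:
    condition_id: str
    slope: float
    intercept: float
    resid_scale: float  # s, with s^2 = SSE / (n - 2)
    n: int


@dataclass
class OutlierRecord:
    gene_id: str
    ptr: float  # log2(P) - log2(R)
    z: float  # standardized residual
    klass: str  # "high" | "low" | "none"
    orthogroup: str | None = None


@dataclass
class ConservedOutlierRanking:
    z_matrix: pd.DataFrame  # orthogroup x condition standardized residuals
    ptr_matrix: pd.DataFrame
    mean_clipped_z: pd.Series  # sorted descending (ties broken by orthogroup ID)
    top: list[str]
    bottom: list[str]
    excluded: list[str]  # orthogroups lacking a z in some requested condition
    clip: float
    k: int


def classify(z: float) -> str:
    if z >= HIGH_THRESHOLD:
        return "high"
    if z <= LOW_THRESHOLD:
        return "low"
    return "none"


def fit_ptr_regression(pair: ProfilePair) -> PtrRegression:
    """Closed-form OLS of P on R; s^2 = SSE/(n-2)."""
    r, p = pair.mrna, pair.protein
    n = r.size
    if n < 3:
        raise FitError(f"{pair.condition_id}: need >= 3 paired genes, got {n}")
    r_mean = r.mean()
    var = float(((r - r_mean) ** 2).sum())
    if var == 0:
        raise FitError(f"{pair.condition_id}: zero mRNA variance")
    slope = float(((r - r_mean) * (p - p.mean())).sum()) / var
    intercept = float(p.mean() - slope * r_mean)
    sse = float(((p - (intercept + slope * r)) ** 2).sum())
    s = float(np.sqrt(max(sse, 0.0) / (n - 2)))
    return PtrRegression(pair.condition_id, slope, intercept, s, n)


def standardized_residuals(
    model: PtrRegression, pair: ProfilePair, omap: OrthologMap | None = None
) -> list[OutlierRecord]:
    """Per-gene standardized residuals and high/low/none classification."""
    resid = pair.protein - (model.intercept + model.slope * pair.mrna)
    if model.resid_scale == 0:
        z = np.zeros_like(resid)  # perfect fit: all residuals are zero
    else:
        z = resid / model.resid_scale
    records = []
    for gene, ptr_val, z_val in zip(pair.gene_ids, pair.ptr, z):
        og = omap.group_of(gene, pair.condition_id) if omap is not None else None
        records.append(OutlierRecord(gene, float(ptr_val), float(z_val),
                                     classify(float(z_val)), og))
    return records


def count_outlier_classes(records: list[OutlierRecord]) -> dict[str, int]:
    """Counts of low/high ptr genes, excluding the unclassified bulk."""
    low = sum(1 for r in records if r.klass == "low")
    high = sum(1 for r in records if r.klass == "high")
    return {"low": low, "high": high}


def outlier_count_table(records_by_condition: dict[str, list[OutlierRecord]]) -> pd.DataFrame:
    rows = {cond: count_outlier_classes(records)
            for cond, records in records_by_condition.items()}
    return pd.DataFrame.from_dict(rows, orient="index")[["low", "high"]]


def conserved_ranking(
    records_by_condition: dict[str, list[OutlierRecord]],
    omap: OrthologMap,
    conditions: list[str] | None = None,
    clip: float = 2.0,
    k: int = 15,
) -> ConservedOutlierRanking:
    """Rank orthogroups by mean clipped standardized residual.

    Restricted to single-copy orthogroups covered by every requested
    condition; orthogroups without a z in some condition (e.g. the gene
    failed detection) are excluded and reported. Ties in the mean are
    broken by orthogroup ID for determinism.
    """
    if conditions is None:
        conditions = list(records_by_condition)
    missing = [c for c in conditions if c not in records_by_condition]
    if missing:
        raise ValueError(f"no outlier records for condition(s) {missing}")

    scope = omap.single_copy_groups(conditions)
    z_by_cond: dict[str, dict[str, tuple[float, float]]] = {}
    for cond in conditions:
        per_og = {}
        for rec in records_by_condition[cond]:
            og = rec.orthogroup or omap.group_of(rec.gene_id, cond)
            if og is not None:
                per_og[og] = (rec.z, rec.ptr)
        z_by_cond[cond] = per_og

    rows_z, rows_ptr, kept, excluded = [], [], [], []
    for og in scope:
        zs, ptrs = [], []
        for cond in conditions:
            entry = z_by_cond[cond].get(og)
            if entry is None:
                break
            zs.append(entry[0])
            ptrs.append(entry[1])
        else:
            kept.append(og)
            rows_z.append(zs)
            rows_ptr.append(ptrs)
            continue
        excluded.append(og)

    z_matrix = pd.DataFrame(rows_z, index=kept, columns=conditions)
    ptr_matrix = pd.DataFrame(rows_ptr, index=kept, columns=conditions)
    clipped = z_matrix.clip(lower=-clip, upper=clip)
    mean_z = clipped.mean(axis=1)
    order = sorted(mean_z.index, key=lambda og: (-mean_z[og], og))
    mean_z = mean_z.loc[order]
    top = order[:k]
    bottom = list(reversed(order[-k:])) if len(order) >= k else list(reversed(order))
    return ConservedOutlierRanking(
        z_matrix.loc[order], ptr_matrix.loc[order], mean_z,
        top, bottom, excluded, clip, k,
    )
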