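"""Normalization, detection filtering, and log2 expression profiles.

mRNA counts go through a PCR-hotspot filter (mean raw count above a
threshold) and reads-per-million normalization. Protein tables are put on
a common scale by dividing each condition by the ratio of its total
abundance to the cross-condition median total. Replicates are aggregated
as log2 of the mean normalized linear abundance; per-gene replicate SDs
are computed on the log2 of positive replicate values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NormalizationError, PairingError
from .io_tables import AbundanceTable

DEFAULT_HOTSPOT_THRESHOLD = 100_000.0  # mean raw reads; strictly greater is removed


@dataclass
class ExpressionProfile:
    """Per-gene log2 normalized abundance for detected genes of one modality."""

    condition_id: str
    modality: str
    gene_ids: list[str]
    log2_abundance: np.ndarray
    replicate_sd: np.ndarray  # SD of log2 over positive replicates; NaN if < 2 positive

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.gene_ids, self.log2_abundance.tolist()))


@dataclass
class ProfilePair:
    """Genes detected in both modalities of one condition, aligned."""

    condition_id: str
    gene_ids: list[str]
    mrna: np.ndarray  # R_ij
    protein: np.ndarray  # P_ij
    mrna_sd: np.ndarray
    protein_sd: np.ndarray

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def ptr(self) -> np.ndarray:
        """Per-gene log2 protein-to-mRNA ratio P_ij - R_ij."""
        return self.protein - self.mrna


def rpm_normalize(table: AbundanceTable) -> AbundanceTable:
    """Reads-per-million normalization of an mRNA count table."""
    if table.modality != "mrna":
        raise NormalizationError(f"rpm_normalize expects mRNA, got {table.modality}")
    totals = table.values.sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise NormalizationError(
            f"condition {table.condition_id}: zero total in replicate "
            f"{table.replicate_ids[zero[0]]!r}"
        )
    values = table.values / totals * 1e6
    return AbundanceTable(table.condition_id, table.modality, list(table.gene_ids),
                          values, list(table.replicate_ids))


def hotspot_filter(
    table: AbundanceTable, threshold: float = DEFAULT_HOTSPOT_THRESHOLD
) -> tuple[AbundanceTable, list[str]]:
    """Remove genes whose mean raw count strictly exceeds ``threshold``.

    Applied to raw counts before RPM normalization.
    """
    means = table.values.mean(axis=1)
    keep = means <= threshold
    removed = [g for g, k in zip(table.gene_ids, keep) if not k]
    if not removed:
        return table, []
    filtered = AbundanceTable(
        table.condition_id,
        table.modality,
        [g for g, k in zip(table.gene_ids, keep) if k],
        table.values[keep],
        list(table.replicate_ids),
    )
    return filtered, removed


def protein_scale(tables: list[AbundanceTable]) -> list[AbundanceTable]:
    """Scale each protein table by total abundance / cross-condition median total.

    After scaling every condition's total equals the original median total,
    so the operation is idempotent.
    """
    if not tables:
        raise ValueError("no tables supplied")
    totals = np.array([t.values.sum() for t in tables])
    if np.any(totals == 0):
        bad = tables[int(np.flatnonzero(totals == 0)[0])].condition_id
        raise NormalizationError(f"condition {bad}: zero total protein abundance")
    median = float(np.median(totals))
    out = []
    for t, total in zip(tables, totals):
        factor = total / median
        out.append(AbundanceTable(t.condition_id, t.modality, list(t.gene_ids),
                                  t.values / factor, list(t.replicate_ids)))
    return out


def _log2_replicate_sd(values: np.ndarray) -> np.ndarray:
    """SD over replicates of log2(abundance), using positive replicates only."""
    n_genes = values.shape[0]
    sd = np.full(n_genes, np.nan)
    positive = values > 0
    counts = positive.sum(axis=1)
    with np.errstate(divide="ignore"):
        logs = np.where(positive, np.log2(np.where(positive, values, 1.0)), np.nan)
    ok = counts >= 2
    if ok.any():
        sd[ok] = np.nanstd(logs[ok], axis=1, ddof=1)
    return sd


def aggregate_and_filter(
    mrna: AbundanceTable,
    protein: AbundanceTable,
    min_protein_replicates: int | None = None,
) -> tuple[ExpressionProfile, ExpressionProfile, ProfilePair]:
    """Apply detection rules and aggregate replicates into log2 profiles.

    A protein is detected when its abundance is > 0 in at least
    ``min_protein_replicates`` replicates (default: all of them). An mRNA
    is detected when its mean normalized abundance is > 0. The paired set
    is the intersection. No pseudocounts are used anywhere.
    """
    if mrna.condition_id != protein.condition_id:
        raise PairingError(
            f"condition mismatch: {mrna.condition_id!r} vs {protein.condition_id!r}"
        )
    if min_protein_replicates is None:
        min_protein_replicates = protein.n_replicates

    mrna_mean = mrna.values.mean(axis=1)
    mrna_detected = mrna_mean > 0
    with np.errstate(divide="ignore"):
        mrna_log2 = np.where(mrna_detected, np.log2(np.where(mrna_detected, mrna_mean, 1.0)), np.nan)
    mrna_sd = _log2_replicate_sd(mrna.values)

    prot_positive = (protein.values > 0).sum(axis=1)
    prot_detected = prot_positive >= min_protein_replicates
    prot_mean = protein.values.mean(axis=1)
    with np.errstate(divide="ignore"):
        prot_log2 = np.where(prot_detected, np.log2(np.where(prot_mean > 0, prot_mean, 1.0)), np.nan)
    prot_sd = _log2_replicate_sd(protein.values)

    mrna_profile = ExpressionProfile(
        mrna.condition_id, "mrna",
        [g for g, d in zip(mrna.gene_ids, mrna_detected) if d],
        mrna_log2[mrna_detected], mrna_sd[mrna_detected],
    )
    prot_profile = ExpressionProfile(
        protein.condition_id, "protein",
        [g for g, d in zip(protein.gene_ids, prot_detected) if d],
        prot_log2[prot_detected], prot_sd[prot_detected],
    )

    prot_index = {g: i for i, g in enumerate(protein.gene_ids)}
    paired_ids, r_vals, p_vals, r_sds, p_sds = [], [], [], [], []
    for i, g in enumerate(mrna.gene_ids):
        if not mrna_detected[i]:
            continue
        j = prot_index.get(g)
        if j is None or not prot_detected[j]:
            continue
        paired_ids.append(g)
        r_vals.append(mrna_log2[i])
        p_vals.append(prot_log2[j])
        r_sds.append(mrna_sd[i])
        p_sds.append(prot_sd[j])

    pair = ProfilePair(
        mrna.condition_id, paired_ids,
        np.asarray(r_vals), np.asarray(p_vals),
        np.asarray(r_sds), np.asarray(p_sds),
    )
    return mrna_profile, prot_profile, pair


def preprocess_condition(
    mrna_raw: AbundanceTable,
    protein_scaled: AbundanceTable,
    hotspot_threshold: float = DEFAULT_HOTSPOT_THRESHOLD,
    min_protein_replicates: int | None = None,
) -> tuple[ExpressionProfile, ExpressionProfile, ProfilePair, list[str]]:
    """Full per-condition path: hotspot filter -> RPM -> detection/aggregation.

    ``protein_scaled`` should already be on the common cross-condition scale
    (see :func:`protein_scale`). Returns the removed hotspot gene IDs too.
    """
    filtered, removed = hotspot_filter(mrna_raw, hotspot_threshold)
    rpm = rpm_normalize(filtered)
    mrna_profile, prot_profile, pair = aggregate_and_filter(
        rpm, protein_scaled, min_protein_replicates
    )
    return mrna_profile, prot_profile, pair, removed
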