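"""Gene-specific RNA-to-protein (RTP) conversion factors.

A factor for orthogroup j is the mean log2 protein-minus-mRNA difference
over the training conditions; predicted protein is that factor added to
the target's mRNA. Leave-one-out validation trains on N-1 conditions and
evaluates on the held-out one; the randomized (k = h) null rebuilds
factors from randomly chosen non-orthologous genes' own paired ptr
values. Improvement is judged by Spearman rho before vs after, with the
exact paired signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import spearman
from .errors import SamplingError, UndefinedCorrelationError
from .io_tables import OrthologMap
from .preprocess import ProfilePair
from .stats import SignedRankResult, signed_rank_test


@dataclass
class RtpFactorSet:
    factors: dict[str, float]  # orthogroup -> mean log2 (P - R) over training conditions
    training_conditions: list[str]
    n_training: int
    excluded: list[str] = field(default_factory=list)  # orthogroups missing somewhere

    def __len__(self) -> int:
        return len(self.factors)


@dataclass
class EvaluationResult:
    condition_id: str
    n: int
    rho_before: float  # Spearman(R, P_obs)
    rho_after: float  # Spearman(P_pred, P_obs)

    @property
    def delta(self) -> float:
        return self.rho_after - self.rho_before


def _paired_ortholog_values(
    pair: ProfilePair, omap: OrthologMap
) -> dict[str, tuple[float, float]]:
    """orthogroup -> (R, P) for single-copy orthogroups in the paired set."""
    out: dict[str, tuple[float, float]] = {}
    for g, r, p in zip(pair.gene_ids, pair.mrna, pair.protein):
        og = omap.group_of(g, pair.condition_id)
        if og is not None and omap.single_copy(og, pair.condition_id):
            out[og] = (float(r), float(p))
    return out


def shared_ortholog_scope(
    pairs: dict[str, ProfilePair], omap: OrthologMap, conditions=None
) -> list[str]:
    """Single-copy orthogroups paired-detected in every listed condition."""
    conds = list(conditions) if conditions is not None else list(pairs)
    sets = []
    for cond in conds:
        sets.append(set(_paired_ortholog_values(pairs[cond], omap)))
    return sorted(set.intersection(*sets)) if sets else []


def compute_rtp(
    pairs: dict[str, ProfilePair],
    omap: OrthologMap,
    gene_scope=None,
) -> RtpFactorSet:
    """factor_j = mean over training conditions of (P_ij - R_ij).

    Orthogroups missing (not single-copy or not paired-detected) in any
    training condition are excluded with a report, never imputed.
    """
    if not pairs:
        raise ValueError("no training conditions supplied")
    training = list(pairs)
    values = {cond: _paired_ortholog_values(pairs[cond], omap) for cond in training}
    if gene_scope is None:
        scope = sorted(set.intersection(*(set(v) for v in values.values())))
        excluded: list[str] = []
    else:
        scope, excluded = [], []
        for og in sorted(gene_scope):
            if all(og in values[cond] for cond in training):
                scope.append(og)
            else:
                excluded.append(og)
    factors = {}
    for og in scope:
        diffs = [values[cond][og][1] - values[cond][og][0] for cond in training]
        factors[og] = float(np.mean(diffs))
    return RtpFactorSet(factors, training, len(training), excluded)


def predict_protein(
    factors: RtpFactorSet, target: ProfilePair, omap: OrthologMap
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """P_pred = factor_j + R_target per orthogroup.

    Restricted to orthogroups with a factor whose target gene is in the
    target's paired set; returns (orthogroups, R, P_pred, P_obs).
    """
    target_values = _paired_ortholog_values(target, omap)
    ogs = sorted(set(factors.factors) & set(target_values))
    r = np.array([target_values[og][0] for og in ogs])
    p_obs = np.array([target_values[og][1] for og in ogs])
    p_pred = np.array([factors.factors[og] for og in ogs]) + r
    return ogs, r, p_pred, p_obs


def evaluate_correction(
    target: ProfilePair, factors: RtpFactorSet, omap: OrthologMap
) -> EvaluationResult:
    """rho_before = Spearman(R, P_obs); rho_after = Spearman(P_pred, P_obs),
    both over the identical gene set."""
    ogs, r, p_pred, p_obs = predict_protein(factors, target, omap)
    if len(ogs) < 3:
        return EvaluationResult(target.condition_id, len(ogs), float("nan"), float("nan"))
    rho_before = spearman(r, p_obs).rho
    rho_after = spearman(p_pred, p_obs).rho
    return EvaluationResult(target.condition_id, len(ogs), rho_before, rho_after)


def leave_one_out(
    pairs: dict[str, ProfilePair],
    omap: OrthologMap,
    gene_scope=None,
    conditions=None,
) -> tuple[list[EvaluationResult], SignedRankResult]:
    """Leave-one-out factor transfer across conditions.

    For each condition, factors are computed from the remaining ones and
    evaluated on it; improvements are aggregated with the one-sided exact
    signed-rank test (after > before).
    """
    conds = list(conditions) if conditions is not None else list(pairs)
    if len(conds) < 2:
        raise ValueError("need >= 2 conditions for leave-one-out")
    if gene_scope is None:
        gene_scope = shared_ortholog_scope(pairs, omap, conds)
    if not gene_scope:
        raise SamplingError(f"no shared orthologs across conditions {conds}")
    results = []
    for held_out in conds:
        training = {c: pairs[c] for c in conds if c != held_out}
        factors = compute_rtp(training, omap, gene_scope=gene_scope)
        results.append(evaluate_correction(pairs[held_out], factors, omap))
    finite = [res for res in results if np.isfinite(res.delta)]
    if finite:
        test = signed_rank_test(
            [res.rho_before for res in finite],
            [res.rho_after for res in finite],
            alternative="greater",
        )
    else:
        test = SignedRankResult(float("nan"), float("nan"), 0, "greater", degenerate=True)
    return results, test


def randomized_rtp(
    pairs: dict[str, ProfilePair],
    omap: OrthologMap,
    gene_scope,
    target: str,
    training_conditions=None,
    n_draws: int = 200,
    seed: int = 0,
) -> list[EvaluationResult]:
    """Randomized (k = h) null: per draw, each (gene j, condition i) factor
    contribution is the paired ptr of a uniformly chosen non-orthologous
    gene, preserving biologically plausible ptr magnitudes."""
    training = (list(training_conditions) if training_conditions is not None
                else [c for c in pairs if c != target])
    if not training:
        raise ValueError("no training conditions")
    scope = sorted(gene_scope)
    if not scope:
        raise SamplingError("empty gene scope")

    # per training condition: ptr values of paired genes outside any orthogroup
    pools = {}
    for cond in training:
        pair = pairs[cond]
        mask = np.array([omap.group_of(g, cond) is None for g in pair.gene_ids])
        if not mask.any():
            raise SamplingError(f"condition {cond}: no non-orthologous paired genes")
        pools[cond] = pair.ptr[mask]

    target_values = _paired_ortholog_values(pairs[target], omap)
    ogs = [og for og in scope if og in target_values]
    if len(ogs) < 3:
        raise SamplingError(f"target {target}: fewer than 3 scoped orthologs")
    r = np.array([target_values[og][0] for og in ogs])
    p_obs = np.array([target_values[og][1] for og in ogs])
    try:
        rho_before = spearman(r, p_obs).rho
    except UndefinedCorrelationError:
        rho_before = float("nan")

    rng = np.random.default_rng(seed)
    results = []
    for _ in range(n_draws):
        contrib = np.empty((len(ogs), len(training)))
        for t, cond in enumerate(training):
            pool = pools[cond]
            contrib[:, t] = pool[rng.integers(0, pool.size, size=len(ogs))]
        p_pred = contrib.mean(axis=1) + r
        rho_after = spearman(p_pred, p_obs).rho
        results.append(EvaluationResult(target, len(ogs), rho_before, rho_after))
    return results
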