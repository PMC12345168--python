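"""Rank/linear correlation, binned scatter summaries, and pairwise
cross-condition ortholog correlation matrices."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import FitError, UndefinedCorrelationError
from .io_tables import OrthologMap
from .preprocess import ProfilePair
from .stats import SignedRankResult, signed_rank_test


@dataclass
class CorrelationResult:
    rho: float
    method: str  # "spearman" | "pearson"
    n: int
    r_squared: float | None = None


@dataclass
class PairMatrix:
    """Symmetric condition-by-condition matrix (ortholog counts or rho)."""

    labels: list[str]
    values: pd.DataFrame
    modality: str
    kind: str  # "counts" | "rho"

    def off_diagonal_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for i, a in enumerate(self.labels) for b in self.labels[i + 1:]]


def _check_vectors(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError(f"need >= 3 points, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")


def spearman(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of average ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_vectors(x, y)
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise UndefinedCorrelationError("zero variance in ranks")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    return CorrelationResult(rho, "spearman", x.size)


def fit_r_squared(x, y) -> CorrelationResult:
    """OLS of y on x; reports Pearson rho and R^2 = 1 - SSE/SST."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    _check_vectors(x, y)
    if np.ptp(x) == 0:
        raise FitError("zero variance in x")
    res = sps.linregress(x, y)
    return CorrelationResult(float(res.rvalue), "pearson", x.size,
                             r_squared=float(res.rvalue**2))


def binned_scatter(x, y, x_edges, y_edges) -> np.ndarray:
    """2-D histogram of (x, y); points outside the edges are clipped to the
    boundary bins so the grid total always equals n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    y_edges = np.asarray(y_edges, dtype=float)
    for edges, name in ((x_edges, "x_edges"), (y_edges, "y_edges")):
        if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
            raise ValueError(f"{name} must be strictly increasing with >= 2 entries")
    eps_x = (x_edges[-1] - x_edges[0]) * 1e-12
    eps_y = (y_edges[-1] - y_edges[0]) * 1e-12
    xc = np.clip(x, x_edges[0], x_edges[-1] - eps_x)
    yc = np.clip(y, y_edges[0], y_edges[-1] - eps_y)
    grid, _, _ = np.histogram2d(xc, yc, bins=[x_edges, y_edges])
    return grid


def pairwise_ortholog_matrix(
    pairs: dict[str, ProfilePair],
    omap: OrthologMap,
    modality: str,
) -> tuple[PairMatrix, PairMatrix]:
    """Pairwise ortholog counts and Spearman rho between conditions.

    For each condition pair the comparison is restricted to single-copy
    orthogroups whose gene is in the *paired* (mRNA+protein detected) set
    of both conditions. Pairs with < 3 shared orthologs get NaN rho.
    """
    if len(pairs) < 2:
        raise ValueError("need >= 2 conditions")
    if modality not in ("mrna", "protein"):
        raise ValueError(f"unknown modality {modality!r}")
    labels = list(pairs)
    values: dict[str, dict[str, float]] = {}
    gene_values: dict[str, dict[str, float]] = {}
    for cond, pair in pairs.items():
        vec = pair.mrna if modality == "mrna" else pair.protein
        per_og: dict[str, float] = {}
        for g, v in zip(pair.gene_ids, vec):
            og = omap.group_of(g, cond)
            if og is not None and omap.single_copy(og, cond):
                per_og[og] = float(v)
        gene_values[cond] = per_og

    n = len(labels)
    counts = np.zeros((n, n))
    rho = np.full((n, n), np.nan)
    np.fill_diagonal(rho, 1.0)
    for i, a in enumerate(labels):
        counts[i, i] = len(gene_values[a])
        for j in range(i + 1, n):
            b = labels[j]
            shared = sorted(set(gene_values[a]) & set(gene_values[b]))
            counts[i, j] = counts[j, i] = len(shared)
            if len(shared) >= 3:
                va = np.array([gene_values[a][og] for og in shared])
                vb = np.array([gene_values[b][og] for og in shared])
                try:
                    rho[i, j] = rho[j, i] = spearman(va, vb).rho
                except UndefinedCorrelationError:
                    pass  # leave NaN marker
    counts_df = pd.DataFrame(counts, index=labels, columns=labels)
    rho_df = pd.DataFrame(rho, index=labels, columns=labels)
    return (PairMatrix(labels, counts_df, modality, "counts"),
            PairMatrix(labels, rho_df, modality, "rho"))


def compare_protein_vs_mrna_conservation(
    rho_mrna: PairMatrix, rho_protein: PairMatrix
) -> tuple[int, SignedRankResult]:
    """Count condition pairs where protein rho exceeds mRNA rho, and test the
    paired differences with the one-sided exact signed-rank test."""
    if rho_mrna.labels != rho_protein.labels:
        raise ValueError("matrices must share condition labels")
    diffs = []
    for a, b in rho_mrna.off_diagonal_pairs():
        dm = rho_mrna.values.loc[a, b]
        dp = rho_protein.values.loc[a, b]
        if np.isfinite(dm) and np.isfinite(dp):
            diffs.append(dp - dm)
    diffs = np.asarray(diffs)
    wins = int((diffs > 0).sum())
    result = signed_rank_test(diffs, alternative="greater")
    return wins, result
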