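"""Essential vs non-essential gene contrasts.

Covers abundance and replicate-SD distribution contrasts (rank-sum
tests), the essential/non-essential correlation split, histogram
summaries with clipped final bins, and an expression-matched control in
which random non-essential subsets are drawn to match the essential mRNA
abundance histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .correlation import spearman
from .errors import MatchingInfeasibleError, UndefinedCorrelationError
from .preprocess import ProfilePair
from .stats import RankSumResult, rank_sum_test

logger = logging.getLogger(__name__)


@dataclass
class EssentialPartition:
    condition_id: str
    essential_idx: np.ndarray  # indices into the paired profile
    non_essential_idx: np.ndarray
    dropped: list[str]  # listed essential IDs absent from the paired set

    @property
    def n_essential(self) -> int:
        return self.essential_idx.size

    @property
    def n_non_essential(self) -> int:
        return self.non_essential_idx.size


@dataclass
class GroupContrast:
    condition_id: str
    n_essential: int
    n_non_essential: int
    median_abundance: dict[str, dict[str, float]]  # modality -> group -> median log2
    abundance_p: dict[str, float]  # modality -> two-sided rank-sum p
    sd_p: dict[str, float]
    rho_essential: float
    rho_non_essential: float
    degenerate: bool = False


@dataclass
class MatchedRhoResult:
    rho_essential: float
    matched_rho: np.ndarray  # one Spearman rho per matched non-essential draw
    quantile: float  # fraction of matched draws below rho_essential; NaN if empty


def partition_by_essentiality(pair: ProfilePair, essential_ids) -> EssentialPartition:
    """Intersect an essential-gene list with the paired set."""
    essential_ids = set(essential_ids)
    in_pair = set(pair.gene_ids)
    dropped = sorted(essential_ids - in_pair)
    mask = np.array([g in essential_ids for g in pair.gene_ids], dtype=bool)
    if dropped:
        logger.warning("%s: %d listed essential gene(s) not in paired set",
                       pair.condition_id, len(dropped))
    if mask.all() and mask.size:
        logger.warning("%s: every paired gene is listed essential", pair.condition_id)
    if essential_ids and not mask.any():
        logger.warning("%s: essential list does not intersect paired set", pair.condition_id)
    return EssentialPartition(
        pair.condition_id,
        np.flatnonzero(mask),
        np.flatnonzero(~mask),
        dropped,
    )


def _safe_spearman(x: np.ndarray, y: np.ndarray) -> float:
    try:
        return spearman(x, y).rho
    except UndefinedCorrelationError:
        return float("nan")


def abundance_and_sd_contrast(pair: ProfilePair, part: EssentialPartition) -> GroupContrast:
    """Two-sided rank-sum contrasts on log2 abundance and replicate SD,
    per modality, plus the essential/non-essential Spearman split."""
    e, ne = part.essential_idx, part.non_essential_idx
    degenerate = e.size < 2 or ne.size < 2
    median_abundance = {"mrna": {}, "protein": {}}
    abundance_p: dict[str, float] = {}
    sd_p: dict[str, float] = {}
    for modality, values, sds in (
        ("mrna", pair.mrna, pair.mrna_sd),
        ("protein", pair.protein, pair.protein_sd),
    ):
        median_abundance[modality]["essential"] = float(np.median(values[e])) if e.size else float("nan")
        median_abundance[modality]["non_essential"] = float(np.median(values[ne])) if ne.size else float("nan")
        if degenerate:
            abundance_p[modality] = float("nan")
            sd_p[modality] = float("nan")
            continue
        abundance_p[modality] = rank_sum_test(values[e], values[ne]).p_value
        se = sds[e][np.isfinite(sds[e])]
        sne = sds[ne][np.isfinite(sds[ne])]
        sd_p[modality] = (rank_sum_test(se, sne).p_value
                          if se.size >= 2 and sne.size >= 2 else float("nan"))
    rho_e = _safe_spearman(pair.mrna[e], pair.protein[e]) if e.size >= 3 else float("nan")
    rho_ne = _safe_spearman(pair.mrna[ne], pair.protein[ne]) if ne.size >= 3 else float("nan")
    return GroupContrast(
        pair.condition_id, e.size, ne.size, median_abundance,
        abundance_p, sd_p, rho_e, rho_ne, degenerate=degenerate,
    )


def histogram_summary(values, bin_size: float, vmin: float | None = None,
                      clip_max: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram with fixed bin size; values above ``clip_max`` accumulate
    in the final bin. Returns (left edges, counts)."""
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return np.array([]), np.array([])
    lo = float(np.floor(values.min() / bin_size) * bin_size) if vmin is None else vmin
    hi = float(values.max()) if clip_max is None else clip_max
    if hi <= lo:
        hi = lo + bin_size
    n_bins = int(np.ceil((hi - lo) / bin_size))
    n_bins = max(n_bins, 1)
    edges = lo + bin_size * np.arange(n_bins + 1)
    clipped = np.clip(values, lo, edges[-1] - bin_size * 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    return edges[:-1], counts


def expression_matched_rho(
    pair: ProfilePair,
    part: EssentialPartition,
    n_iter: int = 1000,
    bin_width: float = 1.0,
    seed: int = 0,
) -> MatchedRhoResult:
    """Compare rho_E against non-essential subsets matched on mRNA abundance.

    For each iteration, non-essential genes are sampled without
    replacement so the sampled mRNA histogram (bins of ``bin_width`` log2
    units) matches the essential histogram exactly per bin.
    """
    e, ne = part.essential_idx, part.non_essential_idx
    if e.size < 3:
        raise UndefinedCorrelationError("need >= 3 essential genes in paired set")
    rho_e = spearman(pair.mrna[e], pair.protein[e]).rho
    if n_iter == 0:
        return MatchedRhoResult(rho_e, np.array([]), float("nan"))

    bins_e = np.floor(pair.mrna[e] / bin_width).astype(int)
    bins_ne = np.floor(pair.mrna[ne] / bin_width).astype(int)
    pool_by_bin: dict[int, np.ndarray] = {
        b: ne[bins_ne == b] for b in np.unique(bins_ne)
    }
    need: dict[int, int] = {int(b): int(c) for b, c in
                            zip(*np.unique(bins_e, return_counts=True))}
    infeasible = [b for b, c in need.items() if len(pool_by_bin.get(b, ())) < c]
    if infeasible:
        raise MatchingInfeasibleError(
            f"{pair.condition_id}: non-essential pool too small in bin(s) "
            f"{sorted(infeasible)} (bin_width={bin_width})",
            bins=sorted(infeasible),
        )
    rng = np.random.default_rng(seed)
    rhos = np.empty(n_iter)
    for it in range(n_iter):
        chosen = np.concatenate([
            rng.choice(pool_by_bin[b], size=c, replace=False) for b, c in need.items()
        ])
        rhos[it] = spearman(pair.mrna[chosen], pair.protein[chosen]).rho
    quantile = float(np.mean(rhos < rho_e))
    return MatchedRhoResult(rho_e, rhos, quantile)
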