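"""Model evaluation: fold construction, AUC, Boyce index, max-SSS threshold.

AUC here is the presence-versus-background ranking statistic (probability
that a random presence outranks a random background point, ties at half
credit).  The continuous Boyce index measures calibration of presence-only
predictions: the Spearman correlation between predicted-to-expected
presence ratios in overlapping suitability windows and the window position.
The max-SSS threshold is the suitability cut-off maximising
sensitivity + specificity, the standard choice for binarising
presence-background model output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import (
    DegenerateBlockError,
    DegenerateThresholdError,
    EvaluationError,
    FoldError,
)
from .grid import GEOGRAPHIC, GridSpec, laea_forward

log = logging.getLogger(__name__)


@dataclass
class FoldAssignment:
    """Fold index (1..k) per cell."""

    cells: np.ndarray  # (n, 2) row/col
    fold: np.ndarray  # (n,) int in 1..k
    k: int
    scheme: str  # "random" | "spatial_block"
    seed: int
    block_size_km: float | None = None

    def in_fold(self, i: int) -> np.ndarray:
        return self.cells[self.fold == i]

    def mapping(self) -> dict[tuple[int, int], int]:
        return {(int(r), int(c)): int(f) for (r, c), f in zip(self.cells, self.fold)}


@dataclass
class EvalReport:
    auc_mean: float
    auc_sd: float
    boyce_mean: float
    boyce_sd: float
    threshold: float
    sens_at_threshold: float
    spec_at_threshold: float
    fold_auc: list[float] = field(default_factory=list)
    fold_boyce: list[float] = field(default_factory=list)
    fold_thresholds: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc_mean": self.auc_mean,
            "auc_sd": self.auc_sd,
            "boyce_mean": self.boyce_mean,
            "boyce_sd": self.boyce_sd,
            "threshold": self.threshold,
            "sens_at_threshold": self.sens_at_threshold,
            "spec_at_threshold": self.spec_at_threshold,
            "fold_auc": self.fold_auc,
            "fold_boyce": self.fold_boyce,
            "fold_thresholds": self.fold_thresholds,
        }


def _as_cells(cells) -> np.ndarray:
    if isinstance(cells, (set, frozenset)):
        cells = sorted(cells)
    return np.asarray(list(cells), dtype=int).reshape(-1, 2)


def random_folds(cells, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Seeded balanced random folds; fold sizes differ by at most one."""
    cells = _as_cells(cells)
    n = cells.shape[0]
    if n < k:
        raise FoldError(f"{n} cells cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold = np.empty(n, dtype=int)
    fold[order] = np.arange(n) % k + 1
    return FoldAssignment(cells=cells, fold=fold, k=k, scheme="random", seed=seed)


def spatial_block_folds(
    cells, grid: GridSpec, block_size_km: float = 300.0, k: int = 5, seed: int = 0
) -> FoldAssignment:
    """Spatial-block folds: square blocks of ``block_size_km``, never split.

    Blocks are assigned largest-first to the fold with the fewest presences
    so far (seeded tie-breaking between equally loaded folds and equally
    sized blocks), which balances presences per fold while keeping each
    block — and the spatial autocorrelation within it — inside one fold.
    """
    cells = _as_cells(cells)
    if grid.crs_id == GEOGRAPHIC:
        lon, lat = grid.rowcol_to_xy(cells[:, 0], cells[:, 1])
        x, y = laea_forward(lon, lat)
        cell_km = grid.dy * 111.195  # nominal; only used for the size check
    else:
        x, y = grid.rowcol_to_xy(cells[:, 0], cells[:, 1])
        cell_km = max(grid.dx, grid.dy)
    if block_size_km <= cell_km:
        raise FoldError(
            f"block size {block_size_km} km must exceed the cell size (~{cell_km:.1f} km)"
        )
    bx = np.floor(np.asarray(x) / block_size_km).astype(int)
    by = np.floor(np.asarray(y) / block_size_km).astype(int)
    block_ids = [(int(a), int(b)) for a, b in zip(bx, by)]
    blocks: dict[tuple[int, int], list[int]] = {}
    for i, bid in enumerate(block_ids):
        blocks.setdefault(bid, []).append(i)
    if len(blocks) == 1:
        raise DegenerateBlockError(
            "all presences fall in one spatial block; use a smaller block size"
        )
    if len(blocks) < k:
        raise FoldError(
            f"only {len(blocks)} occupied blocks for {k} folds; use smaller blocks"
        )
    rng = np.random.default_rng(seed)
    order = sorted(
        blocks, key=lambda bid: (-len(blocks[bid]), rng.random(), bid)
    )
    load = np.zeros(k)
    fold = np.empty(cells.shape[0], dtype=int)
    for bid in order:
        tgt = int(np.argmin(load))  # first minimum: deterministic tie rule
        for i in blocks[bid]:
            fold[i] = tgt + 1
        load[tgt] += len(blocks[bid])
    if np.unique(fold).size < k:
        raise FoldError("a fold received no presences; reduce k or block size")
    return FoldAssignment(
        cells=cells, fold=fold, k=k, scheme="spatial_block", seed=seed,
        block_size_km=block_size_km,
    )


def auc(pred_presence, pred_background) -> float:
    """Rank-based AUC: P(presence score > background score) + half ties.

    1 is perfect ranking, 0.5 is ranking by chance.
    """
    p = np.asarray(pred_presence, dtype=float).ravel()
    b = np.asarray(pred_background, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise EvaluationError("AUC needs non-empty presence and background scores")
    ranks = stats.rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def boyce_index(
    pred_presence,
    pred_landscape,
    n_windows: int = 101,
    window_frac: float = 0.1,
) -> float:
    """Continuous Boyce index in [-1, 1].

    Overlapping windows of width ``window_frac`` of the landscape
    prediction range slide across it; each window's P/E is the ratio of the
    presence fraction to the landscape fraction falling inside.  The index
    is the Spearman correlation between P/E and window midpoint; +1 means
    presences concentrate monotonically in high predictions, 0 is chance.
    Windows with zero landscape mass are dropped, and duplicated P/E values
    are reduced to their first occurrence before correlating (the standard
    treatment; long runs of tied windows would otherwise swamp the rank
    correlation).
    """
    p = np.asarray(pred_presence, dtype=float).ravel()
    l = np.asarray(pred_landscape, dtype=float).ravel()
    if p.size == 0 or l.size == 0:
        raise EvaluationError("Boyce index needs presence and landscape predictions")
    lo, hi = float(l.min()), float(l.max())
    if hi <= lo:
        raise EvaluationError("landscape predictions are constant; Boyce undefined")
    width = window_frac * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for a in starts:
        b = a + width
        e = np.mean((l >= a) & (l <= b))
        if e == 0:
            continue
        pe = np.mean((p >= a) & (p <= b)) / e
        mids.append(a + width / 2.0)
        ratios.append(pe)
    if len(ratios) < 3:
        raise EvaluationError(
            f"only {len(ratios)} usable windows; decrease n_windows or widen windows"
        )
    ratios = np.asarray(ratios)
    mids = np.asarray(mids)
    _, first = np.unique(ratios, return_index=True)
    keep = np.zeros(ratios.size, dtype=bool)
    keep[first] = True
    ratios, mids = ratios[keep], mids[keep]
    if ratios.size < 2 or np.ptp(ratios) == 0:
        return 0.0  # flat P/E profile: indistinguishable from chance
    rho = stats.spearmanr(mids, ratios).statistic
    return float(rho)


def max_sss_threshold(pred_presence, pred_background) -> tuple[float, float, float]:
    """Threshold maximising sensitivity + specificity.

    Candidates are the unique predicted values; sensitivity counts
    presences at or above the threshold, specificity counts background
    strictly below it.  Ties go to the smallest threshold.
    Returns (threshold, sensitivity, specificity).
    """
    p = np.sort(np.asarray(pred_presence, dtype=float).ravel())
    b = np.sort(np.asarray(pred_background, dtype=float).ravel())
    if p.size == 0 or b.size == 0:
        raise EvaluationError("threshold needs presence and background predictions")
    cand = np.unique(np.concatenate([p, b]))
    if cand.size == 1:
        raise DegenerateThresholdError("all predictions identical")
    # exact integer scoring so ties break deterministically at the smallest
    # candidate regardless of float summation order
    n_sens = p.size - np.searchsorted(p, cand, side="left")
    n_spec = np.searchsorted(b, cand, side="left")
    score = n_sens * b.size + n_spec * p.size
    best = int(np.argmax(score))  # first max = smallest candidate
    return (
        float(cand[best]),
        float(n_sens[best] / p.size),
        float(n_spec[best] / b.size),
    )
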