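"""Covariate extraction and variance-inflation-factor (VIF) screening.

VIF_j = 1/(1 - R_j^2), with R_j^2 the coefficient of determination from
regressing covariate j on all other candidates (with intercept).  Values
of 10 or more flag problematic multicollinearity; screening proceeds
stepwise, dropping the single worst covariate per round until all
remaining VIFs fall below the threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateCovariateError, ExtractionError
from .grid import ScenarioStack


@dataclass
class CovariateMatrix:
    """Covariate values at an ordered list of grid cells.

    ``values`` is (n_cells, n_covariates), finite everywhere; column j
    corresponds to ``names[j]`` and row i to ``cells[i]`` (row, col).
    """

    cells: np.ndarray  # (n, 2) int
    names: list[str]
    values: np.ndarray  # (n, p) float

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int).reshape(-1, 2)
        self.values = np.asarray(self.values, dtype=float).reshape(
            self.cells.shape[0], len(self.names)
        )

    @property
    def n(self) -> int:
        return self.cells.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


@dataclass
class VifReport:
    retained: list[str]
    dropped: list[tuple[str, float]]  # (name, VIF at removal), in drop order
    threshold: float
    final_vifs: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained": self.retained,
                "dropped": [{"name": n, "vif_at_removal": v} for n, v in self.dropped],
                "threshold": self.threshold,
                "final_vifs": self.final_vifs,
            },
            indent=2,
        )


def extract(stack: ScenarioStack, selected: list[str], cells) -> CovariateMatrix:
    """Covariate matrix for ``selected`` layers at ``cells`` (row, col pairs).

    Cells are ordered row-major (sorted) when given as a set.  A cell that
    is invalid in any selected layer raises :class:`ExtractionError`.
    """
    if isinstance(cells, (set, frozenset)):
        cells = sorted(cells)
    cells = np.asarray(list(cells), dtype=int).reshape(-1, 2)
    cols = np.empty((cells.shape[0], len(selected)))
    for j, name in enumerate(selected):
        lyr = stack[name]
        if cells.shape[0]:
            valid = lyr.valid_mask[cells[:, 0], cells[:, 1]]
            if not valid.all():
                bad = cells[~valid][0]
                raise ExtractionError(
                    f"cell (row={bad[0]}, col={bad[1]}) is invalid in layer {name!r}"
                )
            cols[:, j] = lyr.values[cells[:, 0], cells[:, 1]]
    return CovariateMatrix(cells=cells, names=list(selected), values=cols)


def _vif_all(x: np.ndarray) -> np.ndarray:
    """VIF of each column of x (intercept included in each auxiliary fit)."""
    n, p = x.shape
    if p == 1:
        return np.array([1.0])
    vifs = np.empty(p)
    for j in range(p):
        yj = x[:, j]
        others = np.delete(x, j, axis=1)
        design = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        # numerical guard: R^2 can exceed 1 by rounding on collinear data
        vifs[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return vifs


def vif_select(m: CovariateMatrix, threshold: float = 10.0) -> VifReport:
    """Stepwise VIF screening.

    Repeatedly drops the covariate with the largest VIF while any VIF is at
    or above ``threshold`` (ties broken by earliest column order), then
    reports the retained set and the VIF each covariate had when removed.
    """
    x = m.values.copy()
    names = list(m.names)
    stds = x.std(axis=0)
    if np.any(stds == 0):
        const = [n for n, s in zip(names, stds) if s == 0]
        raise DegenerateCovariateError(f"constant covariate column(s): {const}")
    dropped: list[tuple[str, float]] = []
    while True:
        vifs = _vif_all(x)
        worst = int(np.argmax(vifs))  # argmax takes the first maximum: tie rule
        if vifs[worst] < threshold or x.shape[1] == 1:
            final = {n: float(v) for n, v in zip(names, vifs)}
            return VifReport(
                retained=names, dropped=dropped, threshold=threshold, final_vifs=final
            )
        dropped.append((names[worst], float(vifs[worst])))
        x = np.delete(x, worst, axis=1)
        del names[worst]
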