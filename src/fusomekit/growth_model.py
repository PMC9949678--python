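"""Additive fusome growth and inheritance model.

The fusome of the female germline cyst starts as the founder cell's
spectrosome (volume ``v0``, normalized to 1) and grows by fusing a "plug" of
new material into every ring canal formed at each division.  Plugs formed at
division round j all have the same volume ``v_j``; a fraction ``beta`` of a
plug is retained by the mother cell and ``1 - beta`` goes to the new
daughter.  Between divisions the relative distribution does not change, so a
cell born at round b holds, after k rounds,

    cell 1:            v0 + beta * (v_1 + ... + v_k)
    cell born at b:    (1 - beta) * v_b + beta * (v_{b+1} + ... + v_k)

out of the total T_k = v0 + sum_j 2**(j-1) * v_j.  The model has two free
parameters: ``alpha``, the volume fraction of cell 1 at the 2-cell stage
(so v1 = v0 (1-alpha)/(alpha-beta)), and ``beta``.  The remaining plug
volumes v2..v4 are fixed by imposing the measured 16-cell group shares of
{cells 1-2 : cells 3-4 : cells 5-8 : cells 9-16} (default ratio 2:1:1:1),
which yields a small linear system.

Fitting compares predicted per-cell volume fractions with measured ones at
all cyst sizes by a sum of squared residuals over an (alpha, beta) grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "GrowthParams",
    "PlugVolumes",
    "StageFractions",
    "FitResult",
    "InfeasibleParametersError",
    "NoFeasibleFitError",
    "STAGES",
    "birth_round",
    "solve_plug_volumes",
    "predict_fractions",
    "ratio_trajectory",
    "stage_fraction_table",
    "fit_parameters",
]

STAGES = (2, 4, 8, 16)
DEFAULT_RATIOS = (2.0, 1.0, 1.0, 1.0)
FEASIBILITY_GAP = 0.01  # minimum alpha - beta on the fitting grid


class InfeasibleParametersError(ValueError):
    """alpha <= beta (or negative plug volumes) make the model undefined."""


class NoFeasibleFitError(RuntimeError):
    """No grid point satisfies the feasibility constraints."""


@dataclass(frozen=True)
class GrowthParams:
    """Model parameters: cell-1 share at the 2-cell stage and plug retention."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0 and 0.0 < self.beta < 1.0):
            raise InfeasibleParametersError(
                f"alpha and beta must lie in (0,1); got ({self.alpha}, {self.beta})"
            )


@dataclass(frozen=True)
class PlugVolumes:
    """Plug volumes per division round, in units of the spectrosome volume v0."""

    v0: float
    v1: float
    v2: float
    v3: float
    v4: float
    feasible: bool = True

    @property
    def v(self) -> np.ndarray:
        return np.array([self.v0, self.v1, self.v2, self.v3, self.v4])

    def total(self, k: int) -> float:
        """Total fusome volume T_k after k division rounds."""
        v = self.v
        return float(v[0] + sum(2 ** (j - 1) * v[j] for j in range(1, k + 1)))


@dataclass(frozen=True)
class StageFractions:
    """Predicted per-cell volume fractions at one cyst size, canonical order."""

    stage: int
    fractions: np.ndarray

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        if len(self.fractions) != self.stage:
            raise ValueError("one fraction per cell required")
        if not np.isclose(self.fractions.sum(), 1.0, atol=1e-9):
            raise ValueError("fractions must sum to 1")


@dataclass
class FitResult:
    """Grid-search least-squares fit of (alpha, beta)."""

    alpha_hat: float
    beta_hat: float
    alphas: np.ndarray
    betas: np.ndarray
    error_surface: np.ndarray  # shape (len(alphas), len(betas)); inf = infeasible
    min_error: float

    @property
    def region5(self) -> np.ndarray:
        """Boolean mask of grid points with error within 5% of the minimum."""
        return self.error_surface <= 1.05 * self.min_error

    @property
    def alpha_range(self) -> Tuple[float, float]:
        a = self.alphas[np.any(self.region5, axis=1)]
        return float(a.min()), float(a.max())

    @property
    def beta_range(self) -> Tuple[float, float]:
        b = self.betas[np.any(self.region5, axis=0)]
        return float(b.min()), float(b.max())


def birth_round(cell: int) -> int:
    """Division round at which canonical cell ``cell`` is born (cell 1 -> 0)."""
    if cell < 1:
        raise ValueError("cells are numbered from 1")
    return 0 if cell == 1 else int(np.ceil(np.log2(cell)))


def solve_plug_volumes(
    params: GrowthParams,
    group_ratios: Sequence[float] = DEFAULT_RATIOS,
) -> PlugVolumes:
    """Solve plug volumes v1..v4 (v0 = 1) from alpha, beta and 16-cell shares.

    v1 follows from the definition of alpha; v2..v4 solve the linear system
    expressing the 16-cell group volume shares {1-2, 3-4, 5-8, 9-16} (the
    four equations are redundant with the normalization, leaving three
    independent ones).  Negative solved volumes are returned with
    ``feasible=False``.
    """
    a, b = params.alpha, params.beta
    if a <= b:
        raise InfeasibleParametersError(
            f"alpha must exceed beta for a positive v1; got ({a}, {b})"
        )
    p = np.asarray(group_ratios, dtype=float)
    if np.any(p <= 0):
        raise ValueError("group ratios must be positive")
    p = p / p.sum()
    v0 = 1.0
    v1 = v0 * (1.0 - a) / (a - b)
    # rows: group shares of cells {3,4}, {5..8}, {9..16}; unknowns (v2,v3,v4)
    m = np.array(
        [
            [2 * (1 - b) - 2 * p[1], 2 * b - 4 * p[1], 2 * b - 8 * p[1]],
            [-2 * p[2], 4 * (1 - b) - 4 * p[2], 4 * b - 8 * p[2]],
            [-2 * p[3], -4 * p[3], 8 * (1 - b) - 8 * p[3]],
        ]
    )
    rhs = p[1:] * (v0 + v1)
    v2, v3, v4 = np.linalg.solve(m, rhs)
    feasible = bool(min(v1, v2, v3, v4) >= 0)
    return PlugVolumes(v0, float(v1), float(v2), float(v3), float(v4), feasible)


def predict_fractions(plugs: PlugVolumes, params: GrowthParams, stage: int) -> StageFractions:
    """Per-cell fusome volume fractions at a cyst size, canonical cell order."""
    if stage not in STAGES:
        raise ValueError(f"stage must be one of {STAGES}")
    k = int(np.log2(stage))
    v = plugs.v
    t_k = plugs.total(k)
    b = params.beta
    frac = np.empty(stage)
    for cell in range(1, stage + 1):
        born = birth_round(cell)
        if born == 0:
            vol = v[0] + b * v[1 : k + 1].sum()
        else:
            vol = (1 - b) * v[born] + b * v[born + 1 : k + 1].sum()
        frac[cell - 1] = vol / t_k
    return StageFractions(stage, frac)


def ratio_trajectory(params: GrowthParams, plugs: Optional[PlugVolumes] = None,
                     group_ratios: Sequence[float] = DEFAULT_RATIOS) -> Tuple[float, ...]:
    """Predicted cell1:cell2 volume ratio at stages 2, 4, 8, 16.

    Strictly decreasing when alpha > beta and all plug volumes are positive:
    the founder's spectrosome advantage is diluted by each added plug.
    """
    if plugs is None:
        plugs = solve_plug_volumes(params, group_ratios)
    out = []
    for stage in STAGES:
        f = predict_fractions(plugs, params, stage).fractions
        out.append(float(f[0] / f[1]))
    return tuple(out)


# ---------------------------------------------------------------------------
# measured-data handling
# ---------------------------------------------------------------------------

def _sorting_groups(stage: int) -> Tuple[Tuple[int, ...], ...]:
    """Cell-index groups (0-based) whose measured order is fixed by volume.

    The pro-oocyte pair {cells 1, 2} is one group (cell 1 is *defined* as
    the larger of the two most-connected fragments); every later birth
    round forms its own group of model-equivalent cells.
    """
    if stage == 2:
        return ((0, 1),)
    groups = [(0, 1)]
    n = 2
    while n < stage:
        groups.append(tuple(range(n, 2 * n)))
        n *= 2
    return tuple(groups)


def cyst_fraction_matrix(table: pd.DataFrame) -> Dict[int, np.ndarray]:
    """Per-stage matrices of per-cyst volume fractions in canonical order.

    Expects columns (cyst_id, stage, cell_label, volume_um3).  Within each
    cyst, volumes are normalized to fractions and cells born in the same
    division round are sorted by descending fraction, so that measured
    f1 >= f2 by construction (cell 1 is the larger pro-oocyte).
    """
    required = {"cyst_id", "stage", "cell_label", "volume_um3"}
    if not required <= set(table.columns):
        raise ValueError(f"volume table must have columns {sorted(required)}")
    out: Dict[int, np.ndarray] = {}
    for stage, sub in table.groupby("stage"):
        stage = int(stage)
        if stage not in STAGES:
            raise ValueError(f"unsupported stage {stage}")
        rows = []
        for _, cyst in sub.groupby("cyst_id"):
            if len(cyst) != stage:
                raise ValueError(
                    f"a stage-{stage} cyst must have {stage} cells, got {len(cyst)}"
                )
            ordered = cyst.sort_values("cell_label")["volume_um3"].to_numpy(float)
            frac = ordered / ordered.sum()
            for g in _sorting_groups(stage):
                idx = np.asarray(g)
                frac[idx] = np.sort(frac[idx])[::-1]
            rows.append(frac)
        out[stage] = np.vstack(rows)
    return out


def stage_fraction_table(table: pd.DataFrame) -> Dict[int, np.ndarray]:
    """Stage-wise mean per-cell volume fractions (means over cysts)."""
    return {s: m.mean(axis=0) for s, m in cyst_fraction_matrix(table).items()}


# ---------------------------------------------------------------------------
# grid-search fit
# ---------------------------------------------------------------------------

def _grid(step: float, lo: float = 0.25, hi: float = 0.75) -> np.ndarray:
    n = int(round((hi - lo) / step))
    return np.round(lo + step * np.arange(n + 1), 10)


@lru_cache(maxsize=8)
def _grid_model_fractions(
    alphas: Tuple[float, ...], betas: Tuple[float, ...], ratios: Tuple[float, ...],
    stages: Tuple[int, ...],
) -> Tuple[np.ndarray, Dict[int, slice]]:
    """Model fraction vectors for every feasible grid point, vectorized.

    Returns an array of shape (n_alpha, n_beta, total_cells) with NaN rows at
    infeasible points, plus per-stage column slices.  This is the batched
    counterpart of solve_plug_volumes + predict_fractions (cross-checked in
    the test suite against the scalar path).
    """
    a = np.asarray(alphas)[:, None]
    b = np.asarray(betas)[None, :]
    p = np.asarray(ratios, dtype=float)
    p = p / p.sum()
    feas = (a - b) > FEASIBILITY_GAP
    with np.errstate(divide="ignore", invalid="ignore"):
        v1 = np.where(feas, (1.0 - a) / (a - b), np.nan)
    bb = np.broadcast_to(b, v1.shape)
    m = np.empty(v1.shape + (3, 3))
    m[..., 0, 0] = 2 * (1 - bb) - 2 * p[1]
    m[..., 0, 1] = 2 * bb - 4 * p[1]
    m[..., 0, 2] = 2 * bb - 8 * p[1]
    m[..., 1, 0] = -2 * p[2]
    m[..., 1, 1] = 4 * (1 - bb) - 4 * p[2]
    m[..., 1, 2] = 4 * bb - 8 * p[2]
    m[..., 2, 0] = -2 * p[3]
    m[..., 2, 1] = -4 * p[3]
    m[..., 2, 2] = 8 * (1 - bb) - 8 * p[3]
    rhs = (1.0 + v1)[..., None] * p[1:]
    v234 = np.linalg.solve(
        m, np.where(np.isfinite(rhs), rhs, 0.0)[..., None]
    )[..., 0]
    v = np.concatenate(
        [np.ones(v1.shape + (1,)), v1[..., None], v234], axis=-1
    )  # (..., 5): v0..v4
    feas = feas & np.all(v >= -1e-12, axis=-1)

    slices: Dict[int, slice] = {}
    cols = []
    start = 0
    for stage in stages:
        k = int(np.log2(stage))
        weights = np.array([2 ** (j - 1) for j in range(1, k + 1)])
        t_k = 1.0 + (v[..., 1 : k + 1] * weights).sum(axis=-1)
        stage_f = np.empty(v1.shape + (stage,))
        for cell in range(1, stage + 1):
            born = birth_round(cell)
            if born == 0:
                vol = 1.0 + bb * v[..., 1 : k + 1].sum(axis=-1)
            else:
                vol = (1 - bb) * v[..., born] + bb * v[..., born + 1 : k + 1].sum(axis=-1)
            stage_f[..., cell - 1] = vol / t_k
        cols.append(stage_f)
        slices[stage] = slice(start, start + stage)
        start += stage
    model = np.concatenate(cols, axis=-1)
    model[~feas] = np.nan
    return model, slices


def fit_parameters(
    table: pd.DataFrame,
    step: float = 0.005,
    alpha_range: Tuple[float, float] = (0.25, 0.75),
    beta_range: Tuple[float, float] = (0.25, 0.75),
    group_ratios: Sequence[float] = DEFAULT_RATIOS,
    residual_mode: str = "mean",
) -> FitResult:
    """Grid-search least-squares fit of (alpha, beta) to measured fractions.

    The error at a grid point is the sum over cyst sizes and cells of squared
    residuals between measured and model volume fractions.  By default each
    cell contributes one residual per stage, computed against the stage-wise
    mean measured fraction; ``residual_mode="per_sample"`` sums residuals over
    every individual cyst instead.  Grid points with alpha - beta <= 0.01 or
    negative solved plug volumes are excluded.
    """
    if residual_mode not in ("mean", "per_sample"):
        raise ValueError("residual_mode must be 'mean' or 'per_sample'")
    per_cyst = cyst_fraction_matrix(table)
    stages = tuple(sorted(per_cyst))
    alphas = _grid(step, *alpha_range)
    betas = _grid(step, *beta_range)
    model, slices = _grid_model_fractions(
        tuple(alphas), tuple(betas), tuple(group_ratios), stages
    )
    err = np.zeros(model.shape[:2])
    for stage in stages:
        m = model[..., slices[stage]]
        if residual_mode == "mean":
            target = per_cyst[stage].mean(axis=0)
            err += ((m - target) ** 2).sum(axis=-1)
        else:
            for row in per_cyst[stage]:
                err += ((m - row) ** 2).sum(axis=-1)
    err[np.isnan(err)] = np.inf
    if not np.isfinite(err).any():
        raise NoFeasibleFitError("no feasible (alpha, beta) grid point")
    i, j = np.unravel_index(np.argmin(err), err.shape)
    return FitResult(
        alpha_hat=float(alphas[i]),
        beta_hat=float(betas[j]),
        alphas=alphas,
        betas=betas,
        error_surface=err,
        min_error=float(err[i, j]),
    )
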