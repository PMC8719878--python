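"""Bootstrap-of-residuals confidence intervals and residual-sweep curves.

Both diagnostics operate on a completed fit.  The bootstrap resamples the
pooled residual vector (both observables, all datasets) with replacement,
adds the resampled residuals onto the optimum-fit predictions to build a
synthetic panel, and refits it starting from the optimum; only refits that
meet the same ``ftol`` convergence criterion enter the samples.  The sweep
evaluates the sum of squared residuals along a log-spaced grid of one slot's
range with every other slot pinned at the optimum -- no re-optimization.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Dict, Optional, Tuple

import numpy as np

from .fitting import FitProblem, FitResult, _run_local
from .ledger import ParameterLedger
from .panel import MutantDataset, PanelData

__all__ = ["BootstrapResult", "SweepCurve", "bootstrap_ci", "residual_sweep"]


@dataclass(frozen=True)
class BootstrapResult:
    """Per-slot bootstrap samples and empirical confidence intervals."""

    n_requested: int
    n_converged: int
    level: float
    samples: Dict[str, np.ndarray]  # converged refit values per free slot
    ci: Dict[str, Tuple[float, float]]

    def __post_init__(self):
        if self.n_converged > self.n_requested:
            raise ValueError("n_converged cannot exceed n_requested")


@dataclass(frozen=True)
class SweepCurve:
    """SSR along one slot's range, all other slots fixed at the optimum."""

    slot_id: str
    grid: np.ndarray
    ssr: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("sweep grid must be strictly increasing")
        if len(self.grid) != len(self.ssr):
            raise ValueError("grid and ssr must have equal length")


def _nearest_rank_interval(values: np.ndarray, level: float) -> Tuple[float, float]:
    lo = np.quantile(values, (1.0 - level) / 2.0, method="nearest")
    hi = np.quantile(values, 1.0 - (1.0 - level) / 2.0, method="nearest")
    return float(lo), float(hi)


def bootstrap_ci(
    fit: FitResult,
    panel: PanelData,
    ledger: ParameterLedger,
    n_boot: int,
    seed: int,
    level: float = 0.95,
    ftol: Optional[float] = None,
    quantile_method: str = "nearest",
) -> BootstrapResult:
    """Bootstrap-of-residuals confidence intervals for every free slot.

    Synthetic observations are the optimum-fit predictions plus residuals
    resampled with replacement from the pooled residual vector; crosslink
    observations are intentionally not clipped to [0, 1] to keep the refits
    unbiased.  Each refit starts from the optimum.  Deterministic given
    ``(seed, n_boot)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    ftol = fit.ftol if ftol is None else ftol

    problem = FitProblem(panel, ledger)
    x_opt = problem.pack({sid: fit.slot_values[sid] for sid in problem.free_ids})
    pooled = fit.residuals
    n_ds = len(panel.datasets)
    n_pts = problem.mg.shape[1]
    pred_xl = np.vstack([fit.predictions[d.dataset_id].f_sensor_on for d in panel.datasets])
    pred_act = np.vstack([fit.predictions[d.dataset_id].activity for d in panel.datasets])

    rng = np.random.default_rng(seed)
    samples: Dict[str, list] = {sid: [] for sid in problem.free_ids}
    n_converged = 0
    for _ in range(n_boot):
        draw = rng.choice(pooled, size=2 * n_ds * n_pts, replace=True)
        xl_b = pred_xl + draw[: n_ds * n_pts].reshape(n_ds, n_pts)
        act_b = pred_act + draw[n_ds * n_pts :].reshape(n_ds, n_pts)
        boot_problem = _clone_problem_with_observations(problem, panel, ledger, xl_b, act_b)
        sol = _run_local(boot_problem, x_opt, ftol, None)
        if sol is None or sol.status != 2:
            continue
        n_converged += 1
        values = boot_problem.unpack(sol.x)
        for sid in problem.free_ids:
            samples[sid].append(values[sid])

    arr = {sid: np.asarray(v) for sid, v in samples.items()}
    ci = {}
    for sid, v in arr.items():
        if len(v) == 0:
            ci[sid] = (float("nan"), float("nan"))
        elif quantile_method == "nearest":
            ci[sid] = _nearest_rank_interval(v, level)
        else:
            lo = np.quantile(v, (1.0 - level) / 2.0, method=quantile_method)
            hi = np.quantile(v, 1.0 - (1.0 - level) / 2.0, method=quantile_method)
            ci[sid] = (float(lo), float(hi))
    return BootstrapResult(
        n_requested=n_boot, n_converged=n_converged, level=level, samples=arr, ci=ci
    )


def _clone_problem_with_observations(problem, panel, ledger, xl, act) -> FitProblem:
    # Synthetic observations live directly on the rescaled scale, so the
    # clone bypasses panel reconstruction and swaps the observation arrays.
    datasets = tuple(
        dc_replace(d, crosslink=xl[i], activity_refactored=act[i])
        for i, d in enumerate(panel.datasets)
    )
    boot_panel = PanelData(datasets=datasets, q=panel.q)
    return FitProblem(boot_panel, ledger)


def residual_sweep(
    fit: FitResult,
    panel: PanelData,
    ledger: ParameterLedger,
    slot_id: str,
    n_grid: int = 100,
) -> SweepCurve:
    """SSR along a log-spaced grid across one slot's bounds.

    All other slots stay pinned at the fitted optimum; a fixed-scope slot
    cannot be swept.  The fitted value is spliced into the grid so the curve
    touches the fit's SSR exactly at the optimum.
    """
    slot = ledger.slots[slot_id]
    if slot.scope == "fixed":
        raise ValueError(f"slot {slot_id} is fixed to {slot.fixed_value}; nothing to sweep")
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    problem = FitProblem(panel, ledger)
    x_opt = problem.pack({sid: fit.slot_values[sid] for sid in problem.free_ids})
    pos = problem.free_ids.index(slot_id)

    grid = np.logspace(np.log10(slot.lower), np.log10(slot.upper), n_grid)
    grid = np.unique(np.concatenate([grid, [fit.slot_values[slot_id]]]))
    ssr = np.empty(len(grid))
    for i, v in enumerate(grid):
        x = x_opt.copy()
        x[pos] = np.log10(v)
        r = problem.residuals(x)
        ssr[i] = float(r @ r)
    return SweepCurve(slot_id=slot_id, grid=grid, ssr=ssr)
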