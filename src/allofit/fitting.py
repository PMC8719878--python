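"""Global/local shared-parameter bounded least-squares engine.

The objective couples every dataset in a panel through a
:class:`~allofit.ledger.ParameterLedger`: free slots are optimized in log10
coordinates inside their box bounds (the parameters span many decades, so
both the optimization metric and the multistart sampling are logarithmic),
fixed slots stay pinned at 1, and the residual vector stacks all crosslink
residuals (dataset-ordered) followed by all rescaled-activity residuals --
10 residuals per dataset on the five-point grid.

Local minimization is SciPy's trust-region-reflective ``least_squares`` with
termination on the relative cost decrease only (``ftol``, criterion 2), so
the ``converged`` flag of a fit means exactly that criterion.  Multistart
draws log-uniform random starts from a seeded generator and returns the
converged fit with the smallest sum of squared residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .ensemble import DoseResponsePrediction
from .ledger import ParameterLedger, ROLES, build_ledger
from .panel import PanelData

__all__ = [
    "FitProblem",
    "FitResult",
    "MultistartError",
    "pack_parameters",
    "unpack_parameters",
    "residuals",
    "fit_once",
    "multistart_fit",
    "compare_models",
]

_BIG = 1e100  # replacement for non-finite residuals; flags a failed region


class MultistartError(RuntimeError):
    """No start converged; carries the best non-converged candidate."""

    def __init__(self, message: str, best_candidate: Optional["FitResult"] = None):
        super().__init__(message)
        self.best_candidate = best_candidate


# ---------------------------------------------------------------------------
# vectorized model evaluation over a whole panel


def _predict_matrix(model: str, P: np.ndarray, mg: np.ndarray):
    """Vectorized (f_sensor_on, f_ak_on, activity) for a parameter matrix.

    ``P`` has one row per dataset with columns in ``ROLES[model]`` order;
    ``mg`` is the (n_datasets, n_doses) molar grid.
    """
    cols = {r: P[:, i : i + 1] for i, r in enumerate(ROLES[model])}
    b_off = (1.0 + mg / cols["kd_off"]) ** 2
    b_on = (1.0 + mg / cols["kd_on"]) ** 2
    b_max = np.maximum(b_off, b_on)
    b_off = b_off / b_max
    b_on = b_on / b_max

    if model == "concerted":
        num = b_on * cols["k"]
        f_on = num / (num + b_off)
        return f_on, f_on, cols["s"] * f_on

    if model == "two_domain":
        s_off_aoff = np.ones_like(cols["k_ak"])
        s_off_aon = cols["k_ak"]
        s_on_aoff = cols["k_sen"]
        s_on_aon = cols["alpha"] * cols["k_sen"] * cols["k_ak"]
    elif model == "three_domain":
        s_off_aoff = 1.0 + cols["k_hamp"]
        s_off_aon = cols["k_ak"] * (1.0 + cols["alpha2"] * cols["k_hamp"])
        s_on_aoff = cols["k_sen"] * (1.0 + cols["alpha1"] * cols["k_hamp"])
        s_on_aon = cols["k_sen"] * cols["k_ak"] * (
            1.0 + cols["alpha1"] * cols["alpha2"] * cols["k_hamp"]
        )
    else:  # pragma: no cover - guarded by ledger validation
        raise ValueError(f"unknown model family {model!r}")

    s_max = np.maximum.reduce([s_off_aoff, s_off_aon, s_on_aoff, s_on_aon])
    s_off_aoff = s_off_aoff / s_max
    s_off_aon = s_off_aon / s_max
    s_on_aoff = s_on_aoff / s_max
    s_on_aon = s_on_aon / s_max

    on_branch = b_on * (s_on_aoff + s_on_aon)
    off_branch = b_off * (s_off_aoff + s_off_aon)
    total = on_branch + off_branch
    f_sensor = on_branch / total
    f_ak = (b_on * s_on_aon + b_off * s_off_aon) / total
    return f_sensor, f_ak, cols["s"] * f_ak


class FitProblem:
    """Precomputed residual machinery for one (panel, ledger) pair.

    Builds the dataset -> slot index matrix once so that a residual
    evaluation is a handful of vectorized array operations.
    """

    def __init__(self, panel: PanelData, ledger: ParameterLedger):
        if len(panel) == 0:
            raise ValueError("empty panel")
        for d in panel.datasets:
            if d.activity_refactored is None:
                raise ValueError(
                    "panel must be rescaled (rescale_activity) before fitting"
                )
            if d.mutant_id not in ledger.assignment:
                raise ValueError(f"construct {d.mutant_id!r} missing from ledger")
        self.panel = panel
        self.ledger = ledger
        self.roles = ledger.roles
        self.free_ids: Tuple[str, ...] = ledger.free_slot_ids()
        self.fixed_ids: Tuple[str, ...] = ledger.fixed_slot_ids()
        self.n_free = len(self.free_ids)
        slot_pos = {sid: i for i, sid in enumerate(self.free_ids)}
        for j, sid in enumerate(self.fixed_ids):
            slot_pos[sid] = self.n_free + j
        self._fixed_values = np.array(
            [ledger.slots[sid].fixed_value for sid in self.fixed_ids], dtype=float
        )
        self.dataset_ids = tuple(d.dataset_id for d in panel.datasets)
        self.idx = np.array(
            [
                [slot_pos[ledger.assignment[d.mutant_id][role]] for role in self.roles]
                for d in panel.datasets
            ],
            dtype=np.intp,
        )
        self.mg = np.vstack([d.mg_molar for d in panel.datasets])
        self.obs_xl = np.vstack([d.crosslink for d in panel.datasets])
        self.obs_act = np.vstack([d.activity_refactored for d in panel.datasets])
        lower = np.array([ledger.slots[sid].lower for sid in self.free_ids])
        upper = np.array([ledger.slots[sid].upper for sid in self.free_ids])
        self.lb = np.log10(lower)
        self.ub = np.log10(upper)

    # -- coordinate transforms ------------------------------------------------

    def pack(self, slot_values: Mapping[str, float]) -> np.ndarray:
        """Map free-slot values to the log10 optimization vector."""
        x = np.empty(self.n_free)
        for i, sid in enumerate(self.free_ids):
            v = slot_values[sid]
            slot = self.ledger.slots[sid]
            if not (slot.lower <= v <= slot.upper):
                raise ValueError(
                    f"slot {sid}: value {v} outside bounds [{slot.lower}, {slot.upper}]"
                )
            x[i] = np.log10(v)
        return x

    def unpack(self, x: np.ndarray) -> Dict[str, float]:
        """Inverse of :meth:`pack`; fixed slots are reported at their value."""
        out = {sid: float(10.0 ** x[i]) for i, sid in enumerate(self.free_ids)}
        for sid in self.fixed_ids:
            out[sid] = float(self.ledger.slots[sid].fixed_value)
        return out

    # -- residuals -------------------------------------------------------------

    def _full_values(self, x: np.ndarray) -> np.ndarray:
        full = np.empty(self.n_free + len(self.fixed_ids))
        full[: self.n_free] = 10.0 ** x
        full[self.n_free :] = self._fixed_values
        return full

    def predict(self, x: np.ndarray):
        P = self._full_values(x)[self.idx]
        return _predict_matrix(self.ledger.model, P, self.mg)

    def residuals(self, x: np.ndarray) -> np.ndarray:
        """Crosslink residual block then rescaled-activity residual block."""
        f_sensor, _, activity = self.predict(x)
        res = np.concatenate(
            [(f_sensor - self.obs_xl).ravel(), (activity - self.obs_act).ravel()]
        )
        return np.nan_to_num(res, nan=_BIG, posinf=_BIG, neginf=-_BIG)

    def predictions(self, x: np.ndarray) -> Dict[str, DoseResponsePrediction]:
        f_sensor, f_ak, activity = self.predict(x)
        return {
            did: DoseResponsePrediction(
                mg=self.mg[i].copy(),
                f_sensor_on=f_sensor[i].copy(),
                f_ak_on=f_ak[i].copy(),
                activity=activity[i].copy(),
            )
            for i, did in enumerate(self.dataset_ids)
        }


@dataclass
class FitResult:
    """Outcome of a (multistart) fit."""

    slot_values: Dict[str, float]
    ssr: float
    converged: bool
    n_starts: int
    seed: Optional[int]
    ftol: float
    status: int
    nfev: int
    model: str
    predictions: Dict[str, DoseResponsePrediction]
    residuals: np.ndarray
    boundary_pinned: Tuple[str, ...] = ()
    start_records: Tuple[Tuple[int, float, bool], ...] = field(default=(), repr=False)
    local_minima: Tuple[Dict[str, float], ...] = field(default=(), repr=False)

    def to_jsonable(self) -> Dict:
        return {
            "model": self.model,
            "slot_values": self.slot_values,
            "ssr": self.ssr,
            "converged": self.converged,
            "n_starts": self.n_starts,
            "seed": self.seed,
            "ftol": self.ftol,
            "boundary_pinned": list(self.boundary_pinned),
            "n_local_minima_within_1pct": len(self.local_minima),
            "predictions": {
                did: {
                    "mg_molar": p.mg.tolist(),
                    "f_sensor_on": p.f_sensor_on.tolist(),
                    "f_ak_on": p.f_ak_on.tolist(),
                    "activity": p.activity.tolist(),
                }
                for did, p in self.predictions.items()
            },
        }


def pack_parameters(ledger: ParameterLedger, slot_values: Mapping[str, float]) -> np.ndarray:
    """Free-slot values -> log10 optimization vector (fixed slots excluded)."""
    x = np.empty(len(ledger.free_slot_ids()))
    for i, sid in enumerate(ledger.free_slot_ids()):
        slot = ledger.slots[sid]
        v = slot_values[sid]
        if not (slot.lower <= v <= slot.upper):
            raise ValueError(
                f"slot {sid}: value {v} outside bounds [{slot.lower}, {slot.upper}]"
            )
        x[i] = np.log10(v)
    return x


def unpack_parameters(ledger: ParameterLedger, x: np.ndarray) -> Dict[str, float]:
    """Inverse of :func:`pack_parameters`; fixed slots reported at 1."""
    free = ledger.free_slot_ids()
    if len(x) != len(free):
        raise ValueError(f"expected vector of length {len(free)}, got {len(x)}")
    out = {sid: float(10.0 ** xi) for sid, xi in zip(free, x)}
    for sid in ledger.fixed_slot_ids():
        out[sid] = float(ledger.slots[sid].fixed_value)
    return out


def residuals(x: np.ndarray, panel: PanelData, ledger: ParameterLedger) -> np.ndarray:
    """Flat residual vector at log10 vector ``x`` (see :class:`FitProblem`)."""
    return FitProblem(panel, ledger).residuals(x)


def _run_local(problem: FitProblem, x0: np.ndarray, ftol: float, max_nfev: Optional[int]):
    import warnings

    try:
        with warnings.catch_warnings():
            # extreme exploratory steps trigger benign divide-by-zero warnings
            # inside the trust-region subproblem
            warnings.simplefilter("ignore", RuntimeWarning)
            return least_squares(
                problem.residuals,
                x0,
                jac="2-point",
                bounds=(problem.lb, problem.ub),
                method="trf",
                ftol=ftol,
                xtol=None,
                gtol=None,
                max_nfev=max_nfev,
            )
    except Exception:  # non-finite cost etc.: flagged failed fit, not an exception
        return None


def _result_from_solution(
    problem: FitProblem,
    x: np.ndarray,
    *,
    converged: bool,
    status: int,
    nfev: int,
    n_starts: int,
    seed: Optional[int],
    ftol: float,
) -> FitResult:
    res = problem.residuals(x)
    pinned = tuple(
        sid
        for i, sid in enumerate(problem.free_ids)
        if x[i] - problem.lb[i] < 1e-6 or problem.ub[i] - x[i] < 1e-6
    )
    return FitResult(
        slot_values=problem.unpack(x),
        ssr=float(res @ res),
        converged=converged,
        n_starts=n_starts,
        seed=seed,
        ftol=ftol,
        status=status,
        nfev=nfev,
        model=problem.ledger.model,
        predictions=problem.predictions(x),
        residuals=res,
        boundary_pinned=pinned,
    )


def fit_once(
    panel: PanelData,
    ledger: ParameterLedger,
    start_values: Mapping[str, float] | np.ndarray,
    ftol: float = 1e-8,
    max_nfev: Optional[int] = None,
) -> FitResult:
    """Single bounded trust-region fit from one start point.

    ``start_values`` is either a slot-value mapping or a log10 vector over
    the free slots.  The ``converged`` flag reports SciPy's relative
    cost-decrease criterion (status 2) only.
    """
    problem = FitProblem(panel, ledger)
    x0 = (
        problem.pack(start_values)
        if isinstance(start_values, Mapping)
        else np.asarray(start_values, dtype=float)
    )
    sol = _run_local(problem, x0, ftol, max_nfev)
    if sol is None:
        return _result_from_solution(
            problem, x0, converged=False, status=-1, nfev=0,
            n_starts=1, seed=None, ftol=ftol,
        )
    return _result_from_solution(
        problem, sol.x, converged=(sol.status == 2), status=sol.status,
        nfev=sol.nfev, n_starts=1, seed=None, ftol=ftol,
    )


def multistart_fit(
    panel: PanelData,
    ledger: ParameterLedger,
    n_starts: int,
    seed: int,
    ftol: float = 1e-8,
    x0: Optional[Mapping[str, float]] = None,
    explore_max_nfev: Optional[int] = None,
    polish_top: int = 0,
) -> FitResult:
    """Best of ``n_starts`` bounded fits from log-uniform random starts.

    Starts are drawn log-uniformly within each free slot's bounds from a
    generator seeded with ``seed``, so results are deterministic given
    ``(seed, n_starts)``.  If ``x0`` is given it replaces the first start.

    ``explore_max_nfev`` caps the function-evaluation budget of each
    exploratory fit; the ``polish_top`` best exploratory solutions are then
    refined without a cap.  This keeps desk-scale multistarts affordable
    while still polishing the winning basins to the ``ftol`` criterion.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    problem = FitProblem(panel, ledger)
    rng = np.random.default_rng(seed)
    starts = problem.lb + (problem.ub - problem.lb) * rng.random((n_starts, problem.n_free))
    if x0 is not None:
        starts[0] = problem.pack(x0)

    solutions: List[Tuple[float, np.ndarray, bool, int, int]] = []
    records: List[Tuple[int, float, bool]] = []
    for i in range(n_starts):
        sol = _run_local(problem, starts[i], ftol, explore_max_nfev)
        if sol is None:
            records.append((i, float("inf"), False))
            continue
        solutions.append((float(sol.cost), sol.x, sol.status == 2, sol.status, sol.nfev))
        records.append((i, float(2.0 * sol.cost), sol.status == 2))

    if polish_top > 0 and solutions:
        solutions.sort(key=lambda t: t[0])
        polished = []
        for cost, x, conv, status, nfev in solutions[: polish_top]:
            sol = _run_local(problem, x, ftol, None)
            if sol is not None:
                polished.append(
                    (float(sol.cost), sol.x, sol.status == 2, sol.status, nfev + sol.nfev)
                )
        solutions = polished + solutions[polish_top:]

    converged_sols = [t for t in solutions if t[2]]
    if not converged_sols:
        best_candidate = None
        if solutions:
            cost, x, conv, status, nfev = min(solutions, key=lambda t: t[0])
            best_candidate = _result_from_solution(
                problem, x, converged=False, status=status, nfev=nfev,
                n_starts=n_starts, seed=seed, ftol=ftol,
            )
        raise MultistartError(
            f"none of {n_starts} starts met the ftol convergence criterion",
            best_candidate=best_candidate,
        )

    cost, x, conv, status, nfev = min(converged_sols, key=lambda t: t[0])
    best = _result_from_solution(
        problem, x, converged=True, status=status, nfev=nfev,
        n_starts=n_starts, seed=seed, ftol=ftol,
    )
    best.start_records = tuple(records)

    # report distinct converged minima within 1% of the best SSR
    best_cost = cost
    minima: List[Dict[str, float]] = []
    seen = set()
    for c, xx, cv, st, nf in sorted(converged_sols, key=lambda t: t[0]):
        if c > 1.01 * best_cost:
            break
        key = tuple(np.round(xx, 3))
        if key in seen:
            continue
        seen.add(key)
        entry = problem.unpack(xx)
        entry["_ssr"] = float(2.0 * c)
        minima.append(entry)
    best.local_minima = tuple(minima)
    return best


def compare_models(
    panel: PanelData,
    annotations,
    n_starts: int = 200,
    seed: int = 0,
    ftol: float = 1e-8,
    explore_max_nfev: Optional[int] = 60,
    polish_top: int = 20,
    families: Sequence[str] = ("concerted", "two_domain", "three_domain"),
) -> Dict[str, Dict]:
    """Multistart fits of all model families under analogous ledgers.

    Returns, per family, the best SSR, free/total parameter counts and the
    winning :class:`FitResult`.  Failed families (no converged start) report
    the best non-converged candidate's SSR with ``converged = False``.
    """
    report: Dict[str, Dict] = {}
    for family in families:
        ledger = build_ledger(annotations, model=family)
        try:
            fit = multistart_fit(
                panel,
                ledger,
                n_starts=n_starts,
                seed=seed,
                ftol=ftol,
                explore_max_nfev=explore_max_nfev,
                polish_top=polish_top,
            )
        except MultistartError as err:
            fit = err.best_candidate
            if fit is None:
                raise
        census = ledger.census()
        report[family] = {
            "ssr": fit.ssr,
            "converged": fit.converged,
            "n_free_parameters": census["free"],
            "n_total_parameters": census["total"],
            "fit": fit,
        }
    return report
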