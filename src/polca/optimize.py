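"""Lennard-Jones meta-model optimization.

Per-grid-point simulated properties (density, enthalpy of vaporization per
molecule) are fitted to second-order response surfaces in coded (sigma,
epsilon) values; a relative-least-squares objective against experimental
targets is minimized by a two-stage steepest descent: a long stage with a
variable (backtracking) step length and up to 4000 iterations, whose
best-ever point seeds a short refinement stage with smaller steps and up
to 100 iterations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np


@dataclass
class DesignGrid:
    """Full-factorial (sigma, epsilon) design with linear coded mapping.

    Coded values map each axis's grid extremes to [-1, +1].
    """

    sigma_levels: np.ndarray  # nm
    epsilon_levels: np.ndarray  # kJ/mol

    def __post_init__(self):
        self.sigma_levels = np.asarray(self.sigma_levels, dtype=float)
        self.epsilon_levels = np.asarray(self.epsilon_levels, dtype=float)
        for lv, name in ((self.sigma_levels, "sigma"), (self.epsilon_levels, "epsilon")):
            if lv.size < 2:
                raise ValueError(f"need at least 2 {name} levels")
            if not np.all(np.diff(lv) > 0):
                raise ValueError(f"{name} levels must be strictly increasing")

    @property
    def points(self) -> np.ndarray:
        """All (sigma, epsilon) combinations, shape (n_sigma*n_eps, 2)."""
        return np.array(list(itertools.product(self.sigma_levels, self.epsilon_levels)))

    def code(self, sigma, epsilon) -> tuple[float, float]:
        def _c(v, lv):
            lo, hi = lv[0], lv[-1]
            return (2.0 * (np.asarray(v, dtype=float) - lo) / (hi - lo)) - 1.0

        return _c(sigma, self.sigma_levels), _c(epsilon, self.epsilon_levels)

    def decode(self, x1, x2) -> tuple[float, float]:
        def _d(x, lv):
            lo, hi = lv[0], lv[-1]
            return lo + (np.asarray(x, dtype=float) + 1.0) / 2.0 * (hi - lo)

        return _d(x1, self.sigma_levels), _d(x2, self.epsilon_levels)

    @property
    def coded_points(self) -> np.ndarray:
        pts = self.points
        x1, x2 = self.code(pts[:, 0], pts[:, 1])
        return np.column_stack([x1, x2])


def build_design_grid(sigma_levels, epsilon_levels) -> DesignGrid:
    return DesignGrid(sigma_levels, epsilon_levels)


def _quad_design(x: np.ndarray) -> np.ndarray:
    x1, x2 = x[:, 0], x[:, 1]
    return np.column_stack([np.ones_like(x1), x1, x2, x1**2, x2**2, x1 * x2])


@dataclass
class MetaModel:
    """Second-order response surface f(x1, x2) with cross term:
    b0 + b1 x1 + b2 x2 + b11 x1^2 + b22 x2^2 + b12 x1 x2."""

    coefficients: np.ndarray  # (b0, b1, b2, b11, b22, b12)
    r2: float
    key: tuple[str, str] = ("", "")  # (molecule, property)

    def __call__(self, x1, x2):
        b0, b1, b2, b11, b22, b12 = self.coefficients
        return b0 + b1 * x1 + b2 * x2 + b11 * x1**2 + b22 * x2**2 + b12 * x1 * x2

    def gradient(self, x1, x2) -> np.ndarray:
        b0, b1, b2, b11, b22, b12 = self.coefficients
        return np.array([b1 + 2 * b11 * x1 + b12 * x2, b2 + 2 * b22 * x2 + b12 * x1])


def fit_metamodels(coded_points: np.ndarray, responses: dict) -> dict:
    """Least-squares response surfaces, one per (molecule, property) key.

    ``responses`` maps key -> array of responses aligned with
    ``coded_points`` rows.
    """
    X = _quad_design(np.asarray(coded_points, dtype=float))
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("collinear design: cannot identify 6 surface coefficients")
    out = {}
    for key, y in responses.items():
        y = np.asarray(y, dtype=float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        pred = X @ beta
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - np.mean(y)) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        out[key] = MetaModel(beta, r2, key if isinstance(key, tuple) else (str(key), ""))
    return out


def objective(metamodels: dict, targets: dict, point) -> float:
    """Mean squared relative deviation between surfaces and targets.

    F(x1, x2) = (1 / (N_mol N_prop)) sum_k [ (f_k(x1,x2) - y_k) / y_k ]^2,
    with the sum over every (molecule, property) pair; non-negative and zero
    iff every surface matches its target at the point.
    """
    if set(metamodels) != set(targets):
        raise ValueError("metamodel and target sets do not match")
    x1, x2 = point
    n = len(metamodels)
    total = 0.0
    for key, mm in metamodels.items():
        y = targets[key]
        total += ((mm(x1, x2) - y) / y) ** 2
    return total / n


def _objective_gradient(metamodels, targets, point) -> np.ndarray:
    x1, x2 = point
    n = len(metamodels)
    g = np.zeros(2)
    for key, mm in metamodels.items():
        y = targets[key]
        g += 2.0 * (mm(x1, x2) - y) / y**2 * mm.gradient(x1, x2)
    return g / n


@dataclass
class OptimizationResult:
    x_coded: np.ndarray
    fun: float
    sigma: float | None
    epsilon: float | None
    trace: list = field(default_factory=list)  # (stage, iter, x1, x2, f, accepted)
    n_iter: int = 0
    diverged: bool = False


def _descent_stage(metamodels, targets, x0, step0, max_iter, stage,
                   trace, step_floor=1e-12, divergence_factor=1e6):
    x = np.asarray(x0, dtype=float).copy()
    f = objective(metamodels, targets, x)
    f0 = f
    best_x, best_f = x.copy(), f
    step = step0
    for it in range(max_iter):
        g = _objective_gradient(metamodels, targets, x)
        gn = np.linalg.norm(g)
        if gn < 1e-14 or step < step_floor:
            break
        x_new = x - step * g / gn
        f_new = objective(metamodels, targets, x_new)
        accepted = f_new < f
        trace.append((stage, it, float(x_new[0]), float(x_new[1]), float(f_new), accepted))
        if accepted:
            x, f = x_new, f_new
            step *= 1.2
            if f < best_f:
                best_x, best_f = x.copy(), f
        else:
            step *= 0.5
        if f_new > divergence_factor * max(f0, 1e-300):
            return best_x, best_f, step, True
    return best_x, best_f, step, False


def optimize(metamodels: dict, targets: dict, start=(0.0, 0.0),
             grid: DesignGrid | None = None, step0: float = 0.1,
             max_iter_stage1: int = 4000, max_iter_stage2: int = 100) -> OptimizationResult:
    """Two-stage steepest descent on the meta-model objective.

    Stage 1: up to ``max_iter_stage1`` iterations, variable (backtracking)
    step starting at ``step0`` coded units.  Its best-ever point seeds
    stage 2: up to ``max_iter_stage2`` iterations with the step reduced
    tenfold.  Returns the best-ever point with the full trace and, when a
    grid is supplied, the decoded physical (sigma, epsilon).
    """
    trace: list = []
    x1b, f1, step_end, div1 = _descent_stage(
        metamodels, targets, start, step0, max_iter_stage1, 1, trace)
    step2 = max(step_end, step0) / 10.0
    x2b, f2, _, div2 = _descent_stage(
        metamodels, targets, x1b, step2, max_iter_stage2, 2, trace)
    best_x, best_f = (x2b, f2) if f2 <= f1 else (x1b, f1)
    sigma = epsilon = None
    if grid is not None:
        sigma, epsilon = grid.decode(best_x[0], best_x[1])
        sigma, epsilon = float(sigma), float(epsilon)
    return OptimizationResult(
        x_coded=np.asarray(best_x), fun=float(best_f), sigma=sigma,
        epsilon=epsilon, trace=trace, n_iter=len(trace), diverged=div1 or div2,
    )
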