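"""Karplus-based 3J coupling prediction and conformer-population fitting.

A vicinal coupling constant depends on the intervening dihedral through
the Karplus relation J(theta) = A cos^2(theta) + B cos(theta) + C.
Ensemble-averaged couplings for each conformer region, together with
experimental couplings, constrain the region populations: the weights A
on the unit simplex minimize

    G(A) = sum_i (J_i^sim(A) - J_i^exp)^2,   J_i^sim(A) = sum_j A_j J_ij.

With fewer couplings than free weights the optimum is a set, not a point;
the fit then reports the bounding box of the optimal set and flags the
solution as non-unique.  Robustness against experimental error is profiled
with a deviation budget (default 0.2 Hz, the typical reported experimental
error): the interval per weight spans all simplex points whose RMS
coupling residual stays within the best-fit RMS plus the budget.  A strict
per-coupling variant (each residual within its best-fit value + budget) is
available via ``mode="per_coupling"``.

Karplus coefficients are deliberately required inputs: published
parameterizations differ by bond type and substitution, so no default set
is hard-coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .similarity import simplex_grid_iter

__all__ = [
    "KarplusParams",
    "CouplingObservable",
    "karplus_j",
    "ensemble_j",
    "fit_j_weights",
    "j_uncertainty",
    "JCouplingFitter",
]


@dataclass(frozen=True)
class KarplusParams:
    """Coefficients of J(theta) = A cos^2 theta + B cos theta + C, in Hz."""

    A: float
    B: float
    C: float
    tag: str = ""

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.A, self.B, self.C])):
            raise ValueError("Karplus coefficients must be finite")


@dataclass(frozen=True)
class CouplingObservable:
    """An experimental 3J coupling (Hz) with its reported error."""

    name: str
    j_exp: float
    sigma: float = 0.2

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def karplus_j(theta: np.ndarray | float, params: KarplusParams) -> np.ndarray | float:
    """Karplus coupling at dihedral(s) theta (radians)."""
    c = np.cos(theta)
    return params.A * c * c + params.B * c + params.C


def ensemble_j(samples: Sequence[float] | np.ndarray, params: KarplusParams) -> float:
    """Ensemble-averaged Karplus coupling over dihedral samples (radians)."""
    arr = np.asarray(samples, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot average an empty dihedral ensemble")
    return float(np.mean(karplus_j(arr, params)))


# ---------------------------------------------------------------------------


def _as_matrix(
    table: pd.DataFrame, observations: Sequence[CouplingObservable]
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """J matrix (n_obs, k), experimental vector, labels from a conformer table.

    ``table``: rows = conformer labels, columns = observable names, values =
    ensemble-averaged simulated couplings in Hz.  Every observable must be
    present for every conformer.
    """
    if not isinstance(table, pd.DataFrame):
        raise TypeError("conformer J table must be a pandas DataFrame")
    names = [o.name for o in observations]
    missing = set(names) - set(table.columns)
    if missing:
        raise ValueError(f"J table lacks observables {sorted(missing)}")
    sub = table[names]
    if sub.isna().any().any():
        raise ValueError("J table is incomplete (NaN entries)")
    J = sub.to_numpy(dtype=float).T  # (n_obs, k)
    j_exp = np.array([o.j_exp for o in observations], dtype=float)
    return J, j_exp, tuple(str(i) for i in table.index)


class JCouplingFitter(BaseEstimator):
    """Fit conformer populations to experimental 3J couplings.

    Parameters
    ----------
    delta : float
        Deviation budget in Hz for the uncertainty profile (default 0.2).
    mode : {"rms", "per_coupling"}
        Acceptance rule of the profile: RMS residual within best + delta,
        or every individual residual within its best-fit value + delta.
    grid_step : float
        Simplex resolution of the exhaustive interval scan (k <= 5).
    random_state : int
        Seed for the stochastic scan used when k > 5.

    Attributes
    ----------
    labels_ : tuple of conformer labels
    weights_ : best-fit simplex weights (maximal entropy among co-optima)
    g_ : residual sum of squares at the optimum (Hz^2)
    residuals_ : per-observable residuals at the optimum (Hz)
    unique_ : False when the optimum is a set (fit under-determined);
        ``intervals_`` then bounds that set at delta = 0 semantics
    intervals_ : (k, 2) min/max weights within the delta acceptance set
    optimal_box_ : (k, 2) bounding box of the exact-optimum set
    """

    def __init__(
        self,
        delta: float = 0.2,
        mode: str = "rms",
        grid_step: float = 0.01,
        max_grid_labels: int = 5,
        n_samples: int = 100_000,
        random_state: int = 0,
    ) -> None:
        self.delta = delta
        self.mode = mode
        self.grid_step = grid_step
        self.max_grid_labels = max_grid_labels
        self.n_samples = n_samples
        self.random_state = random_state

    def _g_batch(self, W: np.ndarray) -> np.ndarray:
        R = W @ self._J_.T - self._jexp_[None, :]
        return np.einsum("ni,ni->n", R, R)

    def _minimize(self) -> np.ndarray:
        k = self._J_.shape[1]
        if k == 1:
            return np.array([1.0])
        bounds = [(0.0, 1.0)] * k
        cons = [{"type": "eq", "fun": lambda a: a.sum() - 1.0}]
        starts = [np.eye(k)[i] for i in range(k)] + [np.full(k, 1.0 / k)]
        cands = []
        for a0 in starts:
            res = minimize(
                lambda a: float(self._g_batch(a[None, :])[0]),
                a0,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": 300, "ftol": 1e-16},
            )
            a = np.clip(res.x, 0.0, None)
            a /= a.sum()
            cands.append((float(self._g_batch(a[None, :])[0]), a))
        g_best = min(g for g, _ in cands)
        ties = [a for g, a in cands if g <= g_best + 1e-12]
        ent = [-np.sum(np.where(a > 0, a * np.log(np.where(a > 0, a, 1.0)), 0.0)) for a in ties]
        return ties[int(np.argmax(ent))]

    def _scan(self, accept_fn) -> tuple[np.ndarray, np.ndarray]:
        """Min/max weights over simplex points passing ``accept_fn(W) -> bool[]``."""
        k = self._J_.shape[1]
        lo = self.weights_.copy()
        hi = self.weights_.copy()
        if k <= self.max_grid_labels:
            n = int(round(1.0 / self.grid_step))
            chunks = simplex_grid_iter(k, n)
        else:
            rng = np.random.default_rng(self.random_state)
            chunks = iter([rng.dirichlet(np.ones(k), size=self.n_samples)])
        for W in chunks:
            ok = accept_fn(W)
            if np.any(ok):
                Wo = W[ok]
                lo = np.minimum(lo, Wo.min(axis=0))
                hi = np.maximum(hi, Wo.max(axis=0))
        return lo, hi

    def _interval_scan(self, delta: float) -> np.ndarray:
        n_obs = self._jexp_.size
        if self.mode == "rms":
            best_rms = np.sqrt(self.g_ / n_obs)
            bound = (best_rms + delta) ** 2 * n_obs

            def accept(W):
                return self._g_batch(W) <= bound + 1e-15

            feas_cons = [{"type": "ineq", "fun": lambda a: bound - float(self._g_batch(a[None, :])[0])}]
        elif self.mode == "per_coupling":
            best_abs = np.abs(self.residuals_)

            def accept(W):
                R = np.abs(W @ self._J_.T - self._jexp_[None, :])
                return np.all(R <= best_abs[None, :] + delta + 1e-15, axis=1)

            feas_cons = []
            for i in range(n_obs):
                b = float(best_abs[i] + delta)
                feas_cons.append(
                    {"type": "ineq", "fun": lambda a, i=i, b=b: b - (a @ self._J_[i] - self._jexp_[i])}
                )
                feas_cons.append(
                    {"type": "ineq", "fun": lambda a, i=i, b=b: b + (a @ self._J_[i] - self._jexp_[i])}
                )
        else:
            raise ValueError(f"unknown uncertainty mode {self.mode!r}")
        lo, hi = self._scan(accept)
        return self._polish_bounds(feas_cons, accept, lo, hi)

    def _polish_bounds(self, feas_cons, accept, lo, hi) -> np.ndarray:
        """Extremize each weight within the acceptance set by SLSQP.

        The grid scan only sees lattice points; near a measure-zero optimal
        fiber (exactly fitted, under-determined systems) the constrained
        extremization recovers the true bounds.
        """
        k = self._J_.shape[1]
        bounds = [(0.0, 1.0)] * k
        cons = [{"type": "eq", "fun": lambda a: a.sum() - 1.0}] + feas_cons
        for i in range(k):
            for sign, arr in ((1.0, lo), (-1.0, hi)):
                res = minimize(
                    lambda a, i=i, s=sign: s * a[i],
                    self.weights_,
                    method="SLSQP",
                    bounds=bounds,
                    constraints=cons,
                    options={"maxiter": 300, "ftol": 1e-12},
                )
                if res.success:
                    a = np.clip(res.x, 0.0, 1.0)
                    a /= a.sum()
                    feasible = all(float(c["fun"](a)) >= -1e-9 for c in feas_cons)
                    if feasible:
                        if sign > 0:
                            lo[i] = min(lo[i], float(a[i]))
                        else:
                            hi[i] = max(hi[i], float(a[i]))
        return np.column_stack([lo, hi])

    def fit(
        self, table: pd.DataFrame, observations: Sequence[CouplingObservable]
    ) -> "JCouplingFitter":
        """Fit region populations to experimental couplings."""
        if len(observations) < 1:
            raise ValueError("need at least one coupling observable")
        J, j_exp, labels = _as_matrix(table, observations)
        self._J_, self._jexp_ = J, j_exp
        self.labels_ = labels
        self.weights_ = self._minimize()
        self.g_ = float(self._g_batch(self.weights_[None, :])[0])
        self.residuals_ = self.weights_ @ J.T - j_exp
        # bounding box of the exact-optimum set (delta = 0); non-degenerate
        # width means the system is under-determined on the simplex
        self.optimal_box_ = self._interval_scan(0.0)
        width = self.optimal_box_[:, 1] - self.optimal_box_[:, 0]
        self.unique_ = bool(np.all(width <= 1e-3))
        self.intervals_ = self._interval_scan(self.delta)
        return self

    def predict(self) -> np.ndarray:
        """Ensemble-averaged couplings (Hz) at the best-fit weights."""
        return self.weights_ @ self._J_.T

    def as_dict(self) -> dict:
        return {
            "labels": list(self.labels_),
            "weights": [float(x) for x in self.weights_],
            "g": self.g_,
            "rms_residual_hz": float(np.sqrt(self.g_ / self._jexp_.size)),
            "unique": self.unique_,
            "optimal_box": [[float(a), float(b)] for a, b in self.optimal_box_],
            "intervals": [[float(a), float(b)] for a, b in self.intervals_],
            "delta_hz": float(self.delta),
            "mode": self.mode,
        }


def fit_j_weights(
    table: pd.DataFrame,
    observations: Sequence[CouplingObservable],
    delta: float = 0.2,
    mode: str = "rms",
    random_state: int = 0,
) -> JCouplingFitter:
    """Fit conformer populations to experimental couplings; returns the fitter."""
    return JCouplingFitter(delta=delta, mode=mode, random_state=random_state).fit(
        table, observations
    )


def j_uncertainty(
    fitter: JCouplingFitter,
    delta: float = 0.2,
) -> np.ndarray:
    """Weight intervals for a given deviation budget (Hz) from a fitted model."""
    return fitter._interval_scan(delta)
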