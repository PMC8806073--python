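"""Spectral similarity scoring and conformer-weight decomposition.

The similarity of a simulated and an experimental spectrum is measured by
the normalized overlap integral

    S = int I_sim I_exp dnu / sqrt(int I_sim^2 dnu * int I_exp^2 dnu)

evaluated over a wavenumber window.  S is invariant to positive rescaling
of either spectrum, symmetric, and bounded in [-1, 1]; S = 1 exactly for
proportional spectra (positive factor).

A candidate ensemble is a convex combination of per-conformer ensemble
spectra, I(A) = sum_i A_i I_i with weights A on the unit simplex.  The
best-fit weights minimize the joint Raman+ROA cost

    F(A) = (1 - S_Raman(A))^2 + (1 - S_ROA(A))^2,

and the robustness of the solution is profiled by finding, per conformer,
the extreme weights among all simplex points whose S_Raman + S_ROA stays
above a fraction (default 0.99) of the best-fit sum.  The same machinery
decomposes anomeric equilibria and chemical mixtures: "conformers" are
then anomers or pure species.

Because S only depends on inner products, all searches are driven by
precomputed Gram matrices, making exhaustive simplex-grid scans cheap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .spectra import ContinuousSpectrum, SpectrumPair, WavenumberGrid

__all__ = [
    "ConformerSpectra",
    "WeightSolution",
    "overlap",
    "compose",
    "cost",
    "fit_weights",
    "weight_uncertainty",
    "SpectralDecomposer",
]


@dataclass(frozen=True)
class ConformerSpectra:
    """Ensemble-averaged spectrum pair per conformer label, on one grid."""

    labels: tuple[str, ...]
    pairs: tuple[SpectrumPair, ...]

    def __post_init__(self) -> None:
        if len(self.labels) < 1:
            raise ValueError("need at least one conformer")
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("conformer labels must be unique")
        if len(self.labels) != len(self.pairs):
            raise ValueError("labels and pairs must align")
        grid = self.pairs[0].grid
        for p in self.pairs[1:]:
            if p.grid != grid:
                raise ValueError("all conformer spectra must share one grid")

    @classmethod
    def from_dict(cls, d: Mapping[str, SpectrumPair]) -> "ConformerSpectra":
        return cls(tuple(d.keys()), tuple(d.values()))

    @property
    def grid(self) -> WavenumberGrid:
        return self.pairs[0].grid

    def __len__(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class WeightSolution:
    """Best-fit conformer weights with overlaps, cost and uncertainty intervals.

    ``intervals[i] = (lo, hi)`` is the range of weight i over all simplex
    points whose S_Raman + S_ROA exceeds ``threshold`` times the best-fit
    sum.  ``rho_raman``/``rho_roa`` are the norm-matching intensity scale
    factors ||I_exp|| / ||I_sim(A)|| (reported for plotting; S itself is
    scale-invariant).
    """

    labels: tuple[str, ...]
    weights: np.ndarray
    s_raman: float
    s_roa: float
    f: float
    intervals: np.ndarray | None = None
    threshold: float = 0.99
    identifiable: bool = True
    rho_raman: float | None = None
    rho_roa: float | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.labels),):
            raise ValueError("weights must align with labels")
        if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        f_check = (1.0 - self.s_raman) ** 2 + (1.0 - self.s_roa) ** 2
        if abs(self.f - f_check) > 1e-9:
            raise ValueError("cost f inconsistent with overlaps")
        if self.intervals is not None:
            iv = np.asarray(self.intervals, dtype=float)
            object.__setattr__(self, "intervals", iv)
            if iv.shape != (len(self.labels), 2):
                raise ValueError("intervals must be (n_labels, 2)")
            if np.any(w < iv[:, 0] - 1e-9) or np.any(w > iv[:, 1] + 1e-9):
                raise ValueError("intervals must contain the best-fit weights")

    def as_dict(self) -> dict:
        d = {
            "labels": list(self.labels),
            "weights": [float(x) for x in self.weights],
            "s_raman": float(self.s_raman),
            "s_roa": float(self.s_roa),
            "f": float(self.f),
            "threshold": float(self.threshold),
            "identifiable": bool(self.identifiable),
        }
        if self.intervals is not None:
            d["intervals"] = [[float(a), float(b)] for a, b in self.intervals]
        if self.rho_raman is not None:
            d["rho_raman"] = float(self.rho_raman)
        if self.rho_roa is not None:
            d["rho_roa"] = float(self.rho_roa)
        return d


# ---------------------------------------------------------------------------
# overlap integral


def _window_slice(grid: WavenumberGrid, window: WavenumberGrid | None) -> np.ndarray:
    pts = grid.points
    if window is None:
        return np.ones_like(pts, dtype=bool)
    sel = (pts >= window.start - 1e-9) & (pts <= window.stop + 1e-9)
    if sel.sum() < 2:
        raise ValueError("window selects fewer than two grid points")
    return sel


def _trapz_weights(x: np.ndarray) -> np.ndarray:
    """Quadrature weights w such that w @ y == trapezoid(y, x)."""
    w = np.zeros_like(x)
    dx = np.diff(x)
    w[:-1] += dx / 2.0
    w[1:] += dx / 2.0
    return w


def overlap(
    sim: ContinuousSpectrum,
    exp: ContinuousSpectrum,
    window: WavenumberGrid | None = None,
) -> float:
    """Normalized overlap integral of two spectra over ``window``.

    Raises ``ValueError`` if either spectrum has zero norm on the window.
    """
    if sim.grid != exp.grid:
        raise ValueError("spectra must share one grid (resample first)")
    sel = _window_slice(sim.grid, window)
    x = sim.grid.points[sel]
    w = _trapz_weights(x)
    a = sim.values[sel]
    b = exp.values[sel]
    na = w @ (a * a)
    nb = w @ (b * b)
    if na <= 0 or nb <= 0:
        raise ValueError("overlap undefined for a zero-norm spectrum on the window")
    s = (w @ (a * b)) / np.sqrt(na * nb)
    return float(np.clip(s, -1.0, 1.0))


def compose(
    weights: Mapping[str, float] | Sequence[float] | np.ndarray,
    conformers: ConformerSpectra,
) -> SpectrumPair:
    """Pointwise weighted sum of conformer spectrum pairs."""
    if isinstance(weights, Mapping):
        missing = set(conformers.labels) - set(weights)
        extra = set(weights) - set(conformers.labels)
        if missing or extra:
            raise ValueError(f"weight labels mismatch (missing {missing}, extra {extra})")
        w = np.array([weights[lab] for lab in conformers.labels], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (len(conformers),):
            raise ValueError("weight vector length must match the number of conformers")
    if np.any(w < -1e-12):
        raise ValueError("weights must be non-negative")
    grid = conformers.grid
    raman = sum(wi * p.raman.values for wi, p in zip(w, conformers.pairs))
    roa = sum(wi * p.roa.values for wi, p in zip(w, conformers.pairs))
    return SpectrumPair(
        ContinuousSpectrum(grid, raman, "raman"),
        ContinuousSpectrum(grid, roa, "roa"),
    )


# ---------------------------------------------------------------------------
# Gram-matrix kernel: S values for batches of weight vectors


class _FitKernel:
    """Precomputed inner products turning S(A) into O(K^2) algebra.

    For each channel c: G_c[ij] = <I_i, I_j>, m_c[i] = <I_i, I_exp>,
    e_c = <I_exp, I_exp>, so S_c(A) = (A.m_c) / sqrt((A.G_c.A) e_c).
    """

    def __init__(
        self,
        conformers: ConformerSpectra,
        experiment: SpectrumPair,
        window: WavenumberGrid | None = None,
    ) -> None:
        if conformers.grid != experiment.grid:
            raise ValueError("conformer and experimental spectra must share one grid")
        self.labels = conformers.labels
        self.k = len(conformers)
        sel = _window_slice(conformers.grid, window)
        x = conformers.grid.points[sel]
        w = _trapz_weights(x)
        self.gram: dict[str, np.ndarray] = {}
        self.m: dict[str, np.ndarray] = {}
        self.e: dict[str, float] = {}
        self._basis: dict[str, np.ndarray] = {}
        for chan in ("raman", "roa"):
            V = np.stack([getattr(p, chan).values[sel] for p in conformers.pairs])
            y = getattr(experiment, chan).values[sel]
            ey = float(w @ (y * y))
            if ey <= 0:
                raise ValueError(f"experimental {chan} spectrum has zero norm on the window")
            self.gram[chan] = (V * w) @ V.T
            self.m[chan] = (V * w) @ y
            self.e[chan] = ey
            self._basis[chan] = V * np.sqrt(w)

    def s_batch(self, W: np.ndarray, chan: str) -> np.ndarray:
        """S_chan for a batch of weight vectors, shape (N, K) -> (N,)."""
        G, m, e = self.gram[chan], self.m[chan], self.e[chan]
        num = W @ m
        qq = np.einsum("nk,kl,nl->n", W, G, W)
        den = np.sqrt(np.maximum(qq, 0.0) * e)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(den > 0, num / den, -np.inf)
        return np.clip(s, -1.0, 1.0)

    def s_pair(self, A: np.ndarray) -> tuple[float, float]:
        W = np.atleast_2d(A)
        return float(self.s_batch(W, "raman")[0]), float(self.s_batch(W, "roa")[0])

    def cost(self, A: np.ndarray) -> float:
        sr, so = self.s_pair(A)
        return (1.0 - sr) ** 2 + (1.0 - so) ** 2

    def s_sum_batch(self, W: np.ndarray) -> np.ndarray:
        return self.s_batch(W, "raman") + self.s_batch(W, "roa")

    def rho(self, A: np.ndarray, chan: str) -> float:
        """Norm-matching scale ||I_exp|| / ||I_sim(A)|| on the window."""
        q = float(A @ self.gram[chan] @ A)
        return float(np.sqrt(self.e[chan] / q)) if q > 0 else float("nan")

    def identifiable(self) -> bool:
        """Numerical full rank of the stacked Raman+ROA conformer basis."""
        if self.k == 1:
            return True
        B = np.hstack([self._basis["raman"], self._basis["roa"]])
        sv = np.linalg.svd(B, compute_uv=False)
        return bool(sv[-1] > max(B.shape) * np.finfo(float).eps * sv[0] * 1e4)


def cost(
    weights: Mapping[str, float] | Sequence[float] | np.ndarray,
    conformers: ConformerSpectra,
    experiment: SpectrumPair,
    window: WavenumberGrid | None = None,
) -> float:
    """Joint Raman+ROA cost F(A) = (1 - S_Raman)^2 + (1 - S_ROA)^2."""
    if isinstance(weights, Mapping):
        w = np.array([weights[lab] for lab in conformers.labels], dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
    return _FitKernel(conformers, experiment, window).cost(w)


# ---------------------------------------------------------------------------
# simplex enumeration


def simplex_grid_iter(k: int, n: int, chunk: int = 200_000) -> Iterator[np.ndarray]:
    """Yield chunks of all weight vectors on the k-simplex at resolution 1/n.

    Enumerates integer compositions of n into k parts (stars and bars),
    divided by n; deterministic lexicographic order.
    """

    def compositions(n_: int, k_: int) -> np.ndarray:
        if k_ == 1:
            return np.array([[n_]], dtype=np.int32)
        blocks = []
        for first in range(n_ + 1):
            rest = compositions(n_ - first, k_ - 1)
            head = np.full((rest.shape[0], 1), first, dtype=np.int32)
            blocks.append(np.hstack([head, rest]))
        return np.vstack(blocks)

    if k == 1:
        yield np.array([[1.0]])
        return
    # enumerate over the first coordinate to bound memory
    for first in range(n + 1):
        rest = compositions(n - first, k - 1)
        head = np.full((rest.shape[0], 1), first, dtype=np.int32)
        block = np.hstack([head, rest]).astype(float) / n
        for i in range(0, block.shape[0], chunk):
            yield block[i : i + chunk]


# ---------------------------------------------------------------------------
# estimator


class SpectralDecomposer(BaseEstimator):
    """Decompose an experimental Raman/ROA pair into conformer weights.

    Minimizes F(A) = (1 - S_Raman(A))^2 + (1 - S_ROA(A))^2 over the unit
    simplex with a deterministic multi-start protocol (every pure-conformer
    vertex, the uniform center, and seeded Dirichlet draws, each polished
    by SLSQP), then profiles per-weight uncertainty intervals from all
    simplex points keeping S_Raman + S_ROA above ``threshold`` times the
    best-fit sum.

    Parameters
    ----------
    window : WavenumberGrid or None
        Wavenumber window for the overlap integrals (None = full grid).
    threshold : float
        Fraction of the best-fit overlap sum defining acceptable solutions
        in the uncertainty profile.
    n_starts : int
        Total number of optimizer starts (vertices + center + random).
    grid_step : float
        Simplex resolution of the exhaustive uncertainty scan.
    max_grid_labels : int
        Up to this many conformers the uncertainty scan is exhaustive;
        beyond, seeded Dirichlet sampling plus constrained polishing.
    n_samples : int
        Number of Dirichlet samples in the stochastic uncertainty scan.
    random_state : int
        Seed for all stochastic pieces; identical inputs and seed give
        identical output.
    compute_intervals : bool
        Skip the uncertainty profile when False (faster).

    Attributes
    ----------
    labels_ : tuple of str
    weights_ : ndarray, best-fit simplex weights
    s_raman_, s_roa_, f_ : floats at the optimum
    intervals_ : ndarray (k, 2) or None
    identifiable_ : bool, False when conformer spectra are numerically
        linearly dependent (weights then not unique)
    rho_raman_, rho_roa_ : norm-matching intensity scale factors
    solution_ : WeightSolution bundling the above
    """

    def __init__(
        self,
        window: WavenumberGrid | None = None,
        threshold: float = 0.99,
        n_starts: int = 32,
        grid_step: float = 0.01,
        max_grid_labels: int = 5,
        n_samples: int = 100_000,
        random_state: int = 0,
        compute_intervals: bool = True,
    ) -> None:
        self.window = window
        self.threshold = threshold
        self.n_starts = n_starts
        self.grid_step = grid_step
        self.max_grid_labels = max_grid_labels
        self.n_samples = n_samples
        self.random_state = random_state
        self.compute_intervals = compute_intervals

    # -- fitting ----------------------------------------------------------

    def _minimize(self, kernel: _FitKernel) -> np.ndarray:
        k = kernel.k
        if k == 1:
            return np.array([1.0])
        rng = np.random.default_rng(self.random_state)
        starts = [np.eye(k)[i] for i in range(k)]
        starts.append(np.full(k, 1.0 / k))
        n_random = max(self.n_starts - len(starts), 0)
        if n_random:
            starts.extend(rng.dirichlet(np.ones(k), size=n_random))
        bounds = [(0.0, 1.0)] * k
        cons = [{"type": "eq", "fun": lambda a: a.sum() - 1.0}]
        candidates: list[tuple[float, np.ndarray]] = []
        for a0 in starts:
            res = minimize(
                kernel.cost,
                a0,
                method="SLSQP",
                bounds=bounds,
                constraints=cons,
                options={"maxiter": 200, "ftol": 1e-14},
            )
            a = np.clip(res.x, 0.0, None)
            s = a.sum()
            a = a / s if s > 0 else np.full(k, 1.0 / k)
            candidates.append((kernel.cost(a), a))
            candidates.append((kernel.cost(a0), np.asarray(a0, dtype=float)))
        f_best = min(f for f, _ in candidates)
        # tie-break co-optimal solutions by maximal entropy (least committal)
        ties = [a for f, a in candidates if f <= f_best + 1e-12]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = [-np.sum(np.where(a > 0, a * np.log(a), 0.0)) for a in ties]
        return ties[int(np.argmax(ent))]

    def _intervals(self, kernel: _FitKernel, best: np.ndarray) -> np.ndarray:
        thr = self.threshold * float(kernel.s_sum_batch(best[None, :])[0])
        k = kernel.k
        lo = best.copy()
        hi = best.copy()
        if k <= self.max_grid_labels:
            n = int(round(1.0 / self.grid_step))
            for W in simplex_grid_iter(k, n):
                ok = kernel.s_sum_batch(W) >= thr - 1e-12
                if np.any(ok):
                    Wo = W[ok]
                    lo = np.minimum(lo, Wo.min(axis=0))
                    hi = np.maximum(hi, Wo.max(axis=0))
        else:
            rng = np.random.default_rng(self.random_state + 1)
            W = rng.dirichlet(np.ones(k), size=self.n_samples)
            ok = kernel.s_sum_batch(W) >= thr - 1e-12
            if np.any(ok):
                Wo = W[ok]
                lo = np.minimum(lo, Wo.min(axis=0))
                hi = np.maximum(hi, Wo.max(axis=0))
            lo, hi = self._polish_bounds(kernel, best, thr, lo, hi)
        return np.column_stack([lo, hi])

    def _polish_bounds(self, kernel, best, thr, lo, hi):
        """Constrained extremization of each weight within the acceptance set."""
        k = kernel.k
        bounds = [(0.0, 1.0)] * k
        cons = [
            {"type": "eq", "fun": lambda a: a.sum() - 1.0},
            {"type": "ineq", "fun": lambda a: float(kernel.s_sum_batch(a[None, :])[0]) - thr},
        ]
        for i in range(k):
            for sign, arr in ((1.0, lo), (-1.0, hi)):
                res = minimize(
                    lambda a, i=i, s=sign: s * a[i],
                    best,
                    method="SLSQP",
                    bounds=bounds,
                    constraints=cons,
                    options={"maxiter": 200, "ftol": 1e-12},
                )
                if res.success:
                    a = np.clip(res.x, 0.0, 1.0)
                    a /= a.sum()
                    if kernel.s_sum_batch(a[None, :])[0] >= thr - 1e-9:
                        if sign > 0:
                            lo[i] = min(lo[i], a[i])
                        else:
                            hi[i] = max(hi[i], a[i])
        return lo, hi

    def fit(self, conformers: ConformerSpectra, experiment: SpectrumPair) -> "SpectralDecomposer":
        """Fit conformer weights to the experimental Raman/ROA pair."""
        kernel = _FitKernel(conformers, experiment, self.window)
        best = self._minimize(kernel)
        sr, so = kernel.s_pair(best)
        self.labels_ = kernel.labels
        self.weights_ = best
        self.s_raman_ = sr
        self.s_roa_ = so
        self.f_ = (1.0 - sr) ** 2 + (1.0 - so) ** 2
        self.identifiable_ = kernel.identifiable()
        self.rho_raman_ = kernel.rho(best, "raman")
        self.rho_roa_ = kernel.rho(best, "roa")
        self.intervals_ = self._intervals(kernel, best) if self.compute_intervals else None
        self._kernel_ = kernel
        self._conformers_ = conformers
        self.solution_ = WeightSolution(
            labels=self.labels_,
            weights=self.weights_,
            s_raman=self.s_raman_,
            s_roa=self.s_roa_,
            f=self.f_,
            intervals=self.intervals_,
            threshold=self.threshold,
            identifiable=self.identifiable_,
            rho_raman=self.rho_raman_,
            rho_roa=self.rho_roa_,
        )
        return self

    def predict(self) -> SpectrumPair:
        """Best-fit composed spectrum pair."""
        return compose(self.weights_, self._conformers_)

    def score(self) -> float:
        """S_Raman + S_ROA at the best fit (larger is better, max 2)."""
        return self.s_raman_ + self.s_roa_


# ---------------------------------------------------------------------------
# functional wrappers


def fit_weights(
    conformers: ConformerSpectra,
    experiment: SpectrumPair,
    window: WavenumberGrid | None = None,
    threshold: float = 0.99,
    random_state: int = 0,
    compute_intervals: bool = True,
) -> WeightSolution:
    """Best-fit simplex weights of conformer spectra to an experimental pair."""
    est = SpectralDecomposer(
        window=window,
        threshold=threshold,
        random_state=random_state,
        compute_intervals=compute_intervals,
    )
    return est.fit(conformers, experiment).solution_


def weight_uncertainty(
    solution: WeightSolution,
    conformers: ConformerSpectra,
    experiment: SpectrumPair,
    window: WavenumberGrid | None = None,
    threshold: float = 0.99,
    grid_step: float = 0.01,
    random_state: int = 0,
) -> np.ndarray:
    """Per-label weight intervals over the relaxed acceptance set.

    A simplex point is acceptable when its S_Raman + S_ROA exceeds
    ``threshold`` times the solution's sum; returns (k, 2) min/max weights.
    """
    est = SpectralDecomposer(
        window=window, threshold=threshold, grid_step=grid_step, random_state=random_state
    )
    kernel = _FitKernel(conformers, experiment, window)
    est.threshold = threshold
    return est._intervals(kernel, np.asarray(solution.weights, dtype=float))
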