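"""Pan-genome accumulation curves, power-law fitting, and openness analysis.

Accumulation curves are built from random permutations of strain inclusion
order (exact enumeration of all n! orders is available for small n).  The
pan-genome trend is fitted as ``y = k * x**alpha``; the core-genome trend as
a power law plus a decreasing linear term ``y = K * x**a + b*x + c``.  A
new-gene exponent strictly between -1 and 0 classifies the pan-genome as
open; the delete-half jackknife maps out the exponent's sampling spread.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DomainError, ParameterError
from .matrix_io import OrthologMatrix

__all__ = [
    "AccumulationCurves",
    "PowerFit",
    "CoreFit",
    "accumulate",
    "fit_power",
    "fit_core",
    "classify_openness",
    "strains_to_threshold",
    "jackknife_alpha",
    "JackknifeResult",
]

_EXACT_MAX_STRAINS = 8
_PERM_BATCH = 256


@dataclass
class AccumulationCurves:
    """Per-permutation pan / core / new counts for k = 1..n strains.

    ``pan``, ``core`` and ``new`` have shape ``(n_orders, n_strains)`` where
    row r is one inclusion order.  ``exact`` marks full enumeration of all
    n! orders (in which case ``n_perm`` is n!).
    """

    pan: np.ndarray
    core: np.ndarray
    new: np.ndarray
    exact: bool
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return self.pan.shape[0]

    @property
    def n_strains(self) -> int:
        return self.pan.shape[1]

    def mean(self, which: str = "pan") -> np.ndarray:
        return getattr(self, which).mean(axis=0)

    def median(self, which: str = "pan") -> np.ndarray:
        return np.median(getattr(self, which), axis=0)

    def curve(self, which: str = "pan", statistic: Literal["mean", "median"] = "mean") -> np.ndarray:
        if statistic == "mean":
            return self.mean(which)
        if statistic == "median":
            return self.median(which)
        raise ParameterError(f"unknown statistic {statistic!r}")

    def summary(self) -> pd.DataFrame:
        """Tidy per-k summary: mean/median/quartiles/min/max for each curve."""
        rows = []
        for which in ("pan", "core", "new"):
            arr = getattr(self, which)
            for k in range(arr.shape[1]):
                col = arr[:, k]
                rows.append(
                    {
                        "curve": which,
                        "k": k + 1,
                        "mean": col.mean(),
                        "median": np.median(col),
                        "q25": np.percentile(col, 25),
                        "q75": np.percentile(col, 75),
                        "min": col.min(),
                        "max": col.max(),
                    }
                )
        return pd.DataFrame(rows)


def _orders_curves(P: np.ndarray, orders: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pan/core/new counts for a batch of inclusion orders.

    P is the (n_strains, n_groups) boolean presence matrix; orders has shape
    (R, n_strains).  Batched boolean accumulate keeps this vectorised.
    """
    pans = []
    cores = []
    for start in range(0, orders.shape[0], _PERM_BATCH):
        chunk = orders[start : start + _PERM_BATCH]
        sub = P[chunk]  # (r, n, g)
        pan = np.logical_or.accumulate(sub, axis=1).sum(axis=2)
        core = np.logical_and.accumulate(sub, axis=1).sum(axis=2)
        pans.append(pan)
        cores.append(core)
    pan = np.concatenate(pans).astype(np.int64)
    core = np.concatenate(cores).astype(np.int64)
    new = np.diff(pan, axis=1, prepend=0)
    return pan, core, new


def accumulate(
    matrix: OrthologMatrix,
    n_perm: int = 10_000,
    seed: int | None = None,
    mode: Literal["auto", "exact", "sample"] = "auto",
) -> AccumulationCurves:
    """Accumulation curves over random (or exhaustively enumerated) orders.

    In ``auto`` mode all n! orders are enumerated when n <= 8; otherwise
    ``n_perm`` uniform random permutations are drawn from a generator seeded
    with ``seed``.
    """
    if matrix.n_strains < 1:
        raise DomainError("need at least one strain")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    n = matrix.n_strains
    P = matrix.presence

    if mode not in ("auto", "exact", "sample"):
        raise ParameterError(f"unknown mode {mode!r}")
    exact = mode == "exact" or (mode == "auto" and n <= _EXACT_MAX_STRAINS)
    if exact and n > _EXACT_MAX_STRAINS:
        raise ParameterError(f"exact mode limited to n <= {_EXACT_MAX_STRAINS} strains")

    if exact:
        orders = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
    else:
        rng = np.random.default_rng(seed)
        orders = np.empty((n_perm, n), dtype=np.intp)
        for r in range(n_perm):
            orders[r] = rng.permutation(n)
    pan, core, new = _orders_curves(P, orders)
    return AccumulationCurves(pan=pan, core=core, new=new, exact=exact, seed=seed)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerFit:
    """Least-squares fit of ``y = k * x**alpha`` (r2 on the original scale)."""

    k: float
    alpha: float
    r2: float
    n_points: int
    converged: bool = True

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.k * np.power(x, self.alpha)


@dataclass(frozen=True)
class CoreFit:
    """Least-squares fit of ``y = K * x**a + b*x + c``."""

    K: float
    a: float
    b: float
    c: float
    r2: float
    n_points: int
    converged: bool = True

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return self.K * np.power(x, self.a) + self.b * x + self.c


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else 0.0
    return 1.0 - ss_res / ss_tot

def fit_power(x: np.ndarray, y: np.ndarray) -> PowerFit:
    """Fit ``y = k * x**alpha`` by nonlinear least squares on the original
    scale, initialised from the log-log linear regression."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D arrays of equal length")
    if len(x) < 3:
        raise ParameterError("need at least 3 points")
    if (x < 1).any():
        raise DomainError("x values must be >= 1")
    if (y <= 0).any():
        raise DomainError("all y values must be positive (log-init impossible)")

    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    p0 = (math.exp(intercept), slope)
    converged = True
    try:
        popt, _ = curve_fit(
            lambda t, k, a: k * np.power(t, a), x, y, p0=p0, maxfev=20_000
        )
        k, alpha = float(popt[0]), float(popt[1])
    except RuntimeError:
        k, alpha = p0
        converged = False
    yhat = k * np.power(x, alpha)
    return PowerFit(k=k, alpha=alpha, r2=_r2(y, yhat), n_points=len(x), converged=converged)


def fit_core(x: np.ndarray, y: np.ndarray) -> CoreFit:
    """Fit ``y = K * x**a + b*x + c`` with multi-start initialisation.

    The 4-parameter surface is multimodal, so initial exponents a0 in
    {-0.5, -1, -2} are tried; for each, (K, b, c) start from the OLS solution
    of y on [x**a0, x, 1].  The best converged SSE wins.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 5:
        raise ParameterError("need at least 5 points")

    def model(t, K, a, b, c):
        return K * np.power(t, a) + b * t + c

    best: tuple[float, np.ndarray] | None = None
    for a0 in (-0.5, -1.0, -2.0):
        A = np.column_stack([np.power(x, a0), x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        p0 = (coef[0], a0, coef[1], coef[2])
        try:
            popt, _ = curve_fit(model, x, y, p0=p0, maxfev=50_000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - model(x, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        # flagged non-convergence: report the best linear-only baseline
        A = np.column_stack([x, np.ones_like(x)])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        yhat = A @ coef
        return CoreFit(0.0, 0.0, float(coef[0]), float(coef[1]), _r2(y, yhat),
                       len(x), converged=False)
    K, a, b, c = (float(v) for v in best[1])
    yhat = model(x, K, a, b, c)
    return CoreFit(K=K, a=a, b=b, c=c, r2=_r2(y, yhat), n_points=len(x))


def classify_openness(fit: PowerFit) -> str:
    """Classify a new-gene power fit: ``open`` iff -1 < alpha < 0, ``closed``
    for alpha <= -1 (boundary inclusive), ``non-decaying`` for alpha >= 0."""
    if not fit.converged:
        raise DomainError("cannot classify a non-converged fit")
    if fit.alpha >= 0:
        return "non-decaying"
    return "open" if fit.alpha > -1.0 else "closed"


def strains_to_threshold(fit: PowerFit, threshold: float = 1.0) -> int:
    """Smallest integer N with ``k * N**alpha <= threshold``.

    Only decaying fits (alpha < 0, k > 0) ever reach the threshold.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    if fit.alpha >= 0 or fit.k <= 0:
        raise DomainError("fit never decays below the threshold (alpha >= 0)")
    if fit.k <= threshold:
        return 1
    N = max(1, math.ceil((fit.k / threshold) ** (1.0 / abs(fit.alpha))))
    while N > 1 and fit.k * (N - 1) ** fit.alpha <= threshold:
        N -= 1
    while fit.k * N**fit.alpha > threshold:
        N += 1
    return N


# ---------------------------------------------------------------------------
# Delete-half jackknife
# ---------------------------------------------------------------------------

@dataclass
class JackknifeResult:
    """Distribution of the new-gene exponent over delete-half subsamples."""

    alphas: np.ndarray
    n_skipped: int
    n_subsamples: int
    seed: int | None = None
    statistic: str = "mean"

    @property
    def mean(self) -> float:
        return float(self.alphas.mean()) if len(self.alphas) else math.nan

    @property
    def min(self) -> float:
        return float(self.alphas.min()) if len(self.alphas) else math.nan

    @property
    def max(self) -> float:
        return float(self.alphas.max()) if len(self.alphas) else math.nan


def jackknife_alpha(
    matrix: OrthologMatrix,
    n_subsamples: int = 2000,
    n_perm_per_subsample: int = 1000,
    seed: int | None = None,
    statistic: Literal["mean", "median"] = "mean",
) -> JackknifeResult:
    """New-gene exponent distribution over random delete-half subsamples.

    Each subsample keeps ceil(n/2) strains drawn without replacement; the
    mean (or median) new-gene curve of ``n_perm_per_subsample`` random orders
    is fitted with :func:`fit_power`.  Degenerate subsamples (no new genes
    beyond k = 1, or a zero point making the fit impossible) are skipped and
    counted.  Subsample RNG streams are spawned from one seed sequence, so
    runs are reproducible.
    """
    n = matrix.n_strains
    if n < 4:
        raise DomainError("jackknife requires at least 4 strains")
    keep = math.ceil(n / 2)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subsamples + 1)
    pick_rng = np.random.default_rng(children[0])

    alphas: list[float] = []
    skipped = 0
    for i in range(n_subsamples):
        idx = pick_rng.choice(n, size=keep, replace=False)
        sub = matrix.select_strains([matrix.strains[j] for j in idx])
        sub_seed = int(children[i + 1].generate_state(1)[0])
        curves = accumulate(sub, n_perm=n_perm_per_subsample, seed=sub_seed, mode="sample")
        ycurve = curves.curve("new", statistic)
        xs = np.arange(1, keep + 1, dtype=float)
        if (ycurve <= 0).any() or np.allclose(ycurve[1:], 0):
            skipped += 1
            continue
        fit = fit_power(xs, ycurve)
        if not fit.converged:
            skipped += 1
            continue
        alphas.append(fit.alpha)
    return JackknifeResult(
        alphas=np.asarray(alphas),
        n_skipped=skipped,
        n_subsamples=n_subsamples,
        seed=seed,
        statistic=statistic,
    )
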