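"""Maturity ogive: logistic fit of maturity on length, L50, and bootstrap.

The logit model P(mature | length) = expit(intercept + slope * length) is fit
by Newton/IRLS maximum likelihood (lengths are centered internally for
conditioning). L50 = -intercept / slope. Uncertainty comes from a
non-parametric case bootstrap with percentile intervals; goodness of fit is
Nagelkerke's rescaled pseudo-R².
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "MaturityRecord",
    "OgiveFit",
    "BootstrapResult",
    "fit_ogive",
    "nagelkerke",
    "bootstrap_L50",
    "ogive_curve",
    "plot_ogive",
]


@dataclass(frozen=True)
class MaturityRecord:
    length: float   # cm
    mature: bool

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be > 0")


@dataclass
class OgiveFit:
    intercept: float
    slope: float
    L50: float
    loglik_full: float
    loglik_null: float
    n: int
    nagelkerke_r2: float
    converged: bool = True

    def as_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "slope": self.slope,
            "L50": self.L50,
            "loglik_full": self.loglik_full,
            "loglik_null": self.loglik_null,
            "n": self.n,
            "nagelkerke_r2": self.nagelkerke_r2,
            "converged": self.converged,
        }


@dataclass
class BootstrapResult:
    reps: int
    L50_median: float
    ci_low: float
    ci_high: float
    seed: int
    l50_values: np.ndarray = field(repr=False, default=None)
    n_dropped: int = 0
    warning: Optional[str] = None


def _coerce(records, mature=None) -> tuple[np.ndarray, np.ndarray]:
    if mature is not None:
        x = np.asarray(records, dtype=float)
        y = np.asarray(mature, dtype=float)
    else:
        recs = list(records)
        x = np.array([r.length for r in recs], dtype=float)
        y = np.array([float(r.mature) for r in recs], dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("lengths and maturity flags must be 1-D and aligned")
    if x.size < 2:
        raise ValueError("need at least 2 records")
    return x, y


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # log expit computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _separated(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    """Midpoint of the separating gap when outcomes are completely separated."""
    xi, xm = x[y == 0], x[y == 1]
    if xi.size == 0 or xm.size == 0:
        return None
    if xi.max() < xm.min():
        return 0.5 * (xi.max() + xm.min())
    if xm.max() < xi.min():
        return 0.5 * (xm.max() + xi.min())
    return None


def _irls(x: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-12):
    """Newton/IRLS MLE on centered lengths. Returns (beta0, beta1, llf, ok)."""
    xbar = x.mean()
    z = x - xbar
    b = np.zeros(2)
    eta = np.zeros_like(z)
    ll = _loglik(eta, y)
    ok = False
    for _ in range(max_iter):
        p = expit(eta)
        w = p * (1.0 - p)
        g0 = np.sum(y - p)
        g1 = np.sum((y - p) * z)
        h00 = np.sum(w)
        h01 = np.sum(w * z)
        h11 = np.sum(w * z * z)
        det = h00 * h11 - h01 * h01
        if det <= 0 or not np.isfinite(det):
            break
        d0 = (h11 * g0 - h01 * g1) / det
        d1 = (h00 * g1 - h01 * g0) / det
        step = 1.0
        for _ in range(30):
            nb = b + step * np.array([d0, d1])
            neta = nb[0] + nb[1] * z
            nll = _loglik(neta, y)
            if nll >= ll - 1e-13:
                break
            step *= 0.5
        b, eta, prev = nb, neta, ll
        ll = nll
        if max(abs(step * d0), abs(step * d1)) < tol * (1.0 + abs(b[1])):
            ok = True
            break
        if abs(ll - prev) < 1e-13 * (1.0 + abs(ll)):
            ok = True
            break
    return b[0] - b[1] * xbar, b[1], ll, ok


def fit_ogive(
    records: Iterable[MaturityRecord] | Sequence[float],
    mature: Optional[Sequence[bool]] = None,
    use_class_midpoints: bool = False,
) -> OgiveFit:
    """Maximum-likelihood logistic ogive of maturity on length.

    Accepts either an iterable of ``MaturityRecord`` or parallel
    lengths/mature sequences. ``use_class_midpoints`` snaps lengths to 1-cm
    class midpoints before fitting. On complete separation the fit is flagged
    non-converged and L50 is the midpoint of the separating gap (with a
    warning); an all-mature or all-immature sample raises ``ValueError``.
    """
    x, y = _coerce(records, mature)
    if use_class_midpoints:
        x = np.floor(x) + 0.5
    n = x.size
    if y.min() == y.max():
        raise ValueError("all outcomes identical: ogive undefined")

    pbar = y.mean()
    ll0 = n * (pbar * math.log(pbar) + (1 - pbar) * math.log(1 - pbar))

    mid = _separated(x, y)
    if mid is not None:
        warnings.warn(
            "complete separation: reporting L50 as the separation midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        return OgiveFit(
            intercept=float("nan"), slope=float("nan"), L50=float(mid),
            loglik_full=0.0, loglik_null=ll0, n=n,
            nagelkerke_r2=nagelkerke(ll0, 0.0, n), converged=False,
        )

    b0, b1, llf, ok = _irls(x, y)
    if b1 == 0:
        raise ValueError("degenerate fit: zero slope, L50 undefined")
    return OgiveFit(
        intercept=float(b0), slope=float(b1), L50=float(-b0 / b1),
        loglik_full=float(llf), loglik_null=float(ll0), n=n,
        nagelkerke_r2=nagelkerke(ll0, llf, n), converged=bool(ok),
    )


def nagelkerke(loglik_null: float, loglik_full: float, n: int) -> float:
    """Nagelkerke's rescaled Cox-Snell pseudo-R²."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if loglik_full < loglik_null - 1e-9:
        raise ValueError("loglik_full must be >= loglik_null")
    cox_snell = 1.0 - math.exp(2.0 * (loglik_null - loglik_full) / n)
    denom = 1.0 - math.exp(2.0 * loglik_null / n)
    if denom == 0.0:
        return 0.0
    return cox_snell / denom


def bootstrap_L50(
    records: Iterable[MaturityRecord] | Sequence[float],
    mature: Optional[Sequence[bool]] = None,
    reps: int = 1000,
    seed: int = 0,
    drop_nonconverged: bool = True,
    use_class_midpoints: bool = False,
) -> BootstrapResult:
    """Case (pairs) bootstrap of L50 with percentile 2.5/97.5 intervals.

    Replicates whose refit fails (one outcome class only, or — by default —
    complete separation / non-convergence) are dropped and counted; a warning
    is recorded when more than 20% of replicates are dropped. With
    ``drop_nonconverged=False`` separated replicates contribute their
    separation-midpoint L50.
    """
    x, y = _coerce(records, mature)
    if use_class_midpoints:
        x = np.floor(x) + 0.5
    rng = np.random.default_rng(seed)
    n = x.size
    values = []
    dropped = 0
    for _ in range(reps):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], y[idx]
        if yb.min() == yb.max():
            dropped += 1
            continue
        mid = _separated(xb, yb)
        if mid is not None:
            if drop_nonconverged:
                dropped += 1
            else:
                values.append(mid)
            continue
        b0, b1, _, ok = _irls(xb, yb)
        if (not ok and drop_nonconverged) or b1 == 0 or not np.isfinite(b0 / b1):
            dropped += 1
            continue
        values.append(-b0 / b1)
    if not values:
        raise ValueError("all bootstrap replicates failed")
    arr = np.sort(np.asarray(values))
    warning = None
    if dropped > 0.2 * reps:
        warning = f"{dropped}/{reps} bootstrap replicates dropped"
        warnings.warn(warning, RuntimeWarning, stacklevel=2)
    # percentile interval with the (B+1) order-statistic convention, rounded
    # outward (Efron's convention; slightly conservative at modest B)
    b = arr.size
    j_lo = max(int(math.floor(0.025 * (b + 1))) - 1, 0)
    j_hi = min(int(math.ceil(0.975 * (b + 1))) - 1, b - 1)
    med = float(np.median(arr))
    return BootstrapResult(
        reps=reps, L50_median=med, ci_low=float(arr[j_lo]), ci_high=float(arr[j_hi]),
        seed=seed, l50_values=arr, n_dropped=dropped, warning=warning,
    )


def ogive_curve(fit: OgiveFit, lengths: Sequence[float]) -> np.ndarray:
    """Predicted mature proportion at each length; exactly 0.5 at L50."""
    if not fit.converged:
        raise ValueError("ogive_curve requires a converged fit")
    return expit(fit.slope * (np.asarray(lengths, dtype=float) - fit.L50))


def plot_ogive(
    fit: OgiveFit,
    records: Iterable[MaturityRecord] | Sequence[float],
    mature: Optional[Sequence[bool]] = None,
    boot: Optional[BootstrapResult] = None,
    path=None,
):
    """Ogive curve with data points, the L50 marker, and an optional CI band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = _coerce(records, mature)
    grid = np.linspace(x.min() - 1, x.max() + 1, 300)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(x, y, s=12, color="0.5", zorder=3, label="individuals")
    ax.plot(grid, ogive_curve(fit, grid), color="k", label="logistic fit")
    ax.plot([fit.L50], [0.5], "ko", ms=8)
    if boot is not None:
        ax.axvspan(boot.ci_low, boot.ci_high, color="0.8", alpha=0.6,
                   label="bootstrap 95% CI")
    ax.set_xlabel("total length (cm)")
    ax.set_ylabel("proportion mature")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
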