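"""Pangenome openness: rarefaction curves and power-law accumulation fits.

The pangenome size analysis follows the classic gene-accumulation approach:
genomes are added in random order, the cumulative number of distinct genes
(total curve) and the number of genes first seen at each step (new-gene
curve) are averaged over permutations, and power-law models are fitted to
the means:

    new genes      n(N) = k * N**r + a
    total genes    y(N) = k * N**gamma + c

The pangenome is called *open* when the integral of the fitted new-gene
curve from the catalog size to infinity diverges — i.e. when a > 0 or
r >= -1 — and the verdict is supported by the parameter confidence
intervals rather than the point estimates.  The Heaps'-law criterion
(gamma in (0, 1) on the total curve) is reported as a secondary signal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .pangenome import PAVMatrix

__all__ = [
    "AccumulationCurve",
    "PowerLawFit",
    "OpennessVerdict",
    "FitError",
    "accumulation_curves",
    "fit_power_law",
    "fit_new_gene_model",
    "fit_total_gene_model",
    "assess_openness",
]


class FitError(RuntimeError):
    """Nonlinear least squares failed to converge from every start."""


@dataclass
class AccumulationCurve:
    """Mean gene-accumulation curves over random genome orderings.

    ``N`` runs 1..G; ``mean_total[i]`` is the mean cumulative distinct-gene
    count after the (i+1)-th genome, ``mean_new[i]`` the mean count of genes
    first observed at that step.
    """

    N: np.ndarray
    mean_total: np.ndarray
    mean_new: np.ndarray
    n_permutations: int
    seed: int | None = None
    exhaustive: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.mean_total) < -1e-9):
            raise ValueError("mean_total must be non-decreasing")
        if not math.isclose(self.mean_new.sum(), self.mean_total[-1], rel_tol=1e-9):
            raise ValueError("sum of mean_new must equal final mean_total")


@dataclass
class PowerLawFit:
    """A fitted three-parameter power law ``k * N**exponent + offset``.

    ``kind`` is ``"new_gene"`` (parameters k, r, a) or ``"total_gene"``
    (parameters k, gamma, c).  Confidence intervals are asymptotic 95%
    intervals from the parameter covariance with t-quantiles.
    """

    kind: str
    k: float
    exponent: float
    offset: float
    ci: dict[str, tuple[float, float]]
    r_squared: float
    residuals: np.ndarray
    degenerate: bool = False

    @property
    def params(self) -> tuple[float, float, float]:
        return self.k, self.exponent, self.offset

    def predict(self, N: np.ndarray) -> np.ndarray:
        return self.k * np.asarray(N, dtype=float) ** self.exponent + self.offset


@dataclass
class OpennessVerdict:
    verdict: str  # "open" | "closed" | "indeterminate"
    reasons: list[str]
    new_fit: PowerLawFit | None = None
    total_fit: PowerLawFit | None = None


# ---------------------------------------------------------------------------
# rarefaction
# ---------------------------------------------------------------------------

def accumulation_curves(
    pav: PAVMatrix,
    n_permutations: int = 10,
    seed: int | None = None,
    exhaustive: bool = False,
) -> AccumulationCurve:
    """Mean total-gene and new-gene counts per sample size over random
    genome orderings.

    Each permutation adds genomes one at a time; a gene counts as *new* at
    the step where it is first observed.  With ``exhaustive=True`` all G!
    orderings are enumerated instead of sampled (only sensible for small G).
    Orderings are sampled independently, so duplicates across permutations
    can occur.
    """
    if pav.n_genomes < 2:
        raise ValueError("need >=2 genomes for accumulation curves")
    if not exhaustive and n_permutations < 1:
        raise ValueError("n_permutations must be >=1")
    arr = pav.presence.to_numpy().astype(bool)
    g = pav.n_genomes
    if exhaustive:
        orders: Sequence[Sequence[int]] = list(itertools.permutations(range(g)))
    else:
        rng = np.random.default_rng(seed)
        orders = [rng.permutation(g) for _ in range(n_permutations)]
    new_sum = np.zeros(g)
    for order in orders:
        ordered = arr[np.asarray(order)]
        # first genome (in this order) carrying each gene
        first = np.argmax(ordered, axis=0)
        new_sum += np.bincount(first, minlength=g)
    mean_new = new_sum / len(orders)
    mean_total = np.cumsum(mean_new)
    return AccumulationCurve(
        N=np.arange(1, g + 1),
        mean_total=mean_total,
        mean_new=mean_new,
        n_permutations=len(orders),
        seed=seed,
        exhaustive=exhaustive,
    )


# ---------------------------------------------------------------------------
# power-law fitting
# ---------------------------------------------------------------------------

def _power_law(N: np.ndarray, k: float, expo: float, off: float) -> np.ndarray:
    return k * N ** expo + off


def fit_power_law(
    N: np.ndarray,
    y: np.ndarray,
    kind: str,
    starts: Sequence[tuple[float, float, float]],
    conf_level: float = 0.95,
) -> PowerLawFit:
    """Nonlinear least squares for ``y = k * N**exponent + offset``.

    Tries every start, keeps the converged fit with the smallest residual
    sum of squares, and raises :class:`FitError` if none converges.
    Parameter CIs come from the asymptotic covariance with t-quantiles on
    n - 3 degrees of freedom; R^2 = 1 - SS_res / SS_tot about the mean.
    """
    N = np.asarray(N, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(N) < 4:
        raise ValueError("need >=4 points to fit a three-parameter model")
    degenerate = bool(np.allclose(y, y[0]))
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for p0 in starts:
        try:
            popt, pcov = optimize.curve_fit(
                _power_law, N, y, p0=p0, maxfev=20000, method="lm"
            )
        except (RuntimeError, optimize.OptimizeWarning, ValueError):
            continue
        if not np.all(np.isfinite(popt)):
            continue
        ssr = float(np.sum((y - _power_law(N, *popt)) ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, popt, pcov)
    if best is None:
        raise FitError(
            f"{kind} power-law fit failed to converge from {len(starts)} starts "
            f"(n={len(N)}, y range {y.min():.3g}..{y.max():.3g})"
        )
    ssr, popt, pcov = best
    residuals = y - _power_law(N, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - ssr / ss_tot if ss_tot > 0 else (1.0 if ssr == 0 else -np.inf)
    dof = max(len(N) - 3, 1)
    tq = stats.t.ppf(0.5 + conf_level / 2, dof)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    names = ("k", "r", "a") if kind == "new_gene" else ("k", "gamma", "c")
    ci = {
        name: (popt[i] - tq * se[i], popt[i] + tq * se[i])
        for i, name in enumerate(names)
    }
    return PowerLawFit(
        kind=kind,
        k=float(popt[0]),
        exponent=float(popt[1]),
        offset=float(popt[2]),
        ci=ci,
        r_squared=r_squared,
        residuals=residuals,
        degenerate=degenerate,
    )


def _loglog_start(N: np.ndarray, y: np.ndarray, off: float) -> tuple[float, float, float]:
    """Seed (k, exponent) from a log-log regression of y - off on N."""
    shifted = y - off
    mask = shifted > 0
    if mask.sum() < 2:
        return 1.0, -1.0, off
    slope, intercept = np.polyfit(np.log(N[mask]), np.log(shifted[mask]), 1)
    return float(np.exp(intercept)), float(slope), off


def fit_new_gene_model(
    curve: AccumulationCurve, include_first: bool = False
) -> PowerLawFit:
    """Fit ``n(N) = k * N**r + a`` to the mean new-gene counts.

    N = 1 is excluded by default: the first step's "new genes" are simply
    the genome's full gene complement and sit off-model.
    """
    mask = curve.N >= (1 if include_first else 2)
    N, y = curve.N[mask].astype(float), curve.mean_new[mask]
    if np.allclose(y, 0):
        # all-zero tail: nothing to fit, the curve has no new-gene signal
        return PowerLawFit(
            kind="new_gene", k=0.0, exponent=0.0, offset=0.0,
            ci={p: (0.0, 0.0) for p in ("k", "r", "a")},
            r_squared=1.0, residuals=np.zeros_like(y), degenerate=True,
        )
    tail = float(np.mean(y[-max(len(y) // 4, 1):]))
    starts = [
        (float(y[0]), -1.0, tail),
        (float(y[0]) - tail, -1.5, tail),
        _loglog_start(N, y, tail * 0.9),
        (float(y[0]), -0.5, 0.0),
    ]
    return fit_power_law(N, y, "new_gene", starts)


def fit_total_gene_model(curve: AccumulationCurve) -> PowerLawFit:
    """Fit ``y(N) = k * N**gamma + c`` to the mean total-gene counts."""
    N, y = curve.N.astype(float), curve.mean_total
    span = float(y[-1] - y[0])
    starts = [
        (span if span > 0 else 1.0, 0.5, float(y[0])),
        _loglog_start(N, y, float(y[0]) * 0.9),
        (max(span, 1.0), 0.8, float(y[0]) - max(span, 1.0) * 0.1),
    ]
    fit = fit_power_law(N, y, "total_gene", starts)
    if span == 0:
        fit.degenerate = True
    return fit


# ---------------------------------------------------------------------------
# openness verdict
# ---------------------------------------------------------------------------

def assess_openness(
    new_fit: PowerLawFit, total_fit: PowerLawFit | None = None
) -> OpennessVerdict:
    """Classify the pangenome via the divergent-integral criterion.

    The integral of k*N**r + a from the catalog size to infinity diverges
    iff a > 0 or r >= -1.  The verdict is CI-supported: *open* when the
    lower CI bound of a is positive or the upper CI bound of r reaches -1;
    *closed* when a's CI does not exceed 0 and r's CI lies entirely below
    -1; otherwise *indeterminate*.  When a total-gene fit is supplied, the
    Heaps criterion gamma in (0, 1) is recorded as a supporting reason.
    """
    reasons: list[str] = []
    if new_fit.degenerate:
        return OpennessVerdict("indeterminate", ["new-gene fit degenerate"], new_fit, total_fit)
    a_lo, a_hi = new_fit.ci["a"]
    r_lo, r_hi = new_fit.ci["r"]
    open_by_a = a_lo > 0
    open_by_r = r_hi >= -1
    if open_by_a:
        reasons.append(f"a > 0 supported by CI ({a_lo:.3f}, {a_hi:.3f})")
    if open_by_r:
        reasons.append(f"r >= -1 supported by CI ({r_lo:.3f}, {r_hi:.3f})")
    if total_fit is not None and not total_fit.degenerate:
        g_lo, g_hi = total_fit.ci["gamma"]
        if 0 < total_fit.exponent < 1:
            reasons.append(
                f"Heaps exponent gamma = {total_fit.exponent:.3f} in (0, 1)"
            )
    if open_by_a or open_by_r:
        return OpennessVerdict("open", reasons, new_fit, total_fit)
    if a_hi <= 0 or (a_lo <= 0 <= a_hi):
        if r_hi < -1:
            reasons.append(
                f"a CI includes or falls below 0 ({a_lo:.3f}, {a_hi:.3f}) "
                f"and r CI entirely < -1 ({r_lo:.3f}, {r_hi:.3f})"
            )
            return OpennessVerdict("closed", reasons, new_fit, total_fit)
    reasons.append("criteria inconclusive")
    return OpennessVerdict("indeterminate", reasons, new_fit, total_fit)
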