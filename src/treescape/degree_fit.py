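"""Degree-distribution model fitting for group-representative MSTs.

Three candidate forms for the normalized degree frequency P(k):

* power law                      P(k) ∝ k^(-alpha)
* exponential                    P(k) ∝ e^(-alpha k)
* exponentially truncated        P(k) ∝ k^(alpha-1) e^(-k/kc)
  power law

The truncated family interpolates between scale-free (kc -> ∞) and
random-graph (exponential) regimes. Each family carries a free scale constant;
fitting is least squares of log P(k) against the family's form over the
observed degrees (MST degrees are small integers, so no binning or CCDF
transform is applied by default; a linear-scale mode is available). Goodness of
fit is R^2 = 1 - SSres/SStot on the fitted scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import InsufficientDataError
from .trees import SpanningTree

FAMILIES = ("power_law", "exponential", "truncated_power_law")


@dataclass
class DegreeHistogram:
    k: np.ndarray  # observed degrees (>=1), zero-count degrees omitted
    count: np.ndarray
    p: np.ndarray  # normalized frequency

    @classmethod
    def from_counts(cls, k, count):
        k = np.asarray(k, dtype=float)
        count = np.asarray(count, dtype=float)
        order = np.argsort(k)
        k, count = k[order], count[order]
        return cls(k=k, count=count, p=count / count.sum())

    @property
    def n_support(self) -> int:
        return len(self.k)


@dataclass
class DistributionFit:
    family: str
    alpha: float
    r_squared: float
    kc: float | None = None
    scale: str = "log"

    def as_dict(self) -> dict:
        d = {"family": self.family, "alpha": self.alpha, "r_squared": self.r_squared,
             "scale": self.scale}
        if self.kc is not None:
            d["kc"] = self.kc
        return d


def degree_histogram(t: SpanningTree) -> DegreeHistogram:
    deg = t.degree_sequence()
    k, count = np.unique(deg, return_counts=True)
    return DegreeHistogram.from_counts(k, count)


def _predict_log(family: str, k: np.ndarray, params) -> np.ndarray:
    if family == "power_law":
        c, alpha = params
        return c - alpha * np.log(k)
    if family == "exponential":
        c, alpha = params
        return c - alpha * k
    if family == "truncated_power_law":
        c, alpha, kc = params
        return c + (alpha - 1.0) * np.log(k) - k / kc
    raise ValueError(f"unknown family {family!r}")


def _r_squared(y, yhat) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 else -np.inf
    return 1.0 - ss_res / ss_tot


def fit_distribution(h: DegreeHistogram, family: str, scale: str = "log") -> DistributionFit:
    """Fit one family to the histogram by least squares.

    Two-parameter (shape) families need >= 2 distinct degrees plus the scale
    constant; the truncated family needs >= 3. The one-parameter-shape families
    are solved exactly by linear regression of log p on the transformed degree;
    the truncated family by nonlinear least squares seeded from both the
    power-law and exponential solutions (so it can never fit worse than the
    power law it nests).
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {FAMILIES}")
    min_support = 3 if family == "truncated_power_law" else 2
    if h.n_support < min_support:
        raise InsufficientDataError(
            f"{family} needs >= {min_support} distinct degrees, got {h.n_support}")

    k = h.k.astype(float)
    y = np.log(h.p)

    if family == "power_law":
        A = np.column_stack([np.ones_like(k), -np.log(k)])
        params, *_ = np.linalg.lstsq(A, y, rcond=None)
        alpha, kc = float(params[1]), None
        full = (params[0], params[1])
    elif family == "exponential":
        A = np.column_stack([np.ones_like(k), -k])
        params, *_ = np.linalg.lstsq(A, y, rcond=None)
        alpha, kc = float(params[1]), None
        full = (params[0], params[1])
    else:
        def model(kk, c, alpha, kc):
            return c + (alpha - 1.0) * np.log(kk) - kk / kc

        # seeds: power-law-like (huge kc) and exponential-like (alpha=1)
        pl = fit_distribution(h, "power_law", scale=scale)
        ex = fit_distribution(h, "exponential", scale=scale)
        seeds = [
            (0.0, 1.0 - pl.alpha, 1e6),
            (0.0, 1.0, 1.0 / max(ex.alpha, 1e-3)),
            (0.0, 1.3, 2.3),
        ]
        best = None
        for p0 in seeds:
            try:
                popt, _ = curve_fit(
                    model, k, y, p0=p0,
                    bounds=([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, 1e8]),
                    maxfev=20_000,
                )
            except RuntimeError:
                continue
            yhat = model(k, *popt)
            r2 = _r_squared(y, yhat)
            if best is None or r2 > best[1]:
                best = (popt, r2)
        if best is None:
            raise InsufficientDataError("truncated power-law fit did not converge")
        popt = best[0]
        alpha, kc = float(popt[1]), float(popt[2])
        full = tuple(popt)

    yhat_log = _predict_log(family, k, full)
    if scale == "log":
        r2 = _r_squared(y, yhat_log)
    elif scale == "linear":
        r2 = _r_squared(h.p, np.exp(yhat_log))
    else:
        raise ValueError("scale must be 'log' or 'linear'")
    return DistributionFit(family=family, alpha=alpha, kc=kc, r_squared=r2, scale=scale)


def compare_fits(h: DegreeHistogram, scale: str = "log") -> dict:
    """Fit all applicable families and rank by R^2.

    On two-point histograms only the one-parameter-shape families are fitted and
    the report is flagged ``partial``.
    """
    fits = {}
    partial = False
    for fam in FAMILIES:
        try:
            fits[fam] = fit_distribution(h, fam, scale=scale)
        except InsufficientDataError:
            partial = True
    if not fits:
        raise InsufficientDataError("no family could be fitted")
    best_r2 = max(f.r_squared for f in fits.values())
    # parsimony tie-break: the truncated family nests both one-parameter
    # families, so an exact tie goes to the simpler form
    tied = [f for f in fits.values() if f.r_squared >= best_r2 - 1e-6]
    winner = min(tied, key=lambda f: (f.kc is not None, -f.r_squared))
    return {"fits": fits, "winner": winner.family, "partial": partial}
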