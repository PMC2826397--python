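"""Two-sided stretched-exponential fits to empirical score histograms.

Empirical null distributions of scoring metrics are summarized by the
density ``f(x) = h * exp(-(b_side * |x - x0|) ** c_side)`` with separate
``(b, c)`` on each side of the mode, which allows tail p-values to be
extrapolated far beyond the range of the simulated sample.

The fit is least squares on log-counts of the non-empty histogram bins,
each side separately; the mode ``x0`` is the midpoint of the modal bin and
``h`` the modal density.  Tail mass uses the closed form via the upper
incomplete gamma function (adaptive quadrature is used as a cross-check in
the test suite, not here).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .formats import ValidationError

__all__ = [
    "StretchedExponentialFit",
    "fit_stretched_exponential",
    "tail_pvalue",
    "below_precision",
    "MIN_PVALUE",
]

# p-values are floored here; a result at the floor means "below precision"
MIN_PVALUE = float(np.finfo(float).tiny)


@dataclass(frozen=True)
class StretchedExponentialFit:
    h: float
    x0: float
    b_left: float
    c_left: float
    b_right: float
    c_right: float

    @property
    def normalization(self) -> float:
        """Integral of the unnormalized density over the real line."""
        return self.h * (
            special.gamma(1 + 1 / self.c_left) / self.b_left
            + special.gamma(1 + 1 / self.c_right) / self.b_right
        )

    def density(self, x):
        """Normalized density at x (vectorized)."""
        x = np.asarray(x, dtype=float)
        d = x - self.x0
        b = np.where(d < 0, self.b_left, self.b_right)
        c = np.where(d < 0, self.c_left, self.c_right)
        return self.h * np.exp(-((b * np.abs(d)) ** c)) / self.normalization

    def _side_mass(self, dist: float, b: float, c: float) -> float:
        """Unnormalized mass beyond distance ``dist`` on one side."""
        u = (b * dist) ** c
        return self.h * special.gamma(1 / c) * special.gammaincc(1 / c, u) / (b * c)


def _fit_side(
    dist: np.ndarray, log_dens: np.ndarray, counts: np.ndarray, log_h: float
) -> tuple[float, float]:
    """Fit (b, c) of log density = log_h - (b*dist)^c by weighted least
    squares on log-counts; weights are sqrt(count) so sparse far-tail bins
    do not dominate."""
    drop = log_h - log_dens  # >= 0 up to histogram noise
    drop = np.maximum(drop, 1e-9)
    w = np.sqrt(counts)
    d_max = dist.max()
    b0 = drop.max() ** 0.5 / d_max  # exact if c = 2

    def residuals(theta):
        b, c = np.exp(theta)
        return w * ((b * dist) ** c - drop)

    sol = optimize.least_squares(
        residuals, x0=[np.log(max(b0, 1e-12)), np.log(2.0)], method="lm"
    )
    b, c = np.exp(sol.x)
    if not (np.isfinite(b) and np.isfinite(c) and b > 0 and c > 0):
        raise ValidationError("stretched-exponential fit did not converge")
    return float(b), float(c)


def fit_stretched_exponential(
    sample, n_bins: int | None = None
) -> StretchedExponentialFit:
    """Fit the two-sided stretched exponential to a metric sample.

    ``n_bins`` defaults to the Freedman-Diaconis rule.  Requires at least
    1000 values and at least 3 non-empty bins strictly on each side of the
    modal bin.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 1000:
        raise ValidationError(f"need >= 1000 sample values, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("sample is constant; null density undefined")
    bins = "fd" if n_bins is None else int(n_bins)
    counts, edges = np.histogram(x, bins=bins, density=False)
    widths = np.diff(edges)
    dens = counts / (counts.sum() * widths)
    centers = 0.5 * (edges[:-1] + edges[1:])

    i_mode = int(np.argmax(dens))
    x0 = float(centers[i_mode])
    h = float(dens[i_mode])
    # refine the mode: a single modal bin wanders with sampling noise, so
    # fit a parabola to log-density over the half-maximum region
    half = (dens >= 0.5 * h) & (counts > 0)
    if half.sum() >= 3:
        coeffs = np.polyfit(
            centers[half], np.log(dens[half]), 2, w=np.sqrt(counts[half])
        )
        if coeffs[0] < 0:
            vertex = -coeffs[1] / (2 * coeffs[0])
            lo, hi = centers[half].min(), centers[half].max()
            if lo <= vertex <= hi:
                x0 = float(vertex)

    left = (centers < x0) & (counts > 0)
    right = (centers > x0) & (counts > 0)
    for side, name in ((left, "left"), (right, "right")):
        if side.sum() < 3:
            raise ValidationError(
                f"fewer than 3 non-empty bins on the {name} side of the mode; "
                "use a larger sample or fewer bins"
            )
    log_h = np.log(h)
    b_l, c_l = _fit_side(x0 - centers[left], np.log(dens[left]), counts[left], log_h)
    b_r, c_r = _fit_side(centers[right] - x0, np.log(dens[right]), counts[right], log_h)
    return StretchedExponentialFit(
        h=h, x0=x0, b_left=b_l, c_left=c_l, b_right=b_r, c_right=c_r
    )


def tail_pvalue(
    fit: StretchedExponentialFit, observed: float, side: str = "upper"
) -> float:
    """Tail mass of the normalized fitted density beyond ``observed``.

    ``side='upper'`` integrates from ``observed`` to +inf, ``'lower'`` from
    -inf to ``observed``.  The result is strictly inside (0, 1): values that
    underflow are floored at :data:`MIN_PVALUE`, which callers may render as
    "below precision" (see :func:`below_precision`).
    """
    if side not in ("upper", "lower"):
        raise ValidationError(f"side must be 'upper' or 'lower', got {side!r}")
    observed = float(observed)
    if not np.isfinite(observed):
        # +inf has no upper tail mass beyond it, -inf none below
        if (side == "upper") == (observed > 0):
            return MIN_PVALUE
        return 1.0
    Z = fit.normalization
    if observed >= fit.x0:
        upper = fit._side_mass(observed - fit.x0, fit.b_right, fit.c_right) / Z
    else:
        below = fit._side_mass(fit.x0 - observed, fit.b_left, fit.c_left) / Z
        upper = 1.0 - below
    p = upper if side == "upper" else 1.0 - upper
    return float(min(max(p, MIN_PVALUE), 1.0 - 1e-16))


def below_precision(p: float) -> bool:
    """True when a p-value hit the numeric underflow floor."""
    return p <= MIN_PVALUE
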