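"""Hartigan's dip statistic for unimodality, with a Monte-Carlo null.

The dip of an empirical distribution is the smallest sup-norm distance
between its ECDF and any unimodal distribution function.  The optimal
unimodal CDF is convex left of the mode and concave right of it, and on
each side the best convex (concave) approximation of the ECDF within a
sup-norm band of half-width t exists iff t is at least half the maximal
excess of the ECDF over its greatest convex minorant (under its least
concave majorant).  Hence

    dip = 1/2 * min over mode splits j of
          max( excess of F over GCM(F^-) on knots < j,
               excess of LCM(F) over F^- on knots >= j )

where F and F^- are the upper and lower step values of the ECDF (the mode
kink may fall between knots, so the two sides decouple).  The left excess
is nondecreasing and the right excess nonincreasing in j, so the
minimizing split is located by bisection on their crossing (a small
neighborhood is re-scanned to guard against flat stretches).  A 50/50
two-point mixture attains the maximal dip of 1/4; n equal values give the
minimal dip 1/(2n).

The p-value is calibrated by simulating the statistic under the uniform
null distribution (the asymptotically least favorable unimodal case) at
the same sample size.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _dedupe(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique knots with upper/lower ECDF values (handles ties exactly)."""
    n = len(x)
    knots, counts = np.unique(x, return_counts=True)
    upper = np.cumsum(counts) / n
    lower = np.concatenate(([0.0], upper[:-1]))
    return knots, lower, upper


def _left_excess(knots: np.ndarray, lower: np.ndarray, upper: np.ndarray, m: int) -> float:
    """Max of F - GCM(F^-) over knots[0..m]; GCM = lower convex hull of (x, F^-)."""
    hull: list[int] = []
    xs, ys = knots, lower
    for i in range(m + 1):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            # pop k if it lies on or above the chord j->i
            if (ys[k] - ys[j]) * (xs[i] - xs[j]) >= (ys[i] - ys[j]) * (xs[k] - xs[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    # evaluate hull at every knot and take max deviation of the upper values
    hx, hy = xs[hull], ys[hull]
    g = np.interp(xs[: m + 1], hx, hy)
    return float(np.max(upper[: m + 1] - g))


def _right_excess(knots: np.ndarray, lower: np.ndarray, upper: np.ndarray, m: int) -> float:
    """Max of LCM(F) - F^- over knots[m..]; LCM = upper concave hull of (x, F)."""
    xs = knots[m:]
    ys = upper[m:]
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            if (ys[k] - ys[j]) * (xs[i] - xs[j]) <= (ys[i] - ys[j]) * (xs[k] - xs[j]):
                hull.pop()
            else:
                break
        hull.append(i)
    g = np.interp(xs, xs[hull], ys[hull])
    return float(np.max(g - lower[m:]))


def dip_statistic(samples: np.ndarray) -> float:
    """Dip statistic of a one-dimensional sample."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        return 0.0
    knots, lower, upper = _dedupe(x)
    k = len(knots)
    if k == 1:
        return 1.0 / (2.0 * n)

    def left(j: int) -> float:
        """Excess on the convex side, knots[0..j-1]; empty side has none."""
        return _left_excess(knots, lower, upper, j - 1) if j >= 1 else 0.0

    def right(j: int) -> float:
        """Excess on the concave side, knots[j..k-1]."""
        return _right_excess(knots, lower, upper, j) if j <= k - 1 else 0.0

    def objective(j: int) -> float:
        return max(left(j), right(j))

    # bisect on the crossing of the monotone left/right excess envelopes
    lo, hi = 0, k
    while hi - lo > 2:
        mid = (lo + hi) // 2
        if left(mid) < right(mid):
            lo = mid
        else:
            hi = mid
    window = range(max(0, lo - 2), min(k, hi + 2) + 1)
    best = min(objective(j) for j in window)
    return 0.5 * best


def dip_test(
    samples: np.ndarray,
    n_boot: int = 199,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Dip statistic and its Monte-Carlo p-value under the uniform null.

    Returns ``(dip, p_value)`` with ``p_value = (1 + #{null >= dip}) /
    (n_boot + 1)``; the smallest attainable p is ``1/(n_boot+1)``.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    x = np.asarray(samples, dtype=float)
    d = dip_statistic(x)
    n = len(x)
    exceed = 0
    for _ in range(n_boot):
        if dip_statistic(rng.uniform(size=n)) >= d:
            exceed += 1
    return d, (1.0 + exceed) / (n_boot + 1.0)
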