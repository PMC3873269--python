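"""Stimulus-response sweeps, hysteresis detection and curve classification.

A sweep varies one production rate (or a linked pair, e.g. Hrk & Bik with
equal multipliers) over a log-spaced grid while every other parameter stays
at its default.  The continuation protocol realizes the two hysteresis
branches: the first grid point starts from the pre-stimulus initial state
recomputed at that stimulus value, each later point starts from the
previous converged steady state.  Sweeping up and then down therefore
traces the attracting low and high branches; where they disagree by more
than the gap factor the system is bistable at that stimulus.

Curves without a branch gap are classified by an effective Hill fit of the
merged monotone curve: n_H > 1.5 reads as sigmoid ("push-button"), smaller
values as hyperbolic ("tuner").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .dynamics import CompiledModel, mac_abundance, steady_state
from .network import RateParams, ReactionNetwork, initial_state

__all__ = [
    "ResponseCurve",
    "BistabilityReport",
    "HillFit",
    "stimulus_sweep",
    "detect_bistability",
    "classify_response",
    "sweep_experiment",
    "DEFAULT_GAP_FACTOR",
]

DEFAULT_GAP_FACTOR = 5.0
_FLOOR = 1.0e-12

#: Canonical stimulus ranges of the replication sweeps, as log10 multiples
#: of each default production rate.  Switch-like stimuli are swept
#: symmetrically about their defaults; Noxa, whose graded "tuner" response
#: lies well above its default production under the default calibration, is
#: swept over the dynamic range of that response.
REPLICATION_RANGES: dict[str | tuple[str, ...], tuple[float, float]] = {
    "kptBid": (-1.5, 1.5),
    "kpBim": (-1.5, 1.5),
    "kpBax": (-1.5, 1.5),
    "kpBak": (-1.5, 1.5),
    "kpPuma": (-1.5, 1.5),
    ("kpBad", "kpBmf"): (-1.5, 1.5),
    ("kpHrk", "kpBik"): (-1.5, 1.5),
    "kpNoxa": (1.5, 4.5),
}


@dataclass
class ResponseCurve:
    """Steady-state MAC abundance along one stimulus grid (stored ascending)."""

    stimulus_param: tuple[str, ...]
    grid: np.ndarray  # ascending absolute values of the first stimulus parameter
    responses: np.ndarray
    direction: str  # "up" or "down": order in which points were visited
    converged: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be stored strictly ascending")
        if self.grid.shape != self.responses.shape:
            raise ValueError("one response per grid point required")
        if self.converged is None:
            self.converged = np.ones(self.grid.shape, dtype=bool)

    @property
    def n_decades(self) -> float:
        return float(np.log10(self.grid[-1] / self.grid[0]))


@dataclass
class BistabilityReport:
    bistable: bool
    lower_threshold: float | None  # stimulus of the down-sweep drop
    upper_threshold: float | None  # stimulus of the up-sweep jump
    width_decades: float | None
    max_branch_gap: float
    gap_factor: float
    bistable_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bistable:
            assert self.lower_threshold < self.upper_threshold or np.isclose(
                self.lower_threshold, self.upper_threshold
            )
            assert self.max_branch_gap >= self.gap_factor


@dataclass
class HillFit:
    vmax: float
    k_half: float
    n_hill: float
    basal: float
    increasing: bool
    rms_error: float


def stimulus_sweep(
    net: ReactionNetwork,
    params: RateParams,
    stimulus_param: str | tuple[str, ...],
    grid: np.ndarray | None = None,
    direction: str = "up",
    decades: float = 3.0,
    n_points: int = 60,
    model: CompiledModel | None = None,
    tol: float | None = None,
) -> ResponseCurve:
    """Continuation sweep of steady-state MAC versus one production rate.

    ``grid`` gives absolute values of the (first) stimulus parameter; when
    omitted it spans ``decades`` log-spaced decades centered on the default.
    Linked parameters (a tuple) are co-varied with equal multipliers.
    """
    names = (stimulus_param,) if isinstance(stimulus_param, str) else tuple(stimulus_param)
    for p in names:
        if p not in params:
            raise ValueError(f"unknown stimulus parameter {p!r}")
    base = params[names[0]]
    if grid is None:
        grid = base * np.logspace(-decades / 2.0, decades / 2.0, n_points)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be positive and strictly ascending")
    model = model if model is not None else CompiledModel(net, params)

    order = np.arange(len(grid)) if direction == "up" else np.arange(len(grid))[::-1]
    responses = np.empty(len(grid))
    converged = np.zeros(len(grid), dtype=bool)
    x = None
    for k in order:
        multiplier = grid[k] / base
        p_k = params.updated(**{p: params[p] * multiplier for p in names})
        m_k = model.with_params(p_k)
        start = initial_state(net, p_k) if x is None else x
        ss = steady_state(net, p_k, start, tol=tol, model=m_k)
        x = ss.state
        responses[k] = mac_abundance(net, x)
        converged[k] = ss.converged
    return ResponseCurve(
        stimulus_param=names,
        grid=grid,
        responses=responses,
        direction=direction,
        converged=converged,
    )


def _branch_ratio(up: np.ndarray, down: np.ndarray) -> np.ndarray:
    hi = np.maximum(up, down) + _FLOOR
    lo = np.minimum(up, down) + _FLOOR
    return hi / lo


def _jump_location(curve: ResponseCurve) -> float:
    """Stimulus value at the largest log-response step along the curve."""
    logr = np.log10(curve.responses + _FLOOR)
    steps = np.abs(np.diff(logr))
    j = int(np.argmax(steps))
    return float(np.sqrt(curve.grid[j] * curve.grid[j + 1]))


def detect_bistability(
    up: ResponseCurve,
    down: ResponseCurve,
    gap_factor: float = DEFAULT_GAP_FACTOR,
) -> BistabilityReport:
    """Compare the two sweep branches on a shared grid.

    Bistable iff the branch responses differ by at least ``gap_factor``
    somewhere; thresholds are the jump locations of each branch.
    """
    if up.grid.shape != down.grid.shape or not np.allclose(up.grid, down.grid):
        raise ValueError("up and down sweeps must share one grid")
    if {up.direction, down.direction} != {"up", "down"}:
        raise ValueError("one 'up' and one 'down' sweep required")
    up_c, down_c = (up, down) if up.direction == "up" else (down, up)
    ratio = _branch_ratio(up_c.responses, down_c.responses)
    gap = float(ratio.max())
    mask = ratio >= gap_factor
    if not mask.any():
        return BistabilityReport(
            bistable=False,
            lower_threshold=None,
            upper_threshold=None,
            width_decades=None,
            max_branch_gap=gap,
            gap_factor=gap_factor,
            bistable_mask=mask,
        )
    upper = _jump_location(up_c)
    lower = _jump_location(down_c)
    if lower > upper:  # jumps within one grid step of each other
        lower, upper = upper, lower
    return BistabilityReport(
        bistable=True,
        lower_threshold=lower,
        upper_threshold=upper,
        width_decades=float(np.log10(upper / lower)),
        max_branch_gap=gap,
        gap_factor=gap_factor,
        bistable_mask=mask,
    )


def fit_hill(
    stimulus: np.ndarray,
    response: np.ndarray,
    increasing: bool | None = None,
    residuals: str = "linear",
) -> HillFit:
    """Effective Hill fit of a dose-response curve.

    Model: basal + vmax * s^n / (k^n + s^n) for rising curves, the
    repressive form vmax * k^n / (k^n + s^n) + basal for falling ones.
    ``residuals="linear"`` (default) fits on the response scale, matching
    what a linear-axis dose-response plot displays; ``"log"`` weights all
    response decades equally.
    """
    if residuals not in ("linear", "log"):
        raise ValueError("residuals must be 'linear' or 'log'")
    s = np.asarray(stimulus, dtype=float)
    y = np.asarray(response, dtype=float)
    if increasing is None:
        increasing = y[-1] >= y[0]

    def model(p):
        vmax, k, n, b = np.exp(p)
        with np.errstate(over="ignore", invalid="ignore"):
            ratio = (s / k) ** n
            act = np.where(np.isfinite(ratio), ratio / (1.0 + ratio), 1.0)
        return b + vmax * (act if increasing else 1.0 - act)

    def resid(p):
        if residuals == "linear":
            scale = np.abs(y).max() + _FLOOR
            return (model(p) - y) / scale
        return np.log(model(p) + _FLOOR) - np.log(y + _FLOOR)

    span = float(y.max() - y.min())
    p0 = np.log([max(span, _FLOOR), float(np.sqrt(s[0] * s[-1])), 1.0, max(y.min(), _FLOOR)])
    lo = np.log([span * 1e-3 + _FLOOR, s[0] * 1e-3, 0.05, _FLOOR])
    hi = np.log([span * 1e3 + 1.0, s[-1] * 1e3, 20.0, max(y.max(), _FLOOR)])
    fit = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi), max_nfev=5000)
    vmax, k, n, b = np.exp(fit.x)
    return HillFit(
        vmax=float(vmax),
        k_half=float(k),
        n_hill=float(n),
        basal=float(b),
        increasing=bool(increasing),
        rms_error=float(np.sqrt(np.mean(fit.fun**2))),
    )


@dataclass
class ResponseClassification:
    label: str  # "bistable" | "sigmoid" | "hyperbolic" | "unresolved"
    report: BistabilityReport
    hill: HillFit | None = None


def classify_response(
    up: ResponseCurve,
    down: ResponseCurve,
    gap_factor: float = DEFAULT_GAP_FACTOR,
    sigmoid_hill_cutoff: float = 1.5,
    monotone_rel_tol: float = 0.02,
) -> ResponseClassification:
    """Bistable / sigmoid / hyperbolic taxonomy of a two-branch sweep."""
    if up.n_decades < 3.0 - 1e-9:
        raise ValueError("classification requires curves spanning >= 3 decades of stimulus")
    report = detect_bistability(up, down, gap_factor=gap_factor)
    if report.bistable:
        return ResponseClassification(label="bistable", report=report)
    merged = 0.5 * (up.responses + down.responses)
    diffs = np.diff(merged)
    scale = np.abs(merged).max() + _FLOOR
    rising = np.all(diffs >= -monotone_rel_tol * scale)
    falling = np.all(diffs <= monotone_rel_tol * scale)
    if not (rising or falling):
        return ResponseClassification(label="unresolved", report=report)
    hill = fit_hill(up.grid, merged, increasing=bool(rising))
    label = "sigmoid" if hill.n_hill > sigmoid_hill_cutoff else "hyperbolic"
    return ResponseClassification(label=label, report=report, hill=hill)


def sweep_experiment(
    net: ReactionNetwork,
    params: RateParams,
    stimulus_param: str | tuple[str, ...],
    grid: np.ndarray | None = None,
    decades: float = 3.0,
    n_points: int = 60,
    gap_factor: float = DEFAULT_GAP_FACTOR,
    model: CompiledModel | None = None,
    classify: bool = True,
) -> tuple[ResponseCurve, ResponseCurve, ResponseClassification | BistabilityReport]:
    """Up sweep, down sweep and their classification in one call."""
    model = model if model is not None else CompiledModel(net, params)
    common = dict(
        grid=grid, decades=decades, n_points=n_points, model=model
    )
    up = stimulus_sweep(net, params, stimulus_param, direction="up", **common)
    down = stimulus_sweep(net, params, stimulus_param, direction="down", **common)
    if classify:
        result = classify_response(up, down, gap_factor=gap_factor)
    else:
        result = detect_bistability(up, down, gap_factor=gap_factor)
    return up, down, result
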