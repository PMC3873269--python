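"""Monte-Carlo co-variation of the 16 production rates.

Each iteration multiplies every production rate by an independent random
factor q, recomputes the pre-stimulus initial condition, solves the model
to steady state and records the MAC abundance.  All other parameters stay
at their defaults.  The default variation law is log-uniform over two
decades, q = 10^U(-1, 1), i.e. symmetric up-/down-regulation in log space;
linear-uniform sampling over an interval is available as an alternative
mode.

The response distribution is strongly bimodal: a pro-survival mode of
near-zero MAC and a pro-MOMP mode of fully assembled channels.  The
threshold separating the two classes is the density minimum between the
two dominant modes of a kernel-density estimate of log10(response + eps).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from ._dip import dip_statistic, dip_test
from .dynamics import CompiledModel, SimulationError, mac_abundance, steady_state
from .network import PRODUCTION_PARAMS, RateParams, ReactionNetwork, initial_state

__all__ = [
    "StimuliMatrix",
    "MonteCarloResult",
    "BimodalityError",
    "sample_production_rates",
    "run_monte_carlo",
    "find_bimodal_threshold",
    "classify_responses",
    "PRO_MOMP",
    "PRO_SURVIVAL",
]

PRO_MOMP = "pro_MOMP"
PRO_SURVIVAL = "pro_survival"

#: Floor added to responses before taking log10 for the density estimate.
LOG_EPS = 1.0e-3

#: Silverman bandwidth multiplier for the response-density estimate.
BW_MULTIPLIER = 1.5

#: A KDE local maximum counts as a dominant mode above this fraction of the
#: global density maximum.
DOMINANCE_FRACTION = 0.1


class BimodalityError(RuntimeError):
    """The response distribution has no well-defined two-mode structure."""


@dataclass
class StimuliMatrix:
    """Iterations x 16 sampled production rates, in the canonical order."""

    values: np.ndarray
    columns: tuple[str, ...] = PRODUCTION_PARAMS

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != len(self.columns):
            raise ValueError("one column per production rate required")
        if np.any(self.values <= 0):
            raise ValueError("sampled production rates must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.columns))

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class MonteCarloResult:
    stimuli: StimuliMatrix
    responses: np.ndarray
    threshold: float | None
    labels: np.ndarray  # PRO_MOMP / PRO_SURVIVAL strings
    seed: int
    q_interval: tuple[float, float]
    sampling: str
    converged: np.ndarray = field(default=None)
    n_excluded: int = 0
    dip: float | None = None
    dip_pvalue: float | None = None

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.converged is None:
            self.converged = np.ones(len(self.responses), dtype=bool)
        if self.threshold is not None:
            want = np.where(self.responses > self.threshold, PRO_MOMP, PRO_SURVIVAL)
            if not np.array_equal(np.asarray(self.labels), want):
                raise ValueError("labels must equal responses > threshold")

    @property
    def pro_momp_fraction(self) -> float:
        return float(np.mean(np.asarray(self.labels) == PRO_MOMP))

    def summary(self) -> dict:
        return {
            "n_iterations": len(self.responses),
            "n_excluded": int(self.n_excluded),
            "seed": int(self.seed),
            "sampling": self.sampling,
            "q_interval": list(self.q_interval),
            "threshold": None if self.threshold is None else float(self.threshold),
            "pro_momp_count": int(np.sum(np.asarray(self.labels) == PRO_MOMP)),
            "pro_survival_count": int(np.sum(np.asarray(self.labels) == PRO_SURVIVAL)),
            "dip": self.dip,
            "dip_pvalue": self.dip_pvalue,
        }


def sample_production_rates(
    defaults: RateParams,
    n_iterations: int,
    q_interval: tuple[float, float] = (0.1, 10.0),
    sampling: str = "log",
    rng: np.random.Generator | int | None = None,
    columns: tuple[str, ...] = PRODUCTION_PARAMS,
) -> StimuliMatrix:
    """Random production-rate vectors: default * q, q fresh per rate per row.

    ``sampling="log"`` draws q log-uniformly over ``q_interval`` (the
    default interval (0.1, 10) spans two decades symmetric about 1);
    ``sampling="linear"`` draws q uniformly over the interval.
    """
    lo, hi = float(q_interval[0]), float(q_interval[1])
    if not (0.0 < lo <= hi) or not np.isfinite(hi):
        raise ValueError(f"invalid q interval ({lo}, {hi})")
    if sampling not in ("log", "linear"):
        raise ValueError("sampling must be 'log' or 'linear'")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    shape = (n_iterations, len(columns))
    if sampling == "log":
        q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=shape))
    else:
        q = rng.uniform(lo, hi, size=shape)
    base = np.array([defaults[c] for c in columns])
    return StimuliMatrix(values=base * q, columns=columns)


def find_bimodal_threshold(
    responses: np.ndarray,
    eps: float = LOG_EPS,
    bw_multiplier: float = BW_MULTIPLIER,
    dominance_fraction: float = DOMINANCE_FRACTION,
    grid_size: int = 512,
) -> float:
    """Density minimum between the two dominant modes of log10(response+eps).

    Raises :class:`BimodalityError` when the smoothed distribution does not
    have exactly two dominant local maxima, rather than returning a
    meaningless number.
    """
    y = np.asarray(responses, dtype=float)
    if len(y) < 100:
        raise ValueError("at least 100 responses required")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("responses must be finite and nonnegative")
    ly = np.log10(y + eps)
    if np.ptp(ly) == 0.0:
        raise BimodalityError("degenerate response distribution")
    kde = gaussian_kde(ly, bw_method="silverman")
    kde.set_bandwidth(kde.factor * bw_multiplier)
    grid = np.linspace(ly.min(), ly.max(), grid_size)
    dens = kde(grid)
    interior = np.nonzero(
        (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    )[0] + 1
    maxima = list(interior)
    if dens[0] > dens[1]:
        maxima.insert(0, 0)
    if dens[-1] > dens[-2]:
        maxima.append(grid_size - 1)
    dominant = [i for i in maxima if dens[i] >= dominance_fraction * dens.max()]
    if len(dominant) < 2:
        raise BimodalityError(
            f"unimodal response distribution ({len(dominant)} dominant mode)"
        )
    if len(dominant) > 2:
        raise BimodalityError(
            f"{len(dominant)} dominant modes; no unique bimodal threshold"
        )
    lo_i, hi_i = sorted(dominant)
    j = lo_i + int(np.argmin(dens[lo_i : hi_i + 1]))
    return float(10.0 ** grid[j] - eps)


def classify_responses(responses: np.ndarray, threshold: float) -> np.ndarray:
    """Dichotomize: strictly above threshold is pro-MOMP, else pro-survival."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y = np.asarray(responses, dtype=float)
    return np.where(y > threshold, PRO_MOMP, PRO_SURVIVAL)


def run_monte_carlo(
    net: ReactionNetwork,
    params: RateParams,
    n_iterations: int,
    q_interval: tuple[float, float] = (0.1, 10.0),
    sampling: str = "log",
    seed: int = 0,
    model: CompiledModel | None = None,
    compute_dip: bool = False,
    require_threshold: bool = False,
) -> MonteCarloResult:
    """Full Monte-Carlo experiment: sample, solve, threshold, label.

    Non-converged iterations are excluded from the density estimate,
    counted and reported (a warning-level situation above 1%).  When the
    response distribution is not bimodal the threshold is ``None`` (or a
    :class:`BimodalityError` if ``require_threshold``).
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    stimuli = sample_production_rates(
        params, n_iterations, q_interval=q_interval, sampling=sampling, rng=rng
    )
    model = model if model is not None else CompiledModel(net, params)
    responses = np.empty(n_iterations)
    converged = np.zeros(n_iterations, dtype=bool)
    for i in range(n_iterations):
        overrides = dict(zip(stimuli.columns, stimuli.values[i]))
        p_i = params.updated(**overrides)
        m_i = model.with_params(p_i)
        try:
            ss = steady_state(net, p_i, initial_state(net, p_i), model=m_i)
        except SimulationError:
            responses[i] = np.nan
            continue
        responses[i] = mac_abundance(net, ss.state)
        converged[i] = ss.converged
    ok = converged & np.isfinite(responses)
    n_excluded = int(n_iterations - ok.sum())

    threshold = None
    dip = dip_p = None
    usable = responses[ok]
    if len(usable) >= 100:
        try:
            threshold = find_bimodal_threshold(usable)
        except BimodalityError:
            if require_threshold:
                raise
    elif n_iterations >= 100 and require_threshold:
        raise BimodalityError("too many excluded iterations for a threshold")
    if compute_dip and len(usable) >= 100:
        dip, dip_p = dip_test(
            np.log10(usable + LOG_EPS), rng=np.random.default_rng(seed + 1)
        )
    if threshold is not None:
        labels = classify_responses(responses, threshold)
    else:
        # no defined threshold: dichotomize at the median for downstream
        # robustness, with threshold=None signalling the failure
        labels = np.where(responses > np.nanmedian(responses), PRO_MOMP, PRO_SURVIVAL)
    result = MonteCarloResult(
        stimuli=stimuli,
        responses=responses,
        threshold=threshold,
        labels=labels,
        seed=seed,
        q_interval=(float(q_interval[0]), float(q_interval[1])),
        sampling=sampling,
        converged=ok,
        n_excluded=n_excluded,
        dip=dip,
        dip_pvalue=dip_p,
    )
    return result
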