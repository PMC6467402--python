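"""One-way sensitivity analysis and cost-neutrality threshold solving.

Each input scalar of the decision model is varied in turn, holding
everything else at base case.  The default sweep range is +/-50% of
the base value, with probabilities clamped to [0, 1]; explicit bounds
override the defaults.  The tornado diagram orders parameters by how
much the net saving moves across the sweep range.  Threshold analysis
solves for the parameter value at which the saving is exactly zero
(the strategies cost the same).

The net saving is affine in every sweepable scalar -- the biopsy rate
is affine in prevalence/sensitivity/specificity, and costs enter the
expected-cost identity linearly -- so the threshold has a closed form
from two model evaluations; a bisection (Brent) root-find on the same
saving function verifies it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import brentq

from .model import evaluate_strategy, saving_vs_comparator
from .params import COST_PARAMS, PROBABILITY_PARAMS, EconParams, ParamsError

__all__ = [
    "SweepSpec",
    "TornadoEntry",
    "ThresholdResult",
    "NoThresholdError",
    "saving_at",
    "one_way_sweep",
    "tornado",
    "threshold_solve",
]

_BISECTION_TOL = 1e-6  # |saving| at the returned root, in currency units
_COST_DOMAIN_FACTOR = 10.0  # threshold search domain for costs: [0, 10 x base]


class NoThresholdError(ValueError):
    """The saving does not change sign over the admissible parameter range."""


@dataclass(frozen=True)
class SweepSpec:
    """One parameter to sweep, with optional explicit bounds.

    When ``low``/``high`` are omitted the defaults are base x 0.5 and
    base x 1.5 (probabilities capped at 1).
    """

    param_name: str
    low: float | None = None
    high: float | None = None

    def __post_init__(self) -> None:
        if self.param_name not in PROBABILITY_PARAMS + COST_PARAMS:
            raise ParamsError(
                f"unknown sweepable parameter {self.param_name!r}; "
                f"expected one of {PROBABILITY_PARAMS + COST_PARAMS}"
            )
        if self.low is not None and self.high is not None and self.low > self.high:
            raise ParamsError(f"sweep bounds must satisfy low <= high, got {self.low} > {self.high}")

    def resolve(self, params: EconParams) -> tuple[float, float]:
        """Concrete (low, high) endpoints at these base parameters."""
        base = params.get(self.param_name)
        if self.param_name in PROBABILITY_PARAMS:
            low = 0.5 * base if self.low is None else self.low
            high = min(1.5 * base, 1.0) if self.high is None else self.high
            if not (0.0 <= low <= 1.0 and 0.0 <= high <= 1.0):
                raise ParamsError(
                    f"sweep bounds for probability {self.param_name!r} must lie in [0, 1], got [{low}, {high}]"
                )
        else:
            low = 0.5 * base if self.low is None else self.low
            high = 1.5 * base if self.high is None else self.high
            if low < 0 or high < 0:
                raise ParamsError(f"sweep bounds for cost {self.param_name!r} must be non-negative")
        return low, high


@dataclass(frozen=True)
class TornadoEntry:
    """Savings at the two sweep endpoints of one parameter."""

    param_name: str
    base_value: float
    low: float
    high: float
    saving_at_low: float
    saving_at_high: float
    base_saving: float

    @property
    def width(self) -> float:
        """Tornado bar width: total swing of the saving across the range."""
        return abs(self.saving_at_high - self.saving_at_low)


def saving_at(params: EconParams, param_name: str | None = None, value: float | None = None) -> float:
    """Net saving of rule-out-first vs procedure-for-all, optionally with one scalar overridden.

    Both arms are re-evaluated at the overridden value (a swept biopsy
    cost changes the comparator's cost too).
    """
    if param_name is not None:
        params.get(param_name)  # validates the name
        params = params.replace(**{param_name: value})
    strategy = evaluate_strategy(params.replace(use_test=True))
    comparator = evaluate_strategy(params.replace(use_test=False))
    return saving_vs_comparator(strategy, comparator)


def one_way_sweep(params: EconParams, spec: SweepSpec | str) -> TornadoEntry:
    """Evaluate the saving at the low and high end of one parameter's range."""
    if isinstance(spec, str):
        spec = SweepSpec(spec)
    low, high = spec.resolve(params)
    return TornadoEntry(
        param_name=spec.param_name,
        base_value=params.get(spec.param_name),
        low=low,
        high=high,
        saving_at_low=saving_at(params, spec.param_name, low),
        saving_at_high=saving_at(params, spec.param_name, high),
        base_saving=saving_at(params),
    )


def tornado(params: EconParams, specs: Sequence[SweepSpec | str]) -> list[TornadoEntry]:
    """One-way sweeps for several parameters, widest bar first.

    Equal widths are broken by parameter name so the ordering is
    deterministic.
    """
    entries = [one_way_sweep(params, spec) for spec in specs]
    entries.sort(key=lambda e: (-e.width, e.param_name))
    return entries


@dataclass(frozen=True)
class ThresholdResult:
    """Parameter value at which the two strategies cost the same."""

    param_name: str
    base_value: float
    neutral_value: float


def threshold_solve(
    params: EconParams,
    param_name: str,
    *,
    domain: tuple[float, float] | None = None,
) -> ThresholdResult:
    """Solve saving(param) = 0 for one scalar, all else at base.

    The search domain defaults to [0, 1] for probabilities and
    [0, 10 x base] for costs.  The saving is affine in each sweepable
    scalar, so the root comes from two evaluations in closed form; a
    Brent bisection on the same function verifies it.  If the saving
    does not change sign over the domain, :class:`NoThresholdError`
    is raised.
    """
    base = params.get(param_name)
    if domain is None:
        if param_name in PROBABILITY_PARAMS:
            domain = (0.0, 1.0)
        else:
            domain = (0.0, _COST_DOMAIN_FACTOR * base if base > 0 else 1.0)
    lo, hi = domain
    s_lo = saving_at(params, param_name, lo)
    s_hi = saving_at(params, param_name, hi)
    if s_lo == s_hi or s_lo * s_hi > 0:
        raise NoThresholdError(
            f"no threshold in range for {param_name!r}: saving is {s_lo:.6g} at {lo:g} and {s_hi:.6g} at {hi:g}"
        )
    root = lo - s_lo * (hi - lo) / (s_hi - s_lo)
    if abs(saving_at(params, param_name, root)) > _BISECTION_TOL:
        # affine assumption violated for this parameterisation: fall back on Brent
        root = brentq(
            lambda x: saving_at(params, param_name, x), lo, hi,
            xtol=1e-12, rtol=8.9e-16,
        )
    verified = brentq(
        lambda x: saving_at(params, param_name, x), lo, hi,
        xtol=1e-12, rtol=8.9e-16,
    )
    if abs(saving_at(params, param_name, verified)) > _BISECTION_TOL or abs(verified - root) > 1e-6 * max(1.0, abs(root)):
        raise NoThresholdError(
            f"threshold for {param_name!r} failed bisection verification (closed form {root}, bisection {verified})"
        )
    return ThresholdResult(param_name=param_name, base_value=base, neutral_value=root)
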