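"""Specification search for the growth trajectory.

Four starting models cross the two search directions with two residual
structures:

1. step-up from the intercept-only model, ID residuals;
2. top-down from the highest-order polynomial, ID residuals;
3. step-up from the intercept-only model, UN residuals;
4. top-down from the highest-order polynomial, UN residuals
   (the "fully saturated" start).

A search compares adjacent polynomial orders under one of six decision
rules and keeps the residual structure fixed throughout.  The more
complex model must *beat* the simpler one by the rule's margin to be
retained; otherwise the simpler model wins:

=========  =================================================
rule       retain the complex model iff
=========  =================================================
lrt        p(delta chi2, delta df) < 0.05
aic        AIC_simple - AIC_complex >= 4
bic        BIC_simple - BIC_complex >= 2
cfi        CFI_complex - CFI_simple >= 0.01
rmsea      RMSEA_simple - RMSEA_complex >= 0.015
srmr       SRMR_simple - SRMR_complex >= 0.01
=========  =================================================

All search models are unconditional (no covariate).  The default maximum
order is ``t - 2``, which leaves at least one degree of freedom under UN
residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import FitOptions, FitResult, baseline_fit, fit_indices, fit_ml, lrt
from .model import ModelSpec

__all__ = [
    "CRITERIA",
    "DEFAULT_CUTOFFS",
    "StartingModel",
    "SearchOptions",
    "TraceStep",
    "SearchResult",
    "compare_models",
    "run_search",
    "ladder_report",
]

CRITERIA = ("lrt", "cfi", "rmsea", "srmr", "aic", "bic")

DEFAULT_CUTOFFS = {
    "aic": 4.0,
    "bic": 2.0,
    "cfi": 0.01,
    "rmsea": 0.015,
    "srmr": 0.01,
    "lrt": 0.05,  # alpha level
}

_STARTING_MODELS = {
    1: ("simplest", "ID"),
    2: ("most_complex", "ID"),
    3: ("simplest", "UN"),
    4: ("most_complex", "UN"),
}


@dataclass(frozen=True)
class StartingModel:
    """One of the four starting models; ``direction`` follows the start."""

    id: int

    def __post_init__(self) -> None:
        if self.id not in _STARTING_MODELS:
            raise ValueError(f"starting model id must be 1-4, got {self.id}")

    @property
    def mean_start(self) -> str:
        return _STARTING_MODELS[self.id][0]

    @property
    def residual_structure(self) -> str:
        return _STARTING_MODELS[self.id][1]

    @property
    def direction(self) -> str:
        return "step_up" if self.mean_start == "simplest" else "top_down"

    @property
    def random_effects_policy(self) -> str:
        # full Psi over as many factors as stay identified for ID;
        # a free UN Theta already absorbs the factor covariance.
        return "none" if self.residual_structure == "UN" else "full_identified"


@dataclass(frozen=True)
class SearchOptions:
    """Search controls: maximum order (default t - 2) and rule cutoffs."""

    max_order: int | None = None
    cutoffs: dict = field(default_factory=dict)
    fit_options: FitOptions = field(default_factory=FitOptions)

    def cutoff(self, criterion: str) -> float:
        return self.cutoffs.get(criterion, DEFAULT_CUTOFFS[criterion])


@dataclass(frozen=True)
class TraceStep:
    """One pairwise comparison in a search trace."""

    order_simple: int
    order_complex: int
    criterion: str
    statistic: float
    decision: str  # "simpler" | "complex"
    flagged: bool  # True when a nonconverged fit forced the decision


@dataclass
class SearchResult:
    """Outcome of one specification search on one dataset."""

    selected_order: int
    trace: list[TraceStep]
    criterion: str
    starting_model: int
    all_converged: bool

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.trace])


def compare_models(
    simple: FitResult,
    complex: FitResult,
    criterion: str,
    options: SearchOptions | None = None,
) -> tuple[str, float, bool]:
    """Decide between a nested pair under one rule.

    Returns ``(decision, statistic, flagged)`` where decision is
    ``"simpler"`` or ``"complex"``.  If either fit failed to converge the
    simpler model is retained and the step flagged.
    """
    if criterion not in CRITERIA:
        raise ValueError(
            f"unknown criterion {criterion!r}; expected one of {CRITERIA}"
        )
    opts = options or SearchOptions()
    cut = opts.cutoff(criterion)
    if not (simple.converged and complex.converged):
        return "simpler", float("nan"), True
    if criterion == "lrt":
        _, _, p = lrt(simple, complex)
        return ("complex" if p < cut else "simpler"), p, False
    if criterion == "aic":
        stat = simple.aic - complex.aic
    elif criterion == "bic":
        stat = simple.bic - complex.bic
    elif criterion == "cfi":
        stat = complex.cfi - simple.cfi
    elif criterion == "rmsea":
        stat = simple.rmsea - complex.rmsea
    else:  # srmr
        stat = simple.srmr - complex.srmr
    return ("complex" if stat >= cut else "simpler"), float(stat), False


class _FitLadder:
    """Lazy per-order fits with indices, shared through an external cache."""

    def __init__(self, dataset, residual, policy, options: SearchOptions, cache=None):
        self.dataset = dataset
        self.residual = residual
        self.policy = policy
        self.options = options
        self.cache = cache if cache is not None else {}
        t = np.asarray(getattr(dataset, "y", dataset)).shape[1]
        self.n_waves = t

    def baseline(self) -> FitResult:
        if "baseline" not in self.cache:
            self.cache["baseline"] = baseline_fit(self.dataset)
        return self.cache["baseline"]

    def fit(self, order: int) -> FitResult:
        key = (order, self.residual, self.policy)
        if key not in self.cache:
            spec = ModelSpec(
                n_waves=self.n_waves,
                mean_order=order,
                residual_structure=self.residual,
                random_effects_policy=self.policy,
            )
            result = fit_ml(self.dataset, spec, self.options.fit_options)
            fit_indices(
                result,
                self.baseline(),
                include_means=self.options.fit_options.srmr_include_means,
            )
            self.cache[key] = result
        return self.cache[key]


def run_search(
    dataset,
    start: StartingModel | int,
    criterion: str,
    options: SearchOptions | None = None,
    cache: dict | None = None,
) -> SearchResult:
    """Run one specification search on a complete wide dataset.

    ``cache`` may be shared across criteria and starting models operating
    on the same dataset; fitted models are keyed by
    ``(order, residual_structure, random_effects_policy)``.
    """
    if isinstance(start, int):
        start = StartingModel(start)
    opts = options or SearchOptions()
    ladder = _FitLadder(
        dataset, start.residual_structure, start.random_effects_policy, opts, cache
    )
    max_order = (
        opts.max_order if opts.max_order is not None else ladder.n_waves - 2
    )
    if not 0 < max_order <= ladder.n_waves - 1:
        raise ValueError(
            f"max_order must lie in [1, {ladder.n_waves - 1}], got {max_order}"
        )

    trace: list[TraceStep] = []
    if start.direction == "step_up":
        order = 0
        while order < max_order:
            decision, stat, flagged = compare_models(
                ladder.fit(order), ladder.fit(order + 1), criterion, opts
            )
            trace.append(
                TraceStep(order, order + 1, criterion, stat, decision, flagged)
            )
            if decision == "simpler":
                break
            order += 1
        selected = order
    else:  # top_down
        order = max_order
        while order >= 1:
            decision, stat, flagged = compare_models(
                ladder.fit(order - 1), ladder.fit(order), criterion, opts
            )
            trace.append(
                TraceStep(order - 1, order, criterion, stat, decision, flagged)
            )
            if decision == "complex":
                break
            order -= 1
        selected = order

    return SearchResult(
        selected_order=selected,
        trace=trace,
        criterion=criterion,
        starting_model=start.id,
        all_converged=not any(s.flagged for s in trace),
    )


def ladder_report(
    dataset,
    residual: str = "UN",
    orders=None,
    policy: str | None = None,
    options: SearchOptions | None = None,
) -> pd.DataFrame:
    """Fit every polynomial order in ``orders`` and tabulate all indices.

    One row per mean order with k, df, log-likelihood, chi-square and the
    six selection criteria — the applied-workflow ladder table.
    """
    opts = options or SearchOptions()
    if policy is None:
        policy = "none" if residual == "UN" else "full_identified"
    ladder = _FitLadder(dataset, residual, policy, opts)
    if orders is None:
        orders = range(0, ladder.n_waves - 1)
    rows = []
    for order in orders:
        result = ladder.fit(order)
        row = {"order": order}
        row.update(result.to_record())
        rows.append(row)
    return pd.DataFrame(rows)
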