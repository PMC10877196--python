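"""Incremental cost-effectiveness statistics for a pair of strategies.

All comparisons treat meniscal repair as the intervention and partial
meniscectomy as the comparator.  A strategy is *dominant* when it both saves
money and gains QALYs; otherwise cost-effectiveness at a willingness-to-pay
threshold lambda is decided by the net monetary benefit
NMB = lambda * dQALY - dCost, with NMB = 0 conservatively classified as not
cost-effective.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .life_tables import LifeTable
from .markov_engine import ArmResult, max_cycles, run_arm
from .parameters import ParameterSet

CLASSIFICATIONS = ("dominant", "cost_effective", "not_cost_effective", "dominated")


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of intervention vs comparator at one WTP."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    classification: str
    wtp: float

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qalys - self.delta_cost


def classify(delta_cost: float, delta_qalys: float, wtp: float) -> str:
    if delta_cost < 0 and delta_qalys > 0:
        return "dominant"
    if delta_cost > 0 and delta_qalys < 0:
        return "dominated"
    return "cost_effective" if wtp * delta_qalys - delta_cost > 0 else "not_cost_effective"


def compare(intervention: ArmResult, comparator: ArmResult, wtp: float = 100000.0) -> CEResult:
    """CEResult for intervention vs comparator run under identical settings."""
    for attr in ("setting", "start_age", "horizon", "correction", "cohort_size"):
        a, b = getattr(intervention, attr), getattr(comparator, attr)
        if a != b:
            raise ValueError(f"arm results differ in {attr}: {a!r} vs {b!r}")
    dc = intervention.discounted_cost - comparator.discounted_cost
    dq = intervention.discounted_qalys - comparator.discounted_qalys
    icer = dc / dq if dq != 0 else None
    return CEResult(dc, dq, icer, classify(dc, dq, wtp), wtp)


def run_comparison(
    params: ParameterSet,
    life_table: LifeTable,
    horizon: int | None = None,
    wtp: float | None = None,
    correction: str = "half_cycle",
) -> tuple[CEResult, ArmResult, ArmResult]:
    """Run both arms under one ParameterSet and compare (MR vs PM)."""
    mr = run_arm(params, life_table, "MR", horizon, correction)
    pm = run_arm(params, life_table, "PM", horizon, correction)
    return compare(mr, pm, params.wtp_threshold if wtp is None else wtp), mr, pm


def ceac(draws, wtp_grid=None) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve.

    ``draws`` is an (n, 2) array-like or DataFrame of (delta_cost,
    delta_qalys) per PSA iteration; the returned frame has one row per WTP
    with the fraction of iterations in which the intervention is
    cost-effective (NMB strictly positive).
    """
    if isinstance(draws, pd.DataFrame):
        arr = draws[["delta_cost", "delta_qalys"]].to_numpy()
    else:
        arr = np.asarray(draws, dtype=float)
    if arr.ndim != 2 or arr.shape[0] == 0 or arr.shape[1] != 2:
        raise ValueError("draws must be a non-empty (n, 2) collection")
    if wtp_grid is None:
        wtp_grid = np.arange(0.0, 150001.0, 1000.0)
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    dc, dq = arr[:, 0], arr[:, 1]
    frac = (wtp_grid[:, None] * dq[None, :] - dc[None, :] > 0).mean(axis=1)
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": frac})


def threshold_search(
    params: ParameterSet,
    life_table: LifeTable,
    param_path: str,
    bounds: tuple[float, float],
    criterion: str = "dominance_boundary",
    wtp: float | None = None,
    xtol: float = 1e-3,
) -> float:
    """Bisect a parameter to the value where the decision flips.

    ``dominance_boundary`` finds where incremental cost crosses zero (the
    intervention stops being cost-saving); ``wtp_boundary`` finds where the
    net monetary benefit crosses zero at the given WTP.
    """
    if criterion not in ("dominance_boundary", "wtp_boundary"):
        raise ValueError(f"unknown criterion {criterion!r}")
    wtp = params.wtp_threshold if wtp is None else wtp

    def g(value: float) -> float:
        res, _, _ = run_comparison(params.replace(**{param_path: value}), life_table, wtp=wtp)
        return res.delta_cost if criterion == "dominance_boundary" else res.nmb

    lo, hi = bounds
    glo, ghi = g(lo), g(hi)
    if lo >= hi or np.sign(glo) == np.sign(ghi):
        def label(v):
            res, _, _ = run_comparison(params.replace(**{param_path: v}), life_table, wtp=wtp)
            return res.classification
        raise ValueError(
            f"no {criterion} crossing for {param_path} on [{lo}, {hi}]: "
            f"endpoints classify as {label(lo)} / {label(hi)}"
        )
    return float(brentq(g, lo, hi, xtol=xtol))


def horizon_sweep(
    params: ParameterSet,
    life_table: LifeTable,
    max_horizon: int | None = None,
    wtp: float | None = None,
    correction: str = "half_cycle",
) -> pd.DataFrame:
    """CEResult per time horizon 1..max_horizon (truncated, no terminal value)."""
    max_horizon = max_cycles(params) if max_horizon is None else max_horizon
    rows = []
    for h in range(1, max_horizon + 1):
        res, _, _ = run_comparison(params, life_table, horizon=h, wtp=wtp, correction=correction)
        rows.append({
            "horizon": h,
            "delta_cost": res.delta_cost,
            "delta_qalys": res.delta_qalys,
            "icer": res.icer,
            "nmb": res.nmb,
            "classification": res.classification,
        })
    return pd.DataFrame(rows)
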