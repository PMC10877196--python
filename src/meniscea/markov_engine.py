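"""Annual-cycle Markov cohort engine for one treatment arm.

The reported model has 7 health states: no OA after the primary procedure,
no OA after a revision resection, osteoarthritis, the TKR cycle (a one-cycle
tunnel so the procedure's cost and disutility attach exactly once), post-TKR,
post-revision-TKR, and death.  Three clocks that the flat 7-state space
cannot carry are tracked through internal sub-states and collapsed for
reporting:

* years since a revision resection, because the banded OA probabilities are
  "years after PM" and a failed repair's revision *is* that patient's first
  partial meniscectomy — by default the OA band clock restarts there
  (``oa_clock="since_last_procedure"``; ``"since_primary"`` keeps one clock).
* post-TKR years, for the optional ``rtkr_clock="since_tkr"`` banding of the
  TKR-revision probability.  The default follows the source model and bands
  the revision probability by years since primary treatment, in which case
  the band depends only on the cycle index.  The tunnel cycle counts as
  post-TKR year 1.
* repair-intact status among OA patients, because the risk of index-procedure
  failure (revision resection) during the failure window is independent of
  whether OA has already set in.  Without this, OA onset at 11.27%/yr would
  deplete the at-risk pool and cumulative revisions could never compound to
  1 - (1 - p_fail)^window, which the lifetime revision counts require.

Within a cycle, competing risks are resolved sequentially: background + any
procedural death first, then failure of the index procedure (while the
window is open), then OA onset or TKR conversion among the survivors of the
earlier stages.  Rows therefore stay stochastic without renormalisation.

Costs and QALYs are accrued with a within-cycle correction (half-cycle by
default, trapezoid as a cross-check, or none), discounted at 3%/yr to
mid-cycle under correction.  The index procedure's cost and disutility fall
at time zero, undiscounted; procedure mortality (0.3%) applies to the index
procedure at time zero and combines multiplicatively with background
mortality for later procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .parameters import ParameterSet

ARMS = ("MR", "PM")

#: reported (public) health states, in order
STATES = (
    "no_oa_post_primary",
    "no_oa_post_revision",
    "oa",
    "tkr",
    "post_tkr",
    "post_rtkr",
    "death",
)

EVENTS = ("revision", "oa_incidence", "tkr", "rtkr", "death")

# internal state layout ----------------------------------------------------
# Sub-state clocks run 1..11+, enough to resolve every band boundary (the
# OA bands change at years 5 and 10, the TKR-revision bands at 4, 9 and 10).
_N_YEARS = 11

_NOOA_P = 0                       # no OA, primary procedure intact
_NOOA_R0 = 1                      # no OA, revised; +y-1 for years-since-revision y=1..11+
_OA_INTACT = _NOOA_R0 + _N_YEARS  # OA, repair intact (failure-eligible)
_OA = _OA_INTACT + 1              # OA, failed/revised or past the window
_TKR1 = _OA + 1                   # TKR tunnel = post-TKR year 1; +y-1 for y=1..11+
_POSTRTKR = _TKR1 + _N_YEARS
_DEATH = _POSTRTKR + 1
N_INTERNAL = _DEATH + 1

#: collapse map internal -> public state index
_PUBLIC_OF = np.array(
    [0] + [1] * _N_YEARS + [2, 2] + [3] + [4] * (_N_YEARS - 1) + [5, 6]
)

_E_REV, _E_OA, _E_TKR, _E_RTKR, _E_DEATH = range(len(EVENTS))


def max_cycles(params: ParameterSet) -> int:
    """Cycles from start_age through the cycle lived at max_age."""
    return params.max_age - params.start_age + 1


def _cycle_inputs(params: ParameterSet, life_table: LifeTable, arm: str, horizon: int):
    """Per-cycle probability vectors (length T, plus (T, years) band grids)."""
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}")
    t = np.arange(1, horizon + 1)
    ages = params.start_age + t - 1
    q = np.asarray(life_table.q_at(ages), dtype=float)
    window = params.failure_window_years
    in_window = np.ones(horizon, bool) if window is None else (t <= window)
    f = np.where(in_window, params.p_fail(arm), 0.0)

    p_oa_fn = params.p_oa_mr if arm == "MR" else params.p_oa_pm
    o = np.array([p_oa_fn(int(tt)) for tt in t])
    rev_fn = params.p_oa_pm if (arm == "MR" and params.post_revision_oa == "pm") else p_oa_fn
    years = np.arange(1, _N_YEARS + 1)
    if params.oa_clock == "since_last_procedure":
        o_rev = np.broadcast_to(
            np.array([rev_fn(int(y)) for y in years]), (horizon, _N_YEARS)
        ).copy()
    else:  # one clock from primary treatment: band depends only on the cycle
        o_rev = np.broadcast_to(
            np.array([rev_fn(int(tt)) for tt in t])[:, None], (horizon, _N_YEARS)
        ).copy()

    if params.rtkr_clock == "since_tkr":
        r = np.broadcast_to(
            np.array([params.p_tkr_revision(int(y)) for y in years]), (horizon, _N_YEARS)
        ).copy()
    else:  # banded by years since primary treatment, i.e. by cycle index
        r = np.broadcast_to(
            np.array([params.p_tkr_revision(int(tt)) for tt in t])[:, None],
            (horizon, _N_YEARS),
        ).copy()
    return q, f, o, o_rev, r


def transition_matrices(
    params: ParameterSet, life_table: LifeTable, arm: str, horizon: int | None = None
):
    """Stacks of per-cycle transition matrices P (T, S, S) and event-intensity
    matrices E (T, n_events, S); E[t, k, s] is the probability that an
    occupant of internal state s experiences event k during cycle t+1
    (fatal procedures included in the event count)."""
    T = max_cycles(params) if horizon is None else min(horizon, max_cycles(params))
    q, f, o, o_rev, r = _cycle_inputs(params, life_table, arm, T)
    m = params.p_procedure_mortality
    k = params.p_oa_to_tkr_annual
    s = 1.0 - q  # background survivors

    P = np.zeros((T, N_INTERNAL, N_INTERNAL))
    E = np.zeros((T, len(EVENTS), N_INTERNAL))

    # no OA, primary intact: death, then failure, then OA among non-failed
    P[:, _NOOA_P, _DEATH] = q + s * f * m
    P[:, _NOOA_P, _NOOA_R0] = s * f * (1.0 - m)
    P[:, _NOOA_P, _OA_INTACT] = s * (1.0 - f) * o
    P[:, _NOOA_P, _NOOA_P] = s * (1.0 - f) * (1.0 - o)
    E[:, _E_REV, _NOOA_P] = s * f
    E[:, _E_OA, _NOOA_P] = s * (1.0 - f) * o

    # no OA, revised (years since revision y = 1..11+): OA risk from the
    # configured clock/arm; one revision max, so no further failure
    for j in range(_N_YEARS):
        state = _NOOA_R0 + j
        nxt = min(state + 1, _NOOA_R0 + _N_YEARS - 1)
        ov = o_rev[:, j]
        P[:, state, _DEATH] = q
        P[:, state, _OA] = s * ov
        P[:, state, nxt] = s * (1.0 - ov)
        E[:, _E_OA, state] = s * ov

    # OA with intact repair: failure still possible; TKR among non-failed
    P[:, _OA_INTACT, _DEATH] = q + s * (f * m + (1.0 - f) * k * m)
    P[:, _OA_INTACT, _OA] = s * f * (1.0 - m)
    P[:, _OA_INTACT, _TKR1] = s * (1.0 - f) * k * (1.0 - m)
    P[:, _OA_INTACT, _OA_INTACT] = s * (1.0 - f) * (1.0 - k)
    E[:, _E_REV, _OA_INTACT] = s * f
    E[:, _E_TKR, _OA_INTACT] = s * (1.0 - f) * k

    # OA (no failure risk): TKR conversion only
    P[:, _OA, _DEATH] = q + s * k * m
    P[:, _OA, _TKR1] = s * k * (1.0 - m)
    P[:, _OA, _OA] = s * (1.0 - k)
    E[:, _E_TKR, _OA] = s * k

    # post-TKR years 1..11+: banded revision risk, at most one revision
    for j in range(_N_YEARS):
        state = _TKR1 + j
        nxt = min(state + 1, _TKR1 + _N_YEARS - 1)
        rv = r[:, j]
        P[:, state, _DEATH] = q + s * rv * m
        P[:, state, _POSTRTKR] = s * rv * (1.0 - m)
        P[:, state, nxt] = s * (1.0 - rv)
        E[:, _E_RTKR, state] = s * rv

    P[:, _POSTRTKR, _DEATH] = q
    P[:, _POSTRTKR, _POSTRTKR] = s
    P[:, _DEATH, _DEATH] = 1.0

    E[:, _E_DEATH, :_DEATH] = P[:, :_DEATH, _DEATH]

    rowsum_err = np.abs(P.sum(axis=2) - 1.0).max()
    if rowsum_err > 1e-12:
        raise AssertionError(f"transition matrix rows deviate from 1 by {rowsum_err}")
    return P, E


def build_transition_matrix(
    params: ParameterSet, life_table: LifeTable, cycle: int, arm: str
) -> np.ndarray:
    """Internal-state transition matrix for one cycle (1-based)."""
    if cycle < 1:
        raise ValueError("cycle is 1-based")
    P, _ = transition_matrices(params, life_table, arm, horizon=cycle)
    return P[cycle - 1]


@dataclass(frozen=True)
class CohortTrace:
    """Occupancy at every cycle boundary plus per-cycle event tallies.

    ``occupancy_internal`` has shape (T+1, N_INTERNAL); row 0 is the start
    (after the index procedure and its mortality).  ``events`` has shape
    (T, n_events): persons experiencing each event during cycle t.
    """

    params: ParameterSet
    arm: str
    occupancy_internal: np.ndarray
    events: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy_internal.shape[0] - 1

    @property
    def occupancy(self) -> np.ndarray:
        """Occupancy collapsed to the 7 reported states, shape (T+1, 7)."""
        out = np.zeros((self.occupancy_internal.shape[0], len(STATES)))
        np.add.at(out.T, _PUBLIC_OF, self.occupancy_internal.T)
        return out

    def to_frame(self) -> pd.DataFrame:
        """One row per cycle boundary: public occupancy and event tallies
        (events in row t are those occurring during cycle t)."""
        df = pd.DataFrame(self.occupancy, columns=STATES)
        df.insert(0, "cycle", np.arange(self.n_cycles + 1))
        ev = np.vstack([np.zeros((1, len(EVENTS))), self.events])
        for j, name in enumerate(EVENTS):
            df[f"event_{name}"] = ev[:, j]
        return df


def run_cohort(
    params: ParameterSet,
    life_table: LifeTable,
    arm: str,
    horizon: int | None = None,
) -> CohortTrace:
    """Project the cohort through the transition matrices.

    The cohort enters the no-OA post-primary state having survived the index
    procedure (procedure mortality attaches to the downstream procedures the
    model itself generates, not at entry).
    """
    T = max_cycles(params) if horizon is None else min(horizon, max_cycles(params))
    if T < 1:
        raise ValueError("horizon must be >= 1")
    P, E = transition_matrices(params, life_table, arm, T)
    X = np.zeros((T + 1, N_INTERNAL))
    n = params.cohort_size
    X[0, _NOOA_P] = n
    events = np.zeros((T, len(EVENTS)))
    for t in range(T):
        events[t] = E[t] @ X[t]
        X[t + 1] = X[t] @ P[t]
    return CohortTrace(params=params, arm=arm, occupancy_internal=X, events=events)


def within_cycle_correct(trace: CohortTrace, method: str = "half_cycle") -> np.ndarray:
    """Effective internal-state occupancy per cycle, shape (T, N_INTERNAL).

    ``half_cycle`` shifts state membership by half a cycle (the classic
    half-duration cycle added at the start), realised by evaluating the
    piecewise-linear occupancy path at cycle midpoints; ``trapezoid``
    integrates the same path cycle by cycle; ``none`` takes end-of-cycle
    occupancy.  The first two are algebraically equivalent and are kept as
    separate code paths as a numerical cross-check.
    """
    X = trace.occupancy_internal
    T = trace.n_cycles
    if method == "half_cycle":
        boundaries = np.arange(T + 1, dtype=float)
        mid = boundaries[:-1] + 0.5
        out = np.empty((T, X.shape[1]))
        for j in range(X.shape[1]):
            out[:, j] = np.interp(mid, boundaries, X[:, j])
        return out
    if method == "trapezoid":
        return 0.5 * (X[:-1] + X[1:])
    if method == "none":
        return X[1:]
    raise ValueError(f"unknown within-cycle correction {method!r}")


def discount_stream(values: np.ndarray, rate: float, offset: float = 0.0) -> float:
    """Present value of per-cycle amounts: sum of v_t / (1+rate)^(t - offset)
    for cycles t = 1..T.  ``offset=0.5`` is mid-cycle timing (used with
    within-cycle correction), ``offset=0`` end-of-cycle."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    values = np.asarray(values, dtype=float)
    t = np.arange(1, values.shape[0] + 1, dtype=float)
    return float(np.sum(values / (1.0 + rate) ** (t - offset)))


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals and lifetime event counts for one arm (cohort scale)."""

    arm: str
    discounted_cost: float
    discounted_qalys: float
    undiscounted_qalys: float
    revisions: float
    oa_cases: float
    tkrs: float
    rtkrs: float
    # provenance, so comparisons can check like-for-like
    setting: str = "hospital"
    start_age: int = 35
    horizon: int = 76
    correction: str = "half_cycle"
    cohort_size: float = 1000.0

    def per_patient(self, value: float) -> float:
        return value / self.cohort_size


def _state_vectors(params: ParameterSet):
    u = np.zeros(N_INTERNAL)
    u[_NOOA_P:_OA_INTACT] = params.u_no_oa
    u[[_OA_INTACT, _OA]] = params.u_oa
    u[_TKR1:_POSTRTKR] = params.u_post_tkr
    u[_POSTRTKR] = params.u_post_rtkr
    c = np.zeros(N_INTERNAL)
    c[_OA_INTACT:_POSTRTKR + 1] = params.cost_oa_state_annual
    return u, c


def accumulate(trace: CohortTrace, params: ParameterSet, correction: str = "half_cycle") -> ArmResult:
    """Turn a trace into discounted cost and QALY totals plus event counts."""
    eff = within_cycle_correct(trace, correction)
    offset = 0.0 if correction == "none" else 0.5
    u, c_state = _state_vectors(params)

    c_event = np.zeros(len(EVENTS))
    c_event[_E_REV] = params.cost_revision()
    c_event[_E_TKR] = params.cost_tkr
    c_event[_E_RTKR] = params.cost_rtkr
    d_event = np.zeros(len(EVENTS))
    d_event[_E_REV] = params.disutil_meniscal_procedure
    d_event[_E_TKR] = params.disutil_tkr
    d_event[_E_RTKR] = params.disutil_rtkr

    n = params.cohort_size
    qaly_stream = eff @ u - trace.events @ d_event
    cost_stream = eff @ c_state + trace.events @ c_event
    index_disutil = n * params.disutil_meniscal_procedure
    qalys = discount_stream(qaly_stream, params.discount_rate_qalys, offset) - index_disutil
    qalys_undisc = float(qaly_stream.sum()) - index_disutil
    cost = n * params.cost_index(trace.arm) + discount_stream(
        cost_stream, params.discount_rate_costs, offset
    )
    ev = trace.events.sum(axis=0)
    return ArmResult(
        arm=trace.arm,
        discounted_cost=cost,
        discounted_qalys=qalys,
        undiscounted_qalys=qalys_undisc,
        revisions=float(ev[_E_REV]),
        oa_cases=float(ev[_E_OA]),
        tkrs=float(ev[_E_TKR]),
        rtkrs=float(ev[_E_RTKR]),
        setting=params.setting,
        start_age=params.start_age,
        horizon=trace.n_cycles,
        correction=correction,
        cohort_size=n,
    )


def run_arm(
    params: ParameterSet,
    life_table: LifeTable,
    arm: str,
    horizon: int | None = None,
    correction: str = "half_cycle",
) -> ArmResult:
    """Convenience: project one arm and accumulate its totals."""
    return accumulate(run_cohort(params, life_table, arm, horizon), params, correction)
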