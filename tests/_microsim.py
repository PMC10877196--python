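"""Individual-level Monte Carlo oracle for the cohort engine.

Re-implements the transition rules patient by patient with independent
uniform draws per decision, sharing nothing with the matrix-based engine
beyond the ParameterSet/LifeTable inputs.  Used to check that the cohort
trace's expected event totals match stochastic reality.
"""

from __future__ import annotations

import numpy as np

from meniscea.life_tables import LifeTable
from meniscea.parameters import ParameterSet


def simulate_events(
    params: ParameterSet,
    life_table: LifeTable,
    arm: str,
    n_individuals: int,
    seed: int = 0,
) -> dict[str, float]:
    """Event totals per ``n_individuals`` patients (same keys as engine events)."""
    rng = np.random.default_rng(seed)
    n = n_individuals
    T = params.max_age - params.start_age + 1
    window = params.failure_window_years

    # per-patient flags; states: 0 no-OA primary, 1 no-OA revised, 2 OA,
    # 3 post-TKR, 4 post-R-TKR, 5 dead
    state = np.zeros(n, dtype=np.int8)
    intact = np.ones(n, dtype=bool)            # primary procedure never failed
    yrs_since_rev = np.zeros(n, dtype=np.int16)
    m = params.p_procedure_mortality
    k = params.p_oa_to_tkr_annual

    counts = {name: 0 for name in ("revision", "oa_incidence", "tkr", "rtkr", "death")}

    def band_oa(fn, years):
        return np.array([fn(int(max(1, y))) for y in years])

    for t in range(1, T + 1):
        age = params.start_age + t - 1
        q = life_table.q_at(age)
        alive = state < 5

        # background death first
        dies = alive & (rng.random(n) < q)
        state[dies] = 5
        counts["death"] += int(dies.sum())
        alive = state < 5

        # index-procedure failure while the window is open, irrespective of OA
        f = params.p_fail(arm) if (window is None or t <= window) else 0.0
        fails = alive & intact & (state <= 2) & (rng.random(n) < f)
        counts["revision"] += int(fails.sum())
        proc_dead = fails & (rng.random(n) < m)
        state[proc_dead] = 5
        counts["death"] += int(proc_dead.sum())
        survived_fail = fails & ~proc_dead
        intact[fails] = False
        newly_revised = survived_fail & (state == 0)
        state[newly_revised] = 1
        yrs_since_rev[newly_revised] = 0
        alive = state < 5

        # OA onset among no-OA patients who did not fail this cycle
        p_oa_fn = params.p_oa_mr if arm == "MR" else params.p_oa_pm
        rev_fn = (
            params.p_oa_pm
            if (arm == "MR" and params.post_revision_oa == "pm")
            else p_oa_fn
        )
        cand_p = alive & (state == 0) & ~fails
        to_oa_p = cand_p & (rng.random(n) < p_oa_fn(t))
        cand_r = alive & (state == 1) & ~newly_revised
        yrs_since_rev[cand_r] += 1
        if params.oa_clock == "since_last_procedure":
            p_rev = band_oa(rev_fn, yrs_since_rev)
        else:
            p_rev = np.full(n, rev_fn(t))
        to_oa_r = cand_r & (rng.random(n) < p_rev)
        to_oa = to_oa_p | to_oa_r
        # a patient who failed while already heading to OA still reaches OA
        state[to_oa] = 2
        counts["oa_incidence"] += int(to_oa.sum())

        # TKR conversion from OA (not for patients who failed this cycle)
        cand_tkr = alive & (state == 2) & ~fails & ~to_oa
        to_tkr = cand_tkr & (rng.random(n) < k)
        counts["tkr"] += int(to_tkr.sum())
        tkr_dead = to_tkr & (rng.random(n) < m)
        state[tkr_dead] = 5
        counts["death"] += int(tkr_dead.sum())
        state[to_tkr & ~tkr_dead] = 3
        alive = state < 5

        # TKR revision (once), banded by the configured clock
        if params.rtkr_clock == "since_primary":
            r = params.p_tkr_revision(t)
        else:
            raise NotImplementedError("oracle covers the since_primary clock")
        cand_rtkr = alive & (state == 3) & ~to_tkr
        to_rtkr = cand_rtkr & (rng.random(n) < r)
        counts["rtkr"] += int(to_rtkr.sum())
        rtkr_dead = to_rtkr & (rng.random(n) < m)
        state[rtkr_dead] = 5
        counts["death"] += int(rtkr_dead.sum())
        state[to_rtkr & ~rtkr_dead] = 4

    return counts
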