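"""Deterministic and probabilistic sensitivity analyses.

One-way analysis re-runs the full paired model at a low and a high value of a
single parameter.  The PSA draws every uncertain parameter jointly from its
assigned distribution, applies the *same* draw to both treatment arms within
an iteration (so the incremental results reflect decision uncertainty, not
arm-independent noise), and records per-patient incremental cost and QALYs
for the cost-effectiveness plane and acceptability curve.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import pandas as pd

from .cea import CEResult, run_comparison
from .life_tables import LifeTable
from .markov_engine import run_arm
from .parameters import ParameterSet, PsaSpec, sample_psa

logger = logging.getLogger(__name__)


def one_way(
    base: ParameterSet,
    life_table: LifeTable,
    param_path: str,
    low: float,
    high: float,
    horizon: int | None = None,
    wtp: float | None = None,
) -> tuple[CEResult, CEResult]:
    """CEResults with one parameter at its low and high value, all else base."""
    results = []
    for value in (low, high):
        res, _, _ = run_comparison(
            base.replace(**{param_path: value}), life_table, horizon=horizon, wtp=wtp
        )
        results.append(res)
    return results[0], results[1]


@dataclass(frozen=True)
class PsaDrawTable:
    """Per-iteration incremental outcomes (per patient) plus run metadata."""

    draws: pd.DataFrame  # columns: iteration, delta_cost, delta_qalys
    seed: int
    n_iterations: int
    setting: str
    start_age: int
    n_resampled: int = 0

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "n_iterations": self.n_iterations,
            "setting": self.setting,
            "start_age": self.start_age,
            "n_resampled": self.n_resampled,
        }

    def fraction_cost_effective(self, wtp: float = 100000.0) -> float:
        nmb = wtp * self.draws["delta_qalys"] - self.draws["delta_cost"]
        return float((nmb > 0).mean())

    def to_csv(self, path, metadata_path=None) -> None:
        self.draws.to_csv(path, index=False)
        if metadata_path is not None:
            with open(metadata_path, "w") as fh:
                json.dump(self.metadata(), fh, indent=2)


def run_psa(
    base: ParameterSet,
    spec: PsaSpec,
    life_table: LifeTable,
    horizon: int | None = None,
    correction: str = "half_cycle",
) -> PsaDrawTable:
    """Run the PSA: one shared parameter draw per iteration, both arms.

    Iterations are seeded independently from the root seed, so the table is
    reproducible and independent of execution order.
    """
    n = base.cohort_size
    rows = []
    for i in range(spec.n_iterations):
        drawn = sample_psa(base, spec, i)
        mr = run_arm(drawn, life_table, "MR", horizon, correction)
        pm = run_arm(drawn, life_table, "PM", horizon, correction)
        rows.append((
            i,
            (mr.discounted_cost - pm.discounted_cost) / n,
            (mr.discounted_qalys - pm.discounted_qalys) / n,
        ))
    draws = pd.DataFrame(rows, columns=["iteration", "delta_cost", "delta_qalys"])
    return PsaDrawTable(
        draws=draws,
        seed=spec.seed,
        n_iterations=spec.n_iterations,
        setting=base.setting,
        start_age=base.start_age,
    )
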