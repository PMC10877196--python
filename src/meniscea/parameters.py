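"""Model inputs: base-case parameters, probability conversions, PSA sampling.

Every quantity the decision model consumes lives in one immutable
:class:`ParameterSet`: annual transition probabilities (including the
time-banded osteoarthritis and TKR-revision probabilities), the relative risk
of OA progression after meniscal repair versus partial meniscectomy, 2021 USD
Medicare costs for both outpatient settings, per-cycle utilities, per-procedure
disutilities, discount rates and the willingness-to-pay threshold.

Probabilities reported in the clinical literature as multi-year cumulative
endpoints are converted to annual cycle probabilities with
:func:`endpoint_to_annual_prob`; the relative risk is applied with
:func:`rr_adjust_prob`.  Probabilistic sensitivity analysis draws are produced
by :func:`sample_psa` from a :class:`PsaSpec` describing each parameter's
distribution family and uncertainty range.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

SCENARIOS = ("all_suture", "various_techniques")
SETTINGS = ("hospital", "asc")

#: annual MR failure probability per effectiveness scenario (from 2-year
#: cumulative failure endpoints of 17.4% and 5.6% respectively)
_MR_FAILURE_BY_SCENARIO = {"all_suture": 0.0912, "various_techniques": 0.0284}


def endpoint_to_annual_prob(cumulative_prob: float, horizon_years: float) -> float:
    """Annual probability p with 1 - (1 - p)**horizon_years = cumulative_prob.

    Converts a cumulative multi-year endpoint (e.g. a 2-year failure rate)
    into the constant per-cycle probability that compounds to it.
    """
    if not 0.0 <= cumulative_prob < 1.0:
        raise ValueError(f"cumulative_prob must be in [0, 1), got {cumulative_prob}")
    if horizon_years < 1:
        raise ValueError(f"horizon_years must be >= 1, got {horizon_years}")
    return 1.0 - (1.0 - cumulative_prob) ** (1.0 / horizon_years)


def rr_adjust_prob(p_annual: float, rr: float, space: str = "probability") -> float:
    """Apply a relative risk to an annual transition probability.

    ``space="probability"`` multiplies directly (p * rr), the package default;
    ``space="rate"`` applies the RR on the exponential-rate scale,
    1 - (1 - p)**rr.  The two agree to first order for small p.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual must be in [0, 1], got {p_annual}")
    if rr <= 0:
        raise ValueError(f"rr must be > 0, got {rr}")
    if space == "probability":
        out = p_annual * rr
    elif space == "rate":
        out = 1.0 - (1.0 - p_annual) ** rr
    else:
        raise ValueError(f"unknown rr space {space!r}")
    if not 0.0 <= out <= 1.0:
        raise ValueError(f"adjusted probability {out} outside [0, 1]")
    return out


@dataclass(frozen=True)
class ParameterSet:
    """One complete, validated model configuration (base case by default)."""

    # demographics / structure
    start_age: int = 35
    cohort_size: float = 1000.0
    max_age: int = 110
    setting: str = "hospital"
    # failure (revision) probabilities, annual
    p_fail_pm_annual: float = 0.002
    p_fail_mr_annual: float = 0.0912
    failure_window_years: int | None = 3  # None = failure possible in every cycle
    # OA progression after PM, annual, banded by years since primary treatment
    p_oa_pm_y1_5: float = 0.1127
    p_oa_pm_y6_10: float = 0.0351
    p_oa_pm_y11plus: float = 0.0089
    rr_oa_mr_vs_pm: float = 0.55
    rr_space: str = "probability"  # how the RR is applied; see rr_adjust_prob
    # OA risk after a failed repair is resected: "pm" = comparator risk (the
    # meniscus is now partially resected), "primary" = keep the arm's RR benefit
    post_revision_oa: str = "pm"
    # clock for the OA bands: years since the most recent meniscal procedure
    # (a revision restarts it) or years since the primary treatment only
    oa_clock: str = "since_last_procedure"
    # clock for the TKR-revision bands: years since primary treatment (flat
    # cycle-indexed bands) or years since the TKR itself
    rtkr_clock: str = "since_primary"
    # OA -> TKR and TKR revision, annual; revision banded by years since TKR
    p_oa_to_tkr_annual: float = 0.0227
    p_rtkr_y1_4: float = 0.019
    p_rtkr_y5_9: float = 0.01
    p_rtkr_y10: float = 0.009
    p_rtkr_y11plus: float = 0.006
    p_procedure_mortality: float = 0.003
    # costs, 2021 USD
    cost_mr_index_hospital: float = 4996.0
    cost_mr_index_asc: float = 3494.0
    cost_pm_hospital: float = 3433.0  # index and revision PM/TM
    cost_pm_asc: float = 1931.0
    cost_tkr: float = 38916.0
    cost_rtkr: float = 46698.0
    cost_oa_state_annual: float = 3486.0  # OA, post-TKR and post-R-TKR states
    # per-cycle utilities and per-procedure disutilities
    u_no_oa: float = 0.9
    u_oa: float = 0.69
    u_post_tkr: float = 0.835
    u_post_rtkr: float = 0.785
    disutil_meniscal_procedure: float = 0.0077
    disutil_tkr: float = 0.025
    disutil_rtkr: float = 0.05
    # economics
    discount_rate_costs: float = 0.03
    discount_rate_qalys: float = 0.03
    wtp_threshold: float = 100000.0

    def __post_init__(self) -> None:
        errors = []
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}={v} outside [0, 1]")
        for name in _UTILITY_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}={v} outside [0, 1]")
        for name in _COST_FIELDS + _DISUTIL_FIELDS:
            if getattr(self, name) < 0:
                errors.append(f"{name}={getattr(self, name)} negative")
        if self.rr_oa_mr_vs_pm <= 0:
            errors.append(f"rr_oa_mr_vs_pm={self.rr_oa_mr_vs_pm} must be > 0")
        if self.rr_space == "probability" and self.rr_oa_mr_vs_pm * self.p_oa_pm_y1_5 > 1:
            errors.append("rr_oa_mr_vs_pm * p_oa_pm_y1_5 exceeds 1")
        if self.setting not in SETTINGS:
            errors.append(f"setting={self.setting!r} not in {SETTINGS}")
        if self.rr_space not in ("probability", "rate"):
            errors.append(f"rr_space={self.rr_space!r} not in ('probability', 'rate')")
        if self.post_revision_oa not in ("pm", "primary"):
            errors.append(f"post_revision_oa={self.post_revision_oa!r} not in ('pm', 'primary')")
        if self.oa_clock not in ("since_last_procedure", "since_primary"):
            errors.append(f"oa_clock={self.oa_clock!r} not in ('since_last_procedure', 'since_primary')")
        if self.rtkr_clock not in ("since_primary", "since_tkr"):
            errors.append(f"rtkr_clock={self.rtkr_clock!r} not in ('since_primary', 'since_tkr')")
        if not self.start_age < self.max_age:
            errors.append(f"start_age={self.start_age} must be below max_age={self.max_age}")
        if self.cohort_size <= 0:
            errors.append("cohort_size must be positive")
        if self.failure_window_years is not None and self.failure_window_years < 0:
            errors.append("failure_window_years must be >= 0 or None")
        for name in ("discount_rate_costs", "discount_rate_qalys"):
            if getattr(self, name) < 0:
                errors.append(f"{name} negative")
        if errors:
            raise ValueError("invalid ParameterSet: " + "; ".join(errors))

    # --- band lookups -----------------------------------------------------
    def p_oa_pm(self, years_since_treatment: int) -> float:
        """Annual OA probability in the PM arm, by years since primary treatment."""
        if years_since_treatment < 1:
            raise ValueError("years_since_treatment starts at 1")
        if years_since_treatment <= 5:
            return self.p_oa_pm_y1_5
        if years_since_treatment <= 10:
            return self.p_oa_pm_y6_10
        return self.p_oa_pm_y11plus

    def p_oa_mr(self, years_since_treatment: int) -> float:
        """Annual OA probability in the MR arm (RR-adjusted PM probability)."""
        return rr_adjust_prob(
            self.p_oa_pm(years_since_treatment), self.rr_oa_mr_vs_pm, self.rr_space
        )

    def p_tkr_revision(self, years_since_tkr: int) -> float:
        """Annual probability of TKR revision, by years since the TKR."""
        if years_since_tkr < 1:
            raise ValueError("years_since_tkr starts at 1")
        if years_since_tkr <= 4:
            return self.p_rtkr_y1_4
        if years_since_tkr <= 9:
            return self.p_rtkr_y5_9
        if years_since_tkr == 10:
            return self.p_rtkr_y10
        return self.p_rtkr_y11plus

    def p_fail(self, arm: str) -> float:
        return self.p_fail_mr_annual if arm.upper() == "MR" else self.p_fail_pm_annual

    # --- setting-resolved costs -------------------------------------------
    def cost_index(self, arm: str) -> float:
        if arm.upper() == "MR":
            return self.cost_mr_index_hospital if self.setting == "hospital" else self.cost_mr_index_asc
        return self.cost_revision()

    def cost_revision(self) -> float:
        """Cost of a PM/TM resection (index PM or any revision, either arm)."""
        return self.cost_pm_hospital if self.setting == "hospital" else self.cost_pm_asc

    def replace(self, **overrides) -> "ParameterSet":
        """Return a copy with the given fields overridden (re-validated)."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ValueError(f"unknown parameter field(s): {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_PROB_FIELDS = (
    "p_fail_pm_annual", "p_fail_mr_annual", "p_oa_pm_y1_5", "p_oa_pm_y6_10",
    "p_oa_pm_y11plus", "p_oa_to_tkr_annual", "p_rtkr_y1_4", "p_rtkr_y5_9",
    "p_rtkr_y10", "p_rtkr_y11plus", "p_procedure_mortality",
)
_UTILITY_FIELDS = ("u_no_oa", "u_oa", "u_post_tkr", "u_post_rtkr")
_COST_FIELDS = (
    "cost_mr_index_hospital", "cost_mr_index_asc", "cost_pm_hospital",
    "cost_pm_asc", "cost_tkr", "cost_rtkr", "cost_oa_state_annual",
)
_DISUTIL_FIELDS = ("disutil_meniscal_procedure", "disutil_tkr", "disutil_rtkr")


def build_parameter_set(
    scenario: str = "all_suture",
    setting: str = "hospital",
    start_age: int = 35,
    overrides: dict | None = None,
) -> ParameterSet:
    """Assemble a validated ParameterSet for a named effectiveness scenario.

    ``scenario`` selects the MR failure probability (all-suture technique
    9.12%/yr, or 2.84%/yr pooled across repair techniques); every other field
    keeps its base value unless explicitly overridden.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}, got {scenario!r}")
    base = ParameterSet(
        setting=setting.lower(),
        start_age=start_age,
        p_fail_mr_annual=_MR_FAILURE_BY_SCENARIO[scenario],
    )
    return base.replace(**overrides) if overrides else base


def load_config(path) -> dict:
    """Read a flat JSON or YAML config of ParameterSet overrides."""
    text = Path(path).read_text()
    cfg = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg


def parameter_set_from_config(config: dict) -> ParameterSet:
    """Build a ParameterSet from a flat config dict (audit-friendly entry point).

    Recognised meta keys: ``scenario`` and ``setting``; every other key must
    name a ParameterSet field.  Unknown keys are rejected by name.
    """
    cfg = dict(config)
    scenario = cfg.pop("scenario", "all_suture")
    setting = cfg.pop("setting", "hospital")
    start_age = cfg.pop("start_age", 35)
    if cfg.get("failure_window_years") in ("unlimited", "none"):
        cfg["failure_window_years"] = None
    return build_parameter_set(scenario, setting, start_age, overrides=cfg)


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParamDist:
    """Sampling distribution for one parameter.

    ``family`` is one of beta / gamma / lognormal / fixed.  Uncertainty is a
    95% central interval: either an explicit ``interval`` (as printed for the
    utilities) or the conventional +/-20% band around the mean, turned into a
    standard deviation as half-width / 1.96.  Distributions are then fit by
    method of moments.
    """

    family: str
    mean: float
    interval: tuple[float, float] | None = None
    rel_halfwidth: float = 0.20

    @property
    def sd(self) -> float:
        if self.family == "fixed":
            return 0.0
        if self.interval is not None:
            return (self.interval[1] - self.interval[0]) / (2 * 1.96)
        return self.rel_halfwidth * self.mean / 1.96

    def sample(self, rng: np.random.Generator) -> float:
        m, s = self.mean, self.sd
        if self.family == "fixed" or s == 0.0:
            return m
        if self.family == "beta":
            nu = m * (1.0 - m) / s**2 - 1.0
            if nu <= 0:
                raise ValueError(f"beta moments infeasible (mean={m}, sd={s})")
            return float(rng.beta(m * nu, (1.0 - m) * nu))
        if self.family == "gamma":
            if m <= 0:
                raise ValueError("gamma needs a positive mean")
            return float(rng.gamma((m / s) ** 2, s**2 / m))
        if self.family == "lognormal":
            if m <= 0:
                raise ValueError("lognormal needs a positive mean")
            sigma2 = np.log1p((s / m) ** 2)
            return float(rng.lognormal(np.log(m) - sigma2 / 2.0, np.sqrt(sigma2)))
        raise ValueError(f"unknown distribution family {self.family!r}")


@dataclass(frozen=True)
class PsaSpec:
    """Distributions, iteration count and seed for one PSA run."""

    distributions: dict[str, ParamDist]
    n_iterations: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for name in self.distributions:
            if name in _FIXED_IN_PSA:
                raise ValueError(f"{name} is structural and is never sampled in PSA")


#: fields that are design choices, not evidence, and are held fixed in PSA
_FIXED_IN_PSA = frozenset({
    "start_age", "max_age", "cohort_size", "setting", "failure_window_years",
    "discount_rate_costs", "discount_rate_qalys", "wtp_threshold", "rr_space",
    "post_revision_oa", "oa_clock", "rtkr_clock",
})

#: explicit 95% intervals printed for the utilities (upper bounds already <= 1)
_UTILITY_INTERVALS = {
    "u_no_oa": (0.72, 1.0),
    "u_oa": (0.55, 0.83),
    "u_post_tkr": (0.68, 1.0),
    "u_post_rtkr": (0.63, 0.94),
}


def default_psa_spec(base: ParameterSet, n_iterations: int = 10000, seed: int = 0) -> PsaSpec:
    """The base-case PSA design: Beta for probabilities and utilities, Gamma
    for costs, Log-normal for the RR and the disutilities; +/-20% ranges except
    the utilities' printed intervals; baseline mortality held fixed."""
    dists: dict[str, ParamDist] = {}
    for name in _PROB_FIELDS:
        dists[name] = ParamDist("beta", getattr(base, name))
    for name in _COST_FIELDS:
        dists[name] = ParamDist("gamma", getattr(base, name))
    for name in _UTILITY_FIELDS:
        dists[name] = ParamDist("beta", getattr(base, name), interval=_UTILITY_INTERVALS[name])
    for name in _DISUTIL_FIELDS:
        dists[name] = ParamDist("lognormal", getattr(base, name))
    dists["rr_oa_mr_vs_pm"] = ParamDist("lognormal", base.rr_oa_mr_vs_pm)
    return PsaSpec(distributions=dists, n_iterations=n_iterations, seed=seed)


def sample_psa(
    base: ParameterSet, spec: PsaSpec, draw_index: int, max_attempts: int = 100
) -> ParameterSet:
    """Draw one perturbed ParameterSet, reproducible from (seed, draw_index).

    Each draw gets its own random stream keyed by (seed, draw_index), so
    iterations are order-independent.  A draw that violates a ParameterSet
    invariant (possible but rare, e.g. an extreme RR draw) is re-sampled from
    the same stream and the retry is logged.
    """
    rng = np.random.default_rng([spec.seed, draw_index])
    names = sorted(spec.distributions)
    for attempt in range(max_attempts):
        overrides = {name: spec.distributions[name].sample(rng) for name in names}
        try:
            drawn = base.replace(**overrides)
        except ValueError:
            logger.info("PSA draw %d attempt %d invalid; re-sampling", draw_index, attempt + 1)
            continue
        return drawn
    raise RuntimeError(f"PSA draw {draw_index}: no valid parameter set in {max_attempts} attempts")


def export_parameters_csv(base: ParameterSet, spec: PsaSpec | None = None, path=None) -> pd.DataFrame:
    """Audit table: one row per parameter with base value, family and 95% range."""
    spec = spec or default_psa_spec(base)
    rows = []
    for f in dataclasses.fields(base):
        value = getattr(base, f.name)
        dist = spec.distributions.get(f.name)
        if dist is None:
            rows.append({"parameter": f.name, "base_value": value,
                         "distribution": "fixed", "low_95": "", "high_95": ""})
        else:
            lo, hi = dist.interval or (dist.mean - 1.96 * dist.sd, dist.mean + 1.96 * dist.sd)
            rows.append({"parameter": f.name, "base_value": value,
                         "distribution": dist.family, "low_95": lo, "high_95": hi})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, index=False)
    return df
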