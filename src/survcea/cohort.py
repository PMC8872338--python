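"""Individual-level synthetic cohorts emulating the four follow-up groups.

The generator draws, per patient, an exponential distant-recurrence time
and an exponential loss-to-follow-up (attrition) time, walks the group's
visit schedule, simulates each visit's diagnostic result from the true
recurrence status, and censors at the first detection, at attrition, or at
the 5-year horizon.  Extra confirmatory investigations are attached to
positive (true or false) findings as overdispersed negative-binomial
counts.  Patients in the no-imaging group accrue clinical reviews, not
scans, so their scan statistics are reported as absent.

:func:`estimate_params` closes the loop the source cohort analysis
performed: constant-hazard MLE from events over person-time at risk, test
sensitivity/specificity from per-visit tallies against true status, with
Wald intervals on the log-hazard and logit scales.  :func:`calibrate`
recovers unprinted model inputs from printed outputs by bounded
derivative-free least squares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field
from scipy import optimize, stats

from .model import compute_outcomes
from .params import STRATEGY_NAMES, ModelParams, StrategySpec, TestPerformance, with_updates

_SUBSTAGES = ("IIIA", "IIIB", "IIIC", "IIID")
_SUBSTAGE_PROBS = (0.28, 0.30, 0.32, 0.10)


class CohortConfig(BaseModel):
    """Generating conditions for a synthetic follow-up cohort."""

    group_sizes: dict[str, int] = Field(
        default={
            "three_four_monthly": 146,
            "six_monthly": 47,
            "twelve_monthly": 284,
            "no_imaging": 346,
        }
    )
    horizon_years: float = Field(default=5.0, gt=0)
    #: per-year distant-recurrence hazard per group
    hazards: dict[str, float] = Field(
        default={
            "three_four_monthly": 0.1597,
            "six_monthly": 0.1196,
            "twelve_monthly": 0.0862,
            "no_imaging": 0.1022,
        }
    )
    test: TestPerformance = TestPerformance(sensitivity=0.79, specificity=0.90)
    clinical_detection_prob: float = Field(default=0.40, ge=0, le=1)
    #: loss-to-follow-up hazard per year (administrative censoring + attrition)
    attrition_rate: float = Field(default=0.44, ge=0)
    #: negative-binomial mean/dispersion of confirmatory work-ups per
    #: positive or equivocal finding
    extra_investigation_mean: float = Field(default=5.0, gt=0)
    extra_investigation_dispersion: float = Field(default=0.6, gt=0)
    seed: int = 0
    strategies: list[StrategySpec] = Field(
        default=[
            StrategySpec(name="three_four_monthly", visits_per_year=4),
            StrategySpec(name="six_monthly", visits_per_year=2),
            StrategySpec(name="twelve_monthly", visits_per_year=1),
            StrategySpec(name="no_imaging", visits_per_year=0, reviews_per_year=2),
        ]
    )

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortConfig":
        return cls.model_validate_json(Path(path).read_text())


@dataclass
class SyntheticPatient:
    id: int
    group: str
    sub_stage: str
    #: latent exponential recurrence time (may exceed the horizon)
    recurrence_time: float
    #: end of observation: min(detection, attrition, horizon)
    followup_end: float
    visit_times: list[float]
    results: list[str]  # TP/FP/TN/FN per attended visit
    detection_time: float | None
    scan_count: int | None  # attended imaging visits; None for no-imaging
    review_count: int
    extra_investigation_count: int

    @property
    def recurred_during_followup(self) -> bool:
        return self.recurrence_time <= self.followup_end


def _exp_time(rng: np.random.Generator, rate: float) -> float:
    return float(rng.exponential(1.0 / rate)) if rate > 0 else math.inf


def _negbin(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    # NB parameterized by mean m and dispersion k: p = k/(k+m)
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Draw one reproducible cohort; identical config implies identical cohort."""
    rng = np.random.default_rng(config.seed)
    specs = {s.name: s for s in config.strategies}
    patients: list[SyntheticPatient] = []
    pid = 0
    for group, n in config.group_sizes.items():
        spec = specs[group]
        n_events = round(spec.events_per_year * config.horizon_years)
        dt = config.horizon_years / max(n_events, 1)
        schedule = [dt * (k + 1) for k in range(n_events)]
        imaging = spec.imaging
        det_prob = config.test.sensitivity if imaging else config.clinical_detection_prob
        fp_rate = (1.0 - config.test.specificity) if imaging else 0.0
        lam = config.hazards[group]
        for _ in range(n):
            rec_time = _exp_time(rng, lam)
            attr_time = _exp_time(rng, config.attrition_rate)
            obs_end = min(attr_time, config.horizon_years)
            visit_times: list[float] = []
            results: list[str] = []
            detection_time: float | None = None
            extra = 0
            for t in schedule:
                if t > obs_end:
                    break
                visit_times.append(t)
                diseased = rec_time <= t
                if diseased:
                    result = "TP" if rng.random() < det_prob else "FN"
                else:
                    result = "FP" if rng.random() < fp_rate else "TN"
                results.append(result)
                if result in ("TP", "FP"):
                    extra += _negbin(
                        rng,
                        config.extra_investigation_mean,
                        config.extra_investigation_dispersion,
                    )
                if result == "TP":
                    detection_time = t
                    break  # detection absorbs: no visits after detection
            followup_end = detection_time if detection_time is not None else obs_end
            patients.append(
                SyntheticPatient(
                    id=pid,
                    group=group,
                    sub_stage=_SUBSTAGES[
                        rng.choice(len(_SUBSTAGES), p=_SUBSTAGE_PROBS)
                    ],
                    recurrence_time=rec_time,
                    followup_end=followup_end,
                    visit_times=visit_times,
                    results=results,
                    detection_time=detection_time,
                    scan_count=len(visit_times) if imaging else None,
                    review_count=0 if imaging else len(visit_times),
                    extra_investigation_count=extra,
                )
            )
            pid += 1
    return patients


@dataclass
class GroupSummary:
    n: int
    scan_mean: float | None
    scan_sd: float | None
    scan_range: tuple[int, int] | None
    extra_mean: float | None
    extra_sd: float | None
    extra_range: tuple[int, int] | None
    recurrence_prop: float | None
    detection_prop: float | None  # among patients recurring during follow-up


@dataclass
class CohortSummary:
    groups: dict[str, GroupSummary]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for name, g in self.groups.items():
            recs.append(
                {
                    "group": name,
                    "n": g.n,
                    "scan_mean": g.scan_mean,
                    "scan_sd": g.scan_sd,
                    "scan_min": None if g.scan_range is None else g.scan_range[0],
                    "scan_max": None if g.scan_range is None else g.scan_range[1],
                    "extra_mean": g.extra_mean,
                    "extra_sd": g.extra_sd,
                    "extra_min": None if g.extra_range is None else g.extra_range[0],
                    "extra_max": None if g.extra_range is None else g.extra_range[1],
                    "recurrence_prop": g.recurrence_prop,
                    "detection_prop": g.detection_prop,
                }
            )
        return pd.DataFrame(recs)


def _stats(values: Sequence[float]) -> tuple[float | None, float | None, tuple | None]:
    if len(values) == 0:
        return None, None, None
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else None  # sample SD
    return mean, sd, (int(arr.min()), int(arr.max()))


def summarize(patients: Sequence[SyntheticPatient]) -> CohortSummary:
    """Exact descriptive statistics per group (sample SD convention)."""
    if not patients:
        raise ValueError("cannot summarize an empty cohort")
    groups: dict[str, GroupSummary] = {}
    order = [g for g in STRATEGY_NAMES if any(p.group == g for p in patients)]
    order += [p.group for p in patients if p.group not in order]
    for name in dict.fromkeys(order):
        members = [p for p in patients if p.group == name]
        scans = [p.scan_count for p in members if p.scan_count is not None]
        extras = [p.extra_investigation_count for p in members]
        scan_mean, scan_sd, scan_range = _stats(scans)
        extra_mean, extra_sd, extra_range = _stats(extras)
        recurred = [p for p in members if p.recurred_during_followup]
        groups[name] = GroupSummary(
            n=len(members),
            scan_mean=scan_mean,
            scan_sd=scan_sd,
            scan_range=scan_range,
            extra_mean=extra_mean,
            extra_sd=extra_sd,
            extra_range=extra_range,
            recurrence_prop=(len(recurred) / len(members)) if members else None,
            detection_prop=(
                sum(p.detection_time is not None for p in recurred) / len(recurred)
                if recurred
                else None
            ),
        )
    return CohortSummary(groups=groups)


@dataclass
class IntervalEstimate:
    estimate: float
    lo: float
    hi: float


@dataclass
class ParamEstimates:
    """Hazard and test-performance estimates with 95% Wald intervals."""

    hazard: dict[str, IntervalEstimate]
    pooled_hazard: IntervalEstimate
    sensitivity: IntervalEstimate | None
    specificity: IntervalEstimate | None
    clinical_detection_prob: IntervalEstimate | None
    events: int
    person_years: float


def _hazard_ci(events: int, person_time: float) -> IntervalEstimate:
    if person_time <= 0:
        raise ValueError("zero person-time at risk")
    if events == 0:
        # exact Poisson upper bound, finite even with no events
        upper = stats.chi2.ppf(0.975, 2) / 2 / person_time
        return IntervalEstimate(0.0, 0.0, float(upper))
    lam = events / person_time
    se_log = 1.0 / math.sqrt(events)  # Wald on the log-hazard scale
    return IntervalEstimate(
        lam, lam * math.exp(-1.959964 * se_log), lam * math.exp(1.959964 * se_log)
    )


def _proportion_ci(successes: int, trials: int) -> IntervalEstimate | None:
    if trials == 0:
        return None
    p = successes / trials
    if successes == 0 or successes == trials:
        # logit Wald is undefined at the boundary; fall back to exact
        lo, hi = stats.beta.ppf(
            [0.025, 0.975], successes + 0.5, trials - successes + 0.5
        )
        return IntervalEstimate(p, float(lo), float(hi))
    logit = math.log(p / (1 - p))
    se = math.sqrt(1.0 / successes + 1.0 / (trials - successes))  # Wald, logit scale
    lo = 1.0 / (1.0 + math.exp(-(logit - 1.959964 * se)))
    hi = 1.0 / (1.0 + math.exp(-(logit + 1.959964 * se)))
    return IntervalEstimate(p, lo, hi)


def estimate_params(patients: Sequence[SyntheticPatient]) -> ParamEstimates:
    """Constant-hazard MLE and test-performance tallies from a cohort.

    Person-time at risk runs to the earlier of recurrence and end of
    follow-up; sensitivity/specificity pool per-visit results against true
    status over the imaging groups, clinical detection over the no-imaging
    group.
    """
    if not patients:
        raise ValueError("no patients")
    hazard: dict[str, IntervalEstimate] = {}
    tot_events, tot_pt = 0, 0.0
    for name in dict.fromkeys(p.group for p in patients):
        members = [p for p in patients if p.group == name]
        events = sum(p.recurred_during_followup for p in members)
        pt = sum(min(p.recurrence_time, p.followup_end) for p in members)
        hazard[name] = _hazard_ci(events, pt)
        tot_events += events
        tot_pt += pt
    tp = fn = tn = fp = 0
    ctp = cfn = 0
    for p in patients:
        imaging = p.scan_count is not None
        for t, res in zip(p.visit_times, p.results):
            if imaging:
                tp += res == "TP"
                fn += res == "FN"
                tn += res == "TN"
                fp += res == "FP"
            else:
                ctp += res == "TP"
                cfn += res == "FN"
    return ParamEstimates(
        hazard=hazard,
        pooled_hazard=_hazard_ci(tot_events, tot_pt),
        sensitivity=_proportion_ci(tp, tp + fn),
        specificity=_proportion_ci(tn, tn + fp),
        clinical_detection_prob=_proportion_ci(ctp, ctp + cfn),
        events=tot_events,
        person_years=tot_pt,
    )


# ---------------------------------------------------------------------------
# calibration of unprinted model inputs to printed outputs

#: StrategyOutcome attributes a calibration target may address
TARGET_QUANTITIES = (
    "expected_cost",
    "expected_cost_error_avoided",
    "effect_correct_diagnosis",
    "effect_error_avoided",
)


@dataclass
class CalibrationTarget:
    strategy: str
    quantity: str  # one of TARGET_QUANTITIES
    value: float

    def __post_init__(self) -> None:
        if self.quantity not in TARGET_QUANTITIES:
            raise ValueError(f"unknown target quantity {self.quantity!r}")


@dataclass
class CalibrationResult:
    params: ModelParams
    free_params: list[str]
    fitted_values: dict[str, float]
    residuals: dict[str, float]  # standardized, keyed "strategy.quantity"
    objective: float
    converged: bool  # optimizer converged AND residuals are negligible
    message: str
    nfev: int


def _predict(params: ModelParams, targets: Sequence[CalibrationTarget]) -> list[float]:
    outcomes = {o.name: o for o in compute_outcomes(params)}
    return [getattr(outcomes[t.strategy], t.quantity) for t in targets]


def calibrate(
    targets: Sequence[CalibrationTarget],
    free_params: Sequence[str],
    params: ModelParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    residual_tol: float = 1e-4,
) -> CalibrationResult:
    """Fit free parameters so model outputs match target values.

    Minimizes the sum of squared standardized residuals (residual divided
    by max(|target|, 1e-6)) with bounded derivative-free search (Powell),
    starting from the current parameter values.  Non-convergence — or a
    best fit whose residuals remain above ``residual_tol`` — is reported
    in the result, never raised.
    """
    if len(free_params) > len(targets):
        raise ValueError(
            f"{len(free_params)} free parameters exceed {len(targets)} targets"
        )
    from .params import get_param

    x0 = np.array([get_param(params, p) for p in free_params], dtype=float)
    bnds = []
    for p, x in zip(free_params, x0):
        if bounds and p in bounds:
            bnds.append(bounds[p])
        elif 0.0 <= x <= 1.0:
            bnds.append((1e-6, 0.999))  # probability-like default
        else:
            bnds.append((0.0, 10.0 * max(x, 1.0)))
    scales = np.array([max(abs(t.value), 1e-6) for t in targets])
    target_vals = np.array([t.value for t in targets])

    def objective(x: np.ndarray) -> float:
        p = with_updates(params, dict(zip(free_params, x)))
        pred = np.array(_predict(p, targets))
        return float((((pred - target_vals) / scales) ** 2).sum())

    res = optimize.minimize(
        objective,
        x0,
        method="Powell",
        bounds=bnds,
        options={"xtol": 1e-10, "ftol": 1e-14, "maxiter": 2000},
    )
    fitted = with_updates(params, dict(zip(free_params, res.x)))
    pred = np.array(_predict(fitted, targets))
    residuals = {
        f"{t.strategy}.{t.quantity}": float((p - t.value) / s)
        for t, p, s in zip(targets, pred, scales)
    }
    max_resid = max(abs(v) for v in residuals.values())
    converged = bool(res.success) and max_resid <= residual_tol
    message = res.message if res.success else f"optimizer failed: {res.message}"
    if res.success and not converged:
        message = (
            f"optimizer converged but max standardized residual {max_resid:.3g} "
            f"exceeds {residual_tol:g}; targets may be unattainable"
        )
    return CalibrationResult(
        params=fitted,
        free_params=list(free_params),
        fitted_values={p: float(v) for p, v in zip(free_params, res.x)},
        residuals=residuals,
        objective=float(res.fun),
        converged=converged,
        message=message,
        nfev=int(res.nfev),
    )


# ---------------------------------------------------------------------------
# cohort CSV I/O (one row per patient; visit results as a delimited field)

#: companion data dictionary for the per-patient CSV
DATA_DICTIONARY = [
    ("id", "integer", "patient identifier, unique within the cohort"),
    ("group", "text", "follow-up strategy group"),
    ("sub_stage", "text", "AJCC sub-stage label (IIIA-D); cosmetic by default"),
    ("recurrence_time", "years", "latent distant-recurrence time; empty if none"),
    ("followup_end", "years", "end of observation: detection, attrition or horizon"),
    ("visit_times", "years;...", "semicolon-delimited attended visit times"),
    ("results", "TP|FP|TN|FN;...", "per-visit diagnostic result, same order"),
    ("detection_time", "years", "time of true-positive diagnosis; empty if none"),
    ("scan_count", "count", "attended imaging visits; empty for the no-imaging group"),
    ("review_count", "count", "attended clinical reviews (no-imaging group)"),
    ("extra_investigation_count", "count", "confirmatory work-ups triggered"),
]


def data_dictionary_frame() -> pd.DataFrame:
    return pd.DataFrame(DATA_DICTIONARY, columns=["column", "unit", "description"])

def cohort_to_frame(patients: Sequence[SyntheticPatient]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": p.id,
                "group": p.group,
                "sub_stage": p.sub_stage,
                "recurrence_time": (
                    p.recurrence_time if math.isfinite(p.recurrence_time) else ""
                ),
                "followup_end": p.followup_end,
                "visit_times": ";".join(f"{t:g}" for t in p.visit_times),
                "results": ";".join(p.results),
                "detection_time": "" if p.detection_time is None else p.detection_time,
                "scan_count": "" if p.scan_count is None else p.scan_count,
                "review_count": p.review_count,
                "extra_investigation_count": p.extra_investigation_count,
            }
            for p in patients
        ]
    )


def cohort_from_frame(df: pd.DataFrame) -> list[SyntheticPatient]:
    patients = []
    for _, r in df.iterrows():
        rec = r["recurrence_time"]
        scan = r["scan_count"]
        det = r["detection_time"]
        patients.append(
            SyntheticPatient(
                id=int(r["id"]),
                group=str(r["group"]),
                sub_stage=str(r["sub_stage"]),
                recurrence_time=(
                    math.inf if rec in ("", None) or pd.isna(rec) else float(rec)
                ),
                followup_end=float(r["followup_end"]),
                visit_times=[
                    float(t) for t in str(r["visit_times"]).split(";") if t
                ],
                results=[s for s in str(r["results"]).split(";") if s],
                detection_time=(
                    None if det in ("", None) or pd.isna(det) else float(det)
                ),
                scan_count=(
                    None if scan in ("", None) or pd.isna(scan) else int(scan)
                ),
                review_count=int(r["review_count"]),
                extra_investigation_count=int(r["extra_investigation_count"]),
            )
        )
    return patients
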