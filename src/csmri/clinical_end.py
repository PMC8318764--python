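"""Early-neurological-deterioration (END) classification and cohort statistics.

Implements the baseline-dependent NIHSS worsening rule, 2x2 contingency
statistics (proportions, odds ratios with Woolf intervals, Pearson
chi-square), a maximum-likelihood logistic model fitted by IRLS, a
synthetic-cohort generator anchored to the packaged worked-example summary
statistics, and a report that recomputes every count-backed percentage in
the packaged fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from csmri._rng import substream

EndRule = Literal["baseline-dependent", "general-delta4"]

NIHSS_MAX = 42


class DegenerateTableError(ValueError):
    """Raised when a contingency table cannot support an odds ratio."""


class UndefinedRateError(ZeroDivisionError):
    """Raised when a proportion is requested over an empty denominator."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NihssTrajectory:
    """NIHSS scores at the five study timepoints (all integers in [0, 42])."""

    baseline: int
    post_thrombolysis: int
    h4: int
    h24: int
    week1: int

    def __post_init__(self) -> None:
        for name in ("baseline", "post_thrombolysis", "h4", "h24", "week1"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 0 <= v <= NIHSS_MAX):
                raise ValueError(f"{name} must be an integer in [0, {NIHSS_MAX}], got {v!r}")

    @property
    def delta_24h(self) -> int:
        return self.h24 - self.baseline


@dataclass(frozen=True)
class PatientRecord:
    """One synthetic patient: covariates, NIHSS trajectory and END label."""

    age: float
    male: bool
    hypertension: bool
    plt: float
    dose: Literal["standard", "low"]
    occlusion_status: Literal["normal", "stenosis", "occlusion"]
    infarct_site: Literal["anterior", "posterior"]
    responsible_artery: Literal["internal-carotid", "middle-cerebral"]
    trajectory: NihssTrajectory
    end_label: bool | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.plt <= 0:
            raise ValueError("platelet count must be positive")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a/b/c/d = exposed+outcome, exposed-only, outcome-only, neither."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise ValueError("counts must be non-negative")
        if self.total == 0:
            raise ValueError("table must have at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


# --------------------------------------------------------------------------
# END classification
# --------------------------------------------------------------------------

def end_threshold(baseline: int) -> int:
    """Worsening threshold for the baseline-dependent rule (inclusive)."""
    return 2 if baseline < 6 else 4


def classify_end(trajectory: NihssTrajectory, rule: EndRule = "baseline-dependent") -> bool:
    """Classify early neurological deterioration from a score trajectory.

    ``baseline-dependent``: END iff the 24-hour score rises by >= 2 when
    the baseline is below 6, or by >= 4 when the baseline is 6 or more.
    ``general-delta4``: END iff the 24-hour score rises by >= 4 regardless
    of baseline.  Both thresholds are inclusive.
    """
    delta = trajectory.delta_24h
    if rule == "baseline-dependent":
        return delta >= end_threshold(trajectory.baseline)
    if rule == "general-delta4":
        return delta >= 4
    raise ValueError(f"unknown END rule {rule!r}")


# --------------------------------------------------------------------------
# contingency statistics
# --------------------------------------------------------------------------

def proportion(count: int, total: int, decimals: int = 2) -> float:
    """Percentage ``100 * count / total`` rounded to ``decimals`` places."""
    if total <= 0:
        raise UndefinedRateError("proportion over an empty denominator")
    if not (0 <= count <= total):
        raise ValueError("count must lie in [0, total]")
    return round(100.0 * count / total, decimals)


def odds_ratio(table: ContingencyTable2x2, ci_level: float = 0.95) -> dict:
    """Cross-product odds ratio with a Woolf log-normal confidence interval.

    When any cell is zero the Haldane–Anscombe 0.5 correction is applied
    to all four cells and flagged in the output.
    """
    if not (0.0 < ci_level < 1.0):
        raise ValueError("ci_level must be in (0, 1)")
    a, b, c, d = table.a, table.b, table.c, table.d
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        raise DegenerateTableError("a full row or column of the table is zero")
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_value = (a * d) / (b * c)
    se_log = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    log_or = np.log(or_value)
    return {
        "or": float(or_value),
        "ci_low": float(np.exp(log_or - z * se_log)),
        "ci_high": float(np.exp(log_or + z * se_log)),
        "ci_level": ci_level,
        "corrected": corrected,
    }


def chi_square_test(table: ContingencyTable2x2, yates: bool = False) -> dict:
    """Pearson chi-square test of independence on a 2x2 table (1 df).

    Continuity correction is off by default; a warning flag is set when
    any expected cell count falls below 1 (the test is still computed).
    """
    observed = table.as_array()
    n = observed.sum()
    expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
    if np.any(expected == 0):
        raise DegenerateTableError("expected count of zero: a margin is empty")
    diff = np.abs(observed - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return {
        "statistic": statistic,
        "p": p,
        "df": 1,
        "warning_low_expected": bool(np.any(expected < 1)),
    }


# --------------------------------------------------------------------------
# logistic model (IRLS)
# --------------------------------------------------------------------------

#: Extractors mapping covariate names to numeric values of a record.
COVARIATE_EXTRACTORS = {
    "age": lambda r: float(r.age),
    "male": lambda r: float(r.male),
    "hypertension": lambda r: float(r.hypertension),
    "plt": lambda r: float(r.plt),
    "dose_standard": lambda r: float(r.dose == "standard"),
    "occlusion": lambda r: float(r.occlusion_status == "occlusion"),
    "stenosis": lambda r: float(r.occlusion_status == "stenosis"),
    "infarct_anterior": lambda r: float(r.infarct_site == "anterior"),
    "artery_internal_carotid": lambda r: float(r.responsible_artery == "internal-carotid"),
    "nihss_baseline": lambda r: float(r.trajectory.baseline),
    "nihss_h4": lambda r: float(r.trajectory.h4),
    "nihss_h24": lambda r: float(r.trajectory.h24),
}


def fit_logistic_arrays(
    x: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    ci_level: float = 0.95,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> dict:
    """Maximum-likelihood logistic regression by iteratively reweighted LS.

    ``x`` excludes the intercept column (added internally).  Returns a
    per-covariate table of B, SE, Wald = (B/SE)^2, OR = exp(B), Wald CI
    and p-value, plus convergence / separation flags.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ValueError("design matrix and outcome lengths differ")
    n, p = x.shape
    if len(names) != p:
        raise ValueError("one name per covariate column is required")
    if n < 10 * p:
        raise ValueError(f"need at least {10 * p} records for {p} covariates")
    if y.min() == y.max():
        raise ValueError("outcome must vary")
    design = np.column_stack([np.ones(n), x])
    beta = np.zeros(p + 1)
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xtwx = design.T @ (design * w[:, None])
        score = design.T @ (y - mu)
        try:
            delta = np.linalg.solve(xtwx, score)
        except np.linalg.LinAlgError:
            break
        beta = beta + delta
        if np.linalg.norm(delta) < tol:
            converged = True
            break
    eta = design @ beta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    xtwx = design.T @ (design * w[:, None])
    try:
        cov = np.linalg.inv(xtwx)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p + 1, np.inf)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    out: dict[str, dict] = {}
    separated = bool(np.any(np.abs(beta) > 30) or not converged)
    for j, name in enumerate(["intercept", *names]):
        b = float(beta[j])
        s = float(se[j])
        wald = (b / s) ** 2 if s > 0 and np.isfinite(s) else float("nan")
        with np.errstate(over="ignore"):  # separated fits legitimately overflow to inf
            out[name] = {
                "beta": b,
                "se": s,
                "wald": wald,
                "or": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * s)),
                "ci_high": float(np.exp(b + z * s)),
                "p": float(stats.chi2.sf(wald, df=1)) if np.isfinite(wald) else float("nan"),
                "estimable": bool(np.isfinite(s) and abs(b) <= 30),
            }
    out["_meta"] = {"converged": converged, "separation_flag": separated, "n": n}
    return out


def fit_logistic(records: Sequence[PatientRecord], covariates: Sequence[str], ci_level: float = 0.95) -> dict:
    """Fit the logistic END model on patient records (see COVARIATE_EXTRACTORS)."""
    for name in covariates:
        if name not in COVARIATE_EXTRACTORS:
            raise ValueError(f"unknown covariate {name!r}")
    if any(r.end_label is None for r in records):
        raise ValueError("all records need an END label")
    x = np.array([[COVARIATE_EXTRACTORS[c](r) for c in covariates] for r in records])
    y = np.array([float(r.end_label) for r in records])
    return fit_logistic_arrays(x, y, covariates, ci_level=ci_level)


def screen_univariate(records: Sequence[PatientRecord], covariates: Sequence[str], p_threshold: float = 0.2) -> list[str]:
    """Keep covariates whose single-covariate model has Wald p below threshold."""
    kept = []
    for name in covariates:
        fit = fit_logistic(records, [name])
        if fit[name]["p"] < p_threshold:
            kept.append(name)
    return kept


# --------------------------------------------------------------------------
# synthetic cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupGaussian:
    """Mean/SD of a continuous covariate in each group."""

    det_mean: float
    det_sd: float
    ctrl_mean: float
    ctrl_sd: float

    def __post_init__(self) -> None:
        if self.det_sd <= 0 or self.ctrl_sd <= 0:
            raise ValueError("standard deviations must be positive")


@dataclass(frozen=True)
class GroupProportion:
    """Probability of a binary covariate in each group."""

    det: float
    ctrl: float

    def __post_init__(self) -> None:
        for v in (self.det, self.ctrl):
            if not (0.0 <= v <= 1.0):
                raise ValueError("proportions must lie in [0, 1]")


def _default_coefficients() -> dict[str, float]:
    # scale anchored near the packaged worked example's reported fit
    return {"intercept": -5.2, "nihss_h4": 0.26, "occlusion": 2.36}


@dataclass(frozen=True)
class CohortSpec:
    """Generative parameters for a synthetic two-group stroke cohort.

    Defaults reproduce the packaged worked-example group summaries:
    group sizes 36/151, age 63+-14 vs 61+-12, platelets 263+-39 vs
    235+-52, the NIHSS trajectory means per timepoint, and the printed
    binary-covariate proportions.  ``mechanism`` selects how END labels
    arise: ``rule`` makes trajectories that satisfy (deterioration group)
    or violate (control group) the baseline-dependent rule exactly;
    ``logistic`` draws labels from the logistic model in
    ``logistic_coefficients`` on pooled covariates.
    """

    n_deterioration: int = 36
    n_control: int = 151
    age: GroupGaussian = GroupGaussian(63, 14, 61, 12)
    plt: GroupGaussian = GroupGaussian(263, 39, 235, 52)
    nihss_baseline: GroupGaussian = GroupGaussian(9.0, 4.0, 9.0, 4.0)
    nihss_post: GroupGaussian = GroupGaussian(9.0, 4.0, 8.8, 4.0)
    nihss_h4: GroupGaussian = GroupGaussian(12.3, 4.0, 8.4, 4.0)
    nihss_h24: GroupGaussian = GroupGaussian(19.6, 5.0, 7.2, 4.0)
    nihss_week1: GroupGaussian = GroupGaussian(13.3, 5.0, 6.8, 4.0)
    male: GroupProportion = GroupProportion(28 / 36, 114 / 151)
    hypertension: GroupProportion = GroupProportion(0.712, 0.536)
    dose_standard: GroupProportion = GroupProportion(0.583, 0.503)
    occlusion_probs_det: tuple[float, float, float] = (0.0, 6 / 36, 30 / 36)
    occlusion_probs_ctrl: tuple[float, float, float] = (22 / 151, 55 / 151, 74 / 151)
    infarct_anterior: GroupProportion = GroupProportion(21 / 36, 96 / 151)
    artery_internal_carotid: GroupProportion = GroupProportion(6 / 22, 10 / 95)
    mechanism: Literal["rule", "logistic"] = "rule"
    logistic_coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_deterioration < 0 or self.n_control < 0:
            raise ValueError("group sizes must be non-negative")
        for probs in (self.occlusion_probs_det, self.occlusion_probs_ctrl):
            arr = np.asarray(probs, dtype=float)
            if arr.size != 3 or np.any(arr < 0) or not np.isclose(arr.sum(), 1.0, atol=1e-9):
                raise ValueError("occlusion probabilities must be a 3-simplex (normal, stenosis, occlusion)")


def _draw_score(rng: np.random.Generator, mean: float, sd: float) -> int:
    return int(np.clip(round(rng.normal(mean, sd)), 0, NIHSS_MAX))


def _make_trajectory(rng: np.random.Generator, spec: CohortSpec, group: str, is_end: bool) -> NihssTrajectory:
    def pick(g: GroupGaussian) -> tuple[float, float]:
        return (g.det_mean, g.det_sd) if group == "det" else (g.ctrl_mean, g.ctrl_sd)

    baseline = _draw_score(rng, *pick(spec.nihss_baseline))
    if is_end:
        # keep the rule satisfiable: baseline + threshold must stay <= 42
        baseline = min(baseline, NIHSS_MAX - end_threshold(baseline))
    post = _draw_score(rng, *pick(spec.nihss_post))
    h4 = _draw_score(rng, *pick(spec.nihss_h4))
    h24 = _draw_score(rng, *pick(spec.nihss_h24))
    thr = end_threshold(baseline)
    if is_end:
        h24 = int(np.clip(max(h24, baseline + thr), 0, NIHSS_MAX))
    else:
        h24 = int(np.clip(min(h24, baseline + thr - 1), 0, NIHSS_MAX))
    week1 = _draw_score(rng, *pick(spec.nihss_week1))
    return NihssTrajectory(baseline=baseline, post_thrombolysis=post, h4=h4, h24=h24, week1=week1)


_OCCLUSION_LEVELS = ("normal", "stenosis", "occlusion")


def _draw_patient(rng: np.random.Generator, spec: CohortSpec, group: str, is_end: bool) -> PatientRecord:
    det = group == "det"
    age = max(18.0, rng.normal(spec.age.det_mean if det else spec.age.ctrl_mean,
                               spec.age.det_sd if det else spec.age.ctrl_sd))
    plt = max(10.0, rng.normal(spec.plt.det_mean if det else spec.plt.ctrl_mean,
                               spec.plt.det_sd if det else spec.plt.ctrl_sd))
    occ_probs = spec.occlusion_probs_det if det else spec.occlusion_probs_ctrl
    return PatientRecord(
        age=float(round(age)),
        male=bool(rng.random() < (spec.male.det if det else spec.male.ctrl)),
        hypertension=bool(rng.random() < (spec.hypertension.det if det else spec.hypertension.ctrl)),
        plt=float(round(plt)),
        dose="standard" if rng.random() < (spec.dose_standard.det if det else spec.dose_standard.ctrl) else "low",
        occlusion_status=_OCCLUSION_LEVELS[rng.choice(3, p=np.asarray(occ_probs, dtype=float))],
        infarct_site="anterior" if rng.random() < (spec.infarct_anterior.det if det else spec.infarct_anterior.ctrl) else "posterior",
        responsible_artery="internal-carotid"
        if rng.random() < (spec.artery_internal_carotid.det if det else spec.artery_internal_carotid.ctrl)
        else "middle-cerebral",
        trajectory=_make_trajectory(rng, spec, group, is_end),
        end_label=is_end,
    )


def simulate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate a deterministic synthetic cohort from the spec.

    ``rule`` mechanism: draws covariates per group and constructs
    trajectories so that the baseline-dependent rule reproduces the group
    label exactly.  ``logistic`` mechanism: draws pooled covariates,
    labels from the logistic model, then builds rule-consistent
    trajectories for the drawn labels.
    """
    rng = substream(spec.seed, "cohort")
    records: list[PatientRecord] = []
    if spec.mechanism == "rule":
        for _ in range(spec.n_deterioration):
            records.append(_draw_patient(rng, spec, "det", True))
        for _ in range(spec.n_control):
            records.append(_draw_patient(rng, spec, "ctrl", False))
        return records
    if spec.mechanism != "logistic":
        raise ValueError(f"unknown mechanism {spec.mechanism!r}")
    coeffs = dict(spec.logistic_coefficients)
    b0 = coeffs.pop("intercept", 0.0)
    n_total = spec.n_deterioration + spec.n_control
    for _ in range(n_total):
        draft = _draw_patient(rng, spec, "ctrl", False)
        eta = b0 + sum(b * COVARIATE_EXTRACTORS[name](draft) for name, b in coeffs.items())
        p = 1.0 / (1.0 + np.exp(-eta))
        is_end = bool(rng.random() < p)
        # keep the covariates that generated the label; only the 24-hour
        # score moves, so the fitted model sees the generative design
        traj = draft.trajectory
        baseline = min(traj.baseline, NIHSS_MAX - end_threshold(traj.baseline)) if is_end else traj.baseline
        thr = end_threshold(baseline)
        if is_end:
            h24 = int(np.clip(max(traj.h24, baseline + thr), 0, NIHSS_MAX))
        else:
            h24 = int(np.clip(min(traj.h24, baseline + thr - 1), 0, NIHSS_MAX))
        traj = NihssTrajectory(baseline=baseline, post_thrombolysis=traj.post_thrombolysis,
                               h4=traj.h4, h24=h24, week1=traj.week1)
        records.append(replace(draft, trajectory=traj, end_label=is_end))
    return records


def cohort_to_dataframe(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort to one row per patient (documented column dictionary)."""
    rows = []
    for r in records:
        rows.append(
            {
                "age": r.age,
                "male": int(r.male),
                "hypertension": int(r.hypertension),
                "plt": r.plt,
                "dose": r.dose,
                "occlusion_status": r.occlusion_status,
                "infarct_site": r.infarct_site,
                "responsible_artery": r.responsible_artery,
                "nihss_baseline": r.trajectory.baseline,
                "nihss_post": r.trajectory.post_thrombolysis,
                "nihss_h4": r.trajectory.h4,
                "nihss_h24": r.trajectory.h24,
                "nihss_week1": r.trajectory.week1,
                "end_label": "" if r.end_label is None else int(r.end_label),
            }
        )
    return pd.DataFrame(rows)


def dataframe_to_cohort(df: pd.DataFrame) -> list[PatientRecord]:
    """Inverse of :func:`cohort_to_dataframe`."""
    records = []
    for _, row in df.iterrows():
        label = row.get("end_label", "")
        records.append(
            PatientRecord(
                age=float(row["age"]),
                male=bool(int(row["male"])),
                hypertension=bool(int(row["hypertension"])),
                plt=float(row["plt"]),
                dose=str(row["dose"]),
                occlusion_status=str(row["occlusion_status"]),
                infarct_site=str(row["infarct_site"]),
                responsible_artery=str(row["responsible_artery"]),
                trajectory=NihssTrajectory(
                    baseline=int(row["nihss_baseline"]),
                    post_thrombolysis=int(row["nihss_post"]),
                    h4=int(row["nihss_h4"]),
                    h24=int(row["nihss_h24"]),
                    week1=int(row["nihss_week1"]),
                ),
                end_label=None if label in ("", None) or (isinstance(label, float) and np.isnan(label)) else bool(int(label)),
            )
        )
    return records


# --------------------------------------------------------------------------
# worked example: packaged printed counts
# --------------------------------------------------------------------------

#: Count-backed percentages from the packaged study summary.  ``decimals``
#: is the precision at which the source printed the percentage;
#: ``count_derived`` marks counts reconstructed from a printed percentage.
WORKED_EXAMPLE_COUNTS: tuple[dict, ...] = (
    {"group": "deterioration", "variable": "end_incidence", "count": 36, "total": 196, "printed": 18.36, "decimals": 2},
    {"group": "control", "variable": "group_share", "count": 151, "total": 196, "printed": 77.04, "decimals": 2},
    {"group": "deterioration", "variable": "male", "count": 28, "total": 36, "printed": 77.78, "decimals": 2},
    {"group": "deterioration", "variable": "female", "count": 8, "total": 36, "printed": 22.22, "decimals": 2},
    {"group": "control", "variable": "male", "count": 114, "total": 151, "printed": 75.5, "decimals": 1},
    {"group": "control", "variable": "female", "count": 37, "total": 151, "printed": 24.5, "decimals": 1},
    {"group": "deterioration", "variable": "dose_standard", "count": 21, "total": 36, "printed": 58.3, "decimals": 1},
    {"group": "deterioration", "variable": "dose_low", "count": 15, "total": 36, "printed": 41.7, "decimals": 1},
    {"group": "control", "variable": "dose_standard", "count": 76, "total": 151, "printed": 50.3, "decimals": 1, "count_derived": True},
    {"group": "deterioration", "variable": "infarct_anterior", "count": 21, "total": 36, "printed": 58.3, "decimals": 1},
    {"group": "deterioration", "variable": "infarct_posterior", "count": 15, "total": 36, "printed": 41.7, "decimals": 1},
    {"group": "control", "variable": "infarct_anterior", "count": 96, "total": 151, "printed": 63.6, "decimals": 1},
    {"group": "control", "variable": "infarct_posterior", "count": 55, "total": 151, "printed": 36.4, "decimals": 1},
    {"group": "deterioration", "variable": "artery_internal_carotid", "count": 6, "total": 36, "printed": 16.7, "decimals": 1},
    {"group": "control", "variable": "artery_internal_carotid", "count": 10, "total": 151, "printed": 6.62, "decimals": 2},
    {"group": "deterioration", "variable": "artery_middle_cerebral", "count": 16, "total": 36, "printed": 44.4, "decimals": 1},
    {"group": "control", "variable": "artery_middle_cerebral", "count": 85, "total": 151, "printed": 56.3, "decimals": 1},
    {"group": "deterioration", "variable": "occlusion", "count": 30, "total": 36, "printed": 83.33, "decimals": 2},
    {"group": "control", "variable": "occlusion", "count": 74, "total": 151, "printed": 49.0, "decimals": 0},
    {"group": "deterioration", "variable": "stenosis", "count": 6, "total": 36, "printed": 16.67, "decimals": 2},
    {"group": "control", "variable": "stenosis", "count": 55, "total": 151, "printed": 36.4, "decimals": 1},
)

#: 2x2 tables assembled from the printed counts (exposure x END status).
WORKED_EXAMPLE_TABLES = {
    "occlusion": ContingencyTable2x2(a=30, b=6, c=74, d=77),
    "internal_carotid": ContingencyTable2x2(a=6, b=30, c=10, d=141),
}

#: Summary figures that cannot be reconciled with integer counts; carried
#: verbatim and flagged instead of silently corrected.
WORKED_EXAMPLE_INCONSISTENCIES = (
    {"item": "enrollment", "detail": "stated enrolment 187 conflicts with the 196 implied by 36/18.36% and 151/77.04%"},
    {"item": "hypertension", "detail": "printed 71.2% / 53.6% do not correspond to integer counts over 36 and 151"},
    {"item": "reported_or_ci", "detail": "reported NIHSS 95% CI 1.023-1.254 does not contain its OR 1.301"},
)


def worked_example_report(ci_level: float = 0.95) -> dict:
    """Recompute every packaged count-backed percentage and table statistic.

    Each entry carries the printed value, the recomputed percentage at
    two decimals and at the printed precision, and a consistency flag
    (|recomputed - printed| <= 0.05 after rounding to the printed
    precision).  Tables get cross-product odds ratios and chi-square
    statistics.  Known irreconcilable figures are listed, not corrected.
    """
    entries = []
    for item in WORKED_EXAMPLE_COUNTS:
        computed = proportion(item["count"], item["total"], decimals=2)
        at_printed = proportion(item["count"], item["total"], decimals=item["decimals"])
        entries.append(
            {
                **{k: item[k] for k in ("group", "variable", "count", "total", "printed", "decimals")},
                "count_derived": bool(item.get("count_derived", False)),
                "computed": computed,
                "computed_at_printed_precision": at_printed,
                "consistent": abs(at_printed - item["printed"]) <= 0.05,
            }
        )
    tables = {}
    for name, table in WORKED_EXAMPLE_TABLES.items():
        tables[name] = {
            "counts": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
            "odds_ratio": odds_ratio(table, ci_level=ci_level),
            "chi_square": chi_square_test(table),
        }
    return {
        "entries": entries,
        "tables": tables,
        "inconsistencies": [dict(x) for x in WORKED_EXAMPLE_INCONSISTENCIES],
    }


def worked_example_markdown(report: dict | None = None) -> str:
    """Render the worked-example report as a Markdown table."""
    report = report or worked_example_report()
    lines = [
        "| group | variable | count | total | printed % | recomputed % | consistent |",
        "|---|---|---|---|---|---|---|",
    ]
    for e in report["entries"]:
        lines.append(
            f"| {e['group']} | {e['variable']} | {e['count']} | {e['total']} | "
            f"{e['printed']} | {e['computed_at_printed_precision']} | {'yes' if e['consistent'] else 'NO'} |"
        )
    lines.append("")
    for name, t in report["tables"].items():
        o = t["odds_ratio"]
        c = t["chi_square"]
        lines.append(
            f"- {name}: OR {o['or']:.3f} (CI {o['ci_low']:.3f}-{o['ci_high']:.3f}), "
            f"chi2 {c['statistic']:.3f}, p {c['p']:.3g}"
        )
    for item in report["inconsistencies"]:
        lines.append(f"- flagged: {item['item']}: {item['detail']}")
    return "\n".join(lines)
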