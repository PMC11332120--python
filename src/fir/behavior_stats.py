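"""Descriptive statistics, mixed-model contrasts, decay fits, model evaluation.

The behavioural analyses operate on coded trial tables:

* descriptive percentages per cell (phase x perceiver class x stimulus);
* classification of participants into fusion vs auditory perceivers from their
  audiovisual exposure fusion fraction;
* binomial generalized linear mixed models on fusion vs non-fusion counts with
  time and perceiver class as fixed effects and participant (plus stimulus, when
  several) random intercepts, summarized by Type-II analysis-of-deviance Wald
  chi-squares and post-hoc pre/post odds ratios whose confidence intervals are
  computed on the log-odds scale and back-transformed;
* nonlinear least-squares fits of the long-term fusion time course,
  fusion = a * exp(b * t) with t in months since the final exposure, tested
  against an intercept-only model by residual F comparison;
* model evaluation: Pearson correlation between the model's predicted %FIR and
  each participant's observed %FIR, with a Fisher r-to-z confidence interval and
  standard errors for the model (binomial sampling at the mean fit) and the
  participants (pooled variance) at each day-1 McGurk count level.

The GLMM is delegated to lme4/car/emmeans through an Rscript subprocess — the
standard mixed-model toolchain for this design; everything else is
numpy/scipy/pandas.
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .dataset_io import CATEGORIES

__all__ = [
    "ContrastResult",
    "GlmmFit",
    "DecayFit",
    "ModelFitSummary",
    "descriptives",
    "classify_perceivers",
    "fusion_counts_prepost",
    "fit_fusion_glmm",
    "odds_ratio_2x2",
    "fit_decay",
    "group_trajectories",
    "evaluate_model",
    "pearson_ci_fisher",
]


class GlmmError(RuntimeError):
    """The mixed-model backend failed to fit (non-convergence or R error)."""


@dataclass(frozen=True)
class ContrastResult:
    name: str
    chi_square: float
    df: int
    p_value: float
    odds_ratio: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if np.isfinite([lo, hi, self.odds_ratio]).all() and not (
            lo <= self.odds_ratio <= hi
        ):
            raise ValueError("odds ratio must lie inside its CI")


@dataclass(frozen=True)
class GlmmFit:
    effects: dict[str, ContrastResult]
    posthoc: dict[str, ContrastResult]
    singular: bool
    converged: bool


@dataclass(frozen=True)
class DecayFit:
    a: float  # initial %fusion at t = 0
    b: float  # per-month log rate (decaying if b < 0)
    monthly_decay_pct: float  # 100 * (1 - e^b)
    model_comparison_p: float
    rss: float
    n: int
    flag: str | None = None


@dataclass(frozen=True)
class ModelFitSummary:
    pearson_r: float
    n: int
    ci95: tuple[float, float]
    p_value: float
    model_sem: dict[float, float]
    participant_sem: dict[float, float]
    flag: str | None = None


# ---------------------------------------------------------------------------
# descriptives and perceiver classes


def descriptives(
    trials: pd.DataFrame, group_by: Sequence[str] = ("phase", "stimulus_id")
) -> pd.DataFrame:
    """Percentage of each response category per cell, with raw counts.

    Long format: one row per (cell x category actually observed).  Empty cells do
    not appear (missing, not zero); percentages always derive from integer counts
    and are invariant to trial order.
    """
    if trials["coded_category"].isna().any() or (trials["coded_category"] == "").any():
        raise ValueError("descriptives needs fully coded trials")
    counts = (
        trials.groupby([*group_by, "coded_category"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    totals = counts.groupby(list(group_by))["count"].transform("sum")
    counts["total"] = totals
    counts["pct"] = 100.0 * counts["count"] / totals
    return counts


def classify_perceivers(
    trials: pd.DataFrame,
    stimulus_id: str,
    threshold: float = 0.5,
) -> pd.DataFrame:
    """Fusion vs auditory perceiver per participant, for one McGurk stimulus.

    A participant is a fusion perceiver iff their exposure-phase fusion fraction
    for the stimulus is >= threshold.  Participants with no exposure trials of the
    stimulus are labelled unclassified.
    """
    out = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        expo = sub[(sub["phase"] == "exposure") & (sub["stimulus_id"] == stimulus_id)]
        if expo.empty:
            out.append((pid, np.nan, "unclassified"))
            continue
        frac = float((expo["coded_category"] == "Fusion").mean())
        cls = "fusion_perceiver" if frac >= threshold else "auditory_perceiver"
        out.append((pid, frac, cls))
    return pd.DataFrame(
        out, columns=["participant_id", "exposure_fusion_fraction", "perceiver_class"]
    )


def fusion_counts_prepost(
    trials: pd.DataFrame,
    aud_stimulus_id: str,
    classes: pd.DataFrame,
) -> pd.DataFrame:
    """Binomial pre/post fusion counts for the GLMM, one row per participant x time.

    Counts fusion vs non-fusion responses to one auditory-only stimulus in the
    pre-test and the 24-h post-test, joined with perceiver classes.
    """
    sub = trials[
        trials["stimulus_id"].eq(aud_stimulus_id)
        & trials["phase"].isin(["pretest", "posttest_24h"])
    ].copy()
    sub["time"] = np.where(sub["phase"] == "pretest", "pre", "post")
    grp = sub.groupby(["participant_id", "time"])
    counts = grp["coded_category"].agg(
        fusion=lambda s: int((s == "Fusion").sum()), total="size"
    )
    counts = counts.reset_index().rename(columns={"participant_id": "participant"})
    cls = classes.rename(
        columns={"participant_id": "participant", "perceiver_class": "cls"}
    )[["participant", "cls"]]
    return counts.merge(cls, on="participant", how="inner")


# ---------------------------------------------------------------------------
# mixed model (R backend)


def _run_glmm_backend(counts: pd.DataFrame, posthoc: bool) -> dict:
    with tempfile.TemporaryDirectory() as tmp:
        in_csv = Path(tmp) / "counts.csv"
        out_json = Path(tmp) / "fit.json"
        counts.to_csv(in_csv, index=False)
        rscript = resources.files("fir").joinpath("glmm.R")
        with resources.as_file(rscript) as rpath:
            proc = subprocess.run(
                ["Rscript", "--vanilla", str(rpath), str(in_csv), str(out_json), "1" if posthoc else "0"],
                capture_output=True,
                text=True,
            )
        if proc.returncode != 0 or not out_json.exists():
            raise GlmmError(f"R GLMM backend failed:\n{proc.stderr[-2000:]}")
        return json.loads(out_json.read_text())


def _wald_or(coef: float, se: float) -> tuple[float, tuple[float, float]]:
    half = 1.959963984540054 * se
    with np.errstate(over="ignore"):
        return float(np.exp(coef)), (float(np.exp(coef - half)), float(np.exp(coef + half)))


def _parse_fit(payload: dict) -> GlmmFit:
    if "error" in payload:
        raise GlmmError(f"GLMM did not converge: {payload['error']}")
    names = list(payload["coef_names"])
    coef = np.asarray(payload["coef"], dtype=float)
    vcov = np.asarray(payload["vcov"], dtype=float)
    se = np.sqrt(np.diag(vcov))

    def coef_for(term: str) -> int | None:
        if term == "time:cls":
            hits = [i for i, n in enumerate(names) if ":" in n]
        else:
            hits = [i for i, n in enumerate(names) if n.startswith(term) and ":" not in n]
        return hits[0] if len(hits) == 1 else None

    effects: dict[str, ContrastResult] = {}
    for row in payload["anova"]:  # records orientation (one dict per term)
        term = row["term"]
        i = coef_for(term)
        if i is not None:
            odds, ci = _wald_or(coef[i], se[i])
        else:  # pragma: no cover - multi-df terms have no single OR
            odds, ci = np.nan, (np.nan, np.nan)
        key = "interaction" if ":" in term else term
        effects[key] = ContrastResult(
            key, float(row["chisq"]), int(row["df"]), float(row["p"]), odds, ci
        )

    posthoc: dict[str, ContrastResult] = {}

    def num(row: dict, key: str, default: float) -> float:
        v = row.get(key)
        return default if v is None else float(v)

    for row in payload.get("posthoc", []):
        # a degenerate (separated) cell can make a CI bound non-finite
        posthoc[str(row["cls"])] = ContrastResult(
            f"post/pre | {row['cls']}",
            num(row, "z", np.nan) ** 2,
            1,
            num(row, "p", np.nan),
            num(row, "odds_ratio", np.nan),
            (num(row, "ci_low", 0.0), num(row, "ci_high", np.inf)),
        )
    return GlmmFit(
        effects=effects,
        posthoc=posthoc,
        singular=bool(payload["singular"]),
        converged=bool(payload["converged"]),
    )


def fit_fusion_glmm(
    counts: pd.DataFrame,
    posthoc: bool = True,
    replicate_col: str | None = None,
) -> GlmmFit | dict[str, GlmmFit | GlmmError]:
    """Binomial GLMM of fusion counts: time x perceiver class, participant random.

    ``counts`` needs columns participant, cls, time ("pre"/"post"), fusion, total
    (and optionally stimulus, which adds a stimulus random intercept; a singular
    fit falls back to the participant-only random structure).  Returns the Type-II
    analysis-of-deviance chi-squares for the main effects and interaction and, if
    ``posthoc``, per-class pre/post odds ratios with back-transformed log-odds CIs.

    With ``replicate_col`` the model is fit independently per replicate in a
    single backend call (used for calibration studies); the result is a dict keyed
    by replicate, with :class:`GlmmError` values for replicates that failed.
    """
    required = {"participant", "cls", "time", "fusion", "total"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing column(s): {sorted(missing)}")
    if (counts["fusion"] > counts["total"]).any() or (counts["fusion"] < 0).any():
        raise ValueError("fusion counts must satisfy 0 <= fusion <= total")
    work = counts.copy()
    if replicate_col is None:
        work["replicate"] = "fit"
    else:
        work = work.rename(columns={replicate_col: "replicate"})
    payload = _run_glmm_backend(work, posthoc)
    results: dict[str, GlmmFit | GlmmError] = {}
    for rep, rep_payload in payload.items():
        try:
            results[rep] = _parse_fit(rep_payload)
        except GlmmError as err:
            if replicate_col is None:
                raise
            results[rep] = err
    if replicate_col is None:
        return results["fit"]
    return results


def odds_ratio_2x2(
    fusion_a: int,
    total_a: int,
    fusion_b: int,
    total_b: int,
    continuity: float = 0.5,
) -> float:
    """Cross-product odds ratio of two binomial samples (group a vs group b).

    When any cell of the implied 2x2 table is zero, ``continuity`` is added to all
    four cells (set it to 0 to disable, yielding 0/inf/nan for degenerate tables).
    """
    if min(fusion_a, fusion_b) < 0 or fusion_a > total_a or fusion_b > total_b:
        raise ValueError("counts must satisfy 0 <= fusion <= total")
    if min(total_a, total_b) <= 0:
        raise ValueError("totals must be positive")
    cells = np.array(
        [fusion_a, total_a - fusion_a, fusion_b, total_b - fusion_b], dtype=float
    )
    if np.any(cells == 0) and continuity:
        cells = cells + continuity
    fa, na, fb, nb = cells
    with np.errstate(divide="ignore", invalid="ignore"):
        return float((fa / na) / (fb / nb))


# ---------------------------------------------------------------------------
# long-term decay


def fit_decay(
    months: Sequence[float],
    fusion_pct: Sequence[float],
    enforce_decay: bool = False,
) -> DecayFit:
    """Nonlinear least squares of fusion = a * exp(b * t), t in months.

    Significance is the residual F comparison against the intercept-only model
    (no change over time).  ``enforce_decay`` constrains b <= 0.  An all-zero
    series is flagged (a = 0, b undefined).
    """
    t = np.asarray(months, dtype=float)
    y = np.asarray(fusion_pct, dtype=float)
    if t.shape != y.shape or t.size < 3:
        raise ValueError("need >= 3 (months, fusion) points")
    if np.all(y == 0):
        return DecayFit(0.0, np.nan, np.nan, 1.0, 0.0, int(t.size), flag="all_zero")
    # start from a log-linear fit where possible
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (float(np.exp(intercept)), float(slope))
    else:
        p0 = (float(max(y.max(), 1e-6)), -0.1)
    if enforce_decay:
        bounds = ([0.0, -np.inf], [np.inf, 0.0])
        p0 = (max(p0[0], 1e-9), min(p0[1], 0.0))
    else:
        bounds = (-np.inf, np.inf)
    import warnings as _warnings
    from scipy.optimize import OptimizeWarning

    with _warnings.catch_warnings():
        # constant series leave the parameter covariance unestimable; we only
        # use the point estimates and our own residual F comparison
        _warnings.simplefilter("ignore", OptimizeWarning)
        popt, _ = curve_fit(
            lambda tt, a, b: a * np.exp(b * tt), t, y, p0=p0, bounds=bounds, maxfev=20_000
        )
    a, b = (float(v) for v in popt)
    rss1 = float(np.sum((y - a * np.exp(b * t)) ** 2))
    rss0 = float(np.sum((y - y.mean()) ** 2))
    n = int(t.size)
    if rss0 - rss1 <= 1e-12:
        p = 1.0
    elif rss1 <= 1e-12:
        p = 0.0
    else:
        f_stat = (rss0 - rss1) / (rss1 / (n - 2))
        p = float(stats.f.sf(f_stat, 1, n - 2))
    return DecayFit(a, b, 100.0 * (1.0 - np.exp(b)), p, rss1, n)


def group_trajectories(
    series: pd.DataFrame,
    low_threshold: float = 10.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Assign each participant's long-term %FIR series to a trajectory class.

    ``series`` is long-format: participant_id, months (0 = 24-h post-test),
    fir_pct.  Rules (thresholds configurable, reported in the output):
    absent if the 24-h value is below ``low_threshold``; otherwise decaying if the
    per-participant exponential fit has b significantly < 0 or the final value
    falls below the threshold; otherwise persistent.  Series with fewer than two
    points are unclassifiable.
    """
    rows = []
    for pid, sub in series.groupby("participant_id", sort=True):
        sub = sub.sort_values("months")
        t = sub["months"].to_numpy(dtype=float)
        y = sub["fir_pct"].to_numpy(dtype=float)
        b = np.nan
        p = np.nan
        if t.size < 2:
            cls = "unclassifiable"
        elif y[0] < low_threshold:
            cls = "absent"
        else:
            if t.size >= 3:
                fit = fit_decay(t, y)
                b, p = fit.b, fit.model_comparison_p
                significant_decay = (not np.isnan(b)) and b < 0 and p < alpha
            else:
                significant_decay = False
            cls = (
                "decaying"
                if significant_decay or y[-1] < low_threshold
                else "persistent"
            )
        rows.append((pid, cls, y[0] if t.size else np.nan, y[-1] if t.size else np.nan, b, p))
    out = pd.DataFrame(
        rows,
        columns=["participant_id", "trajectory", "fir_24h", "fir_final", "decay_b", "decay_p"],
    )
    out.attrs["low_threshold"] = low_threshold
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# model evaluation


def pearson_ci_fisher(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher r-to-z confidence interval, back-transformed to the r scale."""
    if n <= 3:
        return (-1.0, 1.0)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def evaluate_model(
    predicted_fir: Sequence[float],
    observed_fir: Sequence[float],
    day1_counts: Sequence[int] | None = None,
    n_posttest_trials: int = 5,
    rng: np.random.Generator | None = None,
    n_sim: int = 10_000,
) -> ModelFitSummary:
    """Correlate model-predicted with observed per-participant %FIR.

    Returns the Pearson r with a Fisher r-to-z 95% CI, plus per-level standard
    errors for visualization when ``day1_counts`` (the day-1 McGurk count of each
    participant) is given: the model SEM at a level is the SD of simulated
    binomial data at the level's mean predicted rate over ``n_posttest_trials``
    trials (the mean fit itself assumes thousands of trials), and the participant
    SEM is the square root of the pooled across-level FIR variance divided by the
    square root of the number of participants at the level.  Zero variance in
    either vector leaves r undefined (flagged) rather than raising.
    """
    pred = np.asarray(predicted_fir, dtype=float)
    obs = np.asarray(observed_fir, dtype=float)
    keep = ~(np.isnan(pred) | np.isnan(obs))
    pred, obs = pred[keep], obs[keep]
    n = int(pred.size)
    if n < 3:
        raise ValueError("need >= 3 participants with predicted and observed values")
    if np.std(pred) == 0 or np.std(obs) == 0:
        return ModelFitSummary(np.nan, n, (np.nan, np.nan), np.nan, {}, {}, flag="undefined_r")
    r, p = stats.pearsonr(pred, obs)
    ci = pearson_ci_fisher(float(r), n)

    model_sem: dict[float, float] = {}
    participant_sem: dict[float, float] = {}
    if day1_counts is not None:
        levels = np.asarray(day1_counts)[keep]
        if rng is None:
            rng = np.random.default_rng(0)
        # pooled FIR variance across levels, weighted by participants per level
        per_level = {}
        for lev in np.unique(levels):
            vals = obs[levels == lev]
            per_level[float(lev)] = vals
        num = sum(max(len(v) - 1, 0) * np.var(v, ddof=1) if len(v) > 1 else 0.0 for v in per_level.values())
        den = sum(max(len(v) - 1, 0) for v in per_level.values())
        pooled_var = num / den if den > 0 else 0.0
        for lev, vals in per_level.items():
            mean_fit = float(np.mean(pred[levels == lev])) / 100.0
            mean_fit = min(max(mean_fit, 0.0), 1.0)
            draws = rng.binomial(n_posttest_trials, mean_fit, size=n_sim) / n_posttest_trials
            model_sem[lev] = float(np.std(draws, ddof=1) * 100.0)
            participant_sem[lev] = float(np.sqrt(pooled_var) / np.sqrt(len(vals)))
    return ModelFitSummary(float(r), n, ci, float(p), model_sem, participant_sem)
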