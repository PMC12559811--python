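"""Replicate aggregation, treatment contrasts and from-scratch inference.

Covers the statistical layer of the pipeline:

* per-cell means ± SD of the life-history metrics, including the
  unweighted "Mean F_k" rows that average the fed and starved cells;
* signed percent-change contrasts (each UVB level vs. the same-generation
  control, and F5 vs. F1 within treatment);
* a two-way ANOVA (sequential sums of squares) on exposure-survival
  proportions with a Tukey HSD post hoc;
* Kaplan–Meier product-limit curves and the log-rank test, written from
  first principles (reference implementations are used only as test
  oracles);
* percentile bootstrap confidence intervals resampling founding females;
* pigmentation-level classification from %red digital number.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .demography import (
    FEEDINGS,
    GENERATIONS,
    TREATMENTS,
    FounderRecord,
    LifetableResult,
    UndefinedParameterError,
    census_from_founders,
    lifetable,
)
from .io import ExposureOutcome

logger = logging.getLogger("uvbdemog")

METRICS = ("lifespan", "R0", "T", "r")


class UndefinedContrastError(ValueError):
    """Percent change against a zero baseline is undefined."""


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def _metric_value(res: LifetableResult, metric: str) -> float | None:
    if metric == "lifespan":
        return res.mean_lifespan
    if metric == "R0":
        return res.R0
    if metric == "T":
        return res.T
    if metric == "r":
        return res.r_approx
    raise KeyError(metric)


def results_frame(results: list[LifetableResult]) -> pd.DataFrame:
    """One row per cohort with its metadata and the four metrics."""
    return pd.DataFrame(
        {
            "cohort_id": r.cohort_id,
            "generation": r.generation,
            "treatment": r.treatment,
            "feeding": r.feeding,
            "replicate_id": r.replicate_id,
            "lifespan": r.mean_lifespan,
            "R0": r.R0,
            "T": np.nan if r.T is None else r.T,
            "r": np.nan if r.r_approx is None else r.r_approx,
            "r_exact": np.nan if r.r_exact is None else r.r_exact,
        }
        for r in results
    )


def aggregate_cells(results: list[LifetableResult]) -> pd.DataFrame:
    """Per design cell: mean and sample SD (ddof=1) of each metric.

    Returns a tidy frame with columns metric, generation, treatment,
    feeding, mean, sd, n.  ``feeding == "mean"`` rows hold the unweighted
    average of the fed and starved cell means for that generation ×
    treatment, with the SD recomputed across those two cell means
    (descriptive only).  Cohorts whose T or r is undefined (R0 == 0) are
    excluded from the T and r cells.  Empty cells are absent from the
    frame (rendered ND downstream), never zero.
    """
    df = results_frame(results)
    rows: list[dict] = []
    for metric in METRICS:
        for (gen, trt), grp in df.groupby(["generation", "treatment"]):
            cell_means: dict[str, float] = {}
            for feeding in FEEDINGS:
                vals = grp.loc[grp["feeding"] == feeding, metric].dropna()
                if len(vals) == 0:
                    continue
                cell_means[feeding] = float(vals.mean())
                rows.append(
                    {
                        "metric": metric,
                        "generation": gen,
                        "treatment": trt,
                        "feeding": feeding,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                        "n": int(len(vals)),
                    }
                )
            if len(cell_means) == len(FEEDINGS):
                pair = np.array([cell_means[f] for f in FEEDINGS])
                rows.append(
                    {
                        "metric": metric,
                        "generation": gen,
                        "treatment": trt,
                        "feeding": "mean",
                        "mean": float(pair.mean()),
                        "sd": float(pair.std(ddof=1)),
                        "n": 2,
                    }
                )
    out = pd.DataFrame(rows)
    order = {t: i for i, t in enumerate(TREATMENTS)}
    return out.sort_values(
        ["metric", "generation", "feeding", "treatment"],
        key=lambda s: s.map(order) if s.name == "treatment" else s,
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

def percent_change(focal_mean: float, baseline_mean: float) -> float:
    """Signed percent change, 100 · (focal − baseline) / baseline."""
    if baseline_mean == 0:
        raise UndefinedContrastError("baseline mean is zero")
    return 100.0 * (focal_mean - baseline_mean) / baseline_mean


@dataclass(frozen=True)
class ContrastResult:
    """Percent change of one metric between a focal and a baseline cell."""

    family: str  # "vs_control" or "F5_vs_F1"
    metric: str
    generation: str  # focal generation
    treatment: str  # focal treatment
    scope: str  # "fed" | "starved" | "mean"
    focal_mean: float
    baseline_mean: float
    percent_change: float
    n_focal: int
    n_baseline: int
    ci_low: float | None = None
    ci_high: float | None = None


def run_contrasts(cells: pd.DataFrame, scope: str = "mean") -> list[ContrastResult]:
    """Both contrast families for every metric at the given feeding scope.

    (i) each UVB treatment vs. the same-generation control;
    (ii) F5 vs. F1 within each treatment (control included).
    Missing baseline or focal cells are skipped with a logged warning.
    """
    if scope not in FEEDINGS + ("mean",):
        raise ValueError(f"unknown scope {scope!r}")
    sub = cells[cells["feeding"] == scope]
    lookup = {
        (r.metric, r.generation, r.treatment): (r.mean, r.n) for r in sub.itertuples()
    }
    out: list[ContrastResult] = []
    for metric in METRICS:
        for gen in GENERATIONS:
            base = lookup.get((metric, gen, "control"))
            for trt in TREATMENTS[1:]:
                focal = lookup.get((metric, gen, trt))
                if base is None or focal is None:
                    logger.warning(
                        "contrast skipped (missing cell): %s %s %s vs control",
                        metric, gen, trt,
                    )
                    continue
                out.append(
                    ContrastResult(
                        family="vs_control",
                        metric=metric,
                        generation=gen,
                        treatment=trt,
                        scope=scope,
                        focal_mean=focal[0],
                        baseline_mean=base[0],
                        percent_change=percent_change(focal[0], base[0]),
                        n_focal=focal[1],
                        n_baseline=base[1],
                    )
                )
        for trt in TREATMENTS:
            f1 = lookup.get((metric, "F1", trt))
            f5 = lookup.get((metric, "F5", trt))
            if f1 is None or f5 is None:
                logger.warning(
                    "contrast skipped (missing cell): %s F5 vs F1 %s", metric, trt
                )
                continue
            out.append(
                ContrastResult(
                    family="F5_vs_F1",
                    metric=metric,
                    generation="F5",
                    treatment=trt,
                    scope=scope,
                    focal_mean=f5[0],
                    baseline_mean=f1[0],
                    percent_change=percent_change(f5[0], f1[0]),
                    n_focal=f5[1],
                    n_baseline=f1[1],
                )
            )
    return out


def contrasts_frame(contrasts: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "family": c.family,
            "metric": c.metric,
            "generation": c.generation,
            "treatment": c.treatment,
            "scope": c.scope,
            "focal_mean": c.focal_mean,
            "baseline_mean": c.baseline_mean,
            "percent_change": c.percent_change,
            "n_focal": c.n_focal,
            "n_baseline": c.n_baseline,
        }
        for c in contrasts
    )


# ---------------------------------------------------------------------------
# two-way ANOVA and Tukey HSD
# ---------------------------------------------------------------------------

def _dummies(labels: np.ndarray) -> np.ndarray:
    """Full-rank treatment-coded dummies (first level dropped)."""
    levels = sorted(set(labels))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(
    outcomes: list[ExposureOutcome],
    *,
    arcsine: bool = False,
) -> pd.DataFrame:
    """Two-way ANOVA of survival proportions on UVB intensity × generation.

    The response is the proportion alive per replicate dish
    (``n_alive / n_exposed``); ``arcsine=True`` applies the arcsine-square-
    root variance-stabilising transform first.  Sums of squares are
    sequential (Type I), which coincides with Type III for the balanced
    design used in the study.

    Returns a frame with rows "UVB intensity", "Generation",
    "UVB intensity:Generation", "Residuals" and columns df, sum_sq,
    mean_sq, F, p.  With zero residual variance, F is reported as NaN and
    the ``degenerate`` attribute flag is set.
    """
    if not outcomes:
        raise ValueError("no outcomes")
    y = np.array([o.proportion_alive for o in outcomes])
    if arcsine:
        y = np.arcsin(np.sqrt(y))
    a_lab = np.array([o.treatment for o in outcomes])
    b_lab = np.array([o.generation for o in outcomes])
    a, b = len(set(a_lab)), len(set(b_lab))
    n = len(y)
    cells = {(ta, tb) for ta, tb in zip(a_lab, b_lab)}
    if len(cells) < a * b:
        raise ValueError("every UVB x generation cell needs at least one replicate")
    df_res = n - a * b
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    ones = np.ones((n, 1))
    A = _dummies(a_lab)
    B = _dummies(b_lab)
    AB = np.column_stack([A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])])
    rss0 = _rss(y, ones)
    rss_a = _rss(y, np.hstack([ones, A]))
    rss_ab = _rss(y, np.hstack([ones, A, B]))
    rss_full = _rss(y, np.hstack([ones, A, B, AB]))

    rows = {
        "UVB intensity": (a - 1, rss0 - rss_a),
        "Generation": (b - 1, rss_a - rss_ab),
        "UVB intensity:Generation": ((a - 1) * (b - 1), rss_ab - rss_full),
        "Residuals": (df_res, rss_full),
    }
    ms_res = rss_full / df_res
    table = []
    # rss of an exact fit carries lstsq rounding noise (~1e-30)
    degenerate = ms_res <= 1e-20
    for name, (df, ss) in rows.items():
        ms = ss / df
        if name == "Residuals":
            f = p = np.nan
        elif degenerate:
            f = p = np.nan
        else:
            f = ms / ms_res
            p = float(sps.f.sf(f, df, df_res))
        table.append(
            {"term": name, "df": df, "sum_sq": ss, "mean_sq": ms, "F": f, "p": p}
        )
    out = pd.DataFrame(table).set_index("term")
    out.attrs["degenerate"] = bool(degenerate)
    out.attrs["total_ss"] = rss0
    return out


def tukey_hsd(
    outcomes: list[ExposureOutcome],
    *,
    by: str = "cell",
    arcsine: bool = False,
) -> pd.DataFrame:
    """Tukey honest-significant-difference pairwise comparisons.

    ``by`` selects the grouping: ``"cell"`` (treatment × generation, the
    default), ``"treatment"`` or ``"generation"``.  Uses the residual mean
    square and df from the full two-way ANOVA and the studentized-range
    distribution; supports unequal group sizes via the Tukey–Kramer
    standard error.
    """
    anova = two_way_anova(outcomes, arcsine=arcsine)
    ms_res = float(anova.loc["Residuals", "mean_sq"])
    df_res = int(anova.loc["Residuals", "df"])
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")

    def key(o: ExposureOutcome) -> str:
        if by == "cell":
            return f"{o.generation}:{o.treatment}"
        if by == "treatment":
            return o.treatment
        if by == "generation":
            return o.generation
        raise ValueError(f"unknown grouping {by!r}")

    groups: dict[str, list[float]] = {}
    for o in outcomes:
        y = o.proportion_alive
        if arcsine:
            y = float(np.arcsin(np.sqrt(y)))
        groups.setdefault(key(o), []).append(y)
    names = sorted(groups)
    k = len(names)
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        y1, y2 = np.array(groups[g1]), np.array(groups[g2])
        diff = float(y1.mean() - y2.mean())
        se = np.sqrt(ms_res / 2.0 * (1.0 / len(y1) + 1.0 / len(y2)))
        if se == 0:
            q = np.inf if diff else 0.0
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df_res)) if np.isfinite(q) else 0.0
        rows.append({"group1": g1, "group2": g2, "diff": diff, "q": q, "p": min(p, 1.0)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# survival curves
# ---------------------------------------------------------------------------

def kaplan_meier(
    durations: np.ndarray, event_observed: np.ndarray | None = None
) -> pd.DataFrame:
    """Kaplan–Meier product-limit survival estimate.

    Returns one row per distinct event/censor time with columns time,
    at_risk, events, censored and survival (the step value just after
    that time); S(0) = 1.  With no censoring the estimate equals the
    empirical survival function exactly.
    """
    durations = np.asarray(durations, dtype=float)
    if durations.size == 0:
        raise ValueError("empty sample")
    if np.any(durations <= 0):
        raise ValueError("durations must be positive")
    if event_observed is None:
        event_observed = np.ones_like(durations, dtype=bool)
    event_observed = np.asarray(event_observed, dtype=bool)
    if event_observed.shape != durations.shape:
        raise ValueError("event flags must match durations")
    times = np.unique(durations)
    rows = [{"time": 0.0, "at_risk": durations.size, "events": 0, "censored": 0,
             "survival": 1.0}]
    s = 1.0
    for t in times:
        at_risk = int(np.sum(durations >= t))
        d = int(np.sum((durations == t) & event_observed))
        c = int(np.sum((durations == t) & ~event_observed))
        if d:
            s *= 1.0 - d / at_risk
        rows.append(
            {"time": float(t), "at_risk": at_risk, "events": d, "censored": c,
             "survival": s}
        )
    return pd.DataFrame(rows)


def logrank_test(
    durations_a: np.ndarray,
    durations_b: np.ndarray,
    events_a: np.ndarray | None = None,
    events_b: np.ndarray | None = None,
) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p).

    Sums observed-minus-expected deaths in group A over the pooled event
    times with the hypergeometric variance; the statistic is chi-square
    with 1 df under the null of equal hazards.
    """
    da = np.asarray(durations_a, dtype=float)
    db = np.asarray(durations_b, dtype=float)
    ea = np.ones_like(da, dtype=bool) if events_a is None else np.asarray(events_a, bool)
    eb = np.ones_like(db, dtype=bool) if events_b is None else np.asarray(events_b, bool)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        logger.warning("log-rank: no events in either group")
        return 0.0, 1.0
    if not ea.any() or not eb.any():
        logger.warning("log-rank: one group has zero events")
    times = np.unique(np.concatenate([da[ea], db[eb]]))
    o_minus_e = 0.0
    var = 0.0
    for t in times:
        n_a = int(np.sum(da >= t))
        n_b = int(np.sum(db >= t))
        n_tot = n_a + n_b
        d_a = int(np.sum((da == t) & ea))
        d_tot = d_a + int(np.sum((db == t) & eb))
        if n_tot < 2 or d_tot == 0:
            continue
        e_a = d_tot * n_a / n_tot
        o_minus_e += d_a - e_a
        var += (
            d_tot * (n_a / n_tot) * (n_b / n_tot) * (n_tot - d_tot) / (n_tot - 1)
        )
    if var == 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(sps.chi2.sf(chi2, 1))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def bootstrap_ci(
    founders: list[FounderRecord],
    metric: str,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> dict:
    """Percentile bootstrap CI for a life-history metric of one cohort.

    Resamples founding females with replacement within the cohort,
    rebuilds the census and recomputes the metric B times.  Resamples
    where the metric is undefined (R0 == 0 for T and r) are dropped; if
    more than half are undefined the interval is flagged wide and a
    warning logged.  Deterministic given ``seed``.
    """
    if len(founders) < 2:
        raise ValueError("need at least two founders to resample")
    if B < 200:
        raise ValueError("B must be >= 200")
    if metric not in METRICS:
        raise KeyError(metric)
    rng = np.random.default_rng(seed)
    point = _metric_value(lifetable(census_from_founders(founders)), metric)
    n = len(founders)
    stats_: list[float] = []
    undefined = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        resample = [founders[i] for i in idx]
        try:
            res = lifetable(census_from_founders(resample))
        except UndefinedParameterError:
            undefined += 1
            continue
        val = _metric_value(res, metric)
        if val is None:
            undefined += 1
            continue
        stats_.append(val)
    flagged = undefined > B / 2
    if flagged:
        logger.warning(
            "bootstrap: metric %s undefined in %d/%d resamples; interval is wide",
            metric, undefined, B,
        )
    if stats_:
        lo, hi = np.percentile(stats_, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:
        lo = hi = np.nan
    return {
        "metric": metric,
        "point": point,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "B_effective": len(stats_),
        "undefined": undefined,
        "flagged_wide": bool(flagged),
    }


# ---------------------------------------------------------------------------
# pigmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PigmentLevel:
    """Pigmentation class of a xerosome from its %red digital number."""

    percent_red: float
    level: str  # HP | MP | LP | NP | boundary


def classify_pigment(percent_red: float) -> PigmentLevel:
    """Bin %red digital number into pigmentation level.

    Thresholds: HP > 45; MP 38–42; LP 36–37.4; NP < 36.  Values falling
    in the unassigned gaps (37.4, 38) and (42, 45] are classed
    ``boundary`` rather than forced into a neighbouring bin.
    """
    if not 0 <= percent_red <= 100:
        raise ValueError(f"%red DN out of range: {percent_red}")
    if percent_red > 45:
        level = "HP"
    elif 38 <= percent_red <= 42:
        level = "MP"
    elif 36 <= percent_red <= 37.4:
        level = "LP"
    elif percent_red < 36:
        level = "NP"
    else:
        level = "boundary"
    return PigmentLevel(percent_red=percent_red, level=level)
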