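"""Readers, writers and validation for experiment tables.

Census files are long-format CSV, one row per cohort-day::

    cohort_id,generation,treatment,feeding,replicate_id,day,survivors,neonates

with an optional ``censored`` column (count of females removed alive that
day).  Exposure-survival files are one row per replicate dish::

    generation,treatment,replicate_id,n_exposed,n_alive

Reports are TSV with a fixed column order and fixed rounding so reruns on
identical input are byte-identical; empty design cells render as ``ND``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .demography import (
    FEEDINGS,
    GENERATIONS,
    TREATMENT_INTENSITY,
    TREATMENTS,
    CohortCensus,
    round_half_up,
)

EXPOSURE_GENERATIONS = ("F0", "F2", "F4")

CENSUS_COLUMNS = [
    "cohort_id",
    "generation",
    "treatment",
    "feeding",
    "replicate_id",
    "day",
    "survivors",
    "neonates",
]
EXPOSURE_COLUMNS = ["generation", "treatment", "replicate_id", "n_exposed", "n_alive"]

#: literal used in report tables for design cells with no cohorts
ND = "ND"


class ValidationError(ValueError):
    """A file failed validation; ``errors`` lists row-level messages."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


@dataclass(frozen=True)
class ExposureOutcome:
    """Survival outcome of one exposure replicate (50 females per dish).

    Individuals showing trophi (jaw) movements 48 h after the 2-h UVB
    exposure are scored alive.
    """

    generation: str
    treatment: str
    replicate_id: str
    n_exposed: int
    n_alive: int

    def __post_init__(self) -> None:
        if self.generation not in EXPOSURE_GENERATIONS:
            raise ValidationError(
                [f"unknown exposure generation {self.generation!r}"]
            )
        if self.treatment not in TREATMENTS:
            raise ValidationError([f"unknown treatment {self.treatment!r}"])
        if not 0 <= self.n_alive <= self.n_exposed:
            raise ValidationError(
                [
                    f"{self.generation}/{self.treatment}/{self.replicate_id}: "
                    f"n_alive={self.n_alive} outside [0, n_exposed={self.n_exposed}]"
                ]
            )

    @property
    def intensity(self) -> float:
        """UVB irradiance of the treatment, W/m^2."""
        return TREATMENT_INTENSITY[self.treatment]

    @property
    def proportion_alive(self) -> float:
        return self.n_alive / self.n_exposed


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError([f"{path}: missing column(s) {', '.join(missing)}"])


def _check_int(df: pd.DataFrame, col: str, errors: list[str]) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() | (vals != vals.round())]
    for i in bad:
        errors.append(f"row {i + 2}: non-integer {col} {df.loc[i, col]!r}")
    return vals.fillna(-1).astype(int)


def read_census(path) -> list[CohortCensus]:
    """Read and validate a long-format census CSV into cohort objects.

    Row numbers in error messages are 1-based file lines (header = line 1).
    Raises :class:`ValidationError` listing every offending row rather than
    stopping at the first.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, CENSUS_COLUMNS, path)
    errors: list[str] = []
    day = _check_int(df, "day", errors)
    survivors = _check_int(df, "survivors", errors)
    neonates = _check_int(df, "neonates", errors)
    censored = None
    if "censored" in df.columns:
        censored = _check_int(df, "censored", errors)
    for col, vocab in [
        ("generation", GENERATIONS),
        ("treatment", TREATMENTS),
        ("feeding", FEEDINGS),
    ]:
        bad = df.index[~df[col].isin(vocab)]
        for i in bad:
            errors.append(f"row {i + 2}: {col} {df.loc[i, col]!r} not in {vocab}")
    if errors:
        raise ValidationError(errors)

    dup = df.duplicated(subset=["cohort_id", "day"])
    for i in df.index[dup]:
        errors.append(
            f"row {i + 2}: duplicate (cohort_id={df.loc[i, 'cohort_id']!r}, "
            f"day={df.loc[i, 'day']})"
        )
    if errors:
        raise ValidationError(errors)

    work = df.assign(day=day, survivors=survivors, neonates=neonates)
    if censored is not None:
        work = work.assign(censored=censored)
    cohorts: list[CohortCensus] = []
    for cohort_id, grp in work.groupby("cohort_id", sort=True):
        grp = grp.sort_values("day")
        days = grp["day"].to_numpy()
        if days[0] != 0 or np.any(np.diff(days) != 1):
            errors.append(f"cohort {cohort_id!r}: days not contiguous from 0")
            continue
        meta = grp.iloc[0]
        try:
            cohorts.append(
                CohortCensus(
                    cohort_id=str(cohort_id),
                    generation=meta["generation"],
                    treatment=meta["treatment"],
                    feeding=meta["feeding"],
                    replicate_id=str(meta["replicate_id"]),
                    days=days,
                    n_x=grp["survivors"].to_numpy(),
                    b_x=grp["neonates"].to_numpy(),
                    censored=grp["censored"].to_numpy() if censored is not None else None,
                )
            )
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError(errors)
    return cohorts


def write_census(cohorts: list[CohortCensus], path) -> None:
    """Write cohorts back to the long-format census CSV (round-trip safe)."""
    rows = []
    any_censor = any(c.censored is not None for c in cohorts)
    for c in sorted(cohorts, key=lambda c: c.cohort_id):
        for i, day in enumerate(c.days):
            row = {
                "cohort_id": c.cohort_id,
                "generation": c.generation,
                "treatment": c.treatment,
                "feeding": c.feeding,
                "replicate_id": c.replicate_id,
                "day": int(day),
                "survivors": int(c.n_x[i]),
                "neonates": int(c.b_x[i]),
            }
            if any_censor:
                row["censored"] = int(c.censored[i]) if c.censored is not None else 0
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_exposure(path) -> list[ExposureOutcome]:
    """Read and validate an exposure-survival CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, EXPOSURE_COLUMNS, path)
    errors: list[str] = []
    n_exposed = _check_int(df, "n_exposed", errors)
    n_alive = _check_int(df, "n_alive", errors)
    if errors:
        raise ValidationError(errors)
    outcomes: list[ExposureOutcome] = []
    for i in df.index:
        try:
            outcomes.append(
                ExposureOutcome(
                    generation=df.loc[i, "generation"],
                    treatment=df.loc[i, "treatment"],
                    replicate_id=str(df.loc[i, "replicate_id"]),
                    n_exposed=int(n_exposed[i]),
                    n_alive=int(n_alive[i]),
                )
            )
        except ValidationError as exc:
            errors.extend(f"row {i + 2}: {e}" for e in exc.errors)
    if errors:
        raise ValidationError(errors)
    return outcomes


def write_exposure(outcomes: list[ExposureOutcome], path) -> None:
    rows = [
        {
            "generation": o.generation,
            "treatment": o.treatment,
            "replicate_id": o.replicate_id,
            "n_exposed": o.n_exposed,
            "n_alive": o.n_alive,
        }
        for o in outcomes
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

_METRIC_DECIMALS = {"lifespan": 1, "R0": 1, "T": 1, "r": 2}


def format_cell(mean: float, sd: float, decimals: int) -> str:
    if mean is None or (isinstance(mean, float) and np.isnan(mean)):
        return ND
    sd = 0.0 if sd is None or np.isnan(sd) else sd
    fmt = f"{{:.{decimals}f}}"
    return (
        fmt.format(round_half_up(mean, decimals))
        + " ± "
        + fmt.format(round_half_up(sd, decimals))
    )


def write_report(cells: pd.DataFrame, metric: str, path) -> None:
    """Write one summary table (rows: generation × feeding incl. the
    unweighted "mean" rows; columns: treatments) as deterministic TSV.

    ``cells`` is the tidy frame produced by
    :func:`uvbdemog.stats.aggregate_cells` with columns generation,
    feeding, treatment, mean, sd, n for a single metric.
    """
    decimals = _METRIC_DECIMALS.get(metric, 2)
    lookup = {
        (r.generation, r.feeding, r.treatment): (r.mean, r.sd)
        for r in cells.itertuples()
    }
    lines = ["\t".join([metric] + list(TREATMENTS))]
    row_order = [(g, f) for g in GENERATIONS for f in FEEDINGS + ("mean",)]
    for gen, feeding in row_order:
        label = f"Mean {gen}" if feeding == "mean" else f"{gen} {feeding}"
        vals = []
        for trt in TREATMENTS:
            if (gen, feeding, trt) in lookup:
                mean, sd = lookup[(gen, feeding, trt)]
                vals.append(format_cell(mean, sd, decimals))
            else:
                vals.append(ND)
        lines.append("\t".join([label] + vals))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
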