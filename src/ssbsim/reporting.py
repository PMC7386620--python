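"""Prevented-case tables and stratified summaries with display rounding.

Counts are displayed to the nearest 100 at or above 1,000 and to the
nearest 50 below 1,000 (matching the granularity of published
prevented-case tables); percent changes are computed from unrounded counts
and rounded half-up at the display layer only.  Every written table keeps
the unrounded values alongside the display strings so a round trip through
CSV is lossless.
"""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import AGE_GROUPS, SEXES, TABLE_OUTCOMES
from .errors import ValidationError
from .scenarios import ComparisonResult
from .uncertainty import UncertaintyResult

EM_DASH = "—"


def _roundtrip(x: float) -> str:
    """CSV float formatting that parses back to the identical double."""
    return format(x, ".17g")


def round_count(value: float, *, coarse_threshold: float = 1000.0,
                coarse_step: float = 100.0, fine_step: float = 50.0) -> int:
    """Display rounding: nearest 100 from 1,000 up, nearest 50 below."""
    if value < 0:
        raise ValidationError("counts must be nonnegative")
    step = coarse_step if value >= coarse_threshold else fine_step
    return int(math.floor(value / step + 0.5) * step)


def format_count(value: float) -> str:
    """Rounded count with thousands separators, e.g. ``13,300``."""
    return f"{round_count(value):,}"


def percent_change(prevented: float, base_total: float,
                   decimals: int = 1) -> float:
    """100 x prevented / base, half-up rounded to ``decimals`` places."""
    if base_total <= 0:
        raise ValidationError("base total must be positive")
    exact = (Decimal(100) * Decimal(repr(float(prevented)))
             / Decimal(repr(float(base_total))))
    quantum = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(quantum, rounding=ROUND_HALF_UP))


def format_percent(prevented: float, base_total: float,
                   decimals: int = 1) -> str:
    if base_total <= 0:
        return EM_DASH
    return f"{percent_change(prevented, base_total, decimals):.{decimals}f}"


def stratified_summary(result: ComparisonResult) -> pd.DataFrame:
    """Long-format prevented cases per sex x age group x outcome.

    Ordered men then women, ascending age; one row per stratum x outcome
    with the prevented count and the percent of the stratum's base total.
    """
    for outcome in TABLE_OUTCOMES:
        if outcome not in result.prevented_by_stratum:
            raise ValidationError(f"comparison missing outcome '{outcome}'")
        arr = result.prevented_by_stratum[outcome]
        if arr.shape != (len(SEXES), len(AGE_GROUPS)):
            raise ValidationError(
                f"stratified results for '{outcome}' must cover all "
                f"{len(SEXES)}x{len(AGE_GROUPS)} strata")
    rows = []
    for s, sex in enumerate(SEXES):
        for a, group in enumerate(AGE_GROUPS):
            for outcome in TABLE_OUTCOMES:
                rows.append({
                    "scenario": result.scenario_label,
                    "sex": sex, "age_group": group, "outcome": outcome,
                    "prevented": result.prevented_by_stratum[outcome][s, a],
                    "percent_change": result.percent_by_stratum[outcome][s, a],
                })
    if not rows:
        raise ValidationError("empty stratified results")
    return pd.DataFrame(rows)


def prevented_cases_table(
    results: Mapping[str, ComparisonResult],
    uncertainty: UncertaintyResult | None = None,
) -> pd.DataFrame:
    """Prevented-case table: one row per outcome x scenario.

    Keeps unrounded columns (``base``, ``prevented``, ``percent_exact``)
    alongside display strings (``prevented_display``, ``ui_display``,
    ``percent_display``).
    """
    rows = []
    for label, result in results.items():
        for outcome in TABLE_OUTCOMES:
            vals = result.outcomes[outcome]
            row = {
                "scenario": label,
                "outcome": outcome,
                "base": vals["base"],
                "prevented": vals["prevented"],
                "percent_exact": vals["percent_change"],
                "base_display": format_count(vals["base"]),
                "prevented_display": format_count(max(vals["prevented"], 0.0)),
                "percent_display": format_percent(vals["prevented"],
                                                  vals["base"]),
            }
            if (uncertainty is not None
                    and label in uncertainty.ui
                    and outcome in uncertainty.ui[label]):
                lo, hi = uncertainty.ui[label][outcome]
                row["ui_low"] = lo
                row["ui_high"] = hi
                row["ui_display"] = (f"({format_count(max(lo, 0.0))}"
                                     f"–{format_count(max(hi, 0.0))})")
            rows.append(row)
    return pd.DataFrame(rows)


_DATA_DICTIONARY = """\
Data dictionary for prevented-case outputs
==========================================

prevented_cases*.csv
  scenario           scenario label (r<reduction>_c<compensation>_<estimate>)
  outcome            diabetes | mi | stroke | cvd_deaths | total_deaths
  base               unrounded cumulative base-case events over the horizon
  prevented          unrounded base - scenario events (prevented cases)
  percent_exact      unrounded 100 * prevented / base
  base_display       base rounded for display (nearest 100 above 1,000,
                     nearest 50 below), thousands separators
  prevented_display  prevented, same display rounding
  percent_display    percent change, half-up to one decimal ("-" if no base)
  ui_low / ui_high   unrounded 95% uncertainty interval of prevented cases
  ui_display         display-rounded UI

stratified.csv
  scenario, sex, age_group, outcome as above
  prevented          unrounded prevented cases in the stratum
  percent_change     unrounded percent of the stratum's base-case total
"""


def write_tables(
    results: Mapping[str, ComparisonResult],
    outdir: str | Path,
    uncertainty: UncertaintyResult | None = None,
    stratified_for: str | None = None,
) -> dict[str, Path]:
    """Write prevented-case and stratified CSVs plus the data dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    table = prevented_cases_table(results, uncertainty)
    paths["prevented_cases"] = outdir / "prevented_cases.csv"
    table.to_csv(paths["prevented_cases"], index=False,
                 float_format=_roundtrip)
    if stratified_for is not None:
        strat = stratified_summary(results[stratified_for])
        paths["stratified"] = outdir / "stratified.csv"
        strat.to_csv(paths["stratified"], index=False,
                     float_format=_roundtrip)
    paths["data_dictionary"] = outdir / "data_dictionary.txt"
    paths["data_dictionary"].write_text(_DATA_DICTIONARY, encoding="utf-8")
    return paths


def plot_stratified(summary: pd.DataFrame, path: str | Path,
                    outcome: str = "diabetes") -> Path:
    """Bar chart of prevented-percent by age group and sex (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary["outcome"] == outcome]
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.38
    x = np.arange(len(AGE_GROUPS))
    for offset, sex in zip((-width / 2, width / 2), SEXES):
        vals = [
            float(sub[(sub.sex == sex) & (sub.age_group == g)]
                  ["percent_change"].iloc[0]) for g in AGE_GROUPS]
        ax.bar(x + offset, vals, width, label=sex)
    ax.set_xticks(x, AGE_GROUPS)
    ax.set_xlabel("age group")
    ax.set_ylabel(f"prevented {outcome} (% of base case)")
    ax.legend()
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
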