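"""Publication-style report tables (CSV and Markdown).

Three tables mirror the conventional layout of a Sullivan-method paper:
prevalence by sex and age group with confidence intervals and p-values;
total life expectancy with the between-sex difference; and the three-block
healthy / unhealthy / proportion-unhealthy table with significance stars.

All computation upstream is unrounded; numbers are rounded (half-even, one
decimal) only here.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .comparison import GroupComparison
from .life_tables import LifeTable
from .prevalence import PrevalenceTable
from .sullivan import HealthExpectancyTable

__all__ = [
    "prevalence_report",
    "life_expectancy_report",
    "health_expectancy_report",
    "dataframe_to_markdown",
    "write_report",
]

logger = logging.getLogger(__name__)


def _r1(x) -> float:
    """Round half-even to one decimal (render-time only)."""
    return float(np.round(float(x), 1))


def _fmt(x) -> str:
    return f"{_r1(x):.1f}"


def _ci(lo, hi) -> str:
    return f"({_fmt(lo)} - {_fmt(hi)})"


def _star(diff, significant) -> str:
    return f"{_fmt(diff)}*" if significant else _fmt(diff)


def prevalence_report(
    tables: dict[str, PrevalenceTable],
    p_between: np.ndarray | None = None,
    p_within: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Prevalence (%) with 95% CIs per sex and age group.

    ``p_between`` holds one sex-comparison p-value per age group;
    ``p_within`` one age-trend p-value per sex.
    """
    sexes = list(tables)
    first = tables[sexes[0]]
    rows = []
    for i, label in enumerate(first.grid.labels()):
        row: dict = {"age_group": label}
        for sex in sexes:
            t = tables[sex]
            row[f"n_{sex}"] = int(t.n[i]) if np.isfinite(t.n[i]) else ""
            row[f"prevalence_{sex}"] = (
                f"{_fmt(100 * t.prevalence[i])} {_ci(100 * t.ci_low[i], 100 * t.ci_high[i])}"
            )
        if p_between is not None:
            row["p_between_sexes"] = f"{p_between[i]:.4f}"
        rows.append(row)
    df = pd.DataFrame(rows)
    if p_within:
        trend = {"age_group": "p (age trend)"}
        for sex in sexes:
            trend[f"n_{sex}"] = ""
            trend[f"prevalence_{sex}"] = f"{p_within[sex]:.4f}"
        if p_between is not None:
            trend["p_between_sexes"] = ""
        df = pd.concat([df, pd.DataFrame([trend])], ignore_index=True)
    return df


def life_expectancy_report(
    table_a: LifeTable, table_b: LifeTable, comparison: GroupComparison | None = None
) -> pd.DataFrame:
    rows = []
    for i, age in enumerate(table_a.grid.exact_ages):
        row = {
            "age": int(age) if float(age).is_integer() else age,
            f"LE_{table_a.sex or 'a'}": _fmt(table_a.e[i]),
            f"ci_{table_a.sex or 'a'}": _ci(table_a.ci_low[i], table_a.ci_high[i]),
            f"LE_{table_b.sex or 'b'}": _fmt(table_b.e[i]),
            f"ci_{table_b.sex or 'b'}": _ci(table_b.ci_low[i], table_b.ci_high[i]),
        }
        if comparison is not None:
            row["difference"] = _star(comparison.diff[i], comparison.significant[i])
        rows.append(row)
    return pd.DataFrame(rows)


def _check_conservation(het: HealthExpectancyTable) -> None:
    e = het.hle + het.uhle
    lt_e = het.life_table.e if het.life_table is not None else e
    if not np.allclose(e, lt_e, rtol=1e-9, atol=1e-12):
        raise AssertionError("HLE + UHLE does not reproduce the life expectancy column")


def health_expectancy_report(
    blocks: dict[str, dict],
) -> pd.DataFrame:
    """Three stacked blocks (HLE, UHLE, proportion of UHLE) across indicators.

    ``blocks`` maps indicator name to a dict with keys ``men``, ``women``
    (HealthExpectancyTable) and optionally ``hle_diff``, ``uhle_diff``
    (GroupComparison).
    """
    indicators = list(blocks)
    some = blocks[indicators[0]]["men"]
    ages = some.grid.exact_ages
    for b in blocks.values():
        _check_conservation(b["men"])
        _check_conservation(b["women"])
    rows = []
    for quantity, attr in (("HLE", "hle"), ("UHLE", "uhle"), ("prop_UHLE", "prop_uhle")):
        for i, age in enumerate(ages):
            row = {"block": quantity, "age": int(age) if float(age).is_integer() else age}
            for ind in indicators:
                b = blocks[ind]
                row[f"{ind}_men"] = _fmt(getattr(b["men"], attr)[i])
                row[f"{ind}_women"] = _fmt(getattr(b["women"], attr)[i])
                comp = b.get("hle_diff" if quantity == "HLE" else "uhle_diff")
                if quantity == "prop_UHLE":
                    row[f"{ind}_diff"] = _fmt(
                        getattr(b["women"], attr)[i] - getattr(b["men"], attr)[i]
                    )
                elif comp is not None:
                    row[f"{ind}_diff"] = _star(comp.diff[i], comp.significant[i])
            rows.append(row)
    return pd.DataFrame(rows)


def dataframe_to_markdown(df: pd.DataFrame) -> str:
    cols = [str(c) for c in df.columns]
    body = df.astype(str).to_numpy()
    widths = [max(len(c), *(len(r[j]) for r in body)) if len(body) else len(c)
              for j, c in enumerate(cols)]
    def line(cells):
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(cols), "| " + " | ".join("-" * w for w in widths) + " |"]
    out += [line(list(r)) for r in body]
    return "\n".join(out) + "\n"


def write_report(
    output_dir,
    prevalence: dict[str, pd.DataFrame] | None = None,
    life_expectancy: pd.DataFrame | None = None,
    health_expectancy: pd.DataFrame | None = None,
) -> list[Path]:
    """Write whichever report blocks are available; warn about missing ones."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    named = {
        "life_expectancy": life_expectancy,
        "health_expectancy": health_expectancy,
    }
    if prevalence:
        for ind, df in prevalence.items():
            named[f"prevalence_{ind}"] = df
    else:
        named["prevalence"] = None
    for name, df in named.items():
        if df is None:
            logger.warning("report block %r missing; partial report written", name)
            continue
        csv_path = outdir / f"{name}.csv"
        df.to_csv(csv_path, index=False)
        md_path = outdir / f"{name}.md"
        md_path.write_text(dataframe_to_markdown(df))
        written += [csv_path, md_path]
    return written
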