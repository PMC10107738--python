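"""Fetal growth chart references and the 90th-percentile classification rules.

A growth chart maps gestational age to a distribution of estimated fetal
weight (EFW).  Three dialects cover the reference standards in common use:

``mean_sd_log``
    GA -> mean and SD of log10 EFW (FMF-style).  The percentile of an
    observed EFW is the normal CDF of its log10 z-score.
``mean_sd_linear``
    GA -> median EFW in grams and an SD in grams (Hadlock-style, where the
    SD is published as a proportion of the median).  Percentile via the
    normal CDF on the gram scale.
``quantile_table``
    GA -> rows of {percentile: EFW} (NICHD-style), optionally stratified by
    maternal race/ethnicity.  Percentile by monotone linear interpolation
    across the tabulated grid, clamped to (0.5, 99.5).

Parameters are linearly interpolated in GA between knots; there is no
extrapolation beyond chart coverage.  Suspected LGA is EFW at or above the
90th chart percentile (inclusive).  LGA at birth is birth weight at or above
the sex-specific 90th-percentile cutoff of a natality reference, indexed by
completed (floored) gestational week.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ChartError",
    "GrowthChart",
    "BirthweightReference",
    "efw_percentile",
    "is_suspected_lga",
    "is_lga_at_birth",
    "load_chart",
    "write_chart",
    "load_birthweight_reference",
    "write_birthweight_reference",
    "tabulate_quantile_chart",
    "LGA_PERCENTILE",
    "CHART_COVERAGE",
]

LGA_PERCENTILE = 90.0
#: GA interval (weeks) every chart must cover — the study scan window plus
#: the 37th week so the upper boundary interpolates rather than extrapolates.
CHART_COVERAGE = (28.0, 37.0)

_DIALECTS = ("mean_sd_log", "mean_sd_linear", "quantile_table")
_QT_CLAMP = (0.5, 99.5)


class ChartError(ValueError):
    """Chart/reference schema or validation failure."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0 or not np.all(np.isfinite(arr)):
        raise ChartError(f"{name} must be non-empty and finite")
    return arr


@dataclass(frozen=True)
class GrowthChart:
    """A validated growth-chart reference in one of the three dialects.

    For the ``mean_sd_*`` dialects ``mean`` and ``sd`` hold one value per GA
    knot.  For ``quantile_table`` the chart holds a sorted ``percentiles``
    grid and, per stratum (``None`` for an unstratified chart), a
    ``(n_knots, n_percentiles)`` matrix of EFW values.
    """

    name: str
    dialect: str
    ga_weeks: np.ndarray
    mean: np.ndarray | None = None
    sd: np.ndarray | None = None
    percentiles: np.ndarray | None = None
    tables: Mapping[str | None, np.ndarray] | None = None

    def __post_init__(self):
        if self.dialect not in _DIALECTS:
            raise ChartError(f"unknown dialect {self.dialect!r}; expected one of {_DIALECTS}")
        ga = _as_float_array(self.ga_weeks, "ga_weeks")
        object.__setattr__(self, "ga_weeks", ga)
        if np.any(np.diff(ga) <= 0):
            raise ChartError(f"chart {self.name!r}: GA knots must be strictly increasing")
        lo, hi = CHART_COVERAGE
        if ga[0] > lo + 1e-9 or ga[-1] < hi - 1e-9:
            raise ChartError(
                f"chart {self.name!r}: GA knots [{ga[0]}, {ga[-1]}] do not cover "
                f"[{lo}, {hi}]"
            )
        if self.dialect == "quantile_table":
            if self.percentiles is None or self.tables is None:
                raise ChartError(f"chart {self.name!r}: quantile_table needs percentiles and tables")
            pct = _as_float_array(self.percentiles, "percentiles")
            object.__setattr__(self, "percentiles", pct)
            if np.any(np.diff(pct) <= 0):
                raise ChartError(f"chart {self.name!r}: percentile grid must be strictly increasing")
            if LGA_PERCENTILE not in pct:
                raise ChartError(f"chart {self.name!r}: percentile grid must include {LGA_PERCENTILE:g}")
            tables = {}
            for stratum, vals in self.tables.items():
                v = _as_float_array(vals, f"values[{stratum!r}]")
                if v.shape != (ga.size, pct.size):
                    raise ChartError(
                        f"chart {self.name!r}, stratum {stratum!r}: expected shape "
                        f"{(ga.size, pct.size)}, got {v.shape}"
                    )
                bad = np.diff(v, axis=1) <= 0
                if bad.any():
                    i, j = np.argwhere(bad)[0]
                    raise ChartError(
                        f"chart {self.name!r}, stratum {stratum!r}: EFW not strictly "
                        f"increasing in percentile at ga={ga[i]:g} between "
                        f"p{pct[j]:g} and p{pct[j + 1]:g}"
                    )
                tables[stratum] = v
            object.__setattr__(self, "tables", tables)
        else:
            if self.mean is None or self.sd is None:
                raise ChartError(f"chart {self.name!r}: {self.dialect} needs mean and sd columns")
            mean = _as_float_array(self.mean, "mean")
            sd = _as_float_array(self.sd, "sd")
            if mean.shape != ga.shape or sd.shape != ga.shape:
                raise ChartError(f"chart {self.name!r}: mean/sd must align with GA knots")
            if np.any(sd <= 0):
                i = int(np.argmax(sd <= 0))
                raise ChartError(f"chart {self.name!r}: sd must be > 0 (ga={ga[i]:g})")
            object.__setattr__(self, "mean", mean)
            object.__setattr__(self, "sd", sd)

    # -- lookups ---------------------------------------------------------

    @property
    def strata(self) -> list[str] | None:
        if self.dialect != "quantile_table":
            return None
        keys = [k for k in self.tables if k is not None]
        return sorted(keys) if keys else None

    def _check_ga(self, ga) -> np.ndarray:
        ga = np.atleast_1d(np.asarray(ga, dtype=float))
        lo, hi = self.ga_weeks[0], self.ga_weeks[-1]
        if np.any(ga < lo - 1e-9) or np.any(ga > hi + 1e-9):
            bad = ga[(ga < lo - 1e-9) | (ga > hi + 1e-9)][0]
            raise ChartError(
                f"chart {self.name!r}: ga_weeks={bad:g} outside coverage [{lo:g}, {hi:g}]"
            )
        return np.clip(ga, lo, hi)

    def _table_for(self, stratum: str | None) -> np.ndarray:
        if self.strata is None:
            return self.tables[None] if self.dialect == "quantile_table" else None
        if stratum is None:
            raise ChartError(f"chart {self.name!r} is stratified; a stratum is required")
        if stratum not in self.tables:
            raise ChartError(
                f"chart {self.name!r}: stratum {stratum!r} not in chart "
                f"(available: {self.strata})"
            )
        return self.tables[stratum]

    def _interp_rows(self, ga: np.ndarray, matrix: np.ndarray) -> np.ndarray:
        """GA-interpolated rows of a per-knot matrix (exact at knots)."""
        idx = np.clip(np.searchsorted(self.ga_weeks, ga, side="right") - 1, 0,
                      self.ga_weeks.size - 2)
        g0, g1 = self.ga_weeks[idx], self.ga_weeks[idx + 1]
        w = np.where(g1 > g0, (ga - g0) / (g1 - g0), 0.0)
        return matrix[idx] * (1.0 - w)[:, None] + matrix[idx + 1] * w[:, None]

    def percentile(self, efw, ga_weeks, stratum: str | None = None):
        """Chart percentile of ``efw`` grams at ``ga_weeks`` (scalar or array)."""
        scalar = np.isscalar(efw) and np.isscalar(ga_weeks)
        ga = self._check_ga(ga_weeks)
        efw_arr = np.atleast_1d(np.asarray(efw, dtype=float))
        efw_arr, ga = np.broadcast_arrays(efw_arr, ga)
        if self.dialect == "quantile_table":
            rows = self._interp_rows(ga, self._table_for(stratum))
            # EFW below/above the tabulated spread is only known to be
            # extreme: report the clamp bounds rather than extrapolating
            out = np.array([
                _QT_CLAMP[0] if e < row[0] else
                _QT_CLAMP[1] if e > row[-1] else
                np.interp(e, row, self.percentiles)
                for e, row in zip(efw_arr, rows)
            ])
        else:
            if stratum is not None:
                raise ChartError(f"chart {self.name!r} is not stratified")
            mean = np.interp(ga, self.ga_weeks, self.mean)
            sd = np.interp(ga, self.ga_weeks, self.sd)
            t = np.log10(efw_arr) if self.dialect == "mean_sd_log" else efw_arr
            out = norm.cdf((t - mean) / sd) * 100.0
        return float(out[0]) if scalar else out

    def efw_at(self, ga_weeks, percentile, stratum: str | None = None):
        """Inverse lookup: the EFW (grams) sitting at a chart percentile."""
        scalar = np.isscalar(percentile) and np.isscalar(ga_weeks)
        ga = self._check_ga(ga_weeks)
        pct = np.atleast_1d(np.asarray(percentile, dtype=float))
        pct, ga = np.broadcast_arrays(pct, ga)
        if self.dialect == "quantile_table":
            rows = self._interp_rows(ga, self._table_for(stratum))
            out = np.array([
                np.interp(p, self.percentiles, row) for p, row in zip(pct, rows)
            ])
        else:
            mean = np.interp(ga, self.ga_weeks, self.mean)
            sd = np.interp(ga, self.ga_weeks, self.sd)
            t = mean + sd * norm.ppf(pct / 100.0)
            out = 10.0 ** t if self.dialect == "mean_sd_log" else t
        return float(out[0]) if scalar else out


def efw_percentile(efw, ga_weeks, chart: GrowthChart, stratum: str | None = None):
    """Percentile of an EFW on a chart; thin wrapper over ``chart.percentile``."""
    return chart.percentile(efw, ga_weeks, stratum=stratum)


def is_suspected_lga(efw, ga_weeks, chart: GrowthChart, stratum: str | None = None):
    """EFW at or above the chart's 90th percentile (inclusive threshold)."""
    pct = chart.percentile(efw, ga_weeks, stratum=stratum)
    return pct >= LGA_PERCENTILE


# ---------------------------------------------------------------------------
# Birth-weight reference (sex-specific natality-style table)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BirthweightReference:
    """Sex-specific birth-weight percentile cutoffs by completed GA week.

    ``table`` has columns ``sex`` (M/F), ``ga_week`` (completed weeks,
    integer) and ``p90_g``; extra percentile columns are preserved.
    """

    name: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        required = {"sex", "ga_week", "p90_g"}
        missing = required - set(self.table.columns)
        if missing:
            raise ChartError(f"birth-weight reference {self.name!r}: missing columns {sorted(missing)}")
        tab = self.table.copy()
        tab["sex"] = tab["sex"].astype(str)
        tab["ga_week"] = tab["ga_week"].astype(int)
        if tab.duplicated(["sex", "ga_week"]).any():
            raise ChartError(f"birth-weight reference {self.name!r}: duplicate (sex, ga_week) rows")
        for sex, grp in tab.sort_values("ga_week").groupby("sex"):
            if np.any(np.diff(grp["p90_g"].to_numpy()) <= 0):
                raise ChartError(
                    f"birth-weight reference {self.name!r}: p90_g not strictly "
                    f"increasing in GA for sex {sex!r}"
                )
        object.__setattr__(self, "table", tab)
        lut = {(s, w): c for s, w, c in zip(tab["sex"], tab["ga_week"], tab["p90_g"])}
        object.__setattr__(self, "_lut", lut)

    def cutoff_p90(self, infant_sex: str, ga_week: int) -> float:
        key = (str(infant_sex), int(ga_week))
        try:
            return float(self._lut[key])
        except KeyError:
            raise ChartError(
                f"birth-weight reference {self.name!r}: no row for sex={key[0]!r}, "
                f"completed week {key[1]}"
            ) from None

    def column(self, infant_sex: str, ga_week: int, name: str) -> float:
        row = self.table[(self.table["sex"] == str(infant_sex))
                         & (self.table["ga_week"] == int(ga_week))]
        if row.empty or name not in row.columns:
            raise ChartError(
                f"birth-weight reference {self.name!r}: no {name!r} for "
                f"sex={infant_sex!r}, week {int(ga_week)}"
            )
        return float(row[name].iloc[0])


def is_lga_at_birth(bw_g, ga_delivery_weeks, infant_sex, ref: BirthweightReference):
    """Birth weight >= the sex-specific 90th-percentile cutoff (inclusive).

    The reference is indexed by completed gestational weeks, i.e.
    ``floor(ga_delivery_weeks)``.
    """
    if np.isscalar(bw_g):
        week = int(np.floor(ga_delivery_weeks))
        return float(bw_g) >= ref.cutoff_p90(infant_sex, week)
    bw = np.asarray(bw_g, dtype=float)
    weeks = np.floor(np.asarray(ga_delivery_weeks, dtype=float)).astype(int)
    sexes = np.asarray(infant_sex)
    cut = np.array([ref.cutoff_p90(s, w) for s, w in zip(sexes, weeks)])
    return bw >= cut


# ---------------------------------------------------------------------------
# Chart construction helpers
# ---------------------------------------------------------------------------

def tabulate_quantile_chart(
    chart: GrowthChart,
    percentiles: Sequence[float] = (1, 5, 10, 25, 50, 75, 90, 95, 99),
    name: str | None = None,
) -> GrowthChart:
    """Build a quantile_table chart by tabulating another chart at its knots."""
    pct = np.asarray(sorted(percentiles), dtype=float)
    vals = np.column_stack([
        chart.efw_at(chart.ga_weeks, np.full(chart.ga_weeks.size, p)) for p in pct
    ])
    return GrowthChart(
        name=name or f"{chart.name}_tabulated",
        dialect="quantile_table",
        ga_weeks=chart.ga_weeks.copy(),
        percentiles=pct,
        tables={None: vals},
    )


# ---------------------------------------------------------------------------
# File formats: CSV (with a dialect-declaring comment header) and JSON
# ---------------------------------------------------------------------------

def _parse_header_line(line: str, path) -> dict:
    if not line.startswith("#"):
        raise ChartError(f"{path}: first line must declare the chart, e.g. "
                         "'# growth-chart name=<name> dialect=<dialect>'")
    fields = dict(
        tok.split("=", 1) for tok in line.lstrip("#").split() if "=" in tok
    )
    if "dialect" not in fields:
        raise ChartError(f"{path}: header line does not declare dialect=")
    return fields


def load_chart(path, expected_dialect: str | None = None) -> GrowthChart:
    """Load and validate a growth chart from a ``.csv`` or ``.json`` file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        chart = _chart_from_json(json.loads(path.read_text()), path)
    else:
        chart = _chart_from_csv(path)
    if expected_dialect is not None and chart.dialect != expected_dialect:
        raise ChartError(
            f"{path}: dialect {chart.dialect!r} does not match expected "
            f"{expected_dialect!r}"
        )
    return chart


def _chart_from_csv(path: Path) -> GrowthChart:
    with open(path) as fh:
        header = _parse_header_line(fh.readline(), path)
        df = pd.read_csv(fh)
    name = header.get("name", path.stem)
    dialect = header["dialect"]
    if "ga_weeks" not in df.columns:
        raise ChartError(f"{path}: missing ga_weeks column")
    if dialect == "quantile_table":
        pct_cols = [c for c in df.columns if c.startswith("p") and c[1:].replace(".", "").isdigit()]
        if not pct_cols:
            raise ChartError(f"{path}: quantile_table needs percentile columns (p10, p50, ...)")
        pct = np.asarray([float(c[1:]) for c in pct_cols])
        order = np.argsort(pct)
        pct = pct[order]
        pct_cols = [pct_cols[i] for i in order]
        tables = {}
        if "stratum" in df.columns:
            groups = [(str(s), g) for s, g in df.groupby("stratum", sort=True)]
        else:
            groups = [(None, df)]
        ga_ref = None
        for stratum, grp in groups:
            grp = grp.sort_values("ga_weeks")
            ga = grp["ga_weeks"].to_numpy(dtype=float)
            if ga_ref is None:
                ga_ref = ga
            elif ga.shape != ga_ref.shape or not np.allclose(ga, ga_ref):
                raise ChartError(f"{path}: stratum {stratum!r} GA grid differs from the others")
            tables[stratum] = grp[pct_cols].to_numpy(dtype=float)
        return GrowthChart(name=name, dialect=dialect, ga_weeks=ga_ref,
                           percentiles=pct, tables=tables)
    for col in ("mean", "sd"):
        if col not in df.columns:
            raise ChartError(f"{path}: missing {col!r} column for dialect {dialect!r}")
    df = df.sort_values("ga_weeks")
    return GrowthChart(
        name=name, dialect=dialect,
        ga_weeks=df["ga_weeks"].to_numpy(dtype=float),
        mean=df["mean"].to_numpy(dtype=float),
        sd=df["sd"].to_numpy(dtype=float),
    )


def _chart_from_json(doc: dict, path) -> GrowthChart:
    for key in ("name", "dialect", "grid"):
        if key not in doc:
            raise ChartError(f"{path}: JSON chart missing {key!r}")
    dialect = doc["dialect"]
    grid = doc["grid"]
    if dialect == "quantile_table":
        tables: dict = {}
        ga_by_stratum: dict = {}
        pct_ref = None
        for row in grid:
            stratum = row.get("stratum")
            pcts = row["percentiles"]
            keys = np.asarray(sorted(float(k) for k in pcts))
            if pct_ref is None:
                pct_ref = keys
            elif not np.array_equal(keys, pct_ref):
                raise ChartError(f"{path}: inconsistent percentile grids across rows")
            ga_by_stratum.setdefault(stratum, []).append(float(row["ga_weeks"]))
            tables.setdefault(stratum, []).append(
                [float(pcts[k]) for k in sorted(pcts, key=float)]
            )
        ga_ref = None
        out_tables = {}
        for stratum, ga_list in ga_by_stratum.items():
            order = np.argsort(ga_list)
            ga = np.asarray(ga_list)[order]
            if ga_ref is None:
                ga_ref = ga
            elif not np.allclose(ga, ga_ref):
                raise ChartError(f"{path}: stratum {stratum!r} GA grid differs from the others")
            out_tables[stratum] = np.asarray(tables[stratum])[order]
        return GrowthChart(name=doc["name"], dialect=dialect, ga_weeks=ga_ref,
                           percentiles=pct_ref, tables=out_tables)
    ga = np.asarray([float(r["ga_weeks"]) for r in grid])
    order = np.argsort(ga)
    return GrowthChart(
        name=doc["name"], dialect=dialect, ga_weeks=ga[order],
        mean=np.asarray([float(r["mean"]) for r in grid])[order],
        sd=np.asarray([float(r["sd"]) for r in grid])[order],
    )


def write_chart(chart: GrowthChart, path) -> None:
    """Write a chart to ``.csv`` (comment header + table) or ``.json``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        if chart.dialect == "quantile_table":
            grid = []
            for stratum, vals in chart.tables.items():
                for i, ga in enumerate(chart.ga_weeks):
                    row = {"ga_weeks": float(ga),
                           "percentiles": {f"{p:g}": float(v) for p, v in zip(chart.percentiles, vals[i])}}
                    if stratum is not None:
                        row["stratum"] = stratum
                    grid.append(row)
        else:
            grid = [
                {"ga_weeks": float(g), "mean": float(m), "sd": float(s)}
                for g, m, s in zip(chart.ga_weeks, chart.mean, chart.sd)
            ]
        path.write_text(json.dumps(
            {"name": chart.name, "dialect": chart.dialect, "grid": grid}, indent=1
        ))
        return
    with open(path, "w") as fh:
        fh.write(f"# growth-chart name={chart.name} dialect={chart.dialect}\n")
        if chart.dialect == "quantile_table":
            cols = [f"p{p:g}" for p in chart.percentiles]
            frames = []
            for stratum, vals in chart.tables.items():
                df = pd.DataFrame(vals, columns=cols)
                df.insert(0, "ga_weeks", chart.ga_weeks)
                if stratum is not None:
                    df.insert(1, "stratum", stratum)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(fh, index=False)
        else:
            pd.DataFrame({"ga_weeks": chart.ga_weeks, "mean": chart.mean,
                          "sd": chart.sd}).to_csv(fh, index=False)


def load_birthweight_reference(path) -> BirthweightReference:
    """Load a sex-specific birth-weight reference CSV (sex, ga_week, p90_g, ...)."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    return BirthweightReference(name=path.stem, table=df)


def write_birthweight_reference(ref: BirthweightReference, path) -> None:
    ref.table.to_csv(path, index=False)
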