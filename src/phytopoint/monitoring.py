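"""Benchmark bookkeeping.

Repeated trait extractions — or a third-party algorithm's outputs — are
compared against reference-model benchmark values: per-observation signed
deviations and percentages, and summary rows. Mean rows aggregate
*absolute* deviations/percentages, since signed means would let opposite
errors cancel. Display rounding is half-away-from-zero at the printed
precision.

The package ships the reference model's benchmark tables as CSV fixtures
(automated + manual traits per leaf, sensor sigma/point counts, a
template-fitting algorithm's estimates, and a 9-date monitoring series),
loadable via :func:`load_benchmark_table`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParameterError

__all__ = [
    "round_half_away",
    "DeviationReport",
    "compare_to_benchmark",
    "method_agreement",
    "algorithm_error_report",
    "load_benchmark_table",
]

_TABLES = {"table1", "table2", "table3", "table4", "table5"}


def load_benchmark_table(name: str) -> pd.DataFrame:
    """Load one of the shipped benchmark fixtures (``table1``..``table5``)."""
    if name not in _TABLES:
        raise ParameterError(f"unknown benchmark table '{name}'")
    path = resources.files("phytopoint") / "data" / f"{name}.csv"
    with path.open() as fh:
        return pd.read_csv(fh)


def round_half_away(x, decimals: int = 1):
    """Round half away from zero (the convention of printed field tables;
    numpy rounds half to even)."""
    x = np.asarray(x, dtype=np.float64)
    factor = 10.0 ** decimals
    out = np.sign(x) * np.floor(np.abs(x) * factor + 0.5) / factor
    return float(out) if out.ndim == 0 else out


@dataclass
class DeviationReport:
    """Per-observation deviations from one scalar benchmark."""

    rows: pd.DataFrame          # id, value, deviation, percent
    benchmark: float
    unit: str

    @property
    def mean_abs_deviation(self) -> float:
        return float(self.rows["deviation"].abs().mean())

    @property
    def mean_signed_percent(self) -> float:
        return float(self.rows["percent"].mean())

    @property
    def mean_abs_percent(self) -> float:
        return float(self.rows["percent"].abs().mean())

    @property
    def max_abs_percent(self) -> float:
        return float(self.rows["percent"].abs().max())

    def display(self, value_decimals: int = 1) -> pd.DataFrame:
        out = self.rows.copy()
        out["deviation"] = round_half_away(out["deviation"].to_numpy(),
                                           value_decimals)
        out["percent"] = round_half_away(out["percent"].to_numpy(), 1)
        return out


def compare_to_benchmark(observations, benchmark: float,
                         unit: str = "") -> DeviationReport:
    """Deviation report of repeated measurements against one benchmark.

    Parameters
    ----------
    observations : iterable of (id, value)
    benchmark : float
        Reference value (≠ 0); percentages use it as denominator.
    """
    if benchmark == 0:
        raise ParameterError("benchmark must be non-zero")
    obs = list(observations)
    if not obs:
        raise EmptyInputError("no observations")
    ids, values = zip(*obs)
    values = np.asarray(values, dtype=np.float64)
    dev = values - benchmark
    rows = pd.DataFrame({
        "id": ids,
        "value": values,
        "deviation": dev,
        "percent": dev / benchmark * 100.0,
    })
    return DeviationReport(rows, float(benchmark), unit)


def method_agreement(table_a: pd.DataFrame, table_b: pd.DataFrame,
                     trait: str, id_column: str = "leaf"
                     ) -> tuple[pd.Series, float]:
    """Per-item |a − b| for one trait, plus the arithmetic mean.

    Both tables must carry the same ids (e.g. automated vs manual
    measurements of the same leaves).
    """
    a = table_a.set_index(id_column)
    b = table_b.set_index(id_column)
    missing = set(a.index).symmetric_difference(b.index)
    if missing:
        raise ParameterError(f"id mismatch between tables: {sorted(missing)}")
    diffs = (a[trait] - b.loc[a.index, trait]).abs()
    return diffs, float(diffs.mean())


def algorithm_error_report(estimates: pd.DataFrame, benchmark: pd.DataFrame,
                           traits: list[str], id_column: str = "leaf") -> dict:
    """Score an algorithm's per-leaf estimates against benchmark traits.

    Returns ``{"percent": DataFrame of signed percents (1 decimal),
    "mean_abs_percent": {trait: mean of |percent|, 1 decimal}}``. Traits
    missing from the benchmark are skipped with a warning entry.
    """
    est = estimates.set_index(id_column)
    ben = benchmark.set_index(id_column)
    missing_ids = set(est.index) - set(ben.index)
    if missing_ids:
        raise ParameterError(f"estimates contain unknown ids: {sorted(missing_ids)}")
    percent = pd.DataFrame(index=est.index)
    means = {}
    skipped = []
    for trait in traits:
        if trait not in ben.columns or trait not in est.columns:
            skipped.append(trait)
            continue
        pct = (est[trait] - ben.loc[est.index, trait]) / ben.loc[est.index, trait] * 100.0
        percent[trait] = round_half_away(pct.to_numpy(), 1)
        means[trait] = round_half_away(np.abs(pct.to_numpy()).mean(), 1)
    return {"percent": percent, "mean_abs_percent": means, "skipped": skipped}
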