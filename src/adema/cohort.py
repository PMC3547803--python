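"""Cohort tables, configuration, and result I/O.

A cohort is a samples-by-metabolites table of nonnegative concentrations with
a binary class label per sample. Labels are mapped onto the canonical pair
``control`` / ``variable`` (the wild-type and condition groups); by default
the lexicographically first label in the file is treated as control, which the
reader logs — pass ``control_label`` to name it explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .information import CONTROL, VARIABLE

__all__ = ["Cohort", "AdemaConfig", "read_cohort", "results_table", "write_results"]

logger = logging.getLogger("adema")


@dataclass
class Cohort:
    """Concentration matrix plus per-sample class labels.

    values : (n_samples, n_metabolites) nonnegative floats
    labels : per-sample, each ``"control"`` or ``"variable"``
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        n_s, n_m = self.values.shape
        if len(self.sample_ids) != n_s or len(self.metabolite_ids) != n_m:
            raise ValueError("sample/metabolite id lengths do not match values shape")
        if n_m < 1:
            raise ValueError("cohort must contain at least one metabolite")
        if len(set(self.metabolite_ids)) != n_m:
            raise ValueError("metabolite names must be unique")
        if np.isnan(self.values).any():
            raise ValueError("cohort contains missing values")
        bad = set(self.labels) - {CONTROL, VARIABLE}
        if bad:
            raise ValueError(f"unmapped labels: {sorted(bad)}")
        for cls in (CONTROL, VARIABLE):
            if not (self.labels == cls).any():
                raise ValueError(f"cohort has no {cls} samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_metabolites(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.metabolite_ids)
        df.insert(0, "label", self.labels)
        return df


@dataclass
class AdemaConfig:
    """Run parameters.

    M : number of bins (>= 2 for a meaningful analysis)
    k : spline order, in [1, M] — the number of bins an observation can occupy
    max_sub : maximum metabolites per subset (>= 2); larger subsets are split
    strategy : "efm", "neighborhood", "random", or "file"
    n_random_subsets : subset count for the random strategy
    seed : RNG seed (random strategy)
    score_weights : "normalized" (per-class mi-normalized scores) or "raw-mi"
    """

    M: int = 6
    k: int = 3
    max_sub: int = 8
    strategy: str = "efm"
    n_random_subsets: int | None = None
    seed: int = 0
    score_weights: str = "normalized"
    log_base: int = field(default=2, repr=False)  # fixed; binary class I <= 1 bit

    def __post_init__(self) -> None:
        if not (self.M >= self.k >= 1):
            raise ValueError(f"require M >= k >= 1, got M={self.M}, k={self.k}")
        if self.max_sub < 2:
            raise ValueError("max_sub must be >= 2")
        if self.log_base != 2:
            raise ValueError("only base-2 logarithms are supported")


def read_cohort(
    path: str | Path,
    label_column: str = "label",
    control_label: str | None = None,
    sep: str | None = None,
) -> Cohort:
    """Read a delimited cohort table (header row; one row per sample).

    The first column is used as the sample id when unnamed or non-numeric id
    column; all columns except ``label_column`` must be numeric metabolite
    concentrations. The label column must contain exactly two distinct
    values; ``control_label`` names which maps to control (default:
    lexicographically first, logged).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, engine="python")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    first = df.columns[0]
    if first != label_column and not pd.api.types.is_numeric_dtype(df[first]):
        df = df.set_index(first)
    labels_raw = df[label_column].astype(str)
    values = df.drop(columns=[label_column])
    distinct = sorted(labels_raw.unique())
    if len(distinct) != 2:
        raise ValueError(
            f"label column must have exactly two distinct values, found {distinct}"
        )
    if control_label is None:
        control_label = distinct[0]
        logger.info("control label defaulted to %r (vs %r)", control_label, distinct[1])
    elif control_label not in distinct:
        raise ValueError(f"control label {control_label!r} not among {distinct}")
    labels = np.where(labels_raw == control_label, CONTROL, VARIABLE)
    if values.isna().any().any():
        rows, cols = np.nonzero(values.isna().to_numpy())
        raise ValueError(
            f"missing value at row {values.index[rows[0]]!r}, "
            f"column {values.columns[cols[0]]!r}"
        )
    for c in values.columns:
        if not pd.api.types.is_numeric_dtype(values[c]):
            bad = values[~values[c].apply(lambda x: isinstance(x, (int, float)))].index
            raise ValueError(
                f"non-numeric cell in column {c!r}"
                + (f", row {bad[0]!r}" if len(bad) else "")
            )
    return Cohort(
        sample_ids=[str(s) for s in values.index],
        metabolite_ids=[str(c) for c in values.columns],
        values=values.to_numpy(dtype=float),
        labels=labels,
    )


def results_table(levels) -> pd.DataFrame:
    """Render an :class:`~adema.information.ExpectedLevels` as a table with
    columns metabolite, control_bin, variable_bin, delta, direction."""
    rows = []
    for m in levels.metabolites:
        if m in levels.uncovered:
            continue
        rows.append(
            {
                "metabolite": m,
                "control_bin": levels.control_bins[m],
                "variable_bin": levels.variable_bins[m],
                "delta": levels.delta(m),
                "direction": levels.direction(m),
            }
        )
    return pd.DataFrame(
        rows, columns=["metabolite", "control_bin", "variable_bin", "delta", "direction"]
    )


def write_results(table: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a results table as delimited text with exact integer formatting."""
    table.to_csv(path, sep=sep, index=False)
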