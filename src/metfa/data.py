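"""Domain types and delimited-text I/O for multi-environment trial (MET) data.

A MET dataset is a collection of field trials ("environments", unique
year-location combinations), each laid out as a rectangular column x row
grid of plots.  Every plot carries a trial, a genotype (entry), a replicate
block, integer field coordinates and a yield (t/ha, possibly missing).
Plot coordinates are 1-based at the I/O boundary and 0-based internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlotRecord",
    "TrialDesign",
    "METDataset",
    "METValidationError",
    "read_met_csv",
    "write_met_csv",
    "concurrence_matrix",
    "sort_rows_within_columns",
]

REQUIRED_COLUMNS = ("trial", "genotype", "replicate", "column", "row", "yield")


class METValidationError(ValueError):
    """Raised when a MET table violates a structural invariant."""


@dataclass(frozen=True)
class PlotRecord:
    """One field plot: trial, genotype, replicate block, grid position, yield.

    ``column`` and ``row`` are 1-based grid coordinates; ``yield_value`` is
    grain yield in t/ha or None for a missing observation.
    """

    trial: str
    genotype: str
    replicate: str
    column: int
    row: int
    yield_value: float | None


@dataclass(frozen=True)
class TrialDesign:
    """Layout of one trial: grid dimensions, entry list, replicate count."""

    trial: str
    n_cols: int
    n_rows: int
    entries: tuple[str, ...]
    n_reps: int

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise METValidationError(
                f"trial {self.trial!r}: grid dimensions must be >= 1"
            )
        if self.n_reps < 2:
            raise METValidationError(
                f"trial {self.trial!r}: at least two replicates per entry are "
                f"required (got {self.n_reps})"
            )

    @property
    def n_plots(self) -> int:
        return self.n_cols * self.n_rows


@dataclass
class METDataset:
    """Validated plot records plus per-trial layouts.

    Invariants enforced at construction: every record's trial has a design,
    every record's genotype belongs to that trial's entry list, coordinates
    lie inside the grid, and (trial, column, row) is unique.
    """

    trials: list[TrialDesign]
    records: list[PlotRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        designs = {t.trial: t for t in self.trials}
        if len(designs) != len(self.trials):
            raise METValidationError("duplicate trial identifiers in designs")
        seen: dict[tuple[str, int, int], int] = {}
        for i, r in enumerate(self.records):
            if r.trial not in designs:
                raise METValidationError(f"record {i}: unknown trial {r.trial!r}")
            d = designs[r.trial]
            if r.genotype not in d.entries:
                raise METValidationError(
                    f"record {i}: genotype {r.genotype!r} not an entry of "
                    f"trial {r.trial!r}"
                )
            if not (1 <= r.column <= d.n_cols) or not (1 <= r.row <= d.n_rows):
                raise METValidationError(
                    f"record {i}: plot ({r.column}, {r.row}) outside the "
                    f"{d.n_cols} x {d.n_rows} grid of trial {r.trial!r}"
                )
            key = (r.trial, r.column, r.row)
            if key in seen:
                raise METValidationError(
                    f"duplicate plot {key}: records {seen[key]} and {i}"
                )
            seen[key] = i

    @property
    def design_by_trial(self) -> dict[str, TrialDesign]:
        return {t.trial: t for t in self.trials}

    @property
    def trial_names(self) -> list[str]:
        return [t.trial for t in self.trials]

    @property
    def genotypes(self) -> list[str]:
        """Union of entries across trials, in first-appearance order."""
        out: list[str] = []
        seen: set[str] = set()
        for t in self.trials:
            for g in t.entries:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out

    def records_for(self, trial: str) -> list[PlotRecord]:
        return [r for r in self.records if r.trial == trial]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": [r.trial for r in self.records],
                "genotype": [r.genotype for r in self.records],
                "replicate": [r.replicate for r in self.records],
                "column": [r.column for r in self.records],
                "row": [r.row for r in self.records],
                "yield": [r.yield_value for r in self.records],
            }
        )


def concurrence_matrix(d: METDataset) -> np.ndarray:
    """Shared-entry counts between trial pairs.

    Entry (j, k) is the number of genotypes common to trials j and k; the
    diagonal is each trial's entry count.  High concurrence is what makes
    the between-trial genetic covariance estimable.
    """
    if not d.trials:
        raise METValidationError("concurrence requires at least one trial")
    sets = [set(t.entries) for t in d.trials]
    t = len(sets)
    out = np.zeros((t, t), dtype=int)
    for j in range(t):
        for k in range(t):
            out[j, k] = len(sets[j] & sets[k])
    return out


def sort_rows_within_columns(d: METDataset, trial: str) -> np.ndarray:
    """Column-major plot ordering (row varies fastest within each column).

    Returns an integer vector of length n_cols * n_rows whose entry at grid
    slot (c, r) — slot index (c-1)*n_rows + (r-1) — is the index of the
    record occupying that plot, or -1 for a missing (unplanted) plot.  This
    ordering is what makes a separable column x row covariance a Kronecker
    product Sigma_c (x) Sigma_r.
    """
    design = d.design_by_trial.get(trial)
    if design is None:
        raise METValidationError(f"unknown trial {trial!r}")
    order = np.full(design.n_plots, -1, dtype=int)
    for i, r in enumerate(d.records):
        if r.trial == trial:
            order[(r.column - 1) * design.n_rows + (r.row - 1)] = i
    return order


def _parse_positive_int(value, what: str, line: int) -> int:
    try:
        iv = int(value)
    except (TypeError, ValueError):
        raise METValidationError(f"line {line}: {what} {value!r} is not an integer")
    if iv < 1:
        raise METValidationError(f"line {line}: {what} must be >= 1, got {iv}")
    return iv


def read_met_csv(
    path,
    column_map: Mapping[str, str] | None = None,
    layouts: Mapping[str, tuple[int, int]] | None = None,
    layout_json: str | None = None,
    missing_token: str = "NA",
    sep: str = ",",
) -> METDataset:
    """Read a plot-level MET table from delimited text.

    Parameters
    ----------
    path : file path
    column_map : optional mapping from required names (trial, genotype,
        replicate, column, row, yield) to the names used in the file.
    layouts : optional {trial: (n_cols, n_rows)}; inferred as the maximum
        observed column/row per trial when absent.
    layout_json : optional path to a JSON sidecar {trial: [n_cols, n_rows]}.
    missing_token : string marking a missing yield (default "NA").
    """
    column_map = dict(column_map or {})
    names = {k: column_map.get(k, k) for k in REQUIRED_COLUMNS}
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing_cols = [v for v in names.values() if v not in df.columns]
    if missing_cols:
        raise METValidationError(f"missing required columns: {missing_cols}")
    if len(df) == 0:
        raise METValidationError("no records")

    if layout_json is not None:
        with open(layout_json) as fh:
            layouts = {k: tuple(v) for k, v in json.load(fh).items()}

    records: list[PlotRecord] = []
    per_trial: dict[str, dict] = {}
    dup_check: dict[tuple[str, int, int], int] = {}
    for idx, rec in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, rec))
        line = idx + 2  # header on line 1
        trial = str(row_d[names["trial"]])
        genotype = str(row_d[names["genotype"]])
        replicate = str(row_d[names["replicate"]])
        col = _parse_positive_int(row_d[names["column"]], "column", line)
        row = _parse_positive_int(row_d[names["row"]], "row", line)
        raw_y = str(row_d[names["yield"]]).strip()
        if raw_y == missing_token or raw_y == "":
            y: float | None = None
        else:
            try:
                y = float(raw_y)
            except ValueError:
                raise METValidationError(
                    f"line {line}: yield {raw_y!r} is neither numeric nor the "
                    f"missing token {missing_token!r}"
                )
        key = (trial, col, row)
        if key in dup_check:
            raise METValidationError(
                f"duplicate plot {key}: lines {dup_check[key]} and {line}"
            )
        dup_check[key] = line
        records.append(PlotRecord(trial, genotype, replicate, col, row, y))
        info = per_trial.setdefault(
            trial, {"cols": 0, "rows": 0, "entries": [], "reps": set()}
        )
        info["cols"] = max(info["cols"], col)
        info["rows"] = max(info["rows"], row)
        if genotype not in info["entries"]:
            info["entries"].append(genotype)
        info["reps"].add(replicate)

    trials = []
    for trial, info in per_trial.items():
        n_cols, n_rows = info["cols"], info["rows"]
        if layouts and trial in layouts:
            n_cols, n_rows = layouts[trial]
        trials.append(
            TrialDesign(
                trial=trial,
                n_cols=n_cols,
                n_rows=n_rows,
                entries=tuple(info["entries"]),
                n_reps=len(info["reps"]),
            )
        )
    return METDataset(trials=trials, records=records)


def write_met_csv(
    d: METDataset, path, missing_token: str = "NA", sep: str = ","
) -> None:
    """Write a dataset back to delimited text (round-trips with read_met_csv)."""
    with open(path, "w") as fh:
        fh.write(sep.join(REQUIRED_COLUMNS) + "\n")
        for r in d.records:
            y = missing_token if r.yield_value is None else repr(r.yield_value)
            fh.write(
                sep.join(
                    [r.trial, r.genotype, r.replicate, str(r.column), str(r.row), y]
                )
                + "\n"
            )


def write_layout_json(d: METDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {t.trial: [t.n_cols, t.n_rows] for t in d.trials}, fh, indent=1
        )
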