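"""Reading, writing and summarizing trial tables.

Trial tables are tab-separated text with a fixed header::

    trial_id  first_species  second_species  n_offered  emerged_first  emerged_second  n_unparasitized

``second_species`` is ``NA`` (or empty) for single-species baselines.
Species labels are free strings; they are mapped to internal indices
1/2 in order of a caller-supplied pair or of first appearance.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .inference import Trial

TRIAL_COLUMNS = [
    "trial_id",
    "first_species",
    "second_species",
    "n_offered",
    "emerged_first",
    "emerged_second",
    "n_unparasitized",
]


def write_trials(table: pd.DataFrame, path: str | Path) -> None:
    """Write a trial table as TSV with the canonical column order."""
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trial table lacks columns: {missing}")
    table[TRIAL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`.

    The literal ``NA`` marking single-species baselines is kept as a
    string in ``second_species`` (it is a category, not a missing value).
    """
    table = pd.read_csv(path, sep="\t", dtype={"trial_id": str}, keep_default_na=False, na_values=[""])
    for col in ("n_offered", "emerged_first", "emerged_second", "n_unparasitized"):
        if col in table.columns:
            table[col] = pd.to_numeric(table[col], errors="coerce").astype("int64")
    missing = [c for c in TRIAL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: trial table lacks columns: {missing}")
    return table


def species_labels(table: pd.DataFrame) -> tuple[str, str]:
    """The two species labels of a table, in order of first appearance."""
    seen: list[str] = []
    for col in ("first_species", "second_species"):
        for v in table[col]:
            if isinstance(v, str) and v != "NA" and v not in seen:
                seen.append(v)
    if len(seen) != 2:
        raise ValueError(f"expected exactly two species labels, found {seen}")
    return seen[0], seen[1]


def table_to_trials(table: pd.DataFrame, labels: tuple[str, str] | None = None) -> list[Trial]:
    """Convert a trial table to :class:`~igparasitoid.inference.Trial` objects."""
    if labels is None:
        labels = species_labels(table)
    index = {labels[0]: 1, labels[1]: 2}
    trials = []
    for row in table.itertuples(index=False):
        second = row.second_species
        is_single = not isinstance(second, str) or second == "NA" or second == ""
        trials.append(
            Trial(
                trial_id=str(row.trial_id),
                first=index[row.first_species],
                second=None if is_single else index[second],
                n_offered=int(row.n_offered),
                emerged_first=int(row.emerged_first),
                emerged_second=int(row.emerged_second),
                n_unparasitized=None if pd.isna(row.n_unparasitized) else int(row.n_unparasitized),
            )
        )
    return trials


def summarize_emergence(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-protocol parasitism percentages from aggregate counts.

    ``counts`` needs columns first, second, exposed, emerged_first,
    emerged_second (one row per protocol).  Percentages are
    100 × emerged / exposed, printed at 2 decimals.
    """
    out = counts.copy()
    out["pct_first"] = (100.0 * out["emerged_first"] / out["exposed"]).round(2)
    out["pct_second"] = np.where(
        out["second"].isna(),
        np.nan,
        (100.0 * out["emerged_second"] / out["exposed"]).round(2),
    )
    # the total column is the sum of the per-species percentages as printed
    out["pct_total"] = (out["pct_first"] + out["pct_second"].fillna(0.0)).round(2)
    return out


def aggregate_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a trial table into per-protocol aggregate counts."""
    t = table.copy()
    t["second_species"] = t["second_species"].where(
        t["second_species"].apply(lambda v: isinstance(v, str) and v not in ("", "NA")), np.nan
    )
    grouped = (
        t.groupby(["first_species", "second_species"], dropna=False)
        .agg(
            exposed=("n_offered", "sum"),
            emerged_first=("emerged_first", "sum"),
            emerged_second=("emerged_second", "sum"),
        )
        .reset_index()
        .rename(columns={"first_species": "first", "second_species": "second"})
    )
    return grouped


def report_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a trial table and attach parasitism percentages."""
    return summarize_emergence(aggregate_trials(table))


def trials_from_file(path: str | Path) -> tuple[list[Trial], tuple[str, str]]:
    """Read a trial table and return trials plus the species-label pair."""
    table = read_trials(path)
    labels = species_labels(table)
    return table_to_trials(table, labels), labels
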