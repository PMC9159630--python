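"""Reading and writing the three tabular schemas, and bundled examples.

Three CSV layouts are supported, all with required headers and integer
counts:

* trials — one row per two-arm trial, columns ``e0,n0,e1,n1``;
* meta-analyses — as trials with a leading ``ma.id`` column grouping rows
  into meta-analyses (groups split in order of first appearance);
* networks — long format, one row per arm, columns ``sid,tid,e,n``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .meta import MADataset
from .nma import ArmRecord, NMADataset
from .tables import TwoByTwoTable

__all__ = [
    "read_trials",
    "read_ma",
    "read_nma",
    "write_trials",
    "write_ma",
    "write_nma",
    "load_example",
    "EXAMPLES",
]

#: Names accepted by :func:`load_example`.
EXAMPLES = ("copd", "ad_head", "ns_head", "sc_head")


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for c in required:
        col = pd.to_numeric(df[c], errors="coerce")
        bad = df.index[col.isna() | (col != col.round())]
        if len(bad):
            raise ValueError(f"{path}: non-integer value in column {c!r}, row {bad[0] + 2}")
        df[c] = col.astype(int)
    return df


def _tables_from_frame(df: pd.DataFrame, path) -> list[TwoByTwoTable]:
    tables = []
    for idx, row in df.iterrows():
        try:
            tables.append(TwoByTwoTable(row["e0"], row["n0"], row["e1"], row["n1"]))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from None
    return tables


def read_trials(path) -> list[TwoByTwoTable]:
    """Wide per-trial schema: columns e0, n0, e1, n1."""
    df = _read_csv(path, ("e0", "n0", "e1", "n1"))
    return _tables_from_frame(df, path)


def read_ma(path) -> list[MADataset]:
    """Meta-analysis schema: ma.id, e0, n0, e1, n1; one dataset per ma.id."""
    df = _read_csv(path, ("ma.id", "e0", "n0", "e1", "n1"))
    out = []
    for _, grp in df.groupby("ma.id", sort=False):
        out.append(MADataset(studies=tuple(_tables_from_frame(grp.reset_index(drop=True), path))))
    return out


def read_nma(path) -> NMADataset:
    """Long arm-level schema: sid, tid, e, n."""
    df = _read_csv(path, ("sid", "tid", "e", "n"))
    arms = []
    for idx, row in df.iterrows():
        try:
            arms.append(ArmRecord(row["sid"], row["tid"], row["e"], row["n"]))
        except ValueError as exc:
            raise ValueError(f"{path}: row {idx + 2}: {exc}") from None
    try:
        return NMADataset(tuple(arms))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from None


def write_trials(tables: list[TwoByTwoTable], path) -> None:
    pd.DataFrame(
        [{"e0": t.e0, "n0": t.n0, "e1": t.e1, "n1": t.n1} for t in tables]
    ).to_csv(path, index=False)


def write_ma(datasets: list[MADataset], path) -> None:
    rows = []
    for i, d in enumerate(datasets, start=1):
        for t in d.studies:
            rows.append({"ma.id": i, "e0": t.e0, "n0": t.n0, "e1": t.e1, "n1": t.n1})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_nma(dataset: NMADataset, path) -> None:
    pd.DataFrame(
        [{"sid": a.sid, "tid": a.tid, "e": a.e, "n": a.n} for a in dataset.arms]
    ).to_csv(path, index=False)


def load_example(name: str):
    """Load a bundled example dataset by name.

    ``copd`` and ``sc_head`` are arm-level networks, ``ad_head`` a list of
    trials, ``ns_head`` a list of meta-analyses (see datasets/PROVENANCE.md
    for the clinical sources).
    """
    if name not in EXAMPLES:
        raise KeyError(f"unknown example {name!r}; choose from {EXAMPLES}")
    ref = resources.files("fragility.datasets") / f"{name}.csv"
    with resources.as_file(ref) as path:
        if name in ("copd", "sc_head"):
            return read_nma(path)
        if name == "ad_head":
            return read_trials(path)
        return read_ma(path)


def example_path(name: str) -> Path:
    """Filesystem path of a bundled example CSV (for CLI/tests)."""
    if name not in EXAMPLES:
        raise KeyError(f"unknown example {name!r}; choose from {EXAMPLES}")
    with resources.as_file(resources.files("fragility.datasets") / f"{name}.csv") as p:
        return Path(p)
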