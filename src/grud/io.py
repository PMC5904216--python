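"""Long-format CSV input/output.

One observation per row: ``sample_id,time,variable,value``.  Irregular
sampling makes a wide layout ill-defined (different samples observe
different variables at different times), so the tidy long layout is the one
interchange format; e.g. a sample observing heart rate at t=0 and t=2.5 and
glucose at t=2.5 occupies three rows.  Labels travel in a separate
``sample_id,label[,label...]`` CSV.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import Dataset, TimeSeriesSample, build_mask

__all__ = ["read_long_csv", "write_long_csv", "read_labels_csv", "write_labels_csv"]

_COLUMNS = ["sample_id", "time", "variable", "value"]


def read_long_csv(path, variables: list[str] | None = None) -> Dataset:
    """Parse a long-format observation file into an (unlabeled) Dataset.

    Per sample, the union of its observation times becomes the stamp vector,
    shifted so the first stamp is 0.  Duplicate (sample, time, variable)
    rows are rejected — the data model has no defined semantics for them.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    if df.empty:
        raise ValueError("empty dataset file")
    dup = df.duplicated(subset=["sample_id", "time", "variable"])
    if dup.any():
        lines = (np.flatnonzero(dup) + 2).tolist()  # header is line 1
        raise ValueError(f"duplicate (sample_id, time, variable) at lines {lines}")
    if variables is None:
        variables = sorted(df["variable"].unique())
    else:
        unknown = set(df["variable"]) - set(variables)
        if unknown:
            raise ValueError(f"unknown variables: {sorted(unknown)}")
    var_index = {v: d for d, v in enumerate(variables)}
    samples = []
    for sid, group in df.groupby("sample_id", sort=True):
        times = np.sort(group["time"].unique())
        t_index = {t: i for i, t in enumerate(times)}
        raw = np.full((len(times), len(variables)), np.nan)
        for _, row in group.iterrows():
            raw[t_index[row["time"]], var_index[row["variable"]]] = row["value"]
        values, mask = build_mask(raw)
        samples.append(
            TimeSeriesSample(values=values, mask=mask,
                             stamps=times - times[0], sample_id=sid)
        )
    return Dataset(samples=samples, variable_names=list(variables))


def write_long_csv(dataset: Dataset, path) -> None:
    """Serialize observed entries only, full float precision."""
    rows = []
    for s in dataset.samples:
        for t in range(s.T):
            for d in range(s.D):
                if s.mask[t, d] == 1:
                    rows.append(
                        (s.sample_id, repr(float(s.stamps[t])),
                         dataset.variable_names[d], repr(float(s.values[t, d])))
                    )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_labels_csv(path, sample_ids: list) -> np.ndarray:
    """Labels aligned to ``sample_ids``; multi-column files give an N x n matrix."""
    df = pd.read_csv(path).set_index("sample_id")
    missing = [sid for sid in sample_ids if sid not in df.index]
    if missing:
        raise ValueError(f"labels missing for samples: {missing[:5]}")
    arr = df.loc[list(sample_ids)].to_numpy()
    return arr[:, 0] if arr.shape[1] == 1 else arr


def write_labels_csv(dataset: Dataset, path) -> None:
    labels = np.atleast_2d(np.asarray(dataset.labels))
    if labels.shape[0] == 1:
        labels = labels.T
    cols = ["label"] if labels.shape[1] == 1 else [
        f"label{j}" for j in range(labels.shape[1])
    ]
    df = pd.DataFrame(labels, columns=cols)
    df.insert(0, "sample_id", [s.sample_id for s in dataset.samples])
    df.to_csv(path, index=False)
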