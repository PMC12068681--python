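"""Diary panel container and delimited-text I/O.

A :class:`DiaryPanel` holds a rectangular subjects x days x items array of
continuous symptom scores on a 0-100 scale, an optional block of 0-7
auxiliary items (rarely endorsed perceptual-disturbance items that are not
modelled but cross-tabulated post hoc), and a per-subject severity subgroup
label.  Days a subject did not complete are represented as rows of NaN, so
every subject spans the same 1..T day index.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DiaryPanel",
    "ColumnMap",
    "read_diary_long",
    "write_diary_long",
    "write_results",
    "read_sequences",
]


@dataclasses.dataclass
class DiaryPanel:
    """Subjects x days x items diary observations.

    Parameters
    ----------
    y : ndarray, shape (N, T, q)
        Continuous item scores; NaN marks a missing observation.  Days are
        implicitly indexed 1..T for every subject.
    subject_ids : sequence of str
        One label per subject.
    item_names : sequence of str
        One label per modelled item.
    subgroup : ndarray, shape (N,)
        Per-subject categorical severity label, constant within subject.
    aux : ndarray, shape (N, T, a), optional
        Auxiliary 0-7 items (e.g. hallucination items) kept out of the HMM.
    aux_names : sequence of str, optional
    """

    y: np.ndarray
    subject_ids: Sequence[str]
    item_names: Sequence[str]
    subgroup: np.ndarray
    aux: np.ndarray | None = None
    aux_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if self.y.ndim != 3:
            raise ValueError("y must have shape (N, T, q)")
        n, t, q = self.y.shape
        if q < 1 or t < 2:
            raise ValueError("need q >= 1 items and T >= 2 days")
        if len(self.subject_ids) != n or len(self.item_names) != q:
            raise ValueError("subject_ids/item_names do not match y")
        self.subject_ids = list(map(str, self.subject_ids))
        self.item_names = list(map(str, self.item_names))
        self.subgroup = np.asarray(self.subgroup)
        if self.subgroup.shape != (n,):
            raise ValueError("subgroup must have one entry per subject")
        obs = self.y[~np.isnan(self.y)]
        if obs.size and not np.all(np.isfinite(obs)):
            raise ValueError("non-missing scores must be finite")
        if self.aux is not None:
            self.aux = np.asarray(self.aux, dtype=float)
            if self.aux.shape[:2] != (n, t):
                raise ValueError("aux must align with y on (N, T)")
            if self.aux_names is None:
                self.aux_names = [f"aux{j + 1}" for j in range(self.aux.shape[2])]
            self.aux_names = list(map(str, self.aux_names))

    @property
    def n_subjects(self) -> int:
        return self.y.shape[0]

    @property
    def n_days(self) -> int:
        return self.y.shape[1]

    @property
    def n_items(self) -> int:
        return self.y.shape[2]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (N, T, q); True where the observation is missing."""
        return np.isnan(self.y)

    @property
    def day_missing(self) -> np.ndarray:
        """Boolean (N, T); True where every modelled item is missing."""
        return np.isnan(self.y).all(axis=2)

    def subset_items(self, names: Sequence[str]) -> "DiaryPanel":
        """Return a panel restricted to the modelled items in ``names``."""
        idx = [self.item_names.index(n) for n in names]
        return DiaryPanel(
            y=self.y[:, :, idx],
            subject_ids=self.subject_ids,
            item_names=[self.item_names[i] for i in idx],
            subgroup=self.subgroup.copy(),
            aux=None if self.aux is None else self.aux.copy(),
            aux_names=None if self.aux_names is None else list(self.aux_names),
        )


@dataclasses.dataclass
class ColumnMap:
    """How a delimited diary export maps onto panel fields.

    Wide layout (default): one row per subject-day, one column per item.
    Tidy layout: one row per subject-day-item with ``item``/``value`` columns.
    """

    subject: str = "subject"
    day: str = "day"
    subgroup: str = "subgroup"
    items: Sequence[str] | None = None
    aux_items: Sequence[str] | None = None
    item: str | None = None   # tidy layout: column holding the item name
    value: str | None = None  # tidy layout: column holding the score
    missing_code: str | float | None = None


def _coerce_numeric(col: pd.Series, missing_code, context: str) -> pd.Series:
    if missing_code is not None:
        col = col.mask(col.astype(str) == str(missing_code))
    out = pd.to_numeric(col, errors="coerce")
    bad = out.isna() & col.notna()
    if bad.any():
        raise ValueError(f"non-numeric value {col[bad].iloc[0]!r} in {context}")
    return out


def read_diary_long(path: str | Path, spec: ColumnMap | None = None) -> DiaryPanel:
    """Read a delimited diary file into a :class:`DiaryPanel`.

    Day gaps are materialised as all-missing rows so every subject covers
    the full 1..T range.  Duplicate subject-day rows raise.
    """
    spec = spec or ColumnMap()
    df = pd.read_csv(path, dtype={spec.subject: str},
                     float_precision="round_trip")

    if spec.item is not None and spec.value is not None:
        wide = df.pivot_table(
            index=[spec.subject, spec.day, spec.subgroup],
            columns=spec.item,
            values=spec.value,
            aggfunc="first",
        ).reset_index()
        counts = df.groupby([spec.subject, spec.day, spec.item]).size()
        if (counts > 1).any():
            s, d, _ = counts[counts > 1].index[0]
            raise ValueError(f"duplicate subject-day: subject {s} day {d}")
        df = wide
        items = spec.items or [c for c in wide.columns
                               if c not in (spec.subject, spec.day, spec.subgroup)]
    else:
        items = spec.items
        if items is None:
            items = [c for c in df.columns
                     if c not in (spec.subject, spec.day, spec.subgroup)
                     and c not in (spec.aux_items or [])]

    dup = df.duplicated(subset=[spec.subject, spec.day])
    if dup.any():
        row = df.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate subject-day: subject {row[spec.subject]} day {row[spec.day]}"
        )

    df = df.copy()
    df[spec.day] = _coerce_numeric(df[spec.day], None, "day column").astype(int)
    t_max = int(df[spec.day].max())
    subjects = list(dict.fromkeys(df[spec.subject]))
    aux_items = list(spec.aux_items or [])

    n, q, a = len(subjects), len(items), len(aux_items)
    y = np.full((n, t_max, q), np.nan)
    aux = np.full((n, t_max, a), np.nan) if a else None
    subgroup = np.empty(n, dtype=object)

    for j, sid in enumerate(subjects):
        block = df[df[spec.subject] == sid]
        groups = block[spec.subgroup].unique()
        if len(groups) != 1:
            raise ValueError(f"subgroup not constant within subject {sid}")
        subgroup[j] = groups[0]
        days = block[spec.day].to_numpy() - 1
        for k, name in enumerate(items):
            vals = _coerce_numeric(block[name], spec.missing_code, f"item {name}")
            y[j, days, k] = vals.to_numpy()
        for k, name in enumerate(aux_items):
            vals = _coerce_numeric(block[name], spec.missing_code, f"aux item {name}")
            aux[j, days, k] = vals.to_numpy()

    try:
        subgroup = subgroup.astype(int)
    except (ValueError, TypeError):
        subgroup = subgroup.astype(str)
    return DiaryPanel(y=y, subject_ids=subjects, item_names=list(items),
                      subgroup=subgroup, aux=aux,
                      aux_names=aux_items or None)


def write_diary_long(panel: DiaryPanel, path: str | Path) -> None:
    """Write a panel back to wide-layout CSV (inverse of :func:`read_diary_long`)."""
    n, t, _ = panel.y.shape
    rows = {
        "subject": np.repeat(panel.subject_ids, t),
        "day": np.tile(np.arange(1, t + 1), n),
        "subgroup": np.repeat(panel.subgroup, t),
    }
    for k, name in enumerate(panel.item_names):
        rows[name] = panel.y[:, :, k].ravel()
    if panel.aux is not None:
        for k, name in enumerate(panel.aux_names):
            rows[name] = panel.aux[:, :, k].ravel()
    # 17 significant digits keeps the float64 round trip bit-exact
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_results(summary: pd.DataFrame,
                  sequences,
                  outdir: str | Path,
                  metadata: dict | None = None) -> dict[str, Path]:
    """Write fit outputs: parameter summary, decoded sequences, run metadata.

    ``sequences`` is an iterable of :class:`~diaryhmm.hmm.StateSequence`.
    Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["summary"] = outdir / "parameter_summary.csv"
    summary.to_csv(paths["summary"], index=False)

    recs = []
    for seq in sequences:
        for t, s in enumerate(seq.states, start=1):
            recs.append((seq.subject_id, t, int(s)))
    paths["sequences"] = outdir / "state_sequences.csv"
    pd.DataFrame(recs, columns=["subject", "day", "state"]).to_csv(
        paths["sequences"], index=False)

    paths["metadata"] = outdir / "run_metadata.json"
    with open(paths["metadata"], "w") as fh:
        json.dump(metadata or {}, fh, indent=2, default=str)
    return paths


def read_sequences(path: str | Path) -> pd.DataFrame:
    """Read back a state-sequence CSV written by :func:`write_results`."""
    return pd.read_csv(path, dtype={"subject": str})
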