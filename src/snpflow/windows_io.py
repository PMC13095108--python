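"""Longitudinal visit-table I/O and sliding-window construction.

Reads TADPOLE-style CSVs (one row per patient visit: roster id, exam date,
eleven numeric cognitive/MRI features, and a CN/MCI/AD diagnosis), applies
a missing-data policy, standardizes features on the training split only,
and reshapes each patient's date-sorted visit sequence into sliding
windows of k consecutive (features, label) pairs whose target is the
immediately following visit's label. A patient with V visits therefore
yields max(0, V - k) windows; patients with fewer than k+1 visits yield
none. Train/test splitting is at the patient level (all windows of a
patient land on one side) to keep overlapping visit windows from leaking
across the split.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The eleven modelling features, in canonical column order.
FEATURE_COLUMNS = [
    "CDRSB", "ADAS11", "ADAS13", "MMSE", "RAVLT_immediate", "FAQ",
    "Ventricles", "Hippocampus", "WholeBrain", "Entorhinal", "MidTemp",
]

ID_COLUMN = "RID"
DATE_COLUMN = "EXAMDATE"
DX_COLUMN = "DX"

#: Diagnosis string -> ordinal class. CN=0, MCI=1, AD=2.
DX_MAP = {
    "CN": 0, "NL": 0,
    "MCI": 1, "EMCI": 1, "LMCI": 1,
    "AD": 2, "DEMENTIA": 2,
}

CLASS_NAMES = ["CN", "MCI", "AD"]


@dataclass
class VisitRecord:
    """One patient visit: id, date, 11-feature vector (may hold NaN), label."""

    patient_id: str
    exam_date: date
    features: np.ndarray
    label: int

    def __post_init__(self):
        self.features = np.asarray(self.features, dtype=np.float64)
        if self.label not in (0, 1, 2):
            raise ValueError(f"label must be 0 (CN), 1 (MCI) or 2 (AD), got {self.label}")


@dataclass
class WindowSample:
    """k consecutive (features, label) context pairs plus the next visit's label."""

    patient_id: str
    window_start_index: int
    context_features: np.ndarray  # (k, F)
    context_labels: np.ndarray    # (k,)
    target_label: int
    target_features: Optional[np.ndarray] = None  # used only by the training-time posterior pass
    context_dates: Optional[List[date]] = None
    target_date: Optional[date] = None

    @property
    def k(self) -> int:
        return self.context_features.shape[0]


class Standardizer:
    """Per-feature z-scoring fitted on training rows only (no test leakage)."""

    def __init__(self):
        self.mean_: Optional[np.ndarray] = None
        self.std_: Optional[np.ndarray] = None

    def fit(self, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean_ = np.nanmean(X, axis=0)
        std = np.nanstd(X, axis=0, ddof=0)
        self.std_ = np.where(std < 1e-12, 1.0, std)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean_) / self.std_

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise RuntimeError("Standardizer not fitted")
        return np.asarray(Z, dtype=np.float64) * self.std_ + self.mean_


def read_visits(path, columns: Optional[Dict[str, str]] = None) -> List[VisitRecord]:
    """Parse a visit CSV into date-sorted per-patient :class:`VisitRecord` lists.

    ``columns`` optionally remaps the canonical names (RID, EXAMDATE, DX and
    the 11 features) to the file's actual headers. Rows whose diagnosis
    string cannot be mapped to CN/MCI/AD, or whose date fails to parse, are
    dropped with a logged count. Missing feature cells are kept as NaN for
    the missing-data policy to handle.
    """
    colmap = {c: c for c in [ID_COLUMN, DATE_COLUMN, DX_COLUMN] + FEATURE_COLUMNS}
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, dtype={colmap[ID_COLUMN]: str})
    missing = [colmap[c] for c in colmap if colmap[c] not in df.columns]
    if missing:
        raise ValueError(f"CSV is missing mandatory columns: {missing}")

    dates = pd.to_datetime(df[colmap[DATE_COLUMN]], errors="coerce")
    n_bad_date = int(dates.isna().sum())
    dx = df[colmap[DX_COLUMN]].astype(str).str.strip().str.upper().map(DX_MAP)
    n_bad_dx = int(dx.isna().sum())
    keep = (~dates.isna()) & (~dx.isna())
    if n_bad_date:
        logger.warning("dropped %d rows with unparseable EXAMDATE", n_bad_date)
    if n_bad_dx:
        logger.warning("dropped %d rows with unmappable DX", n_bad_dx)

    feat_cols = [colmap[c] for c in FEATURE_COLUMNS]
    records: List[VisitRecord] = []
    sub = df.loc[keep]
    feats = sub[feat_cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=np.float64)
    for (pid, d, y), x in zip(
        zip(sub[colmap[ID_COLUMN]], dates[keep], dx[keep].astype(int)), feats
    ):
        records.append(VisitRecord(str(pid), d.date(), x, int(y)))

    records.sort(key=lambda r: (r.patient_id, r.exam_date))
    deduped: List[VisitRecord] = []
    for r in records:
        if deduped and deduped[-1].patient_id == r.patient_id and deduped[-1].exam_date == r.exam_date:
            logger.warning("dropped duplicate visit for %s at %s", r.patient_id, r.exam_date)
            continue
        deduped.append(r)
    return deduped


def write_visits(visits: Sequence[VisitRecord], path,
                 columns: Optional[Dict[str, str]] = None) -> None:
    """Write visits back to the same CSV dialect read_visits parses."""
    colmap = {c: c for c in [ID_COLUMN, DATE_COLUMN, DX_COLUMN] + FEATURE_COLUMNS}
    if columns:
        colmap.update(columns)
    inv_dx = {0: "CN", 1: "MCI", 2: "AD"}
    rows = []
    for v in visits:
        row = {colmap[ID_COLUMN]: v.patient_id,
               colmap[DATE_COLUMN]: v.exam_date.isoformat(),
               colmap[DX_COLUMN]: inv_dx[v.label]}
        for name, val in zip(FEATURE_COLUMNS, v.features):
            row[colmap[name]] = "" if np.isnan(val) else val
        rows.append(row)
    order = [colmap[c] for c in [ID_COLUMN, DATE_COLUMN] + FEATURE_COLUMNS + [DX_COLUMN]]
    pd.DataFrame(rows, columns=order).to_csv(path, index=False)


def handle_missing(visits: Sequence[VisitRecord], policy: str,
                   medians: Optional[np.ndarray] = None) -> List[VisitRecord]:
    """Resolve NaN feature cells.

    ``drop_row`` removes any visit with a missing feature. ``ffill_then_median``
    forward-fills within each patient's date-sorted sequence, then fills the
    remainder with per-feature medians (pass training-set medians via
    ``medians`` to avoid leakage; they are computed from the given visits
    otherwise).
    """
    if policy == "drop_row":
        return [v for v in visits if not np.isnan(v.features).any()]
    if policy != "ffill_then_median":
        raise ValueError(f"unknown missing-data policy: {policy}")

    if medians is None:
        allx = np.array([v.features for v in visits])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            medians = np.nanmedian(allx, axis=0)
    if np.isnan(medians).any():
        bad = [FEATURE_COLUMNS[i] for i in np.flatnonzero(np.isnan(medians))]
        raise ValueError(f"median fallback impossible: feature(s) entirely missing: {bad}")

    out: List[VisitRecord] = []
    last: Dict[str, np.ndarray] = {}
    for v in sorted(visits, key=lambda r: (r.patient_id, r.exam_date)):
        x = v.features.copy()
        prev = last.get(v.patient_id)
        nan = np.isnan(x)
        if prev is not None:
            x[nan] = prev[nan]
            nan = np.isnan(x)
        x[nan] = medians[nan]
        last[v.patient_id] = x
        out.append(VisitRecord(v.patient_id, v.exam_date, x, v.label))
    return out


def group_by_patient(visits: Sequence[VisitRecord]) -> Dict[str, List[VisitRecord]]:
    groups: Dict[str, List[VisitRecord]] = {}
    for v in visits:
        groups.setdefault(v.patient_id, []).append(v)
    for pid in groups:
        groups[pid].sort(key=lambda r: r.exam_date)
    return groups


def make_windows(visits: Sequence[VisitRecord], k: int = 4) -> List[WindowSample]:
    """Stride-1 sliding windows: k context visits, target = next visit's label.

    A patient with V visits emits max(0, V - k) windows; patients with
    V < k + 1 are effectively excluded.
    """
    if k < 1:
        raise ValueError("window length k must be >= 1")
    samples: List[WindowSample] = []
    for pid, seq in group_by_patient(visits).items():
        for start in range(len(seq) - k):
            ctx = seq[start:start + k]
            tgt = seq[start + k]
            samples.append(WindowSample(
                patient_id=pid,
                window_start_index=start,
                context_features=np.stack([v.features for v in ctx]),
                context_labels=np.array([v.label for v in ctx], dtype=np.int64),
                target_label=tgt.label,
                target_features=tgt.features.copy(),
                context_dates=[v.exam_date for v in ctx],
                target_date=tgt.exam_date,
            ))
    return samples


def split_patients(patients: Sequence[str], test_fraction: float, seed: int,
                   stratify_labels: Optional[Dict[str, int]] = None,
                   ) -> Tuple[List[str], List[str]]:
    """Patient-level train/test split, stratified by each patient's last label.

    Deterministic given the seed. A stratum with fewer than 2 patients
    triggers a warning and an unstratified split.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    patients = sorted(set(map(str, patients)))
    rng = np.random.default_rng(seed)

    strata: Dict[int, List[str]]
    if stratify_labels is None:
        strata = {0: list(patients)}
    else:
        strata = {}
        for pid in patients:
            strata.setdefault(int(stratify_labels[pid]), []).append(pid)
        if any(len(v) < 2 for v in strata.values()):
            warnings.warn("a stratum has < 2 patients; falling back to unstratified split")
            strata = {0: list(patients)}

    train, test = [], []
    for lab in sorted(strata):
        ids = strata[lab]
        perm = rng.permutation(len(ids))
        n_test = int(round(test_fraction * len(ids)))
        for rank, idx in enumerate(perm):
            (test if rank < n_test else train).append(ids[idx])
    return sorted(train), sorted(test)


@dataclass
class WindowDataset:
    """A serializable windowed dataset with split membership and metadata."""

    windows: List[WindowSample]
    k: int
    feature_names: List[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    train_ids: List[str] = field(default_factory=list)
    test_ids: List[str] = field(default_factory=list)
    schema_version: int = 1

    def subset(self, ids: Sequence[str]) -> List[WindowSample]:
        ids = set(ids)
        return [w for w in self.windows if w.patient_id in ids]

    def save(self, path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "k": self.k,
            "feature_names": self.feature_names,
            "train_ids": self.train_ids,
            "test_ids": self.test_ids,
            "windows": [
                {
                    "patient_id": w.patient_id,
                    "window_start_index": w.window_start_index,
                    "context_features": w.context_features.tolist(),
                    "context_labels": w.context_labels.tolist(),
                    "target_label": int(w.target_label),
                    "target_features": None if w.target_features is None else w.target_features.tolist(),
                }
                for w in self.windows
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "WindowDataset":
        with open(path) as fh:
            payload = json.load(fh)
        windows = [
            WindowSample(
                patient_id=w["patient_id"],
                window_start_index=w["window_start_index"],
                context_features=np.array(w["context_features"]),
                context_labels=np.array(w["context_labels"], dtype=np.int64),
                target_label=w["target_label"],
                target_features=None if w["target_features"] is None else np.array(w["target_features"]),
            )
            for w in payload["windows"]
        ]
        return cls(windows=windows, k=payload["k"], feature_names=payload["feature_names"],
                   train_ids=payload["train_ids"], test_ids=payload["test_ids"],
                   schema_version=payload["schema_version"])
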