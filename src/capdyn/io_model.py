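"""Data model and I/O for ROI time series, cohort manifests, and network atlases.

The pipeline operates on per-subject region-of-interest (ROI) signal matrices
(T frames x R regions) extracted from resting-state fMRI, a cohort manifest
carrying group membership and nuisance covariates, and an atlas table mapping
each ROI to a large-scale functional network (default label set: ATN, DMN,
SMN, VN, SCN, CN).

File dialects
-------------
* series: one TSV per subject, no header, T rows x R columns, named
  ``<subject_id>.tsv``; time runs down the rows, frames are 0-indexed.
* manifest: CSV with header
  ``subject_id,group,age,sex,education,site,mean_fd,hamd``.
* atlas: CSV with header ``roi_index,roi_name,network``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education",
    "site",
    "mean_fd",
    "hamd",
]

ATLAS_COLUMNS = ["roi_index", "roi_name", "network"]

#: Default 6-network partition used with 116-region anatomical parcellations.
DEFAULT_NETWORKS = ("ATN", "DMN", "SMN", "VN", "SCN", "CN")


@dataclass
class RoiTimeSeries:
    """One subject's T x R ROI signal matrix.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier (matches the manifest and the file name).
    data : ndarray, shape (T, R)
        Signal matrix; arbitrary units before standardization, z-units after.
    tr_seconds : float
        Repetition time in seconds (time between consecutive frames).
    standardized : bool
        True once each column has been z-scored.
    """

    subject_id: str
    data: np.ndarray
    tr_seconds: float = 2.0
    standardized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError(f"{self.subject_id}: series must be 2-D (T x R)")
        t, r = self.data.shape
        if t < 2 or r < 2:
            raise ValueError(
                f"{self.subject_id}: need T >= 2 and R >= 2, got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"{self.subject_id}: series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"{self.subject_id}: tr_seconds must be positive")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class NetworkAtlas:
    """Mapping of every ROI to exactly one network label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ATLAS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"atlas is missing columns {missing}")
        idx = np.sort(self.table["roi_index"].to_numpy())
        expected = np.arange(len(self.table))
        if not np.array_equal(idx, expected):
            raise ValueError("atlas roi_index must be a contiguous 0..R-1 range")
        if self.table["network"].isna().any() or (self.table["network"] == "").any():
            raise ValueError("atlas contains an empty network label")
        self.table = self.table.sort_values("roi_index").reset_index(drop=True)

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def networks(self) -> list[str]:
        """Distinct network labels in first-appearance order."""
        return list(dict.fromkeys(self.table["network"]))

    def roi_networks(self) -> np.ndarray:
        """Length-R array of network labels, ordered by roi_index."""
        return self.table["network"].to_numpy()


@dataclass
class CohortManifest:
    """Per-subject demographics, covariates and symptom scores.

    ``hamd`` (17-item Hamilton Depression Rating Scale) may be missing for
    healthy controls; other covariates are expected but subjects with missing
    covariates are dropped (with a logged count) from adjusted analyses rather
    than rejected at load time.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest is missing columns {missing}")
        dup = self.table["subject_id"][self.table["subject_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate subject_id in manifest: {sorted(set(dup))}")
        if (self.table["mean_fd"].dropna() < 0).any():
            raise ValueError("mean_fd must be >= 0")
        self.table = self.table.reset_index(drop=True)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.table["subject_id"])

    @property
    def groups(self) -> pd.Series:
        return self.table.set_index("subject_id")["group"]

    def subset(self, subject_ids: list[str]) -> "CohortManifest":
        sub = self.table[self.table["subject_id"].isin(subject_ids)]
        return CohortManifest(sub.copy())


def zscore_series(ts: RoiTimeSeries, *, _force: bool = False) -> RoiTimeSeries:
    """Column-wise z-score a series (zero mean, unit sample SD per ROI).

    Uses the sample standard deviation (``ddof=1``). Re-standardizing an
    already standardized series is refused unless ``_force`` is set (used only
    to verify idempotence numerically).
    """
    if ts.standardized and not _force:
        raise ValueError(f"{ts.subject_id}: series is already standardized")
    sd = ts.data.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise ValueError(
            f"{ts.subject_id}: zero-variance ROI column(s) {zero.tolist()}"
        )
    z = (ts.data - ts.data.mean(axis=0)) / sd
    return replace(ts, data=z, standardized=True)


def _read_series_file(path: Path, subject_id: str, tr_seconds: float) -> RoiTimeSeries:
    data = np.loadtxt(path, delimiter="\t", ndmin=2)
    return RoiTimeSeries(subject_id=subject_id, data=data, tr_seconds=tr_seconds)


def load_cohort(
    manifest_path: str | Path,
    series_dir: str | Path,
    atlas_path: str | Path,
    tr_seconds: float = 2.0,
) -> tuple[CohortManifest, list[RoiTimeSeries], NetworkAtlas]:
    """Read and cross-validate a cohort: manifest + per-subject series + atlas.

    Every manifest subject must have a ``<subject_id>.tsv`` series file in
    ``series_dir`` whose column count matches the atlas. Series are returned
    in manifest order, unstandardized.
    """
    manifest_path, series_dir, atlas_path = map(Path, (manifest_path, series_dir, atlas_path))
    for p in (manifest_path, atlas_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    if not series_dir.is_dir():
        raise FileNotFoundError(str(series_dir))

    manifest = CohortManifest(pd.read_csv(manifest_path))
    atlas = NetworkAtlas(pd.read_csv(atlas_path))

    series: list[RoiTimeSeries] = []
    for sid in manifest.subject_ids:
        f = series_dir / f"{sid}.tsv"
        if not f.exists():
            raise FileNotFoundError(f"no series file for subject {sid!r} ({f})")
        ts = _read_series_file(f, sid, tr_seconds)
        if ts.n_rois != atlas.n_rois:
            raise ValueError(
                f"subject {sid!r}: series has {ts.n_rois} ROIs but atlas has "
                f"{atlas.n_rois}"
            )
        series.append(ts)
    return manifest, series, atlas


def save_cohort(
    out_dir: str | Path,
    manifest: CohortManifest,
    series: list[RoiTimeSeries],
    atlas: NetworkAtlas,
) -> Path:
    """Write a cohort to disk in the standard text dialects.

    Series are written at 17 significant digits so that a load/save/load
    round-trip reproduces the matrices bit-for-bit.
    """
    out_dir = Path(out_dir)
    sdir = out_dir / "series"
    sdir.mkdir(parents=True, exist_ok=True)
    manifest.table.to_csv(out_dir / "manifest.csv", index=False)
    atlas.table.to_csv(out_dir / "atlas.csv", index=False)
    for ts in series:
        np.savetxt(sdir / f"{ts.subject_id}.tsv", ts.data, delimiter="\t", fmt="%.17g")
    return out_dir
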