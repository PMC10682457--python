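"""Light parcel-level rsfMRI preparation.

Volumetric steps (motion correction, registration, spatial smoothing) are
assumed done upstream; this module handles the one-dimensional part of the
pipeline: volume trimming, temporal band-pass filtering, motion QC via
framewise displacement, and mask averaging to obtain the global (gBOLD) and
CSF-inflow signals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BoldSession",
    "QCReport",
    "trim_volumes",
    "bandpass",
    "framewise_displacement",
    "session_qc",
    "masked_mean",
    "read_bold_tsv",
    "write_bold_tsv",
    "read_series_tsv",
    "write_series_tsv",
    "read_motion_tsv",
    "write_motion_tsv",
    "load_session",
    "nifti_to_parcel_matrix",
]

#: Rotation-to-translation conversion radius (mm) for framewise displacement,
#: i.e. arc length on a 50 mm sphere approximating the cortical surface.
FD_ROTATION_RADIUS_MM = 50.0


@dataclass
class BoldSession:
    """One subject's resting-state session at parcel resolution.

    Attributes
    ----------
    bold : (n_parcels, n_volumes) array
        Parcel-wise BOLD time courses (arbitrary units).
    csf : (n_volumes,) array
        CSF-inflow signal from the bottom-slice CSF mask.
    motion : (n_volumes, 6) array
        Rigid-body motion trace: 3 translations (mm), 3 rotations (rad).
    tr : float
        Repetition time in seconds.
    parcel_ids : list of str
        One identifier per row of ``bold``.
    meta : dict
        Free-form subject/session metadata.
    """

    bold: np.ndarray
    csf: np.ndarray
    motion: np.ndarray
    tr: float
    parcel_ids: list[str] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bold = np.asarray(self.bold, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        self.motion = np.asarray(self.motion, dtype=float)
        if self.bold.ndim != 2:
            raise ValueError("bold must be a 2-D parcels x time matrix")
        if self.bold.shape[1] != self.csf.shape[0]:
            raise ValueError(
                f"bold has {self.bold.shape[1]} volumes but csf has "
                f"{self.csf.shape[0]}"
            )
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must have 6 columns")
        if self.motion.shape[0] != self.csf.shape[0]:
            raise ValueError("motion and csf lengths differ")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not np.all(np.isfinite(self.bold)) or not np.all(np.isfinite(self.csf)):
            raise ValueError("session contains non-finite values")
        if not self.parcel_ids:
            self.parcel_ids = [f"p{i:03d}" for i in range(self.bold.shape[0])]
        if len(self.parcel_ids) != self.bold.shape[0]:
            raise ValueError("parcel_ids length must match bold rows")

    @property
    def n_parcels(self) -> int:
        return self.bold.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.bold.shape[1]

    def gbold(self) -> np.ndarray:
        """Global BOLD signal: unweighted mean over all parcels."""
        return self.bold.mean(axis=0)


@dataclass
class QCReport:
    """Motion quality-control summary for one session."""

    mean_fd: float
    n_discarded_front: int
    n_discarded_back: int
    included: bool

    def __post_init__(self) -> None:
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be non-negative")


def trim_volumes(session: BoldSession, n_front: int = 5, n_back: int = 5) -> BoldSession:
    """Discard the leading/trailing volumes of every series in a session.

    The defaults drop 5 volumes at each end (magnetization steady state and
    filter edge effects); 10+10 is the sensitivity-analysis variant.
    """
    if n_front < 0 or n_back < 0:
        raise ValueError("trim counts must be non-negative")
    n = session.n_volumes
    if n <= n_front + n_back:
        raise ValueError(
            f"cannot trim {n_front}+{n_back} volumes from a session of length {n}"
        )
    stop = n - n_back
    return replace(
        session,
        bold=session.bold[:, n_front:stop].copy(),
        csf=session.csf[n_front:stop].copy(),
        motion=session.motion[n_front:stop].copy(),
    )


def _bandpass_sos(tr: float, low: float, high: float, order: int):
    nyquist = 1.0 / (2.0 * tr)
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyquist:
        raise ValueError(
            f"high cut-off {high} Hz is at or above the Nyquist frequency "
            f"{nyquist:.4g} Hz for tr={tr} s"
        )
    # butter() doubles the order for band-pass designs; halve so that the
    # realized filter is `order`-pole before the forward-backward pass.
    return signal.butter(order // 2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")


def bandpass(
    series: np.ndarray,
    tr: float,
    low: float = 0.01,
    high: float = 0.1,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    Forward-backward application (``sosfiltfilt``) preserves timing, which
    matters because lagged cross-correlations are computed downstream.
    """
    series = np.asarray(series, dtype=float)
    sos = _bandpass_sos(tr, low, high, order)
    return signal.sosfiltfilt(sos, series, axis=-1)


def bandpass_session(
    session: BoldSession, low: float = 0.01, high: float = 0.1
) -> BoldSession:
    """Band-pass the BOLD matrix and CSF series of a session (motion untouched)."""
    return replace(
        session,
        bold=bandpass(session.bold, session.tr, low, high),
        csf=bandpass(session.csf, session.tr, low, high),
    )


def framewise_displacement(motion: np.ndarray) -> np.ndarray:
    """Power-style framewise displacement from a time x 6 motion trace.

    FD(t) = sum |delta translation| + R * sum |delta rotation|, with rotations
    in radians converted to mm of arc on an R = 50 mm sphere. The first frame
    has no predecessor and is assigned FD = 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must have 6 columns, got shape {motion.shape}")
    d = np.diff(motion, axis=0)
    fd = np.abs(d[:, :3]).sum(axis=1) + FD_ROTATION_RADIUS_MM * np.abs(d[:, 3:]).sum(axis=1)
    return np.concatenate([[0.0], fd])


def session_qc(
    session: BoldSession,
    fd_threshold: float = 0.5,
    n_discarded_front: int = 0,
    n_discarded_back: int = 0,
) -> QCReport:
    """Motion inclusion decision: excluded iff mean FD strictly exceeds threshold."""
    mean_fd = float(framewise_displacement(session.motion).mean())
    return QCReport(
        mean_fd=mean_fd,
        n_discarded_front=n_discarded_front,
        n_discarded_back=n_discarded_back,
        included=mean_fd <= fd_threshold,
    )


def masked_mean(matrix: np.ndarray, mask: Sequence[int] | np.ndarray) -> np.ndarray:
    """Unweighted mean over the selected rows at each time point.

    ``mask`` may be a boolean vector over rows or an integer index set.
    """
    matrix = np.asarray(matrix, dtype=float)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.shape[0] != matrix.shape[0]:
            raise ValueError("boolean mask length must match row count")
        idx = np.flatnonzero(mask)
    else:
        idx = mask.astype(int)
    if idx.size == 0:
        raise ValueError("mask selects no rows")
    return matrix[idx].mean(axis=0)


# ---------------------------------------------------------------------------
# Plain-text readers / writers (TSV parcels x time with a parcel-ID header)


def write_bold_tsv(path: str | Path, bold: np.ndarray, parcel_ids: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(bold).T, columns=list(parcel_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_bold_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return df.to_numpy(dtype=float).T, [str(c) for c in df.columns]


def write_series_tsv(path: str | Path, series: np.ndarray, name: str = "value") -> None:
    pd.DataFrame({name: np.asarray(series)}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_series_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").iloc[:, 0].to_numpy(dtype=float)


MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_motion_tsv(path: str | Path, motion: np.ndarray) -> None:
    pd.DataFrame(np.asarray(motion), columns=MOTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_motion_tsv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, sep="\t").to_numpy(dtype=float)


def load_session(
    bold_path: str | Path,
    csf_path: str | Path,
    motion_path: str | Path,
    tr: float,
    meta: Mapping | None = None,
) -> BoldSession:
    """Assemble a session from its three on-disk TSV components."""
    bold, ids = read_bold_tsv(bold_path)
    return BoldSession(
        bold=bold,
        csf=read_series_tsv(csf_path),
        motion=read_motion_tsv(motion_path),
        tr=tr,
        parcel_ids=ids,
        meta=dict(meta or {}),
    )


def nifti_to_parcel_matrix(
    img_path: str | Path, label_path: str | Path
) -> tuple[np.ndarray, list[str]]:
    """Average a 4-D NIfTI within each label of a 3-D parcellation volume.

    Converts voxel data to the parcels x time representation used everywhere
    else; label 0 is treated as background. Requires ``nibabel``.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("NIfTI input requires the 'nibabel' package") from exc
    img = nib.load(str(img_path))
    labels_img = nib.load(str(label_path))
    data = np.asarray(img.dataobj, dtype=float)
    labels = np.asarray(labels_img.dataobj).astype(int)
    if data.ndim != 4:
        raise ValueError("expected a 4-D BOLD image")
    if labels.shape != data.shape[:3]:
        raise ValueError("label volume does not match image grid")
    ids = [int(v) for v in np.unique(labels) if v != 0]
    flat = data.reshape(-1, data.shape[3])
    lab_flat = labels.reshape(-1)
    rows = [flat[lab_flat == v].mean(axis=0) for v in ids]
    if not rows:
        raise ValueError("label volume contains no non-zero parcels")
    return np.vstack(rows), [str(v) for v in ids]
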