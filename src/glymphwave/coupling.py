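"""gBOLD/rBOLD-CSF cross-correlation coupling and global-signal presence maps.

The coupling statistic is the Pearson correlation between a BOLD signal and
the CSF-inflow signal at a fixed positive lag (+3 s by default, where the
negative peak of the group-mean cross-correlation function sits). More
negative coupling is read as stronger BOLD-CSF coupling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import BoldSession

__all__ = [
    "DEFAULT_REFERENCE_LAG",
    "DEFAULT_MAX_LAG",
    "CouplingResult",
    "crosscorr_function",
    "coupling_at_reference",
    "rbold_csf_map",
    "gbold_presence_map",
]

DEFAULT_REFERENCE_LAG = 3.0  # seconds; negative CCF peak of the group mean
DEFAULT_MAX_LAG = 12.0  # seconds; half-width of the lag grid


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, or NaN when either overlap segment is constant."""
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


@dataclass
class CouplingResult:
    """Cross-correlation function over a symmetric lag grid.

    ``ccf[k]`` is the Pearson correlation between ``x(t)`` and
    ``y(t + lags[k])`` computed over the overlapping samples only; a positive
    lag therefore examines ``y`` later in time than ``x``. ``coupling_value``
    is the correlation at ``reference_lag``; ``min_lag``/``min_value`` locate
    the most negative point of the function.
    """

    lags: np.ndarray
    ccf: np.ndarray
    coupling_value: float
    reference_lag: float
    requested_lag: float
    min_lag: float
    min_value: float
    off_grid_reference: bool = False

    def at(self, lag: float) -> float:
        idx = int(np.argmin(np.abs(self.lags - lag)))
        return float(self.ccf[idx])


def crosscorr_function(
    x: np.ndarray,
    y: np.ndarray,
    tr: float,
    max_lag: float = DEFAULT_MAX_LAG,
    reference_lag: float = DEFAULT_REFERENCE_LAG,
) -> CouplingResult:
    """Lagged Pearson cross-correlation of two equal-length series.

    Each lag is evaluated on the overlapping samples only (no zero padding,
    which would bias r toward zero increasingly with lag). Lags run over the
    sampling grid ``k * tr`` for ``|k * tr| <= max_lag``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if tr <= 0:
        raise ValueError("tr must be positive")
    k_max = int(np.floor(max_lag / tr + 1e-9))
    n = x.size
    if n < 3 * k_max and k_max > 0:
        raise ValueError(
            f"series of length {n} too short for max_lag {max_lag} s at tr {tr} s"
        )
    ks = np.arange(-k_max, k_max + 1)
    ccf = np.empty(ks.size)
    for i, k in enumerate(ks):
        if k >= 0:
            ccf[i] = _pearson(x[: n - k] if k else x, y[k:])
        else:
            ccf[i] = _pearson(x[-k:], y[:k])
    lags = ks * tr
    # reference lag snapped to the grid for sessions whose tr does not divide it
    ref_idx = int(np.argmin(np.abs(lags - reference_lag)))
    off_grid = not np.isclose(lags[ref_idx], reference_lag, atol=1e-9)
    if off_grid:
        warnings.warn(
            f"reference lag {reference_lag} s is off the tr={tr} s grid; "
            f"using nearest grid lag {lags[ref_idx]:.3g} s",
            stacklevel=2,
        )
    finite = np.isfinite(ccf)
    if finite.any():
        min_i = int(np.nanargmin(np.where(finite, ccf, np.inf)))
        min_lag, min_value = float(lags[min_i]), float(ccf[min_i])
    else:
        min_lag, min_value = np.nan, np.nan
    return CouplingResult(
        lags=lags,
        ccf=ccf,
        coupling_value=float(ccf[ref_idx]),
        reference_lag=float(lags[ref_idx]),
        requested_lag=float(reference_lag),
        min_lag=min_lag,
        min_value=min_value,
        off_grid_reference=off_grid,
    )


def coupling_at_reference(result: CouplingResult, reference_lag: float | None = None) -> float:
    """Coupling scalar: the cross-correlation at the (nearest-grid) reference lag."""
    if reference_lag is None:
        return result.coupling_value
    return result.at(reference_lag)


def gbold_csf_coupling(
    session: BoldSession,
    max_lag: float = DEFAULT_MAX_LAG,
    reference_lag: float = DEFAULT_REFERENCE_LAG,
) -> CouplingResult:
    """Cross-correlation of the session's global BOLD signal with its CSF signal."""
    return crosscorr_function(session.gbold(), session.csf, session.tr, max_lag, reference_lag)


def rbold_csf_map(
    session: BoldSession,
    max_lag: float = DEFAULT_MAX_LAG,
    reference_lag: float = DEFAULT_REFERENCE_LAG,
) -> pd.Series:
    """Per-parcel BOLD-CSF coupling at the reference lag (same CSF for all parcels)."""
    values = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # one off-grid warning suffices at session level
        for pid, row in zip(session.parcel_ids, session.bold):
            res = crosscorr_function(row, session.csf, session.tr, max_lag, reference_lag)
            values[pid] = res.coupling_value
    return pd.Series(values, name="rbold_csf_coupling")


def gbold_presence_map(session: BoldSession) -> pd.Series:
    """Per-parcel Spearman correlation between the parcel series and gBOLD.

    Quantifies how strongly the global signal is expressed locally; constant
    parcel series yield NaN (flagged as missing rather than raising).
    """
    g = session.gbold()
    if np.ptp(g) == 0:
        raise ValueError("global signal is constant; presence undefined")
    values = {}
    for pid, row in zip(session.parcel_ids, session.bold):
        if np.ptp(row) == 0:
            values[pid] = np.nan
        else:
            values[pid] = float(stats.spearmanr(row, g).statistic)
    return pd.Series(values, name="gbold_presence")
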