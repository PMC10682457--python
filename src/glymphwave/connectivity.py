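"""Functional connectivity with and without global-signal removal.

Nuisance time courses (CSF, white matter, the six motion parameters, and
optionally the global BOLD signal) are regressed out of every parcel series
in a single OLS, after which pairwise Pearson correlations form the FC
matrix. Region-level FC is the mean of the raw correlations over the
relevant parcel pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hierarchy import HierarchyMasks

__all__ = ["FCMatrix", "nuisance_regress", "fc_matrix", "summarize_fc"]


@dataclass
class FCMatrix:
    """Symmetric parcel x parcel Pearson correlation matrix (diagonal = 1)."""

    values: pd.DataFrame
    gbold_removed: bool = False
    constant_parcels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values.to_numpy()
        if v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")

    def loc(self, a: str, b: str) -> float:
        return float(self.values.loc[a, b])


def nuisance_regress(
    parcel_ts: np.ndarray,
    regressors: np.ndarray | None,
    include_gbold: bool = False,
    gbold: np.ndarray | None = None,
) -> np.ndarray:
    """OLS residuals of each parcel series on [intercept, regressors(, gBOLD)].

    All nuisances are removed in one joint least-squares fit so the result
    does not depend on regressor ordering. Raises when the design matrix is
    rank-deficient, naming the collinear columns.
    """
    parcel_ts = np.atleast_2d(np.asarray(parcel_ts, dtype=float))
    n_t = parcel_ts.shape[1]
    cols: list[np.ndarray] = [np.ones(n_t)]
    names = ["intercept"]
    if regressors is not None and np.size(regressors):
        reg = np.asarray(regressors, dtype=float)
        if reg.ndim == 1:
            reg = reg[:, None]
        if reg.shape[0] != n_t:
            raise ValueError("regressors must have one row per time point")
        cols.extend(reg.T)
        names.extend(f"regressor_{i}" for i in range(reg.shape[1]))
    if include_gbold:
        if gbold is None:
            raise ValueError("include_gbold=True requires the gbold series")
        g = np.asarray(gbold, dtype=float)
        if g.shape[0] != n_t:
            raise ValueError("gbold length mismatch")
        cols.append(g)
        names.append("gbold")
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify columns that add no rank when appended incrementally
        collinear = []
        r = 0
        for j in range(design.shape[1]):
            r_new = np.linalg.matrix_rank(design[:, : j + 1])
            if r_new == r:
                collinear.append(names[j])
            r = r_new
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(design, parcel_ts.T, rcond=None)
    return parcel_ts - (design @ beta).T


def fc_matrix(parcel_ts: np.ndarray, parcel_ids: list[str] | None = None,
              gbold_removed: bool = False) -> FCMatrix:
    """Full pairwise Pearson correlation matrix of parcel time courses.

    Constant series give NaN rows/columns and are reported in
    ``constant_parcels``; the diagonal is set to exactly 1 for all parcels.
    """
    ts = np.atleast_2d(np.asarray(parcel_ts, dtype=float))
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 time points for FC")
    if parcel_ids is None:
        parcel_ids = [f"p{i:03d}" for i in range(ts.shape[0])]
    sd = ts.std(axis=1)
    constant = [pid for pid, s in zip(parcel_ids, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(ts)
    np.fill_diagonal(corr, 1.0)
    df = pd.DataFrame(corr, index=parcel_ids, columns=parcel_ids)
    return FCMatrix(values=df, gbold_removed=gbold_removed, constant_parcels=constant)


def summarize_fc(fc: FCMatrix, masks: HierarchyMasks) -> tuple[float, float, float]:
    """(within_higher, within_lower, between) mean raw correlations.

    Within-region values average the unique unordered parcel pairs of that
    region; the between value averages all higher x lower pairs. The diagonal
    never contributes.
    """
    ids = list(fc.values.index)
    higher = [p for p in ids if p in masks.higher]
    lower = [p for p in ids if p in masks.lower]
    if len(higher) < 2 or len(lower) < 2:
        raise ValueError("each mask needs at least 2 parcels for a within-FC summary")

    def within(group: list[str]) -> float:
        sub = fc.values.loc[group, group].to_numpy()
        iu = np.triu_indices(len(group), k=1)
        return float(np.nanmean(sub[iu]))

    between = float(np.nanmean(fc.values.loc[higher, lower].to_numpy()))
    return within(higher), within(lower), between
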