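"""Subject-level functional connectivity matrices from ROI time series.

A subject's resting-state signal is summarised as a timepoints x regions
matrix of mean BOLD time courses, one column per region of interest (ROI).
Functional connectivity between two regions is the Pearson correlation of
their time courses, variance-stabilised with Fisher's r-to-z transform
(atanh).  The working object downstream is therefore a symmetric
region x region matrix of Fisher-z values.

System-segregation analyses operate on a "prepared" matrix: the diagonal
and every negative connection are set to 0 (zeroed edges remain in the
denominators of any averages taken later — they are values of 0, not
missing data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("gripseg")

#: correlations are clipped to +/- (1 - CLIP) before atanh, which diverges at |r| = 1
CLIP = 1e-7


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's ROI time-series matrix (T timepoints x R regions)."""

    subject_id: str
    values: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        if values.ndim != 2:
            raise ValueError("time series must be a 2-D timepoints x regions matrix")
        t, r = values.shape
        if t < 3:
            raise ValueError(f"need at least 3 timepoints, got {t}")
        if r < 2:
            raise ValueError(f"need at least 2 regions, got {r}")
        if r != len(self.region_ids):
            raise ValueError("region_ids length does not match number of columns")
        if len(set(self.region_ids)) != r:
            raise ValueError("region_ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains missing or non-finite values")
        sd = values.std(axis=0)
        dead = [rid for rid, s in zip(self.region_ids, sd) if s == 0.0]
        if dead:
            raise ValueError(f"zero-variance region(s): {', '.join(dead)}")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric region x region Fisher-z connectivity matrix.

    ``prepared`` marks the segregation-ready state: diagonal exactly 0 and
    no negative entries.
    """

    subject_id: str
    z: np.ndarray
    region_ids: tuple[str, ...]
    prepared: bool = False

    def __post_init__(self) -> None:
        z = np.asarray(self.z, dtype=float)
        object.__setattr__(self, "z", z)
        object.__setattr__(self, "region_ids", tuple(self.region_ids))
        r = len(self.region_ids)
        if z.shape != (r, r):
            raise ValueError("z must be square and match region_ids")
        if not np.allclose(z, z.T, atol=1e-12, rtol=0.0):
            raise ValueError("z must be symmetric")
        if self.prepared:
            if np.any(np.diag(z) != 0.0):
                raise ValueError("prepared matrix must have a zero diagonal")
            if np.any(z < 0.0):
                raise ValueError("prepared matrix must be non-negative")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def index_of(self, region_id: str) -> int:
        try:
            return self.region_ids.index(region_id)
        except ValueError:
            raise KeyError(f"unknown region: {region_id}") from None


def compute_fc(ts: ROITimeSeries) -> ConnectivityMatrix:
    """Pearson-correlate every pair of region time courses and Fisher-transform.

    ``z[i, j] = atanh(r_ij)`` with ``|r|`` clipped to ``1 - 1e-7`` (a clip is
    logged: it signals a numerically degenerate pair, typically a perfect
    linear dependence).  The diagonal is set to 0 and the matrix is made
    exactly symmetric by mirroring the upper triangle.
    """
    r = np.corrcoef(ts.values, rowvar=False)
    iu = np.triu_indices(ts.n_regions, k=1)
    n_clip = int(np.sum(np.abs(r[iu]) > 1.0 - CLIP))
    if n_clip:
        msg = (
            f"subject {ts.subject_id}: {n_clip} region pair(s) at |r| ~ 1; "
            f"clipped to {1.0 - CLIP} before Fisher transform"
        )
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    r = np.clip(r, -(1.0 - CLIP), 1.0 - CLIP)
    z = np.arctanh(r)
    # mirror the upper triangle so the result is exactly symmetric
    out = np.zeros_like(z)
    out[iu] = z[iu]
    out = out + out.T
    return ConnectivityMatrix(ts.subject_id, out, ts.region_ids, prepared=False)


def prepare_matrix(m: ConnectivityMatrix) -> ConnectivityMatrix:
    """Zero the diagonal and every negative connection (idempotent)."""
    z = m.z.copy()
    np.fill_diagonal(z, 0.0)
    z[z < 0.0] = 0.0
    return ConnectivityMatrix(m.subject_id, z, m.region_ids, prepared=True)


# ---------------------------------------------------------------------------
# delimited-text I/O
# ---------------------------------------------------------------------------

def read_timeseries(path, subject_id: str | None = None, sep: str = "\t") -> ROITimeSeries:
    """Read a per-subject delimited table: header = region ids, one row per timepoint."""
    df = pd.read_csv(path, sep=sep)
    sid = subject_id if subject_id is not None else _stem(path)
    return ROITimeSeries(sid, df.to_numpy(dtype=float), tuple(map(str, df.columns)))


def write_matrix(m: ConnectivityMatrix, path, sep: str = "\t") -> None:
    """Write an R x R matrix with region-id header and index, round-trip stable."""
    df = pd.DataFrame(m.z, index=list(m.region_ids), columns=list(m.region_ids))
    df.to_csv(path, sep=sep, float_format="%.17g")


def read_matrix(path, subject_id: str | None = None, prepared: bool = False,
                sep: str = "\t") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    sid = subject_id if subject_id is not None else _stem(path)
    return ConnectivityMatrix(sid, df.to_numpy(dtype=float),
                              tuple(map(str, df.columns)), prepared=prepared)


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]
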