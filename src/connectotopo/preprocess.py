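"""Temporal conditioning of ROI signals.

The fixed pipeline order is the standard resting-state sequence applied
after imaging-space steps: discard initial volumes -> linear detrend ->
band-pass filter -> nuisance regression. Each step maps a
:class:`~connectotopo.dataset.RoiTimeSeriesSet` to a new one; region count
and ordering never change.

The band-pass filter is a zero-phase forward-backward Butterworth
(default order 4) applied with reflection ("even") padding, which matters
for short series (a few hundred volumes) where filter transients would
otherwise leak into the estimate of every correlation.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy import signal as sps

from .dataset import RoiTimeSeriesSet

__all__ = [
    "discard_initial_volumes",
    "linear_detrend",
    "bandpass",
    "nuisance_regress",
    "preprocess",
    "bandpass_array",
]

log = logging.getLogger(__name__)


def discard_initial_volumes(ts: RoiTimeSeriesSet, n_discard: int) -> RoiTimeSeriesSet:
    """Drop the first ``n_discard`` time points of every subject.

    Early volumes are routinely excluded to avoid magnetisation
    non-equilibrium at the start of a scan (e.g. 239 acquired volumes with
    the first 10 dropped leaves 229).
    """
    if n_discard < 0:
        raise ValueError(f"n_discard must be non-negative, got {n_discard}")
    shortest = min(s.n_timepoints for s in ts.subjects)
    if n_discard >= shortest:
        raise ValueError(
            f"n_discard={n_discard} would empty a series of length {shortest}"
        )
    return ts.map_data(lambda x: x[n_discard:]) if n_discard else ts


def linear_detrend(ts: RoiTimeSeriesSet) -> RoiTimeSeriesSet:
    """Remove, per region, the least-squares line over the time index.

    Includes intercept removal, so each output column has (numerically)
    zero mean and zero linear trend. A constant input column becomes all
    zeros.
    """
    shortest = min(s.n_timepoints for s in ts.subjects)
    if shortest < 3:
        raise ValueError("linear detrend needs at least 3 time points")
    return ts.map_data(lambda x: sps.detrend(x, axis=0, type="linear"))


def bandpass_array(
    x: np.ndarray,
    low_hz: float,
    high_hz: float,
    fs: float,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a (time x region) array."""
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz at fs={fs} Hz)"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x, axis=0, padtype="even")


def bandpass(
    ts: RoiTimeSeriesSet,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
) -> RoiTimeSeriesSet:
    """Band-pass every region signal to ``[low_hz, high_hz]``.

    Resting-state analyses conventionally keep 0.01-0.08 Hz, the band in
    which spontaneous BOLD fluctuations carry the connectivity signal.
    Filtering is zero-phase (forward-backward), so peak timing is
    preserved and no phase distortion enters the correlations.
    """
    return ts.map_data(lambda x: bandpass_array(x, low_hz, high_hz, ts.sampling_hz, order))


def _regress_out(x: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of each column of ``x`` on [intercept, regressors]."""
    t = x.shape[0]
    design = np.column_stack([np.ones(t), regressors]) if regressors.size else np.ones((t, 1))
    # drop collinear columns (QR rank check), keeping the earliest of each set
    q, r = np.linalg.qr(design)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    if not keep.all():
        dropped = [i - 1 for i in np.nonzero(~keep)[0]]  # -1: skip intercept slot
        log.warning("nuisance regression: dropping collinear regressor columns %s", dropped)
        design = design[:, keep]
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def nuisance_regress(
    ts: RoiTimeSeriesSet,
    regressors: dict | None = None,
) -> RoiTimeSeriesSet:
    """Project externally supplied nuisance signals out of every region.

    Parameters
    ----------
    ts
        Dataset; if ``regressors`` is None each subject's own ``nuisance``
        matrix is used (subjects without one pass through unchanged apart
        from intercept removal).
    regressors
        Optional mapping ``subject_id -> (time x k) array`` overriding the
        per-subject matrices.

    Notes
    -----
    Whole-brain, white-matter and CSF signals cannot be derived from
    parcel averages alone, so they are accepted here as supplied columns
    rather than recomputed.
    """
    out = []
    for s in ts.subjects:
        reg = None
        if regressors is not None:
            reg = regressors.get(s.subject_id)
        elif s.nuisance is not None:
            reg = s.nuisance
        if reg is None:
            reg = np.empty((s.n_timepoints, 0))
        reg = np.asarray(reg, dtype=float)
        if reg.shape[0] != s.n_timepoints:
            raise ValueError(
                f"subject {s.subject_id}: regressor length {reg.shape[0]} "
                f"!= {s.n_timepoints} time points"
            )
        out.append(s.with_data(_regress_out(s.data, reg), nuisance=s.nuisance))
    return RoiTimeSeriesSet(out, tr_seconds=ts.tr_seconds)


def preprocess(
    ts: RoiTimeSeriesSet,
    n_discard: int = 10,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    filter_order: int = 4,
    regressors: dict | None = None,
) -> RoiTimeSeriesSet:
    """Run the full conditioning pipeline in its fixed order."""
    log.info(
        "preprocess: discard=%d -> detrend -> bandpass [%g, %g] Hz -> nuisance",
        n_discard, low_hz, high_hz,
    )
    ts = discard_initial_volumes(ts, n_discard)
    ts = linear_detrend(ts)
    ts = bandpass(ts, low_hz, high_hz, order=filter_order)
    ts = nuisance_regress(ts, regressors)
    return ts
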