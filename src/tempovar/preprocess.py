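"""Conditioning of registered 4D BOLD data into analysis-ready ROI series.

The pipeline starts from spatially registered data (a 4D image plus an
integer label atlas, or a ready-made T x R table) and applies the standard
resting-state conditioning sequence:

    discard initial volumes -> linear detrend -> temporal band-pass
    (0.01-0.08 Hz) -> nuisance regression (motion, WM, CSF, global mean)

plus an optional left/right hemisphere flip implemented as a swap of
homologous-region columns, so that in a mixed-lesion-side cohort the left
hemisphere is always the ipsilesional one.  Volume-level registration
(slice timing, realignment, normalisation) is out of scope: it is assumed
done upstream.
"""

from __future__ import annotations

import warnings

import numpy as np

from .series import HomologousPairing, NuisanceSet, RoiTimeSeries

__all__ = [
    "extract_roi_timeseries",
    "discard_initial_volumes",
    "detrend_linear",
    "bandpass",
    "regress_nuisance",
    "flip_hemispheres",
    "condition_series",
]


def extract_roi_timeseries(
    image_4d,
    atlas,
    tr_seconds: float | None = None,
    region_ids: list[int] | None = None,
) -> RoiTimeSeries:
    """Average voxel time series within each atlas parcel.

    Parameters
    ----------
    image_4d
        A nibabel spatial image of shape (X, Y, Z, T) or a plain array.
    atlas
        A nibabel image or array of shape (X, Y, Z) with integer labels;
        0 is background.
    tr_seconds
        Sampling interval; if None it is taken from the image header zooms
        (4th zoom) when available, else defaults to 2.0.
    region_ids
        Explicit list of label ids to extract, in the given order.  Ids
        absent from the atlas produce a warning and an all-NaN column
        flagged for downstream exclusion.  Default: all nonzero labels in
        ascending order.

    Returns
    -------
    RoiTimeSeries
        T x R matrix; column r is the voxel mean of region r at each time
        point; region labels are the stringified label ids.
    """
    data, hdr_tr = _image_data(image_4d, ndim=4)
    labels, _ = _image_data(atlas, ndim=3)
    if data.shape[:3] != labels.shape:
        raise ValueError(
            f"image grid {data.shape[:3]} does not match atlas grid {labels.shape}"
        )
    if not np.all(labels == np.round(labels)):
        raise ValueError("atlas contains non-integer labels")
    labels = labels.astype(int)

    present = np.unique(labels)
    present = present[present != 0]
    ids = list(region_ids) if region_ids is not None else [int(v) for v in present]
    if not ids:
        raise ValueError("no nonzero labels to extract")

    T = data.shape[3]
    flat = data.reshape(-1, T)
    lab_flat = labels.ravel()
    out = np.empty((T, len(ids)))
    for c, rid in enumerate(ids):
        mask = lab_flat == rid
        if not mask.any():
            warnings.warn(
                f"label {rid} absent from atlas; column flagged all-NaN",
                stacklevel=2,
            )
            out[:, c] = np.nan
        else:
            out[:, c] = flat[mask].mean(axis=0)

    if tr_seconds is None:
        tr_seconds = hdr_tr if hdr_tr and hdr_tr > 0 else 2.0
    return RoiTimeSeries(out, tuple(str(i) for i in ids), tr_seconds=tr_seconds)


def _image_data(img, ndim: int) -> tuple[np.ndarray, float | None]:
    """Return (array, header TR or None) from a nibabel image or array."""
    tr = None
    if hasattr(img, "get_fdata"):
        data = np.asarray(img.get_fdata())
        zooms = img.header.get_zooms()
        if len(zooms) >= 4:
            tr = float(zooms[3])
    else:
        data = np.asarray(img, dtype=float)
    if data.ndim != ndim:
        raise ValueError(f"expected a {ndim}-D image, got shape {data.shape}")
    return data, tr


def discard_initial_volumes(series: RoiTimeSeries, n_discard: int = 5) -> RoiTimeSeries:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard < 0:
        raise ValueError("n_discard must be >= 0")
    if n_discard == 0:
        return series
    if series.n_volumes <= n_discard:
        raise ValueError(
            f"cannot discard {n_discard} of {series.n_volumes} volumes"
        )
    return series.with_values(series.values[n_discard:], step="discard")


def detrend_linear(series: RoiTimeSeries) -> RoiTimeSeries:
    """Remove each column's least-squares linear trend (and mean)."""
    T = series.n_volumes
    if T < 3:
        raise ValueError("need at least 3 volumes to detrend")
    t = np.arange(T, dtype=float)
    X = np.column_stack([np.ones(T), t - t.mean()])
    beta, *_ = np.linalg.lstsq(X, np.nan_to_num(series.values), rcond=None)
    resid = series.values - X @ beta
    return series.with_values(resid, step="detrend")


def bandpass(
    series: RoiTimeSeries, low_hz: float = 0.01, high_hz: float = 0.08
) -> RoiTimeSeries:
    """Ideal discrete-Fourier band-pass filter.

    Frequency bins outside [low_hz, high_hz] are zeroed; in-band bins are
    kept exactly, so a pure in-band sinusoid passes with unit gain and the
    DC component is removed whenever ``low_hz > 0``.
    """
    nyquist = 1.0 / (2.0 * series.tr_seconds)
    if not (0.0 <= low_hz < high_hz):
        raise ValueError("need 0 <= low_hz < high_hz")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency "
            f"{nyquist:.4f} Hz for TR={series.tr_seconds} s"
        )
    T = series.n_volumes
    freqs = np.fft.rfftfreq(T, d=series.tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(np.nan_to_num(series.values), axis=0)
    spec[~keep] = 0.0
    filtered = np.fft.irfft(spec, n=T, axis=0)
    # restore NaN flags on missing-region columns
    nan_cols = np.isnan(series.values).all(axis=0)
    filtered[:, nan_cols] = np.nan
    return series.with_values(filtered, step="bandpass")


def regress_nuisance(series: RoiTimeSeries, nuisance: NuisanceSet) -> RoiTimeSeries:
    """OLS-remove nuisance regressors (plus an intercept) from each column.

    Residuals are orthogonal to every regressor.  Raises on a rank-deficient
    design, naming the collinear regressors.
    """
    reg = nuisance.regressors
    if reg.shape[0] != series.n_volumes:
        raise ValueError(
            f"nuisance rows ({reg.shape[0]}) != series volumes ({series.n_volumes})"
        )
    X = np.column_stack([np.ones(series.n_volumes), reg])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        collinear = _collinear_names(X, nuisance.regressor_names)
        raise ValueError(
            "nuisance design is rank deficient; collinear regressors: "
            + ", ".join(collinear)
        )
    beta, *_ = np.linalg.lstsq(X, np.nan_to_num(series.values), rcond=None)
    resid = series.values - X @ beta
    return series.with_values(resid, step="regress")


def _collinear_names(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    """Greedily identify regressors that do not increase design rank."""
    out = []
    cols = [X[:, 0]]  # intercept
    for j, name in enumerate(names, start=1):
        trial = np.column_stack(cols + [X[:, j]])
        if np.linalg.matrix_rank(trial) == len(cols):
            out.append(name)
        else:
            cols.append(X[:, j])
    return out or list(names)


def flip_hemispheres(series: RoiTimeSeries, pairing: HomologousPairing) -> RoiTimeSeries:
    """Swap each homologous (left, right) column pair; midline unchanged.

    Equivalent, at the parcel level of a symmetric atlas, to flipping the
    image along the midsagittal plane before extraction.  Applying the flip
    twice returns the input.
    """
    pairing.validate(series.n_regions)
    perm = np.arange(series.n_regions)
    for l, r in pairing.pairs:
        perm[l], perm[r] = perm[r], perm[l]
    return series.with_values(series.values[:, perm], step="flip_lr")


def condition_series(
    series: RoiTimeSeries,
    n_discard: int = 5,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    nuisance: NuisanceSet | None = None,
    flip: HomologousPairing | None = None,
) -> RoiTimeSeries:
    """Apply the full conditioning sequence in canonical order.

    Flip (if requested) is applied first; it commutes with every per-column
    step.  The nuisance set, if given, must already be aligned with the
    post-discard series length.
    """
    if flip is not None:
        series = flip_hemispheres(series, flip)
    series = discard_initial_volumes(series, n_discard)
    series = detrend_linear(series)
    series = bandpass(series, low_hz, high_hz)
    if nuisance is not None:
        series = regress_nuisance(series, nuisance)
    return series
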