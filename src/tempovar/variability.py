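"""Regional temporal variability of dynamic functional connectivity.

The statistic: a conditioned T x R series is cut into n = floor(T / l)
nonoverlapping windows of length l volumes.  Within window i the R x R
Pearson-correlation network F_i is computed; region k's *connectivity
profile* F_{i,k} is its row of F_i (the constant self-entry excluded by
default).  The temporal variability of region k at window length l is

    V_k(l) = 1 - mean_{i < j} corr(F_{i,k}, F_{j,k}),

i.e. one minus the average pairwise similarity of the region's network
profile across windows.  V_k lies in [0, 2]: 0 when the profile never
changes, large when the region reconfigures its affiliations.  To avoid an
arbitrary window length, V_k(l) is computed for l = 10..20 volumes and
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import RoiTimeSeries

DEFAULT_LENGTHS: tuple[int, ...] = tuple(range(10, 21))

__all__ = [
    "DEFAULT_LENGTHS",
    "WindowedNetworkStack",
    "VariabilityResult",
    "segment_windows",
    "window_fc",
    "build_stack",
    "variability_one_length",
    "temporal_variability",
]


def segment_windows(n_volumes: int, l: int) -> list[tuple[int, int]]:
    """Nonoverlapping window spans (0-based, half-open) of length ``l``.

    The series is cut from the start into n = floor(T / l) windows; the
    trailing ``T mod l`` volumes are dropped.  At least two windows are
    required for a pairwise-comparison statistic.
    """
    if l < 3:
        raise ValueError("window length must be >= 3 volumes")
    if n_volumes < 2 * l:
        raise ValueError(
            f"need at least {2 * l} volumes for two windows of length {l}, "
            f"got {n_volumes}"
        )
    n = n_volumes // l
    return [(i * l, (i + 1) * l) for i in range(n)]


def window_fc(values: np.ndarray, span: tuple[int, int]) -> np.ndarray:
    """Pearson-correlation network over one window.

    Returns the R x R matrix with unit diagonal.  Regions with zero
    variance inside the window get a full NaN row/column (diagonal
    included), which marks them degenerate; the caller decides the
    exclusion policy.
    """
    start, end = span
    if end - start < 3:
        raise ValueError("window must span at least 3 volumes")
    seg = np.asarray(values, dtype=float)[start:end]
    sd = seg.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        F = np.corrcoef(seg, rowvar=False)
    np.fill_diagonal(F, 1.0)
    degenerate = sd == 0
    if degenerate.any():
        # full NaN row/col (diagonal included) marks the region degenerate
        F[degenerate, :] = np.nan
        F[:, degenerate] = np.nan
    # clip numerical overshoot
    return np.clip(F, -1.0, 1.0)


@dataclass(frozen=True)
class WindowedNetworkStack:
    """All per-window correlation networks for one window length."""

    window_length: int
    windows: np.ndarray  # (n, R, R)
    window_spans: tuple[tuple[int, int], ...]
    region_labels: tuple[str, ...]

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_regions(self) -> int:
        return self.windows.shape[1]

    def degenerate_regions(self) -> list[int]:
        """Regions with zero variance in some window (NaN own diagonal)."""
        diags = self.windows[:, np.arange(self.n_regions), np.arange(self.n_regions)]
        return [int(i) for i in np.nonzero(np.isnan(diags).any(axis=0))[0]]


def build_stack(series: RoiTimeSeries, l: int) -> WindowedNetworkStack:
    """Segment a series and compute every window's correlation network.

    All windows of one length are correlated in a single batched pass;
    the result is identical (to floating-point) to calling
    :func:`window_fc` per span.
    """
    spans = segment_windows(series.n_volumes, l)
    n = len(spans)
    seg = np.asarray(series.values, dtype=float)[: n * l].reshape(n, l, -1)
    xc = seg - seg.mean(axis=1, keepdims=True)
    sd = np.sqrt((xc**2).mean(axis=1))  # (n, R)
    cov = np.einsum("nlr,nls->nrs", xc, xc) / l
    with np.errstate(invalid="ignore", divide="ignore"):
        mats = cov / (sd[:, :, None] * sd[:, None, :])
    R = mats.shape[1]
    mats[:, np.arange(R), np.arange(R)] = 1.0
    degenerate = sd == 0  # (n, R)
    if degenerate.any():
        for i in range(n):
            bad = degenerate[i]
            if bad.any():
                mats[i, bad, :] = np.nan
                mats[i, :, bad] = np.nan
    mats = np.clip(mats, -1.0, 1.0)
    return WindowedNetworkStack(
        window_length=l,
        windows=mats,
        window_spans=tuple(spans),
        region_labels=series.region_labels,
    )


def variability_one_length(
    stack: WindowedNetworkStack,
    k: int,
    include_self: bool = False,
    exclude: tuple[int, ...] = (),
) -> float:
    """V_k(l) = 1 - mean pairwise correlation of region k's profiles.

    The profile of region k in window i is row k of F_i.  By default the
    self-entry (constant 1) is excluded, leaving an (R-1)-dimensional
    vector; ``include_self=True`` keeps the full R-dimensional row for
    literal replication of the textbook definition.  ``exclude`` removes
    further entries (e.g. degenerate regions) from every profile.
    """
    n, R = stack.n_windows, stack.n_regions
    if n < 2:
        raise ValueError("need at least 2 windows")
    profiles = stack.windows[:, k, :]  # (n, R)
    keep = np.ones(R, dtype=bool)
    keep[list(exclude)] = False
    if not include_self:
        keep[k] = False
    profiles = profiles[:, keep]
    if np.isnan(profiles).any():
        i = int(np.nonzero(np.isnan(profiles).any(axis=1))[0][0])
        raise ValueError(
            f"region {k} has a non-finite connectivity profile in window {i}"
        )
    sd = profiles.std(axis=1)
    if (sd == 0).any():
        i = int(np.nonzero(sd == 0)[0][0])
        raise ValueError(
            f"region {k} has a zero-variance connectivity profile in window {i}"
        )
    C = np.corrcoef(profiles)  # n x n profile-similarity matrix
    iu = np.triu_indices(n, k=1)
    return float(1.0 - C[iu].mean())


def _batched_variability(
    stack: WindowedNetworkStack,
    include_self: bool,
    exclude: tuple[int, ...],
) -> np.ndarray:
    """V_k for every region at once; NaN at excluded regions.

    Equivalent to calling :func:`variability_one_length` per region, but
    the profile-correlation matrices for all regions are computed in one
    batched pass.
    """
    n, R = stack.n_windows, stack.n_regions
    if n < 2:
        raise ValueError("need at least 2 windows")
    X = stack.windows.transpose(1, 0, 2)  # (R, n, R): profiles per region
    keep = np.ones((R, R), dtype=bool)
    keep[:, list(exclude)] = False
    keep[list(exclude), :] = False
    if not include_self:
        np.fill_diagonal(keep, False)
    active = [k for k in range(R) if k not in exclude]
    out = np.full(R, np.nan)
    if not active:
        return out
    Xa = np.nan_to_num(X[active])  # masked-out NaN entries become inert zeros
    W = keep[active].astype(float)[:, None, :]  # (Ra, 1, R)
    c = W.sum(axis=2)  # (Ra, 1)
    mean = (Xa * W).sum(axis=2) / c  # (Ra, n)
    Xc = (Xa - mean[:, :, None]) * W
    norm = np.sqrt((Xc**2).sum(axis=2))  # (Ra, n)
    if (norm == 0).any():
        k_bad, i_bad = np.argwhere(norm == 0)[0]
        raise ValueError(
            f"region {active[int(k_bad)]} has a zero-variance connectivity "
            f"profile in window {int(i_bad)}"
        )
    C = Xc @ Xc.transpose(0, 2, 1) / (norm[:, :, None] * norm[:, None, :])
    iu = np.triu_indices(n, k=1)
    out[active] = 1.0 - C[:, iu[0], iu[1]].mean(axis=1)
    return out


@dataclass(frozen=True)
class VariabilityResult:
    """Per-region V_k for each window length plus the across-length mean."""

    region_labels: tuple[str, ...]
    window_lengths: tuple[int, ...]
    per_length: np.ndarray  # (n_lengths, R); NaN for excluded regions
    include_self: bool
    excluded_regions: tuple[str, ...] = ()

    @property
    def mean(self) -> np.ndarray:
        """Unweighted arithmetic mean of V_k across window lengths."""
        return self.per_length.mean(axis=0)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.per_length.T,
            index=list(self.region_labels),
            columns=[f"V_l{l}" for l in self.window_lengths],
        )
        df.index.name = "region"
        df["V_mean"] = self.mean
        return df


def temporal_variability(
    series: RoiTimeSeries,
    length_set: tuple[int, ...] = DEFAULT_LENGTHS,
    include_self: bool = False,
) -> VariabilityResult:
    """Compute V_k at every window length and average across lengths.

    Regions flagged as degenerate (zero variance in some window, or all-NaN
    missing-label columns) under any length are excluded from the result
    (NaN in every slot) and reported in ``excluded_regions`` rather than
    silently imputed.
    """
    lengths = tuple(sorted(set(int(l) for l in length_set)))
    if not lengths:
        raise ValueError("length_set must be nonempty")
    if series.n_volumes < 2 * max(lengths):
        raise ValueError(
            f"series of {series.n_volumes} volumes too short for window "
            f"length {max(lengths)} (need >= {2 * max(lengths)})"
        )
    R = series.n_regions
    per_length = np.full((len(lengths), R), np.nan)
    excluded: set[int] = set(
        i for i in range(R) if np.isnan(series.values[:, i]).all()
    )
    stacks = []
    for li, l in enumerate(lengths):
        stack = build_stack(series, l)
        excluded.update(stack.degenerate_regions())
        stacks.append(stack)
    excl = tuple(sorted(excluded))
    for li, stack in enumerate(stacks):
        per_length[li] = _batched_variability(stack, include_self, excl)
    return VariabilityResult(
        region_labels=series.region_labels,
        window_lengths=lengths,
        per_length=per_length,
        include_self=include_self,
        excluded_regions=tuple(series.region_labels[i] for i in sorted(excluded)),
    )
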