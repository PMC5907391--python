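"""Core in-memory container for parcellated BOLD-like time series.

A :class:`RoiTimeSeries` holds a T x R matrix of regional signals (T time
points sampled every ``tr_seconds``, R atlas regions) together with the
ordered region labels and an append-only log of the conditioning steps that
produced it.  Every preprocessing operation returns a new instance; the log
is used to enforce the fixed conditioning order
(discard -> detrend -> bandpass -> regress).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

# Canonical conditioning order.  "flip" commutes with the per-column steps
# and may appear anywhere; the others must be applied in this sequence.
STEP_ORDER = ("discard", "detrend", "bandpass", "regress")


class ConditioningOrderError(RuntimeError):
    """Raised when a conditioning step is applied out of canonical order."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """T x R regional time-series matrix with labels and sampling interval.

    Parameters
    ----------
    values
        Array of shape (T, R); column r is the mean signal of region r.
    region_labels
        R region names (AAL-style) or stringified integer label ids, in
        column order.
    tr_seconds
        Sampling interval (repetition time) in seconds.
    conditioning_log
        Ordered names of the conditioning steps already applied.
    """

    values: np.ndarray
    region_labels: tuple[str, ...]
    tr_seconds: float = 2.0
    conditioning_log: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "region_labels", tuple(str(l) for l in self.region_labels))
        if values.ndim != 2:
            raise ValueError(f"values must be 2-D (T x R), got shape {values.shape}")
        T, R = values.shape
        if T < 1 or R < 2:
            raise ValueError(f"need T >= 1 and R >= 2, got T={T}, R={R}")
        if len(self.region_labels) != R:
            raise ValueError(
                f"{len(self.region_labels)} labels for {R} columns"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        # A column may be all-NaN (flagged missing region) but a column with
        # no finite values *and* no NaN marker is nonsense.
        finite_or_nan = np.isfinite(values) | np.isnan(values)
        if not finite_or_nan.all():
            raise ValueError("values contain inf entries")

    # -- basic views ----------------------------------------------------
    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def flagged_regions(self) -> list[str]:
        """Labels of all-NaN columns (e.g. atlas labels absent from the data)."""
        mask = np.isnan(self.values).all(axis=0)
        return [l for l, m in zip(self.region_labels, mask) if m]

    # -- log handling ---------------------------------------------------
    def with_values(self, values: np.ndarray, step: str | None = None) -> "RoiTimeSeries":
        """Return a copy with new values, optionally recording ``step``.

        Steps named in :data:`STEP_ORDER` must be appended in canonical
        order; any other step name (e.g. ``flip_lr``) is recorded freely.
        """
        log = self.conditioning_log
        if step is not None:
            if step in STEP_ORDER:
                rank = STEP_ORDER.index(step)
                prior = [STEP_ORDER.index(s) for s in log if s in STEP_ORDER]
                if prior and max(prior) > rank:
                    raise ConditioningOrderError(
                        f"cannot apply {step!r} after "
                        f"{STEP_ORDER[max(prior)]!r}; canonical order is "
                        + " -> ".join(STEP_ORDER)
                    )
            log = log + (step,)
        return replace(self, values=np.asarray(values, dtype=float), conditioning_log=log)


@dataclass(frozen=True)
class HomologousPairing:
    """Left/right homologous region pairing for hemisphere flipping.

    ``pairs`` holds (left, right) column indices; ``unpaired`` holds the
    midline / vermis columns that have no contralateral homologue.  Together
    they must cover every region exactly once.
    """

    pairs: tuple[tuple[int, int], ...]
    unpaired: tuple[int, ...] = ()

    def validate(self, n_regions: int) -> None:
        seen: set[int] = set()
        for l, r in self.pairs:
            for idx in (l, r):
                if idx in seen:
                    raise ValueError(f"region index {idx} appears twice in pairing")
                seen.add(idx)
        for idx in self.unpaired:
            if idx in seen:
                raise ValueError(f"region index {idx} appears twice in pairing")
            seen.add(idx)
        missing = sorted(set(range(n_regions)) - seen)
        if missing:
            raise ValueError(f"pairing does not cover regions {missing}")
        extra = sorted(seen - set(range(n_regions)))
        if extra:
            raise ValueError(f"pairing references unknown region indices {extra}")

    @classmethod
    def from_labels(cls, labels: Sequence[str]) -> "HomologousPairing":
        """Build a pairing from ``_L``/``_R`` suffixed labels.

        Labels ending in ``_L`` are paired with the same stem ending in
        ``_R``; everything else (vermis, midline) is left unpaired.
        """
        index = {str(l): i for i, l in enumerate(labels)}
        pairs: list[tuple[int, int]] = []
        used: set[int] = set()
        for name, i in index.items():
            if name.endswith("_L"):
                partner = name[:-2] + "_R"
                j = index.get(partner)
                if j is None:
                    raise ValueError(f"no right homologue for {name!r}")
                pairs.append((i, j))
                used.update((i, j))
        unpaired = tuple(i for i in range(len(labels)) if i not in used)
        return cls(pairs=tuple(pairs), unpaired=unpaired)


@dataclass(frozen=True)
class NuisanceSet:
    """Nuisance regressors: motion parameters, WM / CSF / global means.

    ``regressors`` is T x C, aligned with the series *after* initial volume
    discard.
    """

    regressors: np.ndarray
    regressor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        reg = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        object.__setattr__(self, "regressors", reg)
        object.__setattr__(self, "regressor_names", tuple(self.regressor_names))
        if reg.shape[1] != len(self.regressor_names):
            raise ValueError(
                f"{len(self.regressor_names)} names for {reg.shape[1]} regressors"
            )
        if not np.isfinite(reg).all():
            raise ValueError("nuisance regressors must be finite")
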