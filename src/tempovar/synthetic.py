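"""Synthetic cohorts of state-switching multivariate BOLD-like series.

Real resting-state connectivity is nonstationary: a region's correlation
pattern with the rest of the brain drifts between quasi-stable
configurations.  The generator emulates that premise with the minimal model
under which the temporal-variability statistic has signal: piecewise-
stationary Gaussian series whose correlation structure switches between
hidden states.

Two sampling engines are provided:

* :func:`simulate_series` — one *global* hidden-state path: within each
  dwell segment all regions are drawn from the active state's correlation
  matrix.  Useful for fixtures and for convergence checks against a known
  correlation matrix.
* :func:`simulate_region_switching` — each region follows its own
  dwell process, switching which shared latent factor it loads on.  A
  region with a shorter mean dwell reconfigures its connectivity profile
  more often and therefore has higher expected temporal variability; the
  mean dwell is the generator's single "switching intensity" knob.

:func:`simulate_cohort` uses the per-region engine to build a two-group
longitudinal cohort (patients scanned at three poststroke stages, controls
once at baseline), applies group/stage/region switching-intensity
multipliers, and couples each patient's behavioral-score recovery to the
realized change in one designated region's temporal variability.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .series import RoiTimeSeries
from .variability import DEFAULT_LENGTHS, temporal_variability

__all__ = [
    "DwellSampler",
    "StateSwitchingModel",
    "CohortDesign",
    "BehaviorCoupling",
    "GroundTruth",
    "SyntheticCohort",
    "AtlasLayout",
    "default_region_labels",
    "make_block_states",
    "default_model",
    "simulate_series",
    "simulate_region_switching",
    "simulate_cohort",
    "write_fixture_nifti",
]

# ---------------------------------------------------------------------------
# model types


@dataclass(frozen=True)
class DwellSampler:
    """Distribution over hidden-state run lengths, in volumes (support >= 1).

    ``geometric`` draws run lengths with the given mean (memoryless
    switching); ``fixed`` always returns round(mean).
    """

    mean: float
    kind: str = "geometric"

    def __post_init__(self) -> None:
        if self.mean < 1:
            raise ValueError("mean dwell length must be >= 1 volume")
        if self.kind not in ("geometric", "fixed"):
            raise ValueError(f"unknown dwell sampler kind {self.kind!r}")

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            return max(1, int(round(self.mean)))
        return int(rng.geometric(1.0 / self.mean))


@dataclass(frozen=True)
class StateSwitchingModel:
    """Hidden-state model for one multivariate series.

    ``states`` are R x R correlation matrices (symmetric, unit diagonal,
    positive semidefinite); ``dwell`` governs how long a state persists;
    ``noise_sd`` is independent observation noise added on top of the
    unit-variance latent signal; ``factor_loading`` is the latent-factor
    loading used by the per-region switching engine (within-state
    correlation between two regions on the same factor = loading**2).
    """

    n_regions: int
    states: tuple[np.ndarray, ...]
    dwell: DwellSampler
    noise_sd: float = 0.2
    tr_seconds: float = 2.0
    region_labels: tuple[str, ...] | None = None
    factor_loading: float = 0.8

    def __post_init__(self) -> None:
        states = tuple(np.asarray(S, dtype=float) for S in self.states)
        object.__setattr__(self, "states", states)
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if not states:
            raise ValueError("need at least one state matrix")
        for idx, S in enumerate(states):
            if S.shape != (self.n_regions, self.n_regions):
                raise ValueError(
                    f"state {idx} has shape {S.shape}, expected "
                    f"({self.n_regions}, {self.n_regions})"
                )
            if not np.allclose(S, S.T, atol=1e-10):
                raise ValueError(f"state {idx} is not symmetric")
            if not np.allclose(np.diag(S), 1.0, atol=1e-10):
                raise ValueError(f"state {idx} does not have a unit diagonal")
            if np.linalg.eigvalsh(S).min() < -1e-8:
                raise ValueError(f"state {idx} is not positive semidefinite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 < self.factor_loading < 1:
            raise ValueError("factor_loading must be in (0, 1)")
        if self.region_labels is not None:
            labels = tuple(str(l) for l in self.region_labels)
            if len(labels) != self.n_regions:
                raise ValueError("region_labels length mismatch")
            object.__setattr__(self, "region_labels", labels)

    @property
    def labels(self) -> tuple[str, ...]:
        if self.region_labels is not None:
            return self.region_labels
        return tuple(f"R{i + 1:03d}" for i in range(self.n_regions))


def default_region_labels(n_regions: int = 10) -> tuple[str, ...]:
    """AAL-style labels: homologous L/R pairs plus vermis if n is odd."""
    stems = ["PreCG", "PoCG", "SMA", "HIP", "STG", "SFG", "INS", "THA",
             "ACG", "FFG", "CAL", "PCUN"]
    labels: list[str] = []
    for stem in stems:
        if len(labels) + 2 > n_regions:
            break
        labels.extend([f"{stem}_L", f"{stem}_R"])
    i = 1
    while len(labels) < n_regions:
        labels.append(f"Vermis_{i}")
        i += 1
    return tuple(labels[:n_regions])


def make_block_states(
    n_regions: int,
    n_states: int = 3,
    rho: float = 0.64,
    seed: int = 0,
) -> tuple[np.ndarray, ...]:
    """Random two-block correlation matrices (within-block corr = rho).

    Each state partitions the regions into two blocks at random; a
    block-constant correlation matrix with rho < 1 is always positive
    semidefinite.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    states = []
    for _ in range(n_states):
        assign = rng.integers(0, 2, size=n_regions)
        if assign.min() == assign.max():  # avoid a degenerate single block
            assign[0] = 1 - assign[0]
        same = assign[:, None] == assign[None, :]
        S = np.where(same, rho, 0.0)
        np.fill_diagonal(S, 1.0)
        states.append(S)
    return tuple(states)


def default_model(
    n_regions: int = 10,
    mean_dwell: float = 100.0,
    n_states: int = 3,
    noise_sd: float = 0.2,
    tr_seconds: float = 2.0,
    factor_loading: float = 0.8,
) -> StateSwitchingModel:
    """Study-condition model: 10 regions, three connectivity states,
    loading 0.8, and a quasi-stable baseline (mean dwell 100 volumes,
    ~3 min at TR = 2 s) so that region-specific switching-intensity
    multipliers have real dynamic range against the background."""
    return StateSwitchingModel(
        n_regions=n_regions,
        states=make_block_states(n_regions, n_states, rho=factor_loading**2),
        dwell=DwellSampler(mean=mean_dwell),
        noise_sd=noise_sd,
        tr_seconds=tr_seconds,
        region_labels=default_region_labels(n_regions),
        factor_loading=factor_loading,
    )


@dataclass(frozen=True)
class BehaviorCoupling:
    """Linear link between the coupled region's variability change and the
    behavioral-score change: dScore = slope * dV + N(0, noise_sd**2)."""

    slope: float = 150.0
    noise_sd: float = 5.0


@dataclass(frozen=True)
class CohortDesign:
    """Two-group, three-stage longitudinal cohort layout.

    Defaults mirror the study conditions: 19 subjects per group, stages
    acute / subacute / early_chronic, controls scanned once at baseline,
    200 analysed volumes per run, behavioral scale 0-66 (upper-limb
    Fugl-Meyer), mean acute score ~34.
    """

    n_per_group: int = 19
    stages: tuple[str, ...] = ("acute", "subacute", "early_chronic")
    control_stage: str = "baseline"
    control_sessions: int = 1
    n_volumes: int = 200
    effect_map: Mapping[tuple[str, str, str], float] = field(default_factory=dict)
    coupled_region: str = "PreCG_L"
    coupling: BehaviorCoupling = field(default_factory=BehaviorCoupling)
    subject_effect_sd: float = 0.35
    recovery_gain: float = 21.5
    stage2_fraction: float = 0.42
    base_score: float = 33.6
    score_sd: float = 14.5
    score_bounds: tuple[float, float] = (0.0, 66.0)
    length_set: tuple[int, ...] = DEFAULT_LENGTHS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if len(self.stages) < 1:
            raise ValueError("need at least one patient stage")
        if self.control_sessions < 1:
            raise ValueError("control_sessions must be >= 1")
        lo, hi = self.score_bounds
        if not lo < hi:
            raise ValueError("score_bounds must be increasing")

    def validate_regions(self, labels: Iterable[str]) -> None:
        labels = set(labels)
        for (_, _, region) in self.effect_map:
            if region not in labels:
                raise ValueError(f"effect_map references unknown region {region!r}")
        if self.coupled_region not in labels:
            raise ValueError(f"coupled region {self.coupled_region!r} not in model")

    def multiplier(self, group: str, stage: str, region: str) -> float:
        return float(self.effect_map.get((group, stage, region), 1.0))


@dataclass
class GroundTruth:
    """What the generator actually did, for recovery tests.

    ``state_paths`` maps a series key to its hidden-state path: a (T,)
    state-id array for the global engine, or an (R, T) factor-id array for
    the per-region engine.  ``nominal_dwell`` maps the same keys to the
    per-region mean dwell lengths used (shorter = more switching).
    """

    state_paths: dict = field(default_factory=dict)
    nominal_dwell: dict = field(default_factory=dict)
    true_slope: float | None = None
    designed_r: float | None = None
    delta_v: dict = field(default_factory=dict)
    delta_score: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """Generated series plus long-format subject metadata."""

    series: dict  # (subject_id, stage) -> RoiTimeSeries
    metadata: pd.DataFrame  # subject_id, group, stage, lesion_side, score


# ---------------------------------------------------------------------------
# sampling engines


def _stream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-entity RNG stream, insertion-order independent."""
    digest = zlib.crc32("/".join(tokens).encode())
    return np.random.default_rng([int(seed) % (2**31), digest])


def simulate_series(
    model: StateSwitchingModel,
    n_volumes: int,
    seed: int,
    max_window_length: int = max(DEFAULT_LENGTHS),
) -> tuple[RoiTimeSeries, GroundTruth]:
    """Draw one series from the global hidden-state path.

    Dwell segments are sampled until they cover ``n_volumes``; each segment
    is assigned a state (uniformly among the states other than the previous
    one); within a segment, samples are i.i.d. multivariate normal with the
    active state's correlation matrix, plus independent N(0, noise_sd**2)
    observation noise.  Identical (model, n_volumes, seed) give
    bit-identical output.
    """
    if n_volumes < 2 * max_window_length:
        raise ValueError(
            f"n_volumes must be >= {2 * max_window_length} "
            f"(two windows at the maximum window length)"
        )
    rng = np.random.default_rng(int(seed) % (2**31))
    T, R = n_volumes, model.n_regions
    n_states = len(model.states)

    path = np.empty(T, dtype=np.int64)
    t = 0
    current = int(rng.integers(n_states))
    while t < T:
        run = model.dwell.sample(rng)
        path[t : t + run] = current
        t += run
        if n_states > 1:
            step = int(rng.integers(1, n_states))
            current = (current + step) % n_states
    chols = [np.linalg.cholesky(S + 1e-10 * np.eye(R)) for S in model.states]
    z = rng.standard_normal((T, R))
    x = np.empty((T, R))
    for s in range(n_states):
        mask = path == s
        if mask.any():
            x[mask] = z[mask] @ chols[s].T
    if model.noise_sd > 0:
        x = x + model.noise_sd * rng.standard_normal((T, R))
    series = RoiTimeSeries(x, model.labels, tr_seconds=model.tr_seconds)
    truth = GroundTruth(
        state_paths={"series": path},
        nominal_dwell={"series": np.full(R, model.dwell.mean)},
    )
    return series, truth


def simulate_region_switching(
    n_volumes: int,
    mean_dwells: np.ndarray,
    rng: np.random.Generator,
    n_factors: int = 3,
    loading: float = 0.8,
    noise_sd: float = 0.2,
    dwell_kind: str = "geometric",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-region factor-switching engine.

    ``n_factors`` latent standard-normal signals are shared by all regions.
    Region r follows its own run-length process with mean dwell
    ``mean_dwells[r]``; within a run it loads on one factor:

        x_r(t) = loading * f_{a_r(t)}(t) + sqrt(1 - loading**2) * eps_r(t)

    so two regions currently on the same factor correlate at loading**2 and
    a region that switches factors more often reconfigures its connectivity
    profile more.  Returns (T x R values, R x T factor paths).
    """
    mean_dwells = np.asarray(mean_dwells, dtype=float)
    R = mean_dwells.size
    if np.any(mean_dwells < 1):
        raise ValueError("mean dwell lengths must be >= 1 volume")
    T = int(n_volumes)
    factors = rng.standard_normal((T, n_factors))
    eps = rng.standard_normal((T, R))
    paths = np.empty((R, T), dtype=np.int64)
    for r in range(R):
        sampler = DwellSampler(mean=float(mean_dwells[r]), kind=dwell_kind)
        t = 0
        current = int(rng.integers(n_factors))
        while t < T:
            run = sampler.sample(rng)
            paths[r, t : t + run] = current
            t += run
            if n_factors > 1:
                step = int(rng.integers(1, n_factors))
                current = (current + step) % n_factors
    sig = loading * np.take_along_axis(factors, paths.T, axis=1)
    x = sig + np.sqrt(1.0 - loading**2) * eps
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal((T, R))
    return x, paths


# ---------------------------------------------------------------------------
# cohort generation


def simulate_cohort(
    design: CohortDesign,
    model: StateSwitchingModel | None = None,
) -> tuple[SyntheticCohort, GroundTruth]:
    """Generate the full longitudinal cohort.

    Patients get one series per stage; controls get ``control_sessions``
    sessions (default one baseline scan).  A region's mean dwell for a
    given (group, stage) is ``model.dwell.mean / multiplier``, so
    switching-intensity multipliers > 1 shorten dwells and raise expected
    temporal variability.  The designated coupled region additionally gets
    a per-patient log-normal jitter of its stage-2 multiplier; each
    patient's behavioral-score change from first to last stage is then

        recovery_gain + slope * (V at stage 2 - V at stage 1) + noise

    evaluated on the region's realized temporal variability, which makes
    the downstream change-change correlation a designed property of the
    cohort.  Scores are clamped to ``score_bounds``.
    """
    if model is None:
        model = default_model()
    design.validate_regions(model.labels)
    labels = model.labels
    R = model.n_regions
    coupled_idx = labels.index(design.coupled_region)
    n_factors = max(2, len(model.states))

    series: dict[tuple[str, str], RoiTimeSeries] = {}
    truth = GroundTruth(true_slope=design.coupling.slope)
    rows = []

    def _one_series(subject: str, group: str, stage: str, dwells: np.ndarray):
        rng = _stream(design.seed, "series", subject, stage)
        x, paths = simulate_region_switching(
            design.n_volumes,
            dwells,
            rng,
            n_factors=n_factors,
            loading=model.factor_loading,
            noise_sd=model.noise_sd,
        )
        s = RoiTimeSeries(x, labels, tr_seconds=model.tr_seconds)
        series[(subject, stage)] = s
        truth.state_paths[(subject, stage)] = paths
        truth.nominal_dwell[(subject, stage)] = dwells
        return s

    # -- patients ------------------------------------------------------
    stage1, stage_last = design.stages[0], design.stages[-1]
    stage2 = design.stages[1] if len(design.stages) > 1 else design.stages[0]
    for p in range(design.n_per_group):
        subject = f"P{p + 1:02d}"
        srng = _stream(design.seed, "subject", subject)
        jitter = float(np.exp(design.subject_effect_sd * srng.standard_normal()))
        lesion_side = "L" if srng.random() < 0.5 else "R"

        v_by_stage: dict[str, float] = {}
        for stage in design.stages:
            dwells = np.array(
                [
                    model.dwell.mean / design.multiplier("patient", stage, lab)
                    for lab in labels
                ]
            )
            if stage == stage2:
                dwells[coupled_idx] = max(1.0, dwells[coupled_idx] / jitter)
            s = _one_series(subject, "patient", stage, dwells)
            if stage in (stage1, stage2):
                res = temporal_variability(s, design.length_set)
                v_by_stage[stage] = float(res.mean[coupled_idx])

        dv = v_by_stage[stage2] - v_by_stage[stage1]
        truth.delta_v[subject] = dv

        score1 = float(
            np.clip(
                design.base_score + design.score_sd * srng.standard_normal(),
                *design.score_bounds,
            )
        )
        dscore = (
            design.recovery_gain
            + design.coupling.slope * dv
            + design.coupling.noise_sd * srng.standard_normal()
        )
        truth.delta_score[subject] = dscore
        score_last = float(np.clip(score1 + dscore, *design.score_bounds))
        score_mid = float(
            np.clip(
                score1
                + design.stage2_fraction * dscore
                + 0.5 * design.coupling.noise_sd * srng.standard_normal(),
                *design.score_bounds,
            )
        )
        scores = {stage1: score1, stage2: score_mid, stage_last: score_last}
        for stage in design.stages:
            rows.append(
                {
                    "subject_id": subject,
                    "group": "patient",
                    "stage": stage,
                    "lesion_side": lesion_side,
                    "score": scores.get(stage, np.nan),
                }
            )

    # designed change-change correlation given the realized dV spread
    dvs = np.array(list(truth.delta_v.values()))
    if dvs.size >= 2 and dvs.std(ddof=1) > 0:
        num = abs(design.coupling.slope) * dvs.std(ddof=1)
        truth.designed_r = float(
            np.sign(design.coupling.slope)
            * num
            / np.hypot(num, design.coupling.noise_sd)
        )
    else:
        truth.designed_r = 0.0

    # -- controls ------------------------------------------------------
    control_stages = (
        [design.control_stage]
        if design.control_sessions == 1
        else list(design.stages[: design.control_sessions])
    )
    for c in range(design.n_per_group):
        subject = f"C{c + 1:02d}"
        for stage in control_stages:
            dwells = np.array(
                [
                    model.dwell.mean / design.multiplier("control", stage, lab)
                    for lab in labels
                ]
            )
            _one_series(subject, "control", stage, dwells)
            rows.append(
                {
                    "subject_id": subject,
                    "group": "control",
                    "stage": stage,
                    "lesion_side": "",
                    "score": np.nan,
                }
            )

    metadata = pd.DataFrame(rows, columns=["subject_id", "group", "stage", "lesion_side", "score"])
    return SyntheticCohort(series=series, metadata=metadata), truth


# ---------------------------------------------------------------------------
# NIfTI fixtures


@dataclass(frozen=True)
class AtlasLayout:
    """Voxel geometry for tiny NIfTI fixtures.

    ``voxels`` maps integer label ids to voxel coordinate lists inside
    ``shape``.  Series columns are assigned to label ids in ascending-id
    order, matching the extraction convention.
    """

    shape: tuple[int, int, int]
    voxels: Mapping[int, tuple[tuple[int, int, int], ...]]

    def validate(self, n_regions: int) -> None:
        if len(self.voxels) != n_regions:
            raise ValueError(
                f"layout has {len(self.voxels)} regions, series has {n_regions}"
            )
        seen: set[tuple[int, int, int]] = set()
        for rid, vox in self.voxels.items():
            if int(rid) <= 0:
                raise ValueError("label ids must be positive integers")
            if len(vox) == 0:
                raise ValueError(f"region {rid} has no voxels")
            for v in vox:
                v = tuple(int(c) for c in v)
                if any(not 0 <= c < s for c, s in zip(v, self.shape)):
                    raise ValueError(f"voxel {v} outside grid {self.shape}")
                if v in seen:
                    raise ValueError(f"voxel {v} assigned to more than one region")
                seen.add(v)

    @classmethod
    def cubes(cls, n_regions: int, shape=(10, 10, 10), side: int = 2) -> "AtlasLayout":
        """Simple non-overlapping cube per region, label ids 1..n."""
        per_axis = shape[0] // side
        voxels = {}
        for i in range(n_regions):
            ix, iy, iz = i % per_axis, (i // per_axis) % per_axis, i // per_axis**2
            if iz >= shape[2] // side:
                raise ValueError("grid too small for the requested region count")
            vox = tuple(
                (ix * side + a, iy * side + b, iz * side + c)
                for a in range(side)
                for b in range(side)
                for c in range(side)
            )
            voxels[i + 1] = vox
        return cls(shape=tuple(shape), voxels=voxels)


def write_fixture_nifti(
    series: RoiTimeSeries,
    layout: AtlasLayout,
    bold_path,
    atlas_path,
    voxel_noise_sd: float = 0.0,
    seed: int = 0,
) -> None:
    """Write a 4D BOLD NIfTI plus its 3D integer label atlas.

    Every voxel of region r carries region r's series (plus optional
    i.i.d. voxel noise), so extraction round-trips the input exactly when
    ``voxel_noise_sd`` is 0.
    """
    import nibabel as nib

    layout.validate(series.n_regions)
    rng = np.random.default_rng(seed)
    T = series.n_volumes
    data = np.zeros(layout.shape + (T,), dtype=np.float64)
    atlas = np.zeros(layout.shape, dtype=np.int16)
    for col, rid in enumerate(sorted(layout.voxels)):
        for v in layout.voxels[rid]:
            trace = series.values[:, col]
            if voxel_noise_sd > 0:
                trace = trace + voxel_noise_sd * rng.standard_normal(T)
            data[v[0], v[1], v[2], :] = trace
            atlas[v[0], v[1], v[2]] = rid
    affine = np.eye(4)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr_seconds))
    nib.save(img, str(bold_path))
    nib.save(nib.Nifti1Image(atlas, affine), str(atlas_path))
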