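"""Synthetic multi-subject BOLD datasets with planted, recoverable effects.

The generator emulates the statistical structure the univariate and
multivariate analyses assume, on a deliberately small voxel grid (no MNI
space, no atlas anatomy):

* univariate condition and modulator effects: HRF-convolved regressors built
  from a session event table, scaled by per-ROI amplitudes with Gaussian
  between-subject deviations (e.g. a negative density slope in the
  "auditory" ROI: sparser stacks drive a stronger response);
* multivoxel density patterns: a voxelwise pattern, fixed across subjects
  (the across-participant searchlight requires a shared voxel code), enters
  as +pattern/2 on high-density stacks and -pattern/2 on low-density ones;
* noise: AR(1) (default coefficient 0.3) plus cosine drift spanning the
  high-pass band, plus a leak of the nuisance series (six motion random
  walks and a 0.25-Hz respiration sinusoid aliased to the TR grid).

Everything is seeded and reproducible; effect amplitudes of zero give a
pure-noise null dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy.signal import lfilter

from .glm import (
    HRFParams,
    ModulatorSpec,
    _dct_highpass_basis,
    _sample_convolved,
    canonical_hrf,
    condition_spec_whole_trial,
    condition_spec_adjust,
    stack_events,
    DEFAULT_HP_CUTOFF_HZ,
)

__all__ = [
    "VolumeGrid",
    "EffectSpec",
    "PatternSpec",
    "SubjectDataset",
    "make_grid_and_rois",
    "generate_nuisance",
    "generate_subject",
    "generate_cohort",
]

DEFAULT_TR_S = 1.056
DEFAULT_VOXEL_MM = 3.0
DEFAULT_SHAPE = (20, 20, 16)

#: Default ROI centres as fractions of the grid shape.
DEFAULT_ROI_CENTERS = {
    "auditory": (0.28, 0.30, 0.42),
    "hippocampus": (0.68, 0.32, 0.38),
    "ifg": (0.32, 0.70, 0.55),
    "cingulate": (0.68, 0.70, 0.60),
}
#: Default ROI size: ~80 voxels at 3 mm, on the order of a small anatomical
#: region (a 33-voxel blob is too small for smoothed group peaks to resolve).
DEFAULT_ROI_VOXELS = 80


@dataclass(frozen=True)
class VolumeGrid:
    """Acquisition grid: shape, isotropic voxel size, TR, volume count."""

    shape: tuple[int, int, int] = DEFAULT_SHAPE
    voxel_size_mm: float = DEFAULT_VOXEL_MM
    tr_s: float = DEFAULT_TR_S
    n_volumes: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) <= 0 or self.voxel_size_mm <= 0 or self.tr_s <= 0:
            raise ValueError("grid dimensions, voxel size and TR must be positive")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size_mm
        return aff

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_volumes) * self.tr_s


@dataclass(frozen=True)
class PatternSpec:
    """A planted multivoxel pattern: which ROI, which labels, what size.

    ``scheme`` names the binary labelling the pattern discriminates
    ("density" splits adjustment stacks at the scale midpoint; "target"
    splits memory trials by target level over the whole trial).  ``sd`` is
    the voxelwise SD of the pattern; the realised pattern is shared by every
    subject in a cohort.
    """

    roi: str
    scheme: str = "density"
    sd: float = 1.0


@dataclass
class EffectSpec:
    """Amplitudes and noise parameters for the generator.

    ``univariate_betas`` maps ROI name -> {regressor name -> amplitude},
    where regressor names refer to whole-trial condition blocks (MA/MP/...)
    or the adjustment-phase density modulator ("density").  Amplitudes are
    in units of the noise SD (so an amplitude of 1 is a 1-sigma effect per
    frame before HRF dilution).
    """

    univariate_betas: dict[str, dict[str, float]] = field(default_factory=dict)
    patterns: tuple[PatternSpec, ...] = ()
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_sd: float = 0.5
    nuisance_leak_sd: float = 0.2
    subject_sigma: float = 0.2
    #: Between-subject SD of the multiplicative pattern amplitude (subjects
    #: share the voxel code but express it with different strength; without
    #: this, group t-statistics at pattern voxels diverge).
    pattern_subject_sigma: float = 0.3
    respiration_hz: float = 0.25

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise SD must be positive")


@dataclass
class SubjectDataset:
    """One synthetic participant: BOLD grid, events, nuisance, provenance."""

    bold: np.ndarray               # (x, y, z, t)
    events: pd.DataFrame
    nuisance: pd.DataFrame
    grid: VolumeGrid
    brain_mask: np.ndarray
    rois: dict[str, np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.bold)):
            raise ValueError("BOLD contains non-finite values")
        if self.bold.shape[-1] != self.grid.n_volumes:
            raise ValueError("BOLD volume count must match the grid")

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.bold.astype(np.float32), self.grid.affine)

    def save(self, directory: str | Path, stem: str = "subject") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        nib.save(self.to_nifti(), directory / f"{stem}_bold.nii")
        self.events.to_csv(directory / f"{stem}_events.tsv", sep="\t",
                           index=False, na_rep="n/a")
        self.nuisance.to_csv(directory / f"{stem}_nuisance.tsv", sep="\t",
                             index=False)


def make_grid_and_rois(
    shape: tuple[int, int, int] = DEFAULT_SHAPE,
    voxel_size_mm: float = DEFAULT_VOXEL_MM,
    tr_s: float = DEFAULT_TR_S,
    roi_centers: dict[str, tuple[float, float, float]] | None = None,
    roi_voxels: int | dict[str, int] = DEFAULT_ROI_VOXELS,
) -> tuple[VolumeGrid, np.ndarray, dict[str, np.ndarray]]:
    """Build the grid, an ellipsoidal brain mask, and disjoint blob ROIs.

    Each ROI takes exactly the requested number of voxels: the nearest
    voxels to its centre (ties broken lexicographically) inside the brain
    mask and not already claimed by an earlier ROI.  Purely deterministic.
    """
    grid = VolumeGrid(shape=shape, voxel_size_mm=voxel_size_mm, tr_s=tr_s)
    idx = np.indices(shape, dtype=float)
    center = (np.asarray(shape, dtype=float) - 1) / 2
    semi = np.asarray(shape, dtype=float) * 0.48
    dist2 = sum(((idx[d] - center[d]) / semi[d]) ** 2 for d in range(3))
    brain_mask = dist2 <= 1.0

    if roi_centers is None:
        roi_centers = DEFAULT_ROI_CENTERS
    if isinstance(roi_voxels, int):
        roi_voxels = {name: roi_voxels for name in roi_centers}

    rois: dict[str, np.ndarray] = {}
    claimed = np.zeros(shape, dtype=bool)
    flat_coords = np.argwhere(np.ones(shape, dtype=bool))
    for name, frac in roi_centers.items():
        n_req = roi_voxels[name]
        c = np.asarray(frac) * (np.asarray(shape) - 1)
        d2 = np.sum((flat_coords - c) ** 2, axis=1)
        order = np.lexsort((flat_coords[:, 2], flat_coords[:, 1],
                            flat_coords[:, 0], d2))
        mask = np.zeros(shape, dtype=bool)
        taken = 0
        for i in order:
            co = tuple(flat_coords[i])
            if not brain_mask[co] or claimed[co]:
                continue
            mask[co] = True
            taken += 1
            if taken == n_req:
                break
        if taken < n_req:
            raise ValueError(f"ROI {name!r} does not fit in the brain mask")
        rois[name] = mask
        claimed |= mask
    return grid, brain_mask, rois


def generate_nuisance(
    grid: VolumeGrid, rng: np.random.Generator,
    respiration_hz: float = 0.25,
) -> pd.DataFrame:
    """Six motion random walks (mm) plus a respiration sinusoid on the TR grid."""
    t = grid.frame_times
    cols = {}
    for i in range(6):
        steps = rng.normal(0.0, 0.02, size=grid.n_volumes)
        cols[f"motion_{i}"] = np.cumsum(steps)
    phase = rng.uniform(0, 2 * np.pi)
    cols["respiration"] = np.sin(2 * np.pi * respiration_hz * t + phase)
    return pd.DataFrame(cols)


def _ar1_noise(rng, rho, sd, shape_vt):
    """Stationary AR(1) series, SD ``sd``, along the first axis."""
    white = rng.normal(0.0, sd * np.sqrt(1 - rho**2), size=shape_vt)
    return lfilter([1.0], [1.0, -rho], white, axis=0)


def _residualize(y: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    X = np.column_stack(basis)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _density_label_regressors(
    events: pd.DataFrame, n_levels: int, frame_times, tr_s, hrf, oversample
) -> tuple[np.ndarray, np.ndarray]:
    """Convolved low- and high-density label regressors over adjust stacks."""
    stacks = stack_events(events)
    high = stacks.density_level >= n_levels // 2
    out = []
    for sel in (~high, high):
        ev = stacks[sel]
        col = np.zeros(len(frame_times))
        if len(ev):
            col = _sample_convolved(
                ev["onset"].to_numpy(), ev["duration"].to_numpy(),
                np.ones(len(ev)), frame_times, tr_s, hrf, oversample,
            )
        out.append(col)
    return out[0], out[1]


def _binary_density_diff(
    events: pd.DataFrame, n_levels: int, frame_times, tr_s, hrf, oversample
) -> np.ndarray:
    """Convolved (high - low) density-label regressor over adjustment stacks."""
    low, high = _density_label_regressors(
        events, n_levels, frame_times, tr_s, hrf, oversample
    )
    return high - low


def _binary_target_diff(
    events: pd.DataFrame, n_levels: int, frame_times, tr_s, hrf, oversample
) -> np.ndarray:
    """Convolved (high - low) target-label regressor over whole memory trials."""
    spans = []
    for _, g in events[events.condition.isin(["MA", "MP"])].groupby("trial_index"):
        instr = g[g.event_type == "instruction"].iloc[0]
        rating = g[g.event_type == "rating_window"].iloc[0]
        spans.append((instr.onset, rating.onset + rating.duration - instr.onset,
                      int(g["target_level"].iloc[0])))
    out = np.zeros(len(frame_times))
    for onset, dur, target in spans:
        sign = 1.0 if target >= n_levels // 2 else -1.0
        out += sign * _sample_convolved(
            [onset], [dur], [1.0], frame_times, tr_s, hrf, oversample
        )
    return out


def generate_subject(
    grid: VolumeGrid,
    brain_mask: np.ndarray,
    rois: dict[str, np.ndarray],
    events: pd.DataFrame,
    effect_spec: EffectSpec,
    seed: int,
    shared_patterns: dict[tuple[str, str], np.ndarray] | None = None,
    n_levels: int = 26,
    oversample: int = 16,
) -> SubjectDataset:
    """Simulate one subject's 4D BOLD from an event table and effect spec.

    ``shared_patterns`` maps (roi, scheme) to the cohort-shared voxel
    pattern; when absent the subject draws its own (single-subject use).
    """
    rng = np.random.default_rng(seed)
    end = events["onset"].max() + events["duration"].max()
    n_volumes = int(np.ceil(end / grid.tr_s)) + int(8 / grid.tr_s)
    grid = VolumeGrid(grid.shape, grid.voxel_size_mm, grid.tr_s, n_volumes)
    frame_times = grid.frame_times
    hrf = canonical_hrf(grid.tr_s / oversample)

    n_vox = int(np.prod(grid.shape))
    bold = np.zeros((n_volumes, n_vox))

    # Nuisance and drift first: plants are orthogonalized against them.
    nuisance = generate_nuisance(grid, rng, effect_spec.respiration_hz)
    drift_basis = _dct_highpass_basis(n_volumes, grid.tr_s, DEFAULT_HP_CUTOFF_HZ)
    common_basis = [nuisance[c].to_numpy() for c in nuisance.columns]
    common_basis += [drift_basis[:, k] for k in range(drift_basis.shape[1])]
    common_basis.append(np.ones(n_volumes))

    # Regressor bank.
    regressors: dict[str, np.ndarray] = {}
    for name, ev in condition_spec_whole_trial(events).items():
        regressors[name] = _sample_convolved(
            ev["onset"].to_numpy(), ev["duration"].to_numpy(),
            np.ones(len(ev)), frame_times, grid.tr_s, hrf, oversample,
        )
    stacks = stack_events(events)
    values = stacks["density_level"].to_numpy(dtype=float)
    density_linear = _sample_convolved(
        stacks["onset"].to_numpy(), stacks["duration"].to_numpy(),
        values - values.mean(), frame_times, grid.tr_s, hrf, oversample,
    )
    # The linear modulator and the binary label split are strongly
    # correlated, so the two planted density effects must be mutually
    # identifiable: the univariate effect enters through the modulator
    # component orthogonal to the label design space (label regressors,
    # nuisance, drift, constant) and the multivoxel pattern (below) through
    # the raw label contrast.  A GLM carrying the label regressors plus a
    # label-orthogonalized modulator then recovers the planted slope
    # exactly, and the label contrast recovers the pattern, with zero
    # cross-talk under OLS.
    label_low, label_high = _density_label_regressors(
        events, n_levels, frame_times, grid.tr_s, hrf, oversample
    )
    regressors["density"] = _residualize(
        density_linear, [label_low, label_high] + common_basis
    )

    # Univariate ROI effects with between-subject amplitude deviations.
    for roi_name, betas in effect_spec.univariate_betas.items():
        roi_flat = rois[roi_name].reshape(-1)
        for reg_name, amp in betas.items():
            if reg_name not in regressors:
                raise ValueError(f"unknown regressor {reg_name!r} in effect spec")
            amp_s = amp + rng.normal(0.0, effect_spec.subject_sigma * abs(amp))
            bold[:, roi_flat] += np.outer(regressors[reg_name],
                                          np.full(roi_flat.sum(), amp_s))

    # Shared multivoxel patterns.
    diff_builders = {"density": _binary_density_diff, "target": _binary_target_diff}
    for pat in effect_spec.patterns:
        key = (pat.roi, pat.scheme)
        if shared_patterns is not None and key in shared_patterns:
            pattern = shared_patterns[key]
        else:
            pattern = rng.normal(0.0, pat.sd, size=int(rois[pat.roi].sum()))
        diff = diff_builders[pat.scheme](
            events, n_levels, frame_times, grid.tr_s, hrf, oversample
        )
        amp_s = 1.0 + rng.normal(0.0, effect_spec.pattern_subject_sigma)
        roi_flat = rois[pat.roi].reshape(-1)
        bold[:, roi_flat] += 0.5 * amp_s * np.outer(diff, pattern)

    # Noise, drift, nuisance leak.
    bold += _ar1_noise(rng, effect_spec.ar1_rho, effect_spec.noise_sd,
                       (n_volumes, n_vox))
    if drift_basis.shape[1]:
        coefs = rng.normal(0.0, effect_spec.drift_sd,
                           size=(drift_basis.shape[1], n_vox))
        bold += drift_basis @ coefs
    for col in nuisance.columns:
        leak = rng.normal(0.0, effect_spec.nuisance_leak_sd, size=n_vox)
        series = nuisance[col].to_numpy()
        bold += np.outer(series - series.mean(), leak)

    bold4d = bold.T.reshape(*grid.shape, n_volumes)
    bold4d[~brain_mask] = 0.0
    return SubjectDataset(
        bold=bold4d, events=events, nuisance=nuisance, grid=grid,
        brain_mask=brain_mask, rois=rois, seed=seed,
    )


def generate_cohort(
    grid: VolumeGrid,
    brain_mask: np.ndarray,
    rois: dict[str, np.ndarray],
    events: pd.DataFrame | list[pd.DataFrame],
    effect_spec: EffectSpec,
    n_subjects: int = 25,
    rng: np.random.Generator | int | None = None,
    n_levels: int = 26,
) -> list[SubjectDataset]:
    """Simulate a cohort with patterns shared across subjects.

    ``events`` may be one table (all subjects saw the same schedule) or one
    per subject.  Noise, drift, nuisance and univariate amplitude deviations
    are independent across subjects; the multivoxel patterns are drawn once
    from the cohort generator so that across-participant decoding has a
    consistent voxel code to find.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    rng = np.random.default_rng(rng)
    shared = {
        (pat.roi, pat.scheme): rng.normal(0.0, pat.sd,
                                          size=int(rois[pat.roi].sum()))
        for pat in effect_spec.patterns
    }
    if isinstance(events, pd.DataFrame):
        events = [events] * n_subjects
    if len(events) != n_subjects:
        raise ValueError("need one event table per subject")
    seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        generate_subject(grid, brain_mask, rois, events[s], effect_spec,
                         int(seeds[s]), shared, n_levels)
        for s in range(n_subjects)
    ]
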