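"""First- and second-level GLM analysis for the synthetic BOLD pipeline.

First level: task phases enter as boxcars convolved with the canonical
double-gamma HRF; per-event covariates (density, distance from target,
elapsed time, performance) enter as centered, serially orthogonalized
parametric modulators; a discrete-cosine high-pass basis (cutoff 1/230 Hz,
twice the longest interval between same-condition trials) and nuisance
series complete the design.  Fitting is voxelwise OLS with optional AR(1)
prewhitening (coefficient pooled over the mask from OLS residuals).

Second level: voxelwise one-sample t-tests over subjects, with family-wise
error control by sign-flip max-statistic permutation (Bonferroni available
as a fast fallback) and cluster extraction by 6-connectivity.  Small-volume
correction restricts the same procedure to an a priori mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import gammaln
from scipy.stats import t as t_dist

__all__ = [
    "HRFParams",
    "canonical_hrf",
    "condition_spec_whole_trial",
    "condition_spec_adjust",
    "stack_events",
    "ModulatorSpec",
    "DesignMatrix",
    "build_design",
    "GLMResult",
    "fit_glm",
    "StatMap",
    "contrast_map",
    "group_inference",
    "FWEResult",
    "threshold_fwe",
]

DEFAULT_HP_CUTOFF_HZ = 1.0 / 230.0


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma parameters (SPM convention, seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0
    length: float = 32.0


def _gamma_pdf(t: np.ndarray, shape: float, scale: float) -> np.ndarray:
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    out[pos] = np.exp(
        (shape - 1) * np.log(tp) - tp / scale - gammaln(shape) - shape * np.log(scale)
    )
    return out


def canonical_hrf(
    dt: float, params: HRFParams = HRFParams()
) -> np.ndarray:
    """Sample the canonical HRF at resolution ``dt`` seconds, unit peak.

    Difference of two gamma densities: a response peaking near 5 s minus a
    late undershoot (peak 16 s) scaled by 1/ratio, over ``params.length``
    seconds.  The kernel is zero at t = 0 and integrates to a positive net
    response.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, params.length, dt)
    h = _gamma_pdf(t, params.peak_delay / params.peak_disp, params.peak_disp)
    h -= _gamma_pdf(
        t, params.undershoot_delay / params.undershoot_disp, params.undershoot_disp
    ) / params.ratio
    return h / h.max()


# ---------------------------------------------------------------------------
# Event-table -> regressor helpers


def condition_spec_whole_trial(events: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One whole-trial block per condition (instructions through rating)."""
    spec = {}
    for cond, g in events.groupby("condition", sort=True):
        rows = []
        for _, trial in g.groupby("trial_index"):
            instr = trial[trial.event_type == "instruction"].iloc[0]
            rating = trial[trial.event_type == "rating_window"].iloc[0]
            end = rating.onset + rating.duration
            rows.append(dict(onset=instr.onset, duration=end - instr.onset))
        spec[cond] = pd.DataFrame(rows).sort_values("onset", ignore_index=True)
    return spec


def condition_spec_adjust(events: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """One 8-s adjustment-phase block per trial, grouped by condition."""
    stacks = events[events.event_type == "adjust_stack"]
    spec = {}
    for cond, g in stacks.groupby("condition", sort=True):
        rows = []
        for _, trial in g.groupby("trial_index"):
            onset = trial["onset"].min()
            end = trial["onset"].max() + trial["duration"].iloc[-1]
            rows.append(dict(onset=onset, duration=end - onset))
        spec[cond] = pd.DataFrame(rows).sort_values("onset", ignore_index=True)
    return spec


def stack_events(events: pd.DataFrame) -> pd.DataFrame:
    """All adjustment-phase stack events with their density levels."""
    stacks = events[events.event_type == "adjust_stack"]
    return stacks[["onset", "duration", "density_level", "condition",
                   "trial_index"]].sort_values("onset", ignore_index=True)


@dataclass(frozen=True)
class ModulatorSpec:
    """A parametric modulator: per-event values scaling a set of events.

    ``values`` has one entry per event (in onset order).  By default the
    events and the serial-orthogonalization basis come from ``parent``:
    modulators sharing a parent are orthogonalized in declared order, each
    against the parent boxcar and all earlier siblings.  Alternatively an
    explicit ``events`` frame (onset/duration columns) and an explicit
    ``ortho_against`` tuple of column names can be given, e.g. to enter a
    fine-grained covariate orthogonal to several condition regressors.
    """

    name: str
    parent: str | None
    values: tuple[float, ...]
    events: object | None = None          # pd.DataFrame with onset/duration
    ortho_against: tuple[str, ...] | None = None


@dataclass
class DesignMatrix:
    matrix: pd.DataFrame
    frame_times: np.ndarray
    task_columns: list[str]
    ortho_order: list[str] = field(default_factory=list)

    @property
    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()


def _sample_convolved(
    onsets, durations, amplitudes, frame_times, tr_s, hrf, oversample
) -> np.ndarray:
    """Boxcar at high resolution, convolve with HRF, sample at frames."""
    dt = tr_s / oversample
    n_hi = int(np.ceil((frame_times[-1] + tr_s) / dt)) + hrf.size
    hi = np.zeros(n_hi)
    for on, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(on / dt))
        i1 = max(i0 + 1, int(round((on + dur) / dt)))
        hi[i0:min(i1, n_hi)] += amp
    conv = np.convolve(hi, hrf)[:n_hi]
    idx = np.round(frame_times / dt).astype(int)
    return conv[idx]


def _dct_highpass_basis(n_frames: int, tr_s: float, cutoff_hz: float) -> np.ndarray:
    """Cosine drift columns spanning frequencies below the cutoff.

    The number of columns is floor(2 * T * cutoff) for a run of T seconds,
    the standard DCT-basis count for a high-pass band edge.
    """
    total_s = n_frames * tr_s
    k_max = int(np.floor(2.0 * total_s * cutoff_hz))
    n = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (2 * n + 1) / (2 * n_frames)) for k in
            range(1, k_max + 1)]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def _residualize(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def build_design(
    events: pd.DataFrame,
    condition_spec: dict[str, pd.DataFrame],
    n_volumes: int,
    tr_s: float,
    modulators: tuple[ModulatorSpec, ...] = (),
    nuisance: pd.DataFrame | None = None,
    hp_cutoff_hz: float = DEFAULT_HP_CUTOFF_HZ,
    hrf_params: HRFParams = HRFParams(),
    oversample: int = 16,
) -> DesignMatrix:
    """Assemble the first-level design matrix.

    ``condition_spec`` maps regressor names to event frames with ``onset``
    and ``duration`` columns (build them from the session event table with
    whatever trial/phase selection the analysis calls for).  ``events`` is
    kept for provenance only; all columns come from ``condition_spec``,
    ``modulators`` and ``nuisance``.  Raises on rank deficiency, naming the
    collinear columns.
    """
    frame_times = np.arange(n_volumes) * tr_s
    hrf = canonical_hrf(tr_s / oversample, hrf_params)
    cols: dict[str, np.ndarray] = {}
    ortho_order: list[str] = []

    for name, ev in condition_spec.items():
        cols[name] = _sample_convolved(
            ev["onset"].to_numpy(),
            ev["duration"].to_numpy(),
            np.ones(len(ev)),
            frame_times,
            tr_s,
            hrf,
            oversample,
        )

    siblings: dict[str, list[str]] = {}
    for mod in modulators:
        if mod.events is not None:
            ev = mod.events
        else:
            if mod.parent not in condition_spec:
                raise ValueError(f"modulator {mod.name!r} has unknown parent "
                                 f"{mod.parent!r}")
            ev = condition_spec[mod.parent]
        values = np.asarray(mod.values, dtype=float)
        if values.size != len(ev):
            raise ValueError(
                f"modulator {mod.name!r}: one value per event required"
            )
        centered = values - values.mean()
        if np.allclose(centered, 0):
            warnings.warn(
                f"modulator {mod.name!r} is constant over its events; dropped"
            )
            continue
        col = _sample_convolved(
            ev["onset"].to_numpy(),
            ev["duration"].to_numpy(),
            centered,
            frame_times,
            tr_s,
            hrf,
            oversample,
        )
        # Serial orthogonalization: declared basis, or parent followed by
        # earlier siblings in declared order.
        if mod.ortho_against is not None:
            basis = [cols[c] for c in mod.ortho_against]
        else:
            basis = [cols[mod.parent]]
            basis += [cols[s] for s in siblings.get(mod.parent, [])]
        col = _residualize(col, np.column_stack(basis))
        cols[mod.name] = col
        if mod.parent is not None:
            siblings.setdefault(mod.parent, []).append(mod.name)
        ortho_order.append(mod.name)

    task_columns = list(cols)

    if nuisance is not None:
        for name in nuisance.columns:
            series = nuisance[name].to_numpy(dtype=float)
            if series.size != n_volumes:
                raise ValueError(f"nuisance column {name!r} length mismatch")
            cols[f"nuis_{name}"] = series

    drift = _dct_highpass_basis(n_volumes, tr_s, hp_cutoff_hz)
    for k in range(drift.shape[1]):
        cols[f"drift_{k + 1}"] = drift[:, k]
    cols["constant"] = np.ones(n_volumes)

    X = pd.DataFrame(cols, index=frame_times)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1])
               if abs(r[i, i]) < 1e-8 * abs(r).max()]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    return DesignMatrix(X, frame_times, task_columns, ortho_order)


# ---------------------------------------------------------------------------
# First-level fit


@dataclass
class GLMResult:
    betas: dict[str, np.ndarray]   # column name -> volume (or flat vector)
    residuals: np.ndarray          # (n_frames, n_voxels), whitened scale
    sigma: np.ndarray              # residual SD per voxel
    df: int
    design: DesignMatrix
    shape: tuple[int, ...]         # spatial shape of the input
    mask: np.ndarray | None
    ar1_rho: float = 0.0

    def beta_map(self, name: str) -> np.ndarray:
        return self.betas[name]


def _flatten_bold(bold: np.ndarray, mask: np.ndarray | None):
    if bold.ndim == 2:  # (frames, voxels) already
        return bold, None
    spatial = bold.shape[:-1]
    flat = bold.reshape(-1, bold.shape[-1]).T
    if mask is not None:
        flat = flat[:, mask.reshape(-1)]
    return flat, spatial


def _unflatten(vec: np.ndarray, spatial, mask) -> np.ndarray:
    if spatial is None:
        return vec
    out = np.full(int(np.prod(spatial)), np.nan)
    if mask is not None:
        out[mask.reshape(-1)] = vec
    else:
        out[:] = vec
    return out.reshape(spatial)


def fit_glm(
    bold: np.ndarray,
    design: DesignMatrix,
    ar1: bool = False,
    mask: np.ndarray | None = None,
) -> GLMResult:
    """Voxelwise (prewhitened) OLS fit of the design to a 4D BOLD array.

    With ``ar1=True`` the AR(1) coefficient is estimated from the pooled
    lag-1 autocorrelation of first-pass OLS residuals over the mask, and
    both data and design are prewhitened (first frame scaled by
    sqrt(1 - rho^2)) before the final fit.
    """
    Y, spatial = _flatten_bold(np.asarray(bold, dtype=float), mask)
    X = design.values
    if Y.shape[0] != X.shape[0]:
        raise ValueError("BOLD frame count must match design rows")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("singular design matrix")

    rho = 0.0
    if ar1:
        beta0, *_ = np.linalg.lstsq(X, Y, rcond=None)
        res0 = Y - X @ beta0
        num = np.sum(res0[1:] * res0[:-1])
        den = np.sum(res0[:-1] ** 2)
        rho = float(num / den) if den > 0 else 0.0
        rho = float(np.clip(rho, -0.95, 0.95))
        W_first = np.sqrt(1.0 - rho**2)
        Yw = np.empty_like(Y)
        Yw[0] = Y[0] * W_first
        Yw[1:] = Y[1:] - rho * Y[:-1]
        Xw = np.empty_like(X)
        Xw[0] = X[0] * W_first
        Xw[1:] = X[1:] - rho * X[:-1]
        Y, X = Yw, Xw

    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    residuals = Y - X @ beta
    df = Y.shape[0] - rank
    sigma = np.sqrt(np.sum(residuals**2, axis=0) / df)
    betas = {
        name: _unflatten(beta[i], spatial, mask)
        for i, name in enumerate(design.matrix.columns)
    }
    return GLMResult(
        betas=betas,
        residuals=residuals,
        sigma=sigma,
        df=df,
        design=design,
        shape=spatial if spatial is not None else (Y.shape[1],),
        mask=mask,
        ar1_rho=rho,
    )


# ---------------------------------------------------------------------------
# Contrasts and group inference


@dataclass
class StatMap:
    """A 3D statistic volume with its mask and (where relevant) df."""

    values: np.ndarray
    kind: str  # "beta" | "t" | "distance"
    mask: np.ndarray | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if self.mask is not None:
            inside = self.values[self.mask]
            if not np.all(np.isfinite(inside)):
                raise ValueError("statistic map non-finite inside mask")


def contrast_map(result: GLMResult, weights: dict[str, float]) -> StatMap:
    """Weighted combination of beta maps (e.g. the memory main effect)."""
    missing = [k for k in weights if k not in result.betas]
    if missing:
        raise ValueError(f"unknown contrast columns: {missing}")
    if len(weights) > 1 and abs(sum(weights.values())) > 1e-12:
        warnings.warn("difference contrast weights do not sum to zero")
    values = sum(w * np.nan_to_num(result.betas[name])
                 for name, w in weights.items())
    return StatMap(np.asarray(values, dtype=float), "beta", result.mask)


def group_inference(
    maps: np.ndarray | list[np.ndarray], mask: np.ndarray | None = None
) -> StatMap:
    """Voxelwise one-sample t across subjects (df = n - 1).

    Voxels with zero between-subject variance are masked out (set NaN and
    removed from the returned mask).
    """
    data = np.asarray(maps, dtype=float)
    n = data.shape[0]
    if n < 3:
        raise ValueError("group inference needs at least three subjects")
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    good = sd > 0
    t[~good] = np.nan
    out_mask = good if mask is None else (mask & good)
    return StatMap(t, "t", out_mask, df=n - 1)


@dataclass
class FWEResult:
    tmap: StatMap
    threshold: float
    clusters: pd.DataFrame
    fwe_p: float          # family-wise p of the observed max statistic
    method: str


def _cluster_table(
    tmap: np.ndarray, sig: np.ndarray, min_cluster: int,
    roi_labels: dict[str, np.ndarray] | None,
) -> pd.DataFrame:
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    rows = []
    for sign in (1, -1):
        labeled, n = ndimage.label(sig & (np.sign(np.nan_to_num(tmap)) == sign),
                                   structure=structure)
        for lab in range(1, n + 1):
            voxels = np.argwhere(labeled == lab)
            if len(voxels) < min_cluster:
                continue
            vals = tmap[tuple(voxels.T)]
            peak = voxels[np.argmax(np.abs(vals))]
            region = ""
            if roi_labels:
                for rname, rmask in roi_labels.items():
                    if rmask[tuple(peak)]:
                        region = rname
                        break
            rows.append(
                dict(region=region, voxels=len(voxels),
                     peak_i=int(peak[0]), peak_j=int(peak[1]),
                     peak_k=int(peak[2]),
                     peak_stat=float(vals[np.argmax(np.abs(vals))]))
            )
    cols = ["region", "voxels", "peak_i", "peak_j", "peak_k", "peak_stat"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values("peak_stat", key=np.abs, ascending=False,
                          ignore_index=True)


def threshold_fwe(
    subject_maps: np.ndarray | list[np.ndarray],
    mask: np.ndarray,
    alpha: float = 0.05,
    method: str = "permutation",
    min_cluster: int = 5,
    svc_mask: np.ndarray | None = None,
    n_perm: int = 1999,
    rng: np.random.Generator | int | None = None,
    roi_labels: dict[str, np.ndarray] | None = None,
) -> FWEResult:
    """Family-wise-error-corrected group map with a cluster table.

    Sign-flip max-statistic permutation (default): under the symmetric null
    each subject's map sign is exchangeable; the two-sided max |t| over the
    search volume across random flips gives the FWE threshold at ``alpha``.
    The observed labelling counts as one permutation, so the family-wise
    p-value is ``(1 + #{perm max >= observed max}) / (n_perm + 1)``.
    ``svc_mask`` restricts the whole procedure (max statistic included) to
    an a priori region; ``method='bonferroni'`` divides alpha by the voxel
    count instead.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    data = np.asarray(subject_maps, dtype=float)
    n = data.shape[0]
    search = mask if svc_mask is None else (mask & svc_mask)
    group = group_inference(data, search)
    eff_mask = group.mask
    flat = data.reshape(n, -1)[:, eff_mask.reshape(-1)]
    sq_sum = np.sum(flat**2, axis=0)

    def _max_abs_t(signs: np.ndarray) -> np.ndarray:
        # Shared arithmetic for observed and permuted statistics, so that
        # sign patterns reproducing the observed labelling tie exactly.
        means = (signs @ flat) / n
        var = (sq_sum[None, :] - n * means**2) / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tperm = means / np.sqrt(var / n)
        return np.nanmax(np.abs(tperm), axis=1)

    obs_max = float(_max_abs_t(np.ones((1, n)))[0])

    if method == "permutation":
        rng = np.random.default_rng(rng)
        maxes = np.empty(n_perm + 1)
        maxes[0] = obs_max
        block = 256
        done = 0
        while done < n_perm:
            b = min(block, n_perm - done)
            signs = rng.choice([-1.0, 1.0], size=(b, n))
            maxes[1 + done : 1 + done + b] = _max_abs_t(signs)
            done += b
        k = int(np.ceil((1 - alpha) * (n_perm + 1)))
        threshold = float(np.sort(maxes)[k - 1])
        fwe_p = float(np.mean(maxes >= obs_max))
    elif method == "bonferroni":
        n_vox = int(eff_mask.sum())
        threshold = float(t_dist.isf(alpha / (2 * n_vox), df=n - 1))
        p_min = 2 * t_dist.sf(obs_max, df=n - 1)
        fwe_p = float(min(1.0, p_min * n_vox))
    else:
        raise ValueError(f"unknown FWE method {method!r}")

    sig = np.zeros_like(eff_mask)
    sig[eff_mask] = np.abs(group.values[eff_mask]) >= threshold
    clusters = _cluster_table(group.values, sig, min_cluster, roi_labels)
    return FWEResult(group, threshold, clusters, fwe_p, method)
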