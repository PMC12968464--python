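"""Across-participant crossnobis searchlight.

Condition patterns (beta maps for two binary labels) are compared with the
cross-validated whitened Euclidean ("crossnobis") distance.  For every
searchlight sphere and leave-one-participant-out fold,

    d = (mean of training subjects' whitened pattern difference)
        . (left-out subject's whitened pattern difference) / P

with P the sphere's voxel count.  Because training and test differences
carry independent noise, the estimator is unbiased: it averages to zero
when the labels carry no information (and can legitimately go negative),
unlike the naive squared distance, which is positive under the null.

Whitening is per subject and per sphere: the noise covariance of the sphere
voxels is estimated from GLM residuals with Ledoit-Wolf-style shrinkage of
the off-diagonal entries toward zero ("retain variances": the target is the
diagonal of the sample covariance), and patterns are multiplied by the
inverse matrix square root.  A cheaper per-voxel variant ("diag", dividing
by residual SDs) and no whitening are also available.

Fold distance maps are Gaussian-smoothed and passed to the same one-sample
permutation inference as the univariate pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .glm import FWEResult, threshold_fwe

__all__ = [
    "label_events",
    "SearchlightSpheres",
    "searchlight_neighborhoods",
    "shrunk_covariance",
    "whitening_matrix",
    "whiten_betas",
    "crossnobis_loso",
    "naive_distance_map",
    "fwhm_to_sigma",
    "smooth_map",
    "smooth_and_test",
]

FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


# ---------------------------------------------------------------------------
# Binary labelling schemes


def label_events(
    events: pd.DataFrame, scheme: str, n_levels: int = 26
) -> pd.DataFrame:
    """Binary label series for one of the three decoding schemes.

    ``density``: every adjustment-phase stack (all conditions) is labelled
    low/high by splitting the scale at its midpoint (levels 0..12 vs 13..25
    of the 26-level scale); the label can change within a trial as the
    density is adjusted.  ``direction``: stacks of adjustment trials are
    labelled by the press direction active at stack onset (unpressed stacks
    carry no label).  ``target``: one label per memory trial, low/high
    target, spanning the whole trial.  Raises when the events contain no
    trials the scheme applies to.
    """
    if scheme == "density":
        stacks = events[events.event_type == "adjust_stack"].copy()
        if stacks.empty:
            raise ValueError("density labelling needs adjustment-phase stacks")
        stacks["label"] = np.where(
            stacks["density_level"] >= n_levels // 2, "high", "low"
        )
        return stacks[["onset", "duration", "condition", "trial_index", "label"]]

    if scheme == "direction":
        adj = events[events.condition.isin(["MA", "NA"])]
        stacks = adj[adj.event_type == "adjust_stack"]
        presses = adj[adj.event_type == "press"]
        if stacks.empty:
            raise ValueError("direction labelling needs MA or NA trials")
        rows = []
        for _, st in stacks.iterrows():
            active = presses[
                (presses.trial_index == st.trial_index)
                & (presses.onset <= st.onset)
                & (presses.onset + presses.duration > st.onset)
            ]
            if active.empty:
                continue
            rows.append(
                dict(onset=st.onset, duration=st.duration,
                     condition=st.condition, trial_index=st.trial_index,
                     label="up" if active.iloc[0]["value"] == "denser" else "down")
            )
        if not rows:
            raise ValueError("no pressed stacks to label")
        return pd.DataFrame(rows)

    if scheme == "target":
        mem = events[events.condition.isin(["MA", "MP"])]
        if mem.empty:
            raise ValueError("target labelling needs memory (MA/MP) trials")
        rows = []
        for _, g in mem.groupby("trial_index"):
            target = g["target_level"].iloc[0]
            if pd.isna(target):
                raise ValueError("memory trial without target level")
            instr = g[g.event_type == "instruction"].iloc[0]
            rating = g[g.event_type == "rating_window"].iloc[0]
            rows.append(
                dict(onset=instr.onset,
                     duration=rating.onset + rating.duration - instr.onset,
                     condition=g["condition"].iloc[0],
                     trial_index=g["trial_index"].iloc[0],
                     label="high" if int(target) >= n_levels // 2 else "low")
            )
        return pd.DataFrame(rows)

    raise ValueError(f"unknown labelling scheme {scheme!r}")


# ---------------------------------------------------------------------------
# Searchlight geometry


@dataclass
class SearchlightSpheres:
    """All in-mask spheres: centers, flat member indices, reduceat segments."""

    shape: tuple[int, int, int]
    centers: np.ndarray          # (N, 3) voxel coordinates
    center_flat: np.ndarray      # (N,) flat indices
    members_concat: np.ndarray   # concatenated flat member indices
    seg_starts: np.ndarray       # (N,) starts into members_concat
    sizes: np.ndarray            # (N,) member counts

    def __len__(self) -> int:
        return len(self.centers)

    def members(self, i: int) -> np.ndarray:
        end = (self.seg_starts[i + 1] if i + 1 < len(self)
               else len(self.members_concat))
        return self.members_concat[self.seg_starts[i]:end]


def searchlight_neighborhoods(
    mask: np.ndarray, radius_mm: float, voxel_size_mm: float
) -> SearchlightSpheres:
    """Spherical neighborhoods of every in-mask voxel.

    Members are all in-mask voxels whose center-to-center Euclidean distance
    is at most ``radius_mm`` (the center always belongs).  With 3-mm voxels
    and the 4-mm radius an interior sphere has 7 members: the center plus
    its six face neighbors (edge neighbors sit at 3*sqrt(2) ~ 4.24 mm).
    """
    if radius_mm < 0:
        raise ValueError("radius must be nonnegative")
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    offs = []
    for dx in range(-r_vox, r_vox + 1):
        for dy in range(-r_vox, r_vox + 1):
            for dz in range(-r_vox, r_vox + 1):
                if voxel_size_mm * np.sqrt(dx**2 + dy**2 + dz**2) <= radius_mm:
                    offs.append((dx, dy, dz))
    offsets = np.array(sorted(offs))
    shape = mask.shape
    centers = np.argwhere(mask)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    members_list = []
    seg_starts = np.empty(len(centers), dtype=np.int64)
    sizes = np.empty(len(centers), dtype=np.int64)
    pos = 0
    cand = centers[:, None, :] + offsets[None, :, :]          # (N, K, 3)
    inside = np.all((cand >= 0) & (cand < np.array(shape)), axis=2)
    flat_all = cand @ strides
    for i in range(len(centers)):
        ok = inside[i]
        flat = flat_all[i][ok]
        flat = flat[mask.reshape(-1)[flat]]
        members_list.append(flat)
        seg_starts[i] = pos
        sizes[i] = len(flat)
        pos += len(flat)
    return SearchlightSpheres(
        shape=shape,
        centers=centers,
        center_flat=centers @ strides,
        members_concat=np.concatenate(members_list),
        seg_starts=seg_starts,
        sizes=sizes,
    )


# ---------------------------------------------------------------------------
# Noise covariance shrinkage and whitening


def shrunk_covariance(
    residuals: np.ndarray, shrinkage: float | None = None
) -> tuple[np.ndarray, float]:
    """Sample covariance with off-diagonals shrunk toward zero.

    The shrinkage target is the diagonal of the sample covariance (variances
    retained).  The weight, when not given, is the Ledoit-Wolf-style
    analytic optimum (Schafer-Strimmer form): the summed estimated sampling
    variance of the off-diagonal entries over their summed squares, clipped
    to [0, 1].  Returns (covariance, weight).
    """
    X = np.asarray(residuals, dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least two residual frames")
    Xc = X - X.mean(axis=0)
    S = (Xc.T @ Xc) / (n - 1)
    if shrinkage is None:
        W = Xc[:, :, None] * Xc[:, None, :]          # (n, p, p)
        var_s = n / (n - 1) ** 3 * np.sum((W - W.mean(axis=0)) ** 2, axis=0)
        off = ~np.eye(p, dtype=bool)
        denom = np.sum(S[off] ** 2)
        shrinkage = float(np.clip(np.sum(var_s[off]) / denom, 0.0, 1.0)) \
            if denom > 0 else 1.0
    sigma = S.copy()
    sigma[~np.eye(p, dtype=bool)] *= 1.0 - shrinkage
    return sigma, shrinkage


def whitening_matrix(sigma: np.ndarray) -> np.ndarray:
    """Inverse matrix square root of a symmetric positive-definite matrix."""
    w, v = np.linalg.eigh(sigma)
    if np.any(w <= 0):
        raise ValueError("covariance not positive definite")
    return (v / np.sqrt(w)) @ v.T


def whiten_betas(
    betas: np.ndarray, residuals: np.ndarray,
    shrinkage: float | None = None,
) -> np.ndarray:
    """Whiten pattern vectors by the shrunk noise covariance of one sphere.

    ``betas`` is (..., P) over the sphere's P voxels, ``residuals`` (T, P)
    from the same subject's GLM.  Raises when the sphere outgrows the
    residual degrees of freedom.
    """
    betas = np.asarray(betas, dtype=float)
    if residuals.shape[0] <= betas.shape[-1]:
        raise ValueError("sphere larger than residual degrees of freedom")
    sigma, _ = shrunk_covariance(residuals, shrinkage)
    return betas @ whitening_matrix(sigma)


def _batched_lw_whiten(Xm: np.ndarray, Dm: np.ndarray) -> np.ndarray:
    """Whiten many spheres of one subject at once.

    Xm: (T, G, P) residuals gathered per sphere; Dm: (G, P) pattern diffs.
    Returns whitened diffs (G, P).
    """
    T = Xm.shape[0]
    Xc = Xm - Xm.mean(axis=0)
    S = np.einsum("tgp,tgq->gpq", Xc, Xc) / (T - 1)
    W2 = np.einsum("tgp,tgq->tgpq", Xc, Xc)
    var_s = T / (T - 1) ** 3 * np.sum((W2 - W2.mean(axis=0)) ** 2, axis=0)
    P = S.shape[-1]
    off = ~np.eye(P, dtype=bool)
    denom = np.sum(S[:, off] ** 2, axis=1)
    lam = np.where(denom > 0,
                   np.clip(np.sum(var_s[:, off], axis=1) /
                           np.where(denom > 0, denom, 1.0), 0.0, 1.0),
                   1.0)
    sigma = S * (1.0 - lam[:, None, None])
    diag = np.arange(P)
    sigma[:, diag, diag] = S[:, diag, diag]
    w, v = np.linalg.eigh(sigma)
    w = np.maximum(w, 1e-12)
    Wm = np.einsum("gpk,gk,gqk->gpq", v, 1.0 / np.sqrt(w), v)
    return np.einsum("gpq,gq->gp", Wm, Dm)


# ---------------------------------------------------------------------------
# Crossnobis estimator


def _sphere_groups(spheres: SearchlightSpheres) -> dict[int, np.ndarray]:
    """Indices of spheres grouped by member count (for rectangular batching)."""
    groups: dict[int, list[int]] = {}
    for i, s in enumerate(spheres.sizes):
        groups.setdefault(int(s), []).append(i)
    return {p: np.array(idx) for p, idx in groups.items()}


def _flat(map3d: np.ndarray) -> np.ndarray:
    return np.asarray(map3d, dtype=float).reshape(-1)


def crossnobis_loso(
    betas_per_subject: list[dict[str, np.ndarray]],
    spheres: SearchlightSpheres,
    residuals_per_subject: list[np.ndarray] | None = None,
    whiten: str | None = "lw_retain_var",
    chunk: int = 512,
) -> list[np.ndarray]:
    """Leave-one-participant-out crossnobis distance maps.

    ``betas_per_subject`` holds, per subject, the two labelled beta volumes
    (any two keys; sorted order fixes the sign of the difference).
    ``residuals_per_subject`` are (frames, n_voxels-flat) arrays feeding the
    whitening ('lw_retain_var' for the full sphere covariance, 'diag' for
    per-voxel scaling, None to skip).  Returns one 3D distance map per fold
    (NaN off-center), fold s = testing subject s on the mean pattern
    difference of all the others, normalised by sphere size.
    """
    n_sub = len(betas_per_subject)
    if n_sub < 3:
        raise ValueError("leave-one-out needs at least three subjects")
    labels = sorted(betas_per_subject[0])
    if len(labels) != 2:
        raise ValueError("exactly two labels required")
    for b in betas_per_subject:
        if sorted(b) != labels:
            raise ValueError("all subjects must carry the same two labels")
    if whiten in ("lw_retain_var", "diag") and residuals_per_subject is None:
        raise ValueError("whitening requires residuals")

    shape = spheres.shape
    diffs = np.stack([
        _flat(b[labels[1]]) - _flat(b[labels[0]]) for b in betas_per_subject
    ])
    diffs = np.nan_to_num(diffs)

    if whiten == "diag":
        for s in range(n_sub):
            sd = np.std(residuals_per_subject[s], axis=0, ddof=1)
            diffs[s] = diffs[s] / np.where(sd > 0, sd, 1.0)

    n_spheres = len(spheres)
    # whitened member diffs per subject per sphere, ragged -> concat layout
    tilde = np.empty((n_sub, spheres.members_concat.size))
    if whiten == "lw_retain_var":
        groups = _sphere_groups(spheres)
        for p, idx in groups.items():
            members = np.stack([spheres.members(i) for i in idx])  # (G, P)
            for s in range(n_sub):
                R = residuals_per_subject[s]
                if R.shape[0] <= p:
                    raise ValueError(
                        "sphere larger than residual degrees of freedom"
                    )
                out = np.empty((len(idx), p))
                for c0 in range(0, len(idx), chunk):
                    sl = slice(c0, c0 + chunk)
                    Xm = R[:, members[sl]]            # (T, g, P)
                    Dm = diffs[s][members[sl]]        # (g, P)
                    out[sl] = _batched_lw_whiten(Xm, Dm)
                for row, i in enumerate(idx):
                    st = spheres.seg_starts[i]
                    tilde[s, st:st + p] = out[row]
    else:
        for s in range(n_sub):
            tilde[s] = diffs[s][spheres.members_concat]

    fold_maps = []
    total = tilde.sum(axis=0)
    for f in range(n_sub):
        train = (total - tilde[f]) / (n_sub - 1)
        prod = train * tilde[f]
        d = np.add.reduceat(prod, spheres.seg_starts) / spheres.sizes
        vol = np.full(int(np.prod(shape)), np.nan)
        vol[spheres.center_flat] = d
        fold_maps.append(vol.reshape(shape))
    return fold_maps


def naive_distance_map(
    betas_per_subject: list[dict[str, np.ndarray]],
    spheres: SearchlightSpheres,
    residuals_per_subject: list[np.ndarray] | None = None,
    whiten: str | None = None,
) -> np.ndarray:
    """Non-cross-validated squared distance of the mean pattern difference.

    The biased counterpart of the crossnobis estimator: squared norm of the
    across-subject mean difference per sphere, over sphere size.  Positive
    in expectation even under the null (the bias the cross-validated
    estimator removes).
    """
    labels = sorted(betas_per_subject[0])
    diffs = np.stack([
        _flat(b[labels[1]]) - _flat(b[labels[0]]) for b in betas_per_subject
    ])
    diffs = np.nan_to_num(diffs)
    if whiten == "diag":
        for s in range(len(diffs)):
            sd = np.std(residuals_per_subject[s], axis=0, ddof=1)
            diffs[s] = diffs[s] / np.where(sd > 0, sd, 1.0)
    mean = diffs.mean(axis=0)
    prod = (mean**2)[spheres.members_concat]
    d = np.add.reduceat(prod, spheres.seg_starts) / spheres.sizes
    vol = np.full(int(np.prod(spheres.shape)), np.nan)
    vol[spheres.center_flat] = d
    return vol.reshape(spheres.shape)


# ---------------------------------------------------------------------------
# Smoothing and group inference


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian kernel SD in voxels for a given FWHM in mm."""
    return fwhm_mm / (FWHM_TO_SIGMA * voxel_size_mm)


def smooth_map(
    volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Gaussian-smooth a 3D map, renormalising at mask edges.

    NaNs (and out-of-mask voxels) are excluded by smoothing the zero-filled
    map and dividing by the smoothed support.  ``fwhm_mm=0`` returns the
    input unchanged.
    """
    if fwhm_mm == 0:
        return volume.copy()
    sigma = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    support = np.isfinite(volume)
    if mask is not None:
        support &= mask
    filled = np.where(support, volume, 0.0)
    num = ndimage.gaussian_filter(filled, sigma)
    den = ndimage.gaussian_filter(support.astype(float), sigma)
    out = np.full_like(volume, np.nan, dtype=float)
    good = den > 1e-6
    out[good] = num[good] / den[good]
    out[~support] = np.nan
    return out


def smooth_and_test(
    fold_maps: list[np.ndarray],
    fwhm_mm: float,
    voxel_size_mm: float,
    mask: np.ndarray,
    alpha: float = 0.05,
    method: str = "permutation",
    min_cluster: int = 5,
    svc_mask: np.ndarray | None = None,
    n_perm: int = 1999,
    rng: np.random.Generator | int | None = None,
    roi_labels: dict[str, np.ndarray] | None = None,
) -> FWEResult:
    """Smooth fold distance maps and run the one-sample group inference.

    Maps are smoothed with a Gaussian kernel of ``fwhm_mm`` FWHM, then
    passed to the shared sign-flip permutation FWE machinery (one map per
    fold, t against zero, df = folds - 1).
    """
    if len(fold_maps) < 3:
        raise ValueError("need at least three fold maps")
    smoothed = np.stack([
        np.nan_to_num(smooth_map(m, fwhm_mm, voxel_size_mm, mask))
        for m in fold_maps
    ])
    return threshold_fwe(
        smoothed, mask, alpha=alpha, method=method, min_cluster=min_cluster,
        svc_mask=svc_mask, n_perm=n_perm, rng=rng, roi_labels=roi_labels,
    )
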