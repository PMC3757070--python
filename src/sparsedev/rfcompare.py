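"""Nonparametric receptive-field shape comparison by image registration.

Two receptive fields are considered to have the same shape if one can be
mapped onto the other by a similarity transform — translation, rotation
and isotropic rescaling.  The match between a target RF and a transformed
candidate is scored by R^2, the squared Pearson correlation of their
pixel vectors, i.e. the fraction of target variance a linear function
(gain plus offset, sign included) of the transformed candidate explains.

For a dictionary of candidates (e.g. model RFs) the best fit for a target
is the transform/candidate pair maximizing R^2 over an exhaustive search
of the dictionary.  Applied within a set of experimental-style RFs in a
leave-one-out fashion, the same machinery yields the "explainable
variance" — the ceiling imposed by measurement noise and shape diversity
— against which a model dictionary's mean fit is expressed as a fraction
of explainable variance.

The transform search is multi-start: a coarse grid over rotation and
log-scale, with the translation at each node solved globally by
normalized cross-correlation, followed by a derivative-free simplex
refinement of all four parameters from the best node.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.ndimage import affine_transform
from scipy.optimize import minimize

__all__ = [
    "SimilarityTransform",
    "RegistrationFit",
    "standardize_rf",
    "transform_rf",
    "r_squared",
    "half_turn_equivalent",
    "fit_similarity",
    "best_fit_from_dictionary",
    "explainable_variance",
    "fraction_explained",
    "fits_to_frame",
]


@dataclasses.dataclass
class SimilarityTransform:
    """Translation (dx right, dy down, pixels), rotation (radians, about
    the window center) and isotropic scale factor (> 0)."""

    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")


@dataclasses.dataclass
class RegistrationFit:
    """Best transform and score for one target RF."""

    transform: SimilarityTransform
    r_squared: float
    candidate_index: int | None = None
    target_label: str | None = None

    def __post_init__(self) -> None:
        if not (-1e-9 <= self.r_squared <= 1 + 1e-9):
            raise ValueError("r_squared outside [0, 1]")


def standardize_rf(rf: np.ndarray, window: int) -> np.ndarray:
    """Crop a ``window`` x ``window`` region around the absolute peak.

    The crop is centered on the pixel of maximum absolute value (first in
    row-major order on ties) and shifted inward at the borders so the
    full window always fits.  RFs already at the window size pass
    through unchanged.
    """
    arr = np.asarray(rf, dtype=float)
    if arr.ndim != 2:
        raise ValueError("rf must be a 2D array")
    er, ec = arr.shape
    if window > er or window > ec:
        raise ValueError("window larger than rf")
    if (er, ec) == (window, window):
        return arr.copy()
    pr, pc = np.unravel_index(np.argmax(np.abs(arr)), arr.shape)
    r0 = int(np.clip(pr - window // 2, 0, er - window))
    c0 = int(np.clip(pc - window // 2, 0, ec - window))
    return arr[r0 : r0 + window, c0 : c0 + window].copy()


def _inverse_matrix_offset(t: SimilarityTransform, shape):
    c = (np.array(shape) - 1.0) / 2.0
    cos, sin = np.cos(t.rotation), np.sin(t.rotation)
    rot = np.array([[cos, -sin], [sin, cos]])  # acts on (row, col)
    inv = rot.T / t.scale
    shift = np.array([t.dy, t.dx])
    offset = c - inv @ (c + shift)
    return inv, offset


def transform_rf(rf: np.ndarray, t: SimilarityTransform, order: int = 3) -> np.ndarray:
    """Apply a similarity transform with spline interpolation.

    Rotation and scaling are about the window center, followed by the
    translation; pixels mapped from outside the source are 0.  Output
    has the input's shape.  Cubic interpolation (default) is exact at
    sample points, so the identity transform returns the input to within
    round-off, and keeps inverse-composition error small on band-limited
    RF content where bilinear would not.
    """
    arr = np.asarray(rf, dtype=float)
    inv, offset = _inverse_matrix_offset(t, arr.shape)
    return affine_transform(arr, inv, offset=offset, order=order, mode="constant", cval=0.0)


def r_squared(target: np.ndarray, candidate: np.ndarray) -> float:
    """Squared Pearson correlation between flattened pixel vectors.

    Affine-invariant in either argument (gain, offset and sign do not
    matter).  A constant candidate scores 0 by convention; a constant
    target is rejected.
    """
    t = np.asarray(target, dtype=float).ravel()
    c = np.asarray(candidate, dtype=float).ravel()
    if t.shape != c.shape:
        raise ValueError("target and candidate shapes differ")
    tc = t - t.mean()
    st = tc @ tc
    if st == 0:
        raise ValueError("target is constant")
    cc = c - c.mean()
    sc = cc @ cc
    if sc == 0:
        return 0.0
    r = (tc @ cc) / np.sqrt(st * sc)
    return float(min(r * r, 1.0))


def half_turn_equivalent(
    t: SimilarityTransform, symmetry_center_rc: tuple[float, float], shape
) -> SimilarityTransform:
    """The transform equivalent to ``t`` for a half-turn-symmetric pattern.

    R^2 ignores sign, so a candidate that is (anti)symmetric under a
    half turn about ``symmetry_center_rc`` (row, col) is matched equally
    well by ``t`` composed with that half turn: rotation shifts by 180
    degrees and, when the symmetry center is off the window center, the
    translation changes accordingly.  Useful for comparing recovered
    against true parameters up to this intrinsic ambiguity.
    """
    c = (np.array(shape, dtype=float) - 1.0) / 2.0
    cos, sin = np.cos(t.rotation), np.sin(t.rotation)
    A1 = t.scale * np.array([[cos, -sin], [sin, cos]])
    b1 = c + np.array([t.dy, t.dx]) - A1 @ c
    mu = np.asarray(symmetry_center_rc, dtype=float)
    A2 = -A1
    b2 = A1 @ (2.0 * mu) + b1
    shift = b2 - c + A2 @ c
    return SimilarityTransform(
        dx=float(shift[1]),
        dy=float(shift[0]),
        rotation=float((t.rotation + np.pi) % (2.0 * np.pi)),
        scale=t.scale,
    )


_DEFAULT_ROTATIONS = np.deg2rad(np.arange(0.0, 360.0, 10.0))
_DEFAULT_SCALES = 2.0 ** np.linspace(-1.0, 1.0, 9)


def _grid_search(target, cand0, rotations, scales, max_shift):
    """Best (r2, rotation, scale, dy, dx) over the coarse transform grid.

    Translation is solved per node by exhaustive normalized
    cross-correlation (zero-filled shifts, Pearson over the full window)
    evaluated with FFTs for the whole warped-candidate stack at once.
    """
    e = target.shape[0]
    size = 2 * e
    nodes = [(r, s) for s in scales for r in rotations]
    warps = np.empty((len(nodes), e, e))
    for k, (rot, sc) in enumerate(nodes):
        warps[k] = transform_rf(cand0, SimilarityTransform(0.0, 0.0, rot, sc))

    t = target.astype(float)
    n = t.size
    t_mean = t.mean()
    t_ss = ((t - t_mean) ** 2).sum()

    pad_t = np.zeros((size, size))
    pad_t[:e, :e] = t
    ft = np.fft.rfft2(pad_t)
    pad_ones = np.zeros((size, size))
    pad_ones[:e, :e] = 1.0
    fones = np.fft.rfft2(pad_ones)

    flip = warps[:, ::-1, ::-1]
    pad_c = np.zeros((len(nodes), size, size))
    pad_c[:, :e, :e] = flip
    fc = np.fft.rfft2(pad_c)
    pad_c[:, :e, :e] = flip**2
    fc2 = np.fft.rfft2(pad_c)

    cross = np.fft.irfft2(ft[None] * fc, s=(size, size))
    s1 = np.fft.irfft2(fones[None] * fc, s=(size, size))
    s2 = np.fft.irfft2(fones[None] * fc2, s=(size, size))

    num = cross - t_mean * s1
    den = t_ss * np.clip(s2 - s1**2 / n, 0.0, None)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(den > 1e-12 * max(t_ss, 1.0) ** 2, num**2 / den, 0.0)

    # valid linear-correlation indices: shift = idx - (e - 1)
    shifts = np.arange(2 * e - 1) - (e - 1)
    valid = np.abs(shifts) <= max_shift
    r2 = r2[:, : 2 * e - 1, : 2 * e - 1]
    r2[:, ~valid, :] = -1.0
    r2[:, :, ~valid] = -1.0
    r2 = np.nan_to_num(r2, nan=-1.0)

    per_node = r2.reshape(len(nodes), -1)
    flat_idx = per_node.argmax(axis=1)
    node_best = per_node[np.arange(len(nodes)), flat_idx]
    ii, jj = np.unravel_index(flat_idx, r2.shape[1:])
    rots = np.array([n[0] for n in nodes])
    scs = np.array([n[1] for n in nodes])
    return node_best, rots, scs, shifts[ii].astype(float), shifts[jj].astype(float)


def fit_similarity(
    target: np.ndarray,
    candidate: np.ndarray,
    rotations: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    max_shift: float | None = None,
    refine: bool = True,
    refine_maxfev: int = 400,
) -> RegistrationFit:
    """Find the similarity transform of ``candidate`` maximizing R^2.

    The candidate is mean-centered before warping (its surround then
    fills with zeros).  A coarse grid over rotation (default 0-350 deg in
    10 deg steps) and scale (default 2^[-1, 1], 9 log-uniform steps) with
    exhaustive translation search seeds a Nelder-Mead refinement of
    (dx, dy, rotation, log scale).  Because R^2 ignores sign, patterns
    with near half-turn symmetry create a second basin at rotation
    + 180 deg; refinement is therefore started both from the best grid
    node and from the best node in the far-rotation basin, keeping the
    better result.  Failed registrations score 0 with an identity
    transform, and are retained in downstream statistics.
    """
    t = np.asarray(target, dtype=float)
    c = np.asarray(candidate, dtype=float)
    if t.shape != c.shape or t.ndim != 2 or t.shape[0] != t.shape[1]:
        raise ValueError("target and candidate must be equal-shaped square arrays")
    if np.ptp(t) == 0:
        raise ValueError("target is constant")
    if rotations is None:
        rotations = _DEFAULT_ROTATIONS
    if scales is None:
        scales = _DEFAULT_SCALES
    if max_shift is None:
        max_shift = t.shape[0] / 2.0

    cand0 = c - c.mean()
    if np.ptp(cand0) == 0:
        return RegistrationFit(SimilarityTransform(), 0.0)

    node_r2, rots, scs, dys, dxs = _grid_search(
        t, cand0, np.asarray(rotations), np.asarray(scales), max_shift
    )
    top = int(np.argmax(node_r2))
    starts = [top]
    # best node in the opposite-rotation basin (angular distance > 90 deg)
    ang = np.abs((rots - rots[top] + np.pi) % (2 * np.pi) - np.pi)
    far = ang > np.pi / 2
    if far.any():
        cand_idx = np.flatnonzero(far)
        starts.append(int(cand_idx[np.argmax(node_r2[cand_idx])]))

    best = RegistrationFit(
        SimilarityTransform(dxs[top], dys[top], rots[top], scs[top]),
        max(float(node_r2[top]), 0.0),
    )
    if not refine:
        return best

    def neg_r2(params):
        pdx, pdy, prot, plog_s = params
        try:
            warped = transform_rf(
                cand0, SimilarityTransform(pdx, pdy, prot, float(np.exp(plog_s)))
            )
            val = r_squared(t, warped)
        except (ValueError, FloatingPointError):
            return 1.0
        return -val if np.isfinite(val) else 1.0

    for k in starts:
        x0 = np.array([dxs[k], dys[k], rots[k], np.log(scs[k])])
        res = minimize(
            neg_r2,
            x0,
            method="Nelder-Mead",
            options=dict(
                maxfev=refine_maxfev,
                xatol=1e-3,
                fatol=1e-8,
                initial_simplex=x0
                + np.vstack([np.zeros(4), np.diag([0.6, 0.6, np.deg2rad(6.0), 0.08])]),
            ),
        )
        r2_ref = -float(res.fun)
        if np.isfinite(r2_ref) and r2_ref > best.r_squared:
            pdx, pdy, prot, plog_s = res.x
            best = RegistrationFit(
                SimilarityTransform(
                    float(pdx), float(pdy), float(prot), float(np.exp(plog_s))
                ),
                min(r2_ref, 1.0),
            )
    return best


def best_fit_from_dictionary(
    target: np.ndarray, dictionary: np.ndarray, **fit_kwargs
) -> RegistrationFit:
    """Exhaustive search: fit every candidate, return the highest R^2.

    Ties resolve to the first index.
    """
    dictionary = np.asarray(dictionary, dtype=float)
    if dictionary.ndim != 3 or dictionary.shape[0] == 0:
        raise ValueError("dictionary must be a non-empty stack (n, edge, edge)")
    best: RegistrationFit | None = None
    for idx in range(dictionary.shape[0]):
        fit = fit_similarity(target, dictionary[idx], **fit_kwargs)
        if best is None or fit.r_squared > best.r_squared:
            best = dataclasses.replace(fit, candidate_index=idx)
    return best


@dataclasses.dataclass
class ExplainableVariance:
    """Leave-one-out best-fit R^2 within a set of RFs."""

    values: np.ndarray
    mean: float
    sd: float
    fits: list[RegistrationFit]


def explainable_variance(rf_set: np.ndarray, **fit_kwargs) -> ExplainableVariance:
    """Leave-one-out explainable variance of an RF set.

    Each RF is fit by the dictionary of all the others; the returned mean
    and standard deviation of the best-fit R^2 values quantify how much
    of the set's pixel variance is explainable by shape repetition at
    all, the ceiling for any model dictionary.
    """
    rfs = np.asarray(rf_set, dtype=float)
    if rfs.ndim != 3 or rfs.shape[0] < 2:
        raise ValueError("need at least two RFs")
    n = rfs.shape[0]
    fits = []
    for i in range(n):
        others = np.delete(rfs, i, axis=0)
        fit = best_fit_from_dictionary(rfs[i], others, **fit_kwargs)
        # re-index into the full set
        ci = fit.candidate_index + (fit.candidate_index >= i)
        fits.append(dataclasses.replace(fit, candidate_index=int(ci), target_label=str(i)))
    values = np.array([f.r_squared for f in fits])
    return ExplainableVariance(
        values=values, mean=float(values.mean()), sd=float(values.std()), fits=fits
    )


def fraction_explained(
    model_dictionary: np.ndarray,
    target_set: np.ndarray,
    loo: ExplainableVariance | None = None,
    **fit_kwargs,
) -> dict:
    """Fraction of explainable target variance captured by a model.

    Numerator: mean best-fit R^2 of each target against the model
    dictionary.  Denominator: mean leave-one-out R^2 within the target
    set (pass a precomputed ``loo`` to reuse it).  Returns both means,
    their ratio, and the per-target fits.
    """
    targets = np.asarray(target_set, dtype=float)
    if targets.ndim != 3 or targets.shape[0] == 0:
        raise ValueError("target set must be a non-empty stack")
    model_fits = [
        dataclasses.replace(
            best_fit_from_dictionary(targets[i], model_dictionary, **fit_kwargs),
            target_label=str(i),
        )
        for i in range(targets.shape[0])
    ]
    model_values = np.array([f.r_squared for f in model_fits])
    if loo is None:
        loo = explainable_variance(targets, **fit_kwargs)
    mean_model = float(model_values.mean())
    return dict(
        mean_model=mean_model,
        sd_model=float(model_values.std()),
        mean_loo=loo.mean,
        sd_loo=loo.sd,
        fraction=mean_model / loo.mean if loo.mean > 0 else np.nan,
        model_fits=model_fits,
        loo=loo,
    )


def fits_to_frame(fits: list[RegistrationFit]) -> pd.DataFrame:
    """Tabulate fits (target, best candidate, transform, R^2) for CSV export."""
    return pd.DataFrame(
        dict(
            target=[f.target_label for f in fits],
            best_candidate=[f.candidate_index for f in fits],
            dx=[f.transform.dx for f in fits],
            dy=[f.transform.dy for f in fits],
            rot_deg=[np.rad2deg(f.transform.rotation) for f in fits],
            scale=[f.transform.scale for f in fits],
            r2=[f.r_squared for f in fits],
        )
    )
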