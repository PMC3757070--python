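"""Sparseness measures and the multi-unit recording emulation.

Three measures are computed from a non-negative activity matrix with
units on the rows and stimuli on the columns (for spiking models the
entries are spike counts per presented image):

* activity sparseness ``S_A`` -- the fraction of units whose activity did
  not rise above a spike-count threshold, averaged over stimuli;
* Treves-Rolls population sparseness ``S_P`` -- per stimulus,
  ``[1 - (sum a / N)^2 / (sum a^2 / N)] / (1 - 1/N)``, averaged over
  stimuli (the Vinje-Gallant normalization maps it onto [0, 1]);
* Treves-Rolls lifetime sparseness ``S_L`` -- the same functional form
  applied per unit across stimuli, averaged over units.

Extracellular developmental recordings pool nearby cells; that is
emulated by summing the spike counts of fixed random groups of units
(default 8) into "multi-unit" channels before computing the measures.
"""

from __future__ import annotations

import logging

import numpy as np

__all__ = [
    "activity_sparseness",
    "tr_population_sparseness",
    "tr_lifetime_sparseness",
    "make_multiunit",
    "multiunit_grouping",
]

logger = logging.getLogger(__name__)


def _as_activity(mat: np.ndarray) -> np.ndarray:
    arr = np.asarray(mat, dtype=float)
    if arr.ndim != 2:
        raise ValueError("activity matrix must be 2D (units x stimuli)")
    if arr.size == 0:
        raise ValueError("activity matrix must be non-empty")
    if (arr < 0).any():
        raise ValueError("activities must be non-negative")
    return arr


def activity_sparseness(mat: np.ndarray, threshold: float = 0.0) -> float:
    """Mean fraction of units inactive per stimulus.

    A unit counts as active for a stimulus when its activity is strictly
    greater than ``threshold``.  Returns the mean over stimuli of
    ``(N - N_active) / N``.
    """
    arr = _as_activity(mat)
    n_units = arr.shape[0]
    if n_units == 0:
        raise ValueError("need at least one unit")
    n_active = (arr > threshold).sum(axis=0)
    return float(np.mean((n_units - n_active) / n_units))


def _tr_per_column(arr: np.ndarray) -> np.ndarray:
    """Normalized Treves-Rolls value for each column of a units x stimuli array."""
    n = arr.shape[0]
    mean_a = arr.mean(axis=0)
    mean_sq = (arr**2).mean(axis=0)
    out = np.empty(arr.shape[1])
    zero = mean_sq == 0
    if zero.any():
        logger.info(
            "TR sparseness: %d all-zero response vector(s); scored as 1 (maximally sparse)",
            int(zero.sum()),
        )
    out[zero] = 1.0
    nz = ~zero
    out[nz] = (1.0 - mean_a[nz] ** 2 / mean_sq[nz]) / (1.0 - 1.0 / n)
    return out


def tr_population_sparseness(mat: np.ndarray) -> float:
    """Treves-Rolls population sparseness, averaged over stimuli.

    Requires at least two units.  An all-zero population response is
    scored 1 for that stimulus (nothing active is maximally sparse).
    """
    arr = _as_activity(mat)
    if arr.shape[0] < 2:
        raise ValueError("TR population sparseness needs N >= 2 units")
    return float(np.mean(_tr_per_column(arr)))


def tr_lifetime_sparseness(mat: np.ndarray) -> float:
    """Treves-Rolls lifetime sparseness, averaged over units.

    Identical functional form with the roles of units and stimuli
    swapped; requires at least two stimuli.
    """
    arr = _as_activity(mat)
    if arr.shape[1] < 2:
        raise ValueError("TR lifetime sparseness needs >= 2 stimuli")
    return float(np.mean(_tr_per_column(arr.T)))


def multiunit_grouping(n_units: int, group_size: int, seed: int) -> np.ndarray:
    """Random disjoint groups of ``group_size`` unit indices.

    Returns an integer array of shape (n_groups, group_size).  Units
    beyond ``floor(n_units / group_size) * group_size`` are left out.
    """
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > n_units:
        raise ValueError("group_size exceeds number of units")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n_units)
    n_groups = n_units // group_size
    return perm[: n_groups * group_size].reshape(n_groups, group_size)


def make_multiunit(
    mat: np.ndarray, group_size: int = 8, seed: int = 0, groups: np.ndarray | None = None
) -> np.ndarray:
    """Sum activities within fixed random groups of units.

    Emulates a multi-unit recording: each output row is the summed
    activity of one random group of ``group_size`` units.  Pass a
    precomputed ``groups`` array (from :func:`multiunit_grouping`) to
    reuse the same grouping across checkpoints of a run.
    """
    arr = _as_activity(mat)
    if groups is None:
        groups = multiunit_grouping(arr.shape[0], group_size, seed)
    return arr[groups].sum(axis=1)
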