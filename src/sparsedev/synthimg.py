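"""Synthetic training input and receptive-field fixtures.

Natural scenes have an approximately 1/f amplitude (1/f^2 power) spatial
spectrum; the early visual pathway decorrelates this before cortex, which
sparse-coding models emulate by whitening.  This module generates
naturalistic (pink-spectrum) images, whitens them, cuts random patches for
network training, and synthesizes Gabor-shaped receptive fields that serve
as experimental-style targets for shape-comparison benchmarks.

Everything is seeded and deterministic, so downstream simulations are
reproducible without any external image database.
"""

from __future__ import annotations

import dataclasses
import warnings

import h5py
import numpy as np

__all__ = [
    "PatchBatch",
    "GaborSpec",
    "generate_pink_images",
    "whiten",
    "extract_patches",
    "generate_gabor_rf",
    "random_gabor_specs",
    "generate_gabor_set",
    "PatchSampler",
    "save_patches",
    "load_patches",
    "save_rf_stack",
    "load_rf_stack",
    "load_rf_directory",
    "save_mosaic",
]


@dataclasses.dataclass
class PatchBatch:
    """A batch of square, zero-mean image patches.

    Attributes
    ----------
    patches : ndarray, shape (n, edge, edge)
        Pixel intensities, dimensionless.  Each patch is mean-subtracted;
        the batch as a whole is rescaled to ``target_var`` pixel variance.
    patch_edge : int
        Pixels per side.
    seed : int
        Seed used to draw the patch positions.
    """

    patches: np.ndarray
    patch_edge: int
    seed: int

    def __post_init__(self) -> None:
        self.patches = np.asarray(self.patches, dtype=float)
        if self.patches.ndim != 3 or self.patches.shape[1] != self.patches.shape[2]:
            raise ValueError("patches must have shape (n, edge, edge)")
        if self.patches.shape[1] != self.patch_edge:
            raise ValueError("patch_edge inconsistent with patch array")

    @property
    def n_patches(self) -> int:
        return self.patches.shape[0]

    def flat(self) -> np.ndarray:
        """Patches flattened to shape (n, edge*edge)."""
        return self.patches.reshape(self.n_patches, -1)


@dataclasses.dataclass
class GaborSpec:
    """Parameters of a 2D Gabor function on a pixel grid.

    The Gabor is an oriented sinusoid under an elliptical Gaussian
    envelope -- the standard parametric description of V1 simple-cell
    receptive fields.

    center : (x, y) in pixels; orientation in radians (direction of the
    carrier wave vector); frequency in cycles/pixel, must lie in (0, 0.5];
    phase in radians; sigma_along / sigma_across are the envelope widths
    along and across the carrier direction, in pixels; amplitude is
    dimensionless; noise_sd adds i.i.d. Gaussian pixel noise.
    """

    center: tuple[float, float]
    orientation: float
    frequency: float
    phase: float
    sigma_along: float
    sigma_across: float
    amplitude: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma_along > 0 and self.sigma_across > 0):
            raise ValueError("envelope sigmas must be positive")
        if not (0.0 < self.frequency <= 0.5):
            raise ValueError("frequency must lie in (0, 0.5] cycles/pixel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _radial_frequency_grid(edge: int) -> np.ndarray:
    f = np.fft.fftfreq(edge)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    return np.hypot(fx, fy)


def generate_pink_images(n: int, edge: int, seed: int, exponent: float = 1.0) -> np.ndarray:
    """Generate images with a 1/f^(2*exponent) power spectrum.

    White Gaussian noise is shaped in the Fourier domain with an amplitude
    envelope ``1/f**exponent`` (default gives the 1/f^2 power law of
    natural scenes).  Each image is zero-mean and rescaled to unit pixel
    variance.

    Parameters
    ----------
    n : number of images (>= 1)
    edge : image side in pixels (>= 8)
    seed : RNG seed; identical arguments give bitwise-identical output

    Returns
    -------
    ndarray of shape (n, edge, edge)
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if edge < 8:
        raise ValueError("edge must be >= 8")
    rng = np.random.default_rng(seed)
    fr = _radial_frequency_grid(edge)
    envelope = np.zeros_like(fr)
    nz = fr > 0
    envelope[nz] = fr[nz] ** (-exponent)
    noise = rng.standard_normal((n, edge, edge))
    spectra = np.fft.fft2(noise) * envelope[None, :, :]
    images = np.fft.ifft2(spectra).real
    images -= images.mean(axis=(1, 2), keepdims=True)
    sd = images.std(axis=(1, 2), keepdims=True)
    sd[sd == 0] = 1.0
    return images / sd


def _radial_mean(values: np.ndarray, fr: np.ndarray, bins: np.ndarray) -> np.ndarray:
    idx = np.digitize(fr.ravel(), bins) - 1
    idx = np.clip(idx, 0, len(bins) - 2)
    sums = np.bincount(idx, weights=values.ravel(), minlength=len(bins) - 1)
    counts = np.bincount(idx, minlength=len(bins) - 1)
    counts[counts == 0] = 1
    return sums / counts


def whiten(images: np.ndarray, f0_frac: float = 0.4, n_bins: int | None = None) -> np.ndarray:
    """Whiten a stack of square images.

    The batch's radially averaged Fourier amplitude spectrum is estimated,
    and every image is filtered by ``envelope(f) / A(f)`` where ``A`` is
    that measured amplitude and ``envelope(f) = exp(-(f/f0)^4)`` is a soft
    low-pass roll-off with ``f0 = f0_frac * Nyquist``.  For 1/f-amplitude
    input this reduces to the classic ramp-times-roll-off whitening filter
    of the sparse-coding literature; for input that is already white the
    spectral shape is left unchanged up to the roll-off, which also makes
    the operation idempotent in the mid band.

    The DC component is removed, so outputs are zero-mean.  Output is
    rescaled so the batch pixel variance is 1.

    Parameters
    ----------
    images : ndarray (n, edge, edge) or (edge, edge); must be square.
    f0_frac : roll-off frequency as a fraction of Nyquist.
    """
    arr = np.asarray(images, dtype=float)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[1] != arr.shape[2]:
        raise ValueError("images must be square (n, edge, edge)")
    edge = arr.shape[1]
    if edge < 8:
        raise ValueError("edge must be >= 8")

    fr = _radial_frequency_grid(edge)
    spectra = np.fft.fft2(arr)
    amp = np.abs(spectra).mean(axis=0)

    if n_bins is None:
        n_bins = max(8, edge // 2)
    bins = np.linspace(0.0, fr.max() + 1e-12, n_bins + 1)
    radial_amp = _radial_mean(amp, fr, bins)
    centers = 0.5 * (bins[:-1] + bins[1:])
    # interpolate the radial profile back onto the 2D grid
    amp2d = np.interp(fr, centers, radial_amp)
    amp2d[amp2d <= 0] = np.inf

    f0 = f0_frac * 0.5
    envelope = np.exp(-((fr / f0) ** 4))
    filt = envelope / amp2d
    filt[fr == 0] = 0.0

    out = np.fft.ifft2(spectra * filt[None]).real
    out -= out.mean(axis=(1, 2), keepdims=True)
    sd = out.std()
    if sd > 0:
        out = out / sd
    return out[0] if single else out


def extract_patches(
    images: np.ndarray,
    patch_edge: int,
    n_patches: int,
    seed: int,
    target_var: float = 1.0,
) -> PatchBatch:
    """Cut random square patches from an image stack.

    Positions are uniform over all valid top-left corners of all images.
    Each patch is mean-subtracted; the batch is then rescaled so its
    overall pixel variance equals ``target_var``.
    """
    arr = np.asarray(images, dtype=float)
    if arr.ndim == 2:
        arr = arr[None]
    n_img, edge, edge2 = arr.shape
    if edge != edge2:
        raise ValueError("images must be square")
    if patch_edge > edge:
        raise ValueError("patch_edge exceeds image edge")
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    which = rng.integers(0, n_img, size=n_patches)
    max_pos = edge - patch_edge + 1
    rows = rng.integers(0, max_pos, size=n_patches)
    cols = rng.integers(0, max_pos, size=n_patches)
    patches = np.empty((n_patches, patch_edge, patch_edge))
    for k in range(n_patches):
        patches[k] = arr[which[k], rows[k] : rows[k] + patch_edge, cols[k] : cols[k] + patch_edge]
    patches -= patches.mean(axis=(1, 2), keepdims=True)
    var = patches.var()
    if var > 0:
        patches *= np.sqrt(target_var / var)
    return PatchBatch(patches=patches, patch_edge=patch_edge, seed=int(seed))


def generate_gabor_rf(spec: GaborSpec, edge: int, seed: int = 0) -> np.ndarray:
    """Evaluate a Gabor receptive field on an ``edge`` x ``edge`` grid.

    Pixel (row, col) maps to coordinates (x, y) = (col, row).  With
    ``spec.noise_sd == 0`` the output is deterministic.
    """
    ys, xs = np.meshgrid(np.arange(edge), np.arange(edge), indexing="ij")
    cx, cy = spec.center
    dx = xs - cx
    dy = ys - cy
    c, s = np.cos(spec.orientation), np.sin(spec.orientation)
    along = c * dx + s * dy
    across = -s * dx + c * dy
    envelope = np.exp(
        -(along**2) / (2 * spec.sigma_along**2) - (across**2) / (2 * spec.sigma_across**2)
    )
    carrier = np.cos(2 * np.pi * spec.frequency * along + spec.phase)
    rf = spec.amplitude * envelope * carrier
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        rf = rf + rng.normal(0.0, spec.noise_sd, size=rf.shape)
    return rf


def random_gabor_specs(
    n: int,
    edge: int,
    seed: int,
    freq_range: tuple[float, float] = (0.05, 0.25),
    aspect_range: tuple[float, float] = (0.5, 2.0),
    sigma_range: tuple[float, float] = (1.5, 3.5),
    center_jitter: float = 2.0,
    noise_sd: float = 0.0,
) -> list[GaborSpec]:
    """Draw a diverse set of Gabor parameters.

    Orientation uniform on [0, pi); frequency log-uniform on
    ``freq_range``; envelope aspect (sigma_along / sigma_across) uniform
    on ``aspect_range``; phase uniform on [0, 2 pi); centers jittered
    around the grid center by up to ``center_jitter`` pixels per axis.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    mid = (edge - 1) / 2.0
    specs = []
    for _ in range(n):
        sigma = rng.uniform(*sigma_range)
        aspect = rng.uniform(*aspect_range)
        freq = np.exp(rng.uniform(np.log(freq_range[0]), np.log(freq_range[1])))
        specs.append(
            GaborSpec(
                center=(
                    mid + rng.uniform(-center_jitter, center_jitter),
                    mid + rng.uniform(-center_jitter, center_jitter),
                ),
                orientation=rng.uniform(0.0, np.pi),
                frequency=float(freq),
                phase=rng.uniform(0.0, 2 * np.pi),
                sigma_along=sigma * aspect,
                sigma_across=sigma,
                amplitude=1.0,
                noise_sd=noise_sd,
            )
        )
    return specs


def generate_gabor_set(n: int, edge: int, seed: int, **kwargs) -> np.ndarray:
    """Stack of ``n`` random Gabor RFs, shape (n, edge, edge)."""
    specs = random_gabor_specs(n, edge, seed, **kwargs)
    rng_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)
    return np.stack([generate_gabor_rf(sp, edge, int(s)) for sp, s in zip(specs, rng_seeds)])


class PatchSampler:
    """Stream of whitened naturalistic patch batches for network training.

    A pool of pink-spectrum images is generated once and whitened; calls
    to :meth:`batch` then cut fresh random patches.  A fixed held-out
    measurement batch can be drawn with :meth:`measurement_batch`.
    """

    def __init__(
        self,
        patch_edge: int,
        seed: int,
        n_images: int = 40,
        image_edge: int = 128,
        target_var: float = 1.0,
    ) -> None:
        if patch_edge > image_edge:
            raise ValueError("patch_edge exceeds image edge")
        self.patch_edge = patch_edge
        self.seed = int(seed)
        self.target_var = target_var
        self.images = whiten(generate_pink_images(n_images, image_edge, seed))
        self._counter = 0

    def batch(self, n_patches: int) -> PatchBatch:
        self._counter += 1
        sub_seed = (self.seed * 1_000_003 + self._counter) % (2**31 - 1)
        return extract_patches(
            self.images, self.patch_edge, n_patches, sub_seed, self.target_var
        )

    def measurement_batch(self, n_patches: int) -> PatchBatch:
        sub_seed = (self.seed * 1_000_003 + 999_999_937) % (2**31 - 1)
        return extract_patches(
            self.images, self.patch_edge, n_patches, sub_seed, self.target_var
        )


# ---------------------------------------------------------------------------
# I/O

def save_patches(path, batch: PatchBatch) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("patches", data=batch.patches)
        d.attrs["seed"] = batch.seed
        d.attrs["edge"] = batch.patch_edge


def load_patches(path) -> PatchBatch:
    with h5py.File(path, "r") as f:
        d = f["patches"]
        return PatchBatch(
            patches=d[...], patch_edge=int(d.attrs["edge"]), seed=int(d.attrs["seed"])
        )


def save_rf_stack(path, rfs: np.ndarray, **attrs) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rfs", data=np.asarray(rfs, dtype=float))
        for k, v in attrs.items():
            d.attrs[k] = v


def load_rf_stack(path) -> np.ndarray:
    with h5py.File(path, "r") as f:
        return f["rfs"][...]


def load_rf_directory(path, pattern: str = "*") -> np.ndarray:
    """Load an RF stack from a directory of grayscale PNG/TIFF images.

    Files are read in sorted name order; RGB(A) images are averaged over
    channels, and each RF is centered by subtracting its mean (image
    files encode sensitivity around a mid-gray zero).  All images must
    share one square shape.
    """
    import pathlib

    from matplotlib.image import imread

    files = sorted(
        p
        for p in pathlib.Path(path).glob(pattern)
        if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise ValueError(f"no PNG/TIFF files found in {path}")
    rfs = []
    for f in files:
        arr = np.asarray(imread(f), dtype=float)
        if arr.ndim == 3:
            arr = arr[..., :3].mean(axis=2)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError(f"{f} is not a square grayscale image")
        rfs.append(arr - arr.mean())
    shapes = {r.shape for r in rfs}
    if len(shapes) > 1:
        raise ValueError("images have inconsistent shapes")
    return np.stack(rfs)


def save_mosaic(path, rfs: np.ndarray, n_cols: int | None = None) -> None:
    """Write a grayscale PNG mosaic of a stack of square arrays."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rfs = np.asarray(rfs)
    n, edge, _ = rfs.shape
    if n_cols is None:
        n_cols = int(np.ceil(np.sqrt(n)))
    n_rows = int(np.ceil(n / n_cols))
    tile = np.zeros((n_rows * (edge + 1) + 1, n_cols * (edge + 1) + 1))
    scale = np.abs(rfs).max(axis=(1, 2), keepdims=True)
    scale[scale == 0] = 1.0
    normed = rfs / scale
    for k in range(n):
        r, c = divmod(k, n_cols)
        tile[r * (edge + 1) + 1 : r * (edge + 1) + 1 + edge,
             c * (edge + 1) + 1 : c * (edge + 1) + 1 + edge] = normed[k]
    plt.imsave(path, tile, cmap="gray", vmin=-1, vmax=1)
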