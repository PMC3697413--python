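"""Image data model, I/O, continuous sampling and degradation transforms.

Volumes are scalar 3D grids on an axis-aligned world frame: the center of
voxel (i, j, k) sits at ``origin + (i, j, k) * spacing`` (mm).  The template
(end-diastolic) and target (end-systolic) volumes of a registration are both
held in this representation, as are the degraded variants used in the
noise / intensity sensitivity studies.

Intensity between voxel centers is defined by trilinear interpolation, and
the image gradient is the analytic gradient of that interpolant.  Points
outside the grid read as intensity 0 with zero gradient: background in a
gated cardiac PET volume is air/blood with near-zero counts, and a vanishing
out-of-grid force keeps the registration from being pulled by regions where
no data exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "Image3D",
    "NoiseSpec",
    "read_image",
    "write_image",
    "sample_intensity",
    "sample_gradient",
    "add_noise",
    "scale_intensity",
    "intensity_stats",
]


class ImageFormatError(ValueError):
    """Raised when a file cannot be interpreted as a 3D scalar volume."""


@dataclass
class Image3D:
    """A 3D scalar volume with voxel spacing and world origin.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Scalar intensities, stored as float64 even when the source is
        integer counts, so that interpolated force fields are smooth.
    spacing : ndarray, shape (3,)
        Per-axis voxel size in mm; all components > 0.
    origin : ndarray, shape (3,)
        World position (mm) of the center of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ImageFormatError(
                f"expected 3D scalar data, got {self.voxels.ndim}D array"
            )
        if any(n < 2 for n in self.voxels.shape):
            raise ImageFormatError(
                f"each axis needs >= 2 voxels, got shape {self.voxels.shape}"
            )
        if not np.all(self.spacing > 0):
            raise ImageFormatError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ImageFormatError("voxel intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "Image3D":
        return Image3D(self.voxels.copy(), self.spacing.copy(), self.origin.copy())

    def world_to_voxel(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel-index coordinates of world points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.origin) / self.spacing


@dataclass(frozen=True)
class NoiseSpec:
    """Additive zero-mean Gaussian noise level, expressed as an SNR.

    The noise standard deviation is tied to the image: sigma_n = sigma_i / snr,
    where sigma_i is the standard deviation of the image intensities over the
    whole volume, so SNR = sigma_i / sigma_n.
    """

    snr: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError(f"snr must be > 0, got {self.snr}")


def read_image(path: str | Path) -> Image3D:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mha/.mhd) scalar volume."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        itk_img = sitk.ReadImage(str(path))
    except Exception as exc:  # pragma: no cover - SimpleITK error text varies
        raise ImageFormatError(f"unreadable image file {path}: {exc}") from exc
    if itk_img.GetDimension() != 3:
        raise ImageFormatError(
            f"{path}: expected 3D data, file has dimension {itk_img.GetDimension()}"
        )
    if itk_img.GetNumberOfComponentsPerPixel() != 1:
        raise ImageFormatError(
            f"{path}: expected scalar voxels, file has "
            f"{itk_img.GetNumberOfComponentsPerPixel()} components"
        )
    # GetArrayFromImage returns (z, y, x); transpose to (x, y, z).
    arr = sitk.GetArrayFromImage(itk_img).astype(float).transpose(2, 1, 0)
    return Image3D(arr, np.array(itk_img.GetSpacing()), np.array(itk_img.GetOrigin()))


def write_image(img: Image3D, path: str | Path) -> None:
    """Write to NIfTI or MetaImage (format chosen by the file extension)."""
    itk_img = sitk.GetImageFromArray(img.voxels.transpose(2, 1, 0))
    itk_img.SetSpacing(tuple(img.spacing))
    itk_img.SetOrigin(tuple(img.origin))
    sitk.WriteImage(itk_img, str(path))


def _trilinear(img: Image3D, points: np.ndarray, want_gradient: bool):
    """Trilinear value and (optionally) analytic gradient at world points.

    Out-of-grid points contribute zero: the image is conceptually padded
    with a zero shell so that values (and forces) fade at the boundary.
    """
    idx = img.world_to_voxel(points)
    nx, ny, nz = img.shape
    # One-voxel zero padding realises the outside-is-zero policy while
    # keeping the interpolation stencil uniform: intensity fades linearly
    # to zero over the half-voxel shell just outside the outermost centers.
    pad = np.pad(img.voxels, 1, mode="constant")
    q = idx + 1.0  # coordinates in the padded grid
    n_arr = np.array([nx, ny, nz])

    inside = np.all((q >= 0.0) & (q <= n_arr + 1.0), axis=1)
    lo = np.clip(np.floor(q).astype(int), 0, n_arr)  # lo + 1 <= n + 1 is valid
    frac = q - lo
    fx, fy, fz = frac[:, 0], frac[:, 1], frac[:, 2]

    c = np.empty(points.shape[:1] + (2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = pad[lo[:, 0] + dx, lo[:, 1] + dy, lo[:, 2] + dz]

    wx = np.stack([1 - fx, fx], axis=1)
    wy = np.stack([1 - fy, fy], axis=1)
    wz = np.stack([1 - fz, fz], axis=1)
    vals = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, wz)
    vals = np.where(inside, vals, 0.0)
    if not want_gradient:
        return vals, None

    dwx = np.stack([-np.ones_like(fx), np.ones_like(fx)], axis=1)
    gx = np.einsum("nxyz,nx,ny,nz->n", c, dwx, wy, wz) / img.spacing[0]
    gy = np.einsum("nxyz,nx,ny,nz->n", c, wx, dwx, wz) / img.spacing[1]
    gz = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, dwx) / img.spacing[2]
    grad = np.stack([gx, gy, gz], axis=1)
    grad[~inside] = 0.0
    return vals, grad


def sample_intensity(img: Image3D, points: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated intensity at world points (mm).

    Points outside the grid return 0.  Reproduces stored voxel values
    exactly at voxel centers.
    """
    vals, _ = _trilinear(img, np.atleast_2d(np.asarray(points, dtype=float)), False)
    return vals


def sample_gradient(img: Image3D, points: np.ndarray) -> np.ndarray:
    """Analytic spatial gradient of the trilinear interpolant, intensity/mm.

    Within each voxel cell the gradient components are the exact partial
    derivatives of the trilinear form, so image forces assembled from it are
    exactly the negative gradient of the image energy.
    """
    _, grad = _trilinear(img, np.atleast_2d(np.asarray(points, dtype=float)), True)
    return grad


def add_noise(img: Image3D, spec: NoiseSpec) -> tuple[Image3D, Image3D]:
    """Add i.i.d. zero-mean Gaussian noise at the requested SNR.

    sigma_n = sigma_i / snr with sigma_i the intensity standard deviation
    over the whole volume.  Returns (noisy image, noise field); bit
    reproducible for a fixed seed.  SNR >= 1e12 is treated as the
    noise-free limit (sigma_n = 0).
    """
    sigma_i = float(np.std(img.voxels))
    if sigma_i == 0.0:
        raise ValueError("degenerate image: zero intensity standard deviation")
    sigma_n = 0.0 if spec.snr >= 1e12 else sigma_i / spec.snr
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, 1.0, size=img.shape) * sigma_n
    noise_img = Image3D(noise, img.spacing.copy(), img.origin.copy())
    noisy = Image3D(img.voxels + noise, img.spacing.copy(), img.origin.copy())
    return noisy, noise_img


def scale_intensity(img: Image3D, reduction_fraction: float) -> Image3D:
    """Uniformly reduce intensities: every voxel is scaled by (1 - f).

    Emulates reduced tracer uptake; f in [0, 1).
    """
    f = float(reduction_fraction)
    if not (0.0 <= f < 1.0):
        raise ValueError(f"reduction_fraction must be in [0, 1), got {f}")
    return Image3D(img.voxels * (1.0 - f), img.spacing.copy(), img.origin.copy())


def intensity_stats(
    img: Image3D, bins: int = 64
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Full-volume mean, standard deviation and fixed-bin histogram.

    Returns (mean, sd, counts, bin_edges).
    """
    v = img.voxels.ravel()
    counts, edges = np.histogram(v, bins=bins)
    return float(np.mean(v)), float(np.std(v)), counts, edges
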