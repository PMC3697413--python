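"""Synthetic LV phantom: analytic systole rendered as a PET-like image pair.

The phantom emulates a gated cardiac PET study: a bright myocardial wall
(truncated-ellipsoid shell) against a dark blood pool and background,
blurred by an isotropic Gaussian standing in for scanner resolution and
partial-volume averaging.  An analytic, invertible deformation maps the
end-diastolic (template) anatomy to the end-systolic (target) one:

* in-plane, area-preserving radial contraction: every circle of reference
  radius r at height z maps to r' = sqrt(r^2 - c(z)) in the wall and
  outside it, with c(z) chosen so the endocardium shortens by the
  circumferential fraction s(z), graded from base to apex as in normal
  systole; the blood pool scales linearly to match.  In-plane
  incompressibility makes the wall thicken as it contracts (radial
  Green-Lagrange strain > 0, circumferential < 0, det F = 1 in the wall);
* a torsion about the long axis, linear in z and zero at the base;
* a slight dimming of the target frame (uptake varies over the cardiac
  cycle in gated PET, and systolic partial-volume brightening changes the
  apparent wall intensity between frames).

Because the map is closed form, the true deformation gradient - and hence
the true circumferential/radial strain at any sampling location - is known
exactly, which is what makes the phantom usable as a registration ground
truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .imaging import Image3D
from .lvmesh import HexMesh, LVGeometry, build_lv_mesh, local_frames

__all__ = [
    "PhantomSpec",
    "analytic_deformation",
    "inverse_deformation",
    "render_image",
    "make_phantom_pair",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, imaging and deformation parameters of the phantom.

    The default grid is a desk-scale 64 x 64 x 16 volume at 3 x 3 x 7 mm
    (same field of view as the clinical short-axis grid of 100 x 100 x 42
    at 1.5 x 1.5 x 3.5 mm, with 8x fewer voxels); ``full_grid()`` returns
    the clinical-resolution variant.  Intensities are arbitrary units with
    a PET-like bright wall over a dark pool; ``blur_fwhm`` defaults to
    4 mm, a high-resolution-scanner point spread.  ``circ_shortening`` is
    the fractional systolic reduction of the endocardial circumference at
    the base, graded linearly to ``circ_shortening_apex`` at the tip
    (normal systole contracts more apically); ``endo_displacement_mm``, if
    given, overrides both with a uniform amplitude = s * a_endo.
    ``target_intensity_drop`` dims the target frame (default 8%, the scale
    of cycle-dependent uptake differences seen clinically).
    """

    geometry: LVGeometry = field(default_factory=LVGeometry)
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    spacing: tuple[float, float, float] = (3.0, 3.0, 7.0)
    wall_intensity: float = 100.0
    background_intensity: float = 5.0
    blur_fwhm: float = 4.0
    circ_shortening: float = 0.22
    circ_shortening_apex: float | None = 0.36
    endo_displacement_mm: float | None = None
    twist_deg: float = 8.0
    target_intensity_drop: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not self.geometry.a_endo > 0:
            raise ValueError("epi radius must exceed wall thickness")
        if min(self.grid_shape[:2]) < 16:
            raise ValueError("in-plane grid dims must be >= 16")
        if self.blur_fwhm < 0:
            raise ValueError("blur FWHM must be >= 0")
        if not 0.0 <= self.circ_shortening < 1.0:
            raise ValueError("circ_shortening must be in [0, 1)")

    @property
    def shortening(self) -> float:
        """Basal endocardial circumferential shortening fraction."""
        if self.endo_displacement_mm is not None:
            return self.endo_displacement_mm / self.geometry.a_endo
        return self.circ_shortening

    def shortening_at(self, z) -> np.ndarray:
        """Shortening fraction at height z: linear base-to-apex gradient.

        Normal systole contracts more toward the apex; the fraction ramps
        from the basal value at z_base to the apical value at the tip.  A
        uniform value is used when circ_shortening_apex is None or an
        explicit displacement amplitude is given.
        """
        s0 = self.shortening
        s1 = self.circ_shortening_apex
        if s1 is None or self.endo_displacement_mm is not None:
            return np.broadcast_to(np.float64(s0), np.shape(z)).copy()
        geo = self.geometry
        span = geo.z_base + geo.c_endo  # base plane to apex tip
        zeta = np.clip((geo.z_base - np.asarray(z, dtype=float)) / span, 0.0, 1.0)
        return s0 + (s1 - s0) * zeta

    def _shortening_slope(self, z) -> np.ndarray:
        """d(shortening)/dz (zero outside the base-tip span and for
        uniform shortening)."""
        s1 = self.circ_shortening_apex
        if s1 is None or self.endo_displacement_mm is not None:
            return np.zeros(np.shape(z))
        geo = self.geometry
        span = geo.z_base + geo.c_endo
        z = np.asarray(z, dtype=float)
        inside = (z < geo.z_base) & (z > -geo.c_endo)
        return np.where(inside, -(s1 - self.shortening) / span, 0.0)

    @property
    def origin(self) -> np.ndarray:
        """Origin centering the volume on the LV axis."""
        n = np.array(self.grid_shape, dtype=float)
        sp = np.array(self.spacing, dtype=float)
        return -(n - 1) / 2.0 * sp

    def full_grid(self) -> "PhantomSpec":
        """Clinical-resolution variant: 100 x 100 x 42 at 1.5 x 1.5 x 3.5 mm."""
        return replace(self, grid_shape=(100, 100, 42), spacing=(1.5, 1.5, 3.5))


def _contraction_c(spec: PhantomSpec, z):
    """c(z) = k(z) * r_endo(z)^2 with k = 1 - (1 - s(z))^2: the area removed
    from every in-plane circle so the endocardium shortens by fraction s(z)."""
    s = spec.shortening_at(z)
    k = 1.0 - (1.0 - s) ** 2
    geo = spec.geometry
    r2 = geo.a_endo**2 * np.maximum(1.0 - (np.asarray(z) / geo.c_endo) ** 2, 0.0)
    return k * r2


def _contraction_c_prime(spec: PhantomSpec, z):
    s = spec.shortening_at(z)
    k = 1.0 - (1.0 - s) ** 2
    kp = 2.0 * (1.0 - s) * spec._shortening_slope(z)
    geo = spec.geometry
    z = np.asarray(z)
    inside = np.abs(z) < geo.c_endo
    r2 = geo.a_endo**2 * np.maximum(1.0 - (z / geo.c_endo) ** 2, 0.0)
    dr2 = np.where(inside, -2.0 * geo.a_endo**2 * z / geo.c_endo**2, 0.0)
    return kp * r2 + k * dr2


def _twist_angle(spec: PhantomSpec, z):
    """Torsion angle tau(z), zero at the basal plane, linear toward the apex."""
    geo = spec.geometry
    L = geo.z_base - geo.z_apex
    rate = np.deg2rad(spec.twist_deg) / L
    return rate * (geo.z_base - np.asarray(z)), -rate


def analytic_deformation(
    points: np.ndarray, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Map reference points to their end-systolic positions, with exact F.

    Returns (mapped points (n, 3), deformation gradients (n, 3, 3)).  The
    map preserves z and in-plane area (det F = 1 in the wall); the two
    branches (wall/outside vs blood pool) join continuously at the
    endocardium.
    """
    X = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = X[:, 0], X[:, 1], X[:, 2]
    r = np.hypot(x, y)
    geo = spec.geometry
    s = spec.shortening_at(z)
    sp_z = spec._shortening_slope(z)
    c = _contraction_c(spec, z)
    cp = _contraction_c_prime(spec, z)
    r_en = geo.r_endo(z)
    tau, dtau = _twist_angle(spec, z)

    outer = r >= r_en
    rs = np.where(r > 0, r, 1.0)  # guarded radius for the axis

    g = np.where(outer, np.sqrt(np.maximum(r**2 - c, 1e-12)), (1.0 - s) * r)
    dgdr = np.where(outer, rs / np.where(outer, g, 1.0), 1.0 - s)
    dgdz = np.where(outer, -cp / (2.0 * np.where(outer, g, 1.0)), -sp_z * r)

    theta = np.arctan2(y, x)
    thp = theta + tau
    cth, sth = np.cos(theta), np.sin(theta)
    cthp, sthp = np.cos(thp), np.sin(thp)

    xp = g * cthp
    yp = g * sthp

    # chain rule: d(r, theta)/d(x, y) then assemble dF
    F = np.zeros((X.shape[0], 3, 3))
    goverr = np.where(r > 0, g / rs, 1.0 - s)
    F[:, 0, 0] = dgdr * cth * cthp + goverr * sth * sthp
    F[:, 0, 1] = dgdr * sth * cthp - goverr * cth * sthp
    F[:, 0, 2] = dgdz * cthp - g * sthp * dtau
    F[:, 1, 0] = dgdr * cth * sthp - goverr * sth * cthp
    F[:, 1, 1] = dgdr * sth * sthp + goverr * cth * cthp
    F[:, 1, 2] = dgdz * sthp + g * cthp * dtau
    F[:, 2, 2] = 1.0

    mapped = np.stack([xp, yp, z], axis=1)
    return mapped, F


def inverse_deformation(points: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Analytic inverse of :func:`analytic_deformation` (deformed -> reference)."""
    Xp = np.atleast_2d(np.asarray(points, dtype=float))
    xp, yp, z = Xp[:, 0], Xp[:, 1], Xp[:, 2]
    rp = np.hypot(xp, yp)
    geo = spec.geometry
    s = spec.shortening_at(z)
    c = _contraction_c(spec, z)
    r_en_def = (1.0 - s) * geo.r_endo(z)  # deformed endocardial radius
    tau, _ = _twist_angle(spec, z)

    outer = rp >= r_en_def
    r = np.where(outer, np.sqrt(rp**2 + c), rp / (1.0 - s))
    theta = np.arctan2(yp, xp) - tau
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def _wall_indicator(points: np.ndarray, geo: LVGeometry) -> np.ndarray:
    """1 inside the myocardial wall (between the ellipsoids, below the base,
    including the solid apex cap), else 0."""
    x, y, z = points[:, 0], points[:, 1], points[:, 2]
    q_epi = (x**2 + y**2) / geo.a_epi**2 + z**2 / geo.c_epi**2
    q_endo = (x**2 + y**2) / geo.a_endo**2 + z**2 / geo.c_endo**2
    return ((q_epi <= 1.0) & (q_endo >= 1.0) & (z <= geo.z_base)).astype(float)


def render_image(spec: PhantomSpec, use_deformed: bool = False) -> Image3D:
    """Render the (deformed) anatomy into a blurred PET-like volume.

    Voxel centers falling in the wall get ``wall_intensity``, elsewhere
    ``background_intensity``; the field is then convolved with an isotropic
    Gaussian of ``blur_fwhm`` mm.  Deterministic given the spec.
    """
    nx, ny, nz = spec.grid_shape
    sp = np.array(spec.spacing)
    org = spec.origin
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) * sp + org
    if use_deformed:
        pts = inverse_deformation(pts, spec)
    wall = _wall_indicator(pts, spec.geometry).reshape(nx, ny, nz)
    vox = spec.background_intensity + (
        spec.wall_intensity - spec.background_intensity
    ) * wall
    if spec.blur_fwhm > 0:
        sigma_vox = spec.blur_fwhm * _FWHM_TO_SIGMA / sp
        vox = gaussian_filter(vox, sigma=sigma_vox, mode="nearest")
    if use_deformed and spec.target_intensity_drop > 0:
        vox = vox * (1.0 - spec.target_intensity_drop)
    return Image3D(vox, sp.copy(), org.copy())


def make_phantom_pair(
    spec: PhantomSpec | None = None,
    mesh: HexMesh | None = None,
    divisions: tuple[int, int, int] = (24, 8, 4),
) -> tuple[Image3D, Image3D, pd.DataFrame, HexMesh]:
    """Template/target volumes plus the ground-truth strain table.

    The truth table holds the Green-Lagrange circumferential and radial
    strains of the analytic map, evaluated at the mesh Gauss points and
    averaged on the standard slice x region x depth sampling layout (12
    circumferential + 12 radial rows per slice).  Returns (template,
    target, truth table, mesh).
    """
    from .strain_compare import green_lagrange, sample_harp_grid

    spec = spec if spec is not None else PhantomSpec()
    if mesh is None:
        mesh = build_lv_mesh(spec.geometry, divisions)
    template = render_image(spec, use_deformed=False)
    target = render_image(spec, use_deformed=True)

    Xgp = mesh.gauss_coords()
    _, F = analytic_deformation(Xgp.reshape(-1, 3), spec)
    E = green_lagrange(F).reshape(Xgp.shape[:2] + (3, 3))
    truth = sample_harp_grid(E, local_frames(mesh), mesh)
    return template, target, truth, mesh
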