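"""Left-ventricular mesh generation: geometry, fibers, frames, regions.

The LV wall is modelled as the region between two concentric prolate
ellipsoids (endocardial and epicardial surfaces, long axis = z, apex
pointing toward -z), truncated by a basal plane, with an open apex.  It is
discretized into 8-node hexahedra on a structured circumferential x
longitudinal x transmural lattice.

Conventions
-----------
* ``wall_depth``: 0 at the epicardium, 1 at the endocardium.
* Myofiber inclination (helix) angle: angle of the fiber from the local
  circumferential direction within the wall-tangent plane, positive toward
  the base; negative epicardial / positive endocardial values reproduce the
  left-handed-to-right-handed transmural helix.  The transmural profile is
  piecewise linear through (epi, mid, endo) triple, by default
  (-82, 0, 80) degrees.
* Regions: four 90-degree circumferential quadrants per short-axis band,
  anterior = +y, lateral = +x, posterior = -y, septal = -x.
* Quadrature: 2x2x2 Gauss points per hexahedron throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LVGeometry",
    "HexMesh",
    "FiberField",
    "LocalFrame",
    "build_lv_mesh",
    "assign_fibers",
    "perturb_fiber_angles",
    "local_frames",
    "label_regions",
    "export_vtu",
    "export_nodes_csv",
    "GAUSS_1D",
    "gauss_points",
    "shape_functions",
    "shape_gradients",
]

BASELINE_FIBER_ANGLES = (-82.0, 0.0, 80.0)

REGION_NAMES = ("lateral", "anterior", "septal", "posterior")

# 2-point Gauss rule per axis; weights are all 1.
GAUSS_1D = np.array([-1.0, 1.0]) / np.sqrt(3.0)

# Standard VTK/FE hexahedron corner ordering in the parent element
# (xi, eta, zeta) in [-1, 1]^3: bottom face counter-clockwise, then top.
_CORNERS = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)


def gauss_points() -> np.ndarray:
    """The 8 parent-element Gauss points, shape (8, 3); each weight is 1."""
    g = GAUSS_1D
    pts = np.array([[x, y, z] for z in g for y in g for x in g])
    return pts


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """Trilinear shape functions N_a(xi) for points xi (..., 3) -> (..., 8)."""
    xi = np.asarray(xi)
    s = _CORNERS  # (8, 3)
    return (
        (1 + xi[..., None, 0] * s[:, 0])
        * (1 + xi[..., None, 1] * s[:, 1])
        * (1 + xi[..., None, 2] * s[:, 2])
        / 8.0
    )


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """Parent-space shape-function gradients dN_a/dxi, (..., 8, 3)."""
    xi = np.asarray(xi)
    s = _CORNERS
    gx = s[:, 0] * (1 + xi[..., None, 1] * s[:, 1]) * (1 + xi[..., None, 2] * s[:, 2])
    gy = (1 + xi[..., None, 0] * s[:, 0]) * s[:, 1] * (1 + xi[..., None, 2] * s[:, 2])
    gz = (1 + xi[..., None, 0] * s[:, 0]) * (1 + xi[..., None, 1] * s[:, 1]) * s[:, 2]
    return np.stack([gx, gy, gz], axis=-1) / 8.0


@dataclass(frozen=True)
class LVGeometry:
    """Truncated-ellipsoid LV wall geometry (mm).

    The epicardial surface is the ellipsoid x^2/a_epi^2 + y^2/a_epi^2 +
    z^2/c_epi^2 = 1; the endocardium is the concentric ellipsoid with both
    semi-axes reduced by ``wall_thickness``.  The mesh spans z in
    [z_apex, z_base] (open apex, planar base).
    """

    a_epi: float = 31.0
    c_epi: float = 48.0
    wall_thickness: float = 9.0
    z_base: float = 16.0
    z_apex: float = -30.0

    def __post_init__(self) -> None:
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be > 0")
        if self.wall_thickness >= min(self.a_epi, self.c_epi):
            raise ValueError(
                "self-intersecting geometry: wall thickness "
                f"{self.wall_thickness} >= inner radius"
            )
        if not (-self.c_endo < self.z_apex < self.z_base < self.c_endo):
            raise ValueError("z_base/z_apex must lie strictly inside the endocardium")

    @property
    def a_endo(self) -> float:
        return self.a_epi - self.wall_thickness

    @property
    def c_endo(self) -> float:
        return self.c_epi - self.wall_thickness

    def r_endo(self, z):
        """Endocardial radius at height z (mm)."""
        return self.a_endo * np.sqrt(np.maximum(1.0 - (z / self.c_endo) ** 2, 0.0))

    def r_epi(self, z):
        """Epicardial radius at height z (mm)."""
        return self.a_epi * np.sqrt(np.maximum(1.0 - (z / self.c_epi) ** 2, 0.0))

    def wall_radius(self, z, depth):
        """Radius of the constant-depth surface (depth 0 = epi, 1 = endo)."""
        return (1.0 - depth) * self.r_epi(z) + depth * self.r_endo(z)


@dataclass
class HexMesh:
    """Structured hexahedral LV wall mesh.

    node_coords : (n_nodes, 3) mm; elements : (n_elems, 8) node indices;
    wall_depth : per-node transmural coordinate in [0, 1] (0 = epi);
    region : per-element anatomical label; slice_index : per-element
    short-axis band (0 = most basal); divisions : the (n_circ, n_long,
    n_trans) lattice counts.
    """

    node_coords: np.ndarray
    elements: np.ndarray
    wall_depth: np.ndarray
    region: np.ndarray
    slice_index: np.ndarray
    divisions: tuple[int, int, int]
    geometry: LVGeometry | None = None

    @property
    def n_nodes(self) -> int:
        return self.node_coords.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elements.shape[0]

    def element_coords(self) -> np.ndarray:
        """(n_elems, 8, 3) reference corner coordinates."""
        return self.node_coords[self.elements]

    def depth_at_gauss(self) -> np.ndarray:
        """Interpolated wall_depth at the 8 Gauss points, (n_elems, 8)."""
        N = shape_functions(gauss_points())  # (8gp, 8node)
        return np.einsum("ga,ea->eg", N, self.wall_depth[self.elements])

    def gauss_coords(self) -> np.ndarray:
        """Reference-configuration Gauss point positions, (n_elems, 8, 3)."""
        N = shape_functions(gauss_points())
        return np.einsum("ga,eax->egx", N, self.element_coords())

    def reference_jacobians(self) -> np.ndarray:
        """det of the isoparametric Jacobian at each Gauss point, (n_elems, 8)."""
        dN = shape_gradients(gauss_points())  # (8gp, 8node, 3)
        J = np.einsum("eax,gay->egxy", self.element_coords(), dN)
        return np.linalg.det(J)


@dataclass
class FiberField:
    """Transmural myofiber field.

    angles : the (epi, mid, endo) inclination triple in degrees;
    vectors : unit fiber direction at each Gauss point, (n_elems, 8, 3).
    """

    angles: tuple[float, float, float]
    vectors: np.ndarray


@dataclass
class LocalFrame:
    """Orthonormal cardiac triad at each Gauss point.

    circumferential, radial, longitudinal : (n_elems, 8, 3) unit vectors;
    radial is the outward wall normal, longitudinal points apex-to-base,
    circumferential = longitudinal x radial.
    """

    circumferential: np.ndarray
    radial: np.ndarray
    longitudinal: np.ndarray


def build_lv_mesh(
    geometry: LVGeometry | None = None,
    divisions: tuple[int, int, int] = (24, 8, 4),
) -> HexMesh:
    """Mesh the truncated-ellipsoid wall with hexahedra.

    divisions = (circumferential, longitudinal, transmural) element counts;
    node count is nc * (nl + 1) * (nt + 1) (circumference is periodic, apex
    open).  All reference Jacobians are checked positive.
    """
    geo = geometry if geometry is not None else LVGeometry()
    nc, nl, nt = divisions
    if nc < 4 or nl < 2 or nt < 1:
        raise ValueError(f"divisions must be >= (4, 2, 1), got {divisions}")

    theta = 2.0 * np.pi * np.arange(nc) / nc
    z_levels = np.linspace(geo.z_base, geo.z_apex, nl + 1)
    depths = np.linspace(0.0, 1.0, nt + 1)  # 0 = epi

    # node index (ic, il, it) -> flat
    def nid(ic, il, it):
        return (ic % nc) + nc * (il + (nl + 1) * it)

    n_nodes = nc * (nl + 1) * (nt + 1)
    coords = np.zeros((n_nodes, 3))
    depth_arr = np.zeros(n_nodes)
    for it, d in enumerate(depths):
        for il, z in enumerate(z_levels):
            r = geo.wall_radius(z, d)
            for ic, th in enumerate(theta):
                k = nid(ic, il, it)
                coords[k] = (r * np.cos(th), r * np.sin(th), z)
                depth_arr[k] = d

    elems = []
    slice_idx = []
    for it in range(nt):
        for il in range(nl):
            for ic in range(nc):
                # corner ordering chosen to give positive Jacobians:
                # local xi ~ circumferential, eta ~ longitudinal (base->apex),
                # zeta ~ transmural (epi->endo)
                n000 = nid(ic, il, it)
                n100 = nid(ic + 1, il, it)
                n110 = nid(ic + 1, il + 1, it)
                n010 = nid(ic, il + 1, it)
                n001 = nid(ic, il, it + 1)
                n101 = nid(ic + 1, il, it + 1)
                n111 = nid(ic + 1, il + 1, it + 1)
                n011 = nid(ic, il + 1, it + 1)
                elems.append([n000, n100, n110, n010, n001, n101, n111, n011])
                slice_idx.append(il)
    elements = np.array(elems, dtype=int)
    slice_index = np.array(slice_idx, dtype=int)

    mesh = HexMesh(
        node_coords=coords,
        elements=elements,
        wall_depth=depth_arr,
        region=np.empty(len(elements), dtype=object),
        slice_index=slice_index,
        divisions=(nc, nl, nt),
        geometry=geo,
    )
    detJ = mesh.reference_jacobians()
    if np.min(detJ) <= 0:
        # orientation flip: swap top/bottom faces of every element
        mesh.elements = mesh.elements[:, [4, 5, 6, 7, 0, 1, 2, 3]]
        detJ = mesh.reference_jacobians()
    if np.min(detJ) <= 0:
        raise ValueError(f"mesh has non-positive Jacobians (min {np.min(detJ):.3g})")
    mesh.region = label_regions(mesh)
    return mesh


def inclination_angle(depth, angles=BASELINE_FIBER_ANGLES):
    """Helix angle (deg) at wall depth, piecewise linear through the triple.

    depth 0 -> epi angle, 0.5 -> mid angle, 1 -> endo angle.
    """
    d = np.asarray(depth, dtype=float)
    epi, mid, endo = angles
    return np.where(
        d <= 0.5,
        epi + (mid - epi) * (d / 0.5),
        mid + (endo - mid) * ((d - 0.5) / 0.5),
    )


def perturb_fiber_angles(
    angles: tuple[float, float, float], fraction: float
) -> tuple[float, float, float]:
    """Scale the inclination triple by (1 + fraction), rounded to whole degrees.

    fraction +0.05 maps the baseline (-82, 0, 80) to (-86, 0, 84);
    -0.05 maps it to (-78, 0, 76).
    """
    if not abs(fraction) < 1:
        raise ValueError(f"|fraction| must be < 1, got {fraction}")
    return tuple(float(np.round(a * (1.0 + fraction))) for a in angles)


def local_frames(mesh: HexMesh) -> LocalFrame:
    """Cardiac coordinate triads at the Gauss points.

    The radial direction is the outward normal of the constant-depth wall
    surface through the point; longitudinal is the apex-to-base tangent in
    the (r, z) plane; circumferential closes the triad.  Near the apex the
    surface normal tilts into the slice plane smoothly, so no separate
    degenerate-case branch is needed for the open-apex mesh.
    """
    geo = mesh.geometry
    if geo is None:
        raise ValueError("mesh carries no geometry; cannot build frames")
    X = mesh.gauss_coords()  # (e, g, 3)
    d = mesh.depth_at_gauss()  # (e, g)
    x, y, z = X[..., 0], X[..., 1], X[..., 2]
    r = np.sqrt(x**2 + y**2)
    e_r = np.stack([x / r, y / r, np.zeros_like(r)], axis=-1)
    e_z = np.zeros_like(X)
    e_z[..., 2] = 1.0

    # slope dR/dz of the constant-depth surface radius
    h = 1e-6
    dRdz = (geo.wall_radius(z + h, d) - geo.wall_radius(z - h, d)) / (2 * h)
    # outward normal of surface r = R(z): direction e_r - R'(z) e_z
    radial = e_r - dRdz[..., None] * e_z
    radial /= np.linalg.norm(radial, axis=-1, keepdims=True)
    # apex-to-base tangent: +z component positive
    longitudinal = dRdz[..., None] * e_r + e_z
    longitudinal /= np.linalg.norm(longitudinal, axis=-1, keepdims=True)
    circumferential = np.cross(longitudinal, radial)
    circumferential /= np.linalg.norm(circumferential, axis=-1, keepdims=True)
    return LocalFrame(circumferential, radial, longitudinal)


def assign_fibers(
    mesh: HexMesh,
    angles: tuple[float, float, float] = BASELINE_FIBER_ANGLES,
    frames: LocalFrame | None = None,
) -> FiberField:
    """Build the unit myofiber field from the transmural inclination triple.

    The fiber is the circumferential direction rotated about the radial
    (wall-normal) axis by the inclination angle, i.e. it stays in the
    wall-tangent plane: f = cos(alpha) c + sin(alpha) l.
    """
    if not np.all(np.isfinite(angles)):
        raise ValueError("fiber angles must be finite")
    fr = frames if frames is not None else local_frames(mesh)
    alpha = np.deg2rad(inclination_angle(mesh.depth_at_gauss(), angles))
    vec = (
        np.cos(alpha)[..., None] * fr.circumferential
        + np.sin(alpha)[..., None] * fr.longitudinal
    )
    vec /= np.linalg.norm(vec, axis=-1, keepdims=True)
    return FiberField(angles=tuple(float(a) for a in angles), vectors=vec)


def label_regions(mesh: HexMesh) -> np.ndarray:
    """Partition elements into anterior/posterior/septal/lateral quadrants.

    Quadrants are fixed 90-degree circumferential sectors centered on the
    coordinate axes: lateral = +x, anterior = +y, septal = -x,
    posterior = -y; independent of mesh resolution.
    """
    cent = mesh.element_coords().mean(axis=1)
    theta = np.mod(np.arctan2(cent[:, 1], cent[:, 0]) + np.pi / 4, 2 * np.pi)
    quadrant = np.floor(theta / (np.pi / 2)).astype(int) % 4
    return np.array([REGION_NAMES[q] for q in quadrant], dtype=object)


def export_nodes_csv(mesh: HexMesh, path) -> None:
    """Write node coordinates (mm) and wall depth as CSV."""
    data = np.column_stack([mesh.node_coords, mesh.wall_depth])
    np.savetxt(path, data, delimiter=",", header="x,y,z,wall_depth", comments="")


def export_vtu(
    mesh: HexMesh,
    path,
    point_data: dict | None = None,
    cell_data: dict | None = None,
) -> None:
    """Write the mesh as an ASCII VTK XML unstructured grid (.vtu).

    point_data values are (n_nodes,) or (n_nodes, 3) arrays; cell_data
    values are (n_elems,) arrays (object/str arrays are skipped).
    """
    pts = mesh.node_coords
    cells = mesh.elements
    pd = {"wall_depth": mesh.wall_depth}
    if point_data:
        pd.update(point_data)
    cd = {"slice_index": mesh.slice_index.astype(float)}
    if cell_data:
        for k, v in cell_data.items():
            v = np.asarray(v)
            if v.dtype != object and not v.dtype.kind == "U":
                cd[k] = v.astype(float)

    def arr_txt(a):
        return "\n".join(" ".join(f"{x:.9g}" for x in np.atleast_1d(row)) for row in a)

    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write("<UnstructuredGrid>\n")
        f.write(f'<Piece NumberOfPoints="{mesh.n_nodes}" NumberOfCells="{mesh.n_elems}">\n')
        f.write('<Points>\n<DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        f.write(arr_txt(pts) + "\n</DataArray>\n</Points>\n")
        f.write("<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        f.write(arr_txt(cells) + "\n</DataArray>\n")
        f.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(8 * (i + 1)) for i in range(mesh.n_elems)) + "\n</DataArray>\n")
        f.write('<DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(" ".join("12" for _ in range(mesh.n_elems)) + "\n</DataArray>\n")
        f.write("</Cells>\n<PointData>\n")
        for name, v in pd.items():
            v = np.asarray(v, dtype=float)
            ncomp = 1 if v.ndim == 1 else v.shape[1]
            f.write(f'<DataArray type="Float64" Name="{name}" NumberOfComponents="{ncomp}" format="ascii">\n')
            f.write(arr_txt(v) + "\n</DataArray>\n")
        f.write("</PointData>\n<CellData>\n")
        for name, v in cd.items():
            f.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
            f.write(arr_txt(v) + "\n</DataArray>\n")
        f.write("</CellData>\n</Piece>\n</UnstructuredGrid>\n</VTKFile>\n")
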