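"""Seeded generators for every input of the pipeline.

Stands in for the embryo data: layered tetrahedral toepad geometry
(epidermis shell over dermis over a rigid muscle core), light-sheet-like
labelled volumes with Gaussian-blob nuclei, and labyrinthine target fold
networks. All randomness flows through explicit integer seeds; identical
specs and seeds reproduce identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from morphofold.mesh import EPIDERMIS, DERMIS, LayeredTetMesh, boundary_faces

__all__ = [
    "BilayerSlabSpec",
    "ToepadDomeSpec",
    "EduVolumeSpec",
    "LabyrinthSpec",
    "make_bilayer_slab",
    "make_toepad_dome",
    "make_edu_volume",
    "make_labyrinth_network",
]


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class BilayerSlabSpec:
    """Flat bilayer test slab: epidermis film on a dermis substrate.

    Lengths in model units (dermis modulus and growth rate are likewise unit
    scaled). The slab bottom is the rigid muscle boundary.
    """

    lateral_extent_x: float
    lateral_extent_y: float
    thickness_epidermis: float
    thickness_dermis: float
    target_edge_length: float

    def __post_init__(self):
        vals = (
            self.lateral_extent_x,
            self.lateral_extent_y,
            self.thickness_epidermis,
            self.thickness_dermis,
            self.target_edge_length,
        )
        if any(v <= 0 for v in vals):
            raise ValueError("all slab extents must be positive")
        if self.target_edge_length > min(self.thickness_epidermis, self.thickness_dermis):
            raise ValueError(
                "target_edge_length must not exceed the thinnest layer "
                "(each layer needs at least one element through thickness)"
            )


@dataclass(frozen=True)
class ToepadDomeSpec:
    """Dome-shaped bilayer shell over a fixed (rigid muscle) interior boundary.

    ``rigid_core_offset`` is the depth of the dermis–muscle interface below
    the outer surface, measured along the surface normal.
    """

    base_radius: float
    dome_height: float
    thickness_epidermis: float
    rigid_core_offset: float
    target_edge_length: float

    def __post_init__(self):
        if min(self.base_radius, self.dome_height, self.target_edge_length) <= 0:
            raise ValueError("dome dimensions must be positive")
        if not (self.thickness_epidermis < self.rigid_core_offset < self.dome_height):
            raise ValueError(
                "need thickness_epidermis < rigid_core_offset < dome_height"
            )
        if self.thickness_epidermis < 2.0 * self.target_edge_length:
            raise ValueError(
                "epidermal shell thinner than 2 elements; refine "
                "target_edge_length or thicken the epidermis"
            )


@dataclass(frozen=True)
class EduVolumeSpec:
    """Synthetic EdU-stained two-layer volume with Gaussian-blob nuclei.

    An epidermis band of the given thickness sits at the top of axis 0; the
    rest is dermis. Nuclei centres are a homogeneous Poisson process per
    layer; epidermal density = ``dermal_density * epidermal_to_dermal_ratio``.

    The defaults are the study conditions for the proliferation-contrast
    analysis: a 23% epidermal excess over a dermal density of 5e-5
    cells/voxel^3, in a volume large enough (~4000 nuclei per layer) that
    Poisson counting noise on the recovered contrast is ~1 percentage point.
    """

    grid_shape: tuple[int, int, int] = (400, 600, 600)
    epidermis_band_thickness: int = 185
    dermal_density: float = 5e-5
    epidermal_to_dermal_ratio: float = 1.23
    blob_sigma: float = 2.0
    peak_intensity: float = 10.0
    background_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dermal_density < 0 or self.epidermal_to_dermal_ratio < 0:
            raise ValueError("densities must be non-negative")
        if self.blob_sigma < 1.0:
            raise ValueError("blob_sigma must be at least 1 voxel")
        if any(s < 4 * self.blob_sigma for s in self.grid_shape):
            raise ValueError("grid_shape must be at least 4*blob_sigma per axis")
        if not 0 < self.epidermis_band_thickness < self.grid_shape[0]:
            raise ValueError("epidermis band must fit inside the grid")


@dataclass(frozen=True)
class LabyrinthSpec:
    """Band-pass noise labyrinth used as a fixture target fold network."""

    domain_size: float = 10.0
    characteristic_wavelength: float = 1.5
    threshold_quantile: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if not 0 < self.characteristic_wavelength < self.domain_size:
            raise ValueError("wavelength must be positive and below domain_size")


# ---------------------------------------------------------------------------
# tetrahedral generators

# Kuhn subdivision of a unit cube into 6 tets sharing the main diagonal:
# each tet is (origin, origin+e_a, origin+e_a+e_b, far corner) for a
# permutation (a, b, c) of the axes.
_KUHN_PERMS = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]


def _hex_grid_tets(shape: tuple[int, int, int]) -> np.ndarray:
    """Connectivity of the Kuhn triangulation of a structured node grid."""
    nx, ny, nz = shape  # node counts

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    ii, jj, kk = np.meshgrid(
        np.arange(nx - 1), np.arange(ny - 1), np.arange(nz - 1), indexing="ij"
    )
    base = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    tets = []
    unit = np.eye(3, dtype=int)
    for a, b, c in _KUHN_PERMS:
        v0 = base
        v1 = base + unit[a]
        v2 = base + unit[a] + unit[b]
        v3 = base + 1
        tet = np.stack(
            [
                nid(v0[:, 0], v0[:, 1], v0[:, 2]),
                nid(v1[:, 0], v1[:, 1], v1[:, 2]),
                nid(v2[:, 0], v2[:, 1], v2[:, 2]),
                nid(v3[:, 0], v3[:, 1], v3[:, 2]),
            ],
            axis=1,
        )
        tets.append(tet)
    return np.concatenate(tets, axis=0)


def _fix_orientation(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = points[tets]
    vol = np.linalg.det(p[:, 1:] - p[:, :1])
    flip = vol < 0
    tets = tets.copy()
    tets[flip] = tets[flip][:, [0, 2, 1, 3]]
    return tets


def make_bilayer_slab(spec: BilayerSlabSpec, roller_sides: bool = False) -> LayeredTetMesh:
    """Structured bilayer slab mesh; bottom face fixed, N = +z everywhere.

    The grid snaps a node plane to the epidermis–dermis boundary so the
    layer labels partition the elements exactly by centroid depth.

    With ``roller_sides=True`` the lateral faces become symmetry (roller)
    boundaries — nodes on the x faces cannot move in x, nodes on the y faces
    cannot move in y — which emulates a laterally infinite slab and removes
    free-edge artefacts in wrinkling studies.
    """
    h = spec.target_edge_length
    nx = max(1, round(spec.lateral_extent_x / h))
    ny = max(1, round(spec.lateral_extent_y / h))
    nz_d = max(1, round(spec.thickness_dermis / h))
    nz_e = max(1, round(spec.thickness_epidermis / h))
    xs = np.linspace(0.0, spec.lateral_extent_x, nx + 1)
    ys = np.linspace(0.0, spec.lateral_extent_y, ny + 1)
    zs = np.concatenate(
        [
            np.linspace(0.0, spec.thickness_dermis, nz_d + 1),
            np.linspace(
                spec.thickness_dermis,
                spec.thickness_dermis + spec.thickness_epidermis,
                nz_e + 1,
            )[1:],
        ]
    )
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    points = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    tets = _fix_orientation(points, _hex_grid_tets((nx + 1, ny + 1, len(zs))))

    top = zs[-1]
    depth = top - points[tets].mean(axis=1)[:, 2]
    layer = np.where(depth < spec.thickness_epidermis, EPIDERMIS, DERMIS)
    fixed = np.flatnonzero(np.isclose(points[:, 2], 0.0))
    normals = np.tile([0.0, 0.0, 1.0], (len(tets), 1))
    tris, _ = boundary_faces(tets)
    fixed_dofs = np.zeros((len(points), 3), dtype=bool)
    if roller_sides:
        on_x = np.isclose(points[:, 0], 0.0) | np.isclose(points[:, 0], xs[-1])
        on_y = np.isclose(points[:, 1], 0.0) | np.isclose(points[:, 1], ys[-1])
        fixed_dofs[on_x, 0] = True
        fixed_dofs[on_y, 1] = True
    return LayeredTetMesh(points, tets, layer, fixed, normals, tris, fixed_dofs)


def _disk_triangulation(n_rings: int, ring_pts) -> tuple[np.ndarray, np.ndarray]:
    """Ring-based point set on the unit disk with a Delaunay triangulation.

    Returns ``(rho_phi, triangles)`` where ``rho_phi[:, 0]`` is the radial
    fraction in [0, 1] and ``rho_phi[:, 1]`` the azimuth. Ring azimuths are
    staggered between rings to avoid radially aligned slivers.
    """
    from scipy.spatial import Delaunay

    rho, phi = [0.0], [0.0]
    for j in range(1, n_rings + 1):
        m = ring_pts(j)
        offs = 0.5 * (j % 2) * 2 * np.pi / m
        ang = offs + 2 * np.pi * np.arange(m) / m
        rho.extend([j / n_rings] * m)
        phi.extend(ang.tolist())
    rho = np.asarray(rho)
    phi = np.asarray(phi)
    planar = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
    tris = Delaunay(planar).simplices
    # drop near-degenerate boundary slivers (collinear rim points)
    p = planar[tris]
    area = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    tris = tris[area > 1e-12]
    return np.column_stack([rho, phi]), tris


def _prisms_to_tets(bottom: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each, face-consistently.

    ``bottom``/``top`` are (p, 3) global node indices with ``top[i, k]``
    stacked over ``bottom[i, k]``. Quad-face diagonals follow the smallest
    global index, so adjacent prisms always agree (Dompierre et al. rule).
    """
    out = np.empty((len(bottom), 3, 4), dtype=np.int64)
    for i in range(len(bottom)):
        v = np.concatenate([bottom[i], top[i]])
        # rotate so the smallest-indexed vertex is v0 (bottom) or flip decks
        k = int(np.argmin(v))
        if k >= 3:
            v = v[[3, 4, 5, 0, 1, 2]]
            k -= 3
        if k == 1:
            v = v[[1, 2, 0, 4, 5, 3]]
        elif k == 2:
            v = v[[2, 0, 1, 5, 3, 4]]
        if min(v[1], v[5]) < min(v[2], v[4]):
            out[i, 0] = (v[0], v[1], v[2], v[5])
            out[i, 1] = (v[0], v[1], v[5], v[4])
            out[i, 2] = (v[0], v[4], v[5], v[3])
        else:
            out[i, 0] = (v[0], v[1], v[2], v[4])
            out[i, 1] = (v[0], v[4], v[2], v[5])
            out[i, 2] = (v[0], v[4], v[5], v[3])
    return out.reshape(-1, 4)


def make_toepad_dome(spec: ToepadDomeSpec) -> LayeredTetMesh:
    """Dome-shaped bilayer shell over a rigid core.

    The outer surface is the ellipsoidal dome ``(r/R)^2 + (z/H)^2 = 1``
    (a hemisphere when ``H = R``), sampled uniformly in polar angle over an
    unstructured disk triangulation; the shell extends ``rigid_core_offset``
    inward along the analytic surface normal (prisms split into tets), and
    nodes on the inner surface (the dermis–muscle interface) are fixed.
    Per-element N is the outward surface normal at the element's footprint —
    smooth by construction.
    """
    R, H, d = spec.base_radius, spec.dome_height, spec.rigid_core_offset
    # offset validity: stay below the smallest radius of curvature
    r_curv_min = min(R * R / H, H * H / R)
    if d >= r_curv_min:
        raise ValueError(
            f"rigid_core_offset {d} exceeds the dome's minimum radius of "
            f"curvature {r_curv_min:.3g}; inner offset surface would self-intersect"
        )
    h = spec.target_edge_length
    n_rings = max(4, round(0.5 * np.pi * R / h))
    arc = 0.5 * np.pi * R  # meridian length of the unit-angle parametrization

    def ring_pts(j):
        return max(6, round(2 * np.pi * R * np.sin(0.5 * np.pi * j / n_rings) / h))

    rho_phi, dtris = _disk_triangulation(n_rings, ring_pts)
    theta = 0.5 * np.pi * rho_phi[:, 0]
    phi = rho_phi[:, 1]
    x = R * np.sin(theta) * np.cos(phi)
    y = R * np.sin(theta) * np.sin(phi)
    z = H * np.cos(theta)
    nrm = np.column_stack([x / R**2, y / R**2, z / H**2])
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    surf_pts = np.column_stack([x, y, z])

    n_we = max(2, round(spec.thickness_epidermis / h))
    n_wd = max(1, round((d - spec.thickness_epidermis) / h))
    w = np.concatenate(
        [
            np.linspace(0.0, spec.thickness_epidermis, n_we + 1),
            np.linspace(spec.thickness_epidermis, d, n_wd + 1)[1:],
        ]
    )
    nw = len(w)
    n_disk = len(surf_pts)
    # node id = disk_index * nw + depth_level
    points = (
        surf_pts[:, None, :] - w[None, :, None] * nrm[:, None, :]
    ).reshape(-1, 3)
    tet_list = []
    for k in range(nw - 1):
        bottom = dtris * nw + k
        top = dtris * nw + (k + 1)
        tet_list.append(_prisms_to_tets(bottom, top))
    tets = _fix_orientation(points, np.concatenate(tet_list))

    wk = np.tile(w, n_disk)
    depth = wk[tets].mean(axis=1)
    layer = np.where(depth < spec.thickness_epidermis, EPIDERMIS, DERMIS)
    fixed = np.flatnonzero(np.isclose(wk, d))
    node_nrm = np.repeat(nrm, nw, axis=0)
    el_normals = node_nrm[tets].mean(axis=1)
    el_normals /= np.linalg.norm(el_normals, axis=1, keepdims=True)
    tris, _ = boundary_faces(tets)
    mesh = LayeredTetMesh(points, tets, layer, fixed, el_normals, tris)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# EdU-like labelled volume


def make_edu_volume(spec: EduVolumeSpec):
    """Synthetic nuclear-stain volume with per-layer Poisson nuclei.

    Returns ``(intensity, labels, true_centroids)``: a float32 intensity
    volume (sum of isotropic Gaussian blobs plus Gaussian background noise),
    a uint8 label volume (1 = epidermis band, 2 = dermis), and the ground
    truth blob centres as an ``(n, 3)`` float array in 0-based voxel
    coordinates (epidermis centres first).
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.grid_shape
    b = spec.epidermis_band_thickness
    labels = np.full(spec.grid_shape, 2, dtype=np.uint8)
    labels[:b] = 1

    vol_epi = float(b * ny * nx)
    vol_derm = float((nz - b) * ny * nx)
    rho_d = spec.dermal_density
    rho_e = rho_d * spec.epidermal_to_dermal_ratio
    n_epi = rng.poisson(rho_e * vol_epi)
    n_derm = rng.poisson(rho_d * vol_derm)

    centers_epi = rng.uniform(low=[0, 0, 0], high=[b, ny, nx], size=(n_epi, 3))
    centers_derm = rng.uniform(low=[b, 0, 0], high=[nz, ny, nx], size=(n_derm, 3))
    centers = np.vstack([centers_epi, centers_derm])

    intensity = rng.normal(0.0, spec.background_sd, size=spec.grid_shape).astype(
        np.float32
    )
    _paint_blobs(intensity, centers, spec.blob_sigma, spec.peak_intensity)
    return intensity, labels, centers


def _paint_blobs(vol: np.ndarray, centers: np.ndarray, sigma: float, peak: float):
    """Add isotropic Gaussian blobs (in place), truncated at 4 sigma."""
    if len(centers) == 0:
        return
    r = int(np.ceil(4.0 * sigma))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    shape = vol.shape
    for cz, cy, cx in centers:
        iz, iy, ix = int(round(cz)), int(round(cy)), int(round(cx))
        z0, z1 = max(0, iz - r), min(shape[0], iz + r + 1)
        y0, y1 = max(0, iy - r), min(shape[1], iy + r + 1)
        x0, x1 = max(0, ix - r), min(shape[2], ix + r + 1)
        if z0 >= z1 or y0 >= y1 or x0 >= x1:
            continue
        gz = np.exp(-((np.arange(z0, z1) - cz) ** 2) / (2 * sigma**2))
        gy = np.exp(-((np.arange(y0, y1) - cy) ** 2) / (2 * sigma**2))
        gx = np.exp(-((np.arange(x0, x1) - cx) ** 2) / (2 * sigma**2))
        vol[z0:z1, y0:y1, x0:x1] += (
            peak * gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
        ).astype(vol.dtype)


# ---------------------------------------------------------------------------
# labyrinth target networks


def make_labyrinth_network(spec: LabyrinthSpec):
    """Labyrinthine fixture fold network from band-pass filtered noise.

    Seeded white noise is band-pass filtered around the characteristic
    wavelength, thresholded at the given quantile, skeletonized and converted
    to a :class:`morphofold.foldnet.FoldNetwork` (toepad_length = domain
    size). An extreme threshold yields an empty network with a warning.
    """
    from morphofold.foldnet import FoldNetwork, network_from_raster_mask

    rng = np.random.default_rng(spec.seed)
    pixel = spec.characteristic_wavelength / 10.0
    n = int(round(spec.domain_size / pixel))
    noise = rng.standard_normal((n, n))
    # difference of Gaussians centred on the target wavelength
    s = spec.characteristic_wavelength / pixel / (2.0 * np.pi) * np.sqrt(2.0)
    band = ndimage.gaussian_filter(noise, s) - ndimage.gaussian_filter(noise, 2.0 * s)
    mask = band > np.quantile(band, spec.threshold_quantile)
    net = network_from_raster_mask(
        mask, pixel_size=pixel, origin=(0.0, 0.0), toepad_length=spec.domain_size
    )
    if net.graph.number_of_edges() == 0:
        warnings.warn("labyrinth threshold produced an empty network")
    return net
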