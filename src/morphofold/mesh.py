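"""Layered tetrahedral mesh container shared by the generators and the solver."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Layer codes used in ``LayeredTetMesh.layer``.
EPIDERMIS = 0
DERMIS = 1

LAYER_NAMES = {EPIDERMIS: "epidermis", DERMIS: "dermis"}


def tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    """Signed volumes of tetrahedra (positive for correct orientation)."""
    p = points[tets]
    d = p[:, 1:] - p[:, :1]
    return np.linalg.det(d) / 6.0


def boundary_faces(tets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Outward-oriented boundary triangles of a tet mesh.

    Returns ``(faces, owner)`` where ``owner[i]`` is the index of the single
    tetrahedron containing face ``i``. Faces are oriented so their normal
    points out of the owning element (and hence out of the mesh).
    """
    # Faces of tet (v0,v1,v2,v3) oriented with outward normals.
    idx = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
    faces = tets[:, idx].reshape(-1, 3)
    owner = np.repeat(np.arange(len(tets)), 4)
    key = np.sort(faces, axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1
    return faces[on_boundary], owner[on_boundary]


@dataclass
class LayeredTetMesh:
    """Reference tetrahedral mesh with per-element layer labels.

    Attributes
    ----------
    points : (n, 3) float array
        Reference node positions ``X``.
    tets : (m, 4) int array
        Node indices per element, positively oriented.
    layer : (m,) int array
        ``EPIDERMIS`` (0) or ``DERMIS`` (1) per element.
    fixed_nodes : (k,) int array
        Nodes with prescribed zero displacement (the rigid dermis–muscle
        interface and any clamped boundary).
    normals : (m, 3) float array
        Reference outward surface direction ``N`` per element, unit norm.
        Stored in the reference configuration and never updated during
        deformation.
    surface_tris : (s, 3) int array
        Outward-oriented boundary triangles.
    """

    points: np.ndarray
    tets: np.ndarray
    layer: np.ndarray
    fixed_nodes: np.ndarray
    normals: np.ndarray
    surface_tris: np.ndarray = field(default=None)
    #: optional (n, 3) boolean mask of individually constrained DOFs, e.g.
    #: roller (symmetry) boundaries; rows of fully fixed nodes are implied
    fixed_dofs: np.ndarray = field(default=None)

    def __post_init__(self):
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        self.layer = np.ascontiguousarray(self.layer, dtype=np.int64)
        self.fixed_nodes = np.ascontiguousarray(self.fixed_nodes, dtype=np.int64)
        self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
        if self.surface_tris is None:
            self.surface_tris, _ = boundary_faces(self.tets)
        self.surface_tris = np.ascontiguousarray(self.surface_tris, dtype=np.int64)
        if self.fixed_dofs is None:
            self.fixed_dofs = np.zeros((len(self.points), 3), dtype=bool)
        else:
            self.fixed_dofs = np.ascontiguousarray(self.fixed_dofs, dtype=bool)
        self.fixed_dofs[self.fixed_nodes] = True

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        return tet_volumes(self.points, self.tets)

    def edge_lengths(self) -> np.ndarray:
        """Lengths of all unique element edges."""
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        edges = np.concatenate([self.tets[:, [a, b]] for a, b in pairs])
        edges = np.unique(np.sort(edges, axis=1), axis=0)
        d = self.points[edges[:, 0]] - self.points[edges[:, 1]]
        return np.linalg.norm(d, axis=1)

    def aspect_ratios(self) -> np.ndarray:
        """Shape quality per element: ``6*sqrt(2)*V / l_max^3`` (1 for a regular tet)."""
        p = self.points[self.tets]
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        lmax = np.max(
            [np.linalg.norm(p[:, a] - p[:, b], axis=1) for a, b in pairs], axis=0
        )
        return 6.0 * np.sqrt(2.0) * tet_volumes(self.points, self.tets) / lmax**3

    def free_mask(self) -> np.ndarray:
        """Boolean per-node mask, True where the node is fully free to move."""
        return ~self.fixed_dofs.any(axis=1)

    def free_dof_mask(self) -> np.ndarray:
        """Boolean (n, 3) mask of unconstrained degrees of freedom."""
        return ~self.fixed_dofs

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated structural invariant."""
        if self.tets.min(initial=0) < 0 or self.tets.max(initial=-1) >= self.n_nodes:
            raise ValueError("element indices out of range")
        vols = self.volumes()
        if np.any(vols <= 0):
            raise ValueError(f"{np.sum(vols <= 0)} non-positive element volumes")
        if not np.all(np.isin(self.layer, [EPIDERMIS, DERMIS])):
            raise ValueError("unknown layer label")
        norms = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("reference normals must be unit vectors")
        if len(self.fixed_nodes) and (
            self.fixed_nodes.min() < 0 or self.fixed_nodes.max() >= self.n_nodes
        ):
            raise ValueError("fixed node indices out of range")
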