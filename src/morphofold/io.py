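"""File formats: TetGen meshes, PLY surfaces, TIFF volumes, network JSON/GraphML.

Meshes travel as TetGen ``.node``/``.ele`` ASCII pairs (1-based indices) with
a JSON sidecar holding what TetGen cannot: layer labels, the fixed-node set,
per-axis roller constraints and the reference normal field. Surfaces use PLY
(via trimesh), volumes multi-page TIFF (via tifffile), fold networks JSON
(complete round trip) or GraphML (interchange; polylines as encoded strings).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import tifffile
import trimesh
import yaml

from morphofold import foldnet, mech
from morphofold.mesh import DERMIS, EPIDERMIS, LayeredTetMesh

__all__ = [
    "save_mesh",
    "load_mesh",
    "save_surface",
    "load_surface",
    "save_volume",
    "load_volume",
    "save_centroids_csv",
    "load_centroids_csv",
    "save_network_json",
    "load_network_json",
    "save_network_graphml",
    "save_normalizer",
    "load_normalizer",
    "load_layer_params",
    "load_solver_config",
    "save_sim_outputs",
]


# ---------------------------------------------------------------------------
# meshes (TetGen .node/.ele + JSON sidecar)


def save_mesh(mesh: LayeredTetMesh, prefix) -> None:
    """Write ``<prefix>.node``, ``<prefix>.ele`` and ``<prefix>.json``."""
    prefix = Path(prefix)
    with open(prefix.with_suffix(".node"), "w") as fh:
        fh.write(f"{mesh.n_nodes} 3 0 0\n")
        for i, p in enumerate(mesh.points, start=1):
            fh.write(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    with open(prefix.with_suffix(".ele"), "w") as fh:
        fh.write(f"{mesh.n_elements} 4 0\n")
        for i, t in enumerate(mesh.tets + 1, start=1):
            fh.write(f"{i} {t[0]} {t[1]} {t[2]} {t[3]}\n")
    roller = {
        axis: np.flatnonzero(
            mesh.fixed_dofs[:, axis] & ~np.isin(np.arange(mesh.n_nodes), mesh.fixed_nodes)
        ).tolist()
        for axis in range(3)
    }
    sidecar = {
        "layer": mesh.layer.tolist(),
        "fixed_nodes": mesh.fixed_nodes.tolist(),
        "normals": np.round(mesh.normals, 12).tolist(),
        "surface_tris": mesh.surface_tris.tolist(),
        "roller_dofs": roller,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar))


def load_mesh(prefix) -> LayeredTetMesh:
    prefix = Path(prefix)
    with open(prefix.with_suffix(".node")) as fh:
        n = int(fh.readline().split()[0])
        points = np.array(
            [[float(v) for v in fh.readline().split()[1:4]] for _ in range(n)]
        )
    with open(prefix.with_suffix(".ele")) as fh:
        m = int(fh.readline().split()[0])
        tets = (
            np.array([[int(v) for v in fh.readline().split()[1:5]] for _ in range(m)])
            - 1
        )
    side = json.loads(prefix.with_suffix(".json").read_text())
    fixed_dofs = np.zeros((n, 3), dtype=bool)
    for axis, nodes in side.get("roller_dofs", {}).items():
        fixed_dofs[np.asarray(nodes, dtype=int), int(axis)] = True
    return LayeredTetMesh(
        points=points,
        tets=tets,
        layer=np.asarray(side["layer"]),
        fixed_nodes=np.asarray(side["fixed_nodes"], dtype=int),
        normals=np.asarray(side["normals"], dtype=float),
        surface_tris=np.asarray(side["surface_tris"], dtype=int),
        fixed_dofs=fixed_dofs,
    )


# ---------------------------------------------------------------------------
# surfaces and volumes


def save_surface(surface: trimesh.Trimesh, path) -> None:
    surface.export(str(path))


def load_surface(path) -> trimesh.Trimesh:
    out = trimesh.load(str(path), process=False)
    return out


def save_volume(vol: np.ndarray, path) -> None:
    tifffile.imwrite(str(path), np.asarray(vol))


def load_volume(path) -> np.ndarray:
    return tifffile.imread(str(path))


def save_centroids_csv(cells, path) -> None:
    """Centroids as CSV with 0-based voxel coordinates, columns x,y,z.

    Detected positions are stored (z, y, x) in array order; the CSV follows
    the x,y,z convention of the imaging tools.
    """
    pos = np.asarray(cells.positions if hasattr(cells, "positions") else cells)
    arr = pos[:, ::-1] if len(pos) else np.empty((0, 3))
    header = "x,y,z"
    np.savetxt(str(path), arr, delimiter=",", header=header, comments="")


def load_centroids_csv(path) -> np.ndarray:
    """Centroids back in (z, y, x) array order."""
    arr = np.loadtxt(str(path), delimiter=",", skiprows=1, ndmin=2)
    return arr[:, ::-1] if arr.size else np.empty((0, 3))


# ---------------------------------------------------------------------------
# fold networks


def save_network_json(net: foldnet.FoldNetwork, path) -> None:
    G = net.graph
    data = {
        "toepad_length": net.toepad_length,
        "nodes": [
            {"id": int(n), "pos": np.asarray(G.nodes[n]["pos"]).tolist()}
            for n in G.nodes
        ],
        "edges": [
            {
                "u": int(u),
                "v": int(v),
                "polyline": np.asarray(foldnet.oriented_polyline(G, u, v)).tolist(),
            }
            for u, v in G.edges
        ],
        "cycles": [
            {"edges": [[int(a), int(b)] for a, b in c["edges"]], "perimeter": c["perimeter"]}
            for c in net.cycles
        ],
        "incomplete_edges": [[int(a), int(b)] for a, b in net.incomplete_edges],
    }
    Path(path).write_text(json.dumps(data))


def load_network_json(path) -> foldnet.FoldNetwork:
    data = json.loads(Path(path).read_text())
    G = nx.Graph()
    for nd in data["nodes"]:
        G.add_node(nd["id"], pos=np.asarray(nd["pos"], dtype=float))
    for ed in data["edges"]:
        pl = np.asarray(ed["polyline"], dtype=float)
        G.add_edge(
            ed["u"],
            ed["v"],
            polyline=pl,
            start=ed["u"],
            length=float(np.linalg.norm(np.diff(pl, axis=0), axis=1).sum()),
        )
    return foldnet.FoldNetwork(G, data["toepad_length"])


def save_network_graphml(net: foldnet.FoldNetwork, path) -> None:
    G = nx.Graph()
    for n in net.graph.nodes:
        p = net.graph.nodes[n]["pos"]
        G.add_node(n, x=float(p[0]), y=float(p[1]))
    for u, v in net.graph.edges:
        pl = foldnet.oriented_polyline(net.graph, u, v)
        G.add_edge(
            u,
            v,
            length=float(net.graph.edges[u, v]["length"]),
            polyline=json.dumps(np.asarray(pl).tolist()),
        )
    G.graph["toepad_length"] = net.toepad_length
    nx.write_graphml(G, str(path))


def save_normalizer(norm: foldnet.Normalizer, path) -> None:
    Path(path).write_text(
        json.dumps({"mean": norm.mean.tolist(), "sd": norm.sd.tolist()})
    )


def load_normalizer(path) -> foldnet.Normalizer:
    d = json.loads(Path(path).read_text())
    return foldnet.Normalizer(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]))


# ---------------------------------------------------------------------------
# YAML configuration


def load_layer_params(path):
    """Per-layer parameter YAML -> (materials, growth) dicts.

    Expected layout::

        epidermis: {E: 3.0, nu: 0.35, lambda_T: 1.55, lambda_N: 0.0}
        dermis:    {E: 1.0, nu: 0.15, lambda_T: 1.2}
    """
    raw = yaml.safe_load(Path(path).read_text())
    code = {"epidermis": EPIDERMIS, "dermis": DERMIS}
    materials, growth = {}, {}
    for name, layer in raw.items():
        c = code[name]
        materials[c] = mech.ElasticConstants(E=layer["E"], nu=layer["nu"])
        growth[c] = mech.GrowthLaw(
            lambda_N=layer.get("lambda_N", 0.0),
            lambda_T=layer.get("lambda_T", 0.0),
            beta=layer.get("beta", 1.0),
        )
    return materials, growth


def load_solver_config(path) -> mech.SolverConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return mech.SolverConfig(**raw)


# ---------------------------------------------------------------------------
# simulation outputs


def save_sim_outputs(out_dir, mesh: LayeredTetMesh, state: mech.SimState) -> None:
    """Deformed surface (PLY), per-element state (npz + JSON header), log (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_surface(mech.deformed_surface(mesh, state), out / "surface.ply")
    np.savez_compressed(
        out / "element_state.npz",
        positions=state.positions,
        F=state.F,
        Fg=state.Fg,
        Fe=state.Fe,
        sigma=state.sigma,
        psi=state.psi,
        J=state.J,
    )
    (out / "element_state.json").write_text(
        json.dumps(
            {
                "time": state.time,
                "residual": state.residual,
                "n_nodes": int(mesh.n_nodes),
                "n_elements": int(mesh.n_elements),
                "arrays": {
                    "positions": "nodal positions (n,3)",
                    "F": "deformation gradient per element (m,3,3)",
                    "Fg": "growth part (m,3,3)",
                    "Fe": "elastic part (m,3,3)",
                    "sigma": "Cauchy stress (m,3,3)",
                    "psi": "strain energy density (m,)",
                    "J": "det Fe (m,)",
                },
            }
        )
    )
    if state.history is not None and len(state.history):
        np.savetxt(
            out / "convergence.csv",
            state.history,
            delimiter=",",
            header="step,time,residual,energy",
            comments="",
        )
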