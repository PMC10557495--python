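"""Readers and writers: NIfTI/MetaImage volumes, SWC/JSON graphs, CSV tables.

Grid arrays use 0-based (z, y, x) axis order with spacing in mm per axis;
NIfTI files store (x, y, z), so volumes are transposed on the way in and out.
SWC files use 1-based node ids, parent -1 for roots, and encode the vessel
class in the SWC type field (artery = 2, vein = 3, unlabeled = 5).
"""
from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .topology import Particle, TopologyGraph

SWC_ARTERY, SWC_VEIN, SWC_UNLABELED = 2, 3, 5
_CLASS_TO_SWC = {1: SWC_ARTERY, 2: SWC_VEIN, 0: SWC_UNLABELED}
_SWC_TO_CLASS = {v: k for k, v in _CLASS_TO_SWC.items()}


class FormatError(ValueError):
    pass


def write_volume(grid: np.ndarray, spacing, path: str | Path) -> None:
    """Write a (z, y, x) grid with mm spacing as NIfTI (.nii/.nii.gz) or
    MetaImage (.mha/.mhd)."""
    path = Path(path)
    grid = np.asarray(grid)
    if grid.dtype == bool:
        grid = grid.astype(np.uint8)
    sp = [float(s) for s in spacing]
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        xyz = np.ascontiguousarray(grid.transpose(2, 1, 0))
        affine = np.diag([sp[2], sp[1], sp[0], 1.0])
        nib.save(nib.Nifti1Image(xyz, affine), str(path))
    elif name.endswith((".mha", ".mhd")):
        img = sitk.GetImageFromArray(grid)  # SimpleITK arrays are (z, y, x)
        img.SetSpacing((sp[2], sp[1], sp[0]))
        sitk.WriteImage(img, str(path))
    else:
        raise FormatError(f"unknown volume format: {path}")


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a volume; returns ((z, y, x) array, spacing mm (z, y, x))."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such volume file: {path}")
    name = path.name.lower()
    try:
        if name.endswith((".nii", ".nii.gz")):
            img = nib.load(str(path))
            data = np.asarray(img.dataobj)
            zooms = img.header.get_zooms()[:3]
            grid = np.ascontiguousarray(data.transpose(2, 1, 0))
            spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        elif name.endswith((".mha", ".mhd")):
            img = sitk.ReadImage(str(path))
            grid = sitk.GetArrayFromImage(img)
            sx, sy, sz = img.GetSpacing()
            spacing = (float(sz), float(sy), float(sx))
        else:
            raise FormatError(f"unknown volume format: {path}")
    except FormatError:
        raise
    except Exception as e:  # corrupt file, wrong magic, truncated ...
        raise FormatError(f"could not read volume {path}: {e}") from e
    return grid, spacing


def write_graph(
    graph: TopologyGraph,
    path: str | Path,
    fmt: str | None = None,
    labels: np.ndarray | None = None,
) -> None:
    """Write a topology graph as SWC (tree-only) or JSON (lossless)."""
    path = Path(path)
    fmt = fmt or ("swc" if path.suffix == ".swc" else "json")
    if fmt == "swc":
        if graph.n_nodes and len(graph.g.edges) >= graph.n_nodes - len(list(nx.connected_components(graph.g))) + 1:
            raise FormatError("graph contains cycles; SWC is a tree format — use JSON")
        lines = []
        for n in range(graph.n_nodes):
            p = graph.particles[n]
            cls = int(labels[n]) if labels is not None else 0
            parent = graph.parent.get(n)
            z, y, x = p.position
            lines.append(
                f"{n + 1} {_CLASS_TO_SWC.get(cls, SWC_UNLABELED)} "
                f"{x:.4f} {y:.4f} {z:.4f} {p.scale:.4f} "
                f"{-1 if parent is None else parent + 1}"
            )
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        payload = {
            "nodes": [
                {
                    "id": n,
                    "position": [float(v) for v in graph.particles[n].position],
                    "scale": float(graph.particles[n].scale),
                    "orientation": [float(v) for v in graph.particles[n].orientation],
                    "intensity": float(graph.particles[n].intensity),
                    "kind": graph.particles[n].kind,
                    "parent": (None if graph.parent.get(n) is None
                               else int(graph.parent[n])),
                    "label": int(labels[n]) if labels is not None else None,
                }
                for n in range(graph.n_nodes)
            ],
            "edges": [[int(u), int(v)] for u, v in graph.g.edges],
            "roots": [int(r) for r in graph.roots],
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    else:
        raise FormatError(f"unknown graph format {fmt!r}")


def read_graph(path: str | Path) -> tuple[TopologyGraph, np.ndarray | None]:
    """Read a graph written by :func:`write_graph`; returns (graph, labels)."""
    path = Path(path)
    if path.suffix == ".swc":
        particles, edges, labels = [], [], []
        parents = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            nid, typ, x, y, z, r, parent = line.split()
            particles.append(
                Particle(
                    position=np.array([float(z), float(y), float(x)]),
                    scale=float(r),
                    orientation=np.array([1.0, 0.0, 0.0]),
                )
            )
            labels.append(_SWC_TO_CLASS.get(int(typ), 0))
            parents.append(int(parent))
        for i, par in enumerate(parents):
            if par > 0:
                edges.append((par - 1, i))
        roots = [i for i, par in enumerate(parents) if par == -1]
        g = TopologyGraph.from_particles(particles, edges, roots)
        return g, np.asarray(labels, dtype=np.uint8)
    payload = json.loads(path.read_text())
    particles = []
    labels = []
    any_label = False
    for nd in payload["nodes"]:
        particles.append(
            Particle(
                position=np.asarray(nd["position"], float),
                scale=float(nd["scale"]),
                orientation=np.asarray(nd["orientation"], float),
                intensity=float(nd.get("intensity", 0.0)),
                kind=nd.get("kind"),
            )
        )
        lab = nd.get("label")
        any_label = any_label or lab is not None
        labels.append(0 if lab is None else int(lab))
    g = TopologyGraph.from_particles(
        particles, [tuple(e) for e in payload["edges"]], payload["roots"]
    )
    return g, (np.asarray(labels, dtype=np.uint8) if any_label else None)


def write_particles_csv(graph: TopologyGraph, path: str | Path, labels=None) -> None:
    import pandas as pd

    rows = []
    for n in range(graph.n_nodes):
        p = graph.particles[n]
        rows.append({
            "x": p.position[2], "y": p.position[1], "z": p.position[0],
            "scale": p.scale,
            "ox": p.orientation[2], "oy": p.orientation[1], "oz": p.orientation[0],
            "intensity": p.intensity, "kind": p.kind,
            "label": None if labels is None else int(labels[n]),
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_phantom(vol, outdir: str | Path, trees=None) -> None:
    """Write mask / intensity / truth labels as NIfTI plus centerline JSON
    (and per-tree SWC when the tree specs are given)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_volume(vol.mask, vol.spacing, outdir / "mask.nii.gz")
    write_volume(vol.intensity, vol.spacing, outdir / "intensity.nii.gz")
    write_volume(vol.truth_labels, vol.spacing, outdir / "truth_labels.nii.gz")
    cl = {
        label: [
            {"points_mm": pts.tolist(), "radii_mm": radii.tolist()}
            for pts, radii in polys
        ]
        for label, polys in vol.centerlines.items()
    }
    (outdir / "centerlines.json").write_text(json.dumps(
        {"spacing_mm_zyx": list(vol.spacing), "centerlines": cl}, sort_keys=True
    ))
    if trees is not None:
        for tree in trees:
            swc_type = SWC_ARTERY if tree.class_label == "artery" else SWC_VEIN
            lines = []
            children = {}
            parent_of = {}
            for p, c in tree.edges:
                parent_of[c] = p
            for i, (pos, r) in enumerate(tree.nodes):
                z, y, x = pos
                par = parent_of.get(i)
                lines.append(
                    f"{i + 1} {swc_type} {x:.4f} {y:.4f} {z:.4f} {r:.4f} "
                    f"{-1 if par is None else par + 1}"
                )
            (outdir / f"tree_{tree.class_label}.swc").write_text("\n".join(lines) + "\n")
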