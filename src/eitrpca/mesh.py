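"""2-D finite-element phantoms for thoracic EIT simulation.

The phantom is a triangulated disc (optionally flattened into a thorax-like
ellipse) with 16 equispaced boundary electrodes and two elliptical lung
inclusions.  Coordinate convention used throughout the package:

* +y is the ventral (front) direction — the top of reconstructed images;
* +x is the subject's anatomical left — the right half of images, so the
  subject's right lung appears on the image's left, as clinicians expect;
* electrode 1 sits at the ventral midline, numbering proceeds clockwise
  when the image is viewed in this orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay

__all__ = ["PhantomSpec", "make_phantom"]

#: role of each labelled region in the breathing modulation: "area1" regions
#: take the normalised waveform directly, "area2" regions a scaled-down copy.
_REGION_ROLES_HOMOG = {"left_lung": "area1", "right_lung": "area2"}
_REGION_ROLES_HETERO = {
    "left_lung_a": "area1",
    "left_lung_b": "area2",
    "right_lung": "area2",
}


@dataclass(frozen=True)
class PhantomSpec:
    """Triangulated phantom with labelled lung regions and electrode arcs.

    nodes : (N, 2) float array of vertex coordinates.
    elements : (M, 3) int array of triangle vertex indices.
    element_labels : (M,) array of region names ("background" or a lung key).
    region_roles : map from lung region name to its modulation role.
    electrode_edges : per electrode, the boundary edges (node pairs) covered
        by its arc.
    electrode_angles : (16,) electrode centre angles, radians, disc frame.
    boundary : (B, 2) ordered polygon of boundary node coordinates.
    """

    style: str
    nodes: np.ndarray
    elements: np.ndarray
    element_labels: np.ndarray
    region_roles: dict
    electrode_edges: tuple
    electrode_angles: np.ndarray
    boundary: np.ndarray
    background_conductivity: float = 1.0

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    @property
    def n_electrodes(self) -> int:
        return len(self.electrode_edges)

    @property
    def lung_regions(self) -> tuple:
        return tuple(self.region_roles)

    def element_centroids(self) -> np.ndarray:
        return self.nodes[self.elements].mean(axis=1)

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elements]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * np.abs(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def conductivity_vector(self, area1: float, area2: float) -> np.ndarray:
        """Per-element conductivity for one frame: background everywhere,
        ``area1``/``area2`` in the correspondingly-labelled lung regions."""
        sigma = np.full(self.n_elements, self.background_conductivity)
        for name, role in self.region_roles.items():
            sigma[self.element_labels == name] = area1 if role == "area1" else area2
        return sigma


def _disc_points(n_rings: int, seed: int = 0) -> np.ndarray:
    """Concentric-ring point cloud on the unit disc; rings are rotated
    against each other so the Delaunay triangulation has no slivers."""
    pts = [np.zeros((1, 2))]
    for k in range(1, n_rings + 1):
        r = k / n_rings
        m = int(round(2 * np.pi * k))
        th = 2 * np.pi * np.arange(m) / m + 0.35 * k
        pts.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
    return np.vstack(pts)


def _boundary_edges(tri: Delaunay) -> list[tuple[int, int]]:
    """Edges that belong to exactly one triangle."""
    count: dict[tuple[int, int], tuple[int, int]] = {}
    seen: dict[tuple[int, int], int] = {}
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            key = tuple(sorted((simplex[a], simplex[b])))
            seen[key] = seen.get(key, 0) + 1
            count[key] = (simplex[a], simplex[b])
    return [count[k] for k, c in seen.items() if c == 1]


def _inside_ellipse(p: np.ndarray, center, axes) -> np.ndarray:
    return ((p[:, 0] - center[0]) / axes[0]) ** 2 + ((p[:, 1] - center[1]) / axes[1]) ** 2 <= 1.0


def make_phantom(
    style: str = "thorax",
    heterogeneous_left: bool = False,
    n_rings: int = 18,
    electrode_coverage: float = 0.5,
) -> PhantomSpec:
    """Build a 16-electrode phantom.

    Parameters
    ----------
    style
        ``"circular"`` — unit disc; ``"thorax"`` — the disc flattened to a
        chest-like ellipse (dorso-ventral axis 80% of the lateral axis).
    heterogeneous_left
        Split the left lung into ventral/dorsal halves with independent
        conductivity roles, emulating regionally inhomogeneous aeration.
    n_rings
        Mesh density; 18 rings give roughly 2100 triangles.
    electrode_coverage
        Fraction of the inter-electrode arc covered by each electrode.
    """
    if style not in ("circular", "thorax"):
        raise ValueError(f"unknown phantom style {style!r}")
    pts = _disc_points(n_rings)
    tri = Delaunay(pts)
    elements = tri.simplices.copy()
    # enforce counter-clockwise orientation
    p = pts[elements]
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 1, 1] - p[:, 0, 1]
    ) * (p[:, 2, 0] - p[:, 0, 0])
    flip = cross < 0
    elements[flip] = elements[flip][:, [0, 2, 1]]

    # electrodes: 1-based id k sits at 90 deg - (k-1)*22.5 deg, clockwise
    n_elec = 16
    pitch = 2 * np.pi / n_elec
    angles = np.pi / 2 - pitch * np.arange(n_elec)
    half_arc = 0.5 * electrode_coverage * pitch
    bedges = _boundary_edges(tri)
    electrode_edges: list[list[tuple[int, int]]] = [[] for _ in range(n_elec)]
    for a, b in bedges:
        mid = 0.5 * (pts[a] + pts[b])
        th = np.arctan2(mid[1], mid[0])
        for k in range(n_elec):
            d = np.angle(np.exp(1j * (th - angles[k])))
            if abs(d) <= half_arc:
                electrode_edges[k].append((a, b))
                break
    if any(len(e) == 0 for e in electrode_edges):
        raise RuntimeError("mesh too coarse: an electrode covers no boundary edge")

    # lung inclusions, defined in disc coordinates
    centroids = pts[elements].mean(axis=1)
    labels = np.full(elements.shape[0], "background", dtype=object)
    lungs = {
        "left_lung": ((+0.45, -0.08), (0.30, 0.46)),
        "right_lung": ((-0.45, -0.08), (0.30, 0.46)),
    }
    for name, (c, ax) in lungs.items():
        labels[_inside_ellipse(centroids, c, axes=ax)] = name
    if heterogeneous_left:
        left = labels == "left_lung"
        labels[left & (centroids[:, 1] > -0.08)] = "left_lung_a"
        labels[left & (centroids[:, 1] <= -0.08)] = "left_lung_b"
        roles = dict(_REGION_ROLES_HETERO)
    else:
        roles = dict(_REGION_ROLES_HOMOG)

    nodes = pts.copy()
    if style == "thorax":
        nodes[:, 1] *= 0.8

    # ordered boundary polygon (by angle) for the image mask
    bnodes = sorted({i for e in bedges for i in e})
    th = np.arctan2(pts[bnodes, 1], pts[bnodes, 0])
    order = np.argsort(th)
    boundary = nodes[np.asarray(bnodes)[order]]

    return PhantomSpec(
        style=style,
        nodes=nodes,
        elements=elements,
        element_labels=np.asarray(labels, dtype=object),
        region_roles=roles,
        electrode_edges=tuple(tuple(e) for e in electrode_edges),
        electrode_angles=angles,
        boundary=boundary,
    )
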