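"""Sensor geometry: quasi-uniform hemispheric layouts with region tags and adjacency.

The layout emulates a whole-head axial-gradiometer array (151 sensors by
default).  Sensors live on the unit upper hemisphere with +y pointing
anterior, +x to the right and +z up.  Region tags partition the array into
the functional groups the analysis refers to (occipital, occipito-parietal,
central-parietal, left-motor, frontal, plus a residual "central" strip);
adjacency is a thresholded Euclidean-distance graph and stands in for a
vendor-supplied sensor-neighbourhood template.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["SensorLayout", "make_layout", "REGIONS"]

#: Region tags used by the generator and by band identification.
REGIONS = (
    "occipital",
    "occipito-parietal",
    "central-parietal",
    "left-motor",
    "central",
    "frontal",
)


@dataclass
class SensorLayout:
    """Sensor positions, region tags and a boolean adjacency matrix.

    Attributes
    ----------
    positions : (n_sensors, 3) float array
        Cartesian coordinates on the unit upper hemisphere.
    regions : (n_sensors,) array of str
        Region tag per sensor (one of :data:`REGIONS`).
    adjacency : (n_sensors, n_sensors) bool array
        Symmetric neighbourhood matrix with an empty diagonal.
    neighbor_radius : float
        Distance threshold that produced ``adjacency``.
    """

    positions: np.ndarray
    regions: np.ndarray
    adjacency: np.ndarray
    neighbor_radius: float = field(default=0.0)

    @property
    def n_sensors(self) -> int:
        return self.positions.shape[0]

    def region_sensors(self, tag: str) -> np.ndarray:
        """Indices of the sensors carrying region ``tag``."""
        if tag not in REGIONS:
            raise ValueError(f"unknown region {tag!r}; expected one of {REGIONS}")
        return np.nonzero(self.regions == tag)[0]

    def validate(self) -> None:
        adj = self.adjacency
        if adj.shape != (self.n_sensors, self.n_sensors):
            raise ValueError("adjacency shape does not match sensor count")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("adjacency diagonal must be empty")

    # ---- serialization (JSON, adjacency as index pairs) -------------------
    def to_json(self, path) -> None:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        payload = {
            "positions": self.positions.tolist(),
            "regions": list(map(str, self.regions)),
            "adjacency_pairs": np.stack([iu, ju], axis=1).tolist(),
            "neighbor_radius": float(self.neighbor_radius),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SensorLayout":
        with open(path) as fh:
            payload = json.load(fh)
        pos = np.asarray(payload["positions"], dtype=float)
        n = pos.shape[0]
        adj = np.zeros((n, n), dtype=bool)
        pairs = np.asarray(payload["adjacency_pairs"], dtype=int)
        if pairs.size:
            adj[pairs[:, 0], pairs[:, 1]] = True
            adj |= adj.T
        return cls(pos, np.asarray(payload["regions"]), adj,
                   float(payload.get("neighbor_radius", 0.0)))


def _hemisphere_points(n: int) -> np.ndarray:
    # Fibonacci lattice on the upper hemisphere; deterministic.
    k = np.arange(n)
    z = (k + 0.5) / n                       # uniform in height -> uniform in area
    phi = k * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _assign_regions(pos: np.ndarray) -> np.ndarray:
    x, y = pos[:, 0], pos[:, 1]
    out = np.empty(pos.shape[0], dtype=object)
    out[:] = "central"
    out[y < -0.55] = "occipital"
    out[(y >= -0.55) & (y < -0.25)] = "occipito-parietal"
    out[(y >= -0.25) & (y < 0.10)] = "central-parietal"
    motor = (y >= 0.10) & (y < 0.45) & (x < -0.10)
    out[motor] = "left-motor"
    out[y >= 0.45] = "frontal"
    return out.astype(str)


def default_neighbor_radius(n_sensors: int) -> float:
    """Radius giving a mean adjacency degree of about six on the hemisphere."""
    return float(np.sqrt(12.0 / n_sensors))


def make_layout(n_sensors: int = 151, neighbor_radius: float | None = None) -> SensorLayout:
    """Build a deterministic quasi-uniform hemispheric sensor layout.

    Parameters
    ----------
    n_sensors : int
        Number of sensors (>= 10).
    neighbor_radius : float, optional
        Euclidean distance threshold for adjacency.  Defaults to a value
        giving a mean degree of roughly six neighbours per sensor.

    Raises
    ------
    ValueError
        If the resulting adjacency graph is disconnected (the radius is too
        small for the sensor density).
    """
    if n_sensors < 10:
        raise ValueError("need at least 10 sensors")
    if neighbor_radius is None:
        neighbor_radius = default_neighbor_radius(n_sensors)
    if neighbor_radius <= 0:
        raise ValueError("neighbor_radius must be positive")
    pos = _hemisphere_points(n_sensors)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = d <= neighbor_radius
    np.fill_diagonal(adj, False)
    n_comp, _ = connected_components(csr_matrix(adj), directed=False)
    if n_comp != 1:
        raise ValueError(
            f"adjacency graph is disconnected ({n_comp} components) at "
            f"radius {neighbor_radius:g}; increase neighbor_radius")
    layout = SensorLayout(pos, _assign_regions(pos), adj, float(neighbor_radius))
    layout.validate()
    return layout
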