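"""Parcel scheme: the spatial and topological scaffold of the connectome.

A :class:`ParcelScheme` holds everything downstream stages need to know about
the parcellation: parcel identities, hemisphere and superregion labels, 3-D
centroids in millimetres, voxel counts, the gray-matter adjacency graph, and
the homotopic (mirror) pairing between hemispheres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist

HEMISPHERES = ("L", "R", "M")
SUPERREGIONS = ("cortex", "subcortex", "cerebellum", "brainstem")


@dataclass(frozen=True)
class ParcelScheme:
    """Immutable description of a brain parcellation.

    Parameters
    ----------
    parcel_ids :
        Integer parcel identifiers, in canonical order. All matrix-valued
        quantities downstream use this order.
    names :
        Human-readable parcel names.
    hemisphere :
        One of ``"L"``, ``"R"``, ``"M"`` (midline) per parcel.
    superregion :
        One of ``cortex``, ``subcortex``, ``cerebellum``, ``brainstem``.
    lobe :
        Free-form lobe / class label per parcel.
    centroids :
        ``(n, 3)`` array of centroid coordinates in mm. The convention is
        x = left(-)/right(+), y = caudal(-)/rostral(+), z = inferior/superior.
    n_voxels :
        Voxel count per parcel (>= 1).
    adjacency :
        Gray-matter adjacency as a frozenset of ``(id_i, id_j)`` pairs with
        ``id_i < id_j``.
    homotopic :
        Mapping parcel id -> homotopic partner id (both directions present).
    """

    parcel_ids: np.ndarray
    names: tuple
    hemisphere: np.ndarray
    superregion: np.ndarray
    lobe: np.ndarray
    centroids: np.ndarray
    n_voxels: np.ndarray
    adjacency: frozenset
    homotopic: dict = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.parcel_ids)
        ids = np.asarray(self.parcel_ids)
        if len(set(ids.tolist())) != n:
            raise ValueError("duplicate parcel ids")
        if self.centroids.shape != (n, 3) or not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be a finite (n, 3) array")
        if np.any(np.asarray(self.n_voxels) < 1):
            raise ValueError("every parcel must contain at least one voxel")
        idset = set(ids.tolist())
        for i, j in self.adjacency:
            if i == j:
                raise ValueError("adjacency must be irreflexive")
            if i > j:
                raise ValueError("adjacency pairs must be stored as (low, high)")
            if i not in idset or j not in idset:
                raise ValueError(f"adjacency references unknown parcel ({i},{j})")
        for a, b in self.homotopic.items():
            if self.homotopic.get(b) != a:
                raise ValueError(f"homotopic map not symmetric at {a}<->{b}")

    # -- basic accessors ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.parcel_ids)

    @property
    def index_of(self) -> dict:
        return {int(p): i for i, p in enumerate(self.parcel_ids)}

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean centroid distances in mm."""
        return squareform(pdist(self.centroids))

    def adjacency_matrix(self) -> np.ndarray:
        """Boolean gray-matter adjacency matrix in canonical parcel order."""
        n = len(self)
        idx = self.index_of
        A = np.zeros((n, n), dtype=bool)
        for i, j in self.adjacency:
            A[idx[i], idx[j]] = A[idx[j], idx[i]] = True
        return A

    def graph(self, hemisphere: str | None = None,
              superregions: tuple | None = None) -> nx.Graph:
        """Gray-matter adjacency as a networkx graph on parcel ids.

        Optionally restricted to a hemisphere and/or a set of superregions;
        the restriction keeps only edges with both endpoints inside the
        selection (nodes outside it are dropped).
        """
        keep = np.ones(len(self), dtype=bool)
        if hemisphere is not None:
            keep &= self.hemisphere == hemisphere
        if superregions is not None:
            keep &= np.isin(self.superregion, list(superregions))
        kept_ids = set(int(p) for p in np.asarray(self.parcel_ids)[keep])
        g = nx.Graph()
        g.add_nodes_from(sorted(kept_ids))
        g.add_edges_from((i, j) for i, j in self.adjacency
                         if i in kept_ids and j in kept_ids)
        return g

    def subset_mask(self, ids) -> np.ndarray:
        return np.isin(self.parcel_ids, np.asarray(list(ids)))

    # -- I/O ----------------------------------------------------------------
    def to_tsv(self, parcels_path, edges_path) -> None:
        """Write parcels (one row each) and the adjacency edge list as TSV."""
        df = pd.DataFrame({
            "parcel_id": self.parcel_ids,
            "name": list(self.names),
            "hemisphere": self.hemisphere,
            "superregion": self.superregion,
            "lobe": self.lobe,
            "x": self.centroids[:, 0],
            "y": self.centroids[:, 1],
            "z": self.centroids[:, 2],
            "n_voxels": self.n_voxels,
            "homotopic_partner": [self.homotopic.get(int(p), -1)
                                  for p in self.parcel_ids],
        })
        df.to_csv(parcels_path, sep="\t", index=False)
        edges = pd.DataFrame(sorted(self.adjacency), columns=["parcel_a", "parcel_b"])
        edges.to_csv(edges_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, parcels_path, edges_path) -> "ParcelScheme":
        df = pd.read_csv(Path(parcels_path), sep="\t")
        edges = pd.read_csv(Path(edges_path), sep="\t")
        homotopic = {}
        for pid, partner in zip(df["parcel_id"], df["homotopic_partner"]):
            if partner >= 0:
                homotopic[int(pid)] = int(partner)
        adjacency = frozenset(
            (int(min(a, b)), int(max(a, b)))
            for a, b in zip(edges["parcel_a"], edges["parcel_b"])
        )
        return cls(
            parcel_ids=df["parcel_id"].to_numpy(),
            names=tuple(df["name"]),
            hemisphere=df["hemisphere"].to_numpy(dtype=object),
            superregion=df["superregion"].to_numpy(dtype=object),
            lobe=df["lobe"].to_numpy(dtype=object),
            centroids=df[["x", "y", "z"]].to_numpy(dtype=float),
            n_voxels=df["n_voxels"].to_numpy(dtype=int),
            adjacency=adjacency,
            homotopic=homotopic,
        )
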