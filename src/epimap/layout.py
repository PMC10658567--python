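"""Electrode array layouts and spatial adjacency graphs.

An :class:`ElectrodeLayout` describes where each recording channel sits in
space (positions in mm, optional grid row/column indices); an
:class:`AdjacencyGraph` captures which electrodes count as spatial
neighbours, with Euclidean edge lengths.  Both are shared by the wavefront
simulator, conduction-velocity estimation and spatial interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .errors import ConfigurationError, InvalidArgumentError

__all__ = [
    "ElectrodeLayout",
    "AdjacencyGraph",
    "grid_layout",
    "build_adjacency",
]


@dataclass(frozen=True)
class ElectrodeLayout:
    """Channel identities and 3-D electrode positions (mm).

    Parameters
    ----------
    channel_ids
        Unique integer label per channel.
    positions
        ``(n, 3)`` float array of positions in millimetres.
    rows, cols
        Optional integer grid indices; ``(row, col)`` pairs must be unique.
    active
        Boolean contact flag per channel (defaults to all-active).
    """

    channel_ids: np.ndarray
    positions: np.ndarray
    rows: np.ndarray | None = None
    cols: np.ndarray | None = None
    active: np.ndarray | None = None

    def __post_init__(self) -> None:
        ids = np.asarray(self.channel_ids, dtype=int)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "channel_ids", ids)
        object.__setattr__(self, "positions", pos)
        if ids.ndim != 1 or ids.size < 2:
            raise InvalidArgumentError("layout needs at least 2 channels")
        if np.unique(ids).size != ids.size:
            raise InvalidArgumentError("channel ids must be unique")
        if pos.shape != (ids.size, 3) or not np.all(np.isfinite(pos)):
            raise InvalidArgumentError("positions must be finite (n, 3) mm")
        if (self.rows is None) != (self.cols is None):
            raise InvalidArgumentError("rows and cols must be given together")
        if self.rows is not None:
            rows = np.asarray(self.rows, dtype=int)
            cols = np.asarray(self.cols, dtype=int)
            object.__setattr__(self, "rows", rows)
            object.__setattr__(self, "cols", cols)
            if rows.shape != ids.shape or cols.shape != ids.shape:
                raise InvalidArgumentError("grid indices must match channels")
            rc = np.stack([rows, cols], axis=1)
            if np.unique(rc, axis=0).shape[0] != ids.size:
                raise InvalidArgumentError("(row, col) pairs must be unique")
        act = (
            np.ones(ids.size, dtype=bool)
            if self.active is None
            else np.asarray(self.active, dtype=bool)
        )
        if act.shape != ids.shape:
            raise InvalidArgumentError("active flags must match channels")
        object.__setattr__(self, "active", act)
        # distinct positions: any coincident pair breaks edge-length > 0
        tree = cKDTree(pos)
        dists, idx = tree.query(pos, k=2)
        if np.any(dists[:, 1] <= 0.0):
            raise InvalidArgumentError("electrode positions must be distinct")

    @property
    def n_channels(self) -> int:
        return int(self.channel_ids.size)

    @property
    def has_grid(self) -> bool:
        return self.rows is not None

    def index_of(self, channel_id: int | np.ndarray) -> np.ndarray | int:
        """Map channel id(s) to positional index(es) in the layout arrays."""
        order = np.argsort(self.channel_ids)
        pos = np.searchsorted(self.channel_ids[order], channel_id)
        pos = np.asarray(pos)
        bad = (pos >= self.n_channels) | (
            self.channel_ids[order][np.minimum(pos, self.n_channels - 1)]
            != channel_id
        )
        if np.any(bad):
            raise KeyError(f"unknown channel id(s): {np.atleast_1d(channel_id)[np.atleast_1d(bad)]}")
        out = order[pos]
        return int(out) if out.ndim == 0 else out

    def median_spacing(self) -> float:
        """Median nearest-neighbour distance (mm) — the grid pitch for
        regular arrays."""
        tree = cKDTree(self.positions)
        dists, _ = tree.query(self.positions, k=2)
        return float(np.median(dists[:, 1]))

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "channel_id": self.channel_ids,
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
            }
        )
        df["row"] = self.rows if self.rows is not None else -1
        df["col"] = self.cols if self.cols is not None else -1
        df["active"] = self.active.astype(int)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ElectrodeLayout":
        df = pd.read_csv(path, comment="#")
        rows = cols = None
        if "row" in df and df["row"].min() >= 0:
            rows = df["row"].to_numpy(int)
            cols = df["col"].to_numpy(int)
        active = df["active"].to_numpy(bool) if "active" in df else None
        return cls(
            channel_ids=df["channel_id"].to_numpy(int),
            positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
            rows=rows,
            cols=cols,
            active=active,
        )


@dataclass(frozen=True)
class AdjacencyGraph:
    """Undirected neighbour graph over electrodes with mm edge lengths."""

    channel_ids: np.ndarray  # nodes (active channels)
    edges: np.ndarray        # (m, 2) channel-id pairs, first < second
    lengths: np.ndarray      # (m,) Euclidean lengths, mm

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        lengths = np.asarray(self.lengths, dtype=float)
        if np.any(edges[:, 0] == edges[:, 1]):
            raise InvalidArgumentError("self-edges are not allowed")
        if np.any(lengths <= 0) or not np.all(np.isfinite(lengths)):
            raise InvalidArgumentError("edge lengths must be positive finite")
        object.__setattr__(self, "channel_ids", np.asarray(self.channel_ids, dtype=int))
        object.__setattr__(self, "edges", edges)
        object.__setattr__(self, "lengths", lengths)

    @property
    def n_nodes(self) -> int:
        return int(self.channel_ids.size)

    def neighbors(self, channel_id: int) -> np.ndarray:
        mask0 = self.edges[:, 0] == channel_id
        mask1 = self.edges[:, 1] == channel_id
        return np.concatenate([self.edges[mask1, 0], self.edges[mask0, 1]])

    def to_sparse(self, weights: np.ndarray | None = None) -> sparse.csr_matrix:
        """Symmetric weighted adjacency over ``channel_ids`` order.

        ``weights`` replaces edge lengths (same ordering) when given — used
        by the simulator to convert lengths into travel times.
        """
        n = self.n_nodes
        lut = {cid: i for i, cid in enumerate(self.channel_ids)}
        i = np.array([lut[c] for c in self.edges[:, 0]], dtype=int)
        j = np.array([lut[c] for c in self.edges[:, 1]], dtype=int)
        w = self.lengths if weights is None else np.asarray(weights, float)
        mat = sparse.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(n, n),
        )
        return mat.tocsr()


def grid_layout(rows: int, cols: int, spacing: float) -> ElectrodeLayout:
    """Planar regular grid of electrodes, row-major consecutive ids.

    ``spacing`` is the inter-electrode pitch in mm.  The default mapping
    array in this package is ``grid_layout(16, 16, 3.5)`` — a 256-channel
    high-density grid with pitch in the 3–4 mm range typical of epicardial
    contact arrays.
    """
    if rows < 1 or cols < 1:
        raise InvalidArgumentError("rows and cols must be >= 1")
    if spacing <= 0:
        raise InvalidArgumentError("spacing must be positive (mm)")
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    rr = rr.ravel()
    cc = cc.ravel()
    pos = np.stack([cc * spacing, rr * spacing, np.zeros(rr.size)], axis=1)
    return ElectrodeLayout(
        channel_ids=np.arange(rows * cols),
        positions=pos,
        rows=rr,
        cols=cc,
    )


def build_adjacency(
    layout: ElectrodeLayout,
    mode: str = "grid8",
    k: int = 8,
    radius: float | None = None,
) -> AdjacencyGraph:
    """Build the neighbour graph over *active* channels.

    Modes
    -----
    ``grid8``
        Each electrode connects to its <= 8 row/col neighbours including
        diagonals (requires grid indices).  Default for regular arrays:
        diagonal edges keep the graph metric close to Euclidean.
    ``knn``
        k nearest active neighbours (symmetrised).
    ``radius``
        All active pairs closer than ``radius`` mm.
    """
    act = layout.active
    ids = layout.channel_ids[act]
    pos = layout.positions[act]
    pairs: set[tuple[int, int]] = set()

    if mode == "grid8":
        if not layout.has_grid:
            raise ConfigurationError("grid8 adjacency requires grid indices")
        rows = layout.rows[act]
        cols = layout.cols[act]
        lut = {(r, c): cid for r, c, cid in zip(rows, cols, ids)}
        for r, c, cid in zip(rows, cols, ids):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if dr == dc == 0:
                        continue
                    other = lut.get((r + dr, c + dc))
                    if other is not None:
                        pairs.add((min(cid, other), max(cid, other)))
    elif mode == "knn":
        if ids.size < 2:
            raise InvalidArgumentError("knn adjacency needs >= 2 active channels")
        kk = min(k, ids.size - 1)
        tree = cKDTree(pos)
        _, idx = tree.query(pos, k=kk + 1)
        for i in range(ids.size):
            for j in idx[i, 1:]:
                a, b = int(ids[i]), int(ids[j])
                pairs.add((min(a, b), max(a, b)))
    elif mode == "radius":
        if radius is None or radius <= 0:
            raise InvalidArgumentError("radius mode requires a positive radius")
        tree = cKDTree(pos)
        for i, j in tree.query_pairs(r=radius):
            a, b = int(ids[i]), int(ids[j])
            pairs.add((min(a, b), max(a, b)))
    else:
        raise InvalidArgumentError(f"unknown adjacency mode: {mode!r}")

    edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    lut_pos = {cid: p for cid, p in zip(ids, pos)}
    lengths = np.array(
        [np.linalg.norm(lut_pos[a] - lut_pos[b]) for a, b in edges], dtype=float
    )
    return AdjacencyGraph(channel_ids=ids, edges=edges, lengths=lengths)
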