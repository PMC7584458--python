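"""Connectome and synthetic graph construction, Laplacians, GraphML I/O.

A connectome is an undirected weighted graph whose vertices are anatomical
regions and whose edges are white-matter tracts carrying two attributes: a
mean fiber count ``n`` and a mean fiber length ``l``.  Transport of protein
concentration is generated by the weighted graph Laplacian built from
``W_ij = n_ij / l_ij**2`` (the inverse-length-squared weighting that a
finite-difference discretization of the continuum diffusion operator would
produce), while the transneuronal damage term uses the distinct adjacency
``A_ij = n_ij / l_ij``.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectomeGraph",
    "DEFAULT_ATTR_MAP",
    "cubic_lattice",
    "load_graphml",
    "save_graphml",
    "laplacian",
]

#: Default GraphML edge-attribute names (braingraph.org dialect); override
#: via the ``attr_map`` argument of :func:`load_graphml` for other dialects.
DEFAULT_ATTR_MAP = {
    "fiber_n": "number_of_fibers",
    "fiber_l": "fiber_length_mean",
}

#: Node-attribute names recognized for region labels / coordinates.
_LABEL_KEYS = ("dn_name", "name", "label")
_COORD_KEYS = (("dn_position_x", "dn_position_y", "dn_position_z"),
               ("x", "y", "z"))


class ConnectomeGraph:
    """An undirected graph with fiber-count/length edges and derived matrices.

    Parameters
    ----------
    edges : sequence of (i, j, n_ij, l_ij)
        0-based vertex indices with mean fiber number and mean fiber length.
    labels : sequence of str, optional
        Anatomical region label per node (defaults to the node index).
    coords : (V, 3) array, optional
        Node coordinates.
    node_ids : sequence, optional
        Original GraphML node ids, preserved for reporting.
    """

    def __init__(self, n_nodes, edges, labels=None, coords=None, node_ids=None):
        self.n_nodes = int(n_nodes)
        edges = [(int(i), int(j), float(n), float(l)) for i, j, n, l in edges]
        for i, j, n, l in edges:
            if i == j:
                raise ValueError(f"self-loop at node {i}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                raise ValueError(f"edge ({i},{j}) out of range")
            if n < 0 or l <= 0:
                raise ValueError(f"edge ({i},{j}) needs n >= 0 and l > 0")
        self.edges = edges
        self.labels = (
            [str(x) for x in labels]
            if labels is not None
            else [str(i) for i in range(self.n_nodes)]
        )
        if len(self.labels) != self.n_nodes:
            raise ValueError("labels length must equal node count")
        self.coords = None if coords is None else np.asarray(coords, dtype=float)
        self.node_ids = list(node_ids) if node_ids is not None else list(range(self.n_nodes))
        self._W = None
        self._A = None

    # -- derived matrices (built lazily, cached) ---------------------------

    def _build(self, power: int) -> sp.csr_matrix:
        if not self.edges:
            return sp.csr_matrix((self.n_nodes, self.n_nodes))
        i, j, n, l = map(np.asarray, zip(*self.edges))
        w = n / l**power
        M = sp.coo_matrix(
            (np.concatenate([w, w]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return M.tocsr()

    @property
    def weight_matrix(self) -> sp.csr_matrix:
        """Weighted adjacency W with W_ij = n_ij / l_ij**2."""
        if self._W is None:
            self._W = self._build(2)
        return self._W

    @property
    def damage_adjacency(self) -> sp.csr_matrix:
        """Damage adjacency A with A_ij = n_ij / l_ij."""
        if self._A is None:
            self._A = self._build(1)
        return self._A

    @property
    def degree_matrix(self) -> sp.dia_matrix:
        """Diagonal weighted degree Dg_ii = sum_j W_ij."""
        return sp.diags(np.asarray(self.weight_matrix.sum(axis=1)).ravel())

    def laplacian(self, rho: float | np.ndarray = 1.0) -> sp.csr_matrix:
        """Weighted graph Laplacian L = rho * (Dg - W).

        ``rho`` may be a scalar effective diffusivity or a per-node vector
        (regionally varying diffusivity scales the corresponding rows).
        """
        L0 = (self.degree_matrix - self.weight_matrix).tocsr()
        rho = np.asarray(rho, dtype=float)
        if rho.ndim == 0:
            return float(rho) * L0
        if rho.shape != (self.n_nodes,):
            raise ValueError("per-node rho must have length n_nodes")
        return sp.diags(rho) @ L0

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def nodes_matching(self, text: str) -> list[int]:
        """Indices of nodes whose region label contains ``text`` (case-insensitive)."""
        needle = text.lower()
        return [i for i, lab in enumerate(self.labels) if needle in lab.lower()]

    def connected_components(self) -> int:
        n, _ = sp.csgraph.connected_components(self.weight_matrix, directed=False)
        return n

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for i in range(self.n_nodes):
            attrs = {"label": self.labels[i]}
            if self.coords is not None:
                attrs.update(zip(("x", "y", "z"), map(float, self.coords[i])))
            g.add_node(self.node_ids[i], **attrs)
        for i, j, n, l in self.edges:
            g.add_edge(
                self.node_ids[i],
                self.node_ids[j],
                **{DEFAULT_ATTR_MAP["fiber_n"]: n, DEFAULT_ATTR_MAP["fiber_l"]: l},
            )
        return g


def laplacian(g: ConnectomeGraph, rho: float | np.ndarray = 1.0) -> sp.csr_matrix:
    """Module-level alias for :meth:`ConnectomeGraph.laplacian`."""
    if np.any(np.asarray(rho) < 0):
        raise ValueError("rho must be nonnegative")
    return g.laplacian(rho)


def cubic_lattice(nx_: int, ny: int, nz: int, spacing: float = 1.0) -> ConnectomeGraph:
    """Regular 3D cubic lattice with nearest-neighbor (6-)connectivity.

    Every edge carries unit fiber count and length ``spacing``, so the graph
    Laplacian equals the standard second-order finite-difference stencil
    with zero-flux boundaries and grid step ``spacing``.  Node labels encode
    the integer coordinates as ``"x,y,z"``.
    """
    if min(nx_, ny, nz) < 1:
        raise ValueError("lattice dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")

    def idx(x, y, z):
        return (x * ny + y) * nz + z

    n_nodes = nx_ * ny * nz
    labels, coords, edges = [], [], []
    for x in range(nx_):
        for y in range(ny):
            for z in range(nz):
                labels.append(f"{x},{y},{z}")
                coords.append((x * spacing, y * spacing, z * spacing))
                if x + 1 < nx_:
                    edges.append((idx(x, y, z), idx(x + 1, y, z), 1.0, spacing))
                if y + 1 < ny:
                    edges.append((idx(x, y, z), idx(x, y + 1, z), 1.0, spacing))
                if z + 1 < nz:
                    edges.append((idx(x, y, z), idx(x, y, z + 1), 1.0, spacing))
    return ConnectomeGraph(n_nodes, edges, labels=labels, coords=np.array(coords))


def _first_key(attrs: dict, candidates) -> str | None:
    for k in candidates:
        if k in attrs:
            return k
    return None


def load_graphml(path, attr_map: dict | None = None) -> ConnectomeGraph:
    """Load a connectome from GraphML.

    ``attr_map`` maps the logical edge attributes ``fiber_n`` and
    ``fiber_l`` to the attribute names used in the file (defaults:
    braingraph.org-style ``number_of_fibers`` / ``fiber_length_mean``).
    Directed edges are symmetrized and duplicate/antiparallel edges merged
    by summing fiber counts and averaging lengths (logged).  A disconnected
    graph is a warning, not an error.
    """
    amap = dict(DEFAULT_ATTR_MAP)
    if attr_map:
        amap.update(attr_map)
    g = nx.read_graphml(path)
    if g.is_directed():
        logger.info("directed GraphML input: symmetrizing edges by summation")
    nodes = list(g.nodes())
    index = {nid: i for i, nid in enumerate(nodes)}

    labels = []
    coords = []
    have_coords = True
    for nid in nodes:
        attrs = g.nodes[nid]
        lk = _first_key(attrs, _LABEL_KEYS)
        labels.append(str(attrs[lk]) if lk else str(nid))
        got = None
        for keys in _COORD_KEYS:
            if all(k in attrs for k in keys):
                got = tuple(float(attrs[k]) for k in keys)
                break
        if got is None:
            have_coords = False
        coords.append(got)

    merged: dict[tuple[int, int], tuple[float, float, int]] = {}
    n_dupes = 0
    for a, b, attrs in g.edges(data=True):
        if a == b:
            logger.info("dropping self-loop at node %r", a)
            continue
        for logical in ("fiber_n", "fiber_l"):
            if amap[logical] not in attrs:
                raise KeyError(
                    f"edge attribute {amap[logical]!r} (for {logical}) missing "
                    f"on edge ({a!r}, {b!r})"
                )
        i, j = sorted((index[a], index[b]))
        n = float(attrs[amap["fiber_n"]])
        l = float(attrs[amap["fiber_l"]])
        if (i, j) in merged:
            n_prev, l_prev, cnt = merged[(i, j)]
            merged[(i, j)] = (n_prev + n, l_prev + l, cnt + 1)
            n_dupes += 1
        else:
            merged[(i, j)] = (n, l, 1)
    if n_dupes:
        logger.info(
            "merged %d duplicate/antiparallel edges (fiber counts summed, "
            "lengths averaged)", n_dupes,
        )
    edges = [(i, j, n, l / cnt) for (i, j), (n, l, cnt) in merged.items()]
    cg = ConnectomeGraph(
        len(nodes),
        edges,
        labels=labels,
        coords=np.array(coords) if have_coords and coords else None,
        node_ids=nodes,
    )
    if cg.n_edges and cg.connected_components() > 1:
        logger.warning("graph is disconnected (%d components)", cg.connected_components())
    return cg


def save_graphml(g: ConnectomeGraph, path) -> None:
    """Write standard GraphML re-loadable by :func:`load_graphml`."""
    if g.n_edges == 0:
        logger.warning("saving graph with no edges")
    nx.write_graphml(g.to_networkx(), path)
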