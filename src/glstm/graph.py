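"""Per-tile graphs: venues as nodes, case food-access categories as hyperedges.

Within one map tile and one week, every diagnosed case contributes one
hyperedge per category it visited that week; the hyperedge spans all venues
of that category in the tile.  The binary adjacency used by the spectral
convolution is the clique expansion of those hyperedges.  Hyperedge
representations are built by multi-head attention over member venues and
written back onto the member nodes.

The attention/aggregation math is written against the dual-mode helpers in
:mod:`glstm.autograd`, so the same code path serves numpy inference and
gradient-tracked training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, as_array, leaky_relu, softmax
from .dataio import CATEGORIES, CaseProfile, TileID
from .splice import PoiFeatureVector


@dataclass
class CaseEdge:
    """One case-category hyperedge over the venues of that category."""

    case_id: str
    category: str
    member_pois: tuple[int, ...]
    representation: np.ndarray | None = None

    def __post_init__(self):
        if len(self.member_pois) < 1:
            raise ValueError("a case edge needs at least one member POI")


@dataclass
class TileGraph:
    """Node features, clique-expanded adjacency, and case edges of one tile."""

    tile: TileID | None
    node_ids: list[str]
    X: np.ndarray
    A: np.ndarray
    edges: list[CaseEdge] = field(default_factory=list)

    @property
    def degrees(self) -> np.ndarray:
        """Degree vector of A + I (always >= 1 thanks to the self-loop)."""
        return 1.0 + self.A.sum(axis=1)

    def validate(self) -> None:
        n = len(self.node_ids)
        if self.A.shape != (n, n):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(self.A, self.A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.A) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        for e in self.edges:
            if any(not (0 <= i < n) for i in e.member_pois):
                raise ValueError(f"edge {e.case_id}/{e.category}: member out of range")


@dataclass
class AttentionParams:
    """Multi-head attention weights for hyperedge aggregation.

    ``W_c`` maps member features into the shared edge space; each of the
    ``K`` heads owns a node projection ``W[k]`` and scoring vector ``b[k]``
    over the concatenated ``[W_c c ; W p]``.
    """

    K: int
    W_c: np.ndarray | Tensor
    W: list
    b: list
    leaky_slope: float = 0.2

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("need at least one attention head")
        if len(self.W) != self.K or len(self.b) != self.K:
            raise ValueError("one W and b per head required")

    @classmethod
    def init(cls, dim: int, K: int = 1, rng: np.random.Generator | None = None,
             leaky_slope: float = 0.2) -> "AttentionParams":
        rng = rng or np.random.default_rng(0)
        lim = 1.0 / np.sqrt(dim)
        return cls(
            K=K,
            W_c=rng.uniform(-lim, lim, (dim, dim)),
            W=[rng.uniform(-lim, lim, (dim, dim)) for _ in range(K)],
            b=[rng.uniform(-lim, lim, 2 * dim) for _ in range(K)],
            leaky_slope=leaky_slope,
        )


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_tile_graph(
    features: list[PoiFeatureVector],
    cases: list[CaseProfile],
    week: int,
    tile: TileID | None = None,
) -> TileGraph:
    """Construct the week-``week`` graph of one tile.

    Nodes are the tile's venues in ``poi_id`` order, with feature rows taken
    at the given week.  For every case and every category that case visited
    that week, a hyperedge spans the tile's venues of that category; the
    adjacency connects every venue pair sharing at least one hyperedge.
    """
    if not features:
        raise ValueError("cannot build a graph for an empty tile")
    feats = sorted(features, key=lambda f: f.poi_id)
    node_ids = [f.poi_id for f in feats]
    X = np.stack([f.node_features(week) for f in feats])
    members_by_cat: dict[str, tuple[int, ...]] = {}
    for j, cat in enumerate(CATEGORIES):
        members = tuple(i for i, f in enumerate(feats) if f.category_onehot[j] > 0)
        if members:
            members_by_cat[cat] = members
    n = len(feats)
    A = np.zeros((n, n))
    edges: list[CaseEdge] = []
    for case in sorted(cases, key=lambda c: c.case_id):
        case.validate()
        for cat in CATEGORIES:
            if case.count(cat, week) <= 0:
                continue
            members = members_by_cat.get(cat)
            if members is None:
                continue  # no venue of that category in this tile
            edges.append(CaseEdge(case.case_id, cat, members))
            idx = np.array(members)
            A[np.ix_(idx, idx)] = 1.0
    np.fill_diagonal(A, 0.0)
    g = TileGraph(tile=tile, node_ids=node_ids, X=X, A=A, edges=edges)
    g.validate()
    return g


# ---------------------------------------------------------------------------
# attention aggregation (dual-mode: ndarray or Tensor)
# ---------------------------------------------------------------------------

def _head_alpha(P, c_rep, W_c, W_k, b_k, slope: float):
    """Attention coefficients of one head over member features ``P`` (m, d)."""
    d = as_array(P).shape[1]
    u = W_c @ c_rep                      # (d,)
    top = b_k[:d] @ u                    # scalar, shared by all members
    bottom = (P @ W_k.T) @ b_k[d:]       # (m,)
    return softmax(leaky_relu(bottom + top, slope), axis=-1)


def edge_representation(P, params: AttentionParams):
    """Eq-style hyperedge vector: mean over heads of attention-weighted W_c p.

    The attention score needs the edge vector and vice versa; the cycle is
    resolved in a single pass by seeding the edge vector with the unweighted
    mean of member features.
    """
    c0 = P.mean(axis=0)
    proj = P @ params.W_c.T              # (m, d)
    acc = None
    for k in range(params.K):
        alpha = _head_alpha(P, c0, params.W_c, params.W[k], params.b[k], params.leaky_slope)
        contrib = alpha @ proj           # (d,)
        acc = contrib if acc is None else acc + contrib
    return acc / float(params.K)


def edge_attention(edge: CaseEdge, graph: TileGraph, params: AttentionParams) -> np.ndarray:
    """Per-head attention coefficients over the edge's members, shape (K, m).

    Coefficients of every head are strictly positive and sum to one.  If the
    edge carries no precomputed representation, the unweighted member mean is
    used to seed the score.
    """
    P = graph.X[np.array(edge.member_pois)]
    c_rep = edge.representation if edge.representation is not None else P.mean(axis=0)
    rows = [
        _head_alpha(P, c_rep, params.W_c, params.W[k], params.b[k], params.leaky_slope)
        for k in range(params.K)
    ]
    return np.stack(rows)


def aggregate_features(X, edge_groups, params: AttentionParams):
    """Attention-aggregate hyperedges and write them back onto member nodes.

    ``edge_groups`` is a list of ``(member_index_array, multiplicity)`` pairs
    (duplicate case edges over the same member set collapse into one group
    with multiplicity equal to the case count).  Each node receives the mean
    of its incident edge representations, added to its feature row; nodes on
    no edge are unchanged.  Works on ndarrays or autograd Tensors.
    """
    n, d = as_array(X).shape
    counts = np.zeros(n)
    acc = None
    reps = []
    for members, mult in edge_groups:
        idx = np.asarray(members, dtype=int)
        P = X[idx]
        c_e = edge_representation(P, params)
        reps.append(c_e)
        ind = np.zeros((n, 1))
        ind[idx, 0] = float(mult)
        term = c_e.reshape(1, d) * ind if isinstance(c_e, Tensor) else ind * as_array(c_e).reshape(1, d)
        acc = term if acc is None else acc + term
        counts[idx] += mult
    if acc is None:
        return X
    inv = np.zeros((n, 1))
    nz = counts > 0
    inv[nz, 0] = 1.0 / counts[nz]
    return X + acc * inv


def aggregate_case_edges(graph: TileGraph, params: AttentionParams) -> np.ndarray:
    """Updated node feature matrix after hyperedge aggregation.

    Also stores each edge's computed representation on the :class:`CaseEdge`.
    Duplicate case edges spanning the same member set carry identical
    representations, so the write-back mean weights each member set by its
    case multiplicity.
    """
    if not graph.edges:
        raise ValueError("graph has no case edges to aggregate")
    groups: dict[tuple[int, ...], int] = {}
    for e in graph.edges:
        groups[e.member_pois] = groups.get(e.member_pois, 0) + 1
    edge_groups = [(np.array(m), mult) for m, mult in sorted(groups.items())]
    rep_by_members = {
        tuple(m): as_array(edge_representation(graph.X[m], params))
        for m, _ in edge_groups
    }
    for e in graph.edges:
        e.representation = rep_by_members[e.member_pois]
    return as_array(aggregate_features(graph.X, edge_groups, params))
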