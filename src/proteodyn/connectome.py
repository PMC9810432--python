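"""Brain connectome: container, I/O, synthetic generator and derived matrices.

The connectome is an undirected, connected, weighted graph.  Nodes are brain
regions labelled by name, lobe and hemisphere; each edge carries the mean
number of axonal fibres ``n_ij`` (dimensionless, > 0) and their mean length
``l_ij`` (cm, > 0).  The initial coupling weight used by both the slow
protein-spreading dynamics and the fast oscillator dynamics is
``w_ij(0) = n_ij / l_ij``.

Axonal transmission delays are ``tau_ij = l_ij / v_ax`` with ``v_ax`` the
axonal conduction speed; for the delay-differential oscillator network they
are quantized to a small number of distinct levels.

Because the tractography-derived reference connectome is not redistributable,
:func:`generate_synthetic_connectome` builds a structurally analogous network:
bilateral mirror-paired cortical/subcortical regions covering all seven lobe
labels, a single midline brain-stem node, the named disease seed regions
(bilateral entorhinal cortex for tau; six bilateral neocortical/limbic pairs,
i.e. 12 nodes, for amyloid-beta), and randomly placed edges with plausible
fibre counts and lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, ParameterError, ValidationError

LOBES = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "limbic",
    "subcortical",
    "brain-stem",
)
HEMISPHERES = ("left", "right", "midline")

BRAIN_STEM_LOBE = "brain-stem"

#: Regions seeded with toxic tau (both hemispheres).
TAU_SEED_REGIONS = ("entorhinal",)

#: Regions seeded with toxic amyloid-beta (both hemispheres -> 12 nodes).
#: Five pairs are the classic early-amyloid regions; "superior frontal" is the
#: extra neocortical pair that brings the seed count to the canonical 12.
AMYLOID_SEED_REGIONS = (
    "precuneus",
    "isthmus cingulate",
    "insula",
    "medial orbitofrontal",
    "lateral orbitofrontal",
    "superior frontal",
)

# Bilateral (name, lobe) pairs used by the synthetic generator: disease seed
# regions first, then a fill catalogue ordered so every lobe label appears
# even in small networks.
_SEED_PAIRS = (
    ("entorhinal", "limbic"),
    ("precuneus", "parietal"),
    ("isthmus cingulate", "limbic"),
    ("insula", "temporal"),
    ("medial orbitofrontal", "frontal"),
    ("lateral orbitofrontal", "frontal"),
    ("superior frontal", "frontal"),
)
_FILL_PAIRS = (
    ("lateral occipital", "occipital"),
    ("thalamus", "subcortical"),
    ("superior parietal", "parietal"),
    ("middle temporal", "temporal"),
    ("posterior cingulate", "limbic"),
    ("rostral middle frontal", "frontal"),
    ("cuneus", "occipital"),
    ("hippocampus", "subcortical"),
    ("inferior parietal", "parietal"),
    ("superior temporal", "temporal"),
    ("caudal anterior cingulate", "limbic"),
    ("caudal middle frontal", "frontal"),
    ("lingual", "occipital"),
    ("putamen", "subcortical"),
    ("supramarginal", "parietal"),
    ("inferior temporal", "temporal"),
    ("parahippocampal", "limbic"),
    ("pars opercularis", "frontal"),
    ("pericalcarine", "occipital"),
    ("caudate", "subcortical"),
    ("postcentral", "parietal"),
    ("fusiform", "temporal"),
    ("rostral anterior cingulate", "limbic"),
    ("pars triangularis", "frontal"),
    ("precentral", "frontal"),
    ("amygdala", "subcortical"),
    ("paracentral", "parietal"),
    ("transverse temporal", "temporal"),
    ("frontal pole", "frontal"),
    ("pallidum", "subcortical"),
    ("banks superior temporal", "temporal"),
    ("pars orbitalis", "frontal"),
    ("temporal pole", "temporal"),
    ("accumbens", "subcortical"),
)

NODE_COLUMNS = ("index", "name", "lobe", "hemisphere")
EDGE_COLUMNS = ("i", "j", "n_fibres", "length_cm")


@dataclass(frozen=True)
class RegionNode:
    """A brain region: 0-based index, name, lobe and hemisphere labels."""

    index: int
    name: str
    lobe: str
    hemisphere: str

    def __post_init__(self) -> None:
        if self.lobe not in LOBES:
            raise ValidationError(f"unknown lobe label {self.lobe!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere label {self.hemisphere!r}")


class Connectome:
    """Undirected, connected, weighted brain network.

    Edges are stored once with ``i < j``; fibre counts and lengths are
    strictly positive.  Construction validates all invariants.
    """

    def __init__(
        self,
        nodes: Sequence[RegionNode],
        edge_i: Iterable[int],
        edge_j: Iterable[int],
        n_fibres: Iterable[float],
        length_cm: Iterable[float],
    ) -> None:
        self.nodes = tuple(nodes)
        n = len(self.nodes)
        if n == 0:
            raise ValidationError("connectome needs at least one node")
        if tuple(nd.index for nd in self.nodes) != tuple(range(n)):
            raise ValidationError("node indices must be 0..n-1 in order")

        i = np.asarray(list(edge_i), dtype=np.int64)
        j = np.asarray(list(edge_j), dtype=np.int64)
        nf = np.asarray(list(n_fibres), dtype=float)
        lc = np.asarray(list(length_cm), dtype=float)
        if not (i.shape == j.shape == nf.shape == lc.shape):
            raise ValidationError("edge arrays must have equal length")
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise ValidationError("edge endpoint out of range")
        if np.any(i == j):
            raise ValidationError("self-loops are not allowed")
        if np.any(nf <= 0):
            raise ValidationError("fibre counts must be positive")
        if np.any(lc <= 0):
            raise ValidationError("fibre lengths must be positive")

        # canonical storage: i < j, sorted lexicographically
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        order = np.lexsort((hi, lo))
        self.edge_i = lo[order]
        self.edge_j = hi[order]
        self.n_fibres = nf[order]
        self.length_cm = lc[order]

        keys = self.edge_i * n + self.edge_j
        if np.unique(keys).size != keys.size:
            raise ValidationError("duplicate (or reversed duplicate) edges")

        if n > 1:
            adj = coo_matrix(
                (np.ones(self.edge_i.size), (self.edge_i, self.edge_j)), shape=(n, n)
            )
            n_comp, _ = connected_components(adj, directed=False)
            if n_comp != 1:
                raise ValidationError(f"graph is disconnected ({n_comp} components)")

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.edge_i.size)

    @property
    def lobes(self) -> np.ndarray:
        return np.array([nd.lobe for nd in self.nodes])

    def seed_indices(self, region_names: Iterable[str]) -> np.ndarray:
        """Node indices whose region name is in ``region_names`` (all hemispheres)."""
        wanted = set(region_names)
        return np.array(
            [nd.index for nd in self.nodes if nd.name in wanted], dtype=np.int64
        )

    # -- tables and I/O ---------------------------------------------------
    def node_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": [nd.index for nd in self.nodes],
                "name": [nd.name for nd in self.nodes],
                "lobe": [nd.lobe for nd in self.nodes],
                "hemisphere": [nd.hemisphere for nd in self.nodes],
            }
        )

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": self.edge_i,
                "j": self.edge_j,
                "n_fibres": self.n_fibres,
                "length_cm": self.length_cm,
            }
        )

    def write(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>_nodes.csv`` and ``<prefix>_edges.csv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        node_path = prefix.with_name(prefix.name + "_nodes.csv")
        edge_path = prefix.with_name(prefix.name + "_edges.csv")
        self.node_table().to_csv(node_path, index=False)
        # %.17g guarantees bit-exact float round-trips through CSV
        self.edge_table().to_csv(edge_path, index=False, float_format="%.17g")
        return node_path, edge_path

    def to_graphml(self, path: str | Path) -> None:
        import networkx as nx

        g = nx.Graph()
        for nd in self.nodes:
            g.add_node(nd.index, name=nd.name, lobe=nd.lobe, hemisphere=nd.hemisphere)
        for i, j, nf, lc in zip(
            self.edge_i, self.edge_j, self.n_fibres, self.length_cm
        ):
            g.add_edge(int(i), int(j), n_fibres=float(nf), length_cm=float(lc))
        nx.write_graphml(g, str(path))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Connectome):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and np.array_equal(self.edge_i, other.edge_i)
            and np.array_equal(self.edge_j, other.edge_j)
            and np.array_equal(self.n_fibres, other.n_fibres)
            and np.array_equal(self.length_cm, other.length_cm)
        )


def load_connectome(
    node_table: str | Path | pd.DataFrame, edge_table: str | Path | pd.DataFrame
) -> Connectome:
    """Build a validated :class:`Connectome` from node/edge CSV tables.

    Node columns: ``index,name,lobe,hemisphere``; edge columns:
    ``i,j,n_fibres,length_cm``.  Edge rows may use either endpoint order but
    duplicates (including reversed duplicates) are rejected.
    """
    nodes_df = node_table if isinstance(node_table, pd.DataFrame) else pd.read_csv(node_table)
    if not isinstance(edge_table, pd.DataFrame):
        # round_trip parsing keeps written floats bit-exact
        edge_table = pd.read_csv(edge_table, float_precision="round_trip")
    edges_df = edge_table

    missing = set(NODE_COLUMNS) - set(nodes_df.columns)
    if missing:
        raise FormatError(f"node table missing columns: {sorted(missing)}")
    missing = set(EDGE_COLUMNS) - set(edges_df.columns)
    if missing:
        raise FormatError(f"edge table missing columns: {sorted(missing)}")

    nodes_df = nodes_df.sort_values("index")
    nodes = [
        RegionNode(int(r["index"]), str(r["name"]), str(r["lobe"]), str(r["hemisphere"]))
        for _, r in nodes_df.iterrows()
    ]
    return Connectome(
        nodes,
        edges_df["i"].to_numpy(),
        edges_df["j"].to_numpy(),
        edges_df["n_fibres"].to_numpy(),
        edges_df["length_cm"].to_numpy(),
    )


def weight_matrix(c: Connectome) -> np.ndarray:
    """Initial connectivity weights ``w_ij = n_ij / l_ij`` (symmetric, zero diag)."""
    w = np.zeros((c.n_nodes, c.n_nodes))
    vals = c.n_fibres / c.length_cm
    w[c.edge_i, c.edge_j] = vals
    w[c.edge_j, c.edge_i] = vals
    return w


def graph_laplacian(w: np.ndarray) -> np.ndarray:
    """Graph Laplacian ``L = diag(W 1) - W``; rows sum to zero.

    Raises :class:`ValidationError` for an asymmetric input.
    """
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    if not np.allclose(w, w.T, rtol=0.0, atol=1e-12 * max(1.0, np.abs(w).max())):
        raise ValidationError("weight matrix must be symmetric")
    return np.diag(w.sum(axis=1)) - w


def delay_matrix(c: Connectome, v_ax: float, n_levels: int) -> np.ndarray:
    """Axonal delays ``tau_ij = l_ij / v_ax`` (s), quantized to ``n_levels``.

    Raw edge delays are binned into ``n_levels`` uniform-width bins over
    [min, max] and mapped to bin midpoints, so the quantization error is at
    most half a bin width; zero entries mark absent edges.
    """
    if v_ax <= 0:
        raise ParameterError("axonal speed v_ax must be positive")
    if n_levels < 1:
        raise ParameterError("n_levels must be >= 1")
    raw = c.length_cm / v_ax
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        quant = np.full_like(raw, lo)
    else:
        width = (hi - lo) / n_levels
        idx = np.minimum(((raw - lo) / width).astype(int), n_levels - 1)
        quant = lo + (idx + 0.5) * width
    tau = np.zeros((c.n_nodes, c.n_nodes))
    tau[c.edge_i, c.edge_j] = quant
    tau[c.edge_j, c.edge_i] = quant
    return tau


def _region_pairs(n_pairs: int) -> list[tuple[str, str]]:
    pairs = list(_SEED_PAIRS)
    if n_pairs < len(pairs):
        raise ParameterError(
            f"need at least {2 * len(_SEED_PAIRS) + 2 + 1} nodes to place all "
            "seed regions and lobe labels"
        )
    catalogue = list(_FILL_PAIRS)
    k = 0
    while len(pairs) < n_pairs:
        base_name, lobe = catalogue[k % len(catalogue)]
        rep = k // len(catalogue)
        name = base_name if rep == 0 else f"{base_name} {rep + 1}"
        pairs.append((name, lobe))
        k += 1
    return pairs[:n_pairs]


def generate_synthetic_connectome(
    n_nodes: int = 83, n_edges: int = 579, rng_seed: int = 0
) -> Connectome:
    """Generate a reproducible synthetic brain network.

    Layout: ``(n_nodes - 1) // 2`` mirror-paired left/right regions, one
    midline brain-stem node (plus one midline subcortical node when
    ``n_nodes`` is even).  The first pairs are the disease seed regions;
    the fill catalogue guarantees every lobe label is present.  Topology is
    a uniform random spanning tree plus uniformly sampled extra edges; edge
    lengths are Uniform(1, 17) cm and fibre counts LogNormal(1.0, 0.6), which
    puts typical weights n/l on the O(0.1-1) scale commensurate with the
    axonal-decay rate gamma: tau-driven degradation can sever a typical edge
    within the 30-year disease horizon, as the reference tractography network
    evidently allows.
    """
    if n_edges < n_nodes - 1:
        raise ParameterError("n_edges must be at least n_nodes - 1 (connectivity)")
    if n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ParameterError("n_edges exceeds the number of possible pairs")

    rng = np.random.default_rng(rng_seed)
    n_midline = 1 if (n_nodes - 1) % 2 == 0 else 2
    n_pairs = (n_nodes - n_midline) // 2

    nodes: list[RegionNode] = []
    for name, lobe in _region_pairs(n_pairs):
        for hemi in ("left", "right"):
            nodes.append(RegionNode(len(nodes), name, lobe, hemi))
    nodes.append(RegionNode(len(nodes), "brain-stem", BRAIN_STEM_LOBE, "midline"))
    if n_midline == 2:
        nodes.append(RegionNode(len(nodes), "midline thalamus", "subcortical", "midline"))

    # random spanning tree: attach each node (in random order) to an earlier one
    perm = rng.permutation(n_nodes)
    tree = [(int(perm[k]), int(perm[rng.integers(0, k)])) for k in range(1, n_nodes)]
    taken = {(min(a, b), max(a, b)) for a, b in tree}
    iu, ju = np.triu_indices(n_nodes, k=1)
    pool = [
        (int(a), int(b)) for a, b in zip(iu, ju) if (int(a), int(b)) not in taken
    ]
    extra_idx = rng.choice(len(pool), size=n_edges - len(tree), replace=False)
    edges = sorted(taken) + [pool[k] for k in sorted(extra_idx)]

    ei = np.array([e[0] for e in edges])
    ej = np.array([e[1] for e in edges])
    lengths = rng.uniform(1.0, 17.0, size=len(edges))
    fibres = rng.lognormal(mean=1.0, sigma=0.6, size=len(edges))
    return Connectome(nodes, ei, ej, fibres, lengths)
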