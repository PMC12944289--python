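"""Electrode graph construction.

Electrodes are nodes positioned at their 3-D scalp coordinates (10-20
system, normalized to the unit sphere).  Pairwise closeness is encoded by
a Gaussian kernel of the Euclidean distance, beta_ij = exp(-d_ij^2/tau^2),
which serves both as an additive bias on graph-attention logits and as
the ranking used to keep only the strongest fraction of edges (top 20%
by default).  Self-loops are always added at aggregation time so every
node has a non-empty neighborhood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectrodeLayout",
    "GraphSpec",
    "builtin_layout",
    "load_layout",
    "gaussian_bias",
    "median_distance",
    "select_edges",
    "build_graph",
    "DEAP32_CHANNELS",
]

#: Channel order of the 32 EEG channels in DEAP's preprocessed containers.
DEAP32_CHANNELS = [
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "Cz",
    "C4", "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2",
]


@dataclass
class ElectrodeLayout:
    """Named electrodes with 3-D unit-sphere coordinates."""

    channel_names: list[str]
    coords: np.ndarray  # [n, 3]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        n = len(self.channel_names)
        if len(set(self.channel_names)) != n:
            raise ValueError("duplicate channel names")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords must be [{n}, 3]")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if n < 2:
            raise ValueError("a layout needs at least 2 electrodes")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def subset(self, keep) -> "ElectrodeLayout":
        keep = np.asarray(keep)
        return ElectrodeLayout(
            [self.channel_names[i] for i in keep], self.coords[keep]
        )


@dataclass
class GraphSpec:
    """Distance-bias matrix plus the retained undirected edge set."""

    bias: np.ndarray  # [n, n], symmetric, unit diagonal
    tau: float
    edges: frozenset  # of (i, j) with i < j
    edge_fraction: float = 0.2
    self_loops: bool = True
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_nodes(self) -> int:
        return self.bias.shape[0]

    def adjacency_mask(self) -> np.ndarray:
        """Boolean [n, n] neighborhood mask (both directions, plus self-loops)."""
        n = self.n_nodes
        mask = np.zeros((n, n), dtype=bool)
        for i, j in self.edges:
            mask[i, j] = mask[j, i] = True
        if self.self_loops:
            np.fill_diagonal(mask, True)
        return mask

    def subgraph(self, keep) -> "GraphSpec":
        """Induced subgraph on the retained node indices (renumbered)."""
        keep = list(np.asarray(keep))
        remap = {old: new for new, old in enumerate(keep)}
        kept_edges = frozenset(
            (min(remap[i], remap[j]), max(remap[i], remap[j]))
            for i, j in self.edges
            if i in remap and j in remap
        )
        return GraphSpec(
            bias=self.bias[np.ix_(keep, keep)],
            tau=self.tau,
            edges=kept_edges,
            edge_fraction=self.edge_fraction,
            self_loops=self.self_loops,
            channel_names=[self.channel_names[i] for i in keep]
            if self.channel_names
            else [],
        )


def builtin_layout(name: str) -> ElectrodeLayout:
    """Return a shipped montage by name.

    ``"deap32"``: the 32-channel Biosemi cap in DEAP channel order, with
    standard 10-20 positions projected onto the unit sphere (via mne).
    """
    available = ["deap32"]
    if name != "deap32":
        raise ValueError(f"unknown layout {name!r}; available: {available}")
    import mne

    montage = mne.channels.make_standard_montage("biosemi32")
    pos = montage.get_positions()["ch_pos"]
    coords = np.array([pos[ch] for ch in DEAP32_CHANNELS])
    coords = coords / np.linalg.norm(coords, axis=1, keepdims=True)
    return ElectrodeLayout(list(DEAP32_CHANNELS), coords)


def load_layout(path) -> ElectrodeLayout:
    """Read a plain-text montage: one `name x y z` row per electrode."""
    names, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"bad montage row: {line!r}")
            names.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    return ElectrodeLayout(names, np.array(rows))


def median_distance(layout: ElectrodeLayout) -> float:
    """Median pairwise Euclidean distance (the default kernel scale tau)."""
    d = np.linalg.norm(layout.coords[:, None] - layout.coords[None], axis=-1)
    iu = np.triu_indices(layout.n_channels, k=1)
    return float(np.median(d[iu]))


def gaussian_bias(layout: ElectrodeLayout, tau: float) -> np.ndarray:
    """beta_ij = exp(-d_ij^2 / tau^2); symmetric with unit diagonal."""
    if not tau > 0:
        raise ValueError("tau must be positive")
    diff = layout.coords[:, None] - layout.coords[None]
    d2 = np.sum(diff * diff, axis=-1)
    return np.exp(-d2 / tau**2)


def _round_half_even(x: float) -> int:
    return int(np.rint(x))


def select_edges(bias: np.ndarray, edge_fraction: float = 0.2) -> frozenset:
    """Keep the strongest fraction of the n(n-1)/2 unordered pairs.

    Pairs are ranked by bias descending; the kept count is
    round(edge_fraction * n(n-1)/2) with round-half-to-even, floored at 1.
    Ties are broken toward the lexicographically smaller (i, j), so the
    result is deterministic.
    """
    bias = np.asarray(bias)
    n = bias.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    if not (0.0 < edge_fraction <= 1.0):
        raise ValueError("edge_fraction must be in (0, 1]")
    iu, ju = np.triu_indices(n, k=1)
    vals = bias[iu, ju]
    k = max(1, _round_half_even(edge_fraction * len(vals)))
    order = sorted(range(len(vals)), key=lambda t: (-vals[t], iu[t], ju[t]))
    return frozenset((int(iu[t]), int(ju[t])) for t in order[:k])


def build_graph(
    layout: ElectrodeLayout,
    tau: float | None = None,
    edge_fraction: float = 0.2,
    self_loops: bool = True,
) -> GraphSpec:
    """Layout -> GraphSpec with the default tau = median pairwise distance."""
    if tau is None:
        tau = median_distance(layout)
    bias = gaussian_bias(layout, tau)
    edges = select_edges(bias, edge_fraction)
    return GraphSpec(
        bias=bias,
        tau=float(tau),
        edges=edges,
        edge_fraction=edge_fraction,
        self_loops=self_loops,
        channel_names=list(layout.channel_names),
    )
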