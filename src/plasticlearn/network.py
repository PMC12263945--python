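"""Plastic neural graph: neurons, synapses, activation dynamics, and I/O.

The network is a directed weighted graph N = (V, E).  Each neuron carries a
bias, a planar position in the unit square (positions exist solely to define
the inter-neuronal distance used by structural rewiring), and a scalar
activation.  Each ordered pair of distinct neurons may carry at most one
synapse with a nonnegative weight.

Internally the graph is stored densely: an ``(n, n)`` weight matrix indexed
``[pre, post]`` together with a boolean adjacency mask.  Entries outside the
mask are always zero, so matrix expressions over the full arrays are sums
over existing synapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.special import expit

__all__ = [
    "Neuron",
    "Synapse",
    "PlasticNetwork",
    "ACTIVATION_FUNCTIONS",
    "build_network",
    "activate",
    "write_network",
    "read_network",
    "to_graphml",
]

#: Named activation nonlinearities σ accepted by :func:`activate`.
ACTIVATION_FUNCTIONS = {
    "logistic": expit,
    "tanh": np.tanh,
    "identity": lambda x: x,
    "relu": lambda x: np.maximum(x, 0.0),
}


@dataclass(frozen=True)
class Neuron:
    """A single node: integer id, intrinsic bias, planar position, activation."""

    id: int
    bias: float
    position: tuple[float, float]
    activation: float


@dataclass(frozen=True)
class Synapse:
    """A directed connection ``pre -> post`` with a nonnegative weight.

    ``last_update_drive`` records the most recent plasticity drive F applied
    to this synapse (diagnostic; 0 before any weight update).
    """

    pre: int
    post: int
    weight: float
    last_update_drive: float = 0.0


class PlasticNetwork:
    """Directed weighted neural graph with dense weight/adjacency storage.

    Parameters
    ----------
    positions : (n, 2) array of neuron coordinates in the unit square.
    biases : (n,) array of intrinsic biases.
    weights : (n, n) array, ``weights[pre, post]``; zero off the mask.
    mask : (n, n) boolean adjacency, diagonal always False.
    time : simulation time t >= 0.
    """

    def __init__(
        self,
        positions: np.ndarray,
        biases: np.ndarray,
        weights: np.ndarray,
        mask: np.ndarray,
        activations: np.ndarray | None = None,
        time: float = 0.0,
    ):
        positions = np.asarray(positions, dtype=float)
        n = positions.shape[0]
        if positions.shape != (n, 2):
            raise ValueError("positions must have shape (n, 2)")
        if not np.all(np.isfinite(positions)):
            raise ValueError("positions must be finite")
        if np.any(positions < 0.0) or np.any(positions > 1.0):
            raise ValueError("positions must lie in the unit square")
        self.positions = positions
        self.biases = np.asarray(biases, dtype=float).copy()
        if self.biases.shape != (n,):
            raise ValueError("biases must have shape (n,)")
        self.weights = np.asarray(weights, dtype=float).copy()
        self.mask = np.asarray(mask, dtype=bool).copy()
        if self.weights.shape != (n, n) or self.mask.shape != (n, n):
            raise ValueError("weights and mask must have shape (n, n)")
        if np.any(np.diag(self.mask)):
            raise ValueError("self-loops are not allowed")
        self.weights[~self.mask] = 0.0
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if activations is None:
            activations = np.zeros(n)
        self.activations = np.asarray(activations, dtype=float).copy()
        if self.activations.shape != (n,):
            raise ValueError("activations must have shape (n,)")
        if time < 0:
            raise ValueError("time must be nonnegative")
        self.time = float(time)
        # Diagnostic record of the most recent plasticity drive per synapse.
        self.last_drive = np.zeros((n, n))

    # ------------------------------------------------------------------ views

    @property
    def n_neurons(self) -> int:
        return self.positions.shape[0]

    @property
    def n_synapses(self) -> int:
        return int(self.mask.sum())

    @property
    def neurons(self) -> list[Neuron]:
        return [
            Neuron(
                id=i,
                bias=float(self.biases[i]),
                position=(float(self.positions[i, 0]), float(self.positions[i, 1])),
                activation=float(self.activations[i]),
            )
            for i in range(self.n_neurons)
        ]

    @property
    def synapses(self) -> list[Synapse]:
        pre, post = np.nonzero(self.mask)
        return [
            Synapse(
                pre=int(i),
                post=int(j),
                weight=float(self.weights[i, j]),
                last_update_drive=float(self.last_drive[i, j]),
            )
            for i, j in zip(pre, post)
        ]

    def edge_index(self) -> np.ndarray:
        """(m, 2) array of (pre, post) pairs in row-major (lexicographic) order."""
        pre, post = np.nonzero(self.mask)
        return np.column_stack([pre, post])

    def distance_matrix(self) -> np.ndarray:
        """Pairwise Euclidean distances d_ij between neuron positions."""
        diff = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((diff**2).sum(axis=-1))

    def copy(self) -> "PlasticNetwork":
        net = PlasticNetwork(
            self.positions.copy(),
            self.biases.copy(),
            self.weights.copy(),
            self.mask.copy(),
            self.activations.copy(),
            self.time,
        )
        net.last_drive = self.last_drive.copy()
        return net

    # ------------------------------------------------------------- mutation

    def add_synapse(self, pre: int, post: int, weight: float) -> None:
        if pre == post:
            raise ValueError("self-loops are not allowed")
        if weight < 0 or not math.isfinite(weight):
            raise ValueError("weight must be nonnegative and finite")
        self.mask[pre, post] = True
        self.weights[pre, post] = weight

    def remove_synapse(self, pre: int, post: int) -> None:
        self.mask[pre, post] = False
        self.weights[pre, post] = 0.0
        self.last_drive[pre, post] = 0.0


def build_network(
    n_neurons: int,
    edge_density: float,
    seed: int | None = None,
    *,
    weight_init: tuple[float, float] = (0.05, 0.15),
    bias: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PlasticNetwork:
    """Construct a seeded random network N(0).

    Neurons are placed uniformly at random in the unit square; each ordered
    non-self pair becomes a synapse independently with probability
    ``edge_density``, with initial weight drawn uniformly from
    ``weight_init``.  Identical seed (or generator state) implies an
    identical network.
    """
    if n_neurons < 2:
        raise ValueError("n_neurons must be at least 2")
    if not 0.0 <= edge_density <= 1.0:
        raise ValueError("edge_density must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 1.0, size=(n_neurons, 2))
    biases = np.full(n_neurons, float(bias))
    mask = rng.uniform(size=(n_neurons, n_neurons)) < edge_density
    np.fill_diagonal(mask, False)
    lo, hi = weight_init
    weights = rng.uniform(lo, hi, size=(n_neurons, n_neurons))
    weights[~mask] = 0.0
    return PlasticNetwork(positions, biases, weights, mask)


def activate(
    network: PlasticNetwork,
    external_input: np.ndarray,
    activation_fn: str = "logistic",
    convention: str = "incoming",
) -> np.ndarray:
    """Synchronous activation update a_i = σ(Σ_j w_ji a_j + b_i + I_i).

    All neurons read the previous step's activation vector, so the update is
    order-independent and deterministic.  Under the default ``incoming``
    convention a neuron's drive sums over synapses terminating at it;
    ``outgoing`` sums over synapses originating from it (the transpose).
    The network's activations are replaced by the result, which is returned.
    """
    x = np.asarray(external_input, dtype=float)
    if x.shape != (network.n_neurons,):
        raise ValueError(
            f"external_input has length {x.shape}, expected ({network.n_neurons},)"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("external_input must be finite")
    try:
        sigma = ACTIVATION_FUNCTIONS[activation_fn]
    except KeyError:
        raise ValueError(
            f"unknown activation_fn {activation_fn!r}; "
            f"choose from {sorted(ACTIVATION_FUNCTIONS)}"
        ) from None
    if convention == "incoming":
        drive = network.weights.T @ network.activations
    elif convention == "outgoing":
        drive = network.weights @ network.activations
    else:
        raise ValueError("convention must be 'incoming' or 'outgoing'")
    out = sigma(drive + network.biases + x)
    network.activations = np.asarray(out, dtype=float)
    return network.activations


# ----------------------------------------------------------------------- I/O

_EDGE_HEADER = "pre\tpost\tweight"
_NEURON_HEADER = "id\tx\ty\tbias"


def write_network(network: PlasticNetwork, prefix: str) -> tuple[str, str]:
    """Write the network as ``{prefix}.neurons.tsv`` and ``{prefix}.edges.tsv``.

    Floats are serialized with 17 significant digits so the round trip through
    :func:`read_network` is lossless.
    """
    neurons_path = f"{prefix}.neurons.tsv"
    edges_path = f"{prefix}.edges.tsv"
    with open(neurons_path, "w") as fh:
        fh.write(_NEURON_HEADER + "\n")
        for i in range(network.n_neurons):
            fh.write(
                f"{i}\t{network.positions[i, 0]:.17g}\t"
                f"{network.positions[i, 1]:.17g}\t{network.biases[i]:.17g}\n"
            )
    with open(edges_path, "w") as fh:
        fh.write(_EDGE_HEADER + "\n")
        for pre, post in network.edge_index():
            fh.write(f"{pre}\t{post}\t{network.weights[pre, post]:.17g}\n")
    return neurons_path, edges_path


class NetworkFormatError(ValueError):
    """Raised for malformed, duplicate, or self-loop rows in network files."""


def read_network(prefix: str) -> PlasticNetwork:
    """Read a network written by :func:`write_network`.

    Activations and simulation time are not serialized; they are reset to
    zero.  Self-loop rows, duplicate (pre, post) rows, and dangling neuron
    ids are rejected.
    """
    neurons_path = f"{prefix}.neurons.tsv"
    edges_path = f"{prefix}.edges.tsv"
    with open(neurons_path) as fh:
        header = fh.readline().strip()
        if header != _NEURON_HEADER:
            raise NetworkFormatError(f"bad neuron header: {header!r}")
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise NetworkFormatError(f"malformed neuron row: {line!r}")
            rows.append((int(parts[0]), float(parts[1]), float(parts[2]), float(parts[3])))
    ids = [r[0] for r in rows]
    if sorted(ids) != list(range(len(rows))):
        raise NetworkFormatError("neuron ids must be 0..n-1 and unique")
    rows.sort()
    n = len(rows)
    positions = np.array([[r[1], r[2]] for r in rows])
    biases = np.array([r[3] for r in rows])
    weights = np.zeros((n, n))
    mask = np.zeros((n, n), dtype=bool)
    with open(edges_path) as fh:
        header = fh.readline().strip()
        if header != _EDGE_HEADER:
            raise NetworkFormatError(f"bad edge header: {header!r}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise NetworkFormatError(f"malformed edge row: {line!r}")
            pre, post, w = int(parts[0]), int(parts[1]), float(parts[2])
            if pre == post:
                raise NetworkFormatError(f"self-loop row: {pre} -> {post}")
            if not (0 <= pre < n and 0 <= post < n):
                raise NetworkFormatError(f"edge references unknown neuron: {line!r}")
            if mask[pre, post]:
                raise NetworkFormatError(f"duplicate edge row: {pre} -> {post}")
            mask[pre, post] = True
            weights[pre, post] = w
    return PlasticNetwork(positions, biases, weights, mask)


def to_graphml(network: PlasticNetwork, path: str) -> None:
    """Export as directed GraphML with weight as an edge attribute."""
    g = nx.DiGraph()
    for neuron in network.neurons:
        g.add_node(
            neuron.id,
            x=neuron.position[0],
            y=neuron.position[1],
            bias=neuron.bias,
            activation=neuron.activation,
        )
    for syn in network.synapses:
        g.add_edge(syn.pre, syn.post, weight=syn.weight)
    nx.write_graphml(g, path)
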