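"""Graph-attention encoder over the bipartite circRNA-disease graph.

The integrated similarity matrices SC (circRNA x circRNA) and SD
(disease x disease) are projected into a shared F-dimensional space by
trainable matrices MC and MD, stacked into initial node features
X = [SC @ MC ; SD @ MD], and refined by L multi-head graph-attention layers
over the association graph (one undirected edge per known pair, plus a
self-loop on every node so isolated vertices keep their features).

Per head, an edge j -> i is scored e_ij = LeakyReLU(a^T [W h_i || W h_j]),
scores are softmax-normalized over the in-neighborhood of i, and messages
W h_j are aggregated with those weights. Hidden layers concatenate the K
head outputs (each of width F/K) after a nonlinearity; the last layer
averages K full-width heads with no nonlinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat, segment_max_values, segment_sum
from .containers import AssociationMatrix, SimilarityMatrix

__all__ = [
    "BipartiteGraph",
    "EncoderConfig",
    "EncoderState",
    "build_graph",
    "init_node_features",
    "attention_scores",
    "normalize_attention",
    "gat_layer",
    "encode",
]


@dataclass
class BipartiteGraph:
    """Undirected bipartite association graph with per-node self-loops.

    Stored as directed edge arrays (src -> dst) over node ids
    0..n_circ-1 (circRNAs) and n_circ..n_circ+n_dis-1 (diseases); each
    bipartite edge appears in both directions.
    """

    n_circ: int
    n_dis: int
    pairs: list[tuple[int, int]]  # (circ index, disease index), Y=1 cells
    src: np.ndarray = field(init=False)
    dst: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate bipartite edges")
        n = self.n_circ + self.n_dis
        src, dst = [], []
        for ci, dj in self.pairs:
            if not (0 <= ci < self.n_circ and 0 <= dj < self.n_dis):
                raise ValueError(f"edge index out of range: ({ci}, {dj})")
            u, v = ci, self.n_circ + dj
            src += [u, v]
            dst += [v, u]
        # self-loops keep attention defined on isolated nodes
        src += list(range(n))
        dst += list(range(n))
        self.src = np.asarray(src, dtype=np.intp)
        self.dst = np.asarray(dst, dtype=np.intp)

    @property
    def n_nodes(self) -> int:
        return self.n_circ + self.n_dis

    @property
    def n_bipartite_edges(self) -> int:
        return len(self.pairs)


def build_graph(Y: AssociationMatrix) -> BipartiteGraph:
    """One undirected edge per Y=1 cell, plus self-loops on every node."""
    return BipartiteGraph(Y.n_circ, Y.n_dis, Y.positive_pairs())


@dataclass
class EncoderConfig:
    """Hyper-parameters of the attention encoder.

    F is the embedding width, L the number of attention layers, K the number
    of heads. Hidden layers concatenate heads, so F must be divisible by K
    when L > 1.
    """

    F: int = 32
    L: int = 2
    K: int = 4
    leaky_slope: float = 0.2
    activation: str = "elu"  # hidden-layer nonlinearity: "elu" or "identity"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F < 1 or self.L < 1 or self.K < 1:
            raise ValueError("F, L and K must all be >= 1")
        if self.L > 1 and self.F % self.K != 0:
            raise ValueError(
                f"embedding width F={self.F} must be divisible by K={self.K} heads "
                "on concatenating (non-final) layers"
            )
        if self.activation not in ("elu", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


@dataclass
class EncoderState:
    """Trainable encoder parameters: projections MC/MD and per-layer heads.

    layers[l][k] holds the head's shared weight W (F x width) and the two
    halves of the attention vector a = [a_dst ; a_src], split so that
    a^T [W h_i || W h_j] = a_dst . W h_i + a_src . W h_j.
    """

    MC: np.ndarray
    MD: np.ndarray
    layers: list[list[dict[str, np.ndarray]]]

    @classmethod
    def initialize(cls, n_circ: int, n_dis: int, config: EncoderConfig) -> "EncoderState":
        rng = np.random.default_rng(config.seed)
        F = config.F
        mc = _glorot(rng, n_circ, F, (n_circ, F))
        md = _glorot(rng, n_dis, F, (n_dis, F))
        layers = []
        for layer in range(config.L):
            width = F if layer == config.L - 1 else F // config.K
            heads = []
            for _ in range(config.K):
                heads.append(
                    {
                        "W": _glorot(rng, F, width, (F, width)),
                        "a_dst": _glorot(rng, 2 * width, 1, (width, 1)),
                        "a_src": _glorot(rng, 2 * width, 1, (width, 1)),
                    }
                )
            layers.append(heads)
        return cls(mc, md, layers)

    def as_tensors(self, trainable: bool = True) -> "EncoderTensors":
        mc = Tensor(self.MC, requires_grad=trainable)
        md = Tensor(self.MD, requires_grad=trainable)
        layers = [
            [{k: Tensor(v, requires_grad=trainable) for k, v in head.items()} for head in heads]
            for heads in self.layers
        ]
        return EncoderTensors(mc, md, layers)


@dataclass
class EncoderTensors:
    """Autodiff view of EncoderState."""

    MC: Tensor
    MD: Tensor
    layers: list[list[dict[str, Tensor]]]

    def parameters(self) -> dict[str, Tensor]:
        params = {"MC": self.MC, "MD": self.MD}
        for l, heads in enumerate(self.layers):
            for k, head in enumerate(heads):
                for name, t in head.items():
                    params[f"gat.{l}.{k}.{name}"] = t
        return params


def init_node_features(
    SC: SimilarityMatrix | np.ndarray,
    SD: SimilarityMatrix | np.ndarray,
    state: EncoderTensors,
) -> Tensor:
    """Initial features X = [SC @ MC ; SD @ MD], circRNA rows first."""
    sc = SC.values if isinstance(SC, SimilarityMatrix) else np.asarray(SC, dtype=float)
    sd = SD.values if isinstance(SD, SimilarityMatrix) else np.asarray(SD, dtype=float)
    if sc.shape[1] != state.MC.shape[0] or sd.shape[1] != state.MD.shape[0]:
        raise ValueError(
            f"similarity/projection shape mismatch: SC {sc.shape} vs MC {state.MC.shape}, "
            f"SD {sd.shape} vs MD {state.MD.shape}"
        )
    return concat([Tensor(sc) @ state.MC, Tensor(sd) @ state.MD], axis=0)


def attention_scores(
    H: Tensor,
    head: dict[str, Tensor],
    graph: BipartiteGraph,
    leaky_slope: float = 0.2,
) -> tuple[Tensor, Tensor]:
    """Raw edge scores e_ij and transformed features W @ H for one head.

    Returns (e, Hw) where e has one row per directed edge (src -> dst)
    including self-loops.
    """
    Hw = H @ head["W"]
    s_dst = Hw @ head["a_dst"]
    s_src = Hw @ head["a_src"]
    e = (s_dst.gather_rows(graph.dst) + s_src.gather_rows(graph.src)).leaky_relu(leaky_slope)
    if not np.isfinite(e.value).all():
        raise FloatingPointError("non-finite attention scores")
    return e, Hw


def normalize_attention(e: Tensor, graph: BipartiteGraph) -> Tensor:
    """Softmax of edge scores over each destination's in-neighborhood.

    Shift-by-max guards against overflow; the shift is constant per
    neighborhood so gradients are unaffected.
    """
    n = graph.n_nodes
    shift = segment_max_values(e.value, graph.dst, n)
    z = (e - Tensor(shift[graph.dst])).exp()
    denom = segment_sum(z, graph.dst, n)
    return z / denom.gather_rows(graph.dst)


def gat_layer(
    H: Tensor,
    heads: list[dict[str, Tensor]],
    graph: BipartiteGraph,
    is_last: bool,
    leaky_slope: float = 0.2,
    activation: str = "elu",
) -> tuple[Tensor, list[np.ndarray]]:
    """One multi-head attention layer; returns (H', per-head attention).

    Hidden layers concatenate activated head outputs; the last layer
    averages the heads without a nonlinearity.
    """
    outs, alphas = [], []
    for head in heads:
        e, Hw = attention_scores(H, head, graph, leaky_slope)
        alpha = normalize_attention(e, graph)
        msg = segment_sum(alpha * Hw.gather_rows(graph.src), graph.dst, graph.n_nodes)
        alphas.append(alpha.value.copy())
        if is_last:
            outs.append(msg)
        elif activation == "elu":
            outs.append(msg.elu())
        else:
            outs.append(msg)
    if is_last:
        out = outs[0]
        for o in outs[1:]:
            out = out + o
        return out * (1.0 / len(outs)), alphas
    return concat(outs, axis=1), alphas


def encode(
    Y: AssociationMatrix | BipartiteGraph,
    SC: SimilarityMatrix | np.ndarray,
    SD: SimilarityMatrix | np.ndarray,
    config: EncoderConfig,
    state: EncoderState | EncoderTensors | None = None,
    initial_features: np.ndarray | None = None,
    return_attention: bool = False,
):
    """Full encoder forward pass to node embeddings ((Nc+Nd) x F).

    Deterministic given ``state`` (or ``config.seed`` when state is None).
    ``initial_features`` overrides the projected similarities (used by the
    feature-ablation variant).
    """
    graph = Y if isinstance(Y, BipartiteGraph) else build_graph(Y)
    if state is None:
        state = EncoderState.initialize(graph.n_circ, graph.n_dis, config)
    tensors = state.as_tensors(trainable=False) if isinstance(state, EncoderState) else state
    if initial_features is not None:
        H = Tensor(np.asarray(initial_features, dtype=float))
    else:
        H = init_node_features(SC, SD, tensors)
    attn: list[list[np.ndarray]] = []
    for layer_idx, heads in enumerate(tensors.layers):
        H, alphas = gat_layer(
            H,
            heads,
            graph,
            is_last=(layer_idx == len(tensors.layers) - 1),
            leaky_slope=config.leaky_slope,
            activation=config.activation,
        )
        attn.append(alphas)
    if return_attention:
        return H, graph, attn
    return H
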