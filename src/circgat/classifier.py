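"""Pair scoring, negative sampling, loss and end-to-end training.

A circRNA-disease pair is scored by a small fully connected network on the
concatenated node embeddings: hidden layers are LeakyReLU affine maps and
the output layer is a sigmoid, so scores lie strictly in (0, 1). Known
associations are the positive samples; an equal number of negatives is
drawn uniformly from the unknown cells. The loss is mean binary
cross-entropy plus an L2 penalty lambda * ||Theta||^2 over *all* trainable
parameters — projections, attention weights and classifier alike — and
everything is trained jointly with full-batch Adam.

Ablation variants share this trainer:

* ``full``        — projected similarities -> GAT -> NN head (the default);
* ``no_features`` — fixed random-normal initial node features instead of
                    the projected similarities;
* ``no_gat``      — no encoder; the classifier scores concatenated rows of
                    the integrated similarity matrices directly;
* ``no_nn``       — encoder embeddings scored by a sigmoid dot product.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, concat
from .containers import AssociationMatrix, SimilarityMatrix
from .encoder import (
    BipartiteGraph,
    EncoderConfig,
    EncoderState,
    EncoderTensors,
    build_graph,
    encode,
)

__all__ = [
    "PairSample",
    "ClassifierState",
    "TrainConfig",
    "ModelState",
    "VARIANTS",
    "sample_negatives",
    "score_pair",
    "loss",
    "train",
    "predict",
    "rank_for_disease",
]

VARIANTS = ("full", "no_features", "no_gat", "no_nn")


@dataclass(frozen=True)
class PairSample:
    """One (circRNA index, disease index, 0/1 label) training sample."""

    circ: int
    disease: int
    label: int


@dataclass
class TrainConfig:
    """Optimization settings: L2 factor, Adam step size, epochs, sampling."""

    lam: float = 1e-2
    lr: float = 5e-3
    epochs: int = 500
    seed: int = 0
    negative_ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class ClassifierState:
    """Fully connected head: per-layer weights and biases.

    Input width 2F (concatenated pair embedding), one hidden layer of the
    embedding width by default, scalar output.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @classmethod
    def initialize(
        cls,
        input_width: int,
        hidden_width: int,
        n_layers: int,
        rng: np.random.Generator,
    ) -> "ClassifierState":
        if n_layers < 1:
            raise ValueError("classifier needs at least one layer")
        widths = [input_width] + [hidden_width] * (n_layers - 1) + [1]
        weights, biases = [], []
        for fan_in, fan_out in zip(widths[:-1], widths[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            biases.append(np.zeros(fan_out))
        return cls(weights, biases)

    def as_tensors(self, trainable: bool = True) -> list[dict[str, Tensor]]:
        return [
            {"W": Tensor(w, requires_grad=trainable), "b": Tensor(b, requires_grad=trainable)}
            for w, b in zip(self.weights, self.biases)
        ]


def sample_negatives(
    Y: AssociationMatrix,
    n_neg: int,
    seed: int,
    exclude: set[tuple[int, int]] | None = None,
) -> list[PairSample]:
    """Uniform sample without replacement from the Y=0 cells.

    ``exclude`` removes further pairs (e.g. held-out test positives) from
    the candidate pool. Reproducible for a given seed.
    """
    exclude = exclude or set()
    zr, zc = np.nonzero(Y.values == 0)
    candidates = [(int(i), int(j)) for i, j in zip(zr, zc) if (int(i), int(j)) not in exclude]
    if n_neg > len(candidates):
        raise ValueError(
            f"requested {n_neg} negatives but only {len(candidates)} zero cells available "
            f"({len(exclude)} excluded)"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n_neg, replace=False)
    return [PairSample(candidates[k][0], candidates[k][1], 0) for k in sorted(chosen)]


def _classifier_logits(
    feats: Tensor, layers: list[dict[str, Tensor]], leaky_slope: float = 0.2
) -> Tensor:
    """Hidden LeakyReLU affine layers; returns pre-sigmoid logits."""
    h = feats
    for layer in layers[:-1]:
        h = (h @ layer["W"] + layer["b"]).leaky_relu(leaky_slope)
    z = h @ layers[-1]["W"] + layers[-1]["b"]
    if not np.isfinite(z.value).all():
        raise FloatingPointError("non-finite classifier activations")
    return z


def _bce_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits: mean(softplus(z) - y*z).

    Identical to -mean(y log s + (1-y) log(1-s)) with s = sigmoid(z), but
    stays finite when scores saturate in float64.
    """
    y = np.asarray(labels, dtype=float).reshape(-1, 1)
    n = y.shape[0]
    return (logits.softplus() - Tensor(y) * logits).sum() * (1.0 / n)


def score_pair(
    c_emb: np.ndarray, d_emb: np.ndarray, state: ClassifierState, leaky_slope: float = 0.2
) -> float:
    """Score a single pair from its circRNA and disease embeddings."""
    feats = Tensor(np.concatenate([c_emb, d_emb])[None, :])
    logits = _classifier_logits(feats, state.as_tensors(trainable=False), leaky_slope)
    return float(logits.sigmoid().value.item())


def loss(
    scores: np.ndarray | Tensor,
    labels: np.ndarray,
    params: list[np.ndarray] | None = None,
    lam: float = 0.0,
) -> float | Tensor:
    """Mean binary cross-entropy plus lambda * squared L2 over all parameters.

    Accepts a plain array (returns a float) or an autodiff tensor (returns
    a tensor, used inside training).
    """
    labels = np.asarray(labels, dtype=float).reshape(-1, 1)
    n = labels.shape[0]
    if n == 0:
        raise ValueError("loss undefined on an empty batch")
    if isinstance(scores, Tensor):
        y = Tensor(labels)
        ce = (y * scores.log() + (1.0 - y) * (1.0 - scores).log()).sum() * (-1.0 / n)
        if lam and params:
            reg = (params[0] * params[0]).sum()
            for p in params[1:]:
                reg = reg + (p * p).sum()
            ce = ce + reg * lam
        return ce
    s = np.asarray(scores, dtype=float).reshape(-1, 1)
    ce = float(-(labels * np.log(s) + (1 - labels) * np.log(1 - s)).mean())
    if lam and params:
        ce += lam * sum(float((np.asarray(p) ** 2).sum()) for p in params)
    return ce


@dataclass
class ModelState:
    """Trained model: variant, configs, parameters and training provenance."""

    variant: str
    encoder_config: EncoderConfig | None
    train_config: TrainConfig
    encoder: EncoderState | None
    classifier: ClassifierState | None
    fixed_features: np.ndarray | None
    SC: np.ndarray
    SD: np.ndarray
    circ_names: list[str]
    disease_names: list[str]
    train_positives: set[tuple[int, int]]
    graph_pairs: list[tuple[int, int]]
    loss_trace: list[float] = field(default_factory=list)
    norm_trace: list[float] = field(default_factory=list)

    def parameter_census(self) -> dict[str, tuple[int, ...]]:
        """Name -> shape of every trainable tensor (for structural checks)."""
        census: dict[str, tuple[int, ...]] = {}
        if self.encoder is not None:
            if self.variant != "no_features":
                census["MC"] = self.encoder.MC.shape
                census["MD"] = self.encoder.MD.shape
            for l, heads in enumerate(self.encoder.layers):
                for k, head in enumerate(heads):
                    for name, arr in head.items():
                        census[f"gat.{l}.{k}.{name}"] = arr.shape
        if self.classifier is not None:
            for i, (w, b) in enumerate(zip(self.classifier.weights, self.classifier.biases)):
                census[f"nn.{i}.W"] = w.shape
                census[f"nn.{i}.b"] = b.shape
        return census

    def parameter_norm(self) -> float:
        """L2 norm of all trainable parameters."""
        total = 0.0
        if self.encoder is not None:
            if self.variant != "no_features":
                total += float((self.encoder.MC**2).sum() + (self.encoder.MD**2).sum())
            for heads in self.encoder.layers:
                for head in heads:
                    total += sum(float((a**2).sum()) for a in head.values())
        if self.classifier is not None:
            total += sum(float((w**2).sum()) for w in self.classifier.weights)
            total += sum(float((b**2).sum()) for b in self.classifier.biases)
        return float(np.sqrt(total))

    def embeddings(self) -> np.ndarray | None:
        """Node embeddings ((Nc+Nd) x F) for encoder-bearing variants."""
        if self.variant == "no_gat":
            return None
        graph = BipartiteGraph(len(self.circ_names), len(self.disease_names), self.graph_pairs)
        return encode(
            graph,
            self.SC,
            self.SD,
            self.encoder_config,
            state=self.encoder,
            initial_features=self.fixed_features,
        ).value


class _Adam:
    """Adam with decoupled L2 decay on a dict of tensors.

    The cross-entropy gradient goes through the adaptive update; the
    gradient of the lambda * ||Theta||^2 penalty (2 * lambda * p) is applied
    directly, scaled by the step size. Routing the penalty through Adam's
    per-coordinate normalization instead lets its constant pull dominate
    the data gradient and drags the jointly trained model into the
    degenerate all-parameters-zero stationary point (where the balanced
    batch gradient vanishes), so the decay is decoupled in the AdamW sense.
    """

    def __init__(self, params: dict[str, Tensor], lr: float, lam: float = 0.0):
        self.params = params
        self.lr = lr
        self.decay = min(2.0 * lam * lr, 1.0)
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.m = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.v = {k: np.zeros_like(t.value) for k, t in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in self.params.items():
            g = p.grad if p.grad is not None else np.zeros_like(p.value)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            p.value -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            if self.decay:
                p.value *= 1.0 - self.decay

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


def _forward_logits(
    variant: str,
    graph: BipartiteGraph,
    sc: np.ndarray,
    sd: np.ndarray,
    enc_tensors: EncoderTensors | None,
    fixed_features: np.ndarray | None,
    clf_tensors: list[dict[str, Tensor]] | None,
    samples: list[PairSample],
    config: EncoderConfig | None,
) -> Tensor:
    """Pre-sigmoid pair logits for a batch under any variant (autodiff path)."""
    ci = np.array([s.circ for s in samples], dtype=np.intp)
    dj = np.array([s.disease for s in samples], dtype=np.intp)
    if variant == "no_gat":
        feats = Tensor(np.concatenate([sc[ci], sd[dj]], axis=1))
        return _classifier_logits(feats, clf_tensors)
    H = encode(
        graph, sc, sd, config, state=enc_tensors, initial_features=fixed_features
    )
    c_emb = H.gather_rows(ci)
    d_emb = H.gather_rows(graph.n_circ + dj)
    if variant == "no_nn":
        return (c_emb * d_emb).matmul(Tensor(np.ones((config.F, 1))))
    return _classifier_logits(concat([c_emb, d_emb], axis=1), clf_tensors)


def train(
    Y_train: AssociationMatrix,
    SC: SimilarityMatrix | np.ndarray,
    SD: SimilarityMatrix | np.ndarray,
    encoder_config: EncoderConfig | None = None,
    train_config: TrainConfig | None = None,
    samples: list[PairSample] | None = None,
    exclude: set[tuple[int, int]] | None = None,
    variant: str = "full",
) -> ModelState:
    """Joint full-batch Adam training of encoder and classifier.

    Positives are the Y_train=1 cells; if ``samples`` is not given, an equal
    number of negatives (times ``negative_ratio``) is drawn once, excluding
    ``exclude`` (e.g. test positives). Reproducible for a given seed pair.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    encoder_config = encoder_config or EncoderConfig()
    train_config = train_config or TrainConfig()
    sc = SC.values if isinstance(SC, SimilarityMatrix) else np.asarray(SC, dtype=float)
    sd = SD.values if isinstance(SD, SimilarityMatrix) else np.asarray(SD, dtype=float)

    positives = Y_train.positive_pairs()
    if not positives and samples is None:
        raise ValueError("training requires at least one positive association")
    if samples is None:
        n_neg = int(round(train_config.negative_ratio * len(positives)))
        samples = [PairSample(i, j, 1) for i, j in positives] + sample_negatives(
            Y_train, n_neg, train_config.seed, exclude=exclude
        )

    graph = build_graph(Y_train)
    rng = np.random.default_rng(train_config.seed)
    F = encoder_config.F

    enc_tensors = None
    encoder_state = None
    fixed_features = None
    clf_tensors = None
    params: dict[str, Tensor] = {}

    if variant != "no_gat":
        encoder_state = EncoderState.initialize(Y_train.n_circ, Y_train.n_dis, encoder_config)
        if variant == "no_features":
            fixed_features = rng.standard_normal((graph.n_nodes, F))
            enc_tensors = encoder_state.as_tensors(trainable=True)
            enc_params = enc_tensors.parameters()
            enc_params.pop("MC")
            enc_params.pop("MD")
            params.update(enc_params)
        else:
            enc_tensors = encoder_state.as_tensors(trainable=True)
            params.update(enc_tensors.parameters())

    clf_state = None
    if variant not in ("no_nn",):
        input_width = (sc.shape[1] + sd.shape[1]) if variant == "no_gat" else 2 * F
        clf_state = ClassifierState.initialize(input_width, F, 2, rng)
        clf_tensors = clf_state.as_tensors(trainable=True)
        for i, layer in enumerate(clf_tensors):
            params[f"nn.{i}.W"] = layer["W"]
            params[f"nn.{i}.b"] = layer["b"]

    labels = np.array([s.label for s in samples], dtype=float)
    opt = _Adam(params, train_config.lr, train_config.lam)
    trace: list[float] = []
    norm_trace: list[float] = []
    for epoch in range(train_config.epochs):
        opt.zero_grad()
        logits = _forward_logits(
            variant, graph, sc, sd, enc_tensors, fixed_features, clf_tensors, samples,
            encoder_config,
        )
        bce = _bce_logits(logits, labels)
        sq_norm = sum(float((p.value**2).sum()) for p in params.values())
        val = float(bce.value) + train_config.lam * sq_norm
        if not np.isfinite(val):
            raise FloatingPointError(f"training diverged: non-finite loss at epoch {epoch}")
        trace.append(val)
        norm_trace.append(float(np.sqrt(sq_norm)))
        bce.backward()
        opt.step()

    # copy optimized values back into plain-array state
    if encoder_state is not None:
        encoder_state.MC = enc_tensors.MC.value
        encoder_state.MD = enc_tensors.MD.value
        encoder_state.layers = [
            [{k: t.value for k, t in head.items()} for head in heads]
            for heads in enc_tensors.layers
        ]
    if clf_state is not None:
        clf_state.weights = [layer["W"].value for layer in clf_tensors]
        clf_state.biases = [layer["b"].value for layer in clf_tensors]

    return ModelState(
        variant=variant,
        encoder_config=encoder_config,
        train_config=train_config,
        encoder=encoder_state,
        classifier=clf_state,
        fixed_features=fixed_features,
        SC=sc,
        SD=sd,
        circ_names=list(Y_train.circ_names),
        disease_names=list(Y_train.disease_names),
        train_positives={(s.circ, s.disease) for s in samples if s.label == 1},
        graph_pairs=graph.pairs,
        loss_trace=trace,
        norm_trace=norm_trace,
    )


def predict(model: ModelState, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Scores in (0, 1) for arbitrary (circ index, disease index) pairs."""
    samples = [PairSample(i, j, 0) for i, j in pairs]
    graph = BipartiteGraph(len(model.circ_names), len(model.disease_names), model.graph_pairs)
    enc_tensors = model.encoder.as_tensors(trainable=False) if model.encoder else None
    clf_tensors = model.classifier.as_tensors(trainable=False) if model.classifier else None
    logits = _forward_logits(
        model.variant, graph, model.SC, model.SD, enc_tensors, model.fixed_features,
        clf_tensors, samples, model.encoder_config,
    )
    return logits.sigmoid().value.ravel()


def rank_for_disease(
    model: ModelState,
    disease: str,
    top: int | None = None,
    exclude_known: bool = True,
) -> list[tuple[str, float]]:
    """circRNAs ranked by predicted score for one disease.

    Descending by score, ties broken by circRNA name. Known training
    positives are dropped when ``exclude_known`` is on.
    """
    from .containers import normalize_name

    name = normalize_name(disease)
    if name not in model.disease_names:
        hints = difflib.get_close_matches(name, model.disease_names, n=3)
        raise KeyError(f"unknown disease {disease!r}; closest known names: {hints}")
    dj = model.disease_names.index(name)
    candidates = [
        i for i in range(len(model.circ_names))
        if not (exclude_known and (i, dj) in model.train_positives)
    ]
    scores = predict(model, [(i, dj) for i in candidates])
    ranked = sorted(
        zip(candidates, scores), key=lambda t: (-t[1], model.circ_names[t[0]])
    )
    out = [(model.circ_names[i], float(s)) for i, s in ranked]
    return out[:top] if top is not None else out
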