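"""Planted-structure synthetic data: ontology trees and association matrices.

The generator encodes the guilt-by-association assumption the predictor
exploits: circRNAs and diseases carry latent block labels, within-block
associations appear with probability ``p_in`` and cross-block ones with
``p_out`` (a bipartite stochastic block model), and the disease ontology is
a rooted tree whose leaves are the diseases, arranged so that same-block
diseases share a deeper common ancestor than cross-block pairs. Semantic,
functional and kernel similarities therefore all align with the planted
blocks, and held-out within-block edges are recoverable.

The default instance (60 circRNAs x 20 diseases, 4 blocks, p_in=0.9,
p_out=0.02) is the benchmark used throughout the test-suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG

__all__ = ["PlantedModel", "generate_ontology", "generate_associations", "holdout_edges"]

logger = logging.getLogger(__name__)


@dataclass
class PlantedModel:
    """Parameters of the planted bipartite block model and its ontology."""

    n_circ: int = 60
    n_dis: int = 20
    n_blocks: int = 4
    p_in: float = 0.9
    p_out: float = 0.02
    depth: int = 4
    branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if self.n_blocks > min(self.n_circ, self.n_dis):
            raise ValueError("n_blocks cannot exceed min(n_circ, n_dis)")
        if self.depth < 2 or self.branching < 2:
            raise ValueError("ontology needs depth >= 2 and branching >= 2")

    def circ_block(self, i: int) -> int:
        return i * self.n_blocks // self.n_circ

    def disease_block(self, j: int) -> int:
        return j * self.n_blocks // self.n_dis

    def disease_names(self) -> list[str]:
        width = len(str(self.n_dis - 1))
        return [f"disease_{j:0{width}d}" for j in range(self.n_dis)]

    def circ_names(self) -> list[str]:
        width = len(str(self.n_circ - 1))
        return [f"circ_{i:0{width}d}" for i in range(self.n_circ)]


def generate_ontology(model: PlantedModel) -> DiseaseDAG:
    """Rooted is-a tree whose leaves are the model's diseases.

    depth counts tree levels including root and leaves. With depth 2 the
    leaves hang directly under the root (a star, no block structure in the
    ontology). With depth >= 3, level 1 holds one internal term per block
    and each block's diseases sit in a balanced subtree beneath it, so
    same-block leaf pairs share the block ancestor while cross-block pairs
    share only the root.
    """
    terms: dict[str, str] = {"SYN:0000000": "disease (root)"}
    edges: list[tuple[str, str]] = []
    counter = [0]

    def new_term(name: str) -> str:
        counter[0] += 1
        tid = f"SYN:{counter[0]:07d}"
        terms[tid] = name
        return tid

    names = model.disease_names()
    root = "SYN:0000000"

    if model.depth == 2:
        if model.branching < model.n_dis:
            raise ValueError(
                f"tree of depth 2 with branching {model.branching} has fewer leaves "
                f"than {model.n_dis} diseases"
            )
        for name in names:
            tid = new_term(name)
            edges.append((tid, root))
        return DiseaseDAG.from_terms(terms, edges)

    # levels below each block node; branching^inner_levels leaf slots per block
    inner_levels = model.depth - 2
    slots = model.branching**inner_levels
    blocks: dict[int, list[str]] = {}
    for j, name in enumerate(names):
        blocks.setdefault(model.disease_block(j), []).append(name)
    max_block = max(len(v) for v in blocks.values())
    if slots < max_block:
        raise ValueError(
            f"tree of depth {model.depth} / branching {model.branching} provides {slots} "
            f"leaves per block, fewer than the largest block ({max_block} diseases)"
        )

    for b in sorted(blocks):
        block_node = new_term(f"disease block {b}")
        edges.append((block_node, root))
        # grow a balanced subtree only as far as needed, left to right
        frontier = [block_node]
        for level in range(inner_levels - 1):
            needed = -(-len(blocks[b]) // model.branching ** (inner_levels - 1 - level))
            nxt = []
            for idx in range(needed):
                parent = frontier[idx // model.branching]
                tid = new_term(f"disease group {b}.{level}.{idx}")
                edges.append((tid, parent))
                nxt.append(tid)
            frontier = nxt
        for idx, name in enumerate(blocks[b]):
            tid = new_term(name)
            edges.append((tid, frontier[idx // model.branching]))
    return DiseaseDAG.from_terms(terms, edges)


def generate_associations(model: PlantedModel) -> AssociationMatrix:
    """Bipartite block-model 0/1 matrix; deterministic for a given seed.

    All-zero rows and columns are redrawn (up to 100 attempts each) so the
    GIP kernels are well defined; a row that stays empty is left zero with
    a warning.
    """
    rng = np.random.default_rng(model.seed)
    cb = np.array([model.circ_block(i) for i in range(model.n_circ)])
    db = np.array([model.disease_block(j) for j in range(model.n_dis)])
    probs = np.where(cb[:, None] == db[None, :], model.p_in, model.p_out)

    y = (rng.random((model.n_circ, model.n_dis)) < probs).astype(float)
    for i in range(model.n_circ):
        attempts = 0
        while y[i].sum() == 0 and attempts < 100:
            y[i] = (rng.random(model.n_dis) < probs[i]).astype(float)
            attempts += 1
        if y[i].sum() == 0:
            logger.warning("circRNA row %d left all-zero after 100 redraws", i)
    for j in range(model.n_dis):
        attempts = 0
        while y[:, j].sum() == 0 and attempts < 100:
            y[:, j] = (rng.random(model.n_circ) < probs[:, j]).astype(float)
            attempts += 1
        if y[:, j].sum() == 0:
            logger.warning("disease column %d left all-zero after 100 redraws", j)

    return AssociationMatrix(y, model.circ_names(), model.disease_names())


def holdout_edges(
    Y: AssociationMatrix, fraction: float, seed: int
) -> tuple[AssociationMatrix, list[tuple[int, int]]]:
    """Remove ceil(fraction * |positives|) positives uniformly at random.

    Returns the reduced matrix and the held-out positive pairs; together
    they reconstruct Y exactly.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly between 0 and 1")
    positives = Y.positive_pairs()
    n_hold = int(np.ceil(fraction * len(positives)))
    if n_hold >= len(positives):
        raise ValueError(
            f"holding out {n_hold} of {len(positives)} positives would leave none for training"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(positives), size=n_hold, replace=False)
    held = [positives[i] for i in sorted(chosen)]
    y_train = Y.copy()
    for i, j in held:
        y_train.values[i, j] = 0.0
    return y_train, held
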