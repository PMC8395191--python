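"""Disease and circRNA similarity matrices.

Four similarity notions feed the predictor:

* **Semantic similarity (SS)** between diseases, computed on the ontology
  DAG with Wang's measure: each ancestor term of a disease contributes a
  semantic value that decays by a fixed factor per is-a step, and two
  diseases are compared by the contribution of their shared terms relative
  to their total semantic values.
* **Functional similarity (FS)** between circRNAs: two circRNAs are similar
  when the disease groups they are associated with are semantically similar,
  via best-match averaging of SS across the two groups.
* **GIP kernel similarity (GC / GD)**: a Gaussian kernel on the rows
  (circRNAs) or columns (diseases) of the 0/1 association matrix, with the
  bandwidth set to the inverse mean squared profile norm.
* **Integrated similarity (SC / SD)**: FS (resp. SS) where it is nonzero,
  and the GIP kernel elsewhere — the ontology- and profile-based matrices
  are sparse, and the kernel fills the gaps.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix, normalize_name

__all__ = [
    "wang_semantic_values",
    "semantic_similarity",
    "circ_functional_similarity",
    "gip_bandwidth",
    "gip_kernel",
    "integrate",
    "compute_all_similarities",
]

logger = logging.getLogger(__name__)


def wang_semantic_values(dag: DiseaseDAG, term: str, decay: float) -> dict[str, float]:
    """Semantic value S(t) of every ancestor t of ``term`` (including itself).

    S(term) = 1; for an ancestor t, S(t) = decay * max over children of t
    that lie on a path from ``term``. Computed by relaxation over the
    ancestor set, which terminates because the ontology is acyclic.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    s: dict[str, float] = {term: 1.0}
    frontier = [term]
    while frontier:
        nxt: list[str] = []
        for t in frontier:
            contrib = decay * s[t]
            for parent in dag.parents(t):
                if contrib > s.get(parent, 0.0):
                    s[parent] = contrib
                    nxt.append(parent)
        frontier = nxt
    return s


def semantic_similarity(
    dag: DiseaseDAG, diseases: list[str], decay: float = 0.5
) -> SimilarityMatrix:
    """Wang-style semantic similarity matrix SS over the given diseases.

    Diseases are matched to ontology terms by normalized name. A disease with
    no matching term gets an all-zero row/column (including the diagonal);
    downstream integration substitutes its GIP kernel profile instead.
    """
    if not diseases:
        raise ValueError("disease list must not be empty")
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must lie in (0, 1), got {decay}")
    names = [normalize_name(d) for d in diseases]
    n = len(names)

    svals: list[dict[str, float] | None] = []
    unmapped: list[str] = []
    for name in names:
        term = dag.term_for_name(name)
        if term is None:
            svals.append(None)
            unmapped.append(name)
        else:
            svals.append(wang_semantic_values(dag, term, decay))
    if unmapped:
        logger.warning("%d diseases not found in ontology: %s", len(unmapped), unmapped)

    ss = np.zeros((n, n))
    totals = [sum(s.values()) if s is not None else 0.0 for s in svals]
    for i in range(n):
        if svals[i] is None:
            continue
        ss[i, i] = 1.0
        for j in range(i + 1, n):
            if svals[j] is None:
                continue
            shared = svals[i].keys() & svals[j].keys()
            if shared:
                num = sum(svals[i][t] + svals[j][t] for t in shared)
                ss[i, j] = ss[j, i] = num / (totals[i] + totals[j])
    return SimilarityMatrix(ss, names, "semantic")


def circ_functional_similarity(
    SS: SimilarityMatrix, Y: AssociationMatrix
) -> SimilarityMatrix:
    """Functional similarity FS between circRNAs from their disease groups.

    FS(ci, cj) averages, over both directions, the best semantic match of
    each disease in one circRNA's group against the other circRNA's group.
    A circRNA with no associated disease gets FS = 0 off-diagonal and 1 on
    the diagonal (the GIP kernel covers it after integration).
    """
    if SS.kind != "semantic":
        raise ValueError(f"expected a semantic similarity matrix, got {SS.kind!r}")
    if SS.labels != Y.disease_names:
        extra = set(SS.labels) ^ set(Y.disease_names)
        raise ValueError(f"SS/Y disease label mismatch: {sorted(extra) or 'ordering differs'}")

    nc = Y.n_circ
    groups = [np.nonzero(Y.values[i])[0] for i in range(nc)]
    fs = np.eye(nc)
    for i in range(nc):
        di = groups[i]
        if di.size == 0:
            continue
        for j in range(i + 1, nc):
            dj = groups[j]
            if dj.size == 0:
                continue
            # best-match of each disease against the opposite group
            sub = SS.values[np.ix_(di, dj)]
            fs[i, j] = fs[j, i] = (
                sub.max(axis=0).sum() + sub.max(axis=1).sum()
            ) / (di.size + dj.size)
    return SimilarityMatrix(fs, Y.circ_names, "functional")


def gip_bandwidth(Y: AssociationMatrix, axis: str) -> float:
    """Kernel bandwidth gamma = 1 / mean squared profile norm along an axis."""
    if axis not in ("circ", "disease"):
        raise ValueError(f"axis must be 'circ' or 'disease', got {axis!r}")
    profiles = Y.values if axis == "circ" else Y.values.T
    mean_sq = float((profiles**2).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError(
            f"cannot compute GIP bandwidth along axis {axis!r}: all profiles are zero"
        )
    return 1.0 / mean_sq


def gip_kernel(Y: AssociationMatrix, axis: str) -> SimilarityMatrix:
    """Gaussian interaction profile kernel GC (circ rows) or GD (disease cols)."""
    gamma = gip_bandwidth(Y, axis)
    if axis == "circ":
        profiles, labels, kind = Y.values, Y.circ_names, "gip_circ"
    else:
        profiles, labels, kind = Y.values.T, Y.disease_names, "gip_dis"
    sq = (profiles**2).sum(axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * profiles @ profiles.T
    np.maximum(d2, 0.0, out=d2)
    g = np.exp(-gamma * d2)
    g = (g + g.T) / 2.0
    np.fill_diagonal(g, 1.0)
    return SimilarityMatrix(g, labels, kind)


_INTEGRATED_KIND = {
    ("functional", "gip_circ"): "integrated_circ",
    ("semantic", "gip_dis"): "integrated_dis",
}


def integrate(primary: SimilarityMatrix, fallback: SimilarityMatrix) -> SimilarityMatrix:
    """Element-wise composite: primary where nonzero, else the GIP fallback."""
    kind = _INTEGRATED_KIND.get((primary.kind, fallback.kind))
    if kind is None:
        raise ValueError(
            f"cannot integrate {primary.kind!r} with {fallback.kind!r}; expected "
            "(functional, gip_circ) or (semantic, gip_dis)"
        )
    if primary.labels != fallback.labels:
        raise ValueError("label mismatch between primary and fallback similarity matrices")
    values = np.where(primary.values != 0.0, primary.values, fallback.values)
    return SimilarityMatrix(values, primary.labels, kind)


def compute_all_similarities(
    Y: AssociationMatrix,
    dag: DiseaseDAG | None = None,
    decay: float = 0.5,
) -> dict[str, SimilarityMatrix]:
    """Full similarity pipeline: SS, FS, GC, GD and the integrated SC, SD.

    Without an ontology, SS is all-zero and the integrated matrices reduce
    to the GIP kernels.
    """
    if dag is not None:
        ss = semantic_similarity(dag, Y.disease_names, decay)
    else:
        ss = SimilarityMatrix(
            np.zeros((Y.n_dis, Y.n_dis)), Y.disease_names, "semantic"
        )
    fs = circ_functional_similarity(ss, Y)
    gc = gip_kernel(Y, "circ")
    gd = gip_kernel(Y, "disease")
    return {
        "SS": ss,
        "FS": fs,
        "GC": gc,
        "GD": gd,
        "SC": integrate(fs, gc),
        "SD": integrate(ss, gd),
    }
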