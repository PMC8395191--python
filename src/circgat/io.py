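"""Readers and writers for the on-disk formats, plus the run configuration.

Formats: 2-column association TSV (circRNA id, disease name), OBO ontology
subset ([Term] stanzas with id / name / is_a; obsolete terms skipped),
labeled dense matrix TSV (full repr precision, round-trips exactly), metrics
TSV, ranked-prediction TSV, YAML run config and JSON run manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd
import yaml

from .classifier import TrainConfig
from .containers import AssociationMatrix, DiseaseDAG, SimilarityMatrix, normalize_name
from .encoder import EncoderConfig

__all__ = [
    "read_associations",
    "write_associations",
    "read_obo",
    "write_obo",
    "read_matrix",
    "write_matrix",
    "write_metrics",
    "RunConfig",
    "write_manifest",
]

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"circrna", "circrna_id", "circ", "circ_id", "circrna_name"}


def read_associations(path: str | Path) -> AssociationMatrix:
    """Read a 2-column TSV of (circRNA id, disease name) pairs.

    An optional header line is detected by its first token. Pairs are
    deduplicated (duplicates logged) and the matrix is built over sorted
    unique normalized names.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed association row: {line!r}")
            if lineno == 1 and normalize_name(fields[0]) in _HEADER_TOKENS:
                continue
            pairs.append((normalize_name(fields[0]), normalize_name(fields[1])))
    if not pairs:
        raise ValueError(f"{path}: no association rows found")
    unique = sorted(set(pairs))
    if len(unique) < len(pairs):
        logger.warning("%s: dropped %d duplicate pairs", path, len(pairs) - len(unique))
    circ_names = sorted({c for c, _ in unique})
    disease_names = sorted({d for _, d in unique})
    ci = {c: i for i, c in enumerate(circ_names)}
    dj = {d: j for j, d in enumerate(disease_names)}
    values = np.zeros((len(circ_names), len(disease_names)))
    for c, d in unique:
        values[ci[c], dj[d]] = 1.0
    return AssociationMatrix(values, circ_names, disease_names)


def write_associations(Y: AssociationMatrix, path: str | Path) -> None:
    """Write the Y=1 cells as a 2-column TSV."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for i, j in Y.positive_pairs():
            fh.write(f"{Y.circ_names[i]}\t{Y.disease_names[j]}\n")


def read_obo(path: str | Path) -> DiseaseDAG:
    """Parse an OBO file into a DiseaseDAG (is-a edges only).

    Obsolete terms are skipped (obonet drops them); non-is_a relationships
    are ignored; is_a edges to terms absent from the file are dropped with
    a warning. A cyclic ontology is rejected.
    """
    multigraph = obonet.read_obo(str(path))
    g = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        g.add_node(node, name=data.get("name", node), norm_name=normalize_name(data.get("name", node)))
    for child, parent, key in multigraph.edges(keys=True):
        if key != "is_a":
            continue
        if parent not in g or "name" not in multigraph.nodes[parent]:
            logger.warning("dropping dangling is_a edge %s -> %s", child, parent)
            continue
        g.add_edge(child, parent)
    return DiseaseDAG(g)


def write_obo(dag: DiseaseDAG, path: str | Path) -> None:
    """Write the DAG as a minimal OBO file ([Term] stanzas, is_a edges)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            fh.write(f"\n[Term]\nid: {term}\nname: {dag.name_of(term)}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent} ! {dag.name_of(parent)}\n")


def write_matrix(matrix: SimilarityMatrix | AssociationMatrix, path: str | Path) -> None:
    """Labeled dense TSV at full repr precision (exact round-trip)."""
    if isinstance(matrix, AssociationMatrix):
        df = pd.DataFrame(matrix.values, index=matrix.circ_names, columns=matrix.disease_names)
    else:
        df = pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels)
    # repr round-trips float64 exactly; pandas' default formatter does not
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_matrix(path: str | Path, kind: str | None = None):
    """Read a labeled dense TSV; returns SimilarityMatrix when kind is given."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if kind is None:
        return AssociationMatrix(df.to_numpy(), list(df.index), list(df.columns))
    return SimilarityMatrix(df.to_numpy(), list(df.index), kind)


def write_metrics(report, path: str | Path) -> None:
    """Metrics table (one row per fold plus the average) as TSV."""
    report.to_frame().to_csv(path, sep="\t", index_label="fold")


@dataclass
class RunConfig:
    """Serializable description of a full run.

    Paths are checked at load time; the config round-trips losslessly
    through YAML.
    """

    associations: str | None = None
    ontology: str | None = None
    output_dir: str = "."
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    k: int = 5
    repeats: int = 10
    threshold: float = 0.5
    mask_test_edges: bool = True
    decay: float = 0.5
    seed: int = 0

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        enc = EncoderConfig(**raw.pop("encoder", {}))
        trn = TrainConfig(**raw.pop("training", {}))
        cfg = cls(encoder=enc, training=trn, **raw)
        for name in ("associations", "ontology"):
            p = getattr(cfg, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config {name} path does not exist: {p}")
        return cfg

    def dump(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def write_manifest(path: str | Path, **entries) -> None:
    """Machine-readable run manifest (JSON): config, seed, versions, metrics."""
    import circgat

    manifest = {"circgat_version": circgat.__version__, "numpy_version": np.__version__}
    manifest.update(entries)
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
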