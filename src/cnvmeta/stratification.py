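"""Array-group x ancestry-cluster x sex strata for conditioned comparisons.

Ancestry clusters come from modularity-maximizing (Louvain) community
detection on a k-nearest-neighbour graph of the leading genotype principal
components, so samples of similar genetic background are grouped without
reference to case status. Downstream tests condition on the full
(array group, cluster, sex) combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cnv_data import SampleRecord

__all__ = ["Stratum", "cluster_ancestry", "build_strata", "read_pc_matrix",
           "write_strata", "MIN_PER_ARM", "CASE_FRACTION_BOUNDS"]

MIN_PER_ARM = 5
CASE_FRACTION_BOUNDS = (0.10, 0.90)


@dataclass(frozen=True)
class Stratum:
    """One (array_group, ancestry_cluster, sex) analysis unit."""

    array_group: str
    ancestry_cluster: int
    sex: str
    case_ids: frozenset[str]
    control_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.case_ids & self.control_ids:
            raise ValueError("case and control member sets must be disjoint")

    @property
    def stratum_id(self) -> str:
        return f"{self.array_group}|{self.ancestry_cluster}|{self.sex}"

    @property
    def n_case(self) -> int:
        return len(self.case_ids)

    @property
    def n_control(self) -> int:
        return len(self.control_ids)

    def case_fraction(self) -> float:
        return self.n_case / (self.n_case + self.n_control)


def cluster_ancestry(
    pc_matrix: np.ndarray,
    n_pcs: int = 6,
    knn_k: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Louvain ancestry clusters from the first ``n_pcs`` principal components.

    Builds an unweighted, symmetrized k-nearest-neighbour graph on the PC
    coordinates and partitions it by Louvain modularity maximization.
    Deterministic given ``seed``. Returns integer labels (0-based, relabeled
    by descending cluster size).
    """
    import networkx as nx
    from sklearn.neighbors import kneighbors_graph

    X = np.asarray(pc_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("pc_matrix must be 2-dimensional")
    if X.shape[1] < n_pcs:
        raise ValueError(f"pc_matrix has {X.shape[1]} columns, need >= {n_pcs}")
    n = X.shape[0]
    if n < knn_k + 1:
        raise ValueError(f"need at least knn_k + 1 = {knn_k + 1} samples, got {n}")
    X = X[:, :n_pcs]
    adj = kneighbors_graph(X, n_neighbors=knn_k, mode="connectivity")
    adj = adj.maximum(adj.T)  # mutualize: undirected, unweighted
    G = nx.from_scipy_sparse_array(adj)
    communities = nx.community.louvain_communities(G, seed=int(seed))
    # stable relabeling: by size desc, then smallest member index
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(communities):
        for i in members:
            labels[i] = lab
    return labels


def build_strata(
    samples: Sequence[SampleRecord],
    labels: Sequence[int] | dict[str, int] | None = None,
) -> tuple[list[Stratum], list[str]]:
    """Group samples into strata; apply the minimum-size and balance rules.

    A combination is retained only if it has at least ``MIN_PER_ARM`` cases
    and controls and its case fraction lies in ``CASE_FRACTION_BOUNDS``
    (inclusive). Returns ``(strata, dropped_sample_ids)``; the union of
    stratum members and the dropped list partitions the input.

    ``labels`` overrides ``SampleRecord.ancestry_cluster``: either a
    positional sequence aligned to ``samples`` or a mapping by sample id.
    """
    def label_of(i: int, s: SampleRecord) -> int:
        if labels is None:
            if s.ancestry_cluster is None:
                raise ValueError(f"sample {s.sample_id} has no ancestry cluster label")
            return s.ancestry_cluster
        if isinstance(labels, dict):
            return labels[s.sample_id]
        return int(labels[i])

    groups: dict[tuple[str, int, str], tuple[set[str], set[str]]] = {}
    for i, s in enumerate(samples):
        key = (s.array_group, label_of(i, s), s.sex)
        cases, controls = groups.setdefault(key, (set(), set()))
        (cases if s.is_case else controls).add(s.sample_id)

    strata: list[Stratum] = []
    dropped: list[str] = []
    lo, hi = CASE_FRACTION_BOUNDS
    for key in sorted(groups):
        cases, controls = groups[key]
        n_case, n_control = len(cases), len(controls)
        frac = n_case / (n_case + n_control)
        if n_case >= MIN_PER_ARM and n_control >= MIN_PER_ARM and lo <= frac <= hi:
            strata.append(
                Stratum(
                    array_group=key[0],
                    ancestry_cluster=key[1],
                    sex=key[2],
                    case_ids=frozenset(cases),
                    control_ids=frozenset(controls),
                )
            )
        else:
            dropped.extend(sorted(cases | controls))
    return strata, dropped


def read_pc_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a TSV of sample_id + PC1..PCn; returns (sample_ids, matrix)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "sample_id":
        raise ValueError("first column of the PC matrix must be 'sample_id'")
    ids = df["sample_id"].astype(str).tolist()
    mat = df.iloc[:, 1:].to_numpy(dtype=float)
    return ids, mat


def write_strata(strata: Sequence[Stratum], dropped: Sequence[str],
                 path: str | Path, header_comment: str | None = None) -> None:
    """Write stratum assignments as TSV (dropped samples get stratum '-')."""
    with Path(path).open("w") as fh:
        if header_comment:
            fh.write(header_comment if header_comment.endswith("\n")
                     else header_comment + "\n")
        fh.write("sample_id\tstratum_id\tstatus_arm\n")
        for st in strata:
            for sid in sorted(st.case_ids):
                fh.write(f"{sid}\t{st.stratum_id}\tcase\n")
            for sid in sorted(st.control_ids):
                fh.write(f"{sid}\t{st.stratum_id}\tcontrol\n")
        for sid in dropped:
            fh.write(f"{sid}\t-\tdropped\n")


def read_strata(path: str | Path) -> tuple[list[Stratum], list[str]]:
    """Rebuild strata from a ``write_strata`` TSV; inverse of that writer."""
    groups: dict[str, tuple[set[str], set[str]]] = {}
    dropped: list[str] = []
    lines = [l for l in Path(path).read_text().splitlines()
             if l.strip() and not l.startswith("#")]
    for line in lines[1:]:
        sid, stratum_id, arm = line.split("\t")
        if arm == "dropped":
            dropped.append(sid)
            continue
        cases, controls = groups.setdefault(stratum_id, (set(), set()))
        (cases if arm == "case" else controls).add(sid)
    strata = []
    for stratum_id in sorted(groups):
        array_group, cluster, sex = stratum_id.split("|")
        cases, controls = groups[stratum_id]
        strata.append(Stratum(array_group=array_group,
                              ancestry_cluster=int(cluster), sex=sex,
                              case_ids=frozenset(cases),
                              control_ids=frozenset(controls)))
    return strata, dropped
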