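"""Quantitative evaluation of detected complexes.

Partition-level agreement is scored by entropy-based normalized mutual
information (NMI).  Complex-level agreement against a reference catalogue
uses the Jaccard matching score D and the contingency-table statistics
general sensitivity Sn, general positive predictive value PPV and their
geometric mean Acc.  Topological validation uses the connectivity density of
a module and the module-replacement (shift) experiment.

For two partitions pi_a, pi_b of n nodes with class sizes n_i, n_j and
overlaps n_ij:

    NMI = -2 * sum_ij n_ij * log(n_ij * n / (n_i * n_j))
          / ( sum_i n_i * log(n_i / n) + sum_j n_j * log(n_j / n) )

which is 1 exactly for identical partitions and 0 for independent ones.

For predicted complexes P and reference complexes R, with o_ij the Jaccard
overlap |P_i & R_j| / |P_i | R_j|:

    S = mean_i max_j o_ij        T = mean_j max_i o_ij       D = sqrt(S * T)

and on the contingency table t_ji = |R_j & P_i| with N_j = |R_j| and
column sums T_.i:

    Sn  = sum_j N_j * max_i(t_ji / N_j) / sum_j N_j
    PPV = sum_i T_.i * max_j(t_ji / T_.i) / sum_i T_.i
    Acc = sqrt(Sn * PPV)
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from typing import Hashable, Iterable, NamedTuple, Sequence, Union

import networkx as nx
import numpy as np

from .graph_io import ComplexSet

Partition = Sequence[set]
Complexes = Union[ComplexSet, Sequence[set]]


def _as_sets(obj: Complexes) -> list[set]:
    if isinstance(obj, ComplexSet):
        return [set(c) for c in obj.complexes]
    return [set(c) for c in obj]


def _check_partition(classes: Partition, name: str) -> set:
    universe: set = set()
    for cls in classes:
        if not cls:
            raise ValueError(f"partition {name} contains an empty class")
        if universe & cls:
            raise ValueError(f"partition {name} has overlapping classes")
        universe |= cls
    return universe


def nmi(a: Partition, b: Partition) -> float:
    """Entropy-based normalized mutual information between two partitions.

    Both arguments must partition the same universe.  The degenerate 0/0
    case -- both partitions being the single-class partition -- is defined
    as 1 (they are identical).
    """
    ua = _check_partition(a, "a")
    ub = _check_partition(b, "b")
    if ua != ub:
        raise ValueError("partitions cover different universes")
    n = len(ua)
    numer = 0.0
    for ca in a:
        for cb in b:
            nij = len(ca & cb)
            if nij:
                numer += nij * math.log(nij * n / (len(ca) * len(cb)))
    numer *= -2.0
    denom = sum(len(c) * math.log(len(c) / n) for c in a)
    denom += sum(len(c) * math.log(len(c) / n) for c in b)
    if denom == 0.0:  # both partitions are the one-class partition
        return 1.0
    return numer / denom


@dataclass(frozen=True)
class ContingencyTable:
    """Reference-by-predicted overlap counts t_ji with reference sizes N_j."""

    t: np.ndarray          # shape (m references, n predictions)
    row_sizes: np.ndarray  # N_j = |reference_j|

    @property
    def col_sums(self) -> np.ndarray:
        return self.t.sum(axis=0)


def contingency(pred: Complexes, ref: Complexes) -> ContingencyTable:
    """Full |R| x |P| table of intersection sizes between reference and
    predicted complexes."""
    pred_sets = _as_sets(pred)
    ref_sets = _as_sets(ref)
    if not pred_sets or not ref_sets:
        raise ValueError("need at least one predicted and one reference complex")
    t = np.array(
        [[len(r & p) for p in pred_sets] for r in ref_sets], dtype=np.int64
    )
    return ContingencyTable(t, np.array([len(r) for r in ref_sets], dtype=np.int64))


class MatchingScore(NamedTuple):
    D: float
    S: float
    T: float


def matching_score(pred: Complexes, ref: Complexes) -> MatchingScore:
    """Jaccard matching score D = sqrt(S * T).

    S averages, over predicted complexes, the best Jaccard overlap with any
    reference complex; T is the same in the reference-to-predicted direction.
    """
    pred_sets = _as_sets(pred)
    ref_sets = _as_sets(ref)
    if not pred_sets or not ref_sets:
        raise ValueError("need at least one predicted and one reference complex")
    o = np.array(
        [[len(p & r) / len(p | r) for r in ref_sets] for p in pred_sets]
    )
    s = float(o.max(axis=1).mean())
    t = float(o.max(axis=0).mean())
    return MatchingScore(math.sqrt(s * t), s, t)


class Accuracy(NamedTuple):
    Sn: float
    PPV: float
    Acc: float


def sn_ppv_acc(table: ContingencyTable) -> Accuracy:
    """General sensitivity, PPV and geometric accuracy from a contingency table.

    Predicted complexes sharing no protein with any reference (zero column
    sum) contribute nothing to either aggregate.  An all-zero table leaves
    PPV undefined and raises.
    """
    t = table.t
    nj = table.row_sizes
    if not (nj > 0).any():
        raise ValueError("contingency table has no non-empty reference complex")
    ti = table.col_sums
    if t.sum() == 0:
        raise ValueError("all-zero contingency table: PPV undefined")
    sn = float((t.max(axis=1)).sum() / nj.sum())  # sum_j N_j * (max_i t_ji / N_j)
    live = ti > 0
    ppv = float(t[:, live].max(axis=0).sum() / ti[live].sum())
    return Accuracy(sn, ppv, math.sqrt(sn * ppv))


def connectivity_density(g: nx.Graph, module: Iterable[Hashable]) -> float:
    """Sum of within-module degrees over the total edge count of the network.

    Equals twice the module's internal edge count divided by |E|; the whole
    graph scores exactly 2 by the handshake lemma.
    """
    total_edges = g.number_of_edges()
    if total_edges == 0:
        raise ValueError("connectivity density is undefined on an edgeless graph")
    members = set(module)
    if not members <= set(g):
        raise ValueError("module contains vertices outside the graph")
    internal = sum(1 for u, v in g.edges(members) if u in members and v in members)
    return 2.0 * internal / total_edges


def shift_module(
    g: nx.Graph, module: Iterable[Hashable], fraction: float, seed: int = 0
) -> set:
    """Randomly replace a fraction of a module with adjacent outside proteins.

    ceil(fraction * |module|) uniformly chosen members are removed and the
    same number of uniformly chosen outside vertices -- each interacting with
    at least one remaining member -- are added, so the shifted module keeps
    the original size.  Raises when too few eligible outside neighbors exist.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"fraction must lie strictly in (0,1), got {fraction}")
    members = set(module)
    if not members <= set(g):
        raise ValueError("module contains vertices outside the graph")
    n_swap = math.ceil(fraction * len(members))
    rng = random.Random(seed)
    removed = set(rng.sample(sorted(members, key=str), n_swap))
    kept = members - removed
    eligible = sorted(
        {u for v in kept for u in g.adj[v] if u not in members}, key=str
    )
    if len(eligible) < n_swap:
        raise ValueError(
            f"cannot shift module: need {n_swap} replacements but only "
            f"{len(eligible)} outside neighbors are eligible"
        )
    added = set(rng.sample(eligible, n_swap))
    return kept | added
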