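"""Appraisal of ranked predictions against contact maps.

Every prediction is annotated with the shortest path (SP) between its two
columns on the unweighted, undirected contact graph of a reference
structure: nodes are mapped columns, edges are ALL native contacts
(including local ones) — the graph measures the topology of the structure,
while the sequence-separation filter applies only to the predictions.
SP = 1 is a direct contact (true positive); SP = 2 means the two residues
share a contacting neighbour; large SP flags predictions incompatible with
the conformer, and for a homo-dimer candidate the incompatible set is
tested for interface enrichment with an exact hypergeometric upper tail
(Fisher's exact test null: predictions thrown uniformly at all pairs).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from .msa import Alignment, TaxonWeighting, taxon_weights
from .potts import (
    CouplingScoreMatrix,
    PredictionList,
    apc,
    fit_plm,
    frobenius_scores,
    rank_predictions,
)
from .structures import ContactMap

# SP-class boundaries used in the reports; overridable per call.
SP_NEAR = 2
SP_INCOMPATIBLE = 6
SP_DIMER_SUGGESTIVE = 9


@dataclass
class SPAnnotation:
    """One prediction with its shortest-path appraisal."""

    i: int
    j: int
    score: float
    sp: float  # positive integer, math.inf, or nan when unmapped
    cls: str  # TP | near | mid | incompatible | unmapped


@dataclass
class AnnotationSummary:
    n: int
    tp_count: int
    tp_rate: float
    tp_rate_mapped: float  # alternative counting: mapped predictions only
    n_unmapped: int
    sp_histogram: dict[str, int]


@dataclass
class HypergeomTest:
    """Exact enrichment record: n predictions, k hits, K targets, N pairs."""

    n: int
    k: int
    N: int
    K: int
    P_k: float


@dataclass
class SweepPoint:
    """One eukaryote-weight setting of the taxon sweep."""

    W_E: float
    relative_strength: float
    tp_rate: float
    M_eff: float


def classify_sp(sp: float, near: int = SP_NEAR, incompatible: int = SP_INCOMPATIBLE) -> str:
    if math.isnan(sp):
        return "unmapped"
    if sp == 1:
        return "TP"
    if sp <= near:
        return "near"
    if sp < incompatible:
        return "mid"
    return "incompatible"


def contact_graph(cm: ContactMap) -> nx.Graph:
    """Unweighted graph over mapped columns with one edge per native contact."""
    g = nx.Graph()
    if cm.mapped is not None:
        g.add_nodes_from(np.flatnonzero(cm.mapped).tolist())
    else:
        g.add_nodes_from(range(cm.L))
    ii, jj = np.nonzero(np.triu(cm.contacts, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def shortest_path(cm: ContactMap, pair: tuple[int, int], graph: nx.Graph | None = None) -> float:
    """Breadth-first SP length between two mapped columns; +inf if
    disconnected."""
    i, j = pair
    if not (cm.is_mapped(i) and cm.is_mapped(j)):
        raise ValueError(f"column {i if not cm.is_mapped(i) else j} is unmapped")
    g = graph if graph is not None else contact_graph(cm)
    try:
        return float(nx.shortest_path_length(g, i, j))
    except nx.NetworkXNoPath:
        return math.inf


def annotate(
    preds: PredictionList, cm: ContactMap
) -> tuple[list[SPAnnotation], AnnotationSummary]:
    """Shortest-path annotation of every prediction against one map.

    The TP rate keeps unmapped predictions in the denominator; the
    mapped-only alternative is reported alongside.
    """
    g = contact_graph(cm)
    # one BFS per distinct source column
    sources = sorted({int(i) for i, _j, _s in preds if cm.is_mapped(i)})
    sp_from = {s: nx.single_source_shortest_path_length(g, s) for s in sources}
    annos: list[SPAnnotation] = []
    for i, j, score in preds:
        if not (cm.is_mapped(i) and cm.is_mapped(j)):
            sp = math.nan
        else:
            sp = float(sp_from[i].get(j, math.inf))
        annos.append(SPAnnotation(i=i, j=j, score=score, sp=sp, cls=classify_sp(sp)))
    return annos, summarize(annos)


def summarize(annos: list[SPAnnotation]) -> AnnotationSummary:
    n = len(annos)
    tp = sum(1 for a in annos if a.cls == "TP")
    unmapped = sum(1 for a in annos if a.cls == "unmapped")
    hist: dict[str, int] = {}
    for a in annos:
        if math.isnan(a.sp):
            key = "unmapped"
        elif math.isinf(a.sp):
            key = "inf"
        else:
            key = str(int(a.sp))
        hist[key] = hist.get(key, 0) + 1
    mapped = n - unmapped
    return AnnotationSummary(
        n=n,
        tp_count=tp,
        tp_rate=tp / n if n else 0.0,
        tp_rate_mapped=tp / mapped if mapped else 0.0,
        n_unmapped=unmapped,
        sp_histogram=hist,
    )


def union_sp(annos_a: list[SPAnnotation], annos_b: list[SPAnnotation]) -> list[SPAnnotation]:
    """Per-prediction minimum of two conformers' shortest paths.

    This follows the union definition used for two-state appraisal: the SP
    against the union is the minimum of the per-state SPs (not a BFS on the
    union graph, which can only be shorter or equal).  A prediction
    unmapped in one state takes the other state's value; unmapped in both
    stays unmapped.
    """
    if len(annos_a) != len(annos_b):
        raise ValueError("annotation lists must cover the same predictions")
    out: list[SPAnnotation] = []
    for a, b in zip(annos_a, annos_b):
        if (a.i, a.j) != (b.i, b.j):
            raise ValueError("annotation lists must cover the same predictions in order")
        vals = [v for v in (a.sp, b.sp) if not math.isnan(v)]
        sp = min(vals) if vals else math.nan
        out.append(SPAnnotation(i=a.i, j=a.j, score=a.score, sp=sp, cls=classify_sp(sp)))
    return out


def hypergeom_upper_tail(n: int, k: int, N: int, K: int) -> HypergeomTest:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly.

    The null throws the n predictions uniformly at the N candidate pairs of
    which K belong to the target set; the upper tail is the probability of
    k or more hits by chance.
    """
    if not (0 <= k <= min(n, K) and k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts: n={n}, k={k}, N={N}, K={K}")
    if k == 0:
        p = 1.0
    else:
        # sum the log-pmf upper tail: exact and overflow-safe for N ~ 2e5
        ks = np.arange(k, min(n, K) + 1)
        logs = stats.hypergeom.logpmf(ks, N, K, n)
        p = float(np.exp(logs).sum())
        p = min(p, 1.0)
    return HypergeomTest(n=n, k=k, N=N, K=K, P_k=p)


def dimer_relative_strength(
    scores: CouplingScoreMatrix,
    interface_pairs,
    top_pairs,
) -> float:
    """Mean score over the interface pairs over mean score of the top set.

    Both pair sets are fixed from the reference (unweighted) run when used
    across a weight sweep, so the ratio tracks how the same contacts fare
    as the weighting changes.
    """
    interface_pairs = list(interface_pairs)
    top_pairs = list(top_pairs)
    if not interface_pairs or not top_pairs:
        raise ValueError("pair sets must be non-empty")
    num = float(np.mean([scores.S[i, j] for i, j in interface_pairs]))
    den = float(np.mean([scores.S[i, j] for i, j in top_pairs]))
    return num / den


def weight_sweep(
    aln: Alignment,
    grid,
    interface_pairs,
    reference_map: ContactMap,
    n_top: int,
    min_sep: int = 5,
    lambda_h: float = 0.01,
    lambda_J: float = 0.01,
    tol: float = 1e-5,
    reference_top_pairs=None,
) -> list[SweepPoint]:
    """Refit the Potts model along a grid of eukaryote weight fractions.

    At each W_E: taxon-conditional weights -> pseudo-likelihood fit -> APC
    scores -> top-``n_top`` ranking; the sweep point records the relative
    strength of the fixed ``interface_pairs`` (normalized by the fixed
    reference top set when given, else by that run's own top set) and the
    TP rate of the run's predictions against ``reference_map``.
    """
    points: list[SweepPoint] = []
    for W_E in grid:
        w = taxon_weights(aln, TaxonWeighting(float(W_E)))
        model = fit_plm(aln, w, lambda_h=lambda_h, lambda_J=lambda_J, tol=tol)
        scores = apc(frobenius_scores(model))
        preds = rank_predictions(scores, n_top=n_top, min_sep=min_sep)
        top = reference_top_pairs if reference_top_pairs is not None else [
            (i, j) for i, j, _ in preds
        ]
        strength = dimer_relative_strength(scores, interface_pairs, top)
        _, summary = annotate(preds, reference_map)
        points.append(
            SweepPoint(
                W_E=float(W_E),
                relative_strength=strength,
                tp_rate=summary.tp_rate,
                M_eff=w.M_eff,
            )
        )
    return points


# ---------------------------------------------------------------------------
# report writers


def write_annotations(path, preds: PredictionList, named_annos: dict[str, list[SPAnnotation]],
                      interface_pairs=None) -> None:
    """Per-prediction table: i, j, score, one SP column per map, class of
    the last map, interface flag; tab-separated, 1-based."""
    names = list(named_annos)
    iface = set(tuple(p) for p in (interface_pairs or []))
    with open(path, "w") as fh:
        cols = "\t".join(f"sp_{n}" for n in names)
        fh.write(f"# i\tj\tscore\t{cols}\tclass\tinterface (1-based columns)\n")
        for idx, (i, j, s) in enumerate(preds):
            sps = []
            for n in names:
                v = named_annos[n][idx].sp
                sps.append("unmapped" if math.isnan(v) else ("inf" if math.isinf(v) else str(int(v))))
            cls = named_annos[names[-1]][idx].cls
            flag = "1" if (i, j) in iface else "0"
            fh.write(f"{i + 1}\t{j + 1}\t{s:.6g}\t" + "\t".join(sps) + f"\t{cls}\t{flag}\n")


def write_summary(path, blocks: dict[str, dict]) -> None:
    """Machine-readable key-value summary, one `section.key\tvalue` per line."""
    with open(path, "w") as fh:
        for section, kv in blocks.items():
            for key, value in kv.items():
                fh.write(f"{section}.{key}\t{value}\n")
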