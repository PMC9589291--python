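"""UPGMA clustering of pCREs on 1 - PCC distance, cut at 0.39.

pCREs whose subtrees merge entirely below the cutoff form one cluster
(strictly ``height < cutoff``); the linkage itself comes from scipy's
average-linkage implementation.  Cluster summaries report the fraction of
general / time-point-specific members, the per-time-point median min-max
scaled Gini importance (absent when no member is in that time point's
model), and the fraction of members significantly matching each TF family.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .pwm import kmer_to_pwm
from .similarity import MotifSimilarityResult, pwm_pcc


@dataclass
class PCRECluster:
    cluster_id: int
    members: list[str]
    category_fractions: dict[str, float] = field(default_factory=dict)
    median_scaled_importance: dict[str, float | None] = field(default_factory=dict)
    tfbm_match_fraction: dict[str, float] = field(default_factory=dict)


def distance_matrix(pcres: list[str], min_overlap: int = 5) -> np.ndarray:
    """Symmetric 1 - PCC distance between pCRE one-hot PWMs; zero diagonal."""
    if len(pcres) < 2:
        raise ValueError("need at least 2 pCREs for a distance matrix")
    pwms = [kmer_to_pwm(p) for p in pcres]
    n = len(pwms)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pcc = pwm_pcc(pwms[i], pwms[j], min_overlap=min_overlap).pcc
            d[i, j] = d[j, i] = 1.0 - pcc
    return d


def upgma_linkage(dist: np.ndarray) -> np.ndarray:
    return linkage(squareform(dist, checks=False), method="average")


def upgma_cut(
    dist: np.ndarray,
    cutoff: float = 0.39,
    labels: list[str] | None = None,
) -> list[PCRECluster]:
    """Clusters = maximal subtrees whose merge heights are all < cutoff.

    Deterministic: clusters are numbered (and ordered) by their smallest
    member index.  The strict inequality means a merge at exactly the
    cutoff does NOT join its children.
    """
    n = dist.shape[0]
    labels = labels if labels is not None else [str(i) for i in range(n)]
    if n == 1:
        return [PCRECluster(cluster_id=0, members=[labels[0]])]
    Z = upgma_linkage(dist)
    # union-find over merges below the cutoff
    parent = list(range(n + len(Z)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m, (a, b, height, _) in enumerate(Z):
        node = n + m
        if height < cutoff:
            parent[find(int(a))] = node
            parent[find(int(b))] = node
        else:
            # keep the node itself a root of nothing; children stay separate
            parent[node] = node
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda g: min(g))
    return [
        PCRECluster(cluster_id=cid, members=[labels[i] for i in sorted(g)])
        for cid, g in enumerate(ordered)
    ]


def to_newick(dist: np.ndarray, labels: list[str]) -> str:
    """Newick export of the UPGMA tree (branch lengths from merge heights)."""
    from scipy.cluster.hierarchy import to_tree

    Z = upgma_linkage(dist)
    root = to_tree(Z)

    def rec(node):
        if node.is_leaf():
            return labels[node.id], 0.0
        left, lh = rec(node.left)
        right, rh = rec(node.right)
        h = node.dist / 2.0
        return f"({left}:{h - lh:.6f},{right}:{h - rh:.6f})", h

    text, _ = rec(root)
    return text + ";"


def cluster_summary(
    clusters: list[PCRECluster],
    categories: dict[str, str],
    scaled_importance: dict[str, dict[str, float]],
    matches: dict[str, list[MotifSimilarityResult]] | None = None,
    time_points: tuple[str, ...] | None = None,
) -> list[PCRECluster]:
    """Fill per-cluster category fractions, per-time-point median scaled
    importances and TFBM family match fractions in place.

    ``scaled_importance`` maps time point -> {kmer: scaled Gini} for the
    k-mers used in that time point's model; a time point with no cluster
    member in its model gets importance None (absent).
    """
    tps = time_points if time_points is not None else tuple(scaled_importance)
    for cl in clusters:
        n = len(cl.members)
        cats = [categories.get(m, "non_specific") for m in cl.members]
        cl.category_fractions = {
            c: cats.count(c) / n for c in ("general", "specific", "non_specific")
        }
        cl.median_scaled_importance = {}
        for tp in tps:
            imp = scaled_importance.get(tp, {})
            vals = [imp[m] for m in cl.members if m in imp]
            cl.median_scaled_importance[tp] = (
                float(np.median(vals)) if vals else None
            )
        if matches is not None:
            fams = sorted({
                r.family for res in matches.values() for r in res
            })
            cl.tfbm_match_fraction = {}
            for fam in fams:
                hit = sum(
                    1 for m in cl.members
                    if any(r.family == fam and r.significant
                           for r in matches.get(m, []))
                )
                cl.tfbm_match_fraction[fam] = hit / n
    return clusters
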