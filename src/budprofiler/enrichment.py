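"""Annotation enrichment over the cluster hierarchy.

For every annotation term shared by at least two clustered proteins, the
internal dendrogram node with the most significant hypergeometric
over-representation is found; the sum of these best log10 P-values is the
summary statistic S (more negative = more enrichment).  Its significance
is assessed against topology-preserving nulls: the tree is kept fixed and
the proteins are reassigned to leaves either freely or only within groups
of identical subcellular-localization label sets — the constrained null
asks whether enrichment exceeds what localization alone explains.

All P-values are handled in log10 space; the Bonferroni correction for m
hypotheses adds log10(m).  The universe is the set of clustered proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .clustering import Dendrogram

__all__ = [
    "AnnotationTable",
    "EnrichmentResult",
    "hypergeom_logp",
    "bonferroni_log10",
    "best_cluster_scan",
    "s_statistic",
    "permutation_null_S",
]

_LN10 = np.log(10.0)


@dataclass
class AnnotationTable:
    """Protein -> annotation sets, per namespace, over a fixed universe.

    ``terms`` maps namespace -> term -> set of proteins;
    ``localization`` maps protein -> frozenset of localization labels (for
    the exact-set constrained permutation).  Proteins without annotations
    simply appear in no term set.
    """

    universe: tuple[str, ...]
    terms: dict[str, dict[str, frozenset]] = field(default_factory=dict)
    localization: dict[str, frozenset] = field(default_factory=dict)

    @classmethod
    def from_frames(
        cls,
        universe,
        annotations: pd.DataFrame,
        localization: pd.DataFrame | None = None,
    ) -> "AnnotationTable":
        """Build from long-format frames.

        ``annotations`` columns: protein, namespace, term; ``localization``
        columns: protein, labels (pipe-separated label set).
        """
        universe = tuple(universe)
        uni = set(universe)
        terms: dict[str, dict[str, set]] = {}
        for _, row in annotations.iterrows():
            if row["protein"] not in uni:
                continue
            terms.setdefault(row["namespace"], {}).setdefault(
                row["term"], set()
            ).add(row["protein"])
        frozen = {
            ns: {t: frozenset(m) for t, m in d.items()} for ns, d in terms.items()
        }
        loc: dict[str, frozenset] = {}
        if localization is not None:
            for _, row in localization.iterrows():
                if row["protein"] in uni:
                    loc[row["protein"]] = frozenset(
                        str(row["labels"]).split("|")
                    )
        return cls(universe=universe, terms=frozen, localization=loc)

    def eligible_terms(self, namespace: str, min_support: int = 2):
        """Terms annotated to >= min_support universe proteins."""
        return {
            t: m for t, m in self.terms.get(namespace, {}).items()
            if len(m) >= min_support
        }


def hypergeom_logp(n_universe: int, n_term: int, n_cluster: int, k: int) -> float:
    """log10 P(overlap >= k) under the hypergeometric distribution.

    Drawing ``n_cluster`` proteins from a universe of ``n_universe`` of
    which ``n_term`` carry the annotation; upper-tail probability of
    observing ``k`` or more carriers, computed entirely in log space.
    """
    if not (0 <= k <= min(n_term, n_cluster) <= n_universe):
        raise ValueError(
            f"inconsistent counts N={n_universe} K={n_term} "
            f"n={n_cluster} k={k}"
        )
    if k == 0:
        return 0.0
    kmax = min(n_term, n_cluster)
    ks = np.arange(k, kmax + 1)
    log_pmf = (
        gammaln(n_term + 1)
        - gammaln(ks + 1)
        - gammaln(n_term - ks + 1)
        + gammaln(n_universe - n_term + 1)
        - gammaln(n_cluster - ks + 1)
        - gammaln(n_universe - n_term - n_cluster + ks + 1)
        - gammaln(n_universe + 1)
        + gammaln(n_cluster + 1)
        + gammaln(n_universe - n_cluster + 1)
    )
    return float(min(logsumexp(log_pmf) / _LN10, 0.0))


def bonferroni_log10(m: int) -> float:
    """The log10-scale Bonferroni factor for m hypotheses."""
    if m < 1:
        raise ValueError("need >= 1 hypothesis")
    return float(np.log10(m))


@dataclass
class EnrichmentResult:
    """Best-node enrichment of one term over the hierarchy."""

    term: str
    node: int
    cluster_size: int
    term_size: int
    overlap: int
    universe_size: int
    log10_p: float
    log10_p_bonferroni: float


def _node_membership_matrix(dend: Dendrogram) -> tuple[np.ndarray, list[int]]:
    """(n_internal, n_leaves) boolean membership plus node id list."""
    members = dend.node_members()
    nodes = [nid for nid in dend.internal_nodes() if len(members[nid]) >= 2]
    mat = np.zeros((len(nodes), dend.n_leaves), dtype=bool)
    for row, nid in enumerate(nodes):
        mat[row, list(members[nid])] = True
    return mat, nodes


def best_cluster_scan(
    dend: Dendrogram,
    term: str,
    term_proteins: frozenset,
    n_hypotheses: int = 1,
    leaf_assignment: dict[str, int] | None = None,
) -> EnrichmentResult:
    """Scan every internal node for the smallest enrichment P of one term.

    ``leaf_assignment`` maps protein -> leaf index (default: dendrogram
    leaf names in place).  Ties go to the smaller node id.
    """
    if leaf_assignment is None:
        leaf_assignment = {name: i for i, name in enumerate(dend.leaves)}
    in_term = np.zeros(dend.n_leaves, dtype=bool)
    hits = [leaf_assignment[p] for p in term_proteins if p in leaf_assignment]
    if len(hits) < 2:
        raise ValueError(f"term {term!r} has < 2 proteins in the universe")
    in_term[hits] = True
    mat, nodes = _node_membership_matrix(dend)
    n_uni = dend.n_leaves
    n_term = int(in_term.sum())
    best: EnrichmentResult | None = None
    for row, nid in enumerate(nodes):
        n_clu = int(mat[row].sum())
        k = int((mat[row] & in_term).sum())
        lp = hypergeom_logp(n_uni, n_term, n_clu, k)
        if best is None or lp < best.log10_p:
            best = EnrichmentResult(
                term=term, node=nid, cluster_size=n_clu, term_size=n_term,
                overlap=k, universe_size=n_uni, log10_p=lp,
                log10_p_bonferroni=lp + bonferroni_log10(n_hypotheses),
            )
    return best


def s_statistic(
    dend: Dendrogram,
    family: dict[str, frozenset],
    leaf_assignment: dict[str, int] | None = None,
) -> float:
    """S = sum over eligible terms of the best-cluster log10 P."""
    if leaf_assignment is None:
        leaf_assignment = {name: i for i, name in enumerate(dend.leaves)}
    mat, _ = _node_membership_matrix(dend)
    return _s_from_matrix(mat, dend.n_leaves, family, leaf_assignment)


def _s_from_matrix(
    mat: np.ndarray, n_uni: int, family: dict[str, frozenset],
    leaf_assignment: dict[str, int],
) -> float:
    total = 0.0
    counted = False
    sizes = mat.sum(axis=1)
    mat_int = mat.astype(np.int32)
    for term, proteins in family.items():
        in_term = np.zeros(n_uni, dtype=np.int32)
        hits = [leaf_assignment[p] for p in proteins if p in leaf_assignment]
        if len(hits) < 2:
            continue
        in_term[hits] = 1
        counted = True
        overlaps = mat_int @ in_term
        n_term = int(in_term.sum())
        best = min(
            hypergeom_logp(n_uni, n_term, int(nc), int(k))
            for nc, k in zip(sizes, overlaps)
        )
        total += best
    if not counted:
        raise ValueError("no eligible terms (need >= 2 annotated proteins)")
    return total


def permutation_null_S(
    dend: Dendrogram,
    family: dict[str, frozenset],
    constraint: str = "none",
    localization: dict[str, frozenset] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float, float, np.ndarray]:
    """Topology-preserving permutation null for the S statistic.

    The tree is fixed; the proteins are reassigned to leaves either freely
    (``constraint='none'``) or only within groups sharing an identical
    localization label set (``constraint='localization-set'``).  Returns
    (S_observed, Z, empirical p, null samples); p uses the add-one rule,
    and Z is reported although the null need not be normal.  If every
    constrained group is a singleton the null is degenerate (sd 0, Z nan).
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    leaves = list(dend.leaves)
    base = {name: i for i, name in enumerate(leaves)}
    mat, _ = _node_membership_matrix(dend)
    s_obs = _s_from_matrix(mat, dend.n_leaves, family, base)
    if constraint == "localization-set":
        if localization is None:
            raise ValueError("constrained mode needs localization sets")
        groups: dict[frozenset, list[str]] = {}
        for name in leaves:
            groups.setdefault(localization[name], []).append(name)
        group_lists = list(groups.values())
    elif constraint == "none":
        group_lists = [leaves]
    else:
        raise ValueError(f"unknown constraint {constraint!r}")
    null = np.empty(n_perm)
    for t in range(n_perm):
        assignment = dict(base)
        for members in group_lists:
            if len(members) < 2:
                continue
            shuffled = [members[i] for i in rng.permutation(len(members))]
            for orig, new in zip(members, shuffled):
                assignment[new] = base[orig]
        null[t] = _s_from_matrix(mat, dend.n_leaves, family, assignment)
    sd = float(null.std())
    z = float((s_obs - null.mean()) / sd) if sd > 0 else float("nan")
    p = (int(np.sum(null <= s_obs)) + 1) / (n_perm + 1)
    return s_obs, z, float(p), null
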