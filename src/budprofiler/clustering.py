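"""Maximum-likelihood agglomerative clustering of time profiles.

Each protein's 120-value profile is summarised as a diagonal multivariate
Normal (means and variances from the LOESS).  Two clusters are merged at
the cost of the log-likelihood ratio between modelling them with two
Gaussians versus one pooled Gaussian; with plug-in (moment-matched)
parameters the data-independent constants cancel and the score is

    (n/2) sum_d log s_m,d^2 - (n1/2) sum_d log s_1,d^2 - (n2/2) sum_d log s_2,d^2

which is non-negative and zero only for identical components.  Greedy
minimum-score merging yields the dendrogram; no cluster count needs to be
chosen in advance.  Euclidean and correlation metrics with complete
linkage are offered behind the same interface for robustness checks, and
the Bhattacharyya distance compares class profiles independently of their
member counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage as _scipy_linkage

__all__ = [
    "ClusterProfile",
    "Dendrogram",
    "merge_profiles",
    "ml_merge_score",
    "agglomerate",
    "class_profile",
    "bhattacharyya",
    "group_distance_test",
    "write_treeview",
    "VAR_FLOOR",
]

VAR_FLOOR = 1e-6


@dataclass
class ClusterProfile:
    """Size-weighted diagonal-Gaussian summary of a set of profiles."""

    n: float
    mean: np.ndarray
    var: np.ndarray
    members: tuple = ()

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.var = np.maximum(np.asarray(self.var, dtype=float), VAR_FLOOR)
        if self.mean.shape != self.var.shape:
            raise ValueError("mean and variance dimensions differ")
        if self.n < 1:
            raise ValueError("cluster size must be >= 1")

    @property
    def dim(self) -> int:
        return len(self.mean)


def merge_profiles(c1: ClusterProfile, c2: ClusterProfile) -> ClusterProfile:
    """Moment-matched merge: pooled mean and per-dimension pooled variance.

    The pooled variance includes the between-means term, so merging a
    sequence of clusters equals the one-shot moments of the pooled
    membership (associative up to floating tolerance).
    """
    if c1.dim != c2.dim:
        raise ValueError(f"dimension mismatch: {c1.dim} vs {c2.dim}")
    n = c1.n + c2.n
    mean = (c1.n * c1.mean + c2.n * c2.mean) / n
    second = (
        c1.n * (c1.var + c1.mean**2) + c2.n * (c2.var + c2.mean**2)
    ) / n
    return ClusterProfile(
        n=n, mean=mean, var=second - mean**2,
        members=tuple(c1.members) + tuple(c2.members),
    )


def ml_merge_score(c1: ClusterProfile, c2: ClusterProfile) -> float:
    """Log-likelihood ratio of the two-Gaussian vs the merged model.

    Uses the determinants of the diagonal covariances; >= 0, and 0 iff the
    two components share mean and variance.
    """
    m = merge_profiles(c1, c2)
    return float(
        0.5
        * (
            m.n * np.sum(np.log(m.var))
            - c1.n * np.sum(np.log(c1.var))
            - c2.n * np.sum(np.log(c2.var))
        )
    )


@dataclass
class Dendrogram:
    """Binary merge tree over protein profiles.

    ``merges`` lists (left_node, right_node, score, new_profile) in merge
    order; leaves are nodes 0..n-1, internal node i sits at n + i.
    """

    leaves: list[str]
    merges: list[tuple[int, int, float, ClusterProfile]] = field(
        default_factory=list
    )

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_members(self) -> dict[int, frozenset]:
        """Member leaf-index sets for every node (leaves and internal)."""
        members: dict[int, frozenset] = {
            i: frozenset([i]) for i in range(self.n_leaves)
        }
        for i, (a, b, _, _) in enumerate(self.merges):
            members[self.n_leaves + i] = members[a] | members[b]
        return members

    def internal_nodes(self) -> list[int]:
        return [self.n_leaves + i for i in range(len(self.merges))]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster labels after stopping at k clusters."""
        if not 1 <= k <= self.n_leaves:
            raise ValueError("k out of range")
        parent = list(range(self.n_leaves + len(self.merges)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, (a, b, _, _) in enumerate(self.merges[: self.n_leaves - k]):
            new = self.n_leaves + i
            parent[find(a)] = new
            parent[find(b)] = new
        roots = {find(i) for i in range(self.n_leaves)}
        relabel = {r: j for j, r in enumerate(sorted(roots))}
        return np.array([relabel[find(i)] for i in range(self.n_leaves)])

    def leaf_order(self) -> list[int]:
        """Display order: depth-first with the larger child first."""
        if not self.merges:
            return list(range(self.n_leaves))
        sizes: dict[int, int] = {i: 1 for i in range(self.n_leaves)}
        children: dict[int, tuple[int, int]] = {}
        for i, (a, b, _, _) in enumerate(self.merges):
            node = self.n_leaves + i
            children[node] = (a, b)
            sizes[node] = sizes[a] + sizes[b]
        order: list[int] = []
        stack = [self.n_leaves + len(self.merges) - 1]
        while stack:
            node = stack.pop()
            if node < self.n_leaves:
                order.append(node)
            else:
                a, b = children[node]
                first, second = (a, b) if sizes[a] >= sizes[b] else (b, a)
                stack.extend([second, first])
        return order


def agglomerate(
    profiles: list[ClusterProfile], metric: str = "ml"
) -> Dendrogram:
    """Greedy agglomeration until one cluster remains.

    ``metric``: 'ml' (minimum merge score, ties broken by lowest (i, j)
    node-index pair) or 'euclidean'/'correlation' (complete linkage on the
    mean vectors via scipy).  Deterministic given the input order.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 profiles")
    names = [
        (p.members[0] if len(p.members) == 1 else f"profile{i}")
        for i, p in enumerate(profiles)
    ]
    if metric in ("euclidean", "correlation"):
        x = np.vstack([p.mean for p in profiles])
        z = _scipy_linkage(x, method="complete", metric=metric)
        dend = Dendrogram(leaves=[str(nm) for nm in names])
        node_profiles = {i: p for i, p in enumerate(profiles)}
        for i, (a, b, h, _) in enumerate(z):
            a, b = int(a), int(b)
            merged = merge_profiles(node_profiles[a], node_profiles[b])
            node_profiles[len(profiles) + i] = merged
            dend.merges.append((a, b, float(h), merged))
        return dend
    if metric != "ml":
        raise ValueError(f"unknown metric {metric!r}")
    dend = Dendrogram(leaves=[str(nm) for nm in names])
    active: dict[int, ClusterProfile] = dict(enumerate(profiles))
    scores: dict[tuple[int, int], float] = {}
    ids = sorted(active)
    for i_pos, i in enumerate(ids):
        for j in ids[i_pos + 1:]:
            scores[(i, j)] = ml_merge_score(active[i], active[j])
    next_id = len(profiles)
    while len(active) > 1:
        best = min(scores.items(), key=lambda kv: (kv[1], kv[0]))
        (i, j), score = best
        merged = merge_profiles(active[i], active[j])
        dend.merges.append((i, j, score, merged))
        del active[i], active[j]
        scores = {
            pair: s for pair, s in scores.items()
            if i not in pair and j not in pair
        }
        for k in sorted(active):
            scores[(k, next_id)] = ml_merge_score(active[k], merged)
        active[next_id] = merged
        next_id += 1
    return dend


def class_profile(
    profiles: dict[str, ClusterProfile], label_sets: dict[str, frozenset]
) -> dict[frozenset, ClusterProfile]:
    """Merge proteins sharing an exact localization label set.

    Proteins are grouped by exact set equality ("nucleus" and
    "nucleus AND cytoplasm" are distinct classes); each class profile is
    the merge-fold over its members (order-independent up to tolerance).
    """
    if not profiles:
        raise ValueError("no profiles")
    classes: dict[frozenset, list[str]] = {}
    for pid in profiles:
        key = frozenset(label_sets[pid])
        classes.setdefault(key, []).append(pid)
    out = {}
    for key, pids in classes.items():
        merged = profiles[pids[0]]
        for pid in pids[1:]:
            merged = merge_profiles(merged, profiles[pid])
        out[key] = merged
    return out


def bhattacharyya(c1: ClusterProfile, c2: ClusterProfile) -> float:
    """Bhattacharyya distance between two diagonal Gaussians.

    (1/8) (m1-m2)^T S^-1 (m1-m2) + (1/2) log(det S / sqrt(det S1 det S2))
    with S the averaged covariance; symmetric, 0 iff identical, and
    independent of the member counts.
    """
    if c1.dim != c2.dim:
        raise ValueError("dimension mismatch")
    sbar = 0.5 * (c1.var + c2.var)
    dmu = c1.mean - c2.mean
    term_mean = 0.125 * float(np.sum(dmu**2 / sbar))
    term_cov = 0.5 * float(
        np.sum(np.log(sbar) - 0.5 * (np.log(c1.var) + np.log(c2.var)))
    )
    return term_mean + term_cov


def group_distance_test(
    class_profiles: dict,
    groups: dict[str, list],
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> tuple[float, float, float]:
    """Within- vs between-group mean Bhattacharyya distances.

    Related classes should be closer to each other than to the rest; the
    statistic is (mean within-group distance) - (mean distance from a
    grouped class to all classes outside its group), and the null permutes
    the class-to-group assignment over all classes (preserving group
    sizes).  Returns (mean_within, mean_between, empirical p) with the
    add-one rule; singleton groups contribute no within-distance.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    keys = sorted(class_profiles, key=str)
    index = {k: i for i, k in enumerate(keys)}
    n = len(keys)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = bhattacharyya(class_profiles[keys[i]], class_profiles[keys[j]])
            dmat[i, j] = dmat[j, i] = d
    assignments = [
        [index[m] for m in members] for members in groups.values()
    ]

    def statistic(groups_idx) -> tuple[float, float, float]:
        within, between = [], []
        for members in groups_idx:
            mem = set(members)
            others = [i for i in range(n) if i not in mem]
            for a_pos, a in enumerate(members):
                for b in members[a_pos + 1:]:
                    within.append(dmat[a, b])
                for b in others:
                    between.append(dmat[a, b])
        w = float(np.mean(within)) if within else 0.0
        b = float(np.mean(between)) if between else 0.0
        return w, b, w - b

    obs_w, obs_b, obs = statistic(assignments)
    sizes = [len(m) for m in assignments]
    if exact:
        from itertools import permutations as _perms

        null = []
        for perm in _perms(range(n)):
            pos = 0
            groups_idx = []
            for s in sizes:
                groups_idx.append(list(perm[pos:pos + s]))
                pos += s
            null.append(statistic(groups_idx)[2])
        null = np.asarray(null)
        n_eff = len(null)
    else:
        rng = (
            seed if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        null = np.empty(n_perm)
        for t in range(n_perm):
            perm = rng.permutation(n)
            pos = 0
            groups_idx = []
            for s in sizes:
                groups_idx.append(list(perm[pos:pos + s]))
                pos += s
            null[t] = statistic(groups_idx)[2]
        n_eff = n_perm
    p = (int(np.sum(null <= obs)) + 1) / (n_eff + 1)
    return obs_w, obs_b, float(p)


def write_treeview(
    dend: Dendrogram,
    leaf_profiles: list[ClusterProfile],
    basepath: str,
    column_names: list[str] | None = None,
) -> None:
    """Write Java TreeView-compatible CDT + GTR files.

    ``leaf_profiles`` are the original per-protein profiles in leaf order
    0..n-1 (their mean vectors fill the CDT data block, in display leaf
    order).  The GTR score column is a monotone transform of merge order
    (later merges lower), which TreeView uses only for drawing.
    """
    n = dend.n_leaves
    if len(leaf_profiles) != n:
        raise ValueError("one leaf profile per dendrogram leaf required")
    order = dend.leaf_order()
    ncols = leaf_profiles[0].dim
    cols = column_names or [f"V{j}" for j in range(ncols)]

    def node_name(idx: int) -> str:
        return f"GENE{idx}X" if idx < n else f"NODE{idx - n}X"

    n_merges = max(len(dend.merges), 1)
    with open(f"{basepath}.gtr", "w") as fh:
        for i, (a, b, _score, _) in enumerate(dend.merges):
            level = 1.0 - (i + 1) / n_merges
            fh.write(
                f"{node_name(n + i)}\t{node_name(a)}\t{node_name(b)}\t{level:.6f}\n"
            )
    with open(f"{basepath}.cdt", "w") as fh:
        fh.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(cols) + "\n")
        fh.write("EWEIGHT\t\t\t\t" + "\t".join(["1"] * ncols) + "\n")
        for leaf in order:
            name = dend.leaves[leaf]
            vals = "\t".join(f"{v:.6g}" for v in leaf_profiles[leaf].mean)
            fh.write(f"{node_name(leaf)}\t{name}\t{name}\t1\t{vals}\n")
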