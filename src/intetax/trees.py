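"""Neighbor-joining reconstruction and nonparametric rate smoothing.

The delimitation pipeline needs an ultrametric tree (a chronogram in
relative time) but starts from a phylogram whose branch lengths are
substitutions/site. This module reconstructs the phylogram with
Saitou–Nei neighbor joining from a K2P distance matrix, roots it (outgroup
or midpoint), and converts it to a chronogram by nonparametric rate
smoothing (NPRS): node ages are chosen to minimize the squared change in
substitution rate between adjacent branches, with the root age fixed at an
arbitrary 1.0 and all tips at age 0.
"""

from __future__ import annotations

import numpy as np
import dendropy
from scipy.optimize import minimize

from .distances import DistanceMatrix, LabeledAlignment

__all__ = [
    "neighbor_joining",
    "nprs_smooth",
    "is_ultrametric",
    "collapse_haplotypes",
    "node_ages",
    "patristic_matrix",
]

_EPS_DURATION = 1e-9  # minimum branch duration guarding rate = length/duration


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix, outgroup: str | None = None) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with the standard Q-criterion.

    Negative branch-length estimates are clamped to 0 with the deficit moved
    to the adjacent branch of the same join, so path lengths through the
    join are preserved. The unrooted result is rooted on ``outgroup`` when
    given (splitting its pendant edge in half), else at the midpoint.

    Raises ``ValueError`` naming the offending pair if any distance is
    non-finite or flagged saturated.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    bad = np.argwhere(~np.isfinite(dm.values) | dm.saturated)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-finite/saturated distance between {dm.ids[i]!r} and {dm.ids[j]!r}"
        )

    D = dm.values.astype(float).copy()
    # Each active node is a newick fragment (taxon label or joined subtree).
    nodes: list[str] = [_quote(t) for t in dm.ids]
    active = list(range(n))

    def _join(i: int, j: int, li: float, lj: float) -> str:
        li, lj = _clamp_pair(li, lj)
        return f"({nodes[i]}:{li:.12g},{nodes[j]}:{lj:.12g})"

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        ai, aj = divmod(int(np.argmin(q)), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        lj = dij - li
        newick = _join(i, j, li, lj)
        # distances from the new internal node to every other active node
        new_d = {
            k: 0.5 * (D[i, k] + D[j, k] - dij) for k in active if k not in (i, j)
        }
        nodes[i] = newick
        for k, v in new_d.items():
            D[i, k] = D[k, i] = max(v, 0.0)
        active.remove(j)

    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    newick = f"({nodes[a]}:{la:.12g},{nodes[b]}:{lb:.12g},{nodes[c]}:{lc:.12g});"
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)

    if outgroup is not None:
        og = tree.find_node_with_taxon_label(outgroup)
        if og is None:
            raise ValueError(f"outgroup {outgroup!r} not among taxa")
        elen = og.edge.length or 0.0
        tree.reroot_at_edge(og.edge, length1=elen / 2.0, length2=elen / 2.0,
                            update_bipartitions=True)
    else:
        tree.reroot_at_midpoint(update_bipartitions=True)
    tree.seed_node.edge.length = None
    return tree


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0.0:
        lj += li
        li = 0.0
    if lj < 0.0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def _quote(label: str) -> str:
    if any(c in label for c in " ()[]:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


def drop_taxon(tree: dendropy.Tree, label: str) -> dendropy.Tree:
    """Prune one taxon (e.g. the outgroup before smoothing/GMYC)."""
    out = tree.clone(depth=1)
    taxon = out.taxon_namespace.get_taxon(label)
    if taxon is None:
        raise ValueError(f"taxon {label!r} not in tree")
    out.prune_taxa([taxon], suppress_unifurcations=True)
    out.seed_node.edge.length = None
    return out


def collapse_haplotypes(aln: LabeledAlignment) -> tuple[LabeledAlignment, dict[str, list[str]]]:
    """Collapse identical sequences to unique haplotypes.

    Returns the reduced alignment (first specimen id represents each
    haplotype) and the representative -> member-ids expansion map used to
    lift delimitations back to all specimens.
    """
    seen: dict[str, int] = {}
    reps: list[int] = []
    members: dict[str, list[str]] = {}
    for idx, s in enumerate(aln.seqs):
        if s in seen:
            members[aln.ids[seen[s]]].append(aln.ids[idx])
        else:
            seen[s] = idx
            reps.append(idx)
            members[aln.ids[idx]] = [aln.ids[idx]]
    sub = LabeledAlignment(
        [aln.ids[i] for i in reps], [aln.labels[i] for i in reps], [aln.seqs[i] for i in reps]
    )
    return sub, members


# ---------------------------------------------------------------------------
# Nonparametric rate smoothing
# ---------------------------------------------------------------------------

def nprs_smooth(tree: dendropy.Tree, root_age: float = 1.0) -> dendropy.Tree:
    """Nonparametric rate smoothing to an ultrametric tree.

    Minimizes W = sum over internal nodes of sum over child edges of
    (r_child - r_parent)^2, where r = branch length / branch duration, with
    the root contributing the summed squared deviation of its children's
    rates from their mean. Tips are fixed at age 0 and the root at
    ``root_age``; internal ages are optimized as per-node fractions of the
    parent age (bounded quasi-Newton), which enforces age monotonicity
    along every path. The deterministic starting point sets every node age
    proportional to its maximum path length to a tip, so an already
    clock-like tree is a fixed point.
    """
    if root_age <= 0:
        raise ValueError("root_age must be positive")
    if len(tree.seed_node.child_nodes()) > 2:
        raise ValueError("nprs_smooth requires a rooted (bifurcating-root) tree")
    work = tree.clone(depth=1)
    leaves = work.leaf_nodes()
    if len(leaves) < 2:
        raise ValueError("need at least 2 tips")

    # Stable node ordering: preorder; free variables are internal non-root nodes.
    nodes = list(work.preorder_node_iter())
    index = {id(nd): k for k, nd in enumerate(nodes)}
    free = [nd for nd in nodes if nd is not work.seed_node and not nd.is_leaf()]

    # max path length (in substitutions) from each node down to a tip
    below: dict[int, float] = {}
    for nd in work.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = 0.0
        else:
            below[id(nd)] = max(
                below[id(ch)] + (ch.edge.length or 0.0) for ch in nd.child_nodes()
            )

    def ages_from_fracs(fracs: np.ndarray) -> np.ndarray:
        ages = np.zeros(len(nodes))
        ages[index[id(work.seed_node)]] = root_age
        fi = 0
        for nd in nodes:
            if nd is work.seed_node or nd.is_leaf():
                continue
            parent_age = ages[index[id(nd.parent_node)]]
            ages[index[id(nd)]] = fracs[fi] * parent_age
            fi += 1
        return ages

    def objective(fracs: np.ndarray) -> float:
        ages = ages_from_fracs(fracs)
        rate: dict[int, float] = {}
        for nd in nodes:
            if nd is work.seed_node:
                continue
            dur = ages[index[id(nd.parent_node)]] - ages[index[id(nd)]]
            rate[id(nd)] = (nd.edge.length or 0.0) / max(dur, _EPS_DURATION)
        w = 0.0
        for nd in nodes:
            if nd.is_leaf():
                continue
            child_rates = [rate[id(ch)] for ch in nd.child_nodes()]
            if nd is work.seed_node:
                mu = float(np.mean(child_rates))
                w += sum((rc - mu) ** 2 for rc in child_rates)
            else:
                rp = rate[id(nd)]
                w += sum((rc - rp) ** 2 for rc in child_rates)
        return w

    if free:
        x0 = np.empty(len(free))
        denom_root = max(below[id(work.seed_node)], _EPS_DURATION)
        init_age: dict[int, float] = {id(work.seed_node): root_age}
        fi = 0
        for nd in nodes:
            if nd is work.seed_node or nd.is_leaf():
                continue
            a = root_age * below[id(nd)] / denom_root
            pa = init_age[id(nd.parent_node)]
            frac = a / pa if pa > 0 else 0.5
            frac = min(max(frac, 1e-4), 1.0 - 1e-4)
            init_age[id(nd)] = frac * pa
            x0[fi] = frac
            fi += 1
        f0 = objective(x0)
        res = minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(1e-6, 1.0 - 1e-6)] * len(free),
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 2000},
        )
        x_best = res.x if res.fun <= f0 else x0
    else:
        x_best = np.empty(0)

    ages = ages_from_fracs(x_best)
    work.nprs_objective = float(objective(x_best)) if free else float(objective(np.empty(0)))
    work.nprs_objective_init = float(f0) if free else work.nprs_objective
    for nd in nodes:
        nd.age = 0.0 if nd.is_leaf() else float(ages[index[id(nd)]])
        if nd is not work.seed_node:
            nd.edge.length = float(
                ages[index[id(nd.parent_node)]] - (0.0 if nd.is_leaf() else ages[index[id(nd)]])
            )
    work.seed_node.edge.length = None
    return work


# ---------------------------------------------------------------------------
# Ultrametric utilities
# ---------------------------------------------------------------------------

def _tip_depths(tree: dendropy.Tree) -> list[float]:
    depths = []
    for leaf in tree.leaf_node_iter():
        d, nd = 0.0, leaf
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        depths.append(d)
    return depths


def is_ultrametric(tree: dendropy.Tree, tol: float = 1e-6) -> bool:
    """True iff every root-to-tip path length agrees within ``tol``."""
    depths = _tip_depths(tree)
    return (max(depths) - min(depths)) <= tol


def node_ages(tree: dendropy.Tree) -> dict[int, float]:
    """Node ages (time above the tips) of an ultrametric tree, keyed by id()."""
    root_depth = max(_tip_depths(tree))
    ages: dict[int, float] = {}

    def _walk(nd, depth):
        ages[id(nd)] = max(root_depth - depth, 0.0)
        for ch in nd.child_nodes():
            _walk(ch, depth + (ch.edge.length or 0.0))

    _walk(tree.seed_node, 0.0)
    for leaf in tree.leaf_node_iter():
        ages[id(leaf)] = 0.0
    return ages


def patristic_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    """Pairwise path-length matrix in a caller-supplied taxon order."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out
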