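"""Gene trees, duplication-loss reconciliation, and least-squares dating.

Trees are handled as :mod:`dendropy` objects at the API surface (newick in,
newick out; bootstrap supports stored as internal node labels on a 0-100
scale). Reconciliation works on an immutable internal representation so
that all rootings of the gene tree and all binary resolutions of its
polytomies can be enumerated deterministically.

The tree builder is neighbor joining over p- or Poisson-corrected distances
with a nonparametric bootstrap; large-scale maximum-likelihood inference is
deliberately left to external engines, whose newick output drops into the
same downstream operations.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, List, Optional, Sequence, Tuple

import dendropy
import numpy as np
from scipy.optimize import minimize

INF = float("inf")

# ---------------------------------------------------------------------------
# Configuration and result types
# ---------------------------------------------------------------------------


@dataclass
class PhyloConfig:
    support_collapse_threshold: float = 90.0
    max_polytomy_exhaustive: int = 7
    bootstrap_replicates: int = 100
    distance_model: str = "p"  # "p" or "poisson"
    max_candidate_trees: int = 50_000

    def __post_init__(self) -> None:
        if not (0 <= self.support_collapse_threshold <= 100):
            raise ValueError("support_collapse_threshold must be in [0, 100]")
        if self.distance_model not in ("p", "poisson"):
            raise ValueError("distance_model must be 'p' or 'poisson'")


@dataclass
class ReconciliationResult:
    resolved_gene_tree: str  # newick of the chosen rooted, resolved tree
    chosen_root: str
    events: Dict[str, Tuple[int, int]]  # species node label -> (dups, losses)
    ancestral_counts: Dict[str, int]
    total_duplications: int
    total_losses: int
    leaf_counts: Dict[str, int]

    @property
    def total_cost(self) -> int:
        return self.total_duplications + self.total_losses


def default_species_map(leaf_label: str) -> str:
    """Default gene-leaf -> species mapping: label prefix before first '_'."""
    return leaf_label.split("_", 1)[0]


# ---------------------------------------------------------------------------
# Distances + neighbor joining + bootstrap
# ---------------------------------------------------------------------------


def _as_records(sequences) -> List[Tuple[str, str]]:
    if isinstance(sequences, dict):
        items = list(sequences.items())
    else:
        items = list(sequences)
    labels = [l for l, _ in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    return items


def _pairwise_distance(a: str, b: str, model: str) -> float:
    sites = 0
    diffs = 0
    for x, y in zip(a, b):
        if x in "-." or y in "-.":
            continue
        sites += 1
        if x != y:
            diffs += 1
    p = diffs / sites if sites else 0.0
    if model == "poisson":
        p = min(p, 0.95)
        return -math.log(1.0 - p)
    return p


def distance_matrix(records: Sequence[Tuple[str, str]], model: str = "p") -> np.ndarray:
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pairwise_distance(records[i][1], records[j][1], model)
    return d


def _canonical_child_order(tree: dendropy.Tree) -> None:
    """Sort children by their smallest descendant leaf label, in place.

    dendropy's NJ backend iterates identity-hashed sets, so child order is
    not stable between runs; canonical ordering restores byte-identical
    newick output for identical topologies.
    """

    def rec(nd) -> str:
        if nd.is_leaf():
            return nd.taxon.label if nd.taxon else (nd.label or "")
        keyed = sorted((rec(c), c) for c in nd.child_nodes())
        nd.set_child_nodes([c for _, c in keyed])
        return keyed[0][0]

    rec(tree.seed_node)


def nj_tree(labels: Sequence[str], dmat: np.ndarray) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (dendropy backend)."""
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{v:.10f}" for v in dmat[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(buf, delimiter=",")
    tree = pdm.nj_tree()
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    tree.is_rooted = False
    _canonical_child_order(tree)
    return tree


def _bipartitions(tree: dendropy.Tree, all_labels: frozenset) -> set:
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(all_labels) - 1:
            out.add(min(side, frozenset(all_labels - side), key=sorted))
    return out


def build_gene_tree(
    sequences,
    config: Optional[PhyloConfig] = None,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with nonparametric bootstrap supports on internal nodes.

    ``sequences`` is a mapping (or list of pairs) of label -> aligned
    protein sequence; all sequences must have equal length.
    """
    config = config or PhyloConfig()
    records = _as_records(sequences)
    if len(records) < 4:
        raise ValueError("need at least 4 sequences")
    lens = {len(s) for _, s in records}
    if len(lens) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    aln_len = lens.pop()
    cols = [
        i
        for i in range(aln_len)
        if sum(1 for _, s in records if s[i] not in "-.") >= 2
    ]
    if not cols:
        raise ValueError("alignment length 0 after trimming")
    records = [(l, "".join(s[i] for i in cols)) for l, s in records]
    labels = [l for l, _ in records]
    main = nj_tree(labels, distance_matrix(records, config.distance_model))

    all_labels = frozenset(labels)
    counts: Dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    L = len(cols)
    for _ in range(config.bootstrap_replicates):
        idx = rng.integers(0, L, size=L)
        boot = [(l, "".join(s[i] for i in idx)) for l, s in records]
        bt = nj_tree(labels, distance_matrix(boot, config.distance_model))
        for bp in _bipartitions(bt, all_labels):
            counts[bp] = counts.get(bp, 0) + 1

    for node in main.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if not (1 < len(side) < len(all_labels) - 1):
            continue
        key = min(side, frozenset(all_labels - side), key=sorted)
        support = 100.0 * counts.get(key, 0) / config.bootstrap_replicates
        node.label = f"{support:.0f}"
    return main


def collapse_low_support(tree: dendropy.Tree, threshold: float) -> dendropy.Tree:
    """Contract every internal edge whose support is below ``threshold``.

    Children of a collapsed node are reattached to its parent; the leaf set
    is unchanged and the operation is idempotent.
    """
    out = tree.clone(depth=1)
    to_collapse = []
    for node in out.preorder_internal_node_iter():
        if node.parent_node is None:
            continue
        support = None
        if node.label is not None:
            try:
                support = float(node.label)
            except ValueError:
                support = None
        if support is not None and support < threshold:
            to_collapse.append(node)
    for node in to_collapse:
        node.edge.collapse()
    return out


# ---------------------------------------------------------------------------
# Species tree indexing
# ---------------------------------------------------------------------------


class SpeciesIndex:
    """Rooted binary species tree flattened to parent/children arrays."""

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n = len(nodes)
        self.parent = [-1] * self.n
        self.children: List[Tuple[int, ...]] = [()] * self.n
        self.depth = [0] * self.n
        self.label: List[str] = [""] * self.n
        self.leaf_id: Dict[str, int] = {}
        self.ages: List[Optional[float]] = [None] * self.n
        idx = {id(nd): i for i, nd in enumerate(nodes)}
        for i, nd in enumerate(nodes):
            ch = tuple(idx[id(c)] for c in nd.child_nodes())
            if len(ch) not in (0, 2):
                raise ValueError("species tree must be rooted and binary")
            self.children[i] = ch
            for c in ch:
                self.parent[c] = i
            if nd.is_leaf():
                name = nd.taxon.label if nd.taxon else nd.label
                self.leaf_id[name] = i
                self.label[i] = name
            else:
                leaves = sorted(lf.taxon.label for lf in nd.leaf_iter())
                self.label[i] = nd.label or "+".join(leaves)
            if getattr(nd, "age", None) is not None:
                self.ages[i] = nd.age
        self.root = idx[id(tree.seed_node)]
        stack = [self.root]
        while stack:
            u = stack.pop()
            for c in self.children[u]:
                self.depth[c] = self.depth[u] + 1
                stack.append(c)

    def lca(self, a: int, b: int) -> int:
        while a != b:
            if self.depth[a] < self.depth[b]:
                b = self.parent[b]
            else:
                a = self.parent[a]
        return a

    def sibling(self, a: int) -> int:
        p = self.parent[a]
        c1, c2 = self.children[p]
        return c2 if a == c1 else c1


# ---------------------------------------------------------------------------
# Gene tree internal representation and enumeration
# ---------------------------------------------------------------------------
# leaf: ("leaf", species_id, gene_label); internal: ("node", (child, ...))


def _tree_to_graph(tree: dendropy.Tree, sp: SpeciesIndex, species_map) -> tuple:
    """dendropy tree -> (adjacency dict, payload dict for leaves)."""
    nodes = list(tree.preorder_node_iter())
    ids = {id(nd): i for i, nd in enumerate(nodes)}
    adj: Dict[int, List[int]] = {i: [] for i in range(len(nodes))}
    payload: Dict[int, Tuple[int, str]] = {}
    for nd in nodes:
        i = ids[id(nd)]
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            sp_name = species_map(label)
            if sp_name not in sp.leaf_id:
                raise ValueError(f"gene leaf {label!r}: unknown species {sp_name!r}")
            payload[i] = (sp.leaf_id[sp_name], label)
        if nd.parent_node is not None:
            j = ids[id(nd.parent_node)]
            adj[i].append(j)
            adj[j].append(i)
    return adj, payload


def _orient(adj, payload, node, parent):
    children = [
        _orient(adj, payload, nb, node) for nb in sorted(adj[node]) if nb != parent
    ]
    if not children:
        return ("leaf",) + payload[node]
    if len(children) == 1:
        return children[0]
    return ("node", tuple(children))


def all_rootings(adj, payload) -> List[tuple]:
    """All rooted versions of an unrooted gene tree, canonical edge order."""
    edges = sorted(
        {(min(u, v), max(u, v)) for u, nbs in adj.items() for v in nbs}
    )
    if not edges:
        (only,) = payload.keys()
        return [("leaf",) + payload[only]]
    out = []
    seen = set()
    for u, v in edges:
        left = _orient(adj, payload, u, v)
        right = _orient(adj, payload, v, u)
        rooted = ("node", (left, right))
        key = _canonical_key(rooted)
        if key not in seen:
            seen.add(key)
            out.append(rooted)
    return out


def _canonical_key(t) -> tuple:
    if t[0] == "leaf":
        return ("leaf", t[1], t[2])
    return ("node", tuple(sorted(_canonical_key(c) for c in t[1])))


def _all_binary_shapes(items: List) -> Iterable[tuple]:
    """All rooted binary trees over the given subtrees (order-insensitive)."""
    if len(items) == 1:
        yield items[0]
        return
    first, rest = items[0], items[1:]
    k = len(rest)
    for r in range(0, k):
        for combo in itertools.combinations(range(k), r):
            left_items = [first] + [rest[i] for i in combo]
            right_items = [rest[i] for i in range(k) if i not in combo]
            if not right_items:
                continue
            for lt in _all_binary_shapes(left_items):
                for rt in _all_binary_shapes(right_items):
                    yield ("node", (lt, rt))


def _count_resolutions(t, max_exh: int) -> int:
    if t[0] == "leaf":
        return 1
    k = len(t[1])
    sub = 1
    for c in t[1]:
        sub *= _count_resolutions(c, max_exh)
    dbl_fact = 1
    for i in range(3, 2 * k - 2, 2):
        dbl_fact *= i
    return sub * (dbl_fact if 2 < k <= max_exh else 1)


def _resolutions(t, max_exh: int, sp: SpeciesIndex, greedy_all: bool):
    if t[0] == "leaf":
        yield t
        return
    child_lists = [list(_resolutions(c, max_exh, sp, greedy_all)) for c in t[1]]
    for combo in itertools.product(*child_lists):
        items = list(combo)
        if len(items) <= 2:
            yield ("node", tuple(items)) if len(items) == 2 else items[0]
        elif len(items) <= max_exh and not greedy_all:
            yield from _all_binary_shapes(items)
        else:
            yield _greedy_join(items, sp)


def _subtree_lca(t, sp: SpeciesIndex, cache: dict) -> int:
    key = id(t)
    if key in cache:
        return cache[key]
    if t[0] == "leaf":
        v = t[1]
    else:
        v = None
        for c in t[1]:
            m = _subtree_lca(c, sp, cache)
            v = m if v is None else sp.lca(v, m)
    cache[key] = v
    return v


def _greedy_join(items: List, sp: SpeciesIndex):
    """Stepwise polytomy resolution: join the pair with the deepest LCA."""
    cache: dict = {}
    items = list(items)
    while len(items) > 2:
        best = None
        for a, b in itertools.combinations(range(len(items)), 2):
            l = sp.lca(_subtree_lca(items[a], sp, cache), _subtree_lca(items[b], sp, cache))
            key = (-sp.depth[l], a, b)
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        joined = ("node", (items[a], items[b]))
        items = [x for i, x in enumerate(items) if i not in (a, b)] + [joined]
    return ("node", tuple(items))


# ---------------------------------------------------------------------------
# LCA-mapping reconciliation of a rooted binary gene tree
# ---------------------------------------------------------------------------


def _lca_reconcile_cost(t, sp: SpeciesIndex) -> Tuple[int, int]:
    """(duplications, losses) of the LCA-mapping reconciliation."""
    dups = 0
    losses = 0

    def walk(node) -> int:
        nonlocal dups, losses
        if node[0] == "leaf":
            return node[1]
        ms = [walk(c) for c in node[1]]
        m = sp.lca(ms[0], ms[1])
        is_dup = m in ms
        if is_dup:
            dups += 1
        for mc in ms:
            cur = mc
            while cur != m:
                p = sp.parent[cur]
                if p == m:
                    if is_dup:
                        losses += 1
                    break
                losses += 1
                cur = p
        return m

    m_root = walk(t)
    # the family is presumed present (one copy) at the species root: copies
    # lost on the path from the species root down to the gene-tree root
    losses += sp.depth[m_root]
    return dups, losses


def _lca_reconcile_full(t, sp: SpeciesIndex):
    """Event maps of the LCA reconciliation of a rooted binary gene tree.

    Returns (dup_at_node, loss_at_branch, ancestral_counts, mapping of the
    root). Losses are attributed to the species branch on which the copy
    died (keyed by the child node of that branch); ancestral counts are the
    number of gene copies present at each species node, after the events at
    that node.
    """
    dup_at = [0] * sp.n
    loss_at = [0] * sp.n
    counts = [0] * sp.n
    edges = []  # (m_parent, m_child, parent_is_dup, child_is_dup)
    info: Dict[int, Tuple[int, bool]] = {}  # id(node) -> (mapping, is_dup)

    def walk(node) -> Tuple[int, bool]:
        if node[0] == "leaf":
            info[id(node)] = (node[1], False)
            return node[1], False
        ms = [walk(c) for c in node[1]]
        m = sp.lca(ms[0][0], ms[1][0])
        is_dup = m in (ms[0][0], ms[1][0])
        if is_dup:
            dup_at[m] += 1
        for (mc, c_dup), child in zip(ms, node[1]):
            edges.append((m, mc, is_dup, c_dup))
        info[id(node)] = (m, is_dup)
        return m, is_dup

    m_root, root_is_dup = walk(t)

    def add_path_counts(top, bottom, include_top, include_bottom):
        cur = bottom
        first = True
        while True:
            include = True
            if first and not include_bottom:
                include = False
            if cur == top and not include_top:
                include = False
            if include:
                counts[cur] += 1
            first = False
            if cur == top:
                break
            cur = sp.parent[cur]

    for m, mc, p_dup, c_dup in edges:
        # losses along the embedding path
        cur = mc
        while cur != m:
            p = sp.parent[cur]
            if p == m and not p_dup:
                break
            loss_at[sp.sibling(cur)] += 1
            cur = p
        add_path_counts(m, mc, include_top=p_dup, include_bottom=not c_dup)
    # lineage above the gene-tree root: a single copy up to the species
    # root, with one loss in every sister lineage it passed
    add_path_counts(sp.root, m_root, include_top=True, include_bottom=not root_is_dup)
    cur = m_root
    while cur != sp.root:
        loss_at[sp.sibling(cur)] += 1
        cur = sp.parent[cur]
    return dup_at, loss_at, counts, m_root


# ---------------------------------------------------------------------------
# Public reconciliation entry point
# ---------------------------------------------------------------------------


def _is_rooted_input(gt: dendropy.Tree) -> bool:
    """A gene tree counts as rooted when its root is strictly bifurcating."""
    return len(gt.seed_node.child_nodes()) == 2 or len(gt.leaf_nodes()) <= 2


def _rooted_tuple(gt: dendropy.Tree, sp: SpeciesIndex, species_map):
    def rec(nd):
        if nd.is_leaf():
            label = nd.taxon.label if nd.taxon else nd.label
            sp_name = species_map(label)
            if sp_name not in sp.leaf_id:
                raise ValueError(f"gene leaf {label!r}: unknown species {sp_name!r}")
            return ("leaf", sp.leaf_id[sp_name], label)
        ch = [rec(c) for c in nd.child_nodes()]
        if len(ch) == 1:
            return ch[0]
        return ("node", tuple(ch))

    return rec(gt.seed_node)


def reconcile(
    gene_tree,
    species_tree,
    config: Optional[PhyloConfig] = None,
    species_map: Callable[[str], str] = default_species_map,
    reroot: Optional[bool] = None,
) -> ReconciliationResult:
    """Minimum duplication+loss reconciliation with root/polytomy search.

    For an unrooted gene tree (multifurcating root, the newick convention)
    every rooting is tried and the best-scoring root kept; a strictly
    bifurcating root is respected (``reroot`` overrides either behaviour).
    Polytomies are resolved exhaustively when each has at most
    ``config.max_polytomy_exhaustive`` children (greedy deepest-LCA joining
    otherwise). The reconciliation of each rooted binary candidate is the
    classical LCA mapping; the first candidate attaining the minimal
    duplication+loss cost in canonical enumeration order is returned.
    """
    config = config or PhyloConfig()
    gt = _ensure_tree(gene_tree)
    st = _ensure_tree(species_tree, rooted=True)
    sp = SpeciesIndex(st)
    if reroot is None:
        reroot = not _is_rooted_input(gt)
    if reroot:
        adj, payload = _tree_to_graph(gt, sp, species_map)
        rootings = all_rootings(adj, payload)
    else:
        rootings = [_rooted_tuple(gt, sp, species_map)]

    best = None
    for rooted in rootings:
        greedy_all = (
            _count_resolutions(rooted, config.max_polytomy_exhaustive)
            > config.max_candidate_trees
        )
        for cand in _resolutions(rooted, config.max_polytomy_exhaustive, sp, greedy_all):
            d, l = _lca_reconcile_cost(cand, sp)
            if best is None or d + l < best[0]:
                best = (d + l, cand)
    assert best is not None
    _, winner = best
    dup_at, loss_at, counts, m_root = _lca_reconcile_full(winner, sp)
    events = {
        sp.label[i]: (dup_at[i], loss_at[i])
        for i in range(sp.n)
        if dup_at[i] or loss_at[i]
    }
    leaf_counts: Dict[str, int] = {}

    def count_leaves(node):
        if node[0] == "leaf":
            leaf_counts[sp.label[node[1]]] = leaf_counts.get(sp.label[node[1]], 0) + 1
        else:
            for c in node[1]:
                count_leaves(c)

    count_leaves(winner)
    return ReconciliationResult(
        resolved_gene_tree=_to_newick(winner, sp),
        chosen_root=sp.label[m_root],
        events=events,
        ancestral_counts={sp.label[i]: counts[i] for i in range(sp.n)},
        total_duplications=sum(dup_at),
        total_losses=sum(loss_at),
        leaf_counts=leaf_counts,
    )


def _to_newick(t, sp: SpeciesIndex) -> str:
    """Canonical newick of the internal tuple tree (children ordered by
    their smallest leaf label, so equal topologies print identically)."""

    def rec(node):
        if node[0] == "leaf":
            return node[2], node[2]
        keyed = sorted((key, s) for s, key in (rec(c) for c in node[1]))
        return "(" + ",".join(s for _, s in keyed) + ")", keyed[0][0]

    s, _ = rec(t)
    return s + ";"


def _ensure_tree(tree, rooted: bool = False) -> dendropy.Tree:
    if isinstance(tree, dendropy.Tree):
        return tree
    return dendropy.Tree.get(
        data=tree,
        schema="newick",
        rooting="force-rooted" if rooted else "default-rooted",
        preserve_underscores=True,
    )


# ---------------------------------------------------------------------------
# Independent minimum-cost oracle (dynamic program over mappings)
# ---------------------------------------------------------------------------


def min_event_cost(gene_tree, species_tree, species_map=default_species_map,
                   max_polytomy_exhaustive: int = 7,
                   reroot: Optional[bool] = None) -> int:
    """Minimum duplication+loss cost by explicit optimisation over mappings.

    Independent of the LCA-mapping reconciliation: for every rooting and
    binary resolution, a dynamic program minimises the event cost over all
    feasible gene-node -> species-node mappings. Used to cross-validate
    :func:`reconcile`. Rooting convention matches :func:`reconcile`.
    """
    gt = _ensure_tree(gene_tree)
    st = _ensure_tree(species_tree, rooted=True)
    sp = SpeciesIndex(st)
    if reroot is None:
        reroot = not _is_rooted_input(gt)
    if reroot:
        adj, payload = _tree_to_graph(gt, sp, species_map)
        rootings = all_rootings(adj, payload)
    else:
        rootings = [_rooted_tuple(gt, sp, species_map)]
    best = None
    for rooted in rootings:
        for cand in _resolutions(rooted, max_polytomy_exhaustive, sp, False):
            c = _dp_min_cost(cand, sp)
            if best is None or c < best:
                best = c
    return best


def _dp_min_cost(t, sp: SpeciesIndex) -> int:
    n = sp.n

    def rec(node) -> List[float]:
        # c[s]: min cost with node's lineage mapped exactly at species node s
        if node[0] == "leaf":
            c = [INF] * n
            c[node[1]] = 0.0
            return c
        ch = [rec(x) for x in node[1]]
        ins = [_in_costs(cx, sp) for cx in ch]
        c = [INF] * n
        for s in range(n):
            dup = 1.0 + ins[0][s] + ins[1][s]
            best = dup
            if sp.children[s]:
                l, r = sp.children[s]
                spec = min(ins[0][l] + ins[1][r], ins[0][r] + ins[1][l])
                best = min(best, spec)
            c[s] = best
        return c

    croot = rec(t)
    # family presumed present at the species root: charge the descent
    return int(min(croot[s] + sp.depth[s] for s in range(n)))


def _in_costs(c: List[float], sp: SpeciesIndex) -> List[float]:
    """in[s] = min over s' in subtree(s) of c[s'] + (#edges from s to s')."""
    ins = [INF] * sp.n
    for s in range(sp.n):  # postorder ids: children precede parents
        v = c[s]
        for ch in sp.children[s]:
            v = min(v, ins[ch] + 1.0)
        ins[s] = v
    return ins


# ---------------------------------------------------------------------------
# Least-squares dating
# ---------------------------------------------------------------------------


@dataclass
class CalibrationConstraint:
    taxa: Tuple[str, ...]  # node = MRCA of these leaves
    min_age: float
    max_age: float

    def __post_init__(self) -> None:
        if self.min_age > self.max_age:
            raise ValueError("min_age must be <= max_age")


@dataclass
class DatedTree:
    tree: dendropy.Tree  # branch lengths in Ma, node ages annotated
    rate: float
    objective: float
    ages: Dict[str, float]


class InfeasibleCalibration(ValueError):
    pass


def wls_date_tree(
    tree,
    calibrations: Sequence[CalibrationConstraint],
    tip_date: float = 0.0,
    eps: float = 1e-6,
) -> DatedTree:
    """Weighted least-squares dating under a strict clock.

    Estimates a global substitution rate r and node ages t minimising
    ``sum_b w_b (b_len - r * dt_b)^2`` with ``w_b = 1/(b_len + eps)``,
    subject to parent-older-than-child ordering, tips fixed at ``tip_date``,
    and min/max calibration constraints on MRCA nodes.
    """
    if not calibrations:
        raise ValueError("at least one calibration is required")
    t = _ensure_tree(tree, rooted=True).clone(depth=1)
    nodes = list(t.postorder_node_iter())
    idx = {id(nd): i for i, nd in enumerate(nodes)}
    internal = [i for i, nd in enumerate(nodes) if not nd.is_leaf()]
    var_of = {i: k for k, i in enumerate(internal)}
    nvar = len(internal)

    lo = np.zeros(len(nodes))
    hi = np.full(len(nodes), INF)
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            lo[i] = hi[i] = tip_date
    taxon_node = {
        (nd.taxon.label if nd.taxon else nd.label): i
        for i, nd in enumerate(nodes)
        if nd.is_leaf()
    }
    for cal in calibrations:
        ids = [taxon_node[x] for x in cal.taxa]
        m = ids[0]
        depth = {}
        for i in ids[1:]:
            a, b = nodes[m], nodes[i]
            anc_a = set()
            x = a
            while x is not None:
                anc_a.add(id(x))
                x = x.parent_node
            x = b
            while id(x) not in anc_a:
                x = x.parent_node
            m = idx[id(x)]
        lo[m] = max(lo[m], cal.min_age)
        hi[m] = min(hi[m], cal.max_age)

    # feasibility: propagate child minima up, parent maxima down
    for i, nd in enumerate(nodes):  # postorder: children first
        for c in nd.child_nodes():
            lo[i] = max(lo[i], lo[idx[id(c)]])
    for nd in t.preorder_node_iter():
        i = idx[id(nd)]
        if nd.parent_node is not None:
            hi[i] = min(hi[i], hi[idx[id(nd.parent_node)]])
        if lo[i] > hi[i] + 1e-12:
            raise InfeasibleCalibration(
                f"calibration bounds infeasible at node {i} "
                f"(min {lo[i]} > max {hi[i]})"
            )

    edges = []  # (parent_idx, child_idx, blen, weight)
    for i, nd in enumerate(nodes):
        if nd.parent_node is None:
            continue
        b = nd.edge.length or 0.0
        edges.append((idx[id(nd.parent_node)], i, b, 1.0 / (b + eps)))

    root = idx[id(t.seed_node)]
    # initial ages: node height scaled to a feasible root age
    height = np.zeros(len(nodes))
    for i, nd in enumerate(nodes):
        if not nd.is_leaf():
            height[i] = max(
                height[idx[id(c)]] + (c.edge.length or 0.0) for c in nd.child_nodes()
            )
    root_guess = hi[root] if np.isfinite(hi[root]) else max(lo[root], 1.0) * 2
    root_guess = max(root_guess, lo[root], 1e-3)
    scale = root_guess / height[root] if height[root] > 0 else 1.0

    def age_vec(x):
        ages = np.array(lo)  # leaves fixed
        for i in internal:
            ages[i] = x[var_of[i]]
        return ages

    def objective(x):
        ages = age_vec(x)
        r = x[nvar]
        return sum(w * (b - r * (ages[p] - ages[c])) ** 2 for p, c, b, w in edges)

    cons = []
    for p, c, _, _ in edges:
        if p in var_of:
            if c in var_of:
                cons.append(
                    {
                        "type": "ineq",
                        "fun": (lambda x, a=var_of[p], b=var_of[c]: x[a] - x[b]),
                    }
                )
            else:
                tip_age = lo[c]
                cons.append(
                    {"type": "ineq", "fun": (lambda x, a=var_of[p], ta=tip_age: x[a] - ta)}
                )
    bounds = [
        (max(lo[i], tip_date), None if not np.isfinite(hi[i]) else hi[i])
        for i in internal
    ] + [(1e-12, None)]

    best = None
    for mult in (1.0, 0.5, 2.0):
        x0 = np.empty(nvar + 1)
        for i in internal:
            g = height[i] * scale * mult
            g = min(max(g, lo[i]), hi[i] if np.isfinite(hi[i]) else g)
            x0[var_of[i]] = max(g, tip_date + 1e-9)
        x0[nvar] = max(height[root] / max(x0[var_of[root]], 1e-9), 1e-9)
        res = minimize(
            objective,
            x0,
            method="SLSQP",
            bounds=bounds,
            constraints=cons,
            options={"maxiter": 1000, "ftol": 1e-14},
        )
        if best is None or res.fun < best.fun:
            best = res
    x = best.x
    ages = age_vec(x)
    for i, nd in enumerate(nodes):
        nd.age = float(ages[i])
        if nd.parent_node is not None:
            nd.edge.length = float(ages[idx[id(nd.parent_node)]] - ages[i])
    label_of = {}
    for i, nd in enumerate(nodes):
        if nd.is_leaf():
            label_of[i] = nd.taxon.label if nd.taxon else nd.label
        else:
            label_of[i] = nd.label or "+".join(
                sorted(lf.taxon.label for lf in nd.leaf_iter())
            )
    return DatedTree(
        tree=t,
        rate=float(x[nvar]),
        objective=float(best.fun),
        ages={label_of[i]: float(ages[i]) for i in range(len(nodes))},
    )
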