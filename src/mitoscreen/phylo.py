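"""Gene alignment, distance trees with bootstrap, the vertical-vs-HGT
grouping test, concatenation, and a gene-conversion scan.

The tree engine is Kimura two-parameter distances plus neighbour joining
with column-resampling bootstrap.  The grouping test consumes any tree
carrying bootstrap supports, and ``load_tree`` accepts externally computed
Newick trees (e.g. maximum-likelihood trees from another program), so the
distance engine can be swapped out for full-scale replication.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .io import revcomp  # noqa: F401  (re-exported convenience)
from .simulate import STOP_CODONS, translate

# ---------------------------------------------------------------------------
# alignment containers


@dataclass
class MSA:
    """A multiple sequence alignment (rows of equal length, unique taxa)."""

    taxa: list
    rows: list
    name: str = ""
    partitions: list = field(default_factory=list)   # (name, start, end)
    col_map: list | None = None                      # to pre-mask coordinates

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError("taxa/rows length mismatch")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon names")
        if self.rows and len({len(r) for r in self.rows}) != 1:
            raise ValueError("rows must have equal length")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.taxa.index(taxon)]

    def missing_fraction(self) -> np.ndarray:
        arr = np.array([np.frombuffer(r.encode(), np.uint8)
                        for r in self.rows])
        missing = (arr == ord("-")) | (arr == ord("N")) | (arr == ord("X"))
        return missing.mean(axis=0)


def protein_guided_align(cds_set: dict[str, str], name: str = "") -> MSA:
    """Codon-level MSA guided by the protein alignment.

    Sequences are translated (terminal stop trimmed), the proteins aligned
    (trivially when all proteins are already equal length, otherwise with
    mafft), and each aligned residue replaced by its source codon so gaps
    come in multiples of three.  Sequences with internal stop codons are
    dropped with a warning.
    """
    codons = {}
    prots = {}
    for taxon, cds in cds_set.items():
        cds = cds[: len(cds) - len(cds) % 3]
        if cds[-3:] in STOP_CODONS:
            cds = cds[:-3]
        prot = translate(cds)
        if "*" in prot:
            warnings.warn(f"{taxon}: internal stop codon; sequence dropped")
            continue
        codons[taxon] = [cds[i:i + 3] for i in range(0, len(cds), 3)]
        prots[taxon] = prot
    taxa = list(codons)
    if not taxa:
        raise ValueError("no alignable sequences")
    lens = {len(p) for p in prots.values()}
    if len(lens) == 1:
        aligned = [prots[t] for t in taxa]
    else:
        from .annotate import _mafft_align
        aligned = _mafft_align([prots[t] for t in taxa])
    rows = []
    for t, aln in zip(taxa, aligned):
        src = codons[t]
        i = 0
        parts = []
        for aa in aln:
            if aa == "-":
                parts.append("---")
            else:
                parts.append(src[i])
                i += 1
        rows.append("".join(parts))
    return MSA(taxa=taxa, rows=rows, name=name)


def mask_columns(msa: MSA, max_missing: float = 0.5) -> MSA:
    """Remove columns whose missing (gap/ambiguous) fraction exceeds
    ``max_missing``; the old->new coordinate map is retained."""
    frac = msa.missing_fraction()
    keep = np.nonzero(frac <= max_missing)[0]
    if len(keep) == 0:
        raise ValueError("column masking removed every column")
    rows = ["".join(r[i] for i in keep) for r in msa.rows]
    return MSA(taxa=list(msa.taxa), rows=rows, name=msa.name,
               col_map=[int(i) for i in keep])


def concatenate(msas: list[MSA]) -> MSA:
    """Concatenate gene alignments over a shared taxon namespace.

    A taxon absent from one input gets a gap block of that gene's width;
    the partition map records each gene's column range.
    """
    taxa: list = []
    for m in msas:
        for t in m.taxa:
            if t not in taxa:
                taxa.append(t)
    rows = {t: [] for t in taxa}
    partitions = []
    off = 0
    for m in msas:
        L = m.length
        partitions.append((m.name or f"part{len(partitions) + 1}", off, off + L))
        for t in taxa:
            rows[t].append(m.row(t) if t in m.taxa else "-" * L)
        off += L
    return MSA(taxa=taxa, rows=["".join(rows[t]) for t in taxa],
               name="concatenation", partitions=partitions)


# ---------------------------------------------------------------------------
# K2P distances

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")

SATURATION_CEILING = 5.0


def _encode_rows(rows: list[str]) -> np.ndarray:
    conv = np.full(256, 4, np.int8)
    for i, b in enumerate("ACGT"):
        conv[ord(b)] = i
    return np.stack([conv[np.frombuffer(r.encode(), np.uint8)] for r in rows])


def _pair_types(arr: np.ndarray) -> tuple[np.ndarray, list]:
    """Per-pair per-column codes: 0 same, 1 transition, 2 transversion,
    3 missing (gap/ambiguous in either row)."""
    n = arr.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    purine = (arr == 0) | (arr == 2)
    valid = arr < 4
    T = np.empty((len(pairs), arr.shape[1]), np.int8)
    for k, (i, j) in enumerate(pairs):
        ok = valid[i] & valid[j]
        same = arr[i] == arr[j]
        ts = (~same) & (purine[i] == purine[j])
        row = np.where(same, 0, np.where(ts, 1, 2)).astype(np.int8)
        row[~ok] = 3
        T[k] = row
    return T, pairs


def k2p_from_counts(n_same, n_ts, n_tv):
    """K2P distance from site counts; returns (d, saturated)."""
    n = n_same + n_ts + n_tv
    if n == 0:
        return 0.0, False
    P = n_ts / n
    Q = n_tv / n
    return k2p_from_proportions(P, Q)


def k2p_from_proportions(P: float, Q: float):
    a = 1.0 - 2.0 * P - Q
    b = 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return SATURATION_CEILING, True
    return -0.5 * math.log(a * math.sqrt(b)), False


def k2p_distance(msa: MSA) -> tuple[np.ndarray, list]:
    """Pairwise K2P matrix with pairwise deletion of missing sites.

    Returns (matrix, saturated_pairs); saturated pairs are set to the
    configured ceiling.
    """
    if len(msa.taxa) < 2:
        raise ValueError("need >= 2 taxa")
    arr = _encode_rows(msa.rows)
    T, pairs = _pair_types(arr)
    n = len(msa.taxa)
    D = np.zeros((n, n))
    saturated = []
    for k, (i, j) in enumerate(pairs):
        row = T[k]
        d, sat = k2p_from_counts(int((row == 0).sum()), int((row == 1).sum()),
                                 int((row == 2).sum()))
        D[i, j] = D[j, i] = d
        if sat:
            saturated.append((msa.taxa[i], msa.taxa[j]))
    if saturated:
        warnings.warn(f"{len(saturated)} saturated pair(s) set to ceiling")
    return D, saturated


# ---------------------------------------------------------------------------
# neighbour joining


class TreeNode:
    __slots__ = ("name", "children", "support")

    def __init__(self, name=None, children=None, support=None):
        self.name = name
        self.children = children or []  # list of (TreeNode, branch_length)
        self.support = support

    def leaves(self) -> frozenset:
        if self.name is not None and not self.children:
            return frozenset([self.name])
        out = set()
        for c, _ in self.children:
            out |= c.leaves()
        return frozenset(out)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        label = "" if self.support is None else str(int(self.support))
        return f"({inner}){label}"


@dataclass
class PhyloTree:
    """A (possibly bootstrapped) tree: Newick plus bipartition supports."""

    newick: str
    leaf_names: list
    root: TreeNode | None = None
    supports: dict = field(default_factory=dict)  # frozenset(side) -> percent


def nj_tree(dist: np.ndarray, taxa: list[str]) -> PhyloTree:
    """Neighbour joining with deterministic tie-breaking by taxon order.

    Taxa are canonicalized (sorted) first, so the unrooted topology is
    invariant to input order.  Negative branch lengths are clamped to zero
    with the deficit moved to the sibling branch.
    """
    if len(taxa) < 3:
        raise ValueError("need >= 3 taxa")
    if not np.all(np.isfinite(dist)):
        bad = np.argwhere(~np.isfinite(dist))[0]
        raise ValueError(f"non-finite distance between {taxa[bad[0]]!r} "
                         f"and {taxa[bad[1]]!r}")
    order = sorted(range(len(taxa)), key=lambda i: taxa[i])
    D = dist[np.ix_(order, order)].astype(float).copy()
    nodes = [TreeNode(name=taxa[i]) for i in order]
    root = _nj(D, nodes)
    tree = PhyloTree(newick=root.newick(), leaf_names=sorted(taxa), root=root)
    return tree


def _nj(D: np.ndarray, nodes: list[TreeNode]) -> TreeNode:
    n = len(nodes)
    active = list(range(n))
    D = D.copy()
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i_, j_ = np.unravel_index(np.argmin(Q), Q.shape)
        if i_ > j_:
            i_, j_ = j_, i_
        d_ij = sub[i_, j_]
        li = 0.5 * d_ij + (r[i_] - r[j_]) / (2.0 * (m - 2))
        lj = d_ij - li
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        a, b = active[i_], active[j_]
        parent = TreeNode(children=[(nodes[a], li), (nodes[b], lj)])
        new_d = 0.5 * (D[a, :] + D[b, :] - d_ij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_d
        D[:-1, -1] = new_d
        D[-1, -1] = 0.0
        nodes.append(parent)
        active = [x for x in active if x not in (a, b)] + [len(nodes) - 1]
    a, b, c = active
    d_ab, d_ac, d_bc = D[a, b], D[a, c], D[b, c]
    la = max(0.0, 0.5 * (d_ab + d_ac - d_bc))
    lb = max(0.0, 0.5 * (d_ab + d_bc - d_ac))
    lc = max(0.0, 0.5 * (d_ac + d_bc - d_ab))
    return TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])


def _bipartitions(root: TreeNode, all_leaves: frozenset) -> set:
    """Canonical nontrivial bipartitions (side not containing the reference
    leaf, i.e. the lexicographically smallest label)."""
    ref = min(all_leaves)
    out = set()

    def walk(node):
        if not node.children:
            return frozenset([node.name])
        acc = set()
        for c, _ in node.children:
            acc |= walk(c)
        side = frozenset(acc)
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side if ref not in side else all_leaves - side)
        return side

    walk(root)
    return out


def bootstrap_support(msa: MSA, n_reps: int = 1000, seed: int = 0) -> PhyloTree:
    """Column-resampling bootstrap supports on the K2P/NJ tree.

    Support is the percentage of replicate trees containing each bipartition
    of the full-alignment tree; replicates resample alignment columns with
    replacement (seeded, vectorized through per-pair site-type counts).
    """
    D, _ = k2p_distance(msa)
    tree = nj_tree(D, list(msa.taxa))
    all_leaves = frozenset(msa.taxa)
    main_bips = _bipartitions(tree.root, all_leaves)
    if not main_bips or msa.length == 0:
        tree.supports = {}
        return tree

    order = sorted(range(len(msa.taxa)), key=lambda i: msa.taxa[i])
    taxa = [msa.taxa[i] for i in order]
    arr = _encode_rows([msa.rows[i] for i in order])
    T, pairs = _pair_types(arr)
    A_same = (T == 0).astype(np.float64)
    A_ts = (T == 1).astype(np.float64)
    A_tv = (T == 2).astype(np.float64)
    L = arr.shape[1]
    n = len(taxa)
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 13])
    counts = {b: 0 for b in main_bips}
    for _ in range(n_reps):
        w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(np.float64)
        s = A_same @ w
        ts = A_ts @ w
        tv = A_tv @ w
        D = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            d, _sat = k2p_from_counts(s[k], ts[k], tv[k])
            D[i, j] = D[j, i] = d
        rep_root = _nj(D, [TreeNode(name=t) for t in taxa])
        rep_bips = _bipartitions(rep_root, all_leaves)
        for b in main_bips & rep_bips:
            counts[b] += 1
    tree.supports = {b: round(100.0 * c / n_reps) for b, c in counts.items()}
    _annotate_supports(tree.root, all_leaves, tree.supports)
    tree.newick = tree.root.newick()
    return tree


def _annotate_supports(root, all_leaves, supports):
    ref = min(all_leaves)

    def walk(node):
        if not node.children:
            return frozenset([node.name])
        acc = set()
        for c, _ in node.children:
            acc |= walk(c)
        side = frozenset(acc)
        key = side if ref not in side else all_leaves - side
        if key in supports:
            node.support = supports[key]
        return side

    walk(root)


def load_tree(newick: str) -> PhyloTree:
    """Adapter for externally computed trees (internal labels = supports)."""
    import dendropy
    t = dendropy.Tree.get(data=newick, schema="newick")
    leaves = sorted(l.taxon.label for l in t.leaf_node_iter())
    all_leaves = frozenset(leaves)
    ref = min(all_leaves)
    supports = {}
    root = _from_dendropy(t.seed_node)
    for node in t.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= len(all_leaves) - 2:
            key = side if ref not in side else all_leaves - side
            try:
                supports[key] = int(float(node.label))
            except ValueError:
                pass
    return PhyloTree(newick=newick, leaf_names=leaves, root=root,
                     supports=supports)


def _from_dendropy(dnode) -> TreeNode:
    if dnode.is_leaf():
        return TreeNode(name=dnode.taxon.label)
    support = None
    if dnode.label is not None:
        try:
            support = int(float(dnode.label))
        except ValueError:
            pass
    return TreeNode(children=[(_from_dendropy(c), c.edge.length or 0.0)
                              for c in dnode.child_nodes()],
                    support=support)


# ---------------------------------------------------------------------------
# grouping test


@dataclass
class GroupingVerdict:
    """Vertical / HGT / unresolved call for one gene tree."""

    gene: str
    focal_monophyly_support: int
    sister_clade: str
    sister_support: int
    verdict: str  # vertical | hgt_candidate | unresolved


def _reroot_on_outgroup(root: TreeNode, outgroup: set) -> TreeNode:
    """Reroot on the edge separating the outgroup from everything else.

    Bipartition supports are keyed by canonical leaf sets, so they survive
    rerooting without being carried on nodes.
    """
    adj: dict[TreeNode, list] = {}

    def add(u, v, bl):
        adj.setdefault(u, []).append((v, bl))
        adj.setdefault(v, []).append((u, bl))

    def walk(n):
        for c, bl in n.children:
            add(n, c, bl)
            walk(c)

    walk(root)
    if not adj:
        return root

    def side_leaves(avoid, start):
        out = set()
        stack = [(avoid, start)]
        while stack:
            pu, pv = stack.pop()
            if pv.name is not None and not pv.children:
                out.add(pv.name)
            for w, _ in adj.get(pv, []):
                if w is not pu:
                    stack.append((pv, w))
        return frozenset(out)

    og = frozenset(outgroup)
    target = None
    for u in adj:
        for v, bl in adj[u]:
            if side_leaves(u, v) == og:
                target = (u, v, bl)
                break
        if target:
            break
    if target is None:
        # fall back to the edge above a single outgroup leaf
        for u in adj:
            for v, bl in adj[u]:
                if v.name in og and not v.children:
                    target = (u, v, bl)
                    break
            if target:
                break
    if target is None:
        return root

    def build(node, parent):
        kids = [(build(w, node), bl) for w, bl in adj.get(node, [])
                if w is not parent]
        if not kids:
            return TreeNode(name=node.name)
        return TreeNode(children=kids)

    u, v, bl = target
    return TreeNode(children=[(build(v, u), bl / 2.0),
                              (build(u, v), bl / 2.0)])


def grouping_test(tree: PhyloTree, focal_taxa: set, expected_sister: str,
                  expected_group: dict[str, set] | None = None,
                  threshold: int = 80,
                  outgroup: set | None = None,
                  gene: str = "") -> GroupingVerdict:
    """Decide vertical / hgt_candidate / unresolved for a gene tree.

    Vertical: the focal taxa are monophyletic and either the clade
    (focal + expected_sister) or a supported clade confining the focal taxa
    to the expected group exceeds the bootstrap threshold.  HGT candidate:
    the smallest supported clade above the focal taxa places them inside a
    *different* labelled group.  Anything else is unresolved.
    """
    focal_taxa = set(focal_taxa)
    root = tree.root
    if root is None:
        root = load_tree(tree.newick).root
    leaves = root.leaves()
    if not focal_taxa <= leaves:
        raise ValueError(f"focal taxa missing from tree: "
                         f"{sorted(focal_taxa - leaves)}")
    if outgroup:
        root = _reroot_on_outgroup(root, set(outgroup))

    all_leaves = root.leaves()
    ref = min(all_leaves)

    def support_of(side: frozenset) -> int:
        key = side if ref not in side else all_leaves - side
        return tree.supports.get(key, 0)

    # collect clades (leafsets) of the rooted tree
    clades = []

    def walk(node):
        if not node.children:
            return frozenset([node.name])
        acc = set()
        for c, _ in node.children:
            acc |= walk(c)
        side = frozenset(acc)
        clades.append(side)
        return side

    walk(root)
    clades.sort(key=len)

    focal = frozenset(focal_taxa)
    mono_support = 100
    if len(focal) > 1:
        if focal not in clades:
            return GroupingVerdict(gene, 0, "-", 0, "unresolved")
        mono_support = support_of(focal)

    want = focal | {expected_sister}
    if want in clades or (len(all_leaves) - len(want)) <= 1:
        s = support_of(frozenset(want))
        if s > threshold or (len(all_leaves) - len(want)) <= 1:
            return GroupingVerdict(gene, mono_support, expected_sister,
                                   s, "vertical")

    group_of = expected_group or {}
    home_label = next((lab for lab, members in group_of.items()
                       if expected_sister in members), None)

    # smallest supported clade strictly containing the focal taxa
    for side in clades:
        if not (focal < side):
            continue
        s = support_of(side)
        if s <= threshold:
            continue
        others = side - focal
        if home_label is not None and others <= set(group_of[home_label]):
            return GroupingVerdict(gene, mono_support, home_label, s,
                                   "vertical")
        for lab, members in group_of.items():
            if lab != home_label and others <= set(members):
                return GroupingVerdict(gene, mono_support, lab, s,
                                       "hgt_candidate")
        break  # smallest supported enclosing clade is mixed -> unresolved
    sister_s = support_of(frozenset(want)) if want != all_leaves else 0
    return GroupingVerdict(gene, mono_support, expected_sister, sister_s,
                           "unresolved")


# ---------------------------------------------------------------------------
# gene conversion scan


@lru_cache(maxsize=4096)
def _maxrun_null(n_sites: int, n_mismatch: int, n_perms: int,
                 seed: int) -> np.ndarray:
    """Monte Carlo null of the longest identity run when ``n_mismatch``
    mismatches are placed uniformly among ``n_sites`` polymorphic sites."""
    rng = np.random.default_rng([seed & 0x7FFFFFFF, n_sites, n_mismatch])
    base = np.zeros(n_sites, bool)
    if n_mismatch < n_sites:
        base[:n_mismatch] = True  # True = mismatch
    out = np.empty(n_perms, np.int32)
    idx = np.arange(n_sites)
    keys = rng.random((n_perms, n_sites))
    orders = np.argsort(keys, axis=1)
    mats = base[orders]  # each row a permutation of the mismatch pattern
    match = ~mats
    last_mm = np.where(mats, idx, -1)
    last_mm = np.maximum.accumulate(last_mm, axis=1)
    runlen = np.where(match, idx - last_mm, 0)
    out = runlen.max(axis=1).astype(np.int32)
    return out


def _longest_match_run(match: np.ndarray):
    """(length, start, end) of the longest run of True."""
    best = run = 0
    best_lo = lo = 0
    for i, m in enumerate(match):
        if m:
            if run == 0:
                lo = i
            run += 1
            if run > best:
                best = run
                best_lo = lo
        else:
            run = 0
    return best, best_lo, best_lo + best


def geneconv_scan(msa: MSA, n_perms: int = 10000, seed: int = 0,
                  alpha: float = 0.05) -> list[dict]:
    """Pairwise scan for anomalously long identical fragments.

    Restricted to polymorphic columns; for each taxon pair the statistic is
    the longest run of identity across those columns, its null distribution
    obtained by (seeded) column permutation, and p-values are Bonferroni
    corrected over the number of pairs tested.  Pairs identical across all
    polymorphic columns carry no contrast and are skipped.
    """
    if len(msa.taxa) < 3:
        raise ValueError("need >= 3 taxa")
    arr = _encode_rows(msa.rows)
    valid_states = arr < 4
    poly = []
    for c in range(arr.shape[1]):
        col = arr[valid_states[:, c], c]
        if len(np.unique(col)) > 1:
            poly.append(c)
    if len(poly) < 2:
        warnings.warn("fewer than 2 polymorphic columns; nothing to scan")
        return []
    poly = np.array(poly)
    sub = arr[:, poly]
    vs = valid_states[:, poly]
    n = len(msa.taxa)
    results = []
    tested = 0
    stats = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = vs[i] & vs[j]
            if ok.sum() < 2:
                continue
            match = (sub[i] == sub[j]) & ok
            mism = int((~match & ok).sum())
            if mism == 0:
                continue  # no polymorphic contrast within the pair
            tested += 1
            obs, lo, hi = _longest_match_run(match)
            stats.append((i, j, obs, lo, hi, int(ok.sum()), mism))
    for i, j, obs, lo, hi, nsites, mism in stats:
        null = _maxrun_null(nsites, mism, n_perms, seed)
        p = (1.0 + int((null >= obs).sum())) / (n_perms + 1.0)
        p_adj = min(1.0, p * tested)
        if p_adj < alpha:
            results.append({
                "pair": (msa.taxa[i], msa.taxa[j]),
                "fragment": (int(poly[lo]), int(poly[hi - 1]) + 1),
                "score": obs,
                "p_value": p_adj,
            })
    results.sort(key=lambda r: r["p_value"])
    return results
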