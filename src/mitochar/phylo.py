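"""Desk-scale phylogenetics: supermatrix concatenation, K2P, NJ, bootstrap.

A supermatrix is the column-wise concatenation of per-gene alignments with
a partition map; absent taxon x gene cells are gap-filled.  Distances are
Kimura two-parameter, d = -1/2 ln((1-2P-Q) sqrt(1-2Q)) with P/Q the
transition/transversion proportions.  Trees come from Saitou-Nei
neighbor-joining with a deterministic lexicographic tie-break, and clade
support from nonparametric bootstrap resampling of supermatrix columns.
Robinson-Foulds distances and monophyly checks are delegated to dendropy.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, sqrt

import dendropy
import numpy as np
from dendropy.calculate import treecompare

GAP_CHARS = set("-?Nn.")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """Distances outside the log domain of the K2P correction."""


# ---------------------------------------------------------------------------
# supermatrix
# ---------------------------------------------------------------------------


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]  # gene -> half-open column interval

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def partition_text(self) -> str:
        """RAxML-style partition file ("DNA, gene = start-end", 1-based)."""
        lines = [
            f"DNA, {gene} = {lo + 1}-{hi}" for gene, (lo, hi) in self.partitions.items()
        ]
        return "\n".join(lines) + "\n"


def concatenate(
    alignments: dict[str, dict[str, str]], gene_order: list[str] | None = None
) -> Supermatrix:
    """Concatenate per-gene alignments into a partitioned supermatrix.

    Genes follow ``gene_order`` (default: sorted names) so shuffled input
    produces an identical matrix.  Missing taxon x gene cells become gaps.
    """
    genes = gene_order if gene_order is not None else sorted(alignments)
    taxa: list[str] = []
    for gene in genes:
        for taxon in alignments[gene]:
            norm = taxon.strip()
            if norm != taxon and norm in alignments[gene]:
                raise ValueError(f"taxon label collision after normalization: {taxon!r}")
            if norm not in taxa:
                taxa.append(norm)
    taxa = sorted(taxa)
    partitions: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    offset = 0
    for gene in genes:
        aln = {k.strip(): v for k, v in alignments[gene].items()}
        lengths = {len(v) for v in aln.values()}
        if len(lengths) > 1:
            raise ValueError(f"{gene}: unequal sequence lengths {sorted(lengths)}")
        glen = lengths.pop() if lengths else 0
        partitions[gene] = (offset, offset + glen)
        offset += glen
        for t in taxa:
            chunks[t].append(aln.get(t, "-" * glen).upper())
    return Supermatrix(taxa=taxa, rows={t: "".join(chunks[t]) for t in taxa},
                       partitions=partitions)


def mask_gappy_columns(sm: Supermatrix, max_gap_frac: float = 0.5) -> Supermatrix:
    """Drop columns with more than ``max_gap_frac`` gap/ambiguous cells."""
    arr = np.array([list(sm.rows[t]) for t in sm.taxa])
    is_gap = np.isin(arr, list(GAP_CHARS))
    keep = is_gap.mean(axis=0) <= max_gap_frac
    keep_idx = np.where(keep)[0]
    rows = {t: "".join(arr[i, keep_idx]) for i, t in enumerate(sm.taxa)}
    # partitions are remapped to the surviving columns of each gene
    new_parts: dict[str, tuple[int, int]] = {}
    pos = 0
    for gene, (lo, hi) in sm.partitions.items():
        n_kept = int(keep[lo:hi].sum())
        new_parts[gene] = (pos, pos + n_kept)
        pos += n_kept
    return Supermatrix(taxa=list(sm.taxa), rows=rows, partitions=new_parts)


# ---------------------------------------------------------------------------
# K2P distances
# ---------------------------------------------------------------------------


def _k2p_from_counts(n_same: float, n_ts: float, n_tv: float) -> float:
    n = n_same + n_ts + n_tv
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = n_ts / n, n_tv / n
    w1, w2 = 1 - 2 * P - Q, 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(f"K2P log-domain violation (P={P:.3f}, Q={Q:.3f})")
    return -0.5 * log(w1 * sqrt(w2))


def k2p_distance(row_a: str, row_b: str) -> float:
    """K2P substitutions/site between two aligned rows (gaps dropped pairwise)."""
    same = ts = tv = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a in GAP_CHARS or b in GAP_CHARS or a not in "ACGT" or b not in "ACGT":
            continue
        if a == b:
            same += 1
        elif {a, b} <= _PURINES or {a, b} <= _PYRIMIDINES:
            ts += 1
        else:
            tv += 1
    return _k2p_from_counts(same, ts, tv)


def p_distance(row_a: str, row_b: str) -> float:
    same = diff = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        if a not in "ACGT" or b not in "ACGT":
            continue
        if a == b:
            same += 1
        else:
            diff += 1
    return diff / (same + diff)


def _pair_codes(sm: Supermatrix) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Per-pair per-column class codes: 0 unusable, 1 identical, 2 ts, 3 tv."""
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    arrs = []
    for t in sm.taxa:
        arrs.append(np.array([enc.get(c, -1) for c in sm.rows[t]], dtype=np.int8))
    pairs = [(i, j) for i in range(len(sm.taxa)) for j in range(i + 1, len(sm.taxa))]
    codes = np.zeros((len(pairs), sm.n_columns), dtype=np.uint8)
    purine = np.array([True, False, True, False])
    for p, (i, j) in enumerate(pairs):
        a, b = arrs[i], arrs[j]
        valid = (a >= 0) & (b >= 0)
        same = valid & (a == b)
        ts = valid & ~same & (purine[np.clip(a, 0, 3)] == purine[np.clip(b, 0, 3)])
        codes[p][same] = 1
        codes[p][ts] = 2
        codes[p][valid & ~same & ~ts] = 3
    return pairs, codes


def k2p_matrix(sm: Supermatrix) -> np.ndarray:
    pairs, codes = _pair_codes(sm)
    n = len(sm.taxa)
    d = np.zeros((n, n))
    for p, (i, j) in enumerate(pairs):
        counts = np.bincount(codes[p], minlength=4)
        d[i, j] = d[j, i] = _k2p_from_counts(counts[1], counts[2], counts[3])
    return d


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj(names: list[str], dist: np.ndarray) -> dendropy.Tree:
    """Saitou-Nei neighbor-joining; ties broken by lexicographic taxon pairs.

    Returns an unrooted dendropy tree (trifurcating root for n >= 3).
    Negative branch-length estimates are clamped to zero.
    """
    n = len(names)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    if n < 2:
        raise ValueError("need at least 2 taxa")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    # each cluster: (newick fragment, smallest leaf label for tie-breaking)
    nodes = [(name, name) for name in names]
    d = dist.astype(float).copy()

    def join_pair(i, j, li, lj):
        frag = f"({nodes[i][0]}:{max(li, 0.0):.10f},{nodes[j][0]}:{max(lj, 0.0):.10f})"
        return (frag, min(nodes[i][1], nodes[j][1]))

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        candidates = [
            (i, j)
            for i in range(m)
            for j in range(i + 1, m)
            if q[i, j] <= qmin + 1e-12
        ]
        i, j = min(candidates, key=lambda ij: tuple(sorted((nodes[ij[0]][1], nodes[ij[1]][1]))))
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        new_node = join_pair(i, j, li, lj)
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        d2 = np.zeros((m - 1, m - 1))
        d2[:-1, :-1] = d[np.ix_(keep, keep)]
        d2[-1, :-1] = d2[:-1, -1] = new_d[keep]
        nodes = [nodes[k] for k in keep] + [new_node]
        d = d2

    if len(nodes) == 3:
        v0 = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        v1 = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        v2 = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        newick = (
            f"({nodes[0][0]}:{max(v0, 0.0):.10f},{nodes[1][0]}:{max(v1, 0.0):.10f},"
            f"{nodes[2][0]}:{max(v2, 0.0):.10f});"
        )
    else:  # exactly 2
        newick = f"({nodes[0][0]}:{d[0, 1] / 2:.10f},{nodes[1][0]}:{d[0, 1] / 2:.10f});"
    return dendropy.Tree.get(data=newick, schema="newick")


def nj_from_supermatrix(sm: Supermatrix) -> dendropy.Tree:
    return nj(sm.taxa, k2p_matrix(sm))


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def _bipartitions(tree: dendropy.Tree, ns: dendropy.TaxonNamespace) -> set[int]:
    """Non-trivial bipartition bitmasks of an unrooted tree."""
    t = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick",
                          taxon_namespace=ns)
    t.encode_bipartitions()
    n_taxa = len(ns)
    full = (1 << n_taxa) - 1
    out = set()
    for bp in t.bipartition_encoding:
        mask = bp.split_bitmask
        lo = min(mask, full ^ mask)
        size = bin(lo).count("1")
        if 2 <= size <= n_taxa - 2:
            out.add(lo)
    return out


def bootstrap(
    sm: Supermatrix, B: int = 1000, seed: int = 0, per_partition: bool = False
) -> tuple[dendropy.Tree, dict[int, float]]:
    """NJ tree with bootstrap support from column resampling.

    Columns are resampled with replacement across the whole matrix (or
    within each partition when ``per_partition``).  Support on each internal
    edge of the full-matrix tree is the percentage of replicate trees that
    contain its bipartition; it is written into the node labels.
    """
    rng = np.random.default_rng(seed)
    pairs, codes = _pair_codes(sm)
    ncols = sm.n_columns
    n = len(sm.taxa)

    def tree_from_weights(w: np.ndarray) -> dendropy.Tree:
        d = np.zeros((n, n))
        for p, (i, j) in enumerate(pairs):
            counts = np.bincount(codes[p], weights=w, minlength=4)
            d[i, j] = d[j, i] = _k2p_from_counts(counts[1], counts[2], counts[3])
        return nj(sm.taxa, d)

    main_tree = tree_from_weights(np.ones(ncols))
    ns = dendropy.TaxonNamespace(sm.taxa)
    main_bips = _bipartitions(main_tree, ns)
    hits = {bp: 0 for bp in main_bips}
    n_ok = 0
    for _ in range(B):
        if per_partition:
            w = np.zeros(ncols)
            for lo, hi in sm.partitions.values():
                if hi > lo:
                    idx = rng.integers(lo, hi, hi - lo)
                    w += np.bincount(idx, minlength=ncols)
        else:
            idx = rng.integers(0, ncols, ncols)
            w = np.bincount(idx, minlength=ncols).astype(float)
        try:
            rep = tree_from_weights(w)
        except (SaturationError, ValueError):
            continue
        n_ok += 1
        rep_bips = _bipartitions(rep, ns)
        for bp in main_bips:
            if bp in rep_bips:
                hits[bp] += 1
    support = {bp: (100.0 * c / n_ok if n_ok else 0.0) for bp, c in hits.items()}
    _annotate_support(main_tree, ns, support)
    return main_tree, support


def _annotate_support(tree: dendropy.Tree, ns: dendropy.TaxonNamespace,
                      support: dict[int, float]) -> None:
    labels = {t.label: 1 << i for i, t in enumerate(ns)}
    full = (1 << len(ns)) - 1
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        mask = 0
        for leaf in node.leaf_iter():
            mask |= labels[leaf.taxon.label]
        key = min(mask, full ^ mask)
        if key in support:
            node.label = f"{support[key]:.0f}"


# ---------------------------------------------------------------------------
# tree comparison
# ---------------------------------------------------------------------------


def _as_trees(t1, t2) -> tuple[dendropy.Tree, dendropy.Tree]:
    ns = dendropy.TaxonNamespace()
    def conv(t):
        s = t if isinstance(t, str) else t.as_string(schema="newick")
        return dendropy.Tree.get(data=s, schema="newick", taxon_namespace=ns)
    return conv(t1), conv(t2)


def rf_distance(t1, t2) -> int:
    """Unrooted Robinson-Foulds bipartition count between two trees."""
    a, b = _as_trees(t1, t2)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))


def is_monophyletic(tree, taxa, outgroup: str) -> bool:
    """Do ``taxa`` form a clade after rooting on ``outgroup``?"""
    t = tree if isinstance(tree, dendropy.Tree) else dendropy.Tree.get(
        data=str(tree), schema="newick")
    og = [leaf for leaf in t.leaf_node_iter() if leaf.taxon.label == outgroup]
    if not og:
        raise ValueError(f"outgroup {outgroup} not in tree")
    t.to_outgroup_position(og[0], update_bipartitions=False)
    t.is_rooted = True
    target = set(taxa)
    mrca = t.mrca(taxon_labels=sorted(target))
    clade = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    return clade == target


def ts_tv_table(sm: Supermatrix) -> list[dict]:
    """Transition/transversion proportions vs distance, for saturation inspection."""
    pairs, codes = _pair_codes(sm)
    rows = []
    for p, (i, j) in enumerate(pairs):
        counts = np.bincount(codes[p], minlength=4)
        n = counts[1:].sum()
        if n == 0:
            continue
        row = {
            "taxon_a": sm.taxa[i],
            "taxon_b": sm.taxa[j],
            "P_transition": counts[2] / n,
            "Q_transversion": counts[3] / n,
        }
        try:
            row["k2p"] = _k2p_from_counts(counts[1], counts[2], counts[3])
        except SaturationError:
            row["k2p"] = float("nan")
        rows.append(row)
    return rows
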