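"""Synthetic inputs: annotated mitogenomes, evolved alignments, rearranged orders.

Every generator is a pure function of its spec and seed.  Generation logs
carry the injected ground truth (start/stop codons, event lists, the true
tree) for test consumption; the analysis pipeline never reads them.

Composition targeting
---------------------
Partition composition is measured on pooled *sense-strand* sequence while
the whole-genome row is measured on the reference strand, so a genome whose
genes sit on both strands cannot satisfy both kinds of target with a single
per-partition nucleotide distribution.  The generator therefore solves a
small linear program for one composition per (partition, strand) class plus
the non-coding class, constrained so that (a) the length-weighted mixture of
each partition's classes equals the partition target, (b) reference-strand
totals equal the whole-genome target, and (c) every class is a probability
vector; the objective minimizes the largest departure of any class from its
partition target (mimicking real mitogenomes, where strand asymmetry is
spread over both strands).  Integer base counts are then allocated by
largest remainder and laid down by seeded shuffling, which pins every
partition to its target to within a few nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import exp

import numpy as np
from scipy.optimize import linprog

from .codon_usage import DEFAULT_CODE, genetic_code, translate_codon
from .generearrange import GeneOrder, SignedGene
from .records_io import GeneFeature, GenomeRecord, revcomp

BASES = ("A", "C", "G", "T")
_COMPLEMENT_PERM = np.array(
    [[0, 0, 0, 1], [0, 0, 1, 0], [0, 1, 0, 0], [1, 0, 0, 0]], dtype=float
)


class InfeasibleSpecError(ValueError):
    """Composition targets unreachable at the given partition lengths."""


@dataclass
class TemplateEntry:
    symbol: str
    category: str  # PCG / tRNA / rRNA / NCR
    length: int
    strand: str = "H"
    start_codon: str | None = None
    stop_codon: str | None = None  # TAA / TAG / T-- / TA-


@dataclass
class GenomeSpec:
    id: str
    template: list[TemplateEntry]
    composition: dict[str, dict[str, float]]  # partition -> base -> fraction
    circular: bool = True
    seed: int | None = None

    @property
    def length(self) -> int:
        return sum(e.length for e in self.template)


@dataclass
class EvolutionSpec:
    tree: str  # newick with branch lengths (expected substitutions/site)
    n_sites: int
    ts_tv_ratio: float = 2.0
    mode: str = "nt"  # "nt" or "cds"
    omega: float | None = None  # dN/dS acceptance probability in cds mode
    root_seq: str | None = None
    code_id: int = DEFAULT_CODE
    seed: int | None = None


# ---------------------------------------------------------------------------
# composition solving
# ---------------------------------------------------------------------------


def _normalize(target: dict[str, float]) -> np.ndarray:
    v = np.array([target[b] for b in BASES], dtype=float)
    if (v < 0).any() or v.sum() <= 0:
        raise InfeasibleSpecError(f"bad composition target {target}")
    return v / v.sum()


def _solve_class_compositions(
    class_lengths: dict[tuple[str, str], int],
    targets: dict[str, np.ndarray],
    ncr_length: int,
    whole: np.ndarray | None,
    total_length: int,
) -> tuple[dict[tuple[str, str], np.ndarray], np.ndarray]:
    """Per-(partition, strand) compositions + NCR composition via linprog."""
    classes = sorted(class_lengths)
    nv = 4 * len(classes) + 4 + 1  # class comps, NCR comp, max-deviation t
    i_ncr = 4 * len(classes)
    i_t = nv - 1

    A_eq, b_eq = [], []
    # (a) pooled mixture of each partition's strand classes equals its target
    for part in sorted({c[0] for c in classes}):
        part_len = sum(class_lengths[c] for c in classes if c[0] == part)
        for b in range(4):
            row = np.zeros(nv)
            for ci, c in enumerate(classes):
                if c[0] == part:
                    row[4 * ci + b] = class_lengths[c] / part_len
            A_eq.append(row)
            b_eq.append(targets[part][b])
    # probability vectors
    for ci in range(len(classes)):
        row = np.zeros(nv)
        row[4 * ci : 4 * ci + 4] = 1
        A_eq.append(row)
        b_eq.append(1.0)
    row = np.zeros(nv)
    row[i_ncr : i_ncr + 4] = 1
    A_eq.append(row)
    b_eq.append(1.0)
    # (b) reference-strand totals equal the whole-genome target
    if whole is not None:
        for b in range(4):
            row = np.zeros(nv)
            for ci, c in enumerate(classes):
                w = class_lengths[c] / total_length
                if c[1] == "H":
                    row[4 * ci + b] = w
                else:  # L-strand sense counts appear complemented on reference
                    row[4 * ci : 4 * ci + 4] += w * _COMPLEMENT_PERM[b]
            row[i_ncr + b] = ncr_length / total_length
            A_eq.append(row)
            b_eq.append(whole[b])

    # objective: minimize max deviation of any class from its partition target
    A_ub, b_ub = [], []
    anchors = [targets[c[0]] for c in classes] + [
        whole if whole is not None else np.full(4, 0.25)
    ]
    offsets = [4 * ci for ci in range(len(classes))] + [i_ncr]
    for off, anchor in zip(offsets, anchors):
        for b in range(4):
            up = np.zeros(nv)
            up[off + b] = 1
            up[i_t] = -1
            A_ub.append(up)
            b_ub.append(anchor[b])
            dn = np.zeros(nv)
            dn[off + b] = -1
            dn[i_t] = -1
            A_ub.append(dn)
            b_ub.append(-anchor[b])
    c = np.zeros(nv)
    c[i_t] = 1
    res = linprog(
        c,
        A_ub=np.array(A_ub),
        b_ub=np.array(b_ub),
        A_eq=np.array(A_eq),
        b_eq=np.array(b_eq),
        bounds=[(0, 1)] * (nv - 1) + [(0, None)],
        method="highs",
    )
    if not res.success:
        raise InfeasibleSpecError(
            "composition targets unreachable at the given lengths: " + res.message
        )
    x = res.x
    comps = {c_: x[4 * ci : 4 * ci + 4].clip(0) for ci, c_ in enumerate(classes)}
    return comps, x[i_ncr : i_ncr + 4].clip(0)


def _largest_remainder(fracs: np.ndarray, total: int) -> np.ndarray:
    fracs = np.clip(fracs, 0, None)
    fracs = fracs / fracs.sum() if fracs.sum() else np.full(4, 0.25)
    raw = fracs * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:short]] += 1
    return counts


def _subtract_fixed(counts: np.ndarray, fixed: np.ndarray) -> np.ndarray:
    free = counts - fixed
    if (free < 0).any():
        deficit = -free[free < 0].sum()
        free = free.clip(0)
        while deficit > 0:
            i = int(np.argmax(free))
            take = min(deficit, free[i])
            free[i] -= take
            deficit -= take
    return free


def _base_counts(s: str) -> np.ndarray:
    return np.array([s.count(b) for b in BASES])


def _split_codon_positions(free_counts: np.ndarray) -> list[np.ndarray] | None:
    """Split a PCG class's free-position counts into per-codon-position counts.

    Third positions absorb the A-over-T share of the class composition
    (synonymous freedom lets A+T bias concentrate there, which is what makes
    TTA the top codon of AT-rich mitogenomes); first/second positions take
    the balance so the class total is unchanged.
    """
    free_len = int(free_counts.sum())
    n_pos = free_len // 3
    if n_pos == 0 or free_len % 3:
        return None
    f = free_counts / free_len
    t3 = f.copy()
    iA, iT = BASES.index("A"), BASES.index("T")
    t3[iA], t3[iT] = max(f[iA], f[iT]), min(f[iA], f[iT])
    t12 = np.clip((3 * f - t3) / 2, 0, None)
    c3 = _largest_remainder(t3, n_pos)
    c1 = _largest_remainder(t12, n_pos)
    c2 = free_counts - c3 - c1
    # repair negative column sums while keeping position totals at n_pos
    for pos_counts in (c3, c1):
        while (c2 < 0).any():
            b = int(np.argmin(c2))
            give = int(np.argmax(c2))
            if pos_counts[b] <= 0 or c2[give] <= 0:
                break
            move = min(-c2[b], pos_counts[b], c2[give])
            pos_counts[b] -= move
            pos_counts[give] += move
            c2[b] += move
            c2[give] -= move
    if (c2 < 0).any():  # degenerate tiny classes: caller falls back to one pool
        return None
    return [c1, c2, c3]


_STOP_NT = {"TAA": "TAA", "TAG": "TAG", "T--": "T", "TA-": "TA"}


def _repair_internal_stops(seq: list[str], stop_nt: int, rng, stops: set[str]) -> None:
    """Remove in-frame internal stops by swapping third-position bases.

    Swapping two third-position sites preserves both the total and the
    per-codon-position base counts exactly.
    """
    n_full = (len(seq) - stop_nt) // 3
    if n_full < 3:
        return
    for ci in range(1, n_full):
        for _ in range(1000):
            codon = "".join(seq[3 * ci : 3 * ci + 3])
            if codon not in stops:
                break
            cj = int(rng.integers(1, n_full))
            j = 3 * cj + 2
            if cj == ci or seq[j] == seq[3 * ci + 2]:
                continue
            seq[j], seq[3 * ci + 2] = seq[3 * ci + 2], seq[j]
            other = "".join(seq[3 * cj : 3 * cj + 3])
            if other in stops:  # undo swaps that relocate the stop
                seq[j], seq[3 * ci + 2] = seq[3 * ci + 2], seq[j]
        else:
            raise InfeasibleSpecError("could not remove internal stop codons")


def gen_mitogenome(
    spec: GenomeSpec, seed: int | None = None, code_id: int = DEFAULT_CODE
) -> tuple[GenomeRecord, dict]:
    """Generate an annotated circular mitogenome meeting composition targets.

    PCGs start with their policy start codon, end with their policy stop
    (incomplete ``T--``/``TA-`` supported) and contain no in-frame internal
    stop; unannotated template entries become non-coding regions.
    """
    from dataclasses import replace as _replace

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    stops = set(genetic_code(code_id).stop_codons)
    total = spec.length
    template = [_replace(e) for e in spec.template]
    feats = [e for e in template if e.category != "NCR"]
    ncr_length = sum(e.length for e in template if e.category == "NCR")

    for e in feats:
        if e.category == "PCG":
            stop = e.stop_codon or ("TAA" if e.length % 3 == 0 else "T--")
            e.stop_codon = stop
            if stop not in _STOP_NT:
                raise InfeasibleSpecError(f"{e.symbol}: unknown stop policy {stop}")
            if (e.length - 3 - len(_STOP_NT[stop])) % 3 or e.length < 9:
                raise InfeasibleSpecError(
                    f"{e.symbol}: length {e.length} incompatible with stop {stop}"
                )
            e.start_codon = e.start_codon or "ATG"

    class_lengths: dict[tuple[str, str], int] = {}
    for e in feats:
        key = (e.category, e.strand)
        class_lengths[key] = class_lengths.get(key, 0) + e.length
    targets = {
        p: _normalize(t) for p, t in spec.composition.items() if p not in ("whole", "NCR")
    }
    for part in {c[0] for c in class_lengths}:
        if part not in targets:
            targets[part] = np.full(4, 0.25)
    whole = _normalize(spec.composition["whole"]) if "whole" in spec.composition else None

    comps, ncr_comp = _solve_class_compositions(
        class_lengths, targets, ncr_length, whole, total
    )
    if "NCR" in spec.composition:  # explicit NCR target overrides the solved one
        ncr_comp = _normalize(spec.composition["NCR"])

    # integer allocation per class, net of fixed start/stop codons; PCG
    # classes are split into per-codon-position pools
    pools: dict[tuple[str, str], list[list[str]]] = {}
    for key, length in sorted(class_lengths.items()):
        counts = _largest_remainder(comps[key], length)
        fixed = np.zeros(4, dtype=int)
        if key[0] == "PCG":
            for e in feats:
                if (e.category, e.strand) == key:
                    fixed += _base_counts(e.start_codon) + _base_counts(
                        _STOP_NT[e.stop_codon]
                    )
        free = _subtract_fixed(counts, fixed)
        split = _split_codon_positions(free) if key[0] == "PCG" else None
        if split is None:
            pools[key] = [list(rng.permutation(np.repeat(np.array(BASES), free)))]
        else:
            pools[key] = [
                list(rng.permutation(np.repeat(np.array(BASES), c))) for c in split
            ]
    ncr_pool = list(
        rng.permutation(np.repeat(np.array(BASES), _largest_remainder(ncr_comp, ncr_length)))
    )

    # assemble features and genome
    genome_parts: list[str] = []
    features: list[GeneFeature] = []
    log_genes = {}
    pos = 0
    cursors = {k: 0 for k in pools}
    ncr_cursor = 0
    for e in template:
        if e.category == "NCR":
            segment = "".join(ncr_pool[ncr_cursor : ncr_cursor + e.length])
            ncr_cursor += e.length
            genome_parts.append(segment)
            pos += e.length
            continue
        key = (e.category, e.strand)
        if e.category == "PCG":
            stop_str = _STOP_NT[e.stop_codon]
            n_free = e.length - 3 - len(stop_str)
        else:
            stop_str = ""
            n_free = e.length
        cur = cursors[key]
        cls_pools = pools[key]
        if len(cls_pools) == 3:  # positional pools: interleave codon-wise
            m = n_free // 3
            body = []
            for k in range(m):
                body += [cls_pools[0][cur // 3 + k], cls_pools[1][cur // 3 + k],
                         cls_pools[2][cur // 3 + k]]
        else:
            body = cls_pools[0][cur : cur + n_free]
        cursors[key] = cur + n_free
        if e.category == "PCG":
            seq = list(e.start_codon) + body + list(stop_str)
            _repair_internal_stops(seq, len(stop_str), rng, stops)
        else:
            seq = body
        sense = "".join(seq)
        placed = revcomp(sense) if e.strand == "L" else sense
        genome_parts.append(placed)
        features.append(
            GeneFeature(
                name=e.symbol,
                category=e.category,
                start=pos + 1,
                end=pos + e.length,
                strand=e.strand,
                start_codon=e.start_codon if e.category == "PCG" else None,
                stop_codon=e.stop_codon if e.category == "PCG" else None,
            )
        )
        if e.category == "PCG":
            log_genes[e.symbol] = {"start": e.start_codon, "stop": e.stop_codon}
        pos += e.length

    record = GenomeRecord(
        id=spec.id,
        length=total,
        circular=spec.circular,
        sequence="".join(genome_parts),
        features=features,
    )
    log = {
        "seed": seed if seed is not None else spec.seed,
        "rng": "numpy.random.default_rng (PCG64)",
        "genes": log_genes,
        "class_compositions": {f"{k[0]}:{k[1]}": list(v) for k, v in comps.items()},
        "ncr_composition": list(ncr_comp),
        "ncr_length": ncr_length,
    }
    return record, log


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------


def _k2p_probs(t: float, ratio: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after branch length t."""
    alpha = ratio / (ratio + 1.0)
    beta = 1.0 / (2.0 * (ratio + 1.0))
    e1 = exp(-4.0 * beta * t)
    e2 = exp(-2.0 * (alpha + beta) * t)
    p_same = 0.25 + 0.25 * e1 + 0.5 * e2
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 * (1.0 - e1)
    return p_same, p_ts, p_tv

_TS_PARTNER = np.array([2, 3, 0, 1])  # A<->G, C<->T in ACGT encoding
_TV_PARTNER_1 = np.array([1, 0, 1, 0])
_TV_PARTNER_2 = np.array([3, 2, 3, 2])


def _evolve_branch_nt(x: np.ndarray, t: float, ratio: float, rng) -> np.ndarray:
    p_same, p_ts, _ = _k2p_probs(t, ratio)
    u = rng.random(x.size)
    pick = rng.integers(0, 2, x.size)
    tv = np.where(pick == 0, _TV_PARTNER_1[x], _TV_PARTNER_2[x])
    return np.where(u < p_same, x, np.where(u < p_same + p_ts, _TS_PARTNER[x], tv))


def _evolve_branch_cds(
    x: np.ndarray, t: float, ratio: float, omega: float, rng, code_id: int
) -> np.ndarray:
    """Proposal process: K2P point mutations; nonsynonymous ones accepted
    with probability omega, synonymous always, stops rejected."""
    stops = set(genetic_code(code_id).stop_codons)
    alpha = ratio / (ratio + 1.0)
    seq = x.copy()
    n_prop = rng.poisson(t * seq.size)
    bases = "ACGT"
    for _ in range(n_prop):
        site = int(rng.integers(0, seq.size))
        r = rng.random()
        old = seq[site]
        if r < alpha:
            new = _TS_PARTNER[old]
        elif r < alpha + (1 - alpha) / 2:
            new = _TV_PARTNER_1[old]
        else:
            new = _TV_PARTNER_2[old]
        c0 = 3 * (site // 3)
        codon = [bases[b] for b in seq[c0 : c0 + 3]]
        old_codon = "".join(codon)
        codon[site - c0] = bases[new]
        new_codon = "".join(codon)
        if new_codon in stops:
            continue
        if translate_codon(old_codon, code_id) != translate_codon(new_codon, code_id):
            if rng.random() >= omega:
                continue
        seq[site] = new
    return seq


def random_cds(n_codons: int, rng, code_id: int = DEFAULT_CODE) -> str:
    table = genetic_code(code_id)
    sense = sorted(set(table.forward_table) - set(table.stop_codons))
    return "".join(rng.choice(sense) for _ in range(n_codons))


def evolve_on_tree(spec: EvolutionSpec, seed: int | None = None) -> tuple[dict[str, str], dict]:
    """Evolve a root sequence down a Newick tree; returns taxon -> sequence.

    Branch lengths are expected substitutions (nt mode) / proposals (cds
    mode) per site.  Sites are independent; no indels.
    """
    import dendropy

    rng = np.random.default_rng(spec.seed if seed is None else seed)
    tree = dendropy.Tree.get(data=spec.tree, schema="newick")
    if spec.mode == "cds":
        if spec.n_sites % 3:
            raise ValueError("cds mode needs a site count that is a multiple of 3")
        if spec.omega is None:
            raise ValueError("cds mode needs a dN/dS target omega")
    enc = {b: i for i, b in enumerate("ACGT")}
    if spec.root_seq is not None:
        if len(spec.root_seq) != spec.n_sites:
            raise ValueError("root_seq length != n_sites")
        root = np.array([enc[c] for c in spec.root_seq.upper()])
    elif spec.mode == "cds":
        root = np.array([enc[c] for c in random_cds(spec.n_sites // 3, rng, spec.code_id)])
    else:
        root = rng.integers(0, 4, spec.n_sites)

    seqs: dict[int, np.ndarray] = {id(tree.seed_node): root}
    out: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            cur = seqs[id(node)]
        else:
            t = node.edge.length or 0.0
            parent = seqs[id(node.parent_node)]
            if t == 0:
                cur = parent.copy()
            elif spec.mode == "cds":
                cur = _evolve_branch_cds(parent, t, spec.ts_tv_ratio, spec.omega, rng,
                                         spec.code_id)
            else:
                cur = _evolve_branch_nt(parent, t, spec.ts_tv_ratio, rng)
            seqs[id(node)] = cur
        if node.is_leaf():
            out[node.taxon.label] = "".join(bases[cur])
    log = {
        "true_tree": spec.tree,
        "seed": seed if seed is not None else spec.seed,
        "mode": spec.mode,
        "omega": spec.omega,
        "root": "".join(bases[root]),
    }
    return out, log


# ---------------------------------------------------------------------------
# gene-order rearrangement simulator
# ---------------------------------------------------------------------------


def apply_rearrangements(
    order: GeneOrder, events: list, seed: int = 0
) -> tuple[GeneOrder, list[dict]]:
    """Apply translocation / inversion / duplication_loss events in sequence.

    Each event is a type name or a dict with optional explicit ``segment``
    (inclusive index pair) and ``dest`` insertion index; unspecified choices
    are drawn from the seeded generator.  Duplication-loss copies a segment
    in tandem, then deletes one copy of each duplicated gene at random,
    possibly shuffling relative order.
    """
    rng = np.random.default_rng(seed)
    syms: list[SignedGene] = list(order.symbols)
    log: list[dict] = []
    for ev in events:
        ev = {"type": ev} if isinstance(ev, str) else dict(ev)
        typ = ev["type"]
        n = len(syms)
        if "segment" in ev:
            i, j = ev["segment"]
        else:
            seg_len = int(rng.integers(1, max(2, min(4, n))))
            i = int(rng.integers(0, n - seg_len + 1))
            j = i + seg_len - 1
        seg = syms[i : j + 1]
        if typ == "inversion":
            syms[i : j + 1] = [(s, -sgn) for s, sgn in reversed(seg)]
            log.append({"type": typ, "segment": (i, j)})
        elif typ == "translocation":
            rest = syms[:i] + syms[j + 1 :]
            dest = int(ev.get("dest", rng.integers(0, len(rest) + 1)))
            syms = rest[:dest] + seg + rest[dest:]
            log.append({"type": typ, "segment": (i, j), "dest": dest})
        elif typ == "duplication_loss":
            dup = syms[: j + 1] + seg + syms[j + 1 :]
            kept: list[SignedGene] = []
            removed = []
            # for each duplicated gene, keep exactly one of its two copies
            for name, _sgn in seg:
                copies = [k for k, (nm, _) in enumerate(dup) if nm == name]
                drop = copies[int(rng.integers(0, 2))]
                removed.append(drop)
            kept = [sg for k, sg in enumerate(dup) if k not in set(removed)]
            syms = kept
            log.append({"type": typ, "segment": (i, j)})
        else:
            raise ValueError(f"unknown rearrangement type {typ!r}")
    return GeneOrder(order.taxon, syms, order.circular), log
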