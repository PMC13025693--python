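"""Gene-order linearization, LNCR detection, conserved blocks, breakpoints.

A gene order is a signed, usually circular, sequence of gene symbols
(sign = strand).  Circular orders compare equal under rotation.  The
breakpoint distance between two orders over the same symbols is the number
of signed adjacencies present in one but not the other -- a rotation-
invariant pseudo-metric that quantifies rearrangement (e.g. by tandem
duplication followed by random loss of redundant copies).

Long non-coding regions (LNCRs) are maximal unannotated gaps above a
length threshold; the default 500 bp cleanly separates control-region-sized
gaps (~1 kb) from ordinary intergenic spacers (tens of bp).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .records_io import GenomeRecord, feature_length

SignedGene = tuple[str, int]  # (symbol, +1 for strand H / -1 for strand L)

# one-letter amino-acid code of a tRNA symbol: trnK -> K, trnS1 -> S, ...
def trna_letter(symbol: str) -> str:
    if not symbol.startswith("trn"):
        raise ValueError(f"{symbol} is not a tRNA symbol")
    return symbol[3].upper()


@dataclass
class GeneOrder:
    taxon: str
    symbols: list[SignedGene]
    circular: bool = True

    def __post_init__(self):
        names = [s for s, _ in self.symbols]
        if len(set(names)) != len(names):
            raise ValueError(f"{self.taxon}: duplicate symbols; disambiguate with suffixes")

    def names(self) -> list[str]:
        return [s for s, _ in self.symbols]

    def rotated(self, k: int) -> "GeneOrder":
        k %= len(self.symbols)
        return GeneOrder(self.taxon, self.symbols[k:] + self.symbols[:k], self.circular)

    def __eq__(self, other) -> bool:  # rotation-closed equality for circular orders
        if not isinstance(other, GeneOrder):
            return NotImplemented
        if self.circular != other.circular or len(self.symbols) != len(other.symbols):
            return False
        if not self.circular:
            return self.symbols == other.symbols
        n = len(self.symbols)
        return any(self.rotated(k).symbols == other.symbols for k in range(n))


@dataclass
class ConservedBlock:
    symbols: list[SignedGene]
    taxa: list[str]
    reversed_in: list[str] = field(default_factory=list)

    def names(self) -> list[str]:
        return [s for s, _ in self.symbols]


@dataclass
class LNCR:
    start: int
    end: int
    length: int
    upstream: str  # gene before the gap in genomic order
    downstream: str  # gene after the gap
    wraps_origin: bool = False


# ---------------------------------------------------------------------------
# linearization and tRNA block strings
# ---------------------------------------------------------------------------


def linearize(
    record: GenomeRecord, anchor: str = "COIII", include: str = "all"
) -> GeneOrder:
    """Gene order of a record, rotated so ``anchor`` comes first.

    ``include`` is ``all`` or ``pcg_rrna`` (drop tRNAs, the usual view for
    cross-family comparison).
    """
    feats = sorted(record.features, key=lambda f: (f.wraps_origin, f.start))
    if include == "pcg_rrna":
        feats = [f for f in feats if f.category in ("PCG", "rRNA")]
    elif include != "all":
        raise ValueError("include must be 'all' or 'pcg_rrna'")
    symbols: list[SignedGene] = [
        (f.name, 1 if f.strand == "H" else -1) for f in feats if f.category != "NCR"
    ]
    names = [s for s, _ in symbols]
    if anchor not in names:
        raise ValueError(f"anchor {anchor} not annotated in {record.id}")
    k = names.index(anchor)
    return GeneOrder(record.id, symbols[k:] + symbols[:k], record.circular)


def trna_block_string(order: GeneOrder, left: str, right: str) -> str:
    """Consecutive tRNAs strictly between two anchors, as one-letter codes.

    The scan runs forward (circularly) from ``left`` to ``right`` and stops
    at the first non-tRNA gene, so the result is the contiguous tRNA run
    adjacent to ``left``.
    """
    names = order.names()
    if left not in names or right not in names:
        raise ValueError(f"anchors {left}/{right} not in order")
    i, j = names.index(left), names.index(right)
    n = len(names)
    span = (j - i) % n
    letters = []
    for k in range(1, span):
        sym = names[(i + k) % n]
        if not sym.startswith("trn"):
            break
        letters.append(trna_letter(sym))
    return "".join(letters)


# ---------------------------------------------------------------------------
# LNCR detection
# ---------------------------------------------------------------------------


def find_lncrs(record: GenomeRecord, min_len: int = 500) -> list[LNCR]:
    """Maximal unannotated gaps >= ``min_len``, including an origin-spanning gap.

    Overlapping annotations are merged before gap-finding, never clipped.
    """
    if not record.features:
        raise ValueError(f"{record.id}: no annotation")
    L = record.length
    intervals: list[tuple[int, int, str]] = []
    for f in record.features:
        if f.wraps_origin:
            intervals.append((f.start, L, f.name))
            intervals.append((1, f.end, f.name))
        else:
            intervals.append((f.start, f.end, f.name))
    intervals.sort()
    merged: list[list] = []
    for s, e, name in intervals:
        if merged and s <= merged[-1][1] + 1:
            if e > merged[-1][1]:
                merged[-1][1] = e
                merged[-1][2] = name
        else:
            merged.append([s, e, name])
    gaps: list[LNCR] = []
    for (s1, e1, up), (s2, _e2, down) in zip(merged, merged[1:]):
        gap = s2 - e1 - 1
        if gap >= min_len:
            gaps.append(LNCR(e1 + 1, s2 - 1, gap, _last_gene_ending_at(record, e1) or up,
                             down, False))
    if record.circular:
        first, last = merged[0], merged[-1]
        wrap_gap = (L - last[1]) + (first[0] - 1)
        if wrap_gap >= min_len:
            start = last[1] + 1 if last[1] < L else 1
            end = first[0] - 1 if first[0] > 1 else L
            gaps.append(
                LNCR(start, end, wrap_gap,
                     _last_gene_ending_at(record, last[1]) or last[2], first[2],
                     wraps_origin=last[1] < L and first[0] > 1)
            )
    return gaps


def _last_gene_ending_at(record: GenomeRecord, pos: int) -> str | None:
    for f in record.features:
        if not f.wraps_origin and f.end == pos:
            return f.name
    return None


def lncr_coverage_check(record: GenomeRecord) -> int:
    """Genome length minus merged annotated coverage = total unannotated bp."""
    covered = 0
    L = record.length
    intervals = []
    for f in record.features:
        if f.wraps_origin:
            intervals += [(f.start, L), (1, f.end)]
        else:
            intervals.append((f.start, f.end))
    intervals.sort()
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_s is not None:
        covered += cur_e - cur_s + 1
    return L - covered


# ---------------------------------------------------------------------------
# conserved blocks and breakpoint distance
# ---------------------------------------------------------------------------


def _occurs(run: list[SignedGene], order: GeneOrder) -> str | None:
    """'forward'/'reverse' if the signed run is contiguous in the order, else None."""
    syms = order.symbols
    n = len(syms)
    m = len(run)
    if m > n:
        return None
    rev = [(s, -sgn) for s, sgn in reversed(run)]
    limit = n if order.circular else n - m + 1
    for i in range(limit):
        window = [syms[(i + k) % n] for k in range(m)]
        if window == run:
            return "forward"
        if window == rev:
            return "reverse"
    return None


def common_blocks(orders: list[GeneOrder], min_len: int = 1) -> list[ConservedBlock]:
    """Maximal runs contiguous (orientation-consistent) in every order.

    A run matches if it occurs forward, or reversed with flipped signs
    (reverse-complement orientation); taxa where it is reversed are listed.
    Maximality: no extension of the run on either side is common to all.
    """
    if not orders:
        return []
    ref = orders[0]
    n = len(ref.symbols)
    blocks: list[ConservedBlock] = []
    claimed: set[tuple] = set()

    def common(run):
        modes = []
        for o in orders[1:]:
            mode = _occurs(run, o)
            if mode is None:
                return None
            modes.append(mode)
        return modes

    max_span = n if ref.circular else n
    for length in range(min(max_span, n), max(min_len - 1, 0), -1):
        limit = n if ref.circular and length < n else (1 if length == n else n - length + 1)
        for i in range(limit):
            run = [ref.symbols[(i + k) % n] for k in range(length)]
            key = frozenset(s for s, _ in run)
            if any(key <= c for c in claimed):
                continue  # sub-run of an already-reported block
            modes = common(run)
            if modes is None:
                continue
            blocks.append(
                ConservedBlock(
                    symbols=run,
                    taxa=[o.taxon for o in orders],
                    reversed_in=[o.taxon for o, m in zip(orders[1:], modes) if m == "reverse"],
                )
            )
            claimed.add(key)
    return blocks


def _adjacencies(order: GeneOrder) -> set[tuple[SignedGene, SignedGene]]:
    """Canonical signed adjacencies; (a,b) is identified with (-b,-a)."""
    syms = order.symbols
    n = len(syms)
    pairs = []
    last = n if order.circular else n - 1
    for i in range(last):
        a, b = syms[i], syms[(i + 1) % n]
        alt = ((b[0], -b[1]), (a[0], -a[1]))
        pairs.append(min((a, b), alt))
    return set(pairs)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of adjacencies of ``a`` absent from ``b`` (common symbols only)."""
    shared = set(a.names()) & set(b.names())
    dropped = (set(a.names()) | set(b.names())) - shared
    if dropped:
        import warnings

        warnings.warn(f"dropping symbols absent from one order: {sorted(dropped)}")
    fa = GeneOrder(a.taxon, [s for s in a.symbols if s[0] in shared], a.circular)
    fb = GeneOrder(b.taxon, [s for s in b.symbols if s[0] in shared], b.circular)
    return len(_adjacencies(fa) - _adjacencies(fb))
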