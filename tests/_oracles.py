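"""Independent slow reference implementations used only to check the package.

These deliberately share no code with mitochar: translation goes through
Bio.Seq, site/pathway counting is exhaustive enumeration, gap finding uses a
per-position coverage bitmap, and conserved-block mining checks every window
of every order.
"""

from itertools import permutations
from math import log

import numpy as np
from Bio.Seq import Seq


def aa(codon: str, table: int = 5) -> str:
    return str(Seq(codon).translate(table=table))  # '*' for stops


def ref_site_counts(codon: str, table: int = 5):
    s = 0.0
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if aa(mut, table) != "*" and aa(mut, table) == aa(codon, table):
                s += 1 / 3
    return s, 3 - s


def ref_pathway_differences(a: str, b: str, table: int = 5):
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in permutations(diff):
        sd = nd = 0
        cur = a
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if aa(nxt, table) == "*" or aa(cur, table) == "*":
                hit_stop = True
                nd += 1
            elif aa(cur, table) == aa(nxt, table):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if hit_stop else clean).append((sd, nd))
    paths = clean or dirty
    return (
        sum(p[0] for p in paths) / len(paths),
        sum(p[1] for p in paths) / len(paths),
    )


def ref_kaks(codons_a, codons_b, table: int = 5):
    """Brute-force NG86 with JC correction; returns (Ka, Ks, ratio-or-None)."""
    pairs = [
        (x, y)
        for x, y in zip(codons_a, codons_b)
        if len(x) == 3 and len(y) == 3 and set(x + y) <= set("ACGT")
        and aa(x, table) != "*" and aa(y, table) != "*"
    ]
    sa = sum(ref_site_counts(x, table)[0] for x, _ in pairs)
    sb = sum(ref_site_counts(y, table)[0] for _, y in pairs)
    na = sum(ref_site_counts(x, table)[1] for x, _ in pairs)
    nb = sum(ref_site_counts(y, table)[1] for _, y in pairs)
    S, N = (sa + sb) / 2, (na + nb) / 2
    Sd = sum(ref_pathway_differences(x, y, table)[0] for x, y in pairs)
    Nd = sum(ref_pathway_differences(x, y, table)[1] for x, y in pairs)
    pS, pN = Sd / S, Nd / N
    Ks = -0.75 * log(1 - 4 * pS / 3)
    Ka = -0.75 * log(1 - 4 * pN / 3)
    return Ka, Ks, (Ka / Ks if Ks > 0 else None)


def ref_unannotated_gaps(record, min_len):
    """Gap lengths >= min_len via a per-position coverage bitmap."""
    covered = np.zeros(record.length, dtype=bool)
    for f in record.features:
        if f.wraps_origin:
            covered[f.start - 1 :] = True
            covered[: f.end] = True
        else:
            covered[f.start - 1 : f.end] = True
    # runs of uncovered positions on the circle
    if covered.all():
        return []
    idx = np.where(~covered)[0]
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    if record.circular and len(runs) > 1 and runs[0][0] == 0 and runs[-1][1] == record.length - 1:
        first, last = runs.pop(0), runs.pop()
        runs.append((last[0], first[1] + record.length))
    return sorted(r[1] - r[0] + 1 for r in runs if r[1] - r[0] + 1 >= min_len)


def _windows(symbols, circular):
    n = len(symbols)
    out = set()
    max_len = n if circular else n
    for length in range(1, max_len + 1):
        limit = n if (circular and length < n) else (1 if length == n else n - length + 1)
        for i in range(limit):
            win = tuple(symbols[(i + k) % n] for k in range(length))
            out.add(win)
            out.add(tuple((s, -sgn) for s, sgn in reversed(win)))
    return out


def ref_common_blocks(orders):
    """All maximal common runs (as symbol-name tuples in reference orientation)."""
    ref = orders[0]
    n = len(ref.symbols)
    others = [_windows(o.symbols, o.circular) for o in orders[1:]]

    def common(win):
        return all(win in w for w in others)

    out = set()
    for length in range(1, n + 1):
        limit = n if (ref.circular and length < n) else (1 if length == n else n - length + 1)
        for i in range(limit):
            win = tuple(ref.symbols[(i + k) % n] for k in range(length))
            if not common(win):
                continue
            if length < n:
                left = tuple([ref.symbols[(i - 1) % n]] + list(win))
                right = tuple(list(win) + [ref.symbols[(i + length) % n]])
                extendable = (ref.circular or i > 0) and common(left) or (
                    ref.circular or i + length < n
                ) and common(right)
                if extendable and length + 1 <= n:
                    continue
            out.add(tuple(s for s, _ in win))
    return out
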