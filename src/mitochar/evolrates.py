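"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

Synonymous/nonsynonymous *sites* are counted per codon as the fraction of
the three possible point mutations at each position that are synonymous
(mutations to stop codons count as nonsynonymous).  Observed differences
between two codons are averaged over all substitution pathways with equal
weight; pathways passing through a stop codon are excluded and the average
renormalized (if every pathway hits a stop, all are kept).  Proportions are
Jukes-Cantor corrected: K = -(3/4) ln(1 - 4p/3).  Ka/Ks < 1 indicates
purifying selection, > 1 positive selection, = 1 neutrality.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations
from math import isnan, log, nan

import pandas as pd

from .codon_usage import DEFAULT_CODE, genetic_code

_BASES = "ACGT"


class SaturationError(ValueError):
    """A difference proportion >= 3/4; the JC correction is undefined."""


def _code_maps(code_id: int):
    table = genetic_code(code_id)
    return table.forward_table, set(table.stop_codons)


def site_counts(codon: str, code_id: int = DEFAULT_CODE) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon; sum is 3."""
    fwd, stops = _code_maps(code_id)
    if codon in stops:
        raise ValueError(f"stop codon {codon} has no site decomposition")
    aa = fwd[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in stops and fwd[mut] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def cds_site_counts(codons: list[str], code_id: int = DEFAULT_CODE) -> tuple[float, float]:
    s_tot = n_tot = 0.0
    for codon in codons:
        s, n = site_counts(codon, code_id)
        s_tot += s
        n_tot += n
    return s_tot, n_tot


def pathway_differences(
    codon_a: str, codon_b: str, code_id: int = DEFAULT_CODE
) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences between codons."""
    fwd, stops = _code_maps(code_id)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid, fallback = [], []
    for order in permutations(diff_pos):
        sd = nd = 0
        cur = codon_a
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in stops:
                through_stop = True
                nd += 1  # a change into/through a stop is nonsynonymous
            elif cur in stops:
                through_stop = True
                nd += 1
            elif fwd[cur] == fwd[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        (fallback if through_stop else valid).append((sd, nd))
    paths = valid if valid else fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    """JC69 multiple-hit correction of a difference proportion."""
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 3/4: correction undefined")
    return -0.75 * log(1 - 4 * p / 3) + 0.0  # +0.0 normalizes -0.0


@dataclass
class PairwiseRates:
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float  # nan when Ks == 0
    n_codons: int


def _clean_pairs(cds_a: list[str], cds_b: list[str]) -> list[tuple[str, str]]:
    if len(cds_a) != len(cds_b):
        raise ValueError("CDS lists must be equal length (aligned, in frame)")
    ok = set(_BASES)
    return [
        (a, b)
        for a, b in zip(cds_a, cds_b)
        if len(a) == 3 and len(b) == 3 and set(a) <= ok and set(b) <= ok
    ]


def kaks_pair(
    cds_a: list[str], cds_b: list[str], code_id: int = DEFAULT_CODE
) -> PairwiseRates:
    """NG86 Ka/Ks between two aligned, in-frame codon lists.

    Codons containing gaps or ambiguity in either sequence are dropped
    pairwise; stop codons (full or incomplete terminal) are likewise
    excluded.
    """
    _, stops = _code_maps(code_id)
    pairs = [
        (a, b) for a, b in _clean_pairs(cds_a, cds_b) if a not in stops and b not in stops
    ]
    if not pairs:
        raise ValueError("no comparable codons")
    s_a, n_a = cds_site_counts([p[0] for p in pairs], code_id)
    s_b, n_b = cds_site_counts([p[1] for p in pairs], code_id)
    S, N = (s_a + s_b) / 2, (n_a + n_b) / 2
    Sd = Nd = 0.0
    for a, b in pairs:
        sd, nd = pathway_differences(a, b, code_id)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks, Ka = jukes_cantor(pS), jukes_cantor(pN)
    return PairwiseRates(
        S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN, Ks=Ks, Ka=Ka,
        ratio=Ka / Ks if Ks > 0 else nan, n_codons=len(pairs),
    )


def classify_regime(ratio: float, tol: float = 0.01) -> str:
    if isnan(ratio):
        return "undefined"
    if abs(ratio - 1.0) <= tol:
        return "neutral"
    return "purifying" if ratio < 1.0 else "positive"


def _to_codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]


def gene_selection_screen(
    alignments: dict[str, dict[str, str]], code_id: int = DEFAULT_CODE
) -> pd.DataFrame:
    """Mean pairwise Ka/Ks and selection regime per gene.

    ``alignments`` maps gene -> (taxon -> aligned CDS string).  The mean is
    taken over taxon pairs with a defined ratio (Ks > 0, below saturation);
    a gene with no defined pair reports NaN and regime ``undefined``.
    """
    rows = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        ratios, n_pairs = [], 0
        for ta, tb in combinations(sorted(aln), 2):
            n_pairs += 1
            try:
                rates = kaks_pair(_to_codons(aln[ta]), _to_codons(aln[tb]), code_id)
            except (SaturationError, ValueError):
                continue
            if not isnan(rates.ratio):
                ratios.append(rates.ratio)
        mean = sum(ratios) / len(ratios) if ratios else nan
        rows.append(
            {
                "gene": gene,
                "n_pairs": n_pairs,
                "n_defined": len(ratios),
                "mean_kaks": mean,
                "regime": classify_regime(mean) if ratios else "undefined",
            }
        )
    return pd.DataFrame(rows)
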