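"""Strand-aware CDS extraction, start/stop classification, and RSCU.

The default genetic code is NCBI translation table 5 (invertebrate
mitochondrial: ATA=Met, TGA=Trp, AGA/AGG=Ser), the standard code for
cephalopod mtDNA.  Metazoan mitochondrial genes frequently end on an
incomplete stop codon -- a terminal T or TA completed to TAA by
polyadenylation -- which is classified here as ``T--`` / ``TA-`` and never
counted as a coding codon.

RSCU (relative synonymous codon usage) is a codon's count divided by the
mean count of its synonymous family, so values sum to the family size and
1.0 means no bias.  Six-codon leucine and eight-codon serine families are
split by their decoding tRNA, matching mitogenome annotation practice:
L2 = UUR, L1 = CUN, S1 = AGN, S2 = UCN.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from .records_io import GeneFeature, GenomeRecord, feature_sequence

DEFAULT_CODE = 5

_BASES = "TCAG"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


class InternalStopWarning(UserWarning):
    """An in-frame stop codon occurs before the annotated terminus."""


def genetic_code(code_id: int = DEFAULT_CODE) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[code_id]


def translate_codon(codon: str, code_id: int = DEFAULT_CODE) -> str | None:
    """Amino acid (1-letter) or None for a stop codon."""
    table = genetic_code(code_id)
    if codon in table.stop_codons:
        return None
    return table.forward_table[codon]


def synonymous_families(code_id: int = DEFAULT_CODE) -> dict[str, list[str]]:
    """Codon families keyed by amino acid, with tRNA-split Leu/Ser."""
    table = genetic_code(code_id)
    fams: dict[str, list[str]] = {}
    for codon in ALL_CODONS:
        if codon in table.stop_codons:
            continue
        aa = table.forward_table[codon]
        key = aa
        if aa == "L":
            key = "L2" if codon in ("TTA", "TTG") else "L1"
        elif aa == "S":
            key = "S1" if codon.startswith("AG") else "S2"
        fams.setdefault(key, []).append(codon)
    return fams


# ---------------------------------------------------------------------------
# CDS extraction and terminal classification
# ---------------------------------------------------------------------------


def extract_cds(record: GenomeRecord, feature: GeneFeature,
                code_id: int = DEFAULT_CODE) -> list[str]:
    """Sense-strand codon list of a PCG; a trailing 1-2 nt codon is kept.

    Emits :class:`InternalStopWarning` if a full in-frame stop precedes the
    annotated terminus (a frame or annotation error in real data).
    """
    if feature.category != "PCG":
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    seq = feature_sequence(record, feature)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stops = set(genetic_code(code_id).stop_codons)
    for i, codon in enumerate(codons[:-1]):
        if codon in stops:
            warnings.warn(
                f"{feature.name}: internal stop {codon} at codon {i + 1}",
                InternalStopWarning,
                stacklevel=2,
            )
    return codons


def classify_terminal(codons: list[str], code_id: int = DEFAULT_CODE) -> str:
    """Stop label of a codon list: TAA/TAG, incomplete T--/TA-, or none."""
    if not codons:
        return "none"
    last = codons[-1]
    stops = set(genetic_code(code_id).stop_codons)
    if len(last) == 3:
        return last if last in stops else "none"
    if last == "T":
        return "T--"
    if last == "TA":
        return "TA-"
    return "none"


def coding_codons(codons: list[str], code_id: int = DEFAULT_CODE) -> list[str]:
    """Full, non-stop codons (what RSCU and site counting operate on)."""
    stops = set(genetic_code(code_id).stop_codons)
    return [c for c in codons if len(c) == 3 and c not in stops]


# ---------------------------------------------------------------------------
# codon counting and RSCU
# ---------------------------------------------------------------------------


@dataclass
class CodonProfile:
    gene: str
    codon_counts: Counter
    start_codon: str
    stop_codon: str
    n_codons: int  # full codons including any terminal full stop
    n_aa: int  # coding codons (stop excluded)


def count_codons(codons: list[str], code_id: int = DEFAULT_CODE) -> Counter:
    return Counter(coding_codons(codons, code_id))


def rscu(codon_counts: Counter | dict, code_id: int = DEFAULT_CODE) -> pd.DataFrame:
    """RSCU table over all sense codons of the code.

    Within each synonymous family the values sum to the family size; a
    family with zero observations reports all zeros.
    """
    fams = synonymous_families(code_id)
    rows = []
    for aa in sorted(fams):
        family = fams[aa]
        total = sum(codon_counts.get(c, 0) for c in family)
        for codon in sorted(family):
            count = codon_counts.get(codon, 0)
            value = count * len(family) / total if total else 0.0
            rows.append(
                {"codon": codon, "aa": aa, "family_size": len(family),
                 "count": count, "rscu": value}
            )
    return pd.DataFrame(rows)


def gene_profile(record: GenomeRecord, feature: GeneFeature,
                 code_id: int = DEFAULT_CODE) -> CodonProfile:
    codons = extract_cds(record, feature, code_id)
    full = [c for c in codons if len(c) == 3]
    return CodonProfile(
        gene=feature.name,
        codon_counts=count_codons(codons, code_id),
        start_codon=codons[0] if codons else "",
        stop_codon=classify_terminal(codons, code_id),
        n_codons=len(full),
        n_aa=len(coding_codons(codons, code_id)),
    )


def codon_report(record: GenomeRecord, code_id: int = DEFAULT_CODE) -> pd.DataFrame:
    """Per-PCG start/stop/codon inventory (annotation-table Codon columns)."""
    rows = []
    for f in record.features_by_category("PCG"):
        prof = gene_profile(record, f, code_id)
        rows.append(
            {
                "gene": prof.gene,
                "start_codon": prof.start_codon,
                "stop_codon": prof.stop_codon,
                "n_codons": prof.n_codons,
                "n_aa": prof.n_aa,
            }
        )
    return pd.DataFrame(rows)


def pooled_rscu(record: GenomeRecord, code_id: int = DEFAULT_CODE) -> pd.DataFrame:
    """RSCU pooled over all PCGs (the genome-wide codon-bias profile)."""
    pooled: Counter = Counter()
    for f in record.features_by_category("PCG"):
        pooled += count_codons(extract_cds(record, f, code_id), code_id)
    return rscu(pooled, code_id)
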