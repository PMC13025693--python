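"""Consolidated end-to-end characterization of a set of mitogenome records.

Runs the full workflow -- composition/skews, codon usage and RSCU, Ka/Ks
between records where genes are length-compatible, gene order / conserved
blocks / LNCRs / breakpoint distances, and a distance/NJ stage when three
or more records are present -- and returns one JSON-serializable dict.
Stages that are undefined for the given inputs (saturated distances between
non-homologous sequences, trees with fewer than three taxa) are reported as
such rather than omitted.
"""

from __future__ import annotations

import math
from itertools import combinations

from . import __version__
from .codon_usage import codon_report, extract_cds, pooled_rscu
from .compstats import composition_table, partition_composition, round_half_away
from .evolrates import SaturationError, kaks_pair
from .generearrange import breakpoint_distance, common_blocks, find_lncrs, linearize
from .phylo import SaturationError as K2PSaturationError
from .phylo import concatenate, k2p_distance, nj_from_supermatrix
from .records_io import GenomeRecord, feature_sequence


def _order_text(order) -> str:
    return " ".join(("-" if sgn < 0 else "") + name for name, sgn in order.symbols)


def record_section(rec: GenomeRecord, lncr_min: int = 500, anchor: str = "COIII") -> dict:
    sec: dict = {
        "id": rec.id,
        "length": rec.length,
        "census": rec.census(),
        "lncrs": [
            {"start": g.start, "end": g.end, "length": g.length,
             "between": [g.upstream, g.downstream]}
            for g in find_lncrs(rec, lncr_min)
        ],
        "gene_order": _order_text(linearize(rec, anchor=anchor, include="all")),
    }
    if rec.sequence is not None:
        comp = composition_table(rec)
        whole = partition_composition(rec, "whole")
        sec["composition"] = comp
        sec["skews"] = {
            "at_skew": round_half_away(whole.at_skew, 3),
            "gc_skew": round_half_away(whole.gc_skew, 3),
        }
        sec["codons"] = codon_report(rec).to_dict(orient="records")
        rs = pooled_rscu(rec)
        used = rs[rs["count"] > 0].sort_values(["count", "codon"], ascending=[False, True])
        sec["top_codon"] = used.iloc[0]["codon"] if len(used) else None
        sec["rscu"] = {r["codon"]: round(r["rscu"], 4) for _, r in rs.iterrows()}
    return sec


def _equal_length_pcgs(a: GenomeRecord, b: GenomeRecord) -> list[str]:
    la = {f.name: f for f in a.features_by_category("PCG")}
    lb = {f.name: f for f in b.features_by_category("PCG")}
    out = []
    for name in sorted(set(la) & set(lb)):
        fa, fb = la[name], lb[name]
        if (fa.end - fa.start) == (fb.end - fb.start):
            out.append(name)
    return out


def _codons(seq: str) -> list[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def run_report(records: list[GenomeRecord], seed: int = 0, lncr_min: int = 500,
               anchor: str = "COIII", code_id: int = 5) -> dict:
    out: dict = {
        "meta": {
            "tool": "mitochar",
            "version": __version__,
            "seed": seed,
            "config": {"lncr_min": lncr_min, "anchor": anchor, "genetic_code": code_id},
        },
        "records": [record_section(r, lncr_min, anchor) for r in records],
    }
    if len(records) >= 2:
        orders = [linearize(r, anchor=anchor, include="pcg_rrna") for r in records]
        blocks = common_blocks(orders, min_len=2)
        out["conserved_blocks"] = [
            {"genes": b.names(), "reversed_in": b.reversed_in} for b in blocks
        ]
        out["breakpoint_distances"] = [
            {"a": x.taxon, "b": y.taxon, "distance": breakpoint_distance(x, y)}
            for x, y in combinations(orders, 2)
        ]
        sequenced = [r for r in records if r.sequence is not None]
        kaks_rows = []
        for a, b in combinations(sequenced, 2):
            fa = {f.name: f for f in a.features_by_category("PCG")}
            fb = {f.name: f for f in b.features_by_category("PCG")}
            for gene in _equal_length_pcgs(a, b):
                try:
                    rates = kaks_pair(
                        _codons(feature_sequence(a, fa[gene])),
                        _codons(feature_sequence(b, fb[gene])),
                        code_id,
                    )
                    ratio = None if math.isnan(rates.ratio) else round(rates.ratio, 4)
                    kaks_rows.append(
                        {"gene": gene, "a": a.id, "b": b.id,
                         "Ka": round(rates.Ka, 4), "Ks": round(rates.Ks, 4),
                         "ratio": ratio}
                    )
                except (SaturationError, ValueError):
                    kaks_rows.append(
                        {"gene": gene, "a": a.id, "b": b.id, "Ka": None, "Ks": None,
                         "ratio": None, "note": "saturated or undefined"}
                    )
        out["kaks"] = kaks_rows
        # distance / tree stage on genes sharing lengths across all records
        if len(sequenced) >= 2:
            shared = _equal_length_pcgs(sequenced[0], sequenced[1])
            for other in sequenced[2:]:
                shared = [g for g in shared if g in _equal_length_pcgs(sequenced[0], other)]
            if shared:
                aln = {
                    g: {
                        r.id: feature_sequence(
                            r, {f.name: f for f in r.features_by_category("PCG")}[g]
                        )
                        for r in sequenced
                    }
                    for g in shared
                }
                sm = concatenate(aln)
                tree_sec: dict = {"genes": shared, "n_columns": sm.n_columns}
                try:
                    if len(sequenced) >= 3:
                        tree_sec["newick"] = nj_from_supermatrix(sm).as_string(
                            schema="newick").strip()
                    else:
                        tree_sec["k2p_distance"] = round(
                            k2p_distance(*(sm.rows[t] for t in sm.taxa)), 4
                        )
                except K2PSaturationError:
                    tree_sec["note"] = "pairwise distances saturated"
                out["distance_stage"] = tree_sec
    return out
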