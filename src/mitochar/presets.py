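"""Study presets: the two amphitretid octopus mitogenome annotations.

``load_paper_record`` returns the published annotation table (coordinates,
strands, start/stop codons; no sequence) for *Japetella diaphana*
(ON060363, 16,111 bp) or *Amphitretus pelagicus* (ON060364, 17,380 bp).
``paper_genome_spec`` turns a table into a synthetic-genome spec: feature
lengths and strands are kept in annotated order, positive intergenic
spacers become non-coding entries (so the long non-coding regions survive),
overlaps collapse to adjacency, and composition targets are the published
per-partition values.
"""

from __future__ import annotations

from .records_io import GenomeRecord, _data_path, feature_length, read_feature_table
from .synthetic_data import GenomeSpec, TemplateEntry

SPECIES = ("jdiaphana", "apelagicus")

_FILES = {"jdiaphana": "jdiaphana_features.tsv", "apelagicus": "apelagicus_features.tsv"}

# published per-partition nucleotide composition (percent)
COMPOSITION_TARGETS: dict[str, dict[str, dict[str, float]]] = {
    "jdiaphana": {
        "whole": {"A": 40.6, "T": 36.3, "C": 15.4, "G": 7.7},
        "PCG": {"A": 31.9, "T": 43.5, "C": 11.0, "G": 13.5},
        "rRNA": {"A": 37.1, "T": 42.5, "C": 6.0, "G": 14.4},
        "tRNA": {"A": 37.9, "T": 40.6, "C": 8.1, "G": 13.4},
    },
    "apelagicus": {
        "whole": {"A": 40.6, "T": 35.1, "C": 16.8, "G": 7.5},
        "PCG": {"A": 30.7, "T": 42.7, "C": 12.2, "G": 14.4},
        "rRNA": {"A": 36.9, "T": 41.6, "C": 6.1, "G": 15.4},
        "tRNA": {"A": 38.4, "T": 40.1, "C": 8.0, "G": 13.5},
    },
}

# published whole-genome skews (recomputable from the percentages above)
PUBLISHED_SKEWS = {
    "jdiaphana": {"at_skew": 0.056, "gc_skew": -0.333},
    "apelagicus": {"at_skew": 0.073, "gc_skew": -0.383},
}


def _key(species: str) -> str:
    s = species.lower()
    aliases = {
        "jdiaphana": "jdiaphana",
        "japetella": "jdiaphana",
        "japetella_diaphana": "jdiaphana",
        "on060363": "jdiaphana",
        "apelagicus": "apelagicus",
        "amphitretus": "apelagicus",
        "amphitretus_pelagicus": "apelagicus",
        "on060364": "apelagicus",
    }
    if s not in aliases:
        raise KeyError(f"unknown species {species!r}; choose from {SPECIES}")
    return aliases[s]


def load_paper_record(species: str) -> GenomeRecord:
    """The published annotation table as a (sequence-free) GenomeRecord."""
    return read_feature_table(_data_path(_FILES[_key(species)]))


def paper_genome_spec(species: str) -> GenomeSpec:
    """Synthetic-genome spec emulating one of the two study mitogenomes."""
    key = _key(species)
    rec = load_paper_record(key)
    feats = sorted(rec.features, key=lambda f: (f.wraps_origin, f.start))
    template: list[TemplateEntry] = []
    n_ncr = 0
    for i, f in enumerate(feats):
        template.append(
            TemplateEntry(
                symbol=f.name,
                category=f.category,
                length=feature_length(f, rec.length),
                strand=f.strand,
                start_codon=f.start_codon,
                stop_codon=f.stop_codon,
            )
        )
        if i + 1 < len(feats):
            gap = feats[i + 1].start - f.end - 1
        else:  # wrap-around gap back to the first feature
            gap = (rec.length - f.end) + (feats[0].start - 1)
        if gap > 0:
            n_ncr += 1
            template.append(TemplateEntry(f"NCR{n_ncr}", "NCR", gap, "H"))
    return GenomeSpec(
        id=f"{rec.id}-synthetic",
        template=template,
        composition=COMPOSITION_TARGETS[key],
        circular=True,
    )
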