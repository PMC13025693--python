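"""Reading, writing and coordinate arithmetic for annotated mitogenome records.

Records are circular mitochondrial genomes carrying an ordered list of gene
features with 1-based inclusive coordinates, as printed in published
annotation tables.  Strand ``H`` is the reference strand of the deposited
sequence; ``L`` features are read off the complement.  A feature whose span
crosses the origin of the circle sets ``wraps_origin``.

Supported formats: a tab-separated feature table
(``gene from to size strand [start_codon] [stop_codon]`` with the genome
length in a ``# length=`` header), GenBank flat files, FASTA, and Newick.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

CATEGORIES = ("PCG", "tRNA", "rRNA", "NCR")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class MalformedRecordError(ValueError):
    """A record or feature table violates the coordinate/schema contract."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class GeneFeature:
    """One annotated gene or region, 1-based inclusive, on strand H or L."""

    name: str
    category: str
    start: int
    end: int
    strand: str = "H"
    start_codon: str | None = None
    stop_codon: str | None = None
    wraps_origin: bool = False

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise MalformedRecordError(f"unknown category {self.category!r}")
        if self.strand not in ("H", "L"):
            raise MalformedRecordError(f"strand must be H or L, got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise MalformedRecordError(
                f"{self.name}: coordinates must be >= 1 ({self.start}-{self.end})"
            )
        if not self.wraps_origin and self.start > self.end:
            raise MalformedRecordError(
                f"{self.name}: start {self.start} > end {self.end} on a "
                "non-wrapping feature"
            )
        if self.category != "PCG" and (self.start_codon or self.stop_codon):
            raise MalformedRecordError(f"{self.name}: codon fields on non-PCG feature")


@dataclass
class GenomeRecord:
    """An annotated, optionally sequenced, (usually circular) mitogenome."""

    id: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        if self.sequence is not None and len(self.sequence) != self.length:
            raise MalformedRecordError(
                f"{self.id}: sequence length {len(self.sequence)} != declared "
                f"length {self.length}"
            )
        for f in self.features:
            if f.end > self.length or f.start > self.length:
                raise MalformedRecordError(
                    f"{self.id}/{f.name}: coordinate outside [1, {self.length}]"
                )
            if f.wraps_origin and not self.circular:
                raise MalformedRecordError(
                    f"{self.id}/{f.name}: wrap-around feature on a linear record"
                )

    def features_by_category(self, category: str) -> list[GeneFeature]:
        return [f for f in self.features if f.category == category]

    def census(self) -> dict[str, int]:
        """Feature counts per category, e.g. 13 PCG / 22 tRNA / 2 rRNA."""
        return {c: len(self.features_by_category(c)) for c in CATEGORIES}


# ---------------------------------------------------------------------------
# gene-name normalization
# ---------------------------------------------------------------------------


def _data_path(name: str):
    return importlib.resources.files("mitochar.data").joinpath(name)


def load_aliases(path=None) -> dict[str, str]:
    """Alias -> canonical symbol map (case-insensitive aliases)."""
    src = _data_path("gene_aliases.tsv") if path is None else path
    aliases: dict[str, str] = {}
    with open(src, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("alias\t"):
                continue
            alias, canonical = line.split("\t")
            aliases[alias.upper()] = canonical
    return aliases


_ALIASES: dict[str, str] | None = None


def normalize_gene_name(name: str, aliases: dict[str, str] | None = None) -> str:
    """Map dialect names (COX1, rrnL, tRNA-Ser(UCN), trns1, ...) to canonical symbols.

    Canonical symbols follow the annotation-table convention: COI..COIII,
    ND1..ND6, ND4L, ATP6/8, Cytb, 12S/16S, trnX with trnS1/S2 and trnL1/L2
    distinguished.
    """
    global _ALIASES
    if aliases is None:
        if _ALIASES is None:
            _ALIASES = load_aliases()
        aliases = _ALIASES
    key = name.strip()
    upper = key.upper()
    if upper in aliases:
        return aliases[upper]
    if upper.startswith("TRN"):
        rest = key[3:].strip("-_")
        if not rest:
            raise MalformedRecordError(f"cannot normalize tRNA name {name!r}")
        return "trn" + rest[0].upper() + rest[1:].lower()
    if upper in ("12S", "16S"):
        return upper
    if upper == "CYTB":
        return "Cytb"
    if upper in ("ND4L", "NAD4L"):
        return "ND4L"
    if upper.startswith(("ND", "ATP", "CO")):
        return upper
    return key


def infer_category(name: str) -> str:
    """Category from the canonical symbol: trn->tRNA, 12S/16S->rRNA, else PCG."""
    if name.startswith("trn"):
        return "tRNA"
    if name in ("12S", "16S"):
        return "rRNA"
    return "PCG"


# ---------------------------------------------------------------------------
# coordinate arithmetic
# ---------------------------------------------------------------------------


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Span of a feature in bp; wrap-around features count through the origin."""
    if f.wraps_origin:
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


def intergenic_spacer(a: GeneFeature, b: GeneFeature) -> int:
    """Unannotated bp between consecutive features; negative means overlap."""
    return b.start - a.end - 1


def feature_sequence(record: GenomeRecord, f: GeneFeature) -> str:
    """Sense-strand sequence of a feature (reverse-complemented for strand L)."""
    if record.sequence is None:
        raise MalformedRecordError(
            f"{record.id} carries no sequence; generate one with "
            "mitochar.synthetic_data"
        )
    if f.wraps_origin:
        raw = record.sequence[f.start - 1 :] + record.sequence[: f.end]
    else:
        raw = record.sequence[f.start - 1 : f.end]
    return revcomp(raw) if f.strand == "L" else raw


def validate(record: GenomeRecord) -> list[str]:
    """Non-fatal diagnostics: overlaps are reported, never clipped."""
    issues = []
    seen = set()
    for f in record.features:
        key = (f.name, f.start, f.end)
        if key in seen:
            issues.append(f"duplicate feature {f.name} at {f.start}-{f.end}")
        seen.add(key)
    ordered = sorted(record.features, key=lambda f: f.start)
    for a, b in zip(ordered, ordered[1:]):
        if not a.wraps_origin and intergenic_spacer(a, b) < 0:
            issues.append(
                f"overlap: {a.name} ({a.start}-{a.end}) and {b.name} "
                f"({b.start}-{b.end}), {-intergenic_spacer(a, b)} bp"
            )
    return issues


# ---------------------------------------------------------------------------
# feature-table TSV
# ---------------------------------------------------------------------------


def read_feature_table(
    path, length: int | None = None, record_id: str | None = None, circular: bool = True
) -> GenomeRecord:
    """Read an annotation table (one row per gene) into a GenomeRecord.

    The genome length may come from a ``# length=`` header or the ``length``
    argument.  Wrap-around rows are written with ``from`` > ``to``.
    """
    rows = []
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            cells = line.split("\t")
            if cells[0].lower() == "gene":
                continue
            if len(cells) < 5:
                raise MalformedRecordError(f"{path}:{lineno}: expected >=5 columns")
            rows.append((lineno, cells))
    if length is None:
        if "length" not in meta:
            raise MalformedRecordError(f"{path}: no genome length in header or argument")
        length = int(meta["length"].replace(",", ""))
    if record_id is None:
        record_id = meta.get("id", str(path))
    if "circular" in meta:
        circular = meta["circular"].lower() in ("true", "1", "yes")

    features, seen = [], set()
    for lineno, cells in rows:
        name = normalize_gene_name(cells[0])
        start, end = int(cells[1].replace(",", "")), int(cells[2].replace(",", ""))
        strand = cells[4].strip()
        if not (1 <= start <= length and 1 <= end <= length):
            raise MalformedRecordError(
                f"{path}:{lineno}: {name} coordinate outside [1,{length}]"
            )
        key = (name, start, end)
        if key in seen:
            raise MalformedRecordError(f"{path}:{lineno}: duplicate {name} {start}-{end}")
        seen.add(key)
        category = infer_category(name)
        start_codon = cells[5].strip() or None if len(cells) > 5 else None
        stop_codon = cells[6].strip() or None if len(cells) > 6 else None
        if category != "PCG":
            start_codon = stop_codon = None
        features.append(
            GeneFeature(
                name=name,
                category=category,
                start=start,
                end=end,
                strand=strand,
                start_codon=start_codon,
                stop_codon=stop_codon,
                wraps_origin=start > end,
            )
        )
    features.sort(key=lambda f: (f.wraps_origin, f.start))
    return GenomeRecord(
        id=record_id, length=length, circular=circular, sequence=None, features=features
    )


def write_feature_table(record: GenomeRecord, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# id={record.id}\tlength={record.length}\t"
            f"circular={str(record.circular).lower()}\n"
        )
        fh.write("gene\tfrom\tto\tsize\tstrand\tstart_codon\tstop_codon\n")
        for f in record.features:
            fh.write(
                "\t".join(
                    [
                        f.name,
                        str(f.start),
                        str(f.end),
                        str(feature_length(f, record.length)),
                        f.strand,
                        f.start_codon or "",
                        f.stop_codon or "",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# GenBank / FASTA / Newick
# ---------------------------------------------------------------------------

_GB_TYPES = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "NCR": "misc_feature"}
_GB_TYPES_REV = {v: k for k, v in _GB_TYPES.items()}


def write_genbank(record: GenomeRecord, path) -> None:
    """Write a record (sequence required) as a GenBank flat file.

    Wrapped features use a join() compound location; strand L maps to
    complement().  Start/stop codons are kept in qualifiers so the round
    trip is lossless.
    """
    if record.sequence is None:
        raise MalformedRecordError(f"{record.id}: GenBank output needs a sequence")
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                       description="")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        strand = 1 if f.strand == "H" else -1
        if f.wraps_origin:
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, record.length, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"gene": [f.name]}
        if f.start_codon:
            quals["note"] = [f"start_codon={f.start_codon};stop_codon={f.stop_codon}"]
        seqrec.features.append(SeqFeature(loc, type=_GB_TYPES[f.category], qualifiers=quals))
    SeqIO.write([seqrec], path, "genbank")


def read_genbank(path) -> GenomeRecord:
    try:
        seqrec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise MalformedRecordError(f"{path}: unparseable GenBank file: {exc}") from exc
    length = len(seqrec.seq)
    features = []
    for sf in seqrec.features:
        if sf.type == "source" or sf.type not in _GB_TYPES_REV:
            continue
        parts = sf.location.parts
        strand = "H" if (sf.location.strand or 1) >= 0 else "L"
        wraps = len(parts) > 1
        if wraps:
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
        else:
            start, end = int(sf.location.start) + 1, int(sf.location.end)
        name = normalize_gene_name(sf.qualifiers.get("gene", ["?"])[0])
        start_codon = stop_codon = None
        for note in sf.qualifiers.get("note", []):
            if note.startswith("start_codon="):
                fields = dict(kv.split("=") for kv in note.split(";"))
                start_codon = fields.get("start_codon") or None
                stop_codon = fields.get("stop_codon") or None
        features.append(
            GeneFeature(
                name=name,
                category=_GB_TYPES_REV[sf.type],
                start=start,
                end=end,
                strand=strand,
                start_codon=start_codon,
                stop_codon=stop_codon if stop_codon != "None" else None,
                wraps_origin=wraps,
            )
        )
    features.sort(key=lambda f: (f.wraps_origin, f.start))
    return GenomeRecord(
        id=seqrec.id,
        length=length,
        circular=seqrec.annotations.get("topology") == "circular",
        sequence=str(seqrec.seq).upper(),
        features=features,
    )


def read_fasta(path) -> dict[str, str]:
    """FASTA as an ordered name -> sequence map (uppercased)."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in out:
            raise MalformedRecordError(f"{path}: duplicate FASTA id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_newick(path_or_string, taxon_namespace=None) -> dendropy.Tree:
    src = str(path_or_string)
    kwargs = {"taxon_namespace": taxon_namespace} if taxon_namespace else {}
    if src.lstrip().startswith("("):
        return dendropy.Tree.get(data=src, schema="newick", **kwargs)
    return dendropy.Tree.get(path=src, schema="newick", **kwargs)


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def copy_record(record: GenomeRecord) -> GenomeRecord:
    return replace(record, features=[replace(f) for f in record.features])
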