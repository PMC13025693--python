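"""Base composition, A+T/G+C content, and strand skews per genome partition.

Skews follow the standard definitions AT skew = (A - T)/(A + T) and
GC skew = (G - C)/(G + C); mitochondrial strand asymmetry makes these
diagnostic of which strand a partition's genes sit on.  Partition
composition pools the *sense-strand* sequence of every feature in the
partition (the whole-genome partition uses the reference strand), so a
partition mixing H- and L-strand genes reports the pooled sense-strand
mixture rather than reference-strand counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .records_io import GenomeRecord, feature_sequence

PARTITIONS = ("whole", "PCG", "rRNA", "tRNA")


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (the convention of printed tables)."""
    factor = 10**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass
class CompositionSummary:
    n_a: int
    n_t: int
    n_g: int
    n_c: int
    pct_a: float
    pct_t: float
    pct_g: float
    pct_c: float
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float

    @property
    def total(self) -> int:
        return self.n_a + self.n_t + self.n_g + self.n_c

    def rounded(self) -> dict[str, float]:
        """Report at printed precision: percentages 1 dp, skews 3 dp."""
        return {
            "A%": round_half_away(self.pct_a, 1),
            "T%": round_half_away(self.pct_t, 1),
            "C%": round_half_away(self.pct_c, 1),
            "G%": round_half_away(self.pct_g, 1),
            "A+T%": round_half_away(self.at_content, 1),
            "C+G%": round_half_away(self.gc_content, 1),
            "AT_skew": round_half_away(self.at_skew, 3) if not math.isnan(self.at_skew) else float("nan"),
            "GC_skew": round_half_away(self.gc_skew, 3) if not math.isnan(self.gc_skew) else float("nan"),
        }


def composition(seq: str) -> CompositionSummary:
    """Counts, percentages and skews of a nucleotide string (N excluded)."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    n_a, n_t, n_g, n_c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    denom = n_a + n_t + n_g + n_c
    if denom == 0:
        raise ValueError("sequence contains no unambiguous nucleotides")
    at, gc = n_a + n_t, n_g + n_c
    return CompositionSummary(
        n_a=n_a,
        n_t=n_t,
        n_g=n_g,
        n_c=n_c,
        pct_a=100 * n_a / denom,
        pct_t=100 * n_t / denom,
        pct_g=100 * n_g / denom,
        pct_c=100 * n_c / denom,
        at_content=100 * at / denom,
        gc_content=100 * gc / denom,
        at_skew=(n_a - n_t) / at if at else float("nan"),
        gc_skew=(n_g - n_c) / gc if gc else float("nan"),
    )


def skew_from_percent(
    pct_a: float, pct_t: float, pct_g: float, pct_c: float
) -> tuple[float, float]:
    """Skews recomputed from printed percentages, rounded to 3 decimals.

    Exists to validate published composition tables where only percentages
    (not counts) are printed.
    """
    if min(pct_a, pct_t, pct_g, pct_c) < 0:
        raise ValueError("percentages must be non-negative")
    at, gc = pct_a + pct_t, pct_g + pct_c
    at_skew = (pct_a - pct_t) / at if at else float("nan")
    gc_skew = (pct_g - pct_c) / gc if gc else float("nan")
    return (
        round_half_away(at_skew, 3) if not math.isnan(at_skew) else at_skew,
        round_half_away(gc_skew, 3) if not math.isnan(gc_skew) else gc_skew,
    )


def partition_composition(record: GenomeRecord, partition: str) -> CompositionSummary:
    """Composition of one partition: whole genome, PCG, rRNA, or tRNA."""
    key = partition if partition in PARTITIONS else partition.lower()
    matches = [p for p in PARTITIONS if p.lower() == str(key).lower()]
    if not matches:
        raise ValueError(f"unknown partition {partition!r}; choose from {PARTITIONS}")
    partition = matches[0]
    if record.sequence is None:
        raise ValueError(
            f"{record.id} has no sequence; build one with mitochar.synthetic_data"
        )
    if partition == "whole":
        return composition(record.sequence)
    feats = record.features_by_category(partition)
    if not feats:
        raise ValueError(f"{record.id}: no {partition} features")
    pooled = "".join(feature_sequence(record, f) for f in feats)
    return composition(pooled)


def composition_table(record: GenomeRecord) -> dict[str, dict[str, float]]:
    """Per-partition rounded composition summary (printed-table layout)."""
    out = {}
    for part in PARTITIONS:
        try:
            summ = partition_composition(record, part)
        except ValueError:
            continue
        row = {"size_bp": summ.total}
        row.update(summ.rounded())
        out[part] = row
    return out
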