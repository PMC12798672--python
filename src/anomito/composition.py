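"""Base composition, AT/GC strand skews, and codon usage.

Skews follow Perna & Kocher: AT skew = (A - T)/(A + T), GC skew =
(G - C)/(G + C), computed per strand.  Mitogenome strand asymmetry makes the
two strands mirror images (skew(s) = -skew(revcomp(s))), so the strand a
statistic refers to always matters.  Decapod papers conventionally print the
AT skew of the heavy strand together with the GC skew of the light strand;
:func:`paper_style_skews` emits that mixed pair, while :func:`composition`
always reports both pure per-strand values.

Percentages are reported to 1 decimal and skews to 3 decimals, rounding
half-away-from-zero (the convention of the printed tables this package
reproduces).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq

from .mitoio import MITO_TABLE

__all__ = [
    "CompositionProfile",
    "CodonUsageTable",
    "composition",
    "at_skew",
    "gc_skew",
    "paper_style_skews",
    "codon_usage",
    "round_half_away",
    "UndefinedSkew",
]


class UndefinedSkew(ArithmeticError):
    """Raised when a skew denominator (A+T or G+C) is zero."""


def round_half_away(x: float, ndigits: int) -> float:
    """Round half away from zero (printed-table convention, not banker's)."""
    factor = 10 ** ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class CompositionProfile:
    """Counts, percentages and skews for one sequence/strand."""

    counts: dict[str, int]           # A, C, G, T (N excluded)
    n_ambiguous: int
    a_pct: float
    c_pct: float
    g_pct: float
    t_pct: float
    at_content: float
    gc_content: float
    at_skew: float
    gc_skew: float
    strand_label: str = "heavy"


def composition(seq: str, strand_label: str = "heavy") -> CompositionProfile:
    """Composition profile of a DNA sequence (N allowed, excluded from totals)."""
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"ambiguity codes other than N rejected: {sorted(bad)}")
    c = Counter(seq)
    counts = {b: c.get(b, 0) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains only N")
    pct = {b: 100.0 * counts[b] / total for b in "ACGT"}
    a, t, g, cc = counts["A"], counts["T"], counts["G"], counts["C"]
    return CompositionProfile(
        counts=counts,
        n_ambiguous=c.get("N", 0),
        a_pct=round_half_away(pct["A"], 1),
        c_pct=round_half_away(pct["C"], 1),
        g_pct=round_half_away(pct["G"], 1),
        t_pct=round_half_away(pct["T"], 1),
        at_content=round_half_away(pct["A"] + pct["T"], 2),
        gc_content=round_half_away(pct["G"] + pct["C"], 2),
        at_skew=at_skew(a, t) if a + t else float("nan"),
        gc_skew=gc_skew(g, cc) if g + cc else float("nan"),
        strand_label=strand_label,
    )


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); accepts counts or percentages. 3-decimal rounding."""
    if a + t <= 0:
        raise UndefinedSkew("A + T is zero")
    return round_half_away((a - t) / (a + t), 3)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); accepts counts or percentages. 3-decimal rounding."""
    if g + c <= 0:
        raise UndefinedSkew("G + C is zero")
    return round_half_away((g - c) / (g + c), 3)


def paper_style_skews(heavy_strand_seq: str) -> tuple[float, float]:
    """(AT skew of the heavy strand, GC skew of the light strand).

    The mixed convention under which the printed whole-genome skews of the
    anomuran records are reproducible from their printed per-strand
    compositions.  Pure per-strand values come from :func:`composition`.
    """
    heavy = composition(heavy_strand_seq, "heavy")
    light = composition(str(Seq(heavy_strand_seq).reverse_complement()), "light")
    return heavy.at_skew, light.gc_skew


# ---------------------------------------------------------------------------
# Codon usage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts, frequencies per thousand, and RSCU values."""

    counts: dict[str, int]
    per_thousand: dict[str, float]
    rscu: dict[str, float]           # sense codons only
    amino_acid: dict[str, str]       # codon -> aa ("*" for stops)
    total_codons: int


def _synonymous_families() -> dict[str, list[str]]:
    fams: dict[str, list[str]] = {}
    for codon, aa in MITO_TABLE.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    return fams


def codon_usage(cds_list: Sequence[str] | Iterable[str]) -> CodonUsageTable:
    """Codon usage over concatenated coding sequences.

    RSCU for codon c of amino acid a = count(c) * |family(a)| / sum of family
    counts; families with zero observations get RSCU 0 for every member.
    Uses the invertebrate mitochondrial code.
    """
    counts: Counter[str] = Counter()
    for i, cds in enumerate(cds_list):
        cds = cds.upper()
        if len(cds) % 3:
            raise ValueError(f"sequence {i} length {len(cds)} not a multiple of 3")
        for j in range(0, len(cds), 3):
            codon = cds[j:j + 3]
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no countable codons")
    per_thousand = {c: 1000.0 * n / total for c, n in counts.items()}
    aa_of = {**MITO_TABLE.forward_table,
             **{c: "*" for c in MITO_TABLE.stop_codons}}
    rscu: dict[str, float] = {}
    for aa, family in _synonymous_families().items():
        fam_total = sum(counts.get(c, 0) for c in family)
        for c in family:
            rscu[c] = (len(family) * counts.get(c, 0) / fam_total
                       if fam_total else 0.0)
    return CodonUsageTable(dict(counts), per_thousand, rscu, aa_of, total)
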