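"""Reading, writing and canonical naming of annotated mitochondrial genomes.

A metazoan mitogenome carries 13 protein-coding genes (PCGs), 22 tRNAs, two
rRNAs and a non-coding control region (CR).  GenBank annotations label these
genes heterogeneously ("ND1", "NADH dehydrogenase subunit 1", "trnL(taa)"...);
this module maps every label onto a closed 38-symbol vocabulary so that
downstream gene-order and selection analyses can compare records directly.

Coordinates are 1-based inclusive on the deposited plus strand (GenBank
convention).  The deposited plus strand is treated as the "heavy" strand for
composition bookkeeping unless a record says otherwise.  Features that span
the circular origin are stored with ``start > end`` and ``wraps=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "PCGS",
    "TRNAS",
    "RRNAS",
    "GENE_VOCABULARY",
    "GeneFeature",
    "MitoGenome",
    "IntergenicRegion",
    "AnnotationError",
    "FormatError",
    "canonical_name",
    "load_synonyms",
    "read_genbank",
    "read_fasta",
    "locate_control_region",
    "extract_cds",
    "translate_mito",
    "write_feature_table",
    "write_genbank",
    "MIN_CR_LENGTH",
]

PCGS = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)
TRNAS = tuple(
    "trn" + x
    for x in ("A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
              "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y")
)
RRNAS = ("rrnL", "rrnS")
#: 37 genes + CR
GENE_VOCABULARY = PCGS + TRNAS + RRNAS + ("CR",)

#: Invertebrate mitochondrial genetic code (NCBI translation table 5).
MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]

#: Gaps shorter than this are "too compact" to count as a control region.
MIN_CR_LENGTH = 50


class FormatError(ValueError):
    """Input file could not be parsed in the expected format."""


class AnnotationError(ValueError):
    """A record's annotation is missing or unusable."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on the plus strand of a circular mitogenome."""

    name: str              # canonical symbol from GENE_VOCABULARY
    start: int             # 1-based inclusive
    end: int               # 1-based inclusive; < start iff wraps
    strand: str            # "+" or "-"
    kind: str              # "PCG" | "tRNA" | "rRNA" | "CR"
    wraps: bool = False

    def __post_init__(self):
        base = self.name.split("_copy")[0]
        if base not in GENE_VOCABULARY:
            raise ValueError(f"unknown gene symbol {self.name!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.wraps and self.start > self.end:
            raise ValueError(f"{self.name}: start > end without wrap flag")

    def length(self, genome_length: int) -> int:
        if self.wraps:
            return genome_length - self.start + 1 + self.end
        return self.end - self.start + 1


@dataclass
class MitoGenome:
    """A circular annotated mitochondrial genome (deposited plus strand)."""

    accession: str
    taxon: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)
    heavy_strand_is_plus: bool = True
    unmapped: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError("empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        n = len(self.sequence)
        for f in self.features:
            if not (1 <= f.start <= n and 1 <= f.end <= n):
                raise ValueError(f"{f.name}: coordinates outside [1,{n}]")

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"{name} not annotated in {self.accession}")

    def slice(self, start: int, end: int, wraps: bool = False) -> str:
        """Plus-strand subsequence, 1-based inclusive, resolving wraparound."""
        if wraps or start > end:
            return self.sequence[start - 1:] + self.sequence[:end]
        return self.sequence[start - 1:end]


@dataclass(frozen=True)
class IntergenicRegion:
    """A circular gap between consecutive annotated features."""

    start: int
    end: int
    length: int
    flank5: str
    flank3: str
    wraps: bool = False


# ---------------------------------------------------------------------------
# Canonical naming
# ---------------------------------------------------------------------------

def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Load the synonym table; returns {normalized label -> canonical symbol}."""
    if path is None:
        text = (resources.files("anomito") / "data/gene_synonyms.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    table: dict[str, str] = {}
    for canonical, labels in raw.items():
        for label in labels:
            table[_normalize_label(str(label))] = canonical
        table[_normalize_label(canonical)] = canonical
    return table


def _normalize_label(label: str) -> str:
    return re.sub(r"[\s_\-]+", "", label.strip().lower())


_DEFAULT_SYNONYMS: dict[str, str] | None = None


def _default_synonyms() -> dict[str, str]:
    global _DEFAULT_SYNONYMS
    if _DEFAULT_SYNONYMS is None:
        _DEFAULT_SYNONYMS = load_synonyms()
    return _DEFAULT_SYNONYMS


# anticodons that disambiguate the duplicated leucine / serine tRNAs
_ANTICODON_MAP = {
    ("trnL", "tag"): "trnL1", ("trnL", "taa"): "trnL2",
    ("trnS", "tct"): "trnS1", ("trnS", "tga"): "trnS2",
    ("trnL", "uag"): "trnL1", ("trnL", "uaa"): "trnL2",
    ("trnS", "ucu"): "trnS1", ("trnS", "uga"): "trnS2",
}


def canonical_name(label: str, anticodon: str | None = None,
                   synonyms: dict[str, str] | None = None) -> str | None:
    """Map a raw annotation label onto the canonical vocabulary.

    Returns None when the label cannot be resolved.  Ambiguous leucine /
    serine tRNA labels ("trnL", "tRNA-Leu") are resolved by ``anticodon``
    or by an anticodon embedded in the label itself, e.g. ``trnL(taa)``.
    """
    table = synonyms or _default_synonyms()
    norm = _normalize_label(label)
    if norm in table:
        return table[norm]
    # anticodon embedded in the label: trnL(taa), tRNA-Ser (tga) ...
    m = re.match(r"^(.*?)\(([acgtu]{3})\)$", norm)
    embedded = None
    if m:
        norm, embedded = m.group(1), m.group(2)
    base = table.get(norm)
    if base is None and norm in ("trnl", "trnaleu", "leu"):
        base = "trnL"
    if base is None and norm in ("trns", "trnaser", "ser"):
        base = "trnS"
    if base in ("trnL", "trnS"):
        ac = (anticodon or embedded or "").lower().replace("u", "t")
        return _ANTICODON_MAP.get((base, ac))
    return base


# ---------------------------------------------------------------------------
# GenBank / FASTA input
# ---------------------------------------------------------------------------

_KIND_BY_NAME = {**{g: "PCG" for g in PCGS},
                 **{t: "tRNA" for t in TRNAS},
                 **{r: "rRNA" for r in RRNAS},
                 "CR": "CR"}


def read_genbank(path: str | Path,
                 synonyms: dict[str, str] | None = None) -> MitoGenome:
    """Read a single-record GenBank flat file into a :class:`MitoGenome`.

    Gene/tRNA/rRNA/D-loop features are mapped to canonical symbols; labels
    that cannot be resolved are collected in ``genome.unmapped``.  Duplicated
    genes are suffixed ``_copy2``, ``_copy3``... in record order.
    """
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise FormatError(f"{path}: not a parseable GenBank file ({exc})") from exc
    if len(records) != 1:
        raise FormatError(f"{path}: expected exactly one record, got {len(records)}")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    n = len(seq)
    features: list[GeneFeature] = []
    unmapped: list[str] = []
    seen_spans: set[tuple[int, int, str]] = set()
    counts: dict[str, int] = {}
    for feat in rec.features:
        if feat.type not in ("gene", "CDS", "tRNA", "rRNA", "misc_feature", "D-loop"):
            continue
        quals = feat.qualifiers
        labels = (quals.get("gene", []) + quals.get("product", [])
                  + quals.get("note", []) + quals.get("standard_name", []))
        if feat.type == "D-loop":
            labels = labels or ["D-loop"]
        anticodon = None
        for ac in quals.get("anticodon", []) + quals.get("codon_recognized", []):
            m = re.search(r"seq:([acgtu]{3})", ac, re.I) or re.fullmatch(r"([ACGTUacgtu]{3})", ac.strip())
            if m:
                anticodon = m.group(1)
        name = None
        for label in labels:
            name = canonical_name(label, anticodon=anticodon, synonyms=synonyms)
            if name:
                break
        if name is None:
            if labels:
                unmapped.append(f"{feat.type}:{labels[0]}")
            continue
        start = int(feat.location.start) + 1
        end = int(feat.location.end)
        wraps = False
        parts = feat.location.parts
        if len(parts) > 1 and int(parts[0].end) == n and int(parts[-1].start) == 0:
            start = int(parts[0].start) + 1
            end = int(parts[-1].end)
            wraps = True
        strand = "-" if feat.location.strand == -1 else "+"
        span = (start, end, strand)
        if span in seen_spans and any(f.name.split("_copy")[0] == name
                                      and (f.start, f.end, f.strand) == span
                                      for f in features):
            continue  # gene + CDS/tRNA pair annotating the same span
        seen_spans.add(span)
        counts[name] = counts.get(name, 0) + 1
        label = name if counts[name] == 1 else f"{name}_copy{counts[name]}"
        features.append(GeneFeature(label, start, end, strand,
                                    _KIND_BY_NAME[name], wraps))
    if not features:
        raise AnnotationError(f"{rec.id}: no mappable gene features")
    features.sort(key=lambda f: (f.start, f.end))
    taxon = rec.annotations.get("organism", rec.description or rec.id)
    return MitoGenome(
        accession=rec.id, taxon=taxon, sequence=seq,
        circular=rec.annotations.get("topology", "circular") == "circular",
        features=features, unmapped=unmapped,
    )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA; returns [(header, sequence)] uppercase with U mapped to T."""
    path = Path(path)
    records = [(rec.id, str(rec.seq).upper().replace("U", "T"))
               for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


# ---------------------------------------------------------------------------
# Control region and CDS extraction
# ---------------------------------------------------------------------------

def intergenic_gaps(genome: MitoGenome) -> list[IntergenicRegion]:
    """All circular gaps between consecutive annotated features.

    Features (CR excluded) are unrolled onto [1, 2n) so that a feature that
    wraps the origin becomes a single interval; nested features never create
    negative gaps because a running maximum of feature ends is kept.
    """
    feats = [f for f in genome.features if f.kind != "CR"] or list(genome.features)
    n = len(genome)
    unrolled = sorted(
        ((f.start, f.end + n if f.wraps else f.end, f) for f in feats),
        key=lambda t: (t[0], -t[1]))
    gaps: list[IntergenicRegion] = []
    prev_end, prev_feat = unrolled[0][1], unrolled[0][2]
    for start, end, f in unrolled[1:]:
        glen = start - prev_end - 1
        if glen > 0:
            gstart = (prev_end % n) + 1
            gend = ((start - 2) % n) + 1
            gaps.append(IntergenicRegion(gstart, gend, glen, prev_feat.name,
                                         f.name, wraps=gstart > gend))
        if end > prev_end:
            prev_end, prev_feat = end, f
    first_start, _, first_feat = unrolled[0]
    glen = (first_start + n) - prev_end - 1
    if glen > 0:
        gstart = (prev_end % n) + 1
        gend = ((first_start - 2) % n) + 1
        gaps.append(IntergenicRegion(gstart, gend, glen, prev_feat.name,
                                     first_feat.name, wraps=gstart > gend))
    return gaps


def locate_control_region(genome: MitoGenome) -> IntergenicRegion:
    """Locate the control region as the longest circular inter-feature gap.

    An explicitly annotated CR/D-loop feature takes precedence.  Raises
    :class:`AnnotationError` with a "too compact" message when every gap is
    shorter than :data:`MIN_CR_LENGTH`.
    """
    if len(genome.features) < 2:
        raise AnnotationError(f"{genome.accession}: need >=2 features to find gaps")
    for f in genome.features:
        if f.kind == "CR":
            others = sorted((g for g in genome.features if g.kind != "CR"),
                            key=lambda g: g.start)
            flank5 = flank3 = ""
            for g in others:
                if g.end < f.start:
                    flank5 = g.name
                if not flank3 and g.start > f.end:
                    flank3 = g.name
            if others:
                flank5 = flank5 or others[-1].name
                flank3 = flank3 or others[0].name
            return IntergenicRegion(f.start, f.end, f.length(len(genome)),
                                    flank5, flank3, f.wraps)
    best = max(intergenic_gaps(genome), key=lambda g: g.length)
    if best.length < MIN_CR_LENGTH:
        raise AnnotationError(
            f"{genome.accession}: control region too compact "
            f"(largest gap {best.length} bp < {MIN_CR_LENGTH} bp)")
    return best


def translate_mito(cds: str) -> str:
    """Translate with the invertebrate mitochondrial code (table 5)."""
    prot = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i:i + 3]
        if codon in MITO_TABLE.stop_codons:
            prot.append("*")
        else:
            prot.append(MITO_TABLE.forward_table.get(codon, "X"))
    return "".join(prot)


def extract_cds(genome: MitoGenome, gene: str) -> str:
    """Extract a PCG in coding orientation, frame-trimmed, stop removed.

    Minus-strand genes are reverse-complemented; the length is trimmed to a
    multiple of 3 from the 3' end (this also drops incomplete T/TA stops);
    a terminal complete stop codon is removed.  Internal stop codons are
    recorded as a warning on the genome but the sequence is still returned.
    """
    feat = genome.feature(gene)
    if feat.kind != "PCG":
        raise KeyError(f"{gene} is not a protein-coding gene")
    raw = genome.slice(feat.start, feat.end, feat.wraps)
    if feat.strand == "-":
        raw = str(Seq(raw).reverse_complement())
    if len(raw) % 3:
        raw = raw[: len(raw) - len(raw) % 3]
    if len(raw) >= 3 and raw[-3:] in MITO_TABLE.stop_codons:
        raw = raw[:-3]
    if "*" in translate_mito(raw):
        genome.warnings.append(f"{gene}: internal stop codon(s) in CDS")
    return raw


# ---------------------------------------------------------------------------
# Tabular output
# ---------------------------------------------------------------------------

def write_genbank(genome: MitoGenome, path: str | Path) -> None:
    """Write a MitoGenome as a GenBank flat file (round-trips read_genbank)."""
    from Bio.SeqFeature import FeatureLocation, SeqFeature
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(Seq(genome.sequence), id=genome.accession,
                    name=genome.accession.replace(".", "")[:16],
                    description=genome.taxon)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.circular else "linear"
    rec.annotations["organism"] = genome.taxon
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
               "CR": "misc_feature"}
    for f in genome.features:
        loc = FeatureLocation(f.start - 1, f.end,
                              strand=-1 if f.strand == "-" else 1)
        quals = {"gene": [f.name]}
        if f.kind == "CR":
            quals = {"note": ["putative control region"]}
        rec.features.append(SeqFeature(loc, type=type_of[f.kind],
                                       qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


FEATURE_COLUMNS = ("accession", "gene", "start", "end", "strand", "kind")


def write_feature_table(genomes: Iterable[MitoGenome], path: str | Path) -> None:
    """Write the gene-feature table as TSV with the fixed column order."""
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_COLUMNS) + "\n")
        for g in genomes:
            for f in g.features:
                fh.write(f"{g.accession}\t{f.name}\t{f.start}\t{f.end}"
                         f"\t{f.strand}\t{f.kind}\n")
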