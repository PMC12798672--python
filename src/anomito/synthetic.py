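"""Synthetic mitogenomes, control regions and codon pairs with known truth.

Every generator is a pure function of its spec (seed included; the PRNG is
numpy's seeded PCG64), and returns a :class:`TruthBundle` recording exactly
what was planted, so downstream detectors can be validated against ground
truth instead of against themselves.

Defaults emulate the anomuran study conditions: 14-18 kb circular genomes
with 37 named genes plus one control region, heavy-strand base composition
around A 31.7 / T 41.8 / C 9.8 / G 16.7 %, AT-rich control regions of about
1.3 kb carrying a ~47 bp tandem repeat at ~3.6 copies alongside poly-T, GA
and [TA(A)]n motif blocks and hairpin-forming inverted repeats, and coding
pairs evolved at a chosen omega.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .gene_order import GeneOrder, load_reference
from .mitoio import MITO_TABLE, GeneFeature, MitoGenome, PCGS

__all__ = [
    "CRSpec",
    "SyntheticGenomeSpec",
    "CodonPairSpec",
    "TruthBundle",
    "generate_control_region",
    "generate_genome",
    "evolve_codon_pair",
    "structured_trna",
    "HEAVY_STRAND_COMPOSITION",
    "CR_COMPOSITION",
]

#: heavy-strand base fractions of the H. dentata-like study genomes
HEAVY_STRAND_COMPOSITION = {"A": 0.317, "T": 0.418, "C": 0.098, "G": 0.167}
#: control-region base fractions (printed CR composition of the same record)
CR_COMPOSITION = {"A": 0.326, "T": 0.390, "C": 0.120, "G": 0.164}

_STOPS = set(MITO_TABLE.stop_codons)
_SENSE = sorted(MITO_TABLE.forward_table)
_BASES = "ACGT"

#: approximate PCG lengths (codons) typical of decapod mitogenomes
_PCG_CODONS = {"cox1": 512, "cox2": 228, "cox3": 261, "cob": 379,
               "nad1": 312, "nad2": 334, "nad3": 117, "nad4": 446,
               "nad4L": 98, "nad5": 572, "nad6": 156, "atp6": 225,
               "atp8": 53}
_RRNA_LENGTHS = {"rrnL": 1300, "rrnS": 800}


@dataclass
class TruthBundle:
    """Ground truth of a generated object (coordinates 1-based inclusive)."""

    seed: int
    gene_order: GeneOrder | None = None
    rearranged: list = field(default_factory=list)
    repeat: dict | None = None
    motifs: list[dict] = field(default_factory=list)
    hairpins: list[dict] = field(default_factory=list)
    omega: float | None = None
    realized_synonymous: float | None = None
    realized_nonsynonymous: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.gene_order is not None:
            d["gene_order"] = list(self.gene_order.order)
        return d


# ---------------------------------------------------------------------------
# Composition-matched sampling
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, n: int, comp: dict[str, float]) -> str:
    probs = np.array([comp[b] for b in _BASES])
    probs = probs / probs.sum()
    return "".join(np.array(list(_BASES))[rng.choice(4, size=n, p=probs)])


def _codon_distribution(comp: dict[str, float]) -> np.ndarray:
    """Sense-codon probabilities whose base marginal matches ``comp``.

    Iterative proportional fitting of per-base weights: sampling codons as
    independent biased bases conditioned on not being a stop codon would
    distort the marginal (the excluded stops are T/A-rich), so the weights
    are adjusted until the expected composition matches the target.
    """
    target = np.array([comp[b] for b in _BASES])
    target = target / target.sum()
    w = target.copy()
    idx = np.array([[_BASES.index(ch) for ch in c] for c in _SENSE])
    for _ in range(200):
        p = w[idx[:, 0]] * w[idx[:, 1]] * w[idx[:, 2]]
        p = p / p.sum()
        marginal = np.zeros(4)
        for pos in range(3):
            np.add.at(marginal, idx[:, pos], p / 3.0)
        if np.max(np.abs(marginal - target)) < 1e-9:
            break
        w = w * target / np.maximum(marginal, 1e-12)
    p = w[idx[:, 0]] * w[idx[:, 1]] * w[idx[:, 2]]
    return p / p.sum()


def _sample_orf(rng: np.random.Generator, n_codons: int,
                comp: dict[str, float]) -> str:
    probs = _codon_distribution(comp)
    body = "".join(np.array(_SENSE)[rng.choice(len(_SENSE), size=n_codons,
                                               p=probs)])
    return "ATG" + body + "TAA"


def _complement_comp(comp: dict[str, float]) -> dict[str, float]:
    return {"A": comp["T"], "T": comp["A"], "C": comp["G"], "G": comp["C"]}


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Control region
# ---------------------------------------------------------------------------

@dataclass
class CRSpec:
    """Recipe for a synthetic control region."""

    length: int = 1313
    repeat_period: int = 47
    repeat_copies: float = 3.6
    repeat_mutation_rate: float = 0.05
    n_polyT: int = 2
    n_GA_blocks: int = 3
    n_TAA_blocks: int = 2
    hairpin_stems: tuple[tuple[int, int], ...] = ((12, 5),)
    composition: dict[str, float] = field(
        default_factory=lambda: dict(CR_COMPOSITION))
    seed: int = 0


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = _BASES[rng.integers(0, 4)]
    return "".join(out)


def generate_control_region(spec: CRSpec) -> tuple[str, TruthBundle]:
    """Build a control region with planted repeat, motifs and hairpins.

    Elements are placed left to right with random background spacing; the
    truth bundle records 1-based inclusive coordinates of every element.
    """
    rng = np.random.default_rng(spec.seed)
    truth = TruthBundle(seed=spec.seed)

    segments: list[tuple[str, str, dict]] = []   # (kind, seq, meta)
    # tandem repeat: period-length motif tiled copies times, mutated per copy
    motif = _background(rng, spec.repeat_period, spec.composition)
    span = int(round(spec.repeat_period * spec.repeat_copies))
    tiles = []
    while sum(len(t) for t in tiles) < span:
        tiles.append(_mutate(rng, motif, spec.repeat_mutation_rate))
    repeat_seq = "".join(tiles)[:span]
    segments.append(("repeat", repeat_seq,
                     {"period": spec.repeat_period,
                      "copies": round(span / spec.repeat_period, 2),
                      "consensus": motif}))
    for _ in range(spec.n_polyT):
        segments.append(("polyT", "T" * int(rng.integers(6, 11)), {}))
    for _ in range(spec.n_GA_blocks):
        k = int(rng.integers(7, 13))
        block = "".join(rng.choice(["G", "A"], size=k, p=[0.45, 0.55]))
        if block.count("G") < 2:
            block = "GG" + block[2:]
        segments.append(("GA_block", block, {}))
    for _ in range(spec.n_TAA_blocks):
        units = ["TA" if rng.random() < 0.5 else "TAA"
                 for _ in range(int(rng.integers(3, 6)))]
        segments.append(("TAA_block", "".join(units), {}))
    for arm, loop in spec.hairpin_stems:
        # GC-enriched arm so the planted stem is thermodynamically dominant
        arm_seq = "".join(rng.choice(list("GCGA"), size=arm))
        hp = arm_seq + _background(rng, loop, spec.composition) + _revcomp(arm_seq)
        segments.append(("hairpin", hp, {"arm": arm, "loop": loop}))

    planted = sum(len(s) for _, s, _ in segments)
    if planted > spec.length:
        raise ValueError(f"planted elements ({planted} bp) exceed CR length "
                         f"({spec.length} bp)")
    spare = spec.length - planted
    cuts = np.sort(rng.integers(0, spare + 1, size=len(segments)))
    gap_sizes = np.diff(np.concatenate([[0], cuts, [spare]]))
    out = []
    pos = 0
    for (kind, seq, meta), gap in zip(segments, gap_sizes[:-1]):
        filler = _background(rng, int(gap), spec.composition)
        out.append(filler)
        pos += len(filler)
        start, end = pos + 1, pos + len(seq)
        if kind == "repeat":
            truth.repeat = {"start": start, "end": end, **meta}
        elif kind == "hairpin":
            truth.hairpins.append({"start": start, "end": end, **meta})
        else:
            truth.motifs.append({"kind": kind, "start": start, "end": end})
        out.append(seq)
        pos += len(seq)
    out.append(_background(rng, int(gap_sizes[-1]), spec.composition))
    cr = "".join(out)
    assert len(cr) == spec.length
    return cr, truth


# ---------------------------------------------------------------------------
# Whole genomes
# ---------------------------------------------------------------------------

def _default_base_order() -> GeneOrder:
    """Canonical 37-gene order with the CR between rrnS and trnI."""
    ref = load_reference("canonical37")
    order = list(ref.order)
    i = order.index("-rrnS")
    order.insert(i + 1, "+CR")
    return GeneOrder("synthetic-base", tuple(order), include_cr=True)


@dataclass
class SyntheticGenomeSpec:
    """Recipe for a synthetic annotated mitogenome."""

    accession: str = "SYN000001"
    taxon: str = "Synthetica anomura"
    base_order: GeneOrder | None = None
    rearrangements: tuple = ()   # ("transposition", gene, after_gene) or
                                 # ("inversion", first_gene, last_gene)
    composition: dict[str, float] = field(
        default_factory=lambda: dict(HEAVY_STRAND_COMPOSITION))
    cr_spec: CRSpec | None = None
    max_spacer: int = 5
    seed: int = 0


def _apply_rearrangements(order: list[str], events) -> tuple[list[str], list]:
    base = lambda g: g.lstrip("+-")
    rearranged = []
    for ev in events:
        kind = ev[0]
        if kind == "transposition":
            _, gene, after = ev
            sym = next(g for g in order if base(g) == gene)
            order.remove(sym)
            j = next(i for i, g in enumerate(order) if base(g) == after)
            order.insert(j + 1, sym)
            rearranged.append(("transposition", gene, after))
        elif kind == "inversion":
            _, first, last = ev
            i = next(k for k, g in enumerate(order) if base(g) == first)
            j = next(k for k, g in enumerate(order) if base(g) == last)
            if i > j:
                i, j = j, i
            flipped = [("-" + base(g)) if g.startswith("+") else ("+" + base(g))
                       for g in reversed(order[i:j + 1])]
            order[i:j + 1] = flipped
            rearranged.append(("inversion", first, last))
        else:
            raise ValueError(f"unknown rearrangement kind {kind!r}")
    return order, rearranged


def generate_genome(spec: SyntheticGenomeSpec) -> tuple[MitoGenome, TruthBundle]:
    """Assemble a circular annotated genome following the spec's gene order.

    PCGs are random ORFs (invertebrate mito code) at the target heavy-strand
    composition; minus-strand genes are sampled at the complementary
    composition in coding orientation so the deposited plus strand keeps the
    target composition.  The CR is built by :func:`generate_control_region`.
    """
    rng = np.random.default_rng(spec.seed)
    base_order = spec.base_order or _default_base_order()
    order, rearranged = _apply_rearrangements(list(base_order.order),
                                              spec.rearrangements)
    cr_spec = spec.cr_spec or CRSpec(seed=int(rng.integers(0, 2**31)))
    comp = spec.composition
    comp_minus = _complement_comp(comp)

    pieces: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    cr_truth = None
    kind_of = {**{g: "PCG" for g in PCGS}, "rrnL": "rRNA", "rrnS": "rRNA",
               "CR": "CR"}
    for sym in order:
        strand = "-" if sym.startswith("-") else "+"
        gene = sym.lstrip("+-")
        gene_comp = comp if strand == "+" else comp_minus
        if gene in PCGS:
            seq = _sample_orf(rng, _PCG_CODONS[gene], gene_comp)
        elif gene in _RRNA_LENGTHS:
            seq = _background(rng, _RRNA_LENGTHS[gene], gene_comp)
        elif gene == "CR":
            seq, cr_truth = generate_control_region(cr_spec)
        else:   # tRNA
            seq = _background(rng, int(rng.integers(60, 76)), gene_comp)
        if strand == "-":
            seq = _revcomp(seq)
        start = pos + 1
        pos += len(seq)
        features.append(GeneFeature(gene, start, pos, strand,
                                    kind_of.get(gene, "tRNA")))
        pieces.append(seq)
        spacer = int(rng.integers(0, spec.max_spacer + 1))
        pieces.append(_background(rng, spacer, comp))
        pos += spacer
    genome = MitoGenome(spec.accession, spec.taxon, "".join(pieces),
                        circular=True, features=features)
    truth = TruthBundle(seed=spec.seed,
                        gene_order=GeneOrder(spec.accession, tuple(order),
                                             include_cr=True),
                        rearranged=rearranged)
    if cr_truth is not None:
        cr_feat = next(f for f in features if f.name == "CR")
        truth.extras["cr_start"] = cr_feat.start
        truth.extras["cr_end"] = cr_feat.end
        truth.repeat = cr_truth.repeat
        truth.motifs = cr_truth.motifs
        truth.hairpins = cr_truth.hairpins
    return genome, truth


# ---------------------------------------------------------------------------
# Codon-pair evolution
# ---------------------------------------------------------------------------

@dataclass
class CodonPairSpec:
    """Recipe for a homologous coding-sequence pair evolved at a known omega.

    ``t`` is the expected number of synonymous substitutions per synonymous
    site separating the two sequences (both branches together); ``kappa`` is
    the transition/transversion rate ratio of the underlying mutation
    process (default 1: the mutational assumption of NG86-style counting).
    """

    n_codons: int = 500
    omega: float = 0.2
    kappa: float = 1.0
    t: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")


_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def _site_rates(seq: list[str], pos: int, kappa: float, omega: float
                ) -> np.ndarray:
    """Rates of the 4 target bases at one nucleotide position (self = 0)."""
    ci = pos // 3
    codon = seq[ci]
    within = pos % 3
    rates = np.zeros(4)
    aa = MITO_TABLE.forward_table[codon]
    for bi, b in enumerate(_BASES):
        if b == codon[within]:
            continue
        mut = codon[:within] + b + codon[within + 1:]
        if mut in _STOPS:
            continue   # stop-generating changes rejected
        r = kappa if (codon[within], b) in _TRANSITIONS else 1.0
        if MITO_TABLE.forward_table[mut] != aa:
            r *= omega
        rates[bi] = r
    return rates


def evolve_codon_pair(spec: CodonPairSpec) -> tuple[str, str, TruthBundle]:
    """Simulate two sequences from a common ancestor at divergence ``t``.

    A continuous-time process over codons: nucleotide proposals with kappa
    transition bias, synonymous changes accepted at relative rate 1,
    nonsynonymous at rate omega, stop-generating changes rejected.  The
    clock is scaled so one time unit equals one synonymous substitution per
    (NG86) synonymous site of the ancestor; each branch runs for t/2.
    """
    from .kaks import _syn_sites   # site definition shared with the estimator

    rng = np.random.default_rng(spec.seed)
    probs = _codon_distribution({b: 0.25 for b in _BASES})
    anc = list(np.array(_SENSE)[rng.choice(len(_SENSE), size=spec.n_codons,
                                           p=probs)])
    l_s = sum(_syn_sites(c) for c in anc)

    # ancestral total synonymous mutation rate (kappa-weighted)
    def syn_rate_total(seq):
        tot = 0.0
        for ci, codon in enumerate(seq):
            aa = MITO_TABLE.forward_table[codon]
            for within in range(3):
                for b in _BASES:
                    if b == codon[within]:
                        continue
                    mut = codon[:within] + b + codon[within + 1:]
                    if mut in _STOPS:
                        continue
                    if MITO_TABLE.forward_table[mut] == aa:
                        tot += kappa if (codon[within], b) in _TRANSITIONS else 1.0
        return tot

    kappa, omega = spec.kappa, spec.omega
    scale = l_s / syn_rate_total(anc)   # one unit = one syn sub per syn site

    def run_branch(duration: float):
        seq = list(anc)
        n = 3 * spec.n_codons
        rates = np.zeros((n, 4))
        for p in range(n):
            rates[p] = _site_rates(seq, p, kappa, omega)
        rates *= scale
        t_now, n_syn, n_nonsyn = 0.0, 0, 0
        total = rates.sum()
        while True:
            t_now += rng.exponential(1.0 / total)
            if t_now >= duration:
                break
            flat = rates.ravel()
            k = rng.choice(flat.size, p=flat / total)
            p, bi = divmod(k, 4)
            ci, within = divmod(p, 3)
            old = seq[ci]
            new = old[:within] + _BASES[bi] + old[within + 1:]
            if MITO_TABLE.forward_table[new] == MITO_TABLE.forward_table[old]:
                n_syn += 1
            else:
                n_nonsyn += 1
            seq[ci] = new
            for q in range(3 * ci, 3 * ci + 3):
                total -= rates[q].sum()
                rates[q] = _site_rates(seq, q, kappa, omega) * scale
                total += rates[q].sum()
        return "".join(seq), n_syn, n_nonsyn

    s1, syn1, non1 = run_branch(spec.t / 2.0)
    s2, syn2, non2 = run_branch(spec.t / 2.0)
    truth = TruthBundle(seed=spec.seed, omega=spec.omega,
                        realized_synonymous=syn1 + syn2,
                        realized_nonsynonymous=non1 + non2,
                        extras={"t": spec.t, "kappa": spec.kappa,
                                "ancestor_syn_sites": l_s})
    return s1, s2, truth


# ---------------------------------------------------------------------------
# Designed tRNA test sequences
# ---------------------------------------------------------------------------

def structured_trna(drop_d_arm: bool = False) -> str:
    """A designed cloverleaf-folding test sequence built from four stems.

    Acceptor stem 7 bp closing a three-way junction of D, anticodon and T
    hairpins (GC-rich arms so the designed pairing dominates the fold).
    With ``drop_d_arm`` the D hairpin is replaced by an unstructured linker,
    yielding an atypical (two-arm) fold.
    """
    a1, a2 = "GGGGCCG", "CGGCCCC"
    d1, d2 = "GCAGG", "CCTGC"
    c1, c2 = "CTGGG", "CCCAG"
    t1, t2 = "GGTGC", "GCACC"
    d_arm = d1 + "AATAAAA" + d2 if not drop_d_arm else "AATAAAA"
    return (a1 + "TA" + d_arm + "T" + c1 + "TTAAATT" + c2
            + "AT" + t1 + "TAAAAAT" + t2 + "A" + a2)
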