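"""Pairwise Ka/Ks (dN/dS) estimation for mitochondrial protein-coding genes.

Counting follows Nei & Gojobori (NG86) under the invertebrate mitochondrial
code: each codon contributes synonymous site counts equal to the fraction of
its nine single-nucleotide mutations that preserve the amino acid (mutations
creating a stop codon count as nonsynonymous, which keeps L_A + L_S equal to
exactly 3 sites per codon); codons differing at several positions average
their synonymous/nonsynonymous difference counts over all minimal mutation
pathways, excluding pathways that pass through a stop codon (falling back to
all pathways when every one is blocked).  Proportions are corrected for
multiple hits with the Jukes-Cantor formula; omega = Ka/Ks.

Significance per gene is a two-sided Fisher exact test on the 2x2 table
[[S_A, L_A - S_A], [S_S, L_S - S_S]] with real-valued counts rounded
half-away-from-zero, the convention of KaKs_Calculator-style reports.

Interpretation: omega < 1 purifying, omega about 1 neutral, omega > 1
positive (diversifying) selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .composition import round_half_away
from .mitoio import MITO_TABLE, extract_cds, translate_mito

__all__ = [
    "CodonAlignment",
    "KaKsEstimate",
    "WindowScan",
    "codon_align",
    "ng86_counts",
    "kaks_ng86",
    "fisher_exact",
    "sliding_window",
    "classify_selection",
    "depth_pair_report",
    "SaturationError",
    "TABLE2_GENE_ORDER",
]

_STOPS = set(MITO_TABLE.stop_codons)
_AA = MITO_TABLE.forward_table
_BASES = "ACGT"

#: per-gene row order of the pairwise depth-comparison report
TABLE2_GENE_ORDER = ("cox1", "cox2", "nad3", "nad2", "atp8", "atp6", "cox3",
                     "nad5", "nad4", "nad4L", "nad6", "cob", "nad1")

#: neutrality band: |omega - 1| <= this is called neutral
NEUTRAL_TOLERANCE = 0.05


class SaturationError(ArithmeticError):
    """Substitution proportion >= 0.75: Jukes-Cantor correction undefined."""


@dataclass
class CodonAlignment:
    """Paired in-frame codon columns for two sequences."""

    codons1: tuple[str, ...]
    codons2: tuple[str, ...]
    mask: tuple[bool, ...]      # True = column usable (no gap, no stop)
    gene: str = ""

    def __post_init__(self):
        if not (len(self.codons1) == len(self.codons2) == len(self.mask)):
            raise ValueError("misaligned codon rows")

    @property
    def n_codons(self) -> int:
        return len(self.codons1)

    @property
    def n_unmasked(self) -> int:
        return sum(self.mask)

    def window(self, start: int, length: int) -> "CodonAlignment":
        sl = slice(start, start + length)
        return CodonAlignment(self.codons1[sl], self.codons2[sl],
                              self.mask[sl], self.gene)


@dataclass
class KaKsEstimate:
    """NG86 counts and rates for one gene (or window) pair."""

    gene: str
    S_A: float          # nonsynonymous substitutions (pathway-averaged)
    S_S: float          # synonymous substitutions
    L_A: float          # nonsynonymous sites
    L_S: float          # synonymous sites
    Ka: float
    Ks: float
    omega: float        # Ka/Ks; 0.0 when Ka=0, Ks>0; nan when undefined
    omega_defined: bool
    p_fisher: float = float("nan")
    n_codons: int = 0


@dataclass
class WindowScan:
    """Sliding-window Ka/Ks profile along one codon alignment."""

    gene: str
    window_length: int
    step: int
    starts: tuple[int, ...]
    estimates: list[KaKsEstimate] = field(default_factory=list)


# ---------------------------------------------------------------------------
# NG86 site and difference counting (cached tables)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _syn_sites(codon: str) -> float:
    """Synonymous sites of a sense codon (0..3); stop targets = nonsyn."""
    aa = _AA[codon]
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if mut not in _STOPS and _AA[mut] == aa:
                syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences averaged over minimal pathways.

    Pathways through stop codons are excluded; if all are blocked the
    average is over every pathway.  Symmetric in (c1, c2).
    """
    positions = [p for p in range(3) if c1[p] != c2[p]]
    if not positions:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(positions):
        cur = c1
        sd = nd = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if nxt in _STOPS:
                blocked = True
            if cur in _STOPS or nxt in _STOPS:
                nd += 1   # classified nonsyn if counted at all
            elif _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((sd, nd, blocked))
    usable = [(s, n) for s, n, b in paths if not b]
    if not usable:
        usable = [(s, n) for s, n, _ in paths]
    sd = sum(s for s, _ in usable) / len(usable)
    nd = sum(n for _, n in usable) / len(usable)
    return sd, nd


def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise SaturationError(f"proportion {p:.3f} >= 0.75")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0) if p > 0 else 0.0


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


def codon_align(cds1: str, cds2: str, gene: str = "") -> CodonAlignment:
    """Translation-guided codon alignment of two in-frame CDSs.

    The proteins are globally aligned (BLOSUM62, affine gaps) and the
    alignment is back-threaded onto codons; gap columns and columns holding
    a stop codon in either row are masked but kept.
    """
    for label, cds in (("cds1", cds1), ("cds2", cds2)):
        if len(cds) % 3:
            raise ValueError(f"{label} length {len(cds)} not a multiple of 3")
    if not cds1 or not cds2:
        raise ValueError("empty coding sequence")
    p1 = translate_mito(cds1).replace("*", "X")
    p2 = translate_mito(cds2).replace("*", "X")
    aln = _make_aligner().align(p1, p2)[0]
    a1, a2 = str(aln[0]), str(aln[1])
    if not a1:
        raise ValueError("empty alignment overlap")
    ident = sum(x == y for x, y in zip(a1, a2) if x != "-" and y != "-")
    overlap = sum(x != "-" and y != "-" for x, y in zip(a1, a2))
    warn_divergent = overlap > 0 and ident / overlap < 0.30

    codons1, codons2, mask = [], [], []
    i1 = i2 = 0
    for x, y in zip(a1, a2):
        c1 = cds1[3 * i1:3 * i1 + 3] if x != "-" else "---"
        c2 = cds2[3 * i2:3 * i2 + 3] if y != "-" else "---"
        i1 += x != "-"
        i2 += y != "-"
        usable = ("-" not in c1 and "-" not in c2
                  and c1 not in _STOPS and c2 not in _STOPS
                  and set(c1 + c2) <= set(_BASES))
        codons1.append(c1)
        codons2.append(c2)
        mask.append(usable)
    out = CodonAlignment(tuple(codons1), tuple(codons2), tuple(mask), gene)
    out.warn_divergent = warn_divergent  # type: ignore[attr-defined]
    return out


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def ng86_counts(aln: CodonAlignment,
                min_codons: int = 10) -> tuple[float, float, float, float, int]:
    """Raw NG86 sums (S_A, S_S, L_A, L_S, codons used), no correction."""
    if aln.n_unmasked < min_codons:
        raise ValueError(
            f"{aln.gene or 'alignment'}: only {aln.n_unmasked} unmasked "
            f"codons (< {min_codons})")
    sd = nd = 0.0
    ls = la = 0.0
    used = 0
    for c1, c2, ok in zip(aln.codons1, aln.codons2, aln.mask):
        if not ok:
            continue
        used += 1
        s1, s2 = _syn_sites(c1), _syn_sites(c2)
        ls += (s1 + s2) / 2.0
        la += 3.0 - (s1 + s2) / 2.0
        d_s, d_n = _pathway_diffs(c1, c2)
        sd += d_s
        nd += d_n
    return nd, sd, la, ls, used


def kaks_ng86(aln: CodonAlignment, min_codons: int = 10,
              with_fisher: bool = True) -> KaKsEstimate:
    """NG86 Ka/Ks for one codon alignment (see module docstring)."""
    nd, sd, la, ls, used = ng86_counts(aln, min_codons)
    p_s = sd / ls if ls > 0 else 0.0
    p_n = nd / la if la > 0 else 0.0
    ks = _jc_correct(p_s)
    ka = _jc_correct(p_n)
    if ks > 0:
        omega, defined = ka / ks, True
    elif ka == 0:
        omega, defined = float("nan"), False   # identical sequences
    else:
        omega, defined = float("nan"), False   # Ka > 0, Ks = 0
    est = KaKsEstimate(aln.gene, S_A=nd, S_S=sd, L_A=la, L_S=ls,
                       Ka=ka, Ks=ks, omega=omega, omega_defined=defined,
                       n_codons=used)
    if with_fisher:
        est.p_fisher = fisher_exact(est)
    return est


def fisher_exact(est: KaKsEstimate) -> float:
    """Two-sided Fisher exact p for the substitutions-vs-sites 2x2 table."""
    a = int(round_half_away(est.S_A, 0))
    b = int(round_half_away(est.L_A - est.S_A, 0))
    c = int(round_half_away(est.S_S, 0))
    d = int(round_half_away(est.L_S - est.S_S, 0))
    if min(a + b, c + d) <= 0 or (a + c) <= 0:
        return 1.0   # degenerate margin (e.g. no substitutions at all)
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if p <= 0.0:
        p = math.ulp(0.0)   # report smallest positive float, never exactly 0
    return float(p)


def sliding_window(aln: CodonAlignment, window: int = 52,
                   step: int = 12) -> WindowScan:
    """Ka/Ks in sliding codon windows (last partial window dropped).

    Windows with Ks = 0 are flagged through ``omega_defined``/NaN but kept.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    if aln.n_codons < window:
        raise ValueError(f"alignment of {aln.n_codons} codons < window {window}")
    starts = tuple(range(0, aln.n_codons - window + 1, step))
    scan = WindowScan(aln.gene, window, step, starts)
    for s in starts:
        sub = aln.window(s, window)
        try:
            est = kaks_ng86(sub, min_codons=1, with_fisher=False)
        except SaturationError:
            est = KaKsEstimate(aln.gene, *(float("nan"),) * 4,
                               Ka=float("nan"), Ks=float("nan"),
                               omega=float("nan"), omega_defined=False,
                               n_codons=sub.n_unmasked)
        scan.estimates.append(est)
    return scan


def classify_selection(omega: float) -> str:
    """purifying / neutral / positive with a +-0.05 neutrality band at 1."""
    if not math.isfinite(omega):
        raise ValueError("omega undefined")
    if abs(omega - 1.0) <= NEUTRAL_TOLERANCE:
        return "neutral"
    return "positive" if omega > 1.0 else "purifying"


# ---------------------------------------------------------------------------
# Depth-matched pair report
# ---------------------------------------------------------------------------

def depth_pair_report(pairs) -> "pandas.DataFrame":
    """Per-gene Ka/Ks table for depth-matched genome pairs.

    ``pairs`` is an iterable of (genome1, genome2, depth_label) with
    annotated :class:`~anomito.mitoio.MitoGenome` objects.  Rows follow the
    conventional 13-PCG report order; genes missing from either genome are
    reported with status "missing" and skipped.
    """
    import pandas as pd

    rows = []
    for g1, g2, depth_label in pairs:
        pair_name = f"{g1.accession} vs {g2.accession}"
        for no, gene in enumerate(TABLE2_GENE_ORDER, start=1):
            base = {"pair": pair_name, "depth": depth_label,
                    "PCG_no": no, "PCG": gene}
            try:
                cds1 = extract_cds(g1, gene)
                cds2 = extract_cds(g2, gene)
            except KeyError:
                rows.append({**base, "Ka": float("nan"), "Ks": float("nan"),
                             "Ka/Ks": float("nan"), "p_fisher": float("nan"),
                             "status": "missing"})
                continue
            try:
                est = kaks_ng86(codon_align(cds1, cds2, gene))
            except SaturationError:
                rows.append({**base, "Ka": float("nan"), "Ks": float("nan"),
                             "Ka/Ks": float("nan"), "p_fisher": float("nan"),
                             "status": "saturated"})
                continue
            omega_repr = 0.0 if (est.Ka == 0 and est.Ks > 0) else est.omega
            rows.append({**base, "Ka": est.Ka, "Ks": est.Ks,
                         "Ka/Ks": omega_repr, "p_fisher": est.p_fisher,
                         "status": "ok"})
    return pd.DataFrame(rows)
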