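"""Control-region characterization: repeats, motifs, and secondary structure.

The mitochondrial control region (D-loop) regulates replication and
transcription; in anomurans it typically carries a family-conserved tandem
repeat (period about 47 bp, about 3.5 copies), poly-T stretches, purine-rich
GA blocks, [TA(A)]n blocks and hairpin-forming inverted repeats.  This
module detects all of these and folds the region (or tRNAs) to a minimum
free energy via :mod:`anomito.folding`, whose public names are re-exported
here.

Tandem repeats are found TRF-style: k-mer recurrence distances propose
candidate periods, a lag-match scan with TRF's default weights (match +2,
mismatch -7, indel -7) delimits high-scoring regions, and each region is
re-scored by wraparound dynamic programming against the rolling consensus.
Only substitution-type divergence between copies is modelled by the scan;
the wraparound alignment tolerates occasional indels when scoring.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .folding import (AmbiguityError, FoldResult, dotbracket_to_pairs,
                      energy_of_structure, fold_mfe, loop_summary,
                      pairs_to_dotbracket)

__all__ = [
    "TandemRepeat",
    "SSR",
    "InvertedRepeat",
    "MotifBlock",
    "find_tandem_repeats",
    "find_ssrs",
    "find_inverted_repeats",
    "annotate_motifs",
    "classify_trna_structure",
    # folding re-exports
    "FoldResult",
    "fold_mfe",
    "energy_of_structure",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "loop_summary",
    "AmbiguityError",
]

# TRF default scoring weights
MATCH, MISMATCH, INDEL = 2, -7, -7
#: repeats below this copy number are not reported
MIN_COPY_NUMBER = 1.9
#: minimum wraparound alignment score to report a repeat (2 x 10 matched bp)
MIN_REPEAT_SCORE = 20

DEFAULT_SSR_MIN_COPIES = {1: 12, 2: 6, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class TandemRepeat:
    """One tandem repeat: coordinates 1-based inclusive within the region."""

    period: int
    copy_number: float        # aligned span / period, 1 decimal
    start: int
    end: int
    consensus: str
    alignment_score: int
    percent_matches: float


@dataclass(frozen=True)
class SSR:
    """A perfect microsatellite run."""

    unit: str
    copies: int
    start: int
    end: int


@dataclass(frozen=True)
class InvertedRepeat:
    """Two reverse-complementary arms separated by a loop."""

    arm_length: int
    loop_length: int
    arm1_start: int
    arm1_end: int
    arm2_start: int
    arm2_end: int
    matches: float            # percent identity of arm alignment
    score: int


@dataclass(frozen=True)
class MotifBlock:
    """A deterministic motif block (GA run, poly-T, [TA(A)]n, hairpin)."""

    kind: str                 # GA_block | polyT | TAA_block | hairpin
    start: int
    end: int
    subtype: str = "none"     # 5prime | 3prime | none


# ---------------------------------------------------------------------------
# Tandem repeats
# ---------------------------------------------------------------------------

def _candidate_periods(seq: str, min_period: int, max_period: int,
                       k: int = 7) -> list[int]:
    """Periods suggested by recurrence distances of exact k-mers."""
    last_pos: dict[str, int] = {}
    votes: dict[int, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i:i + k]
        if kmer in last_pos:
            d = i - last_pos[kmer]
            if min_period <= d <= max_period:
                votes[d] = votes.get(d, 0) + 1
        last_pos[kmer] = i
    ranked = sorted(votes, key=lambda d: (-votes[d], d))
    out: list[int] = []
    for d in ranked:
        if votes[d] >= 2 and not any(abs(d - o) <= 1 for o in out):
            out.append(d)
    return out[:25]


def _lag_match_regions(seq: str, p: int) -> list[tuple[int, int]]:
    """Maximal positively scoring stretches of seq[i] == seq[i - p]."""
    n = len(seq)
    regions = []
    score, start = 0, p
    best, best_span = 0, None
    for i in range(p, n):
        pts = MATCH if seq[i] == seq[i - p] else MISMATCH
        if score <= 0:
            score, start = 0, i
        score += pts
        if score > best:
            best, best_span = score, (start, i)
        if score <= 0 and best >= MATCH * p:   # close a segment
            regions.append(best_span)
            best, best_span = 0, None
    if best_span is not None and best >= MATCH * p:
        regions.append(best_span)
    # the repeat region includes the leading template copy
    return [(max(s - p, 0), e) for s, e in regions]


def _consensus(seq: str, start: int, end: int, p: int) -> str:
    cols: list[dict[str, int]] = [{} for _ in range(p)]
    for i in range(start, end + 1):
        col = (i - start) % p
        b = seq[i]
        cols[col][b] = cols[col].get(b, 0) + 1
    return "".join(max(c, key=c.get) if c else "A" for c in cols)


def _wrap_align(region: str, consensus: str) -> tuple[int, float]:
    """Wraparound global-ish alignment score of region vs tiled consensus.

    TRF-style: rows are region positions, columns consensus positions with
    a wrap from the last column back to the first; any column may start or
    end the alignment.  Returns (score, percent matches of the best
    per-position lag; diagnostic only).
    """
    p = len(consensus)
    m = len(region)
    prev = np.zeros(p)
    matches = 0
    for i in range(m):
        sub = np.array([MATCH if region[i] == consensus[j] else MISMATCH
                        for j in range(p)])
        diag = np.roll(prev, 1) + sub
        up = prev + INDEL
        cur = np.maximum(diag, up)
        # two passes for horizontal (deletion-in-region) moves across wrap
        for _ in range(2):
            left = np.roll(cur, 1) + INDEL
            cur = np.maximum(cur, left)
        prev = cur
        matches += region[i] == consensus[i % p]
    return int(prev.max()), 100.0 * matches / m


def _extend_span(seq: str, s: int, e: int, cons: str,
                 xdrop: int = 30) -> tuple[int, int]:
    """Greedily extend a repeat span against the tiled consensus (X-drop)."""
    p = len(cons)
    n = len(seq)
    best_gain, best_e, score = 0, e, 0
    for i in range(e + 1, min(n, e + 1 + 3 * p)):
        score += MATCH if seq[i] == cons[(i - s) % p] else MISMATCH
        if score > best_gain:
            best_gain, best_e = score, i
        if score < best_gain - xdrop:
            break
    e = best_e
    best_gain, best_s, score = 0, s, 0
    for i in range(s - 1, max(-1, s - 1 - 3 * p), -1):
        score += MATCH if seq[i] == cons[(i - s) % p] else MISMATCH
        if score > best_gain:
            best_gain, best_s = score, i
        if score < best_gain - xdrop:
            break
    return best_s, e


def find_tandem_repeats(seq: str, min_period: int = 1,
                        max_period: int = 500) -> list[TandemRepeat]:
    """Detect tandem repeats (see module docstring for the algorithm).

    Overlapping reports are merged keeping the highest alignment score
    (smallest period on ties); repeats below 1.9 copies are dropped.
    Returns an empty list when nothing passes the thresholds.
    """
    seq = seq.upper()
    if len(seq) < 2 * min_period:
        raise ValueError("sequence shorter than two minimum periods")
    reports: list[TandemRepeat] = []
    for p in _candidate_periods(seq, max(min_period, 1), max_period):
        for s, e in _lag_match_regions(seq, p):
            cons = _consensus(seq, s, e, p)
            s, e = _extend_span(seq, s, e, cons)
            cons = _consensus(seq, s, e, p)
            span = e - s + 1
            copies = span / p
            if copies < MIN_COPY_NUMBER:
                continue
            score, pct = _wrap_align(seq[s:e + 1], cons)
            if score < MIN_REPEAT_SCORE:
                continue
            reports.append(TandemRepeat(
                period=p, copy_number=round(copies, 1),
                start=s + 1, end=e + 1, consensus=cons,
                alignment_score=score, percent_matches=round(pct, 1)))
    reports.sort(key=lambda r: (-r.alignment_score, r.period))
    kept: list[TandemRepeat] = []
    for r in reports:
        overlap = any(min(r.end, k.end) - max(r.start, k.start) + 1
                      > 0.5 * (r.end - r.start + 1) for k in kept)
        if not overlap:
            kept.append(r)
    kept.sort(key=lambda r: r.start)
    return kept


# ---------------------------------------------------------------------------
# Microsatellites (SSRs)
# ---------------------------------------------------------------------------

def _primitive(unit: str) -> bool:
    for d in range(1, len(unit)):
        if len(unit) % d == 0 and unit == unit[:d] * (len(unit) // d):
            return False
    return True


def find_ssrs(seq: str,
              min_copies: dict[int, int] | None = None) -> list[SSR]:
    """Maximal perfect microsatellite runs, left-greedy.

    ``min_copies`` maps unit length (1-6 bp) to the minimum number of
    copies required for a report.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    thresholds = min_copies or DEFAULT_SSR_MIN_COPIES
    n = len(seq)
    found: list[SSR] = []
    covered: set[tuple[int, int]] = set()
    for u in sorted(thresholds):
        i = 0
        while i + u <= n:
            # extend the run of period u starting at i
            j = i + u
            while j < n and seq[j] == seq[j - u]:
                j += 1
            copies = (j - i) // u
            unit = seq[i:i + u]
            if (copies >= thresholds[u] and _primitive(unit)
                    and set(unit) <= set("ACGT")):
                start, end = i + 1, i + copies * u
                if not any(s <= start and end <= e for s, e in covered):
                    found.append(SSR(unit, copies, start, end))
                    covered.add((start, end))
                i = i + copies * u   # left-greedy: jump past the run
            else:
                i += 1
    found.sort(key=lambda r: (r.start, len(r.unit)))
    return found


# ---------------------------------------------------------------------------
# Inverted repeats
# ---------------------------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def find_inverted_repeats(seq: str, min_arm: int = 10,
                          max_mismatch_pct: float = 25.0,
                          min_loop: int = 3,
                          score_threshold: int = 30,
                          max_hits: int = 25) -> list[InvertedRepeat]:
    """Find inverted repeats by local alignment of seq against its
    reverse complement (einverted-style: match +3, mismatch -4, gap -12).

    Gapless Smith-Waterman restricted to arm1 strictly before arm2;
    non-overlapping hits returned by descending score.
    """
    seq = seq.upper()
    n = len(seq)
    if n < 2 * min_arm:
        raise ValueError("sequence shorter than two minimum arms")
    rc = seq.translate(_RC)[::-1]
    A, B = np.frombuffer(seq.encode(), np.uint8), np.frombuffer(rc.encode(), np.uint8)
    sub = np.where(A[:, None] == B[None, :], 3, -4).astype(np.int32)
    # mask so that seq position i pairs seq position n-1-j with a loop >= min_loop
    ii = np.arange(n)[:, None]
    jj = np.arange(n)[None, :]
    sub[(n - 1 - jj) - ii - 1 < min_loop] = -10**6
    H = np.zeros((n + 1, n + 1), dtype=np.int32)
    for i in range(1, n + 1):
        H[i, 1:] = np.maximum(0, H[i - 1, :-1] + sub[i - 1])
    hits: list[InvertedRepeat] = []
    used = np.zeros(n, dtype=bool)
    flat_order = np.argsort(H.ravel())[::-1]
    for idx in flat_order:
        if len(hits) >= max_hits:
            break
        score = int(H.ravel()[idx])
        if score < score_threshold:
            break
        i, j = divmod(int(idx), n + 1)
        # traceback the gapless diagonal
        e1, e2 = i - 1, j - 1               # last aligned (seq, rc) indices
        li, lj, length, mism = i, j, 0, 0
        while li > 0 and lj > 0 and H[li, lj] > 0:
            length += 1
            mism += seq[li - 1] != rc[lj - 1]
            li, lj = li - 1, lj - 1
        s1, s2rc = li, lj                    # 0-based starts in seq and rc
        arm1 = (s1, e1)
        arm2 = (n - 1 - (j - 1), n - 1 - s2rc)
        if length < min_arm:
            continue
        if 100.0 * mism / length > max_mismatch_pct:
            continue
        if used[arm1[0]:arm1[1] + 1].any() or used[arm2[0]:arm2[1] + 1].any():
            continue
        used[arm1[0]:arm1[1] + 1] = True
        used[arm2[0]:arm2[1] + 1] = True
        hits.append(InvertedRepeat(
            arm_length=length,
            loop_length=arm2[0] - arm1[1] - 1,
            arm1_start=arm1[0] + 1, arm1_end=arm1[1] + 1,
            arm2_start=arm2[0] + 1, arm2_end=arm2[1] + 1,
            matches=round(100.0 * (length - mism) / length, 1),
            score=score))
    hits.sort(key=lambda h: (-h.score, h.arm1_start))
    return hits


# ---------------------------------------------------------------------------
# Motif blocks
# ---------------------------------------------------------------------------

def annotate_motifs(seq: str, min_ga: int = 6, min_polyt: int = 5,
                    min_taa_units: int = 3,
                    include_hairpins: bool = True) -> list[MotifBlock]:
    """Annotate GA blocks, poly-T stretches, [TA(A)]n blocks and hairpins.

    GA blocks are runs of >= ``min_ga`` purines from {G, A} containing at
    least two G; their 5prime/3prime subtype is relative to the longest
    tandem repeat (if one is found).  Hairpin blocks delegate to
    :func:`find_inverted_repeats`.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    blocks: list[MotifBlock] = []
    for m in re.finditer(r"[GA]{%d,}" % min_ga, seq):
        if m.group().count("G") >= 2:
            blocks.append(MotifBlock("GA_block", m.start() + 1, m.end()))
    for m in re.finditer(r"T{%d,}" % min_polyt, seq):
        blocks.append(MotifBlock("polyT", m.start() + 1, m.end()))
    for m in re.finditer(r"(?:TAA|TA){%d,}" % min_taa_units, seq):
        blocks.append(MotifBlock("TAA_block", m.start() + 1, m.end()))
    if include_hairpins and len(seq) >= 20:
        for h in find_inverted_repeats(seq, min_arm=10):
            blocks.append(MotifBlock("hairpin", h.arm1_start, h.arm2_end))
    repeats = find_tandem_repeats(seq) if len(seq) >= 20 else []
    if repeats:
        main = max(repeats, key=lambda r: r.end - r.start)
        blocks = [
            MotifBlock(b.kind, b.start, b.end,
                       "5prime" if b.end < main.start
                       else "3prime" if b.start > main.end else "none")
            if b.kind == "GA_block" else b
            for b in blocks
        ]
    blocks.sort(key=lambda b: (b.start, b.kind))
    return blocks


# ---------------------------------------------------------------------------
# tRNA structure
# ---------------------------------------------------------------------------

def classify_trna_structure(seq: str, temperature: float = 27.0) -> str:
    """Classify a tRNA fold as "cloverleaf" or "atypical".

    Cloverleaf: the MFE structure has a single exterior (acceptor) helix of
    at least 4 stacked pairs closing a junction whose branches end in
    exactly three hairpin loops.
    """
    if not (40 <= len(seq) <= 120):
        raise ValueError(f"tRNA-scale sequence expected (40-120 nt), "
                         f"got {len(seq)}")
    result = fold_mfe(seq, temperature=temperature, max_suboptimals=1)
    summary = loop_summary(result.pairs, len(seq))
    ok = (summary["n_exterior_helices"] == 1
          and summary["exterior_helix_length"] >= 4
          and summary["n_hairpin_loops"] == 3)
    return "cloverleaf" if ok else "atypical"
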