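"""Minimum-free-energy nucleic-acid secondary structure by dynamic programming.

Implements a Zuker-style fold over a packaged Turner-style nearest-neighbour
parameter table: Watson-Crick + GU-wobble stacking terms stored as (dG37, dH)
pairs, and size-dependent hairpin/bulge/internal-loop penalties treated as
purely entropic, so any temperature T is reached through dG(T) = dH - T*dS.
Multibranch loops use the affine model a + b*(unpaired) + c*(branches,
closing helix included).  No pseudoknots, minimum hairpin loop 3 nt,
interior loops capped at 30 unpaired nt during the search (the usual Zuker
heuristic; the standalone evaluator has no cap).

DNA input is folded as RNA (T read as U) by default, mirroring the common
practice of running control-region DNA through an RNA-folding server; a
DNA (SantaLucia-style, Watson-Crick only) stack table is available with
``parameter_set="dna"``.

Suboptimal structures are generated with a Wuchty-style best-first
traceback over an unambiguous grammar, so the first structure emitted is
the MFE structure and energies come out in nondecreasing order.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FoldResult",
    "fold_mfe",
    "energy_of_structure",
    "pairs_to_dotbracket",
    "dotbracket_to_pairs",
    "loop_summary",
    "AmbiguityError",
]

R_GAS = 0.0019872       # kcal / (mol K)
T37 = 310.15            # K
MIN_HAIRPIN = 3
MAXLOOP = 30            # interior-loop search cap (unpaired nt)
INF = float("inf")

# pair type codes
_PAIR_CODES = {"AU": 0, "UA": 1, "GC": 2, "CG": 3, "GU": 4, "UG": 5}
_WOBBLE = {"GU", "UG"}

# Watson-Crick stack table keyed (outer bp, inner bp) where outer = pair
# (i, j), inner = pair (i+1, j-1): values (dG37, dH) in kcal/mol.
_RNA_WC_STACKS: dict[tuple[str, str], tuple[float, float]] = {
    ("AU", "AU"): (-0.93, -6.82),
    ("AU", "UA"): (-1.10, -9.38),
    ("UA", "AU"): (-1.33, -7.69),
    ("UA", "UA"): (-0.93, -6.82),
    ("CG", "UA"): (-2.08, -10.48),
    ("CG", "AU"): (-2.11, -10.44),
    ("GC", "UA"): (-2.24, -11.40),
    ("GC", "AU"): (-2.35, -12.44),
    ("AU", "CG"): (-2.24, -11.40),
    ("UA", "CG"): (-2.35, -12.44),
    ("AU", "GC"): (-2.08, -10.48),
    ("UA", "GC"): (-2.11, -10.44),
    ("CG", "GC"): (-2.36, -10.64),
    ("GC", "GC"): (-3.26, -13.39),
    ("GC", "CG"): (-3.42, -14.88),
    ("CG", "CG"): (-3.26, -13.39),
}

_DNA_WC_STACKS: dict[tuple[str, str], tuple[float, float]] = {
    # SantaLucia-style DNA nearest neighbours, mapped with U standing for T.
    ("AU", "AU"): (-1.00, -7.9),
    ("AU", "UA"): (-0.88, -7.2),
    ("UA", "AU"): (-0.58, -7.2),
    ("UA", "UA"): (-1.00, -7.9),
    ("CG", "AU"): (-1.45, -8.5),
    ("GC", "UA"): (-1.44, -8.4),
    ("CG", "UA"): (-1.28, -7.8),
    ("GC", "AU"): (-1.30, -8.2),
    ("AU", "GC"): (-1.28, -7.8),
    ("UA", "GC"): (-1.45, -8.5),
    ("AU", "CG"): (-1.44, -8.4),
    ("UA", "CG"): (-1.30, -8.2),
    ("CG", "GC"): (-2.17, -10.6),
    ("GC", "CG"): (-2.24, -9.8),
    ("GC", "GC"): (-1.84, -8.0),
    ("CG", "CG"): (-1.84, -8.0),
}

#: penalty added per wobble pair in a stack (dG37, dH), relative to the
#: Watson-Crick analogue obtained by replacing GU->AU and UG->UA.
_WOBBLE_PENALTY = (0.7, 3.0)
_DOUBLE_WOBBLE_EXTRA = (0.5, 1.0)   # both pairs wobble

# loop initiation dG37 tables (treated as pure entropy)
_HAIRPIN_DG37 = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.4}
_BULGE_DG37 = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
_INTERNAL_DG37 = {2: 1.2, 3: 1.6, 4: 1.1, 5: 1.4, 6: 1.8, 7: 2.0,
                  8: 2.3, 9: 2.5, 10: 2.7}
_ASYM_PER_NT = 0.6
_ASYM_MAX = 3.0
_ML_A, _ML_B, _ML_C = 3.4, 0.0, 0.4   # multibranch a + b*unpaired + c*branches


class AmbiguityError(ValueError):
    """Sequence too ambiguous (> 20% N) to fold."""


def _wc_analog(bp: str) -> str:
    return {"GU": "AU", "UG": "UA"}.get(bp, bp)


def _stack_param(outer: str, inner: str, table) -> tuple[float, float]:
    dg, dh = table[(_wc_analog(outer), _wc_analog(inner))]
    n_wob = (outer in _WOBBLE) + (inner in _WOBBLE)
    dg += n_wob * _WOBBLE_PENALTY[0]
    dh += n_wob * _WOBBLE_PENALTY[1]
    if n_wob == 2:
        dg += _DOUBLE_WOBBLE_EXTRA[0]
        dh += _DOUBLE_WOBBLE_EXTRA[1]
    return dg, dh


class _ParamsAtT:
    """All energy terms resolved at one temperature (kcal/mol)."""

    def __init__(self, temperature_c: float, parameter_set: str = "rna",
                 wobble: bool = True):
        if parameter_set not in ("rna", "dna"):
            raise ValueError(f"unknown parameter_set {parameter_set!r}")
        self.T = temperature_c + 273.15
        self.wobble = wobble and parameter_set == "rna"
        scale = self.T / T37   # pure-entropy loop terms scale linearly in T
        table = _RNA_WC_STACKS if parameter_set == "rna" else _DNA_WC_STACKS
        codes = list(_PAIR_CODES)
        self.stack = np.full((6, 6), INF)
        for a in codes:
            for b in codes:
                if not self.wobble and (a in _WOBBLE or b in _WOBBLE):
                    continue
                dg37, dh = _stack_param(a, b, table)
                ds = (dh - dg37) / T37
                self.stack[_PAIR_CODES[a], _PAIR_CODES[b]] = dh - self.T * ds
        self._hairpin = {k: v * scale for k, v in _HAIRPIN_DG37.items()}
        self._bulge = {k: v * scale for k, v in _BULGE_DG37.items()}
        self._internal = {k: v * scale for k, v in _INTERNAL_DG37.items()}
        self.ml_a, self.ml_b, self.ml_c = (
            _ML_A * scale, _ML_B * scale, _ML_C * scale)
        self._js = 1.75 * R_GAS * self.T   # Jacobson-Stockmayer extrapolation

    def _extrapolate(self, table: dict[int, float], size: int) -> float:
        mx = max(table)
        if size <= mx:
            return table[size]
        return table[mx] + self._js * math.log(size / mx)

    def hairpin(self, size: int) -> float:
        if size < MIN_HAIRPIN:
            return INF
        return self._extrapolate(self._hairpin, size)

    def bulge(self, size: int) -> float:
        return self._extrapolate(self._bulge, size)

    def internal(self, l1: int, l2: int) -> float:
        base = self._extrapolate(self._internal, l1 + l2)
        return base + min(_ASYM_MAX, _ASYM_PER_NT * abs(l1 - l2)) * self.T / T37

    def interior_penalty_grid(self) -> np.ndarray:
        """Pen[l1, l2] for 0 <= l1, l2 <= MAXLOOP; (0,0) (a stack) is inf."""
        grid = np.full((MAXLOOP + 1, MAXLOOP + 1), INF)
        for l1 in range(MAXLOOP + 1):
            for l2 in range(MAXLOOP + 1):
                if l1 + l2 == 0 or l1 + l2 > MAXLOOP:
                    continue
                if l1 == 0 or l2 == 0:
                    grid[l1, l2] = self.bulge(l1 + l2)
                else:
                    grid[l1, l2] = self.internal(l1, l2)
        return grid


def _encode(seq: str) -> np.ndarray:
    mapping = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3, "N": 4}
    try:
        return np.array([mapping[ch] for ch in seq], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"unexpected character {exc} in sequence") from exc


_PAIR_TYPE = -np.ones((5, 5), dtype=np.int8)
for _bp, _code in _PAIR_CODES.items():
    _i = {"A": 0, "C": 1, "G": 2, "U": 3}[_bp[0]]
    _j = {"A": 0, "C": 1, "G": 2, "U": 3}[_bp[1]]
    _PAIR_TYPE[_i, _j] = _code


@dataclass
class FoldResult:
    """MFE fold of one sequence."""

    delta_g: float                        # kcal/mol, <= 0
    structure: str                        # dot-bracket
    pairs: tuple[tuple[int, int], ...]    # 0-based (i, j), i < j
    suboptimals: list[tuple[float, str]]  # (dG, dot-bracket), MFE first
    temperature: float                    # degrees C


def pairs_to_dotbracket(pairs, n: int) -> str:
    s = ["."] * n
    for i, j in pairs:
        s[i], s[j] = "(", ")"
    return "".join(s)


def dotbracket_to_pairs(db: str) -> tuple[tuple[int, int], ...]:
    stack, pairs = [], []
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return tuple(sorted(pairs))


# ---------------------------------------------------------------------------
# The fill
# ---------------------------------------------------------------------------

def _fill_kernel(ptype, stack, hp, pen, a_t, b_t, c_t):
    """DP fill over plain loops (numba-compiled when available)."""
    n = ptype.shape[0]
    V = np.full((n, n), INF)
    M = np.full((n, n), INF)
    M2 = np.full((n, n), INF)
    for d in range(4, n):
        for i in range(0, n - d):
            j = i + d
            pt = ptype[i, j]
            if pt >= 0:
                best = hp[d - 1]
                inner = ptype[i + 1, j - 1]
                if inner >= 0 and V[i + 1, j - 1] < INF:
                    cand = stack[pt, inner] + V[i + 1, j - 1]
                    if cand < best:
                        best = cand
                for l1 in range(0, MAXLOOP + 1):
                    p = i + 1 + l1
                    if p > j - 5:
                        break
                    for l2 in range(0, MAXLOOP + 1 - l1):
                        q = j - 1 - l2
                        if q < p + 4:
                            break
                        if l1 + l2 == 0:
                            continue
                        v = V[p, q]
                        if v < INF:
                            cand = v + pen[l1, l2]
                            if cand < best:
                                best = cand
                if M2[i + 1, j - 1] < INF:
                    cand = a_t + c_t + M2[i + 1, j - 1]
                    if cand < best:
                        best = cand
                V[i, j] = best
            # M: >=1 branch; first branch at i, or leading unpaired base
            mbest = M[i + 1, j] + b_t
            for k in range(i + 4, j + 1):
                v = V[i, k]
                if v < INF:
                    if k == j:
                        tail = 0.0
                    else:
                        tail = b_t * (j - k)
                        if M[k + 1, j] < tail:
                            tail = M[k + 1, j]
                    cand = v + c_t + tail
                    if cand < mbest:
                        mbest = cand
            M[i, j] = mbest
            # M2: >=2 branches
            m2best = M2[i + 1, j] + b_t
            for k in range(i + 4, j - 4):
                if V[i, k] < INF and M[k + 1, j] < INF:
                    cand = V[i, k] + c_t + M[k + 1, j]
                    if cand < m2best:
                        m2best = cand
            M2[i, j] = m2best
    fsuf = np.zeros(n + 1)
    for i in range(n - 1, -1, -1):
        best = fsuf[i + 1]
        for k in range(i + 4, n):
            if V[i, k] < INF:
                cand = V[i, k] + fsuf[k + 1]
                if cand < best:
                    best = cand
        fsuf[i] = best
    return V, M, M2, fsuf


try:   # optional speedup; identical semantics either way
    from numba import njit as _njit
    _fill_kernel_fast = _njit(cache=True, fastmath=False)(_fill_kernel)
except Exception:   # pragma: no cover - numba always present in CI image
    _fill_kernel_fast = _fill_kernel


def _fill(enc: np.ndarray, params: _ParamsAtT):
    n = len(enc)
    ptype = np.where(
        (enc[:, None] < 4) & (enc[None, :] < 4),
        _PAIR_TYPE[np.minimum(enc, 3)[:, None], np.minimum(enc, 3)[None, :]],
        -1).astype(np.int8)
    if not params.wobble:
        ptype[(ptype == 4) | (ptype == 5)] = -1
    pen = params.interior_penalty_grid()
    hp = np.array([params.hairpin(s) if s >= MIN_HAIRPIN else INF
                   for s in range(n + 1)])
    kernel = _fill_kernel_fast if n > 60 else _fill_kernel
    V, M, M2, fsuf = kernel(ptype, params.stack, hp, pen,
                            params.ml_a, params.ml_b, params.ml_c)
    return V, M, M2, fsuf, ptype


# ---------------------------------------------------------------------------
# Wuchty-style best-first traceback (unambiguous grammar)
# ---------------------------------------------------------------------------

def _traceback(enc, params, V, M, M2, fsuf, ptype, n_structures, window,
               max_pops=2_000_000):
    n = len(enc)
    mfe = fsuf[0]
    limit = mfe + window + 1e-9
    a_t, b_t, c_t = params.ml_a, params.ml_b, params.ml_c

    def seg_bound(seg):
        kind, i, j = seg
        if kind == "F":
            return fsuf[i]
        return {"V": V, "M": M, "2": M2}[kind][i, j]

    counter = 0
    heap = [(mfe, 0, 0.0, (("F", 0, n - 1),), ())]
    out: list[tuple[float, tuple]] = []
    pops = 0
    while heap and len(out) < n_structures and pops < max_pops:
        bound, _, e, segs, pairs = heapq.heappop(heap)
        pops += 1
        if bound > limit:
            break
        if not segs:
            out.append((e, pairs))
            continue
        (kind, i, j), rest = segs[0], segs[1:]

        def push(extra_e, new_segs, new_pairs=()):
            nonlocal counter
            segs2 = tuple(new_segs) + rest
            e2 = e + extra_e
            b2 = e2 + sum(seg_bound(s) for s in segs2)
            if b2 <= limit:
                counter += 1
                heapq.heappush(heap, (b2, counter, e2, segs2, pairs + new_pairs))

        if kind == "F":
            if i >= n:
                push(0.0, ())
                continue
            push(0.0, (("F", i + 1, n - 1),) if i + 1 < n else ())
            for k in range(i + 4, n):
                if ptype[i, k] >= 0 and V[i, k] < INF:
                    tailsegs = [("V", i, k)]
                    if k + 1 < n:
                        tailsegs.append(("F", k + 1, n - 1))
                    push(0.0, tailsegs)
        elif kind == "V":
            pair = ((i, j),)
            size = j - i - 1
            if size >= MIN_HAIRPIN:
                push(params.hairpin(size), (), pair)
            inner = ptype[i + 1, j - 1] if j - 1 > i + 1 else -1
            if inner >= 0 and V[i + 1, j - 1] < INF:
                push(params.stack[ptype[i, j], inner], (("V", i + 1, j - 1),), pair)
            for p in range(i + 1, min(i + MAXLOOP + 2, j - 4)):
                l1 = p - i - 1
                for q in range(max(p + 4, j - 1 - (MAXLOOP - l1)), j):
                    l2 = j - q - 1
                    if l1 + l2 == 0 or l1 + l2 > MAXLOOP:
                        continue
                    if ptype[p, q] < 0 or V[p, q] == INF:
                        continue
                    loop_e = (params.bulge(l1 + l2) if (l1 == 0 or l2 == 0)
                              else params.internal(l1, l2))
                    push(loop_e, (("V", p, q),), pair)
            if j - i >= 2:
                push(a_t + c_t, (("2", i + 1, j - 1),), pair)
        elif kind == "2":        # M2: >= 2 branches
            if i + 1 < j:
                push(b_t, (("2", i + 1, j),))
            for k in range(i + 4, j - 4):
                if ptype[i, k] >= 0 and V[i, k] < INF:
                    push(c_t, (("V", i, k), ("M", k + 1, j)))
        elif kind == "M":        # >= 1 branch
            if i + 1 < j:
                push(b_t, (("M", i + 1, j),))
            for k in range(i + 4, j + 1):
                if ptype[i, k] >= 0 and V[i, k] < INF:
                    if k == j:
                        push(c_t, (("V", i, k),))
                    else:
                        push(c_t + b_t * (j - k), (("V", i, k),))
                        push(c_t, (("V", i, k), ("M", k + 1, j)))
    return out


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def fold_mfe(seq: str, temperature: float = 27.0, max_suboptimals: int = 20,
             subopt_window: float = 1.0, parameter_set: str = "rna",
             wobble: bool = True) -> FoldResult:
    """Fold a sequence and return the MFE plus near-optimal structures.

    Parameters
    ----------
    seq : DNA or RNA string (T read as U); N allowed up to 20%.
    temperature : folding temperature in degrees Celsius.
    max_suboptimals : number of structures reported (MFE included).
    subopt_window : energy band (kcal/mol) above the MFE for suboptimals.
    """
    seq = seq.upper()
    if not (10 <= len(seq) <= 5000):
        raise ValueError(f"sequence length {len(seq)} outside [10, 5000]")
    if seq.count("N") > 0.2 * len(seq):
        raise AmbiguityError("more than 20% ambiguous bases")
    enc = _encode(seq.replace("T", "U"))
    params = _ParamsAtT(temperature, parameter_set, wobble)
    V, M, M2, fsuf, ptype = _fill(enc, params)
    mfe = float(fsuf[0])
    if mfe >= 0:
        open_chain = "." * len(seq)
        return FoldResult(0.0, open_chain, (), [(0.0, open_chain)], temperature)
    structures = _traceback(enc, params, V, M, M2, fsuf, ptype,
                            max(1, max_suboptimals), subopt_window)
    subopt = [(round(e, 6), pairs_to_dotbracket(p, len(seq)))
              for e, p in structures]
    best_e, best_pairs = structures[0]
    return FoldResult(float(best_e), pairs_to_dotbracket(best_pairs, len(seq)),
                      tuple(sorted(best_pairs)), subopt, temperature)


def energy_of_structure(seq: str, pairs, temperature: float = 27.0,
                        parameter_set: str = "rna",
                        wobble: bool = True) -> float:
    """Free energy of a given structure by direct loop decomposition.

    Independent of the DP fill: the structure is decomposed into its loops
    (hairpin / stack / bulge / internal / multibranch / exterior) and the
    packaged parameters are summed.  Interior loops are not size-capped here.
    Raises ValueError for invalid structures (crossing pairs, unpairable
    bases, hairpin loops < 3 nt).
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    enc = _encode(seq)
    params = _ParamsAtT(temperature, parameter_set, wobble)
    pairs = sorted(tuple(p) for p in pairs)
    partner = {}

    def pair_type(i: int, j: int) -> int:
        if enc[i] >= 4 or enc[j] >= 4:
            return -1
        return int(_PAIR_TYPE[enc[i], enc[j]])

    for i, j in pairs:
        if not (0 <= i < j < n):
            raise ValueError(f"pair ({i},{j}) out of range")
        if i in partner or j in partner:
            raise ValueError("base in two pairs")
        pt = pair_type(i, j)
        if pt < 0 or (not wobble and pt in (4, 5)):
            raise ValueError(f"unpairable bases {seq[i]}{seq[j]} at ({i},{j})")
        partner[i] = j
        partner[j] = i
    for (i1, j1) in pairs:
        for (i2, j2) in pairs:
            if i1 < i2 < j1 < j2:
                raise ValueError("crossing pairs (pseudoknot)")

    def children_of(i: int, j: int) -> tuple[list[tuple[int, int]], int]:
        kids, unpaired, k = [], 0, i + 1
        while k < j:
            if k in partner and partner[k] > k:
                kids.append((k, partner[k]))
                k = partner[k] + 1
            else:
                unpaired += 1
                k += 1
        return kids, unpaired

    energy = 0.0
    stack_tbl = params.stack

    def loop_energy(i: int, j: int) -> float:
        kids, unpaired = children_of(i, j)
        if not kids:
            if unpaired < MIN_HAIRPIN:
                raise ValueError(f"hairpin loop of {unpaired} nt under ({i},{j})")
            return params.hairpin(unpaired)
        if len(kids) == 1:
            (p, q), = kids
            l1, l2 = p - i - 1, j - q - 1
            if l1 == 0 and l2 == 0:
                return float(stack_tbl[pair_type(i, j), pair_type(p, q)])
            if l1 == 0 or l2 == 0:
                return params.bulge(l1 + l2)
            return params.internal(l1, l2)
        return (params.ml_a + params.ml_b * unpaired
                + params.ml_c * (len(kids) + 1))

    # exterior loop is free; recurse into every pair
    for i, j in pairs:
        energy += loop_energy(i, j)
    return energy


def loop_summary(pairs, n: int) -> dict:
    """Counts of hairpin loops and exterior helices for a structure.

    Used by tRNA cloverleaf classification: a cloverleaf has one exterior
    helix of >= 4 stacked pairs (the acceptor stem) closing a multibranch
    loop whose three branches each end in a hairpin loop.
    """
    pairs = sorted(tuple(p) for p in pairs)
    partner = dict(pairs)
    enclosed = {p: False for p in pairs}
    for (i1, j1) in pairs:
        for (i2, j2) in pairs:
            if i1 < i2 and j2 < j1:
                enclosed[(i2, j2)] = True
    exterior = [p for p, e in enclosed.items() if not e]
    hairpins = 0
    for (i, j) in pairs:
        k, has_kid = i + 1, False
        while k < j:
            if k in partner and partner[k] > k:
                has_kid = True
                break
            k += 1
        if not has_kid:
            hairpins += 1
    # length of the outermost helix (allowing bulges of 0 only: strict stack)
    ext_helix_len = 0
    if len(exterior) == 1:
        i, j = exterior[0]
        ext_helix_len = 1
        while (i + 1, j - 1) in enclosed:
            i, j = i + 1, j - 1
            ext_helix_len += 1
    return {"n_pairs": len(pairs), "n_exterior_helices": len(exterior),
            "n_hairpin_loops": hairpins, "exterior_helix_length": ext_helix_len}
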