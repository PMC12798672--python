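"""Circular signed gene orders: canonical form, typing, diffs, breakpoints.

A mitochondrial gene arrangement is modelled as a circular sequence of signed
gene symbols (sign = transcriptional strand).  Two genomes share an
"arrangement type" when their canonicalized orders are string-identical;
canonicalization fixes the rotation (start at +cox1) and the reflection
(if cox1 lies on the minus strand the whole circle is read from the other
strand first), so circular/orientation equivalence reduces to tuple equality.

The breakpoint distance between two orders is the number of signed circular
adjacencies present in one but not the other, a standard rearrangement
statistic that requires no scenario inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "GeneOrder",
    "ArrangementType",
    "RearrangementDiff",
    "canonicalize",
    "partition_types",
    "diff_vs_reference",
    "breakpoint_distance",
    "adjacency_set",
    "load_reference",
    "write_gene_orders",
    "read_gene_orders",
    "CanonicalizationError",
]


class CanonicalizationError(ValueError):
    """Order cannot be canonicalized (cox1 missing)."""


def _base(g: str) -> str:
    return g.lstrip("+-")


def _sign(g: str) -> str:
    return "-" if g.startswith("-") else "+"


def _neg(g: str) -> str:
    return "+" + _base(g) if g.startswith("-") else "-" + _base(g)


def _signed(g: str) -> str:
    return g if g[0] in "+-" else "+" + g


@dataclass(frozen=True)
class GeneOrder:
    """A circular signed gene order for one genome."""

    accession: str
    order: tuple[str, ...]           # signed symbols, e.g. ("+cox1", "-trnQ", ...)
    include_cr: bool = False

    def __post_init__(self):
        object.__setattr__(self, "order", tuple(_signed(g) for g in self.order))
        seen: set[str] = set()
        for g in self.order:
            b = _base(g)
            if b in seen:
                raise ValueError(
                    f"{self.accession}: duplicate symbol {b}; label copies "
                    f"as {b}_copy2 before building a GeneOrder")
            seen.add(b)

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(_base(g) for g in self.order)

    def restricted(self, genes: Iterable[str]) -> "GeneOrder":
        keep = set(genes)
        return GeneOrder(self.accession,
                         tuple(g for g in self.order if _base(g) in keep),
                         self.include_cr)

    def without_cr(self) -> "GeneOrder":
        return GeneOrder(self.accession,
                         tuple(g for g in self.order if _base(g) != "CR"),
                         include_cr=False)


@dataclass
class ArrangementType:
    """An equivalence class of identical canonical gene orders."""

    type_id: int
    members: list[str]
    representative: GeneOrder


@dataclass(frozen=True)
class RearrangementDiff:
    """Differences of one order against a reference order."""

    translocated: tuple[str, ...]
    inverted: tuple[str, ...]
    conserved_blocks: tuple[tuple[str, ...], ...]

    @property
    def is_empty(self) -> bool:
        return not self.translocated and not self.inverted


# ---------------------------------------------------------------------------
# Canonical form and adjacencies
# ---------------------------------------------------------------------------

def canonicalize(order: GeneOrder) -> GeneOrder:
    """Rotate (and reflect if needed) so the order starts at +cox1."""
    genes = list(order.order)
    bases = [_base(g) for g in genes]
    if "cox1" not in bases:
        raise CanonicalizationError(f"{order.accession}: cox1 not present")
    i = bases.index("cox1")
    if _sign(genes[i]) == "-":
        genes = [_neg(g) for g in reversed(genes)]
        bases = [_base(g) for g in genes]
        i = bases.index("cox1")
    rotated = tuple(genes[i:] + genes[:i])
    return GeneOrder(order.accession, rotated, order.include_cr)


def adjacency_set(order: GeneOrder) -> frozenset[tuple[str, str]]:
    """Signed circular adjacencies, orientation-normalized.

    The adjacency (a, b) read on one strand equals (-b, -a) on the other;
    each is stored as the lexicographic minimum of the two readings, which
    makes the set invariant to rotation and reflection.
    """
    genes = order.order
    if len(genes) < 2:
        return frozenset()
    adj = set()
    for a, b in zip(genes, genes[1:] + genes[:1]):
        adj.add(min((a, b), (_neg(b), _neg(a))))
    return frozenset(adj)


# ---------------------------------------------------------------------------
# Typing, diffing, distances
# ---------------------------------------------------------------------------

def partition_types(orders: Sequence[GeneOrder],
                    include_cr: bool = False) -> list[ArrangementType]:
    """Partition genomes into arrangement types by exact canonical equality.

    CR placement is excluded by default (it is a non-coding region, not a
    gene).  type_ids count from 1, assigned in ascending accession order of
    each class's first member for determinism.
    """
    classes: dict[tuple[str, ...], list[GeneOrder]] = {}
    for o in sorted(orders, key=lambda o: o.accession):
        c = canonicalize(o if include_cr else o.without_cr())
        classes.setdefault(c.order, []).append(c)
    out = []
    for i, (key, members) in enumerate(
            sorted(classes.items(), key=lambda kv: kv[1][0].accession), start=1):
        out.append(ArrangementType(i, [m.accession for m in members], members[0]))
    return out


def diff_vs_reference(order: GeneOrder, reference: GeneOrder) -> RearrangementDiff:
    """Classify genes as translocated or inverted relative to a reference.

    Genes absent from either order are ignored.  A gene is *translocated*
    when both of its circular adjacencies are absent from the reference
    (a gene at a single breakpoint boundary is not itself translocated);
    *inverted* when its unsigned neighbourhood is conserved but its strand
    differs.  Conserved blocks are maximal runs of reference adjacencies.
    """
    shared = order.genes & reference.genes
    if len(shared) < 2:
        raise ValueError("orders share fewer than 2 genes")
    o = canonicalize(order.restricted(shared))
    r = canonicalize(reference.restricted(shared))
    adj_r = adjacency_set(r)
    genes = o.order
    k = len(genes)
    ref_sign = {_base(g): _sign(g) for g in r.order}
    ref_unsigned_nb = _unsigned_neighbours(r)
    o_unsigned_nb = _unsigned_neighbours(o)

    translocated, inverted = [], []
    for idx, g in enumerate(genes):
        left = genes[(idx - 1) % k]
        right = genes[(idx + 1) % k]
        a1 = min((left, g), (_neg(g), _neg(left)))
        a2 = min((g, right), (_neg(right), _neg(g)))
        n_conserved = (a1 in adj_r) + (a2 in adj_r)
        b = _base(g)
        if o_unsigned_nb[b] == ref_unsigned_nb[b]:
            if _sign(g) != ref_sign[b]:
                inverted.append(b)
        elif n_conserved == 0:
            translocated.append(b)

    blocks: list[tuple[str, ...]] = []
    cur = [genes[0]]
    for idx in range(1, k):
        a = min((genes[idx - 1], genes[idx]),
                (_neg(genes[idx]), _neg(genes[idx - 1])))
        if a in adj_r:
            cur.append(genes[idx])
        else:
            blocks.append(tuple(cur))
            cur = [genes[idx]]
    wrap = min((genes[-1], genes[0]), (_neg(genes[0]), _neg(genes[-1])))
    if wrap in adj_r and blocks:
        blocks[0] = tuple(cur) + blocks[0]   # run continues across the origin
    elif wrap in adj_r:
        blocks = [tuple(cur)]                # whole circle is one conserved run
    else:
        blocks.append(tuple(cur))
    blocks = [b for b in blocks if len(b) >= 2]
    return RearrangementDiff(tuple(translocated), tuple(inverted),
                             tuple(blocks))


def _unsigned_neighbours(order: GeneOrder) -> dict[str, frozenset[str]]:
    genes = order.order
    k = len(genes)
    return {
        _base(g): frozenset({_base(genes[(i - 1) % k]), _base(genes[(i + 1) % k])})
        for i, g in enumerate(genes)
    }


def breakpoint_distance(o1: GeneOrder, o2: GeneOrder) -> int:
    """Number of signed circular adjacencies of o1 absent from o2.

    Restricted to the genes common to both orders; symmetric when the two
    orders carry the same gene set.
    """
    shared = o1.genes & o2.genes
    a1 = adjacency_set(o1.restricted(shared))
    a2 = adjacency_set(o2.restricted(shared))
    return len(a1 - a2)


# ---------------------------------------------------------------------------
# References and tabular I/O
# ---------------------------------------------------------------------------

def load_reference(which: str = "paper") -> GeneOrder:
    """Load a shipped ground-pattern reference: "paper" or "canonical37"."""
    fname = {"paper": "ground_pattern_paper.txt",
             "canonical37": "ground_pattern_canonical37.txt"}.get(which)
    if fname is None:
        raise ValueError(f"unknown reference {which!r}")
    text = (resources.files("anomito") / "data" / fname).read_text()
    line = next(l for l in text.splitlines() if l.strip() and not l.startswith("#"))
    return GeneOrder(f"reference:{which}", tuple(line.strip().split(",")))


def write_gene_orders(orders: Iterable[GeneOrder], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("accession\torder\n")
        for o in orders:
            fh.write(f"{o.accession}\t{','.join(o.order)}\n")


def read_gene_orders(path: str | Path) -> list[GeneOrder]:
    orders = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("accession"):
            raise ValueError(f"{path}: missing gene-order header")
        for line in fh:
            if not line.strip():
                continue
            acc, order = line.rstrip("\n").split("\t")
            orders.append(GeneOrder(acc, tuple(order.split(","))))
    return orders


def genome_to_order(genome) -> GeneOrder:
    """Build a GeneOrder from an annotated :class:`~anomito.mitoio.MitoGenome`."""
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    return GeneOrder(genome.accession,
                     tuple(f"{f.strand}{f.name}" for f in feats),
                     include_cr=any(f.kind == "CR" for f in feats))
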