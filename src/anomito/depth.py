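"""Habitat-depth categories and the control-region dG / depth association.

Species are binned into the habitat depth categories Terrestrial,
Intertidal (0-30 m), Shallow (30-200 m), Upper bathyal (200-1000 m) and
Deep sea (>1000 m) by the midpoint of their reported depth range.  For each
family with enough usable records, the association between depth and
control-region folding free energy is summarized by a Spearman rank
correlation between depth midpoints and dG midpoints, with a seeded
permutation p-value.

Sign convention: "dG decreases with depth" (more negative, i.e. more stable
structures in deeper water) means rho(depth, dG) < 0.  Carcinized families
(crab-like body plan: by default Lithodidae, Porcellanidae and Lomisidae)
are contrasted against non-carcinized families by the direction of their
trends.  Hydrothermal-vent taxa (Munidopsidae) carry a vent flag and are
reported separately.  The analysis is descriptive: no phylogenetic
correction, no causal claim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "HabitatRecord",
    "DepthCategory",
    "TrendResult",
    "DEPTH_CATEGORIES",
    "CARCINIZED_FAMILIES",
    "assign_depth_category",
    "load_habitat_table",
    "dg_depth_trend",
    "carcinization_contrast",
]

#: half-open depth bins in metres; Terrestrial is an override flag
DEPTH_CATEGORIES = (
    ("Intertidal", 0.0, 30.0),
    ("Shallow", 30.0, 200.0),
    ("Upper bathyal", 200.0, 1000.0),
    ("Deep sea", 1000.0, math.inf),
)

#: default carcinization labels (editable via function arguments)
CARCINIZED_FAMILIES = frozenset({"Lithodidae", "Porcellanidae", "Lomisidae"})

#: |rho| at or below this is reported as direction "none"
DIRECTION_RHO_THRESHOLD = 0.3


@dataclass(frozen=True)
class DepthCategory:
    label: str
    min_m: float
    max_m: float


@dataclass
class HabitatRecord:
    """One species row of the habitat/control-region comparison table."""

    species: str
    family: str
    superfamily: str
    cr_length: int | str | None       # bp, or "Too compact", or None
    at_content: float | None
    repeat_summary: str
    dg_low: float | None              # kcal/mol (dg_low <= dg_high)
    dg_high: float | None
    depth_min: float | None           # metres
    depth_max: float | None
    terrestrial: bool = False
    vent: bool = False
    climate: str = ""

    @property
    def dg_mid(self) -> float | None:
        if self.dg_low is None or self.dg_high is None:
            return None
        return (self.dg_low + self.dg_high) / 2.0

    @property
    def depth_mid(self) -> float | None:
        if self.depth_min is None or self.depth_max is None:
            return None
        return (self.depth_min + self.depth_max) / 2.0


@dataclass(frozen=True)
class TrendResult:
    """Family-wise Spearman trend of dG against depth."""

    family: str
    n: int
    spearman_rho: float
    direction: str            # decreasing | increasing | none
    p_perm: float
    vent: bool = False


def assign_depth_category(depth_min: float, depth_max: float,
                          terrestrial: bool = False) -> DepthCategory:
    """Depth category by range midpoint; half-open bins, terrestrial wins."""
    if terrestrial:
        return DepthCategory("Terrestrial", 0.0, 0.0)
    if depth_min < 0 or depth_max < 0 or depth_min > depth_max:
        raise ValueError(f"bad depth range [{depth_min}, {depth_max}]")
    mid = (depth_min + depth_max) / 2.0
    for label, lo, hi in DEPTH_CATEGORIES:
        if lo <= mid < hi:
            return DepthCategory(label, lo, hi)
    raise AssertionError("unreachable: categories cover [0, inf)")


def load_habitat_table(path: str | Path | None = None) -> list[HabitatRecord]:
    """Load the packaged (or a user-supplied) habitat comparison CSV."""
    if path is None:
        with resources.as_file(
                resources.files("anomito") / "data/habitat_table.csv") as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def num(col):
            v = row.get(col)
            return None if pd.isna(v) else float(v)

        cr = row.get("cr_length")
        if pd.isna(cr):
            cr = None
        else:
            try:
                cr = int(cr)
            except (TypeError, ValueError):
                cr = str(cr)
        records.append(HabitatRecord(
            species=row["species"], family=row["family"],
            superfamily=row["superfamily"], cr_length=cr,
            at_content=num("at_percent"),
            repeat_summary="" if pd.isna(row.get("repeat_summary"))
                           else str(row["repeat_summary"]),
            dg_low=num("dg_low"), dg_high=num("dg_high"),
            depth_min=num("depth_min_m"), depth_max=num("depth_max_m"),
            terrestrial=bool(row.get("terrestrial", False)),
            vent=bool(row.get("vent", False)),
            climate="" if pd.isna(row.get("climate")) else str(row["climate"]),
        ))
    return records


def _usable(rec: HabitatRecord) -> bool:
    return rec.dg_mid is not None and rec.depth_mid is not None \
        and not rec.terrestrial


def dg_depth_trend(records: list[HabitatRecord], min_n: int = 4,
                   n_permutations: int = 10_000,
                   seed: int = 0) -> list[TrendResult]:
    """Family-wise Spearman rho(depth midpoint, dG midpoint).

    Rows without a numeric dG ("Too compact" control regions) or depth are
    excluded; families with fewer than ``min_n`` usable rows are skipped.
    The permutation p-value (two-sided, >=10,000 seeded shuffles) is
    bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[HabitatRecord]] = {}
    for r in records:
        if _usable(r):
            by_family.setdefault(r.family, []).append(r)
    out = []
    for family in sorted(by_family):
        rows = by_family[family]
        if len(rows) < min_n:
            continue
        depth = np.array([r.depth_mid for r in rows])
        dg = np.array([r.dg_mid for r in rows])
        rho = float(stats.spearmanr(depth, dg).statistic)
        # permutation null, vectorized: Spearman = Pearson on ranks, and a
        # permutation of the dG ranks keeps their norm constant
        rx = stats.rankdata(depth) - (len(rows) + 1) / 2.0
        ry = stats.rankdata(dg) - (len(rows) + 1) / 2.0
        perms = rng.permuted(np.tile(ry, (n_permutations, 1)), axis=1)
        null = perms @ rx / (np.linalg.norm(rx) * np.linalg.norm(ry))
        hits = int((np.abs(null) >= abs(rho) - 1e-12).sum())
        p_perm = (hits + 1) / (n_permutations + 1)
        if abs(rho) <= DIRECTION_RHO_THRESHOLD:
            direction = "none"
        else:
            direction = "increasing" if rho > 0 else "decreasing"
        out.append(TrendResult(family, len(rows), rho, direction, p_perm,
                               vent=any(r.vent for r in rows)))
    return out


def carcinization_contrast(trends: list[TrendResult],
                           carcinized: frozenset[str] | set[str] | None = None
                           ) -> pd.DataFrame:
    """Contrast trend directions between carcinized and other families.

    Returns one row per family with its group and a group-level
    sign-concordance column: the fraction of families in the group whose
    direction matches the group's modal direction (NaN for a single group
    with no contrast possible).
    """
    labels = CARCINIZED_FAMILIES if carcinized is None else set(carcinized)
    rows = []
    groups: dict[str, list[TrendResult]] = {"carcinized": [],
                                            "non-carcinized": []}
    for t in trends:
        group = "carcinized" if t.family in labels else "non-carcinized"
        groups[group].append(t)
    concordance = {}
    for group, ts in groups.items():
        dirs = [t.direction for t in ts if t.direction != "none"]
        if dirs:
            modal = max(set(dirs), key=dirs.count)
            concordance[group] = (modal, dirs.count(modal) / len(dirs))
        else:
            concordance[group] = ("none", float("nan"))
    for t in trends:
        group = "carcinized" if t.family in labels else "non-carcinized"
        modal, conc = concordance[group]
        rows.append({"family": t.family, "group": group, "n": t.n,
                     "rho": t.spearman_rho, "direction": t.direction,
                     "p_perm": t.p_perm, "vent": t.vent,
                     "group_modal_direction": modal,
                     "group_concordance": conc})
    return pd.DataFrame(rows)
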