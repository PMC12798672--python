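"""End-to-end orchestration of the comparative mitogenomic analysis.

Stages (each writes TSVs into its own subdirectory of the output tree):

* ``composition`` - per-record base composition, AT/GC skews (per strand and
  in the mixed heavy-AT / light-GC reporting convention), codon usage.
* ``gene_order``  - canonical signed gene orders, arrangement-type
  partition, breakpoint distance and diff against the chosen reference.
* ``selection``   - per-gene NG86 Ka/Ks with Fisher p for depth-matched
  pairs, plus sliding-window profiles.
* ``control_region`` - CR location, tandem repeats, SSRs, motif blocks,
  MFE fold (dot-bracket with dG in the header).
* ``depth_assoc`` - family-wise dG/depth Spearman trends and the
  carcinized-vs-non-carcinized contrast.

A run is a pure function of its :class:`RunConfig` (seed included); the
resolved config, its hash and per-stage status land in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .composition import codon_usage, composition, paper_style_skews
from .control_region import (annotate_motifs, find_ssrs,
                             find_tandem_repeats, fold_mfe)
from .depth import carcinization_contrast, dg_depth_trend, load_habitat_table
from .gene_order import (breakpoint_distance, canonicalize, diff_vs_reference,
                         genome_to_order, load_reference, partition_types,
                         write_gene_orders)
from .kaks import codon_align, depth_pair_report, sliding_window
from .mitoio import (AnnotationError, MitoGenome, extract_cds,
                     locate_control_region, read_genbank, write_feature_table,
                     write_genbank)
from .synthetic import CRSpec, SyntheticGenomeSpec, generate_genome

__all__ = ["RunConfig", "run_pipeline", "make_fixtures", "ConfigError"]

log = logging.getLogger("anomito")

STAGES = ("composition", "gene_order", "selection", "control_region",
          "depth_assoc")


class ConfigError(ValueError):
    """Unknown or inconsistent configuration."""


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    input_dir: str = ""
    out_dir: str = "anomito-out"
    stages: tuple[str, ...] = STAGES
    reference: str = "canonical37"          # or "paper"
    window: int = 52                        # sliding-window length (codons)
    step: int = 12
    fold_temperature: float = 27.0
    fold_max_len: int = 600                 # CRs longer than this are folded
                                            # on their first fold_max_len nt
    min_ga: int = 6
    min_polyt: int = 5
    min_taa_units: int = 3
    pair_manifest: str = ""                 # CSV: accession1,accession2,...
    habitat_csv: str = ""                   # default: packaged fixture
    n_permutations: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stages, (list, tuple)):
            cfg.stages = tuple(cfg.stages)
        bad = set(cfg.stages) - set(STAGES)
        if bad:
            raise ConfigError(f"unknown stages: {sorted(bad)}")
        if cfg.reference not in ("paper", "canonical37"):
            raise ConfigError(f"unknown reference {cfg.reference!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    handlers = [logging.StreamHandler(),
                logging.FileHandler(out / "run.log", mode="w")]
    fmt = "%(asctime)s %(name)s %(levelname)s %(message)s"
    logging.basicConfig(level=logging.INFO, format=fmt, handlers=handlers,
                        force=True)


def _load_genomes(cfg: RunConfig) -> list[MitoGenome]:
    paths = sorted(Path(cfg.input_dir).glob("*.gb"))
    if not paths:
        raise FileNotFoundError(f"no .gb files under {cfg.input_dir!r}")
    genomes = []
    for p in paths:
        g = read_genbank(p)
        log.info("ingest: %s (%s, %d bp, %d features)",
                 g.accession, g.taxon, len(g), len(g.features))
        genomes.append(g)
    return genomes


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _stage_composition(genomes, cfg: RunConfig, out: Path) -> None:
    from Bio.Seq import Seq
    rows, codon_rows = [], []
    for g in genomes:
        heavy = composition(g.sequence, "heavy")
        light = composition(str(Seq(g.sequence).reverse_complement()), "light")
        at_h, gc_l = paper_style_skews(g.sequence)
        for prof in (heavy, light):
            rows.append({"accession": g.accession, "region": "genome",
                         "strand_label": prof.strand_label,
                         "A": prof.a_pct, "C": prof.c_pct, "G": prof.g_pct,
                         "T": prof.t_pct, "pct_AT": prof.at_content,
                         "at_skew": prof.at_skew, "gc_skew": prof.gc_skew})
        rows.append({"accession": g.accession, "region": "genome",
                     "strand_label": "paper-style(H-AT/L-GC)",
                     "A": heavy.a_pct, "C": light.c_pct, "G": light.g_pct,
                     "T": heavy.t_pct, "pct_AT": heavy.at_content,
                     "at_skew": at_h, "gc_skew": gc_l})
        cds_list = []
        for f in g.features:
            if f.kind == "PCG":
                try:
                    cds_list.append(extract_cds(g, f.name))
                except KeyError:
                    pass
        if cds_list:
            usage = codon_usage(cds_list)
            for codon in sorted(usage.counts):
                codon_rows.append({
                    "accession": g.accession, "codon": codon,
                    "aa": usage.amino_acid.get(codon, "?"),
                    "count": usage.counts[codon],
                    "per_thousand": round(usage.per_thousand[codon], 2),
                    "RSCU": round(usage.rscu.get(codon, float("nan")), 3)})
    pd.DataFrame(rows).to_csv(out / "composition.tsv", sep="\t", index=False)
    pd.DataFrame(codon_rows).to_csv(out / "codon_usage.tsv", sep="\t",
                                    index=False)


def _stage_gene_order(genomes, cfg: RunConfig, out: Path) -> None:
    orders = [genome_to_order(g) for g in genomes]
    write_gene_orders([canonicalize(o.without_cr()) for o in orders],
                      out / "gene_orders.tsv")
    types = partition_types(orders)
    pd.DataFrame([{"type_id": t.type_id, "n_members": len(t.members),
                   "members": ";".join(t.members),
                   "representative": ",".join(t.representative.order)}
                  for t in types]).to_csv(out / "arrangement_types.tsv",
                                          sep="\t", index=False)
    ref = load_reference(cfg.reference)
    rows = []
    for o in orders:
        try:
            diff = diff_vs_reference(o.without_cr(), ref)
            rows.append({"accession": o.accession,
                         "reference": cfg.reference,
                         "breakpoints": breakpoint_distance(o.without_cr(), ref),
                         "translocated": ";".join(diff.translocated),
                         "inverted": ";".join(diff.inverted)})
        except ValueError as exc:
            rows.append({"accession": o.accession, "reference": cfg.reference,
                         "breakpoints": "", "translocated": "",
                         "inverted": f"error: {exc}"})
    pd.DataFrame(rows).to_csv(out / "vs_reference.tsv", sep="\t", index=False)
    log.info("gene_order: %d genomes -> %d arrangement types",
             len(orders), len(types))


def _stage_selection(genomes, cfg: RunConfig, out: Path) -> None:
    by_acc = {g.accession: g for g in genomes}
    if cfg.pair_manifest:
        manifest = pd.read_csv(cfg.pair_manifest)
        pairs = [(by_acc[r["accession1"]], by_acc[r["accession2"]],
                  f"{r.get('depth1', '')}|{r.get('depth2', '')}")
                 for _, r in manifest.iterrows()]
    else:
        pairs = [(genomes[i], genomes[i + 1], "unspecified")
                 for i in range(0, len(genomes) - 1, 2)]
    if not pairs:
        log.info("selection: no pairs to compare")
        return
    table = depth_pair_report(pairs)
    table.to_csv(out / "kaks_pairs.tsv", sep="\t", index=False)
    win_rows = []
    for g1, g2, _ in pairs:
        for gene in ("cox1", "nad5", "cob"):
            try:
                aln = codon_align(extract_cds(g1, gene),
                                  extract_cds(g2, gene), gene)
                scan = sliding_window(aln, cfg.window, cfg.step)
            except (KeyError, ValueError):
                continue
            for start, est in zip(scan.starts, scan.estimates):
                win_rows.append({"pair": f"{g1.accession} vs {g2.accession}",
                                 "gene": gene, "window_start_codon": start,
                                 "Ka": est.Ka, "Ks": est.Ks,
                                 "omega": est.omega if est.omega_defined
                                 else float("nan")})
    pd.DataFrame(win_rows).to_csv(out / "kaks_windows.tsv", sep="\t",
                                  index=False)
    log.info("selection: %d pairs, %d window rows", len(pairs), len(win_rows))


def _stage_control_region(genomes, cfg: RunConfig, out: Path) -> None:
    cr_rows, repeat_rows, motif_rows = [], [], []
    vienna = []
    for g in genomes:
        try:
            region = locate_control_region(g)
        except AnnotationError as exc:
            cr_rows.append({"accession": g.accession, "status": str(exc)})
            continue
        seq = g.slice(region.start, region.end, region.wraps)
        prof = composition(seq)
        cr_rows.append({"accession": g.accession, "status": "ok",
                        "start": region.start, "end": region.end,
                        "length": region.length, "flank5": region.flank5,
                        "flank3": region.flank3, "pct_AT": prof.at_content})
        for r in find_tandem_repeats(seq):
            repeat_rows.append({"accession": g.accession, "period": r.period,
                                "copies": r.copy_number, "start": r.start,
                                "end": r.end, "consensus": r.consensus,
                                "score": r.alignment_score,
                                "pct_match": r.percent_matches})
        for b in annotate_motifs(seq, cfg.min_ga, cfg.min_polyt,
                                 cfg.min_taa_units):
            motif_rows.append({"accession": g.accession, "kind": b.kind,
                               "start": b.start, "end": b.end,
                               "subtype": b.subtype})
        for s in find_ssrs(seq):
            motif_rows.append({"accession": g.accession, "kind": "SSR",
                               "start": s.start, "end": s.end,
                               "subtype": f"{s.unit}x{s.copies}"})
        fold_seq = seq[:cfg.fold_max_len]
        result = fold_mfe(fold_seq, temperature=cfg.fold_temperature)
        vienna.append(f"> {g.accession} CR[1:{len(fold_seq)}] "
                      f"dG={result.delta_g:.1f} kcal/mol "
                      f"T={cfg.fold_temperature}C\n{fold_seq}\n"
                      f"{result.structure}\n")
        log.info("control_region: %s CR %d bp, dG(first %d nt) = %.1f",
                 g.accession, region.length, len(fold_seq), result.delta_g)
    pd.DataFrame(cr_rows).to_csv(out / "control_regions.tsv", sep="\t",
                                 index=False)
    pd.DataFrame(repeat_rows).to_csv(out / "tandem_repeats.tsv", sep="\t",
                                     index=False)
    pd.DataFrame(motif_rows).to_csv(out / "motifs.tsv", sep="\t", index=False)
    (out / "structures.vienna").write_text("".join(vienna))


def _stage_depth_assoc(genomes, cfg: RunConfig, out: Path) -> None:
    records = load_habitat_table(cfg.habitat_csv or None)
    trends = dg_depth_trend(records, n_permutations=cfg.n_permutations,
                            seed=cfg.seed)
    pd.DataFrame([{"family": t.family, "n": t.n, "rho": t.spearman_rho,
                   "p_perm": t.p_perm, "direction": t.direction,
                   "vent": t.vent} for t in trends]).to_csv(
        out / "dg_depth_trends.tsv", sep="\t", index=False)
    carcinization_contrast(trends).to_csv(out / "carcinization_contrast.tsv",
                                          sep="\t", index=False)
    log.info("depth_assoc: %d family trends", len(trends))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured stages; returns the manifest dict (also written)."""
    out = Path(cfg.out_dir)
    _setup_logging(out)
    t0 = time.time()
    manifest = {"version": __version__, "config": cfg.to_dict(),
                "config_hash": cfg.hash(), "seed": cfg.seed, "stages": {}}
    genomes = _load_genomes(cfg) if cfg.input_dir else []
    write_feature_table(genomes, out / "features.tsv")
    runners = {"composition": _stage_composition,
               "gene_order": _stage_gene_order,
               "selection": _stage_selection,
               "control_region": _stage_control_region,
               "depth_assoc": _stage_depth_assoc}
    failed = False
    for stage in STAGES:
        if stage not in cfg.stages:
            manifest["stages"][stage] = "skipped"
            continue
        stage_dir = out / stage
        stage_dir.mkdir(parents=True, exist_ok=True)
        try:
            runners[stage](genomes, cfg, stage_dir)
            manifest["stages"][stage] = "ok"
        except Exception as exc:   # partial outputs retained
            log.error("stage %s failed: %s", stage, exc)
            manifest["stages"][stage] = f"failed: {exc}"
            failed = True
    log.info("pipeline finished in %.1f s", time.time() - t0)
    manifest["status"] = "failed" if failed else "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def make_fixtures(outdir: str | Path, n_genomes: int = 6,
                  seed: int = 0) -> dict:
    """Write the packaged reference tables and a synthetic genome set.

    The synthetic set plants three arrangement classes: the base order,
    a trnI/trnM-region transposition shared by two genomes, and a
    two-gene inversion -- together with per-genome truth JSON.
    """
    from importlib import resources
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("habitat_table.csv", "depth_categories.csv",
                 "ground_pattern_paper.txt", "ground_pattern_canonical37.txt"):
        (out / name).write_text(
            (resources.files("anomito") / "data" / name).read_text())
    events = [(), (), (("transposition", "trnI", "trnM"),),
              (("transposition", "trnI", "trnM"),),
              (("inversion", "trnD", "trnD"),), ()]
    truth_all = {}
    gb_dir = out / "genomes"
    gb_dir.mkdir(exist_ok=True)
    for i in range(n_genomes):
        spec = SyntheticGenomeSpec(
            accession=f"SYN{i + 1:06d}", taxon=f"Synthetica specimen{i + 1}",
            rearrangements=events[i % len(events)],
            cr_spec=CRSpec(seed=seed * 1000 + i),
            seed=seed * 100 + i)
        genome, truth = generate_genome(spec)
        write_genbank(genome, gb_dir / f"{spec.accession}.gb")
        truth_all[spec.accession] = truth.to_dict()
    (out / "truth.json").write_text(json.dumps(truth_all, indent=1,
                                               default=str))
    return {"outdir": str(out), "n_genomes": n_genomes,
            "files": sorted(p.name for p in out.iterdir())}
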