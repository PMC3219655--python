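"""Synthetic association tables with a ground-truth ledger.

Emulates the five input tables the pipeline consumes — verified
miRNA->target pairs, a disease gene list, TF binding-site hits in miRNA
promoter windows (1000nt hits nested inside 5000nt hits by construction),
TF-TcoF pairs with a confidence label, and protein-protein interactions —
with configurable counts, densities, role overlaps (a TF may share its id
with a disease target) and planted motifs, so that every pipeline stage is
testable without any database download.

The generator keeps its own bookkeeping of which rows will survive network
construction (the *ledger*): per-window expected census, per-table row
counts, and the planted motif lists.  The ledger is computed from the
generator's intent sets, not by running the construction code, so
ledger-vs-pipeline comparisons are a genuine cross-check.

Noise channels exercised: miRNA rows targeting non-disease genes,
binding-site hits scoring below the 0.9 filter threshold, low-confidence
TcoF links, and PPI rows touching proteins outside the retained set — all
of which construction must discard.

miRNA per-target counts are drawn from a geometric distribution truncated
at the target-pool size (real targeting degree is heavy-tailed: single
hub genes are hit by dozens of miRNAs); every miRNA is guaranteed at least
one disease-associated target and every disease gene at least one miRNA,
so the configured counts equal the constructed role counts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError
from .netmodel import NetworkCensus

__all__ = ["GeneratorConfig", "Ledger", "SynthTables", "generate", "published_scale_config"]

WINDOWS = (1000, 5000)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-data generator; defaults give a small fixture
    (20 miRNAs / 15 targets / 10 TFs / 5 TcoFs) that runs in milliseconds."""

    n_mirnas: int = 20
    n_targets: int = 15
    n_tfs: int = 10
    n_tcofs: int = 5
    n_nondisease_genes: int = 10
    n_distal_tfs: int = 0  # TFs whose sites fall only in the 5000nt window
    mean_targets_per_mirna: float = 2.5
    tf_hit_prob: float = 0.25  # P(binding site | TF-miRNA pair, 5000nt window)
    proximal_hit_fraction: float = 0.5  # P(site within 1000nt | site within 5000nt)
    extra_site_prob: float = 0.05  # chance of a second site in the same promoter
    frac_scores_below_threshold: float = 0.25
    score_pass_range: tuple = (0.9, 1.0)
    score_fail_range: tuple = (0.5, 0.9)
    mean_tfs_per_tcof: float = 2.0
    low_confidence_fraction: float = 0.2
    ppi_density: float = 0.05
    ppi_self_fraction: float = 0.02
    nondisease_target_prob: float = 0.3
    nondisease_ppi_prob: float = 0.3
    tf_target_overlap_fraction: float = 0.1
    n_planted_self_loops: int = 0
    n_planted_feedback_loops: int = 0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "n_mirnas",
            "n_targets",
            "n_tfs",
            "n_tcofs",
            "n_nondisease_genes",
            "n_distal_tfs",
            "n_planted_self_loops",
            "n_planted_feedback_loops",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in (
            "tf_hit_prob",
            "proximal_hit_fraction",
            "extra_site_prob",
            "frac_scores_below_threshold",
            "low_confidence_fraction",
            "ppi_density",
            "ppi_self_fraction",
            "nondisease_target_prob",
            "nondisease_ppi_prob",
            "tf_target_overlap_fraction",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.n_mirnas and self.n_targets and self.mean_targets_per_mirna < 1.0:
            raise ConfigError("mean_targets_per_mirna must be >= 1")
        if self.n_distal_tfs > self.n_tfs:
            raise ConfigError("n_distal_tfs exceeds n_tfs")
        if self.n_overlap_tfs > self.n_targets:
            raise ConfigError("TF/target overlap exceeds the target count")

    @property
    def n_overlap_tfs(self) -> int:
        """Number of (non-distal) TFs sharing an id with a disease target."""
        return int(round(self.tf_target_overlap_fraction * (self.n_tfs - self.n_distal_tfs)))


class SynthTables(NamedTuple):
    mirna_targets: pd.DataFrame
    disease_genes: pd.DataFrame
    tf_hits: pd.DataFrame
    tcof_pairs: pd.DataFrame
    ppi_pairs: pd.DataFrame


@dataclass
class Ledger:
    """Ground truth recorded while generating: what construction must find."""

    planted_self_loops: list  # (mirna, tf) pairs
    planted_feedback_loops: list  # (tf, mirna, target) triples
    row_counts: dict  # table name -> emitted rows
    census: dict  # promoter window -> NetworkCensus

    def as_dict(self) -> dict:
        return {
            "planted_self_loops": [list(p) for p in self.planted_self_loops],
            "planted_feedback_loops": [list(p) for p in self.planted_feedback_loops],
            "row_counts": dict(self.row_counts),
            "census": {str(w): c.as_dict() for w, c in self.census.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class _Site:
    tf: str
    mirna: str
    proximal: bool
    passing: bool
    core: float
    matrix: float


def _truncated_geometric(rng: np.random.Generator, mean: float, upper: int) -> int:
    return int(min(rng.geometric(1.0 / mean), upper))


def _draw_site(rng, cfg: GeneratorConfig, tf: str, mirna: str, proximal: bool) -> _Site:
    passing = rng.random() >= cfg.frac_scores_below_threshold
    lo, hi = cfg.score_pass_range if passing else cfg.score_fail_range
    core = float(lo + (hi - lo) * rng.random())
    matrix = float(lo + (hi - lo) * rng.random())
    return _Site(tf, mirna, proximal, passing, round(core, 4), round(matrix, 4))


def _forced_site(rng, cfg, tf, mirna, proximal) -> _Site:
    lo, hi = cfg.score_pass_range
    return _Site(
        tf,
        mirna,
        proximal,
        True,
        round(float(lo + (hi - lo) * rng.random()), 4),
        round(float(lo + (hi - lo) * rng.random()), 4),
    )


def generate(config: GeneratorConfig) -> tuple[SynthTables, Ledger]:
    """Emit the five association tables plus the ground-truth ledger.

    Deterministic given ``config.seed`` (byte-identical tables).  Raises
    :class:`ConfigError` for infeasible motif-planting requests.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    mirnas = [f"mir-{i:04d}" for i in range(cfg.n_mirnas)]
    targets = [f"GD{i:04d}" for i in range(cfg.n_targets)]
    nondisease = [f"GN{i:04d}" for i in range(cfg.n_nondisease_genes)]
    n_pure = cfg.n_tfs - cfg.n_distal_tfs - cfg.n_overlap_tfs
    if n_pure < 0:
        raise ConfigError("overlap and distal TFs together exceed n_tfs")
    overlap_tfs = targets[: cfg.n_overlap_tfs]
    pure_tfs = [f"TF{i:04d}" for i in range(n_pure + cfg.n_distal_tfs)]
    distal_tfs = pure_tfs[n_pure:]
    nondistal_tfs = overlap_tfs + pure_tfs[:n_pure]
    tfs = nondistal_tfs + distal_tfs
    tcofs = [f"CF{i:04d}" for i in range(cfg.n_tcofs)]

    # --- miRNA targeting (heavy-tailed degree; full bipartite coverage) ----
    targeting: set = set()
    if cfg.n_mirnas and cfg.n_targets:
        for m in mirnas:
            k = _truncated_geometric(rng, cfg.mean_targets_per_mirna, cfg.n_targets)
            for g in rng.choice(cfg.n_targets, size=k, replace=False):
                targeting.add((m, targets[int(g)]))
        covered = {g for _, g in targeting}
        for g in targets:  # every disease gene gets at least one miRNA
            if g not in covered:
                targeting.add((mirnas[int(rng.integers(cfg.n_mirnas))], g))
    noise_targeting = set()
    for m in mirnas:
        if nondisease and rng.random() < cfg.nondisease_target_prob:
            noise_targeting.add((m, nondisease[int(rng.integers(len(nondisease)))]))

    # --- TFBS sites --------------------------------------------------------
    sites: list[_Site] = []
    for tf in tfs:
        distal_only = tf in distal_tfs
        for m in mirnas:
            if rng.random() < cfg.tf_hit_prob:
                proximal = (not distal_only) and rng.random() < cfg.proximal_hit_fraction
                sites.append(_draw_site(rng, cfg, tf, m, proximal))
                if rng.random() < cfg.extra_site_prob:
                    proximal2 = (not distal_only) and rng.random() < cfg.proximal_hit_fraction
                    sites.append(_draw_site(rng, cfg, tf, m, proximal2))
    # retention guarantees: every TF keeps >= 1 passing site in its window
    # (skipped when the config demands that every score fail the filter)
    if mirnas and cfg.frac_scores_below_threshold < 1.0:
        for tf in nondistal_tfs:
            if not any(s.tf == tf and s.proximal and s.passing for s in sites):
                sites.append(
                    _forced_site(rng, cfg, tf, mirnas[int(rng.integers(cfg.n_mirnas))], True)
                )
        for tf in distal_tfs:
            if not any(s.tf == tf and s.passing for s in sites):
                sites.append(
                    _forced_site(rng, cfg, tf, mirnas[int(rng.integers(cfg.n_mirnas))], False)
                )

    # --- TcoF links (high-confidence links only to non-distal TFs) --------
    tcof_rows: list[tuple] = []
    tcof_links: set = set()
    if nondistal_tfs:
        for c in tcofs:
            k = _truncated_geometric(rng, cfg.mean_tfs_per_tcof, len(nondistal_tfs))
            chosen = [nondistal_tfs[int(i)] for i in rng.choice(len(nondistal_tfs), k, replace=False)]
            confs = ["low" if rng.random() < cfg.low_confidence_fraction else "high" for _ in chosen]
            if "high" not in confs:
                confs[0] = "high"
            for tf, conf in zip(chosen, confs):
                tcof_rows.append((tf, c, conf))
                if conf == "high":
                    tcof_links.add(tuple(sorted((tf, c))))

    # --- background PPIs ---------------------------------------------------
    universe = sorted(set(targets) | set(tfs) | set(tcofs))
    n_u = len(universe)
    ppi_background: set = set()
    if n_u:
        draws = rng.random((n_u, n_u))
        iu, ju = np.triu_indices(n_u, k=1)
        for i, j in zip(iu[draws[iu, ju] < cfg.ppi_density], ju[draws[iu, ju] < cfg.ppi_density]):
            ppi_background.add((universe[int(i)], universe[int(j)]))
        for i in np.flatnonzero(rng.random(n_u) < cfg.ppi_self_fraction):
            ppi_background.add((universe[int(i)], universe[int(i)]))
    noise_ppi = set()
    for g in nondisease:
        if universe and rng.random() < cfg.nondisease_ppi_prob:
            partner = universe[int(rng.integers(n_u))]
            noise_ppi.add(tuple(sorted((g, partner))))

    # --- planted motifs ----------------------------------------------------
    planted_self: list = []
    if cfg.n_planted_self_loops:
        pool = [(m, tf) for tf in overlap_tfs for m in mirnas]
        if cfg.n_planted_self_loops > len(pool):
            raise ConfigError(
                f"cannot plant {cfg.n_planted_self_loops} self-loops: only "
                f"{len(pool)} (miRNA, overlap-TF) pairs available"
            )
        for i in rng.choice(len(pool), cfg.n_planted_self_loops, replace=False):
            m, tf = pool[int(i)]
            sites.append(_forced_site(rng, cfg, tf, m, True))
            targeting.add((m, tf))
            planted_self.append((m, tf))

    planted_fbl: list = []
    if cfg.n_planted_feedback_loops:
        space = [
            (tf, m, g)
            for tf in nondistal_tfs
            for m in mirnas
            for g in targets
            if g != tf
        ]
        if cfg.n_planted_feedback_loops > len(space):
            raise ConfigError(
                f"cannot plant {cfg.n_planted_feedback_loops} feedback loops: "
                f"only {len(space)} triples available"
            )
        for i in rng.choice(len(space), cfg.n_planted_feedback_loops, replace=False):
            tf, m, g = space[int(i)]
            sites.append(_forced_site(rng, cfg, tf, m, True))
            targeting.add((m, g))
            ppi_background.add(tuple(sorted((g, tf))))
            planted_fbl.append((tf, m, g))

    # --- ground-truth census per window ------------------------------------
    reg_pairs = {
        1000: {(s.tf, s.mirna) for s in sites if s.proximal and s.passing},
        5000: {(s.tf, s.mirna) for s in sites if s.passing},
    }
    census = {}
    for w in WINDOWS:
        tfs_w = {tf for tf, _ in reg_pairs[w]}
        links_w = {p for p in tcof_links if p[0] in tfs_w or p[1] in tfs_w}
        tcofs_w = {c for link in links_w for c in link if c in set(tcofs)}
        proteins = set(targets) | tfs_w | tcofs_w
        ppi_w = {p for p in ppi_background if p[0] in proteins and p[1] in proteins}
        ppi_w |= links_w
        census[w] = NetworkCensus(
            n_mirnas=cfg.n_mirnas,
            n_targets=cfg.n_targets,
            n_tfs=len(tfs_w),
            n_tcofs=len(tcofs_w),
            n_targeting=len(targeting),
            n_regulation=len(reg_pairs[w]),
            n_ppi=len(ppi_w),
            total_nodes=cfg.n_mirnas + len(proteins),
            total_edges=len(targeting) + len(reg_pairs[w]) + len(ppi_w),
        )

    # --- emit tables (sorted for byte-determinism) -------------------------
    mt_rows = sorted(targeting | noise_targeting)
    mirna_targets = pd.DataFrame(mt_rows, columns=["mirna_id", "target_id"])
    disease_genes = pd.DataFrame({"gene_id": sorted(targets)})
    hit_rows = []
    for s in sites:
        hit_rows.append((s.tf, s.mirna, s.core, s.matrix, 5000))
        if s.proximal:
            hit_rows.append((s.tf, s.mirna, s.core, s.matrix, 1000))
    tf_hits = pd.DataFrame(
        sorted(hit_rows), columns=["tf_id", "mirna_id", "core_score", "matrix_score", "window_nt"]
    )
    tcof_pairs = pd.DataFrame(sorted(tcof_rows), columns=["tf_id", "tcof_id", "confidence"])
    ppi_pairs = pd.DataFrame(
        sorted(ppi_background | noise_ppi), columns=["protein_a", "protein_b"]
    )

    tables = SynthTables(mirna_targets, disease_genes, tf_hits, tcof_pairs, ppi_pairs)
    ledger = Ledger(
        planted_self_loops=sorted(planted_self),
        planted_feedback_loops=sorted(planted_fbl),
        row_counts={name: len(df) for name, df in tables._asdict().items()},
        census=census,
    )
    return tables, ledger


def published_scale_config(seed: int = 0) -> GeneratorConfig:
    """A configuration matching the published networks' role counts (162
    miRNAs, 131 targets, 244 TFs of which 7 bind only distally, 140 TcoFs,
    19 TF/target id overlaps) with densities chosen so the expected per-type
    edge counts approximate the published census (434 targeting edges, 5327
    / 14720 regulation edges at 1000 / 5000nt, ~4400 PPIs)."""
    p_pass_5000 = 14720 / (244 * 162)
    p_pass_1000 = 5327 / (237 * 162)
    frac_below = 0.25
    return GeneratorConfig(
        n_mirnas=162,
        n_targets=131,
        n_tfs=244,
        n_tcofs=140,
        n_nondisease_genes=250,
        n_distal_tfs=7,
        mean_targets_per_mirna=434 / 162,
        tf_hit_prob=p_pass_5000 / (1 - frac_below),
        proximal_hit_fraction=p_pass_1000 / p_pass_5000,
        extra_site_prob=0.05,
        frac_scores_below_threshold=frac_below,
        mean_tfs_per_tcof=3.0,
        low_confidence_fraction=0.2,
        ppi_density=0.034,
        ppi_self_fraction=0.01,
        nondisease_target_prob=0.5,
        nondisease_ppi_prob=0.3,
        tf_target_overlap_fraction=19 / 237,
        seed=seed,
    )
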