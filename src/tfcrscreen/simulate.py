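"""Synthetic regulatory landscapes with known ground truth.

The generator plants TFBS clusters on a small multi-chromosome genome and
emits every file the screen consumes (FIMO TSVs, narrowPeak, gene BED,
expression TSV, variant BEDs, element BED) plus a machine-readable truth
record, so the whole pipeline is testable without any external download.

What it emulates, and how:

* Clusters of TFBS with variable TF complexity: each planted cluster draws
  ``TC_true = 1 + Poisson(cluster_tc_mean)`` distinct TFs, each with
  ``1 + Poisson(sites_per_tf_mean - 1)`` sites scattered
  ``Normal(center, cluster_spread)`` around the cluster center.
* Accessibility that saturates in TF complexity: each cluster carries one
  peak whose score follows
  ``sc_base + sc_slope * min(TC_true, sc_saturation_tc) + Normal(0, sc_noise_sd)``
  (truncated at 0), which reproduces the observed TC-SC correlation
  breakpoint: correlated below the saturation point, decoupled above it.
* Condition structure: shared clusters appear in both tumor and normal
  data (same sites, independently drawn peak noise), gain clusters only in
  tumor, lost clusters only in normal.
* Expression elevated near high-TC clusters, and driver genes planted under
  gain clusters verified to fall in the top TC and SC deciles.
* Mutation density increasing with TC: per-bp variant rates are
  ``base + slope * TC_true`` inside cluster windows and ``base`` elsewhere.

Two deliberate departures from a fully uniform background keep the planted
ground truth well defined. Cluster centers are laid on a separation grid
(``min_cluster_separation >= 10 sigma``) so clusters are identifiable, and
background TFBS of one condition are kept 1.5 kb away from the *other*
condition's exclusive cluster centers - otherwise a stray background TFCR
would occasionally re-label a planted gain/lost cluster as stable and the
planted condition labels would not be a usable truth.
"""
from __future__ import annotations

import dataclasses
import json
import math
from bisect import bisect_left
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from . import io as gio
from .core import identify_tfcrs
from .models import (
    AccessibilityPeak,
    ElementInterval,
    GeneModel,
    Tfcr,
    TfcrParams,
    TfbsRecord,
    VariantRecord,
)
from .screen import TOP_BIN, classify_differential
from .stats import bin_tfcrs

TFBS_HALF_WIDTH = 5  # planted motif hits are 10 bp intervals
TRUTH_WINDOW_HALF = 450  # nominal cluster window (maxdist ~300 + 150 pad)
BACKGROUND_EXCLUSION = 1500  # bp kept clear of opposite-condition exclusive clusters
GENE_EXCLUSION = 2000  # non-driver genes stay this far from gain cluster centers


@dataclass(slots=True)
class SyntheticConfig:
    """Study conditions of the synthetic landscape.

    The defaults define the standard benchmark: 200 planted clusters
    (100 shared, 50 gain, 50 lost) on a 4 x 2 Mb genome with background
    TFBS at 0.05 per kb, accessibility saturating at TC = 50, and eight
    driver genes planted under top-decile gain clusters.
    """

    seed: int = 17
    n_chrom: int = 4
    chrom_length: int = 2_000_000
    n_shared: int = 100
    n_gain: int = 50
    n_lost: int = 50
    tf_panel_size: int = 200
    cluster_tc_mean: float = 45.0
    sites_per_tf_mean: float = 2.0
    cluster_spread: float = 75.0
    background_tfbs_per_kb: float = 0.05
    peak_width_range: tuple[int, int] = (400, 1200)
    sc_base: float = 2.0
    sc_slope: float = 0.2
    sc_saturation_tc: float = 50.0
    sc_noise_sd: float = 0.5
    n_genes: int = 300
    n_driver_genes: int = 8
    expr_lognormal_params: tuple[float, float] = (0.5, 1.0)
    expr_boost_near_top_clusters: float = 8.0
    gene_near_cluster_prob: float = 0.8
    gene_length_range: tuple[int, int] = (2000, 10000)
    mutation_rate_base_per_kb: float = 0.5
    mutation_rate_tc_slope_per_kb: float = 0.05
    min_cluster_separation: int = 5000
    analysis_params: TfcrParams = field(default_factory=TfcrParams)

    def __post_init__(self) -> None:
        for name in ("n_shared", "n_gain", "n_lost", "n_chrom", "n_genes",
                     "n_driver_genes", "tf_panel_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_cluster_separation < 10 * self.analysis_params.sigma:
            raise ValueError(
                "min_cluster_separation must be >= 10 * sigma so planted "
                "clusters are identifiable"
            )

    @property
    def n_clusters(self) -> int:
        return self.n_shared + self.n_gain + self.n_lost


def breakpoint_config(seed: int = 17) -> SyntheticConfig:
    """Study conditions for the TC-SC saturation (breakpoint) analysis.

    The magnitude of a null Pearson correlation scales as 1/sqrt(n), so the
    saturated stratum must be large for |r_high| to concentrate near zero:
    400 tumor-side clusters (shared + gain) with cluster_tc_mean = 55 put
    roughly 320 tumor clusters above the TC = 50 saturation point
    (P(1 + Poisson(55) >= 50) ~ 0.81), at which 0.2 is about 3.6 null
    standard deviations.
    """
    return SyntheticConfig(
        seed=seed,
        n_chrom=4,
        chrom_length=4_000_000,
        n_shared=250,
        n_gain=150,
        n_lost=100,
        cluster_tc_mean=55.0,
        n_driver_genes=0,
    )


@dataclass(slots=True)
class ClusterTruth:
    cluster_id: str
    chrom: str
    center: int
    membership: str  # shared | gain | lost
    tc_true: int
    n_tfbs: dict[str, int]
    peak_score: dict[str, float]

    @property
    def conditions(self) -> tuple[str, ...]:
        return {
            "shared": ("tumor", "normal"),
            "gain": ("tumor",),
            "lost": ("normal",),
        }[self.membership]

    @property
    def window(self) -> tuple[int, int]:
        return (self.center - TRUTH_WINDOW_HALF, self.center + TRUTH_WINDOW_HALF)


@dataclass(slots=True)
class SyntheticTruth:
    clusters: list[ClusterTruth]
    driver_genes: list[dict]
    files: dict[str, str]
    config: SyntheticConfig

    def to_json(self, path) -> None:
        payload = {
            "clusters": [dataclasses.asdict(c) for c in self.clusters],
            "driver_genes": self.driver_genes,
            # basenames only, so the record is portable and reruns into
            # different directories stay byte-identical
            "files": {k: Path(v).name for k, v in self.files.items()},
            "config": dataclasses.asdict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        base = Path(path).parent
        payload["files"] = {
            k: str(base / v) for k, v in payload["files"].items()
        }
        cfg = dict(payload["config"])
        cfg["analysis_params"] = TfcrParams(**cfg["analysis_params"])
        for key in ("peak_width_range", "expr_lognormal_params", "gene_length_range"):
            cfg[key] = tuple(cfg[key])
        return cls(
            clusters=[ClusterTruth(**c) for c in payload["clusters"]],
            driver_genes=payload["driver_genes"],
            files=payload["files"],
            config=SyntheticConfig(**cfg),
        )


# ---------------------------------------------------------------------------
# generation


def _place_centers(cfg: SyntheticConfig, rng: np.random.Generator):
    """Cluster centers on a separation grid with +/-500 bp jitter."""
    margin = 20_000
    per_chrom = [cfg.n_clusters // cfg.n_chrom] * cfg.n_chrom
    for i in range(cfg.n_clusters % cfg.n_chrom):
        per_chrom[i] += 1
    placed: list[tuple[str, int]] = []
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        slots = np.arange(margin, cfg.chrom_length - margin, cfg.min_cluster_separation)
        if len(slots) < per_chrom[c]:
            raise ValueError(
                f"chromosome length {cfg.chrom_length} cannot hold "
                f"{per_chrom[c]} clusters at separation {cfg.min_cluster_separation}"
            )
        chosen = np.sort(rng.choice(len(slots), size=per_chrom[c], replace=False))
        jitter = rng.integers(-500, 501, size=per_chrom[c])
        for pos in np.sort(slots[chosen] + jitter):
            placed.append((chrom, int(pos)))
    return placed


def _sample_background(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    excluded_centers: dict[str, list[int]],
) -> list[tuple[str, int]]:
    """Uniform background TFBS positions avoiding excluded cluster centers."""
    out: list[tuple[str, int]] = []
    rate = cfg.background_tfbs_per_kb / 1000.0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        n = rng.poisson(rate * cfg.chrom_length)
        centers = excluded_centers.get(chrom, [])
        accepted: list[int] = []
        while len(accepted) < n:
            pos = int(rng.integers(TFBS_HALF_WIDTH, cfg.chrom_length - TFBS_HALF_WIDTH))
            i = bisect_left(centers, pos)
            near = any(
                abs(pos - centers[j]) < BACKGROUND_EXCLUSION
                for j in (i - 1, i)
                if 0 <= j < len(centers)
            )
            if not near:
                accepted.append(pos)
        out.extend((chrom, p) for p in accepted)
    return out


def _tf_name(index: int) -> str:
    return f"TF{index:03d}"


def _peak_score(cfg: SyntheticConfig, tc_true: int, rng: np.random.Generator) -> float:
    raw = (
        cfg.sc_base
        + cfg.sc_slope * min(tc_true, cfg.sc_saturation_tc)
        + rng.normal(0.0, cfg.sc_noise_sd)
    )
    return max(0.0, float(raw))


def generate_landscape(
    config: Optional[SyntheticConfig] = None, out_dir=None
) -> SyntheticTruth:
    """Generate the landscape files and ground truth.

    Deterministic given ``config.seed``: the same configuration written
    twice produces byte-identical files. When driver genes are requested
    the generator runs the identification/binning/classification pipeline
    on its own TFBS and peaks (genes, variants and elements play no part in
    TFCR calling, so this is well defined) and plants drivers only under
    gain clusters *verified* to sit in both top deciles of the called tumor
    landscape.
    """
    cfg = config or SyntheticConfig()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    centers = _place_centers(cfg, rng)
    labels = (
        ["shared"] * cfg.n_shared + ["gain"] * cfg.n_gain + ["lost"] * cfg.n_lost
    )
    labels = [labels[i] for i in rng.permutation(cfg.n_clusters)]

    clusters: list[ClusterTruth] = []
    tfbs: dict[str, list[TfbsRecord]] = {"tumor": [], "normal": []}
    peaks: dict[str, list[AccessibilityPeak]] = {"tumor": [], "normal": []}
    for k, ((chrom, center), membership) in enumerate(zip(centers, labels)):
        tc_true = 1 + int(rng.poisson(cfg.cluster_tc_mean))
        tc_true = min(tc_true, cfg.tf_panel_size)
        tf_ids = rng.choice(cfg.tf_panel_size, size=tc_true, replace=False)
        sites: list[TfbsRecord] = []
        for tf in tf_ids:
            n_sites = 1 + int(rng.poisson(max(cfg.sites_per_tf_mean - 1.0, 0.0)))
            offsets = rng.normal(0.0, cfg.cluster_spread, size=n_sites)
            for off in offsets:
                pos = int(round(center + off))
                pos = max(TFBS_HALF_WIDTH, min(cfg.chrom_length - TFBS_HALF_WIDTH, pos))
                sites.append(
                    TfbsRecord(
                        chrom=chrom,
                        start=pos - TFBS_HALF_WIDTH,
                        end=pos + TFBS_HALF_WIDTH,
                        tf_name=_tf_name(int(tf)),
                        motif_id=f"M{int(tf):03d}",
                        strand="+",
                    )
                )
        conditions = (
            ("tumor", "normal") if membership == "shared"
            else (("tumor",) if membership == "gain" else ("normal",))
        )
        n_tfbs: dict[str, int] = {}
        peak_score: dict[str, float] = {}
        for cond in conditions:
            tfbs[cond].extend(sites)
            n_tfbs[cond] = len(sites)
            width = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
            score = _peak_score(cfg, tc_true, rng)
            peaks[cond].append(
                AccessibilityPeak(
                    chrom=chrom,
                    start=max(0, center - width // 2),
                    end=center + width // 2,
                    score=score,
                    source="ATAC" if cond == "tumor" else "DNase",
                    condition=cond,
                )
            )
            peak_score[cond] = score
        clusters.append(
            ClusterTruth(
                cluster_id=f"cl{k:04d}",
                chrom=chrom,
                center=center,
                membership=membership,
                tc_true=tc_true,
                n_tfbs=n_tfbs,
                peak_score=peak_score,
            )
        )

    gain_centers: dict[str, list[int]] = {}
    lost_centers: dict[str, list[int]] = {}
    for cl in clusters:
        if cl.membership == "gain":
            gain_centers.setdefault(cl.chrom, []).append(cl.center)
        elif cl.membership == "lost":
            lost_centers.setdefault(cl.chrom, []).append(cl.center)
    for d in (gain_centers, lost_centers):
        for v in d.values():
            v.sort()

    # Background sites: tumor background avoids lost centers (and vice
    # versa) so chance TFCRs never sit on an opposite-condition-exclusive
    # planted cluster.
    for cond, excluded in (("tumor", lost_centers), ("normal", gain_centers)):
        for chrom, pos in _sample_background(cfg, rng, excluded):
            tf = int(rng.integers(cfg.tf_panel_size))
            tfbs[cond].append(
                TfbsRecord(
                    chrom=chrom,
                    start=pos - TFBS_HALF_WIDTH,
                    end=pos + TFBS_HALF_WIDTH,
                    tf_name=_tf_name(tf),
                    motif_id=f"M{tf:03d}",
                    strand="+",
                )
            )

    # --- driver-gene hosts: gain clusters verified to be TC9 & SC9 -------
    driver_hosts: list[ClusterTruth] = []
    if cfg.n_driver_genes > 0 and cfg.n_gain > 0:
        called = {
            cond: identify_tfcrs(tfbs[cond], peaks[cond], cfg.analysis_params, cond)
            for cond in ("tumor", "normal")
        }
        for cond in ("tumor", "normal"):
            if called[cond]:
                bin_tfcrs(called[cond])
        diff = classify_differential(called["tumor"], called["normal"])
        top_gain = [
            t for t in diff.gain if t.tc_bin == TOP_BIN and t.sc_bin == TOP_BIN
        ]
        matched_ids: set[str] = set()
        for t in top_gain:
            centers_here = gain_centers.get(t.chrom, [])
            i = bisect_left(centers_here, t.summit)
            for j in (i - 1, i):
                if 0 <= j < len(centers_here) and abs(t.summit - centers_here[j]) <= 300:
                    for cl in clusters:
                        if cl.chrom == t.chrom and cl.center == centers_here[j]:
                            matched_ids.add(cl.cluster_id)
        matched = sorted(matched_ids)
        take = min(cfg.n_driver_genes, len(matched))
        chosen = sorted(np.array(matched)[rng.permutation(len(matched))[:take]])
        by_id = {cl.cluster_id: cl for cl in clusters}
        driver_hosts = [by_id[c] for c in chosen]

    # --- genes -----------------------------------------------------------
    genes: list[GeneModel] = []
    expression: dict[str, float] = {}
    driver_records: list[dict] = []
    mu, sd = cfg.expr_lognormal_params
    tc_values = np.array([cl.tc_true for cl in clusters])
    tc_q75 = float(np.quantile(tc_values, 0.75)) if len(tc_values) else 0.0
    counter = 0

    def _make_gene(chrom: str, tss: int, strand: str, length: int) -> GeneModel:
        nonlocal counter
        counter += 1
        gene_id = f"GENE{counter:04d}"
        if strand == "+":
            start, end = tss, tss + length
        else:
            start, end = tss - length + 1, tss + 1
        start = max(0, start)
        return GeneModel(
            gene_id=gene_id, symbol=gene_id, chrom=chrom,
            tss=tss, start=start, end=end, strand=strand,
        )

    def _clear_of_gain(g: GeneModel) -> bool:
        s, e = g.extended_interval(2000)
        for gc in gain_centers.get(g.chrom, []):
            if s < gc + GENE_EXCLUSION and gc - GENE_EXCLUSION < e:
                return False
        return True

    for cl in driver_hosts:
        tss = cl.center + int(rng.integers(-500, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(*cfg.gene_length_range))
        g = _make_gene(cl.chrom, tss, strand, length)
        genes.append(g)
        fpkm = 5.0 + float(rng.lognormal(mu, sd))
        expression[g.gene_id] = round(fpkm, 4)
        driver_records.append(
            {"gene_id": g.gene_id, "cluster_id": cl.cluster_id,
             "fpkm": expression[g.gene_id]}
        )

    for cl in clusters:
        if cl.membership != "shared" or len(genes) >= cfg.n_genes:
            continue
        if rng.random() >= cfg.gene_near_cluster_prob:
            continue
        tss = cl.center + int(rng.integers(-500, 501))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(*cfg.gene_length_range))
        g = _make_gene(cl.chrom, tss, strand, length)
        if not _clear_of_gain(g):
            counter -= 1
            continue
        genes.append(g)
        fpkm = float(rng.lognormal(mu, sd))
        if cl.tc_true >= tc_q75:
            fpkm *= cfg.expr_boost_near_top_clusters
        expression[g.gene_id] = round(fpkm, 4)

    while len(genes) < cfg.n_genes:
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        tss = int(rng.integers(15_000, cfg.chrom_length - 15_000))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(rng.integers(*cfg.gene_length_range))
        g = _make_gene(chrom, tss, strand, length)
        if not _clear_of_gain(g):
            counter -= 1
            continue
        genes.append(g)
        expression[g.gene_id] = round(float(rng.lognormal(mu, sd)), 4)

    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))

    # --- regulatory elements --------------------------------------------
    elements: list[ElementInterval] = []
    for g in genes:
        elements.append(
            ElementInterval(
                chrom=g.chrom, start=max(0, g.tss - 500), end=g.tss + 500,
                element_class="promoter",
            )
        )
    tc_q90 = float(np.quantile(tc_values, 0.90)) if len(tc_values) else 0.0
    tumor_scores = [
        cl.peak_score["tumor"] for cl in clusters if "tumor" in cl.peak_score
    ]
    score_q90 = float(np.quantile(tumor_scores, 0.90)) if tumor_scores else 0.0
    for cl in clusters:
        if cl.tc_true >= tc_q90:
            elements.append(
                ElementInterval(
                    chrom=cl.chrom, start=cl.center - 500, end=cl.center + 500,
                    element_class="enhancer",
                )
            )
        if cl.peak_score.get("tumor", -1.0) >= score_q90:
            elements.append(
                ElementInterval(
                    chrom=cl.chrom, start=cl.center - 300, end=cl.center + 300,
                    element_class="cpg_island",
                )
            )
    for _ in range(20):
        chrom = f"chr{int(rng.integers(cfg.n_chrom)) + 1}"
        start = int(rng.integers(0, cfg.chrom_length - 1000))
        elements.append(
            ElementInterval(chrom=chrom, start=start, end=start + 1000,
                            element_class="other")
        )
    elements.sort(key=lambda e: (e.chrom, e.start, e.element_class))

    # --- variants --------------------------------------------------------
    variants: dict[str, list[VariantRecord]] = {"tumor": [], "normal": []}
    base_p = cfg.mutation_rate_base_per_kb / 1000.0
    slope_p = cfg.mutation_rate_tc_slope_per_kb / 1000.0
    for cond in ("tumor", "normal"):
        for c in range(cfg.n_chrom):
            chrom = f"chr{c + 1}"
            n_bg = int(rng.binomial(cfg.chrom_length, base_p))
            for pos in sorted(rng.integers(0, cfg.chrom_length, size=n_bg)):
                variants[cond].append(VariantRecord(chrom=chrom, pos=int(pos)))
        for cl in clusters:
            if cond not in cl.conditions:
                continue
            ws, we = cl.window
            extra_p = min(1.0, slope_p * cl.tc_true)
            n_extra = int(rng.binomial(we - ws, extra_p))
            for pos in sorted(rng.integers(ws, we, size=n_extra)):
                variants[cond].append(VariantRecord(chrom=cl.chrom, pos=int(pos)))
        variants[cond].sort(key=lambda v: (v.chrom, v.pos))

    # --- write files -----------------------------------------------------
    files: dict[str, str] = {}
    if out is not None:
        for cond in ("tumor", "normal"):
            p = out / f"tfbs_{cond}.fimo.tsv"
            gio.write_fimo_hits(tfbs[cond], p)
            files[f"tfbs_{cond}"] = str(p)
            p = out / f"peaks_{cond}.narrowPeak"
            gio.write_narrowpeak(peaks[cond], p)
            files[f"peaks_{cond}"] = str(p)
            p = out / f"variants_{cond}.bed"
            gio.write_bed(((v.chrom, v.pos, v.pos + 1) for v in variants[cond]), p)
            files[f"variants_{cond}"] = str(p)
        p = out / "genes.bed"
        gio.write_bed(
            ((g.chrom, g.start, g.end, g.gene_id, 0, g.strand) for g in genes), p
        )
        files["genes"] = str(p)
        p = out / "expression.tsv"
        gio.write_expression_table(expression, p)
        files["expression"] = str(p)
        p = out / "elements.bed"
        gio.write_bed(
            ((e.chrom, e.start, e.end, e.element_class) for e in elements), p
        )
        files["elements"] = str(p)

    truth = SyntheticTruth(
        clusters=clusters, driver_genes=driver_records, files=files, config=cfg
    )
    if out is not None:
        truth.to_json(out / "truth.json")
        files["truth"] = str(out / "truth.json")
    return truth


# ---------------------------------------------------------------------------
# recovery evaluation


@dataclass(slots=True)
class RecoveryReport:
    """Agreement between planted clusters and called TFCRs."""

    n_planted: int
    n_called: int
    n_recovered: int
    recall: float
    recall_min3_tfbs: Optional[float]
    precision: Optional[float]
    tc_exact_rate: Optional[float]
    label_confusion: dict[str, int]
    label_exact_rate: Optional[float]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _greedy_match(
    centers: list[tuple[str, int, int]],  # (chrom, center, cluster_index)
    calls: Sequence[Tfcr],
    tol: int,
) -> dict[int, Tfcr]:
    """Greedy nearest-first 1-1 matching of summits to planted centers."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, center, idx in centers:
        by_chrom.setdefault(chrom, []).append((center, idx))
    for v in by_chrom.values():
        v.sort()
    pairs: list[tuple[int, int, int]] = []  # (dist, cluster_idx, call_idx)
    for ci, t in enumerate(calls):
        cands = by_chrom.get(t.chrom, [])
        positions = [c for c, _ in cands]
        i = bisect_left(positions, t.summit)
        for j in (i - 1, i):
            if 0 <= j < len(cands):
                dist = abs(t.summit - cands[j][0])
                if dist <= tol:
                    pairs.append((dist, cands[j][1], ci))
    pairs.sort()
    matched: dict[int, Tfcr] = {}
    used_calls: set[int] = set()
    for _, cluster_idx, call_idx in pairs:
        if cluster_idx in matched or call_idx in used_calls:
            continue
        matched[cluster_idx] = calls[call_idx]
        used_calls.add(call_idx)
    return matched


def evaluate_recovery(
    truth: SyntheticTruth,
    called: Sequence[Tfcr],
    match_tol: int = 300,
) -> RecoveryReport:
    """Score called TFCRs (both conditions pooled) against the planted truth.

    A planted cluster is recovered when a summit of every condition it
    belongs to lies within ``match_tol`` of its center (greedy 1-1
    nearest-first matching). Precision counts summits matching no planted
    center of their condition as false positives. The TC exact-match rate
    is computed per matched (cluster, condition) pair, and label agreement
    compares the gain/lost/stable classification of matched calls with the
    planted membership.
    """
    calls_by_cond: dict[str, list[Tfcr]] = {"tumor": [], "normal": []}
    for t in called:
        calls_by_cond[t.condition].append(t)

    matched: dict[str, dict[int, Tfcr]] = {}
    for cond in ("tumor", "normal"):
        centers = [
            (cl.chrom, cl.center, i)
            for i, cl in enumerate(truth.clusters)
            if cond in cl.conditions
        ]
        matched[cond] = _greedy_match(centers, calls_by_cond[cond], match_tol)

    recovered = [
        i
        for i, cl in enumerate(truth.clusters)
        if all(i in matched[cond] for cond in cl.conditions)
    ]
    n_planted = len(truth.clusters)
    recall = len(recovered) / n_planted if n_planted else 0.0

    idx_min3 = [
        i
        for i, cl in enumerate(truth.clusters)
        if all(cl.n_tfbs.get(cond, 0) >= 3 for cond in cl.conditions)
    ]
    recall_min3 = (
        sum(1 for i in idx_min3 if i in recovered) / len(idx_min3)
        if idx_min3
        else None
    )

    n_called = len(called)
    n_matched_calls = sum(len(m) for m in matched.values())
    precision = n_matched_calls / n_called if n_called else None

    tc_pairs = [
        (truth.clusters[i].tc_true, m.tc)
        for cond in ("tumor", "normal")
        for i, m in matched[cond].items()
    ]
    tc_exact = (
        sum(1 for true_tc, called_tc in tc_pairs if true_tc == called_tc)
        / len(tc_pairs)
        if tc_pairs
        else None
    )

    diff = classify_differential(calls_by_cond["tumor"], calls_by_cond["normal"])
    gain_ids = {t.tfcr_id for t in diff.gain}
    lost_ids = {t.tfcr_id for t in diff.lost}
    confusion: dict[str, int] = {}
    n_label_ok = 0
    n_label_total = 0
    for i in recovered:
        cl = truth.clusters[i]
        if cl.membership == "gain":
            pred = "gain" if matched["tumor"][i].tfcr_id in gain_ids else "stable"
        elif cl.membership == "lost":
            pred = "lost" if matched["normal"][i].tfcr_id in lost_ids else "stable"
        else:
            t_stable = matched["tumor"][i].tfcr_id not in gain_ids
            n_stable = matched["normal"][i].tfcr_id not in lost_ids
            pred = "stable" if (t_stable and n_stable) else "split"
        key = f"{cl.membership}->{pred}"
        confusion[key] = confusion.get(key, 0) + 1
        n_label_total += 1
        if pred == cl.membership or (cl.membership == "shared" and pred == "stable"):
            n_label_ok += 1
    label_exact = n_label_ok / n_label_total if n_label_total else None

    return RecoveryReport(
        n_planted=n_planted,
        n_called=n_called,
        n_recovered=len(recovered),
        recall=recall,
        recall_min3_tfbs=recall_min3,
        precision=precision,
        tc_exact_rate=tc_exact,
        label_confusion=dict(sorted(confusion.items())),
        label_exact_rate=label_exact,
    )
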