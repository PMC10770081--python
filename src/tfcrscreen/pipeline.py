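"""End-to-end orchestration of the screen from one run configuration.

Stages: identify TFCRs per condition -> decile-bin per condition ->
classify gain/lost/stable -> gamma-score and screen candidate genes ->
landscape diagnostics. All stage outputs land in the configured output
directory together with ``manifest.json`` recording parameters, input
checksums and per-stage counts. Outputs contain no timestamps, so a rerun
into a clean directory is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from . import io as gio
from .core import identify_tfcrs
from .models import TfcrParams
from .screen import (
    DEFAULT_FPKM_MIN,
    DEFAULT_PROMOTER_UPSTREAM,
    classify_differential,
    gamma_score,
    screen_candidates,
)
from .stats import (
    bin_tfcrs,
    element_overlap_by_bin,
    expression_enrichment_by_bin,
    mutation_rate_by_bin,
    tc_sc_correlation_split,
)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class RunConfig:
    """Inputs and parameters of a full screening run.

    The TC cutoffs of the correlation diagnostic default to the
    per-condition breakpoints of the bladder study: 170 for tumor and 50
    for normal tissue.
    """

    tumor_tfbs: str
    normal_tfbs: str
    tumor_peaks: str
    normal_peaks: str
    genes: str
    expression: str
    out_dir: str
    elements: Optional[str] = None
    tumor_variants: Optional[str] = None
    normal_variants: Optional[str] = None
    params: TfcrParams = field(default_factory=TfcrParams)
    tc_split_tumor: float = 170.0
    tc_split_normal: float = 50.0
    fpkm_min: float = DEFAULT_FPKM_MIN
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM
    high_expr_cutoff: Optional[float] = None
    max_qvalue: Optional[float] = None
    min_overlap_frac: float = 0.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        params = TfcrParams(**raw.pop("params", {}))
        return cls(params=params, **raw)

    def input_paths(self) -> dict[str, str]:
        paths = {
            "tumor_tfbs": self.tumor_tfbs,
            "normal_tfbs": self.normal_tfbs,
            "tumor_peaks": self.tumor_peaks,
            "normal_peaks": self.normal_peaks,
            "genes": self.genes,
            "expression": self.expression,
        }
        for name in ("elements", "tumor_variants", "normal_variants"):
            value = getattr(self, name)
            if value is not None:
                paths[name] = value
        return paths


def _sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            digest.update(chunk)
    return digest.hexdigest()


def _summaries_frame(summaries) -> "list[dict]":
    return [dataclasses.asdict(s) for s in summaries]


def _write_tsv(rows: list[dict], path) -> None:
    import pandas as pd

    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _split_dict(split) -> dict:
    return {
        "threshold": split.threshold,
        "r_low": split.low.r,
        "p_low": split.low.p,
        "n_low": split.low.n,
        "low_undefined_reason": split.low.undefined_reason,
        "r_high": split.high.r,
        "p_high": split.high.p,
        "n_high": split.high.n,
        "high_undefined_reason": split.high.undefined_reason,
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full screen; returns (and writes) the run manifest."""
    missing = [p for p in config.input_paths().values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {', '.join(missing)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "tfcrscreen",
        "version": __version__,
        "parameters": {
            **{
                k: v
                for k, v in dataclasses.asdict(config).items()
                if k != "params"
            },
            "params": dataclasses.asdict(config.params),
        },
        "inputs": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in config.input_paths().items()
        },
        "stages": {},
    }

    genes = gio.read_bed_like(config.genes, "gene")
    expression = gio.read_expression_table(config.expression)
    elements = (
        gio.read_bed_like(config.elements, "element") if config.elements else None
    )
    variants = {
        "tumor": gio.read_bed_like(config.tumor_variants, "variant")
        if config.tumor_variants
        else None,
        "normal": gio.read_bed_like(config.normal_variants, "variant")
        if config.normal_variants
        else None,
    }

    tfcrs = {}
    for cond, tfbs_path, peaks_path, source in (
        ("tumor", config.tumor_tfbs, config.tumor_peaks, "ATAC"),
        ("normal", config.normal_tfbs, config.normal_peaks, "DNase"),
    ):
        tfbs = gio.read_fimo_hits(tfbs_path, max_qvalue=config.max_qvalue)
        peaks = gio.read_narrowpeak(peaks_path, source=source, condition=cond)
        called = identify_tfcrs(tfbs, peaks, config.params, cond)
        if called:
            bin_tfcrs(called)
        gio.write_tfcr_table(called, out / f"tfcrs_{cond}.tsv")
        tfcrs[cond] = called
        manifest["stages"][f"identify_{cond}"] = {
            "n_tfbs": len(tfbs),
            "n_peaks": len(peaks),
            "n_tfcrs": len(called),
        }
        logger.info("%s: %d TFBS, %d peaks -> %d TFCRs", cond, len(tfbs),
                    len(peaks), len(called))

    diff = classify_differential(
        tfcrs["tumor"], tfcrs["normal"], config.min_overlap_frac
    )
    gio.write_tfcr_table(diff.gain, out / "gain_tfcrs.tsv")
    gio.write_tfcr_table(diff.lost, out / "lost_tfcrs.tsv")
    gio.write_tfcr_table(diff.stable_tumor, out / "stable_tumor_tfcrs.tsv")
    gio.write_tfcr_table(diff.stable_normal, out / "stable_normal_tfcrs.tsv")
    manifest["stages"]["differential"] = {
        "n_gain": len(diff.gain),
        "n_lost": len(diff.lost),
        "n_stable_tumor": len(diff.stable_tumor),
        "n_stable_normal": len(diff.stable_normal),
        "tumor_nonoverlap_fraction": diff.tumor_nonoverlap_fraction,
        "normal_nonoverlap_fraction": diff.normal_nonoverlap_fraction,
    }
    logger.info(
        "differential: %d gain / %d lost / %d+%d stable (non-overlap %.1f%% tumor, %.1f%% normal)",
        len(diff.gain), len(diff.lost), len(diff.stable_tumor),
        len(diff.stable_normal), 100 * diff.tumor_nonoverlap_fraction,
        100 * diff.normal_nonoverlap_fraction,
    )

    candidates = screen_candidates(
        diff,
        genes,
        expression,
        fpkm_min=config.fpkm_min,
        promoter_upstream=config.promoter_upstream,
    )
    _write_tsv(
        [
            {
                "gene_id": c.gene_id,
                "symbol": c.symbol,
                "n_supporting_gain_tfcrs": len(c.supporting_tfcr_ids),
                "max_gamma": c.gamma,
                "fpkm": c.fpkm,
                "passes_expression_filter": c.passes_expression_filter,
                "selected": c.selected,
            }
            for c in candidates
        ],
        out / "candidates.tsv",
    )
    manifest["stages"]["screen"] = {
        "n_candidates": len(candidates),
        "n_selected": sum(1 for c in candidates if c.selected),
    }

    stats_summary: dict = {}
    stats_dir = out / "stats"
    stats_dir.mkdir(exist_ok=True)
    for cond, tc_split in (
        ("tumor", config.tc_split_tumor),
        ("normal", config.tc_split_normal),
    ):
        called = tfcrs[cond]
        if not called:
            continue
        split = tc_sc_correlation_split(called, tc_split)
        stats_summary[f"correlation_split_{cond}"] = _split_dict(split)
        expr_rows = _summaries_frame(
            expression_enrichment_by_bin(
                called, genes, expression,
                high_expr_cutoff=config.high_expr_cutoff,
                promoter_upstream=config.promoter_upstream,
            )
        )
        _write_tsv(expr_rows, stats_dir / f"expression_enrichment_{cond}.tsv")
        if elements is not None:
            _write_tsv(
                _summaries_frame(element_overlap_by_bin(called, elements)),
                stats_dir / f"element_overlap_{cond}.tsv",
            )
        if variants[cond] is not None:
            _write_tsv(
                _summaries_frame(mutation_rate_by_bin(called, variants[cond])),
                stats_dir / f"mutation_rate_{cond}.tsv",
            )
    with open(stats_dir / "summary.json", "w") as fh:
        json.dump(stats_summary, fh, indent=1, sort_keys=True)
    manifest["stages"]["stats"] = {
        "diagnostics": sorted(stats_summary.keys()),
    }

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
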