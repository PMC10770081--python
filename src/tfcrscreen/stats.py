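"""Landscape diagnostics: decile binning, the TC-SC correlation breakpoint,
and per-bin enrichment summaries (expression, regulatory elements, mutation
rate).

Binning is rank-based (equal frequency): with n TFCRs the bin of the TFCR
of rank r (1-based, ascending axis value, ties broken by genomic position)
is floor(10*(r-1)/n). Rank-based deciles keep every bin populated whatever
the shape of the TC or SC distribution, and the bin index is monotone in
the axis value. Binning is always performed within one condition at a time:
tumor TFCRs are ranked against tumor TFCRs only.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats as sps

from .models import ElementInterval, GeneModel, Tfcr, VariantRecord
from .screen import map_tfcrs_to_genes

N_BINS = 10
AXES = ("TC", "SC")


@dataclass(frozen=True, slots=True)
class BinAssignment:
    tfcr_id: str
    axis: str
    bin: int


@dataclass(slots=True)
class StratumCorrelation:
    """Pearson correlation in one TC stratum; undefined values carry a reason."""

    n: int
    r: Optional[float] = None
    p: Optional[float] = None
    undefined_reason: Optional[str] = None


@dataclass(slots=True)
class CorrelationSplit:
    """TC-SC correlation below and above a TC cutoff.

    The analysis mirrors the saturation diagnostic: accessibility grows with
    TF complexity up to a breakpoint and decouples beyond it, so r_low is
    expected positive and r_high near zero when the cutoff sits at the
    saturation point.
    """

    threshold: float
    low: StratumCorrelation
    high: StratumCorrelation

    @property
    def r_low(self) -> Optional[float]:
        return self.low.r

    @property
    def r_high(self) -> Optional[float]:
        return self.high.r


@dataclass(slots=True)
class BinSummary:
    axis: str
    bin: int
    n_tfcr: int
    metric: str
    value: float
    element_class: Optional[str] = None


def assign_decile_bins(
    tfcrs: Sequence[Tfcr], axis: str, set_attr: bool = True
) -> list[BinAssignment]:
    """Assign equal-frequency decile bins (0-9) along TC or SC.

    Ties in the axis value are broken deterministically by (chrom, summit).
    When ``set_attr`` is true the corresponding ``tc_bin``/``sc_bin`` field
    of each TFCR is updated in place.
    """
    if axis not in AXES:
        raise ValueError(f"unknown axis {axis!r}; expected 'TC' or 'SC'")
    if not tfcrs:
        raise ValueError("assign_decile_bins requires at least one TFCR")
    attr = "tc" if axis == "TC" else "sc"
    order = sorted(
        range(len(tfcrs)),
        key=lambda i: (getattr(tfcrs[i], attr), tfcrs[i].chrom, tfcrs[i].summit),
    )
    n = len(tfcrs)
    assignments: list[Optional[BinAssignment]] = [None] * n
    for rank0, i in enumerate(order):
        b = (N_BINS * rank0) // n
        assignments[i] = BinAssignment(tfcrs[i].tfcr_id, axis, b)
        if set_attr:
            setattr(tfcrs[i], "tc_bin" if axis == "TC" else "sc_bin", b)
    return assignments  # type: ignore[return-value]


def bin_tfcrs(tfcrs: Sequence[Tfcr]) -> None:
    """Assign both TC and SC decile bins in place."""
    assign_decile_bins(tfcrs, "TC")
    assign_decile_bins(tfcrs, "SC")


def _stratum(tc: np.ndarray, sc: np.ndarray) -> StratumCorrelation:
    n = len(tc)
    if n < 3:
        return StratumCorrelation(n=n, undefined_reason="fewer than 3 TFCRs")
    if np.ptp(tc) == 0 or np.ptp(sc) == 0:
        return StratumCorrelation(n=n, undefined_reason="constant values")
    r, p = sps.pearsonr(tc, sc)
    return StratumCorrelation(n=n, r=float(r), p=float(p))


def tc_sc_correlation_split(
    tfcrs: Sequence[Tfcr], threshold: float
) -> CorrelationSplit:
    """Pearson r(TC, SC) in the strata TC < threshold and TC >= threshold."""
    if not tfcrs:
        raise ValueError("tc_sc_correlation_split requires TFCRs")
    tc = np.array([t.tc for t in tfcrs], dtype=float)
    sc = np.array([t.sc for t in tfcrs], dtype=float)
    low = tc < threshold
    return CorrelationSplit(
        threshold=threshold,
        low=_stratum(tc[low], sc[low]),
        high=_stratum(tc[~low], sc[~low]),
    )


def scan_correlation_breakpoint(
    tfcrs: Sequence[Tfcr], candidates: Sequence[float]
) -> tuple[float, CorrelationSplit]:
    """Exploratory helper: the cutoff maximizing |r_low - r_high|.

    This scan is a convenience diagnostic, not part of the published
    screening procedure, which fixes the cutoffs per condition.
    """
    best: Optional[tuple[float, float, CorrelationSplit]] = None
    for thr in candidates:
        split = tc_sc_correlation_split(tfcrs, thr)
        if split.r_low is None or split.r_high is None:
            continue
        gap = abs(split.r_low - split.r_high)
        if best is None or gap > best[0]:
            best = (gap, thr, split)
    if best is None:
        raise ValueError("no candidate cutoff produced defined correlations in both strata")
    return best[1], best[2]


def _require_bins(tfcrs: Sequence[Tfcr], axis: str) -> list[int]:
    attr = "tc_bin" if axis == "TC" else "sc_bin"
    bins = [getattr(t, attr) for t in tfcrs]
    if any(b is None for b in bins):
        raise ValueError(f"{axis} bins not assigned; run assign_decile_bins first")
    return bins  # type: ignore[return-value]


def _per_bin(
    tfcrs: Sequence[Tfcr], axis: str
) -> dict[int, list[Tfcr]]:
    bins = _require_bins(tfcrs, axis)
    grouped: dict[int, list[Tfcr]] = defaultdict(list)
    for t, b in zip(tfcrs, bins):
        grouped[b].append(t)
    return grouped


def default_high_expression_cutoff(expression: dict[str, float]) -> float:
    """Top quartile of genes with FPKM > 0."""
    nonzero = [v for v in expression.values() if v > 0]
    if not nonzero:
        return float("inf")
    return float(np.quantile(nonzero, 0.75))


def expression_enrichment_by_bin(
    tfcrs: Sequence[Tfcr],
    genes: Sequence[GeneModel],
    expression: dict[str, float],
    high_expr_cutoff: Optional[float] = None,
    promoter_upstream: int = 2000,
    axes: Sequence[str] = AXES,
) -> list[BinSummary]:
    """Per bin: the proportion of TFCRs covering >= 1 highly expressed gene.

    Coverage uses the same promoter-extended rule as the gene screen. The
    default cutoff for "highly expressed" is the top quartile of
    nonzero-FPKM genes.
    """
    for axis in axes:
        _require_bins(tfcrs, axis)
    if not genes:
        warnings.warn("no genes supplied; all enrichment proportions are 0",
                      stacklevel=2)
    if high_expr_cutoff is None:
        high_expr_cutoff = default_high_expression_cutoff(expression)
    high_genes = [
        g for g in genes if expression.get(g.gene_id, 0.0) >= high_expr_cutoff
    ]
    coverage = map_tfcrs_to_genes(tfcrs, high_genes, promoter_upstream)
    out: list[BinSummary] = []
    for axis in axes:
        for b, members in sorted(_per_bin(tfcrs, axis).items()):
            covered = sum(1 for t in members if coverage.get(t.tfcr_id))
            out.append(
                BinSummary(
                    axis=axis,
                    bin=b,
                    n_tfcr=len(members),
                    metric="high_expr_proportion",
                    value=covered / len(members),
                )
            )
    return out


def element_overlap_by_bin(
    tfcrs: Sequence[Tfcr],
    elements: Sequence[ElementInterval],
    axes: Sequence[str] = AXES,
) -> list[BinSummary]:
    """Per bin and element class (plus pooled): proportion of TFCRs whose
    window overlaps >= 1 annotated element."""
    trees: dict[tuple[str, str], IntervalTree] = defaultdict(IntervalTree)
    pooled: dict[str, IntervalTree] = defaultdict(IntervalTree)
    classes = sorted({e.element_class for e in elements})
    for e in elements:
        trees[(e.chrom, e.element_class)].addi(e.start, e.end)
        pooled[e.chrom].addi(e.start, e.end)
    out: list[BinSummary] = []
    for axis in axes:
        for b, members in sorted(_per_bin(tfcrs, axis).items()):
            for cls in [*classes, "pooled"]:
                if cls == "pooled":
                    hit = sum(
                        1
                        for t in members
                        if pooled[t.chrom].overlap(t.window_start, t.window_end)
                    )
                else:
                    hit = sum(
                        1
                        for t in members
                        if trees[(t.chrom, cls)].overlap(t.window_start, t.window_end)
                    )
                out.append(
                    BinSummary(
                        axis=axis,
                        bin=b,
                        n_tfcr=len(members),
                        metric="element_proportion",
                        value=hit / len(members),
                        element_class=cls,
                    )
                )
    return out


def mutation_rate_by_bin(
    tfcrs: Sequence[Tfcr],
    variants: Sequence[VariantRecord],
    axes: Sequence[str] = AXES,
) -> list[BinSummary]:
    """Per bin: variants per kb of TFCR window.

    rate = (sum of variants falling in each window) / (sum of window
    lengths) * 1000. Windows are counted independently; overlapping windows
    are not merged, so a variant under two TFCRs counts once per TFCR. The
    rate is therefore invariant to sharding the variant list.
    """
    pos_by_chrom: dict[str, np.ndarray] = {}
    grouped: dict[str, list[int]] = defaultdict(list)
    for v in variants:
        grouped[v.chrom].append(v.pos)
    for chrom, positions in grouped.items():
        pos_by_chrom[chrom] = np.array(sorted(positions), dtype=np.int64)
    out: list[BinSummary] = []
    for axis in axes:
        for b, members in sorted(_per_bin(tfcrs, axis).items()):
            n_var = 0
            total_len = 0
            for t in members:
                total_len += t.window_length
                positions = pos_by_chrom.get(t.chrom)
                if positions is None:
                    continue
                lo = np.searchsorted(positions, t.window_start, side="left")
                hi = np.searchsorted(positions, t.window_end, side="left")
                n_var += int(hi - lo)
            rate = (n_var / total_len * 1000.0) if total_len else 0.0
            out.append(
                BinSummary(
                    axis=axis,
                    bin=b,
                    n_tfcr=len(members),
                    metric="mutation_rate_per_kb",
                    value=rate,
                )
            )
    return out
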