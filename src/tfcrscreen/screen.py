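"""Tumor-vs-normal differential classification and the candidate-gene screen.

A tumor TFCR whose window shares no base pair with any normal TFCR window
is a gain-TFCR; the symmetric normal-only case is a lost-TFCR; windows that
overlap across conditions are stable. Gain-TFCRs are scored with a
carcinogenic-potential gamma over their TC/SC decile bins, and genes
covered by gain-TFCRs in both top deciles (TC9 and SC9, i.e. gamma = 1
under the default score) pass to the expression filter (FPKM >= 5).

The gamma formula is a pluggable strategy: the default
``gamma = (tc_bin + 1) * (sc_bin + 1) / 100`` is the simplest score that is
monotone in each decile and attains its maximum of 1 exactly on TC9 & SC9,
making "gamma = 1" coincide with the top-decile selection rule.
"""
from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from intervaltree import IntervalTree

from .models import CandidateGene, GeneModel, Tfcr

DEFAULT_FPKM_MIN = 5.0
DEFAULT_PROMOTER_UPSTREAM = 2000
TOP_BIN = 9


@dataclass(slots=True)
class DifferentialSets:
    """Partition of tumor and normal TFCRs by cross-condition window overlap."""

    gain: list[Tfcr] = field(default_factory=list)
    lost: list[Tfcr] = field(default_factory=list)
    stable_tumor: list[Tfcr] = field(default_factory=list)
    stable_normal: list[Tfcr] = field(default_factory=list)

    @property
    def tumor_nonoverlap_fraction(self) -> float:
        n = len(self.gain) + len(self.stable_tumor)
        return len(self.gain) / n if n else 0.0

    @property
    def normal_nonoverlap_fraction(self) -> float:
        n = len(self.lost) + len(self.stable_normal)
        return len(self.lost) / n if n else 0.0


def _windows_tree(tfcrs: Sequence[Tfcr]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in tfcrs:
        trees[t.chrom].addi(t.window_start, t.window_end)
    return trees


def _overlaps(
    t: Tfcr, trees: dict[str, IntervalTree], min_overlap_frac: float
) -> bool:
    hits = trees[t.chrom].overlap(t.window_start, t.window_end)
    if not hits:
        return False
    if min_overlap_frac <= 0:
        return True
    need = min_overlap_frac * t.window_length
    return any(
        min(iv.end, t.window_end) - max(iv.begin, t.window_start) >= need
        for iv in hits
    )


def classify_differential(
    tumor_tfcrs: Sequence[Tfcr],
    normal_tfcrs: Sequence[Tfcr],
    min_overlap_frac: float = 0.0,
) -> DifferentialSets:
    """Partition TFCRs into gain / lost / stable by window overlap.

    Overlap means >= 1 shared base pair between half-open windows unless
    ``min_overlap_frac`` requires a minimum overlap relative to the query
    window. An empty side is valid (everything on the other side becomes
    gain or lost) but is reported with a warning.
    """
    if not tumor_tfcrs or not normal_tfcrs:
        warnings.warn(
            "one condition has no TFCRs; the differential partition is degenerate",
            stacklevel=2,
        )
    normal_trees = _windows_tree(normal_tfcrs)
    tumor_trees = _windows_tree(tumor_tfcrs)
    out = DifferentialSets()
    for t in tumor_tfcrs:
        (out.stable_tumor if _overlaps(t, normal_trees, min_overlap_frac) else out.gain).append(t)
    for t in normal_tfcrs:
        (out.stable_normal if _overlaps(t, tumor_trees, min_overlap_frac) else out.lost).append(t)
    return out


def gamma_score(tfcr: Tfcr) -> float:
    """Default carcinogenic potential: (tc_bin + 1)(sc_bin + 1) / 100."""
    if tfcr.tc_bin is None or tfcr.sc_bin is None:
        raise ValueError(
            f"TFCR {tfcr.tfcr_id} has unassigned decile bins; "
            "run assign_decile_bins before scoring"
        )
    return (tfcr.tc_bin + 1) * (tfcr.sc_bin + 1) / 100.0


def map_tfcrs_to_genes(
    tfcrs: Sequence[Tfcr],
    genes: Sequence[GeneModel],
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
) -> dict[str, set[str]]:
    """Map each TFCR to the genes it covers.

    A gene is covered when the TFCR window overlaps the gene body extended
    upstream of the TSS by ``promoter_upstream`` bp (strand-aware).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for g in genes:
        s, e = g.extended_interval(promoter_upstream)
        trees[g.chrom].addi(s, e, g.gene_id)
    return {
        t.tfcr_id: {
            iv.data for iv in trees[t.chrom].overlap(t.window_start, t.window_end)
        }
        for t in tfcrs
    }


def screen_candidates(
    diff: DifferentialSets,
    genes: Sequence[GeneModel],
    expression: dict[str, float],
    fpkm_min: float = DEFAULT_FPKM_MIN,
    promoter_upstream: int = DEFAULT_PROMOTER_UPSTREAM,
    gamma: Callable[[Tfcr], float] = gamma_score,
) -> list[CandidateGene]:
    """Screen genes covered by top-decile (TC9 & SC9) gain-TFCRs.

    The candidate list contains every gene covered by >= 1 gain-TFCR in
    both top deciles; ``selected`` additionally requires FPKM >= fpkm_min.
    Genes missing from the expression table are retained (with a warning)
    but never selected. Output is sorted by descending max supporting gamma
    then gene id, and is invariant to the input row order.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    coverage = map_tfcrs_to_genes(diff.gain, genes, promoter_upstream)
    supporting: dict[str, list[Tfcr]] = defaultdict(list)
    for t in diff.gain:
        for gene_id in coverage.get(t.tfcr_id, ()):
            supporting[gene_id].append(t)
    candidates: list[CandidateGene] = []
    for gene_id, tfcrs in supporting.items():
        if not any(t.tc_bin == TOP_BIN and t.sc_bin == TOP_BIN for t in tfcrs):
            continue
        fpkm = expression.get(gene_id)
        if fpkm is None:
            warnings.warn(
                f"gene {gene_id} covered by gain-TFCRs but absent from the "
                "expression table; it cannot pass the FPKM filter",
                stacklevel=2,
            )
        passes = fpkm is not None and fpkm >= fpkm_min
        candidates.append(
            CandidateGene(
                gene_id=gene_id,
                symbol=gene_by_id[gene_id].symbol,
                supporting_tfcr_ids=tuple(
                    sorted(t.tfcr_id for t in tfcrs)
                ),
                gamma=max(gamma(t) for t in tfcrs),
                fpkm=fpkm,
                passes_expression_filter=passes,
                selected=passes,
            )
        )
    candidates.sort(key=lambda c: (-c.gamma, c.gene_id))
    return candidates


def apply_fpkm_filter(
    gene_fpkm: dict[str, float], fpkm_min: float = DEFAULT_FPKM_MIN
) -> list[str]:
    """The false-positive filter on a precomputed candidate table.

    Given candidate genes with their FPKM values, keep those expressed at
    FPKM >= fpkm_min. This is the filtering stage that reduces an initial
    coverage-based gene list to the final candidates.
    """
    return sorted(g for g, v in gene_fpkm.items() if v >= fpkm_min)
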