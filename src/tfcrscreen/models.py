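"""Domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open (BED convention). Readers in
:mod:`tfcrscreen.io` convert from on-disk conventions (e.g. FIMO's 1-based
inclusive coordinates) at parse time, so everything downstream can assume a
single convention.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

VALID_STRANDS = {"+", "-", "."}
ELEMENT_CLASSES = {"promoter", "enhancer", "cpg_island", "other"}
CONDITIONS = {"tumor", "normal"}
PEAK_SOURCES = {"ATAC", "DNase"}


@dataclass(frozen=True, slots=True)
class TfbsRecord:
    """One motif hit: a transcription-factor binding site.

    The Gaussian kernel of the density profile is centered on
    :attr:`midpoint`, the integer floor of the interval center.
    """

    chrom: str
    start: int
    end: int
    tf_name: str
    motif_id: str = ""
    strand: str = "."
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid TFBS interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if not self.tf_name:
            raise ValueError("tf_name must be nonempty")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self):
        return (self.chrom, self.start, self.end, self.tf_name)


@dataclass(frozen=True, slots=True)
class AccessibilityPeak:
    """One open-chromatin peak (ATAC-seq or DNase-seq) with a signal score."""

    chrom: str
    start: int
    end: int
    score: float
    source: str = "ATAC"
    condition: str = "tumor"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid peak interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.score < 0:
            raise ValueError(f"negative peak score {self.score}")
        if self.source not in PEAK_SOURCES:
            raise ValueError(f"unknown peak source {self.source!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


@dataclass(frozen=True, slots=True)
class GeneModel:
    """A gene with a strand-aware TSS anchor and a body interval."""

    gene_id: str
    symbol: str
    chrom: str
    tss: int
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        anchor = self.start if self.strand == "+" else self.end - 1
        if self.tss != anchor:
            raise ValueError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"{self.strand} strand body [{self.start}, {self.end})"
            )
        if not (self.start <= self.tss < self.end):
            raise ValueError(f"gene {self.gene_id}: TSS outside gene body")

    def extended_interval(self, promoter_upstream: int) -> tuple[int, int]:
        """Gene body extended upstream of the TSS by ``promoter_upstream`` bp."""
        if self.strand == "+":
            return (max(0, self.start - promoter_upstream), self.end)
        return (self.start, self.end + promoter_upstream)


@dataclass(frozen=True, slots=True)
class VariantRecord:
    """A single-position variant (SNV-style)."""

    chrom: str
    pos: int
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"negative variant position {self.pos}")


@dataclass(frozen=True, slots=True)
class ElementInterval:
    """A regulatory-element annotation (promoter, enhancer, CpG island, ...)."""

    chrom: str
    start: int
    end: int
    element_class: str = "other"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"invalid element interval [{self.start}, {self.end})"
            )
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")


@dataclass(slots=True)
class TfcrParams:
    """Parameters of TFCR identification.

    sigma
        Width (SD, bp) of the unit-height Gaussian placed on each TFBS
        midpoint. Default 300 bp.
    grid_step
        Spacing (bp) of the density evaluation grid. Default 10 bp; summit
        coordinates are grid coordinates, so sub-grid structure (negligible
        at sigma=300) is not resolved.
    contrib_threshold
        A TFBS contributes to a TFCR when its kernel evaluated at the summit
        exceeds this intensity. Default 0.1, equivalent to a distance cutoff
        of sigma*sqrt(2*ln(1/0.1)) ~= 643.8 bp at sigma=300.
    window_pad
        Padding (bp) added to the maximum summit-to-contributor distance to
        form the TFCR window; default 150 bp (half the kernel width).
    min_summit_density
        Optional floor on the density value at a summit; default 0 keeps
        every strict local maximum.
    """

    sigma: float = 300.0
    grid_step: int = 10
    contrib_threshold: float = 0.1
    window_pad: int = 150
    min_summit_density: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.grid_step < 1:
            raise ValueError("grid_step must be >= 1")
        if not (0.0 < self.contrib_threshold < 1.0):
            raise ValueError("contrib_threshold must be in (0, 1)")
        if self.window_pad < 0:
            raise ValueError("window_pad must be >= 0")

    @property
    def contrib_radius(self) -> float:
        """Distance at which the kernel equals ``contrib_threshold``."""
        return self.sigma * math.sqrt(2.0 * math.log(1.0 / self.contrib_threshold))


@dataclass(slots=True)
class Tfcr:
    """A called TFBS-clustered region.

    tc (TF complexity) is the number of distinct TFs among the contributing
    TFBS; sc (accessibility score) is the mean signal of accessibility peaks
    overlapping the window. Decile bins (0-9) are assigned per condition by
    :func:`tfcrscreen.stats.assign_decile_bins`.
    """

    tfcr_id: str
    chrom: str
    summit: int
    window_start: int
    window_end: int
    tc: int
    sc: float
    condition: str
    contributing: tuple = ()
    n_tfbs: int = -1
    tc_bin: Optional[int] = None
    sc_bin: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_tfbs < 0:
            self.n_tfbs = len(self.contributing)
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def window_length(self) -> int:
        return self.window_end - self.window_start

    def row(self) -> tuple:
        """Serialized field tuple used by the TFCR table writer."""
        return (
            self.chrom,
            self.window_start,
            self.window_end,
            self.tfcr_id,
            self.summit,
            self.tc,
            self.sc,
            self.tc_bin,
            self.sc_bin,
            self.condition,
            self.n_tfbs,
        )


@dataclass(slots=True)
class CandidateGene:
    """A gene covered by gain-TFCRs, with its carcinogenic-potential score."""

    gene_id: str
    symbol: str
    supporting_tfcr_ids: tuple
    gamma: float
    fpkm: Optional[float]
    passes_expression_filter: bool
    selected: bool


def sorted_tfbs(records: Sequence[TfbsRecord]) -> list[TfbsRecord]:
    return sorted(records, key=TfbsRecord.sort_key)
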