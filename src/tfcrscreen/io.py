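"""Readers and writers for the on-disk formats the screen touches.

Supported inputs: FIMO motif-scan TSV (TFBS), ENCODE narrowPeak / BED5
(accessibility peaks), BED6 gene tables, BED3 or minimal VCF variant lists,
BED4 regulatory-element annotations, and two-column gene-expression TSVs.
Everything is normalized to 0-based half-open coordinates at read time.

The TFCR table written by :func:`write_tfcr_table` is a tab-separated
BED-like file with a ``#``-prefixed header; :func:`read_tfcr_table` is its
lossless inverse on the serialized fields.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .models import (
    AccessibilityPeak,
    ElementInterval,
    GeneModel,
    Tfcr,
    TfbsRecord,
    VariantRecord,
    sorted_tfbs,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Raised for malformed rows; carries the file path and line number."""

    def __init__(self, path: PathLike, lineno: int, message: str):
        super().__init__(f"{path}:{lineno}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _data_lines(path: PathLike):
    """Yield (lineno, stripped line) skipping blanks and '#' comments."""
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def _parse_int(path: PathLike, lineno: int, token: str, what: str) -> int:
    try:
        return int(token)
    except ValueError:
        raise ParseError(path, lineno, f"non-integer {what}: {token!r}") from None


def _parse_float(path: PathLike, lineno: int, token: str, what: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise ParseError(path, lineno, f"non-numeric {what}: {token!r}") from None


# ---------------------------------------------------------------------------
# FIMO


FIMO_COLUMNS = (
    "motif_id",
    "motif_alt_id",
    "sequence_name",
    "start",
    "stop",
    "strand",
    "score",
    "p-value",
    "q-value",
    "matched_sequence",
)


def read_fimo_hits(
    path: PathLike, max_qvalue: Optional[float] = None
) -> list[TfbsRecord]:
    """Read a FIMO TSV into TFBS records.

    FIMO coordinates are 1-based inclusive; they are converted to 0-based
    half-open here, which preserves interval length: (stop - start + 1) in
    the file equals (end - start) internally. ``tf_name`` is taken from
    ``motif_alt_id`` when present, else ``motif_id``. The optional
    ``max_qvalue`` filter drops weaker hits; by default every hit in the
    file is ingested.
    """
    records: list[TfbsRecord] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if fields[0] == "motif_id":  # header line
            continue
        if len(fields) < 6:
            raise ParseError(path, lineno, f"expected >= 6 columns, got {len(fields)}")
        motif_id, motif_alt_id, chrom = fields[0], fields[1], fields[2]
        start1 = _parse_int(path, lineno, fields[3], "start")
        stop1 = _parse_int(path, lineno, fields[4], "stop")
        if stop1 < start1:
            raise ParseError(path, lineno, f"stop {stop1} < start {start1}")
        if start1 < 1:
            raise ParseError(path, lineno, f"FIMO start must be >= 1, got {start1}")
        strand = fields[5] if fields[5] in {"+", "-"} else "."
        score = (
            _parse_float(path, lineno, fields[6], "score")
            if len(fields) > 6 and fields[6] not in ("", ".")
            else None
        )
        if max_qvalue is not None and len(fields) > 8 and fields[8] not in ("", "."):
            qvalue = _parse_float(path, lineno, fields[8], "q-value")
            if qvalue > max_qvalue:
                continue
        records.append(
            TfbsRecord(
                chrom=chrom,
                start=start1 - 1,
                end=stop1,
                tf_name=motif_alt_id or motif_id,
                motif_id=motif_id,
                strand=strand,
                score=score,
            )
        )
    return sorted_tfbs(records)


def write_fimo_hits(records: Sequence[TfbsRecord], path: PathLike) -> None:
    """Write TFBS records as a FIMO-style TSV (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("\t".join(FIMO_COLUMNS) + "\n")
        for r in sorted_tfbs(records):
            score = "" if r.score is None else f"{r.score:g}"
            fh.write(
                f"{r.motif_id or r.tf_name}\t{r.tf_name}\t{r.chrom}\t"
                f"{r.start + 1}\t{r.end}\t{r.strand}\t{score}\t\t\t\n"
            )


# ---------------------------------------------------------------------------
# Accessibility peaks


def read_narrowpeak(
    path: PathLike,
    source: str = "ATAC",
    condition: str = "tumor",
    score_column: Optional[int] = None,
) -> list[AccessibilityPeak]:
    """Read ENCODE narrowPeak (BED6+4) or BED5 accessibility peaks.

    For narrowPeak rows the score is the continuous ``signalValue``
    (column 7), not the capped BED score; for BED5 rows it is column 5.
    ``score_column`` (1-based) overrides the default choice.
    """
    peaks: list[AccessibilityPeak] = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 5:
            raise ParseError(path, lineno, f"expected >= 5 columns, got {len(fields)}")
        chrom = fields[0]
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        if end <= start:
            raise ParseError(path, lineno, f"end {end} <= start {start}")
        if score_column is not None:
            col = score_column - 1
        elif len(fields) >= 10:
            col = 6  # narrowPeak signalValue
        else:
            col = 4  # BED5 score
        if col >= len(fields):
            raise ParseError(path, lineno, f"score column {col + 1} missing")
        score = _parse_float(path, lineno, fields[col], "score")
        if score < 0:
            raise ParseError(path, lineno, f"negative score {score}")
        peaks.append(
            AccessibilityPeak(
                chrom=chrom,
                start=start,
                end=end,
                score=score,
                source=source,
                condition=condition,
            )
        )
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end))
    return peaks


def write_narrowpeak(peaks: Sequence[AccessibilityPeak], path: PathLike) -> None:
    """Write peaks in ENCODE narrowPeak format (score in signalValue)."""
    with open(path, "w") as fh:
        for i, p in enumerate(sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))):
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\tpeak{i + 1}\t0\t.\t"
                f"{p.score!r}\t-1\t-1\t{(p.end - p.start) // 2}\n"
            )


# ---------------------------------------------------------------------------
# BED-like gene / variant / element tables


def read_bed_like(
    path: PathLike, kind: str
) -> list:
    """Read a BED-like table of the given ``kind``.

    kind='gene'
        BED6 (chrom, start, end, name, score, strand); the TSS is the start
        for + strand genes and end-1 for - strand genes. Missing strand is
        an error.
    kind='variant'
        BED3+ (or minimal VCF, detected by a ``##fileformat=VCF`` first
        line); a variant is the interval start position.
    kind='element'
        BED4 with the element class in column 4; unknown classes are kept
        with a warning as class 'other'.
    """
    if kind == "variant" and _is_vcf(path):
        return _read_vcf_positions(path)
    out: list = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(path, lineno, f"expected >= 3 columns, got {len(fields)}")
        chrom = fields[0]
        start = _parse_int(path, lineno, fields[1], "start")
        end = _parse_int(path, lineno, fields[2], "end")
        if kind == "gene":
            if len(fields) < 6:
                raise ParseError(path, lineno, "gene rows need name and strand (BED6)")
            name, strand = fields[3], fields[5]
            if strand not in {"+", "-"}:
                raise ParseError(path, lineno, f"missing/invalid gene strand {strand!r}")
            tss = start if strand == "+" else end - 1
            out.append(
                GeneModel(
                    gene_id=name,
                    symbol=fields[6] if len(fields) > 6 else name,
                    chrom=chrom,
                    tss=tss,
                    start=start,
                    end=end,
                    strand=strand,
                )
            )
        elif kind == "variant":
            vid = fields[3] if len(fields) > 3 else None
            out.append(VariantRecord(chrom=chrom, pos=start, id=vid))
        elif kind == "element":
            if len(fields) < 4:
                raise ParseError(path, lineno, "element rows need a class in column 4")
            cls = fields[3].lower()
            if cls not in {"promoter", "enhancer", "cpg_island", "other"}:
                warnings.warn(
                    f"{path}:{lineno}: unknown element class {fields[3]!r}, "
                    "recorded as 'other'",
                    stacklevel=2,
                )
                cls = "other"
            out.append(ElementInterval(chrom=chrom, start=start, end=end, element_class=cls))
        else:
            raise ValueError(f"unknown kind {kind!r}")
    out.sort(key=lambda r: (r.chrom, getattr(r, "start", getattr(r, "pos", 0))))
    return out


def _is_vcf(path: PathLike) -> bool:
    with open(path) as fh:
        first = fh.readline()
    return first.startswith("##fileformat=VCF")


def _read_vcf_positions(path: PathLike) -> list[VariantRecord]:
    """Minimal VCF reader: CHROM/POS only, converted to 0-based."""
    out: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(path, lineno, "VCF row needs CHROM and POS")
            pos1 = _parse_int(path, lineno, fields[1], "POS")
            if pos1 < 1:
                raise ParseError(path, lineno, f"VCF POS must be >= 1, got {pos1}")
            vid = fields[2] if len(fields) > 2 and fields[2] != "." else None
            out.append(VariantRecord(chrom=fields[0], pos=pos1 - 1, id=vid))
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


# ---------------------------------------------------------------------------
# Expression


def read_expression_table(path: PathLike) -> dict[str, float]:
    """Read a two-column (gene_id, FPKM) TSV into a mapping.

    An optional single header line is tolerated. Duplicate gene ids and
    negative FPKM values are errors.
    """
    table: dict[str, float] = {}
    first_data = True
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(path, lineno, "expected two tab-separated columns")
        gene_id, value = fields[0], fields[1]
        if first_data:
            first_data = False
            try:
                float(value)
            except ValueError:
                continue  # header line
        fpkm = _parse_float(path, lineno, value, "FPKM")
        if fpkm < 0:
            raise ParseError(path, lineno, f"negative FPKM {fpkm} for {gene_id}")
        if gene_id in table:
            raise ParseError(path, lineno, f"duplicate gene_id {gene_id!r}")
        table[gene_id] = fpkm
    return table


def write_expression_table(expression: dict[str, float], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tfpkm\n")
        for gene_id in sorted(expression):
            fh.write(f"{gene_id}\t{expression[gene_id]!r}\n")


# ---------------------------------------------------------------------------
# TFCR tables

TFCR_HEADER = (
    "#chrom\twindow_start\twindow_end\ttfcr_id\tsummit\ttc\tsc\t"
    "tc_bin\tsc_bin\tcondition\tn_tfbs"
)


def write_tfcr_table(tfcrs: Sequence[Tfcr], path: PathLike) -> None:
    """Write scored TFCRs as a BED-like TSV; unassigned bins become 'NA'.

    Floats are written with ``repr`` so the paired reader round-trips the
    record set exactly.
    """
    with open(path, "w") as fh:
        fh.write(TFCR_HEADER + "\n")
        for t in tfcrs:
            (chrom, ws, we, tid, summit, tc, sc, tcb, scb, cond, n) = t.row()
            tcb_s = "NA" if tcb is None else str(tcb)
            scb_s = "NA" if scb is None else str(scb)
            fh.write(
                f"{chrom}\t{ws}\t{we}\t{tid}\t{summit}\t{tc}\t{sc!r}\t"
                f"{tcb_s}\t{scb_s}\t{cond}\t{n}\n"
            )


def read_tfcr_table(path: PathLike) -> list[Tfcr]:
    """Read a TFCR table written by :func:`write_tfcr_table`.

    Contributing TFBS are not serialized; records come back with an empty
    ``contributing`` tuple and the stored ``n_tfbs`` count.
    """
    tfcrs: list[Tfcr] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) != 11:
            raise ParseError(path, lineno, f"expected 11 columns, got {len(fields)}")
        tfcrs.append(
            Tfcr(
                tfcr_id=fields[3],
                chrom=fields[0],
                summit=_parse_int(path, lineno, fields[4], "summit"),
                window_start=_parse_int(path, lineno, fields[1], "window_start"),
                window_end=_parse_int(path, lineno, fields[2], "window_end"),
                tc=_parse_int(path, lineno, fields[5], "tc"),
                sc=_parse_float(path, lineno, fields[6], "sc"),
                condition=fields[9],
                n_tfbs=_parse_int(path, lineno, fields[10], "n_tfbs"),
                tc_bin=None if fields[7] == "NA" else _parse_int(path, lineno, fields[7], "tc_bin"),
                sc_bin=None if fields[8] == "NA" else _parse_int(path, lineno, fields[8], "sc_bin"),
            )
        )
    return tfcrs


def write_bed(intervals: Iterable[tuple], path: PathLike) -> None:
    """Write raw (chrom, start, end, *extra) tuples as BED."""
    with open(path, "w") as fh:
        for row in intervals:
            fh.write("\t".join(str(x) for x in row) + "\n")
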