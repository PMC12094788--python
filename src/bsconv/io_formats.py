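"""Readers and writers for the file formats the framework touches.

Bismark-style per-cytosine reports (7-column TSV), SAM records carrying
Bismark methylation-call tags (XM/XR/XG), FASTA genomes, and the package's
own tabular outputs.

Coordinate conventions: cytosine reports are 1-based (Bismark convention);
all internal window arithmetic is 0-based half-open. Conversion happens only
at the read/write boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam
from Bio import SeqIO

CONTEXTS = ("CG", "CHG", "CHH")

#: XM-tag call characters: upper case = unconverted (read as methylated),
#: lower case = converted. Z/z CpG, X/x CHG, H/h CHH, U/u unknown context.
_XM_CONTEXT = {
    "Z": "CG", "z": "CG",
    "X": "CHG", "x": "CHG",
    "H": "CHH", "h": "CHH",
    "U": "unknown", "u": "unknown",
}

#: Bismark convention: (XG genome conversion, XR read conversion) -> strand class.
STRAND_CLASSES = ("OT", "OB", "CTOT", "CTOB")
_STRAND_FROM_TAGS = {
    ("CT", "CT"): "OT",
    ("CT", "GA"): "CTOT",
    ("GA", "CT"): "OB",
    ("GA", "GA"): "CTOB",
}


@dataclass(frozen=True)
class CytosineSiteRecord:
    """One genomic cytosine with unconverted/converted read counts.

    ``meth_count`` counts reads observed as (unconverted) cytosine,
    ``unmeth_count`` reads observed as (converted) thymine. ``pos`` is
    1-based, matching the Bismark cytosine-report convention.
    """

    chrom: str
    pos: int
    strand: str
    meth_count: int
    unmeth_count: int
    context: str
    trinucleotide: str = "NNN"

    @property
    def coverage(self) -> int:
        return self.meth_count + self.unmeth_count


@dataclass(frozen=True)
class MethylationCall:
    """A single cytosine call within a read."""

    read_offset: int
    context: str
    unconverted: bool


@dataclass(frozen=True)
class ReadCalls:
    """Per-read methylation-call vector with bisulphite strand class.

    ``strand_class`` is one of OT (original top), OB (original bottom),
    CTOT/CTOB (their PCR complements). ``calls`` holds one entry per
    cytosine in the read, ordered by strictly increasing read offset.
    """

    read_id: str
    strand_class: str
    calls: tuple[MethylationCall, ...]

    def __post_init__(self) -> None:
        offsets = [c.read_offset for c in self.calls]
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("read offsets must be strictly increasing")
        if self.strand_class not in STRAND_CLASSES:
            raise ValueError(f"unknown strand class {self.strand_class!r}")

    @property
    def n_calls(self) -> int:
        return len(self.calls)

    @property
    def n_unconverted(self) -> int:
        return sum(c.unconverted for c in self.calls)

    @property
    def unconverted_fraction(self) -> float:
        if not self.calls:
            raise ValueError("read has no cytosine calls")
        return self.n_unconverted / self.n_calls


@dataclass(frozen=True)
class GenomeSequence:
    """A named chromosome sequence, uppercase-normalised."""

    chrom: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        object.__setattr__(self, "sequence", self.sequence.upper())


class ReportFormatError(ValueError):
    """A malformed line in a cytosine report; names the offending line."""


def _parse_report_line(line: str, lineno: int) -> CytosineSiteRecord:
    fields = line.rstrip("\n").split("\t")
    if len(fields) != 7:
        raise ReportFormatError(
            f"line {lineno}: expected 7 tab-separated columns, got {len(fields)}"
        )
    chrom, pos_s, strand, meth_s, unmeth_s, context, trinuc = fields
    try:
        pos = int(pos_s)
        meth = int(meth_s)
        unmeth = int(unmeth_s)
    except ValueError as exc:
        raise ReportFormatError(f"line {lineno}: non-integer field ({exc})") from exc
    if meth < 0 or unmeth < 0:
        raise ReportFormatError(f"line {lineno}: negative count")
    if pos < 1:
        raise ReportFormatError(f"line {lineno}: position must be >= 1")
    if strand not in ("+", "-"):
        raise ReportFormatError(f"line {lineno}: strand must be + or -")
    if context not in CONTEXTS:
        raise ReportFormatError(
            f"line {lineno}: context {context!r} not in {CONTEXTS}"
        )
    return CytosineSiteRecord(
        chrom=chrom,
        pos=pos,
        strand=strand,
        meth_count=meth,
        unmeth_count=unmeth,
        context=context,
        trinucleotide=trinuc,
    )


def read_cytosine_report(
    path: str | Path,
    region: Optional[tuple[str, int, int]] = None,
) -> Iterator[CytosineSiteRecord]:
    """Stream records from a Bismark-style cytosine report.

    Parameters
    ----------
    path
        Tab-separated file with columns chrom, position (1-based), strand,
        count-methylated, count-unmethylated, context, trinucleotide.
    region
        Optional ``(chrom, start, end)``; only records on ``chrom`` with
        ``start < pos <= end`` (half-open on 1-based positions) are yielded.

    Yields records in file order. Malformed lines raise
    :class:`ReportFormatError` naming the line number.
    """
    path = Path(path)
    with path.open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            rec = _parse_report_line(line, lineno)
            if region is not None:
                chrom, start, end = region
                if rec.chrom != chrom or not (start < rec.pos <= end):
                    continue
            yield rec


def write_cytosine_report(
    records: Iterable[CytosineSiteRecord], path: str | Path
) -> None:
    """Write records as a 7-column Bismark-style cytosine report."""
    with Path(path).open("w") as handle:
        for rec in records:
            handle.write(
                f"{rec.chrom}\t{rec.pos}\t{rec.strand}\t{rec.meth_count}\t"
                f"{rec.unmeth_count}\t{rec.context}\t{rec.trinucleotide}\n"
            )


def parse_methylation_tags(record: pysam.AlignedSegment) -> ReadCalls:
    """Extract per-read methylation calls from Bismark XM/XR/XG tags.

    One call is produced per non-``.`` character of the XM string; an upper
    case character means the base was read as cytosine (unconverted). The
    strand class follows the Bismark convention on (XG, XR):
    (CT,CT)->OT, (CT,GA)->CTOT, (GA,CT)->OB, (GA,GA)->CTOB.
    """
    for tag in ("XM", "XR", "XG"):
        if not record.has_tag(tag):
            raise ValueError(f"record {record.query_name!r} lacks tag {tag}")
    xm = record.get_tag("XM")
    xr = record.get_tag("XR")
    xg = record.get_tag("XG")
    seq_len = record.query_length or len(record.query_sequence or "")
    if seq_len and len(xm) != seq_len:
        raise ValueError(
            f"record {record.query_name!r}: XM length {len(xm)} != read length {seq_len}"
        )
    key = (str(xg), str(xr))
    if key not in _STRAND_FROM_TAGS:
        raise ValueError(f"unrecognised XG/XR pair {key!r}")
    calls = []
    for offset, char in enumerate(xm):
        if char == ".":
            continue
        if char not in _XM_CONTEXT:
            raise ValueError(f"unrecognised XM character {char!r} at offset {offset}")
        calls.append(
            MethylationCall(
                read_offset=offset,
                context=_XM_CONTEXT[char],
                unconverted=char.isupper(),
            )
        )
    return ReadCalls(
        read_id=record.query_name or "",
        strand_class=_STRAND_FROM_TAGS[key],
        calls=tuple(calls),
    )


def read_tagged_sam(path: str | Path) -> Iterator[ReadCalls]:
    """Stream :class:`ReadCalls` from a SAM file with Bismark tags.

    Unmapped records (FLAG 0x4) are skipped; no index is required.
    """
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for record in sam:
            if record.is_unmapped:
                continue
            yield parse_methylation_tags(record)


def read_fasta(path: str | Path) -> dict[str, GenomeSequence]:
    """Load a FASTA file into named, uppercase-normalised sequences."""
    return {
        rec.id: GenomeSequence(chrom=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def gc_fraction(sequence: str, start: int, end: int) -> float:
    """G+C fraction of ``sequence[start:end]`` (0-based half-open).

    N bases are excluded from numerator and denominator; an all-N slice
    returns NaN. An empty slice is an error.
    """
    if not (0 <= start < end <= len(sequence)):
        raise ValueError(f"invalid slice [{start}, {end}) for length {len(sequence)}")
    window = sequence[start:end].upper()
    acgt = sum(window.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (window.count("G") + window.count("C")) / acgt


# ---------------------------------------------------------------------------
# Tabular output schemas

TABLE_SCHEMAS: dict[str, tuple[str, ...]] = {
    "windows": (
        "chrom", "start", "end", "y", "n", "rate", "mean_coverage", "gc",
        "n_cg", "n_chg", "n_chh",
    ),
    "read_categories": ("category", "count"),
    "positional_profile": ("strand_class", "offset", "unconverted", "total"),
    "state_calls": (
        "locus_id", "n_cg", "n_chg", "n_chh", "p_cg", "p_chg", "p_chh",
        "loglik_um", "loglik_gbm", "loglik_tem",
        "post_um", "post_gbm", "post_tem", "call",
    ),
    "estimates": ("locus_id", "y", "n", "raw_p", "theta_hat", "clamped"),
    "simulation_estimates": (
        "rep", "coverage", "n_loci", "scenario", "estimate",
    ),
    "simulation_summary": (
        "coverage", "n_loci", "scenario", "mean_deviation", "rms_deviation", "bias",
    ),
}


def write_table(rows: Sequence[dict], path: str | Path, schema: str) -> None:
    """Write homogeneous rows as a TSV with the named schema's column order.

    Every row must carry exactly the schema's keys; an empty row list
    produces a header-only file. The output round-trips through
    :func:`read_table`.
    """
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; known: {sorted(TABLE_SCHEMAS)}")
    columns = TABLE_SCHEMAS[schema]
    for i, row in enumerate(rows):
        if set(row) != set(columns):
            raise ValueError(
                f"row {i} keys {sorted(row)} do not match schema {schema!r} "
                f"columns {sorted(columns)}"
            )
    frame = pd.DataFrame(list(rows), columns=list(columns))
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, validating the header."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    frame = pd.read_csv(path, sep="\t")
    expected = list(TABLE_SCHEMAS[schema])
    if list(frame.columns) != expected:
        raise ReportFormatError(
            f"{path}: header {list(frame.columns)} does not match schema "
            f"{schema!r} ({expected})"
        )
    return frame


def read_bed_loci(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read BED3(+name) locus annotations; coordinates stay 0-based half-open."""
    loci = []
    with Path(path).open() as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ReportFormatError(f"line {lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            if start < 0 or end <= start:
                raise ReportFormatError(f"line {lineno}: invalid interval")
            loci.append((chrom, start, end, name))
    return loci


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse a 1-based inclusive ``chrom:start-end`` string to 0-based half-open."""
    try:
        chrom, span = region.rsplit(":", 1)
        start_s, end_s = span.split("-")
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"cannot parse region {region!r} (chrom:start-end)") from exc
    if start < 1 or end < start:
        raise ValueError(f"invalid region bounds in {region!r}")
    return chrom, start - 1, end
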