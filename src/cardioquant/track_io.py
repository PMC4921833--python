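"""Genomic track and interval I/O.

Reads and writes the text formats the Pol II scoring engine consumes:
WIG (fixedStep / variableStep), bedGraph, BED3/BED6/narrowPeak peak calls,
and a BED-like tab-separated gene table.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  WIG is 1-based on disk and is
converted on read/write; bedGraph and BED are already 0-based half-open and
pass through unchanged.  Chromosome names are matched by exact string
comparison — no ``chr`` aliasing is performed (use
:func:`check_chrom_compatibility` to diagnose name-set mismatches).

Binned coverage is held in :class:`BinnedTrack`: one float array per
chromosome, one value per ``bin_width`` bp, starting at position 0.
Positions beyond the stored array are implicitly zero, so sparse files
(zero bins omitted, as MACS writes them) round-trip losslessly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = frozenset({"+", "-", "."})


class TrackParseError(ValueError):
    """Malformed track/table file; message names the offending line."""


class TrackValidationError(ValueError):
    """Structurally parseable input that violates a contract (negative
    value, overlapping intervals, bad strand, ...)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic span, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise TrackValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise TrackValidationError(
                f"invalid strand {self.strand!r} (must be one of +, -, .)"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene body: the stranded span from transcription start site (TSS)
    to transcript end (TES).

    For a '+' gene tss == interval.start and tes == interval.end; for a
    '-' gene the roles swap.  The body must be at least 10 bp so that each
    of the 10 body blocks spans >= 1 bp.
    """

    interval: GenomicInterval
    name: str

    MIN_BODY_BP = 10

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise TrackValidationError(
                f"gene {self.name!r}: strand must be + or -, "
                f"got {self.interval.strand!r}"
            )
        if len(self.interval) < self.MIN_BODY_BP:
            raise TrackValidationError(
                f"gene {self.name!r}: body is {len(self.interval)} bp, "
                f"minimum is {self.MIN_BODY_BP} bp"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tes(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def body_length(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class PeakCall:
    """One peak call (e.g. a MACS peak); consumed, never produced, here."""

    interval: GenomicInterval
    name: Optional[str] = None
    score: Optional[float] = None


@dataclass
class BinnedTrack:
    """Fixed-width binned coverage, one array per chromosome.

    ``values[chrom][i]`` covers genomic span ``[i*bin_width, (i+1)*bin_width)``.
    ``total_mapped_reads`` is the library depth used for per-million
    normalization; it cannot be inferred from a WIG file and may be None
    until supplied.  ``normalized`` flags whether values are depth-normalized
    densities (per million mapped reads per bp) rather than raw per-bin reads.
    """

    bin_width: int = 10
    values: Dict[str, np.ndarray] = field(default_factory=dict)
    total_mapped_reads: Optional[int] = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.bin_width < 1:
            raise TrackValidationError(f"bin_width must be >= 1, got {self.bin_width}")
        if self.total_mapped_reads is not None and self.total_mapped_reads < 1:
            raise TrackValidationError(
                f"total_mapped_reads must be >= 1, got {self.total_mapped_reads}"
            )
        for chrom, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim != 1:
                raise TrackValidationError(f"{chrom}: bin values must be 1-D")
            if np.any(~np.isfinite(arr)) or np.any(arr < 0):
                raise TrackValidationError(
                    f"{chrom}: bin values must be finite and non-negative"
                )
            self.values[chrom] = arr

    @property
    def chroms(self) -> List[str]:
        return sorted(self.values)

    def bin_values(self, chrom: str) -> np.ndarray:
        if chrom not in self.values:
            raise KeyError(f"chromosome {chrom!r} not in track")
        return self.values[chrom]

    def interval_integral(self, chrom: str, start: int, end: int) -> float:
        """Integral of the per-bp value over ``[start, end)``.

        For a normalized track this is integrated density; for a raw track
        each bin's reads are spread uniformly over the bin (value/bin_width
        per bp).  Bins absent from the array count as zero.  ``start`` may
        not be negative; callers clip first.
        """
        if start < 0:
            raise ValueError(f"negative start {start}; clip before integrating")
        if end <= start:
            return 0.0
        arr = self.values.get(chrom)
        if arr is None or arr.size == 0:
            return 0.0
        w = self.bin_width
        end = min(end, arr.size * w)
        if end <= start:
            return 0.0
        first_bin, last_bin = start // w, (end - 1) // w
        per_bp = arr[first_bin : last_bin + 1]
        if not self.normalized:
            per_bp = per_bp / w
        if first_bin == last_bin:
            return float(per_bp[0] * (end - start))
        total = float(np.sum(per_bp[1:-1])) * w
        total += float(per_bp[0]) * ((first_bin + 1) * w - start)
        total += float(per_bp[-1]) * (end - last_bin * w)
        return total

    def total_signal(self) -> float:
        """Sum of all bin values across chromosomes."""
        return float(sum(a.sum() for a in self.values.values()))

    def allclose(self, other: "BinnedTrack", rtol: float = 1e-9) -> bool:
        if self.bin_width != other.bin_width:
            return False
        chroms = set(self.values) | set(other.values)
        for c in chroms:
            a = self.values.get(c, np.zeros(0))
            b = other.values.get(c, np.zeros(0))
            n = max(a.size, b.size)
            a = np.pad(a, (0, n - a.size))
            b = np.pad(b, (0, n - b.size))
            if not np.allclose(a, b, rtol=rtol, atol=0.0):
                return False
        return True


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def _open_lines(path) -> Iterator[tuple]:
    with open(path, "r", encoding="utf-8", newline=None) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            yield lineno, line


def _parse_kv(fields: Sequence[str], lineno: int, path) -> Dict[str, str]:
    out = {}
    for f in fields:
        if "=" not in f:
            raise TrackParseError(
                f"{path}:{lineno}: malformed header token {f!r} (expected key=value)"
            )
        k, v = f.split("=", 1)
        out[k] = v
    return out


def _value_or_raise(token: str, lineno: int, path) -> float:
    try:
        v = float(token)
    except ValueError:
        raise TrackParseError(f"{path}:{lineno}: non-numeric value {token!r}") from None
    if math.isnan(v):
        raise TrackValidationError(f"{path}:{lineno}: NaN value")
    if v < 0:
        raise TrackValidationError(f"{path}:{lineno}: negative value {v}")
    return v


class _TrackBuilder:
    """Accumulates (chrom, start_bp, value) records into bin arrays."""

    def __init__(self, bin_width: int):
        self.bin_width = bin_width
        self.bins: Dict[str, Dict[int, float]] = {}

    def add(self, chrom: str, start: int, value: float, lineno: int, path) -> None:
        if start % self.bin_width != 0:
            raise TrackParseError(
                f"{path}:{lineno}: position {start} is not aligned to "
                f"bin width {self.bin_width}"
            )
        d = self.bins.setdefault(chrom, {})
        idx = start // self.bin_width
        if idx in d:
            raise TrackValidationError(
                f"{path}:{lineno}: duplicate coverage for {chrom} bin at {start}"
            )
        d[idx] = value

    def build(self, **kwargs) -> BinnedTrack:
        values = {}
        for chrom, d in self.bins.items():
            arr = np.zeros(max(d) + 1 if d else 0, dtype=float)
            for idx, v in d.items():
                arr[idx] = v
            values[chrom] = arr
        return BinnedTrack(bin_width=self.bin_width, values=values, **kwargs)


def read_wig(
    path,
    total_mapped_reads: Optional[int] = None,
    normalized: bool = False,
) -> BinnedTrack:
    """Read a fixedStep or variableStep WIG file into a :class:`BinnedTrack`.

    WIG positions are 1-based on disk; internally a record at 1-based
    position ``p`` becomes a bin starting at ``p - 1``.  Every declaration
    in one file must use the same step/span (one bin width per file).
    Positions absent from the file are zero.  ``total_mapped_reads`` is the
    library depth (WIG does not carry it); leave None if unknown.
    """
    path = Path(path)
    builder: Optional[_TrackBuilder] = None
    mode = None  # ("fixed", chrom, next_start, step) or ("variable", chrom, span)
    saw_data = False

    for lineno, line in _open_lines(path):
        fields = line.split()
        head = fields[0]
        if head == "fixedStep":
            kv = _parse_kv(fields[1:], lineno, path)
            try:
                chrom = kv["chrom"]
                start1 = int(kv["start"])
                step = int(kv["step"])
            except KeyError as e:
                raise TrackParseError(
                    f"{path}:{lineno}: fixedStep header missing {e.args[0]!r}"
                ) from None
            except ValueError:
                raise TrackParseError(
                    f"{path}:{lineno}: non-integer field in fixedStep header"
                ) from None
            span = int(kv.get("span", step))
            if span != step:
                raise TrackParseError(
                    f"{path}:{lineno}: span {span} != step {step}; only "
                    "contiguous non-overlapping bins are supported"
                )
            if builder is None:
                builder = _TrackBuilder(step)
            elif builder.bin_width != step:
                raise TrackParseError(
                    f"{path}:{lineno}: step {step} differs from earlier "
                    f"step {builder.bin_width}; mixed bin widths are unsupported"
                )
            if start1 < 1:
                raise TrackParseError(
                    f"{path}:{lineno}: WIG start must be >= 1 (1-based), got {start1}"
                )
            mode = ["fixed", chrom, start1 - 1, step]
        elif head == "variableStep":
            kv = _parse_kv(fields[1:], lineno, path)
            if "chrom" not in kv:
                raise TrackParseError(
                    f"{path}:{lineno}: variableStep header missing 'chrom'"
                )
            span = int(kv.get("span", 1))
            if builder is None:
                builder = _TrackBuilder(span)
            elif builder.bin_width != span:
                raise TrackParseError(
                    f"{path}:{lineno}: span {span} differs from earlier "
                    f"span {builder.bin_width}; mixed bin widths are unsupported"
                )
            mode = ["variable", kv["chrom"], span]
        elif mode is None:
            raise TrackParseError(
                f"{path}:{lineno}: data line before any fixedStep/variableStep header"
            )
        elif mode[0] == "fixed":
            if len(fields) != 1:
                raise TrackParseError(
                    f"{path}:{lineno}: fixedStep data line must hold one value"
                )
            v = _value_or_raise(fields[0], lineno, path)
            _, chrom, next_start, step = mode
            builder.add(chrom, next_start, v, lineno, path)
            mode[2] = next_start + step
            saw_data = True
        else:  # variable
            if len(fields) != 2:
                raise TrackParseError(
                    f"{path}:{lineno}: variableStep data line must be "
                    "'position value'"
                )
            try:
                pos1 = int(fields[0])
            except ValueError:
                raise TrackParseError(
                    f"{path}:{lineno}: non-integer position {fields[0]!r}"
                ) from None
            if pos1 < 1:
                raise TrackParseError(
                    f"{path}:{lineno}: WIG position must be >= 1, got {pos1}"
                )
            v = _value_or_raise(fields[1], lineno, path)
            builder.add(mode[1], pos1 - 1, v, lineno, path)
            saw_data = True

    if builder is None:
        raise TrackParseError(f"{path}: no fixedStep/variableStep declaration found")
    if not saw_data:
        logger.warning("%s: no data lines; returning all-zero track", path)
    return builder.build(total_mapped_reads=total_mapped_reads, normalized=normalized)


def read_bedgraph(
    path,
    bin_width: Optional[int] = None,
    total_mapped_reads: Optional[int] = None,
    normalized: bool = False,
) -> BinnedTrack:
    """Read a 4-column bedGraph (0-based half-open) into a BinnedTrack.

    Intervals must be non-overlapping and each must align to and span a
    whole number of bins.  When ``bin_width`` is None it is inferred as the
    GCD of all interval starts and lengths.
    """
    path = Path(path)
    records = []
    for lineno, line in _open_lines(path):
        fields = line.split()
        if len(fields) < 4:
            raise TrackParseError(
                f"{path}:{lineno}: bedGraph needs 4 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise TrackParseError(
                f"{path}:{lineno}: non-integer coordinates"
            ) from None
        if start < 0 or end <= start:
            raise TrackValidationError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        v = _value_or_raise(fields[3], lineno, path)
        records.append((fields[0], start, end, v, lineno))

    if bin_width is None:
        g = 0
        for _, start, end, _, _ in records:
            g = math.gcd(g, start)
            g = math.gcd(g, end - start)
        bin_width = g if g > 0 else 1

    # overlap check per chromosome
    by_chrom: Dict[str, list] = {}
    for rec in records:
        by_chrom.setdefault(rec[0], []).append(rec)
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r[1])
        for a, b in zip(recs, recs[1:]):
            if b[1] < a[2]:
                raise TrackValidationError(
                    f"{path}:{b[4]}: interval [{b[1]}, {b[2]}) overlaps "
                    f"[{a[1]}, {a[2]}) on {chrom}"
                )

    builder = _TrackBuilder(bin_width)
    for chrom, start, end, v, lineno in records:
        if start % bin_width or (end - start) % bin_width:
            raise TrackParseError(
                f"{path}:{lineno}: interval [{start}, {end}) is not a whole "
                f"number of {bin_width} bp bins"
            )
        for s in range(start, end, bin_width):
            builder.add(chrom, s, v, lineno, path)
    if not records:
        logger.warning("%s: empty bedGraph; returning empty track", path)
    return builder.build(total_mapped_reads=total_mapped_reads, normalized=normalized)


def read_gene_table(path) -> List[GeneModel]:
    """Read a BED-like tab/space-separated gene table.

    Columns: chrom, start, end, name, strand (0-based half-open).  Strand
    must be '+' or '-'; bodies shorter than 10 bp and duplicate names are
    rejected.
    """
    path = Path(path)
    genes: List[GeneModel] = []
    seen = set()
    for lineno, line in _open_lines(path):
        fields = line.split()
        if len(fields) < 5:
            raise TrackParseError(
                f"{path}:{lineno}: gene table needs >= 5 columns "
                "(chrom, start, end, name, strand)"
            )
        chrom, name, strand = fields[0], fields[3], fields[4]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise TrackParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if strand not in ("+", "-"):
            raise TrackValidationError(
                f"{path}:{lineno}: gene {name!r} strand must be + or -, got {strand!r}"
            )
        if end <= start:
            raise TrackValidationError(
                f"{path}:{lineno}: gene {name!r} has end <= start "
                f"({start} >= {end})"
            )
        if name in seen:
            raise TrackValidationError(
                f"{path}:{lineno}: duplicate gene name {name!r}"
            )
        seen.add(name)
        try:
            genes.append(GeneModel(GenomicInterval(chrom, start, end, strand), name))
        except TrackValidationError as e:
            raise TrackValidationError(f"{path}:{lineno}: {e}") from None
    return genes


def read_peaks(path) -> List[PeakCall]:
    """Read peak calls from BED3, BED6 or narrowPeak.

    Columns beyond (chrom, start, end, name, score) are ignored.  Name '.'
    and score absent/'.'/-1 map to None.
    """
    path = Path(path)
    peaks: List[PeakCall] = []
    for lineno, line in _open_lines(path):
        fields = line.split()
        if len(fields) < 3:
            raise TrackParseError(
                f"{path}:{lineno}: BED needs >= 3 columns, got {len(fields)}"
            )
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError:
            raise TrackParseError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or end <= start:
            raise TrackValidationError(
                f"{path}:{lineno}: invalid interval [{start}, {end})"
            )
        name = fields[3] if len(fields) > 3 and fields[3] != "." else None
        score: Optional[float] = None
        if len(fields) > 4 and fields[4] not in (".", ""):
            try:
                score = float(fields[4])
            except ValueError:
                raise TrackParseError(
                    f"{path}:{lineno}: non-numeric score {fields[4]!r}"
                ) from None
            if score == -1:
                score = None
        strand = fields[5] if len(fields) > 5 and fields[5] in VALID_STRANDS else "."
        peaks.append(PeakCall(GenomicInterval(fields[0], start, end, strand), name, score))
    if not peaks:
        logger.warning("%s: no peaks found", path)
    return peaks


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_wig(track: BinnedTrack, path, *, sparse: bool = True) -> None:
    """Write a BinnedTrack as fixedStep WIG (1-based on disk).

    With ``sparse`` (default) runs of zero bins are omitted, each non-zero
    run getting its own fixedStep declaration — readers treat missing bins
    as zero, so the round trip is lossless.  Values use repr precision
    (round-trips within 1e-9 relative).
    """
    w = track.bin_width
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom in track.chroms:
            arr = track.values[chrom]
            if arr.size == 0:
                continue
            if sparse:
                nz = np.flatnonzero(arr)
                if nz.size == 0:
                    # keep the chromosome visible with an explicit zero bin
                    fh.write(f"fixedStep chrom={chrom} start=1 step={w} span={w}\n0\n")
                    continue
                # split into runs of consecutive non-zero bins
                breaks = np.flatnonzero(np.diff(nz) > 1) + 1
                for run in np.split(nz, breaks):
                    start1 = int(run[0]) * w + 1
                    fh.write(
                        f"fixedStep chrom={chrom} start={start1} step={w} span={w}\n"
                    )
                    for idx in run:
                        fh.write(f"{_fmt(arr[idx])}\n")
            else:
                fh.write(f"fixedStep chrom={chrom} start=1 step={w} span={w}\n")
                for v in arr:
                    fh.write(f"{_fmt(v)}\n")


def write_bedgraph(track: BinnedTrack, path, *, sparse: bool = True) -> None:
    """Write a BinnedTrack as bedGraph, merging equal-valued adjacent bins."""
    w = track.bin_width
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for chrom in track.chroms:
            arr = track.values[chrom]
            i = 0
            while i < arr.size:
                j = i
                while j + 1 < arr.size and arr[j + 1] == arr[i]:
                    j += 1
                if arr[i] != 0 or not sparse:
                    fh.write(f"{chrom}\t{i * w}\t{(j + 1) * w}\t{_fmt(arr[i])}\n")
                i = j + 1


def _fmt(v: float) -> str:
    """Shortest exact-ish decimal: integers stay integral, floats use repr."""
    f = float(v)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def check_chrom_compatibility(track: BinnedTrack, genes: Sequence[GeneModel]) -> List[str]:
    """Preflight: return gene-table chromosome names absent from the track.

    Name matching is exact (no 'chr' prefix aliasing); an empty result means
    every gene can be quantified.
    """
    missing = sorted({g.chrom for g in genes} - set(track.values))
    if missing:
        logger.warning(
            "gene table chromosomes absent from track: %s", ", ".join(missing)
        )
    return missing
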