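"""Per-region read counting from coordinate-sorted alignment files.

Counting is naive by design: every mapped alignment record whose reference
span overlaps a region by at least one base is counted for that region, so
a read straddling two adjacent regions contributes to both.  By default no
flag class is excluded (secondary, supplementary and duplicate records all
count); ``CountingOptions`` can restrict to primary records, drop
duplicates, require a minimum mapping quality, or count templates (distinct
read names) instead of records.

BAM files must be coordinate-sorted and indexed (counts use the index);
plain SAM files are supported through a one-pass in-memory scan, which is
intended for small files and test fixtures.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence, Union

import pandas as pd
import pysam

from .annotation import GenicRegion
from .errors import DataError
from .intergenic import IntergenicRegion

logger = logging.getLogger(__name__)

Region = Union[GenicRegion, IntergenicRegion]


@dataclass
class CountingOptions:
    """Flag filters applied to alignment records before counting."""

    primary_only: bool = False
    exclude_duplicates: bool = False
    min_mapq: int = 0
    count_unit: Literal["record", "template"] = "record"

    def accepts(self, read: "pysam.AlignedSegment") -> bool:
        if read.is_unmapped:
            return False
        if self.primary_only and (read.is_secondary or read.is_supplementary):
            return False
        if self.exclude_duplicates and read.is_duplicate:
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        return True


@dataclass
class AlignmentSource:
    """A SAM/BAM file playing the INPUT or IP role for one sample."""

    path: str | Path
    role: Literal["INPUT", "IP"]
    sample_id: str
    _sam_cache: dict | None = field(default=None, repr=False, compare=False)
    _warned_contigs: set = field(default_factory=set, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.path = Path(self.path)
        if self.role not in ("INPUT", "IP"):
            raise ValueError(f"role must be INPUT or IP, got {self.role!r}")

    @property
    def is_sam(self) -> bool:
        return self.path.suffix.lower() == ".sam"

    def open(self) -> pysam.AlignmentFile:
        mode = "r" if self.is_sam else "rb"
        return pysam.AlignmentFile(str(self.path), mode)

    def _ensure_indexed(self, af: pysam.AlignmentFile) -> None:
        if not af.has_index():
            raise DataError(
                f"{self.path}: BAM file has no index; run "
                f"'samtools sort' and 'samtools index' first"
            )

    def _load_sam(self, options: CountingOptions) -> dict:
        """One-pass scan of a SAM file into per-contig span lists."""
        spans: dict[str, list[tuple[int, int, str]]] = {}
        with self.open() as af:
            for read in af.fetch(until_eof=True):
                if not options.accepts(read):
                    continue
                spans.setdefault(read.reference_name, []).append(
                    (read.reference_start, read.reference_end, read.query_name)
                )
        return spans

    def count_region(self, region: Region, options: CountingOptions) -> int:
        """Count accepted records overlapping *region* by >= 1 base."""
        if region.end < region.start:  # degenerate: zero bases, zero reads
            return 0
        start0, end0 = region.start - 1, region.end
        if self.is_sam:
            cache_key = (options.primary_only, options.exclude_duplicates, options.min_mapq)
            if self._sam_cache is None or self._sam_cache[0] != cache_key:
                self._sam_cache = (cache_key, self._load_sam(options), set(self.references()))
            if region.contig not in self._sam_cache[2]:
                self._warn_missing(region.contig)
                return 0
            contig_spans = self._sam_cache[1].get(region.contig, [])
            if options.count_unit == "template":
                return len(
                    {name for s, e, name in contig_spans if s < end0 and e > start0}
                )
            return sum(1 for s, e, _ in contig_spans if s < end0 and e > start0)
        with self.open() as af:
            self._ensure_indexed(af)
            if region.contig not in af.references:
                self._warn_missing(region.contig)
                return 0
            if options.count_unit == "template":
                names = {
                    read.query_name
                    for read in af.fetch(region.contig, start0, end0)
                    if options.accepts(read)
                }
                return len(names)
            return sum(
                1 for read in af.fetch(region.contig, start0, end0)
                if options.accepts(read)
            )

    def _warn_missing(self, contig: str) -> None:
        if contig not in self._warned_contigs:
            self._warned_contigs.add(contig)
            warnings.warn(
                f"{self.path}: contig {contig!r} absent from alignment header; "
                f"its regions get count 0",
                stacklevel=2,
            )

    def total_mapped_primary(self) -> int:
        """Number of primary mapped records (the depth denominator rule)."""
        n = 0
        with self.open() as af:
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                n += 1
        return n

    def references(self) -> list[str]:
        with self.open() as af:
            return list(af.references)


def count_reads_in_region(
    aln: AlignmentSource,
    region: Region,
    options: CountingOptions | None = None,
) -> int:
    """Count reads in one region (see :class:`AlignmentSource.count_region`)."""
    return aln.count_region(region, options or CountingOptions())


def _region_key(region: Region) -> tuple[str, int, int, str]:
    rid = region.region_id if isinstance(region, GenicRegion) else region.region_id
    return (region.contig, region.start, region.end, rid)


def build_count_table(
    input_aln: AlignmentSource,
    ip_aln: AlignmentSource,
    regions: Sequence[Region],
    options: CountingOptions | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """Count INPUT and IP reads for every region.

    Returns a DataFrame with one row per region, in region order, with
    columns ``contig, start, end, region_id, input_count, ip_count``.
    The result is identical for any worker count: work is split over
    contiguous region chunks with one alignment handle per worker and
    reassembled in order.
    """
    if not regions:
        raise DataError("build_count_table: empty region list")
    options = options or CountingOptions()

    in_refs = set(input_aln.references())
    ip_refs = set(ip_aln.references())
    if in_refs != ip_refs:
        warnings.warn(
            f"reference name mismatch between {input_aln.path} and {ip_aln.path}: "
            f"only in INPUT {sorted(in_refs - ip_refs)}, "
            f"only in IP {sorted(ip_refs - in_refs)}",
            stacklevel=2,
        )

    def count_chunk(chunk: Sequence[Region]) -> list[tuple[int, int]]:
        # fresh sources per worker: pysam handles are not thread-safe
        src_in = AlignmentSource(input_aln.path, "INPUT", input_aln.sample_id)
        src_ip = AlignmentSource(ip_aln.path, "IP", ip_aln.sample_id)
        return [
            (src_in.count_region(r, options), src_ip.count_region(r, options))
            for r in chunk
        ]

    if workers <= 1:
        pairs = [
            (input_aln.count_region(r, options), ip_aln.count_region(r, options))
            for r in regions
        ]
    else:
        size = max(1, -(-len(regions) // workers))
        chunks = [regions[i : i + size] for i in range(0, len(regions), size)]
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(count_chunk, chunks))
        pairs = [p for chunk in results for p in chunk]

    rows = [
        _region_key(r) + pair for r, pair in zip(regions, pairs)
    ]
    df = pd.DataFrame(
        rows, columns=["contig", "start", "end", "region_id", "input_count", "ip_count"]
    )
    df.attrs["input_sample"] = input_aln.sample_id
    df.attrs["ip_sample"] = ip_aln.sample_id
    df.attrs["counting_options"] = vars(options).copy()
    return df


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def total_sequences(source: Union[str, Path, AlignmentSource]) -> int:
    """Total-read denominator from a FASTQ file or an alignment file.

    FASTQ (plain or gzip): the number of records, with a structural check
    that the file is made of well-formed 4-line records.  Alignment files:
    the number of primary mapped records (secondary/supplementary records
    are never part of the depth denominator).
    """
    if isinstance(source, AlignmentSource):
        return source.total_mapped_primary()
    path = Path(source)
    if path.suffix.lower() in (".sam", ".bam"):
        return AlignmentSource(path, "INPUT", path.stem).total_mapped_primary()
    n = 0
    with _open_maybe_gzip(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            lines = [header] + [fh.readline() for _ in range(3)]
            if any(not l for l in lines) :
                raise DataError(
                    f"{path}: truncated FASTQ record at index {n} "
                    f"(file is not a multiple of 4 lines)"
                )
            if not lines[0].startswith("@") or not lines[2].startswith("+"):
                raise DataError(f"{path}: malformed FASTQ record at index {n}")
            n += 1
    return n
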