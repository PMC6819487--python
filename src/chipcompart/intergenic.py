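"""Intergenic region derivation.

For each contig the intergenic regions (IGRs) are the gaps between
consecutive annotated genes in coordinate order, plus a leading region when
the first gene does not start at base 1 and a trailing region when the last
gene ends before the contig end.  A contig with no annotated genes yields a
single whole-contig region.

The raw gap between an adjacent gene pair is ``next_start - prev_end``.
Only pairs with raw gap >= 0 produce a region; overlapping pairs (negative
gap) are excluded and collected into a diagnostic report, since overlapping
gene annotations would otherwise produce regions of negative size.  Gaps of
0 or 1 produce *degenerate* regions containing zero bases; they are kept by
default (they can never accumulate reads) so that region inventories match
the gap rule exactly, and can be dropped with ``drop_empty``.

IGRs are recomputed from the annotation on every run, never cached, so a
refreshed annotation immediately refreshes the regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .annotation import ContigTable, GenicRegion
from .errors import DataError

CONTIG_START = "contig-start"
CONTIG_END = "contig-end"

BoundsMode = Literal["exclusive", "touching"]


@dataclass(frozen=True)
class IntergenicRegion:
    """A derived inter-feature interval (1-based inclusive).

    ``end < start`` is permitted only for degenerate (zero-base) regions.
    ``flank_left``/``flank_right`` name the bounding gene, or the sentinels
    ``"contig-start"``/``"contig-end"`` at contig boundaries.
    """

    contig: str
    start: int
    end: int
    raw_gap: int
    degenerate: bool
    flank_left: str
    flank_right: str

    @property
    def length(self) -> int:
        """Number of bases in the region (0 for degenerate regions)."""
        return max(0, self.end - self.start + 1)

    @property
    def region_id(self) -> str:
        return f"IGR:{self.contig}:{self.start}-{self.end}"


@dataclass(frozen=True)
class NegativeGapEntry:
    contig: str
    prev_region_id: str
    next_region_id: str
    raw_gap: int


@dataclass
class NegativeGapReport:
    """Adjacent overlapping gene pairs excluded from the IGR output."""

    entries: list[NegativeGapEntry]

    def __len__(self) -> int:
        return len(self.entries)


def raw_gap(prev_end: int, next_start: int) -> int:
    """Gap between an adjacent gene pair: ``next_start - prev_end``.

    Zero is the boundary of the keep rule: regions with raw gap >= 0 are
    emitted (degenerate when the gap is 0 or 1), negative gaps are not.
    """
    if prev_end <= 0 or next_start <= 0:
        raise DataError("raw_gap requires positive 1-based coordinates")
    return next_start - prev_end


def _check_sorted(genes: Sequence[GenicRegion]) -> None:
    keys = [(g.contig, g.start) for g in genes]
    if keys != sorted(keys):
        raise DataError("genes must be sorted by (contig, start)")


def derive_intergenic(
    genes: Sequence[GenicRegion],
    contigs: ContigTable,
    *,
    bounds: BoundsMode = "exclusive",
    drop_empty: bool = False,
) -> tuple[list[IntergenicRegion], NegativeGapReport]:
    """Compute intergenic regions and the negative-gap report.

    Parameters
    ----------
    genes:
        Genic regions sorted by (contig, start); every contig must appear
        in *contigs*.
    contigs:
        Contig lengths; contigs without genes yield one whole-contig region.
    bounds:
        ``"exclusive"`` (default) emits ``[prev_end+1, next_start-1]`` so
        IGRs never share a base with their bounding genes;
        ``"touching"`` emits ``[prev_end, next_start]``, a compatibility
        convention where IGRs share their boundary base with the genes.
    drop_empty:
        Remove degenerate (zero-base) regions from the output.

    Returns
    -------
    (regions, report):
        Regions sorted by (contig, start); the report lists exactly the
        adjacent pairs whose raw gap was negative.
    """
    if bounds not in ("exclusive", "touching"):
        raise ValueError(f"unknown bounds mode {bounds!r}")
    _check_sorted(genes)
    by_contig: dict[str, list[GenicRegion]] = {}
    for g in genes:
        if g.contig not in contigs:
            raise DataError(f"gene {g.region_id}: contig {g.contig!r} not in contig table")
        by_contig.setdefault(g.contig, []).append(g)

    regions: list[IntergenicRegion] = []
    negatives: list[NegativeGapEntry] = []

    def emit(contig: str, start: int, end: int, gap: int, left: str, right: str) -> None:
        degenerate = (end - start + 1) <= 0
        if degenerate and drop_empty:
            return
        regions.append(
            IntergenicRegion(
                contig=contig, start=start, end=end, raw_gap=gap,
                degenerate=degenerate, flank_left=left, flank_right=right,
            )
        )

    touching = bounds == "touching"

    for contig, length in contigs.items():
        cgenes = by_contig.get(contig, [])
        if not cgenes:
            # gap as if flanked by virtual genes ending at 0 / starting at length+1
            emit(contig, 1, length, length + 1, CONTIG_START, CONTIG_END)
            continue
        first = cgenes[0]
        if first.start >= 2:
            emit(contig, 1, first.start if touching else first.start - 1,
                 first.start, CONTIG_START, first.region_id)
        for prev, nxt in zip(cgenes, cgenes[1:]):
            gap = raw_gap(prev.end, nxt.start)
            if gap < 0:
                negatives.append(
                    NegativeGapEntry(contig, prev.region_id, nxt.region_id, gap)
                )
                continue
            if touching:
                emit(contig, prev.end, nxt.start, gap,
                     prev.region_id, nxt.region_id)
            else:
                emit(contig, prev.end + 1, nxt.start - 1, gap,
                     prev.region_id, nxt.region_id)
        last = cgenes[-1]
        if last.end < length:
            emit(contig, last.end if touching else last.end + 1, length,
                 length + 1 - last.end, last.region_id, CONTIG_END)
    regions.sort(key=lambda r: (r.contig, r.start))
    return regions, NegativeGapReport(entries=negatives)
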