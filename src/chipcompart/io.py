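"""CSV/BED writers and readers shared by the CLI and pipeline.

Every CSV written by the tool starts with ``#``-prefixed metadata lines
recording the package version and a hash of the resolved run configuration,
so an output file identifies the code and settings that produced it.
Readers therefore pass ``comment='#'`` to pandas.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation import GenicRegion
from .intergenic import IntergenicRegion, NegativeGapReport


@dataclass(frozen=True)
class SimpleRegion:
    """Minimal region view used when regions are read back from CSV."""

    contig: str
    start: int
    end: int
    region_id: str


def config_hash(config: dict) -> str:
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_csv(df: pd.DataFrame, path: str | Path, config: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        fh.write(f"# chipcompart v{__version__}\n")
        if config is not None:
            fh.write(f"# config_hash={config_hash(config)}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def genic_regions_frame(regions: Sequence[GenicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.contig, r.start, r.end, r.region_id, r.description) for r in regions],
        columns=["contig", "start", "end", "region_id", "description"],
    )


def intergenic_regions_frame(regions: Sequence[IntergenicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.contig, r.start, r.end, r.region_id, r.raw_gap, r.degenerate,
             r.flank_left, r.flank_right)
            for r in regions
        ],
        columns=["contig", "start", "end", "region_id", "raw_gap", "degenerate",
                 "flank_left", "flank_right"],
    )


def negative_gap_frame(report: NegativeGapReport) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.contig, e.prev_region_id, e.next_region_id, e.raw_gap)
         for e in report.entries],
        columns=["contig", "prev_region_id", "next_region_id", "raw_gap"],
    )


def read_regions(path: str | Path) -> list[SimpleRegion]:
    """Load a regions CSV (genic or intergenic) into counting-ready objects."""
    df = read_csv(path)
    return [
        SimpleRegion(str(r.contig), int(r.start), int(r.end), str(r.region_id))
        for r in df.itertuples(index=False)
    ]


def write_bed(regions: Sequence[IntergenicRegion], path: str | Path) -> None:
    """Export regions as BED (0-based half-open; degenerate regions skipped,
    since BED cannot represent zero-length intervals)."""
    path = Path(path)
    with path.open("w") as fh:
        for r in regions:
            if r.length <= 0:
                continue
            fh.write(f"{r.contig}\t{r.start - 1}\t{r.end}\t{r.region_id}\n")
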