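"""Genome annotation handling: definition profiles, contig tables, genic regions.

A *definition profile* tells the pipeline which GFF3 records constitute the
"genic" compartment for a given organism and how to cut a usable identifier
and description out of the free-form attribute column.  The same annotation
file can therefore be mined for ``gene`` records, ``mRNA`` records, or any
other feature type, without touching code: profiles are plain ``key=value``
text files shipped alongside the data.

All coordinates are 1-based inclusive (the GFF3 convention) and are used
unchanged throughout the package; conversion to 0-based half-open happens
only at the BED writer and at pysam call sites.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

_PROFILE_KEYS = ("filter1", "filter2", "delim1", "delim2", "delim3")


@dataclass(frozen=True)
class DefinitionProfile:
    """Feature selection and attribute-cutting rules for one organism.

    Parameters
    ----------
    filter1:
        Feature type (GFF3 column 3) selecting the records of interest,
        e.g. ``"gene"`` or ``"mRNA"``.  Required, non-empty.
    filter2:
        Optional substring that the attribute column (column 9) must also
        contain; empty string disables the secondary filter.
    delim1, delim2, delim3:
        Delimiters used to cut the identifier and description out of the
        attribute column: ``delim1`` separates attribute fields, ``delim2``
        separates key from value within a field, and ``delim3`` truncates
        the description at its first occurrence.
    """

    filter1: str
    filter2: str = ""
    delim1: str = ";"
    delim2: str = "="
    delim3: str = ","

    def __post_init__(self) -> None:
        if not self.filter1:
            raise ConfigurationError("filter1 must be a non-empty string")
        for name in ("delim1", "delim2", "delim3"):
            if not getattr(self, name):
                raise ConfigurationError(f"{name} must be a non-empty string")

    def to_file(self, path: str | Path) -> None:
        """Write the profile as a ``key=value`` file (lossless round-trip)."""
        lines = [f"{k}={getattr(self, k)}" for k in _PROFILE_KEYS]
        Path(path).write_text("\n".join(lines) + "\n")


def _unquote(value: str) -> str:
    if len(value) >= 2 and value[0] == value[-1] and value[0] in "\"'":
        return value[1:-1]
    return value


def load_definition_profile(path: str | Path) -> DefinitionProfile:
    """Read a definition profile from a ``key=value`` text file.

    Lines starting with ``#`` and blank lines are ignored.  Values may be
    quoted so that delimiters like ``;`` remain readable.  A duplicated key
    is tolerated (last occurrence wins, with a warning); unknown keys are
    warned about and skipped; a missing ``filter1`` is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"definition profile not found: {path}")
    values: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ConfigurationError(
                f"{path}:{lineno}: expected key=value, got {line!r}"
            )
        key, _, value = line.partition("=")
        key = key.strip()
        value = _unquote(value.strip())
        if key not in _PROFILE_KEYS:
            logger.warning("%s:%d: unknown profile key %r ignored", path, lineno, key)
            continue
        if key in values:
            logger.warning("%s:%d: duplicate key %r; last value wins", path, lineno, key)
        values[key] = value
    if "filter1" not in values or not values["filter1"]:
        raise ConfigurationError(f"{path}: required key 'filter1' missing")
    defaults = DefinitionProfile(filter1=values["filter1"])
    return replace(defaults, **values)


@dataclass
class ContigTable:
    """Ordered mapping of contig (scaffold) name to length in bp."""

    entries: dict[str, int] = field(default_factory=dict)

    def add(self, name: str, length: int) -> None:
        if name in self.entries:
            raise DataError(f"duplicated contig name: {name!r}")
        if length < 1:
            raise DataError(f"contig {name!r} has non-positive length {length}")
        self.entries[name] = int(length)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> int:
        return self.entries[name]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def items(self):
        return self.entries.items()


def read_contig_table(path: str | Path) -> ContigTable:
    """Build a :class:`ContigTable` from a FASTA file or a ``.fai`` index.

    ``.fai`` files are recognised by extension; anything else is parsed as
    FASTA and lengths are taken from the sequences themselves.  Duplicate
    contig names and zero-length sequences are errors.
    """
    path = Path(path)
    table = ContigTable()
    if path.suffix == ".fai":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise DataError(f"{path}:{lineno}: malformed FAI line")
            table.add(cols[0], int(cols[1]))
    else:
        for record in SeqIO.parse(str(path), "fasta"):
            table.add(record.id, len(record.seq))
    if len(table) == 0:
        raise DataError(f"{path}: no contigs found")
    return table


@dataclass(frozen=True)
class GenicRegion:
    """One annotated feature interval (1-based inclusive) on a contig."""

    contig: str
    start: int
    end: int
    region_id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise DataError(
                f"invalid genic interval {self.contig}:{self.start}-{self.end}"
            )
        if not self.region_id:
            raise DataError(f"empty region_id at {self.contig}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _cut_attributes(
    attributes: str, profile: DefinitionProfile
) -> tuple[str | None, str]:
    """Extract (region_id, description) from a GFF3 attribute column.

    The first ``delim1`` field's value (after ``delim2``) is the identifier;
    the second field's value, truncated at the first ``delim3``, is the
    description.  Returns ``(None, "")`` when no identifier can be cut out.
    """
    fields = [f for f in attributes.split(profile.delim1) if f.strip()]
    if not fields:
        return None, ""
    first = fields[0]
    if profile.delim2 not in first:
        return None, ""
    region_id = first.split(profile.delim2, 1)[1].strip()
    if not region_id:
        return None, ""
    description = ""
    if len(fields) > 1:
        second = fields[1]
        value = second.split(profile.delim2, 1)[1] if profile.delim2 in second else second
        description = value.split(profile.delim3, 1)[0].strip()
    return region_id, description


def extract_genic_regions(
    gff3: str | Path,
    profile: DefinitionProfile,
    contigs: ContigTable | None = None,
) -> list[GenicRegion]:
    """Parse a GFF3 file into the genic regions selected by *profile*.

    A record is kept when its feature type (column 3) equals ``filter1``
    and, if ``filter2`` is non-empty, its attribute column contains
    ``filter2`` as a substring.  Output is sorted by (contig, start, end).

    Consistency checks: malformed lines, ``start > end`` and coordinates
    beyond the contig length (when *contigs* is given) are errors.  Records
    whose attributes cannot be cut with the profile delimiters fall back to
    a positional ``contig:start-end`` identifier with a warning.  Strand is
    ignored: counting downstream is strand-agnostic.
    """
    gff3 = Path(gff3)
    regions: list[GenicRegion] = []
    seen_ids: set[str] = set()
    with gff3.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith("##FASTA"):
                break
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise DataError(
                    f"{gff3}:{lineno}: expected 9 tab-separated columns, got {len(cols)}"
                )
            contig, _source, ftype, start_s, end_s = cols[0], cols[1], cols[2], cols[3], cols[4]
            if ftype != profile.filter1:
                continue
            attributes = cols[8]
            if profile.filter2 and profile.filter2 not in attributes:
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise DataError(f"{gff3}:{lineno}: non-integer coordinates") from exc
            if start > end:
                raise DataError(
                    f"{gff3}:{lineno}: start {start} > end {end} for {contig}"
                )
            if contigs is not None:
                if contig not in contigs:
                    raise DataError(f"{gff3}:{lineno}: unknown contig {contig!r}")
                if end > contigs[contig]:
                    raise DataError(
                        f"{gff3}:{lineno}: end {end} beyond contig {contig!r} "
                        f"length {contigs[contig]}"
                    )
            region_id, description = _cut_attributes(attributes, profile)
            if region_id is None:
                region_id = f"{contig}:{start}-{end}"
                logger.warning(
                    "%s:%d: attributes not parseable with profile delimiters; "
                    "using positional id %s",
                    gff3,
                    lineno,
                    region_id,
                )
            if region_id in seen_ids:
                logger.warning("duplicate region_id %r (kept)", region_id)
            seen_ids.add(region_id)
            regions.append(
                GenicRegion(contig=contig, start=start, end=end,
                            region_id=region_id, description=description)
            )
    regions.sort(key=lambda r: (r.contig, r.start, r.end))
    return regions
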