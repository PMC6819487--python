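"""Self-contained synthetic ChIP-seq fixtures with recorded ground truth.

The generator emits a small random genome (FASTA + FAI), a GFF3 annotation,
and for each planned sample a coordinate-sorted indexed BAM, a matching SAM
text file and a gzipped FASTQ — everything a pipeline run needs, plus a
``FixtureTruth`` table recording exactly how many reads were placed in each
target interval per sample.

Reads are single-end, fixed-length, and placed uniformly at random wholly
inside their target interval; alignment coordinates are written directly
(no aligner round-trip), so per-region counts are known exactly at write
time.  Sequence content is i.i.d. uniform ACGT — counting never looks at
it.  The same seed reproduces every emitted byte (gzip members are written
with a zeroed timestamp).

Counts can be planned as fixed integers or as Poisson rates; Poisson
sampling happens once, at generation time, and the *sampled* counts are
what the truth table records.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .errors import DataError

DEFAULT_READ_LENGTH = 66  # single-end HiSeq-style read length


@dataclass(frozen=True)
class ReadTarget:
    """An interval (1-based inclusive) into which reads are planted."""

    contig: str
    start: int
    end: int
    label: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SamplePlan:
    """Read plan for one sample: counts (or Poisson rates) per target label."""

    sample_id: str
    role: Literal["INPUT", "IP"]
    counts: Mapping[str, float]
    clusters_pf: int = 20_000_000
    tagged: bool = True


@dataclass(frozen=True)
class FixturePlan:
    """Complete description of a synthetic dataset.

    ``genes`` drives only the GFF3 annotation; ``targets`` drives only read
    placement, so reads can be planted in genic intervals, intergenic gaps,
    or anywhere else.  ``count_mode`` selects fixed counts or Poisson
    sampling of the per-target values.
    """

    seed: int
    contigs: Sequence[tuple[str, int]]
    genes: Mapping[str, Sequence[tuple[int, int, str]]]
    targets: Sequence[ReadTarget]
    samples: Sequence[SamplePlan]
    read_length: int = DEFAULT_READ_LENGTH
    count_mode: Literal["fixed", "poisson"] = "fixed"

    def validate(self) -> None:
        lengths = dict(self.contigs)
        if len(lengths) != len(self.contigs):
            raise DataError("duplicate contig names in plan")
        for contig, gene_list in self.genes.items():
            if contig not in lengths:
                raise DataError(f"genes reference unknown contig {contig!r}")
            for start, end, gid in gene_list:
                if not (1 <= start <= end <= lengths[contig]):
                    raise DataError(f"gene {gid} out of contig bounds")
        labels = set()
        for t in self.targets:
            if t.contig not in lengths:
                raise DataError(f"target {t.label} on unknown contig {t.contig!r}")
            if not (1 <= t.start <= t.end <= lengths[t.contig]):
                raise DataError(f"target {t.label} out of contig bounds")
            if t.label in labels:
                raise DataError(f"duplicate target label {t.label!r}")
            labels.add(t.label)
        by_label = {t.label: t for t in self.targets}
        for s in self.samples:
            for label, count in s.counts.items():
                if label not in by_label:
                    raise DataError(f"sample {s.sample_id} plans reads for "
                                    f"unknown target {label!r}")
                if count > 0 and by_label[label].length < self.read_length:
                    raise DataError(
                        f"target {label} ({by_label[label].length} bp) is shorter "
                        f"than the read length {self.read_length}; plan 0 reads "
                        f"or enlarge it"
                    )


@dataclass
class FixtureOutput:
    """Paths of everything one fixture emitted, plus its ground truth."""

    directory: Path
    fasta: Path
    fai: Path
    gff3: Path
    bams: dict[str, Path]
    sams: dict[str, Path]
    fastqs: dict[str, Path]
    truth: pd.DataFrame
    truth_csv: Path
    clusters_pf: dict[str, int]


def _write_fasta(path: Path, sequences: dict[str, str]) -> None:
    with path.open("w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _write_gff3(path: Path, plan: FixturePlan) -> None:
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for contig, _length in plan.contigs:
            for start, end, gid in sorted(plan.genes.get(contig, [])):
                fh.write(
                    f"{contig}\tfixture\tgene\t{start}\t{end}\t.\t+\t.\t"
                    f"ID={gid};Name={gid},synthetic\n"
                )


def make_fixture(plan: FixturePlan, outdir: str | Path) -> FixtureOutput:
    """Materialize a plan into files and return paths + ground truth."""
    plan.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(plan.seed)

    lengths = dict(plan.contigs)
    sequences = {
        name: "".join(rng.choice(list("ACGT"), size=length))
        for name, length in plan.contigs
    }
    fasta = outdir / "genome.fasta"
    _write_fasta(fasta, sequences)
    pysam.faidx(str(fasta))
    fai = Path(str(fasta) + ".fai")

    gff3 = outdir / "annotation.gff3"
    _write_gff3(gff3, plan)

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": length} for name, length in plan.contigs],
    }
    ref_index = {name: i for i, (name, _l) in enumerate(plan.contigs)}
    targets = {t.label: t for t in plan.targets}

    bams: dict[str, Path] = {}
    sams: dict[str, Path] = {}
    fastqs: dict[str, Path] = {}
    truth_rows = []
    clusters_pf = {}

    for sample in plan.samples:
        clusters_pf[sample.sample_id] = sample.clusters_pf
        reads: list[tuple[int, int, str, str]] = []  # (ref_id, pos0, name, seq)
        for label in sorted(sample.counts):
            target = targets[label]
            planned = sample.counts[label]
            if plan.count_mode == "poisson":
                emitted = int(rng.poisson(planned))
            else:
                emitted = int(planned)
            if emitted > 0 and target.length < plan.read_length:
                raise DataError(f"target {label} too short for sampled reads")
            hi = target.end - plan.read_length + 1  # 1-based last valid start
            starts = rng.integers(target.start, hi + 1, size=emitted)
            contig_seq = sequences[target.contig]
            for i, s in enumerate(sorted(starts)):
                name = f"{sample.sample_id}:{label}:{i}"
                seq = contig_seq[s - 1 : s - 1 + plan.read_length]
                reads.append((ref_index[target.contig], int(s) - 1, name, seq))
            truth_rows.append(
                {
                    "sample_id": sample.sample_id,
                    "role": sample.role,
                    "tagged": sample.tagged,
                    "label": label,
                    "contig": target.contig,
                    "start": target.start,
                    "end": target.end,
                    "planned": planned,
                    "emitted": emitted,
                }
            )
        reads.sort(key=lambda r: (r[0], r[1], r[2]))

        bam = outdir / f"{sample.sample_id}.bam"
        sam = outdir / f"{sample.sample_id}.sam"
        for path, mode in ((str(sam), "w"), (str(bam), "wb")):
            with pysam.AlignmentFile(path, mode, header=header) as af:
                for ref_id, pos0, name, seq in reads:
                    seg = pysam.AlignedSegment(af.header)
                    seg.query_name = name
                    seg.query_sequence = seq
                    seg.flag = 0
                    seg.reference_id = ref_id
                    seg.reference_start = pos0
                    seg.mapping_quality = 60
                    seg.cigarstring = f"{len(seq)}M"
                    seg.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
                    af.write(seg)
        pysam.index(str(bam))
        bams[sample.sample_id] = bam
        sams[sample.sample_id] = sam

        fastq = outdir / f"{sample.sample_id}.fastq.gz"
        with open(fastq, "wb") as raw, gzip.GzipFile(
            fileobj=raw, mode="wb", mtime=0
        ) as gz:
            for _ref, _pos, name, seq in reads:
                gz.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n".encode())
        fastqs[sample.sample_id] = fastq

    truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "role", "tagged", "label", "contig", "start",
                 "end", "planned", "emitted"],
    )
    truth_csv = outdir / "truth.csv"
    truth.to_csv(truth_csv, index=False)
    return FixtureOutput(
        directory=outdir, fasta=fasta, fai=fai, gff3=gff3, bams=bams,
        sams=sams, fastqs=fastqs, truth=truth, truth_csv=truth_csv,
        clusters_pf=clusters_pf,
    )


def make_untagged_background(
    plan: FixturePlan,
    sticky_labels: Sequence[str],
    sticky_factor: float = 10.0,
    baseline_ip: float | None = None,
) -> FixturePlan:
    """Extend a plan with an untagged INPUT/IP pair sharing sticky regions.

    Nonspecific ("sticky") targets pull down DNA regardless of the tag, so
    the untagged IP sample receives the same ``sticky_factor``-elevated
    rate there as the tagged IP; everywhere else the untagged IP stays at
    the INPUT baseline (enrichment ~= 1).  Downstream, Filter 1 subtracts
    this shared background so sticky targets fail while targets enriched
    only in the tagged sample pass.  Truth marks sticky targets via the
    returned plan's untagged sample counts.
    """
    tagged_inputs = [s for s in plan.samples if s.role == "INPUT" and s.tagged]
    if not tagged_inputs:
        raise DataError("plan has no tagged INPUT sample to mirror")
    template = tagged_inputs[0]
    labels = {t.label for t in plan.targets}
    unknown = set(sticky_labels) - labels
    if unknown:
        raise DataError(f"sticky labels not in plan targets: {sorted(unknown)}")

    untagged_input = SamplePlan(
        sample_id="untagged_input",
        role="INPUT",
        counts=dict(template.counts),
        clusters_pf=template.clusters_pf,
        tagged=False,
    )
    ip_counts = {}
    for label, base in template.counts.items():
        level = base if baseline_ip is None else baseline_ip
        if label in sticky_labels:
            level = level * sticky_factor
        ip_counts[label] = level
    untagged_ip = SamplePlan(
        sample_id="untagged_ip",
        role="IP",
        counts=ip_counts,
        clusters_pf=template.clusters_pf,
        tagged=False,
    )
    return replace(plan, samples=list(plan.samples) + [untagged_input, untagged_ip])


def minimal_plan(seed: int = 0) -> FixturePlan:
    """Two contigs, three genes, fixed planted counts — the smoke-test plan."""
    contigs = [("ctgA", 10_000), ("ctgB", 6_000)]
    genes = {
        "ctgA": [(1_001, 2_000, "G1"), (3_001, 4_000, "G2")],
        "ctgB": [(501, 1_500, "G3")],
    }
    targets = [
        ReadTarget("ctgA", 1_001, 2_000, "G1"),
        ReadTarget("ctgA", 3_001, 4_000, "G2"),
        ReadTarget("ctgB", 501, 1_500, "G3"),
        ReadTarget("ctgA", 2_001, 3_000, "IGR1"),
    ]
    pf = 1_000_000
    samples = [
        SamplePlan("tag_input", "INPUT", {"G1": 50, "G2": 50, "G3": 50, "IGR1": 50}, pf),
        SamplePlan("tag_ip", "IP", {"G1": 250, "G2": 40, "G3": 60, "IGR1": 30}, pf),
    ]
    return FixturePlan(seed=seed, contigs=contigs, genes=genes,
                       targets=targets, samples=samples)


def edge_case_plan(seed: int = 0) -> FixturePlan:
    """Exercises edge rules: gene at base 1, overlapping genes, empty contig."""
    contigs = [("edge1", 5_000), ("edge2", 4_000), ("bare", 2_000)]
    genes = {
        "edge1": [(1, 800, "E1"), (700, 1_600, "E2"), (1_601, 2_400, "E3")],
        "edge2": [(1_000, 4_000, "E4")],
    }
    targets = [
        ReadTarget("edge1", 1, 800, "E1"),
        ReadTarget("edge1", 2_401, 5_000, "IGR_tail"),
        ReadTarget("bare", 1, 2_000, "IGR_bare"),
    ]
    pf = 1_000_000
    samples = [
        SamplePlan("tag_input", "INPUT", {"E1": 40, "IGR_tail": 40, "IGR_bare": 40}, pf),
        SamplePlan("tag_ip", "IP", {"E1": 120, "IGR_tail": 20, "IGR_bare": 40}, pf),
    ]
    return FixturePlan(seed=seed, contigs=contigs, genes=genes,
                       targets=targets, samples=samples)


def poisson_plan(seed: int = 0, n_regions: int = 60, rate: float = 100.0) -> FixturePlan:
    """Many same-size genic targets with Poisson-sampled counts."""
    region_len = 500
    spacing = 300
    per_contig = 30
    contigs = []
    genes: dict[str, list[tuple[int, int, str]]] = {}
    targets = []
    made = 0
    c = 0
    while made < n_regions:
        name = f"pc{c}"
        take = min(per_contig, n_regions - made)
        length = (region_len + spacing) * take + spacing
        contigs.append((name, length))
        genes[name] = []
        pos = spacing + 1
        for _ in range(take):
            gid = f"P{made}"
            genes[name].append((pos, pos + region_len - 1, gid))
            targets.append(ReadTarget(name, pos, pos + region_len - 1, gid))
            pos += region_len + spacing
            made += 1
        c += 1
    pf = 1_000_000
    rng = np.random.default_rng(seed + 7)
    enrich = rng.uniform(0.5, 4.0, size=n_regions)
    input_counts = {t.label: rate for t in targets}
    ip_counts = {t.label: rate * enrich[i] for i, t in enumerate(targets)}
    samples = [
        SamplePlan("tag_input", "INPUT", input_counts, pf),
        SamplePlan("tag_ip", "IP", ip_counts, pf),
    ]
    return FixturePlan(seed=seed, contigs=contigs, genes=genes, targets=targets,
                       samples=samples, count_mode="poisson")


PRESETS = {
    "minimal": minimal_plan,
    "edge-cases": edge_case_plan,
    "poisson": poisson_plan,
}
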