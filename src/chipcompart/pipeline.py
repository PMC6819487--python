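"""End-to-end run orchestration: regions -> count -> enrich -> summarize.

``run_pipeline`` executes the whole analysis from a :class:`RunConfig` and
writes the five standard outputs into the output directory:

- ``genic_enrichment.csv`` and ``intergenic_enrichment.csv`` — the two
  per-region post-processing tables;
- ``FINAL.table.<INPUT>-<IP>.genic.csv`` / ``....intergenic.csv`` — the raw
  count tables per sample pair;
- ``negative_gaps.csv`` — overlapping gene pairs excluded from the IGR set;
- ``compartment_summary.csv`` — genic vs intergenic localization;
- ``run_metadata.txt`` — resolved configuration, depth denominators with
  provenance, and the headline region/filter counts.

Any stage failure raises with a stage-named message; partially written
outputs are removed.
"""

from __future__ import annotations

import json
import logging
import re
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .annotation import (
    DefinitionProfile,
    load_definition_profile,
    extract_genic_regions,
    read_contig_table,
)
from .counting import AlignmentSource, CountingOptions, build_count_table, total_sequences
from .enrichment import (
    DEFAULT_THRESHOLD,
    SampleNormalization,
    enrichment_table,
    replicate_enrichment,
    summarize_compartments,
)
from .errors import ChipCompartError, DataError
from .intergenic import derive_intergenic
from . import io as cio

logger = logging.getLogger(__name__)


@dataclass
class SamplePair:
    """One INPUT/IP alignment pair (tagged replicate or untagged control)."""

    input_path: Path
    ip_path: Path
    input_id: str
    ip_id: str


@dataclass
class RunConfig:
    """Fully resolved configuration for one end-to-end run."""

    gff3: Path
    genome: Path                       # FASTA or FAI
    profile: Path
    pairs: list[SamplePair]            # tagged replicates
    untagged_pairs: list[SamplePair] = field(default_factory=list)
    outdir: Path = Path("chipcompart_out")
    threshold: float = DEFAULT_THRESHOLD
    clusters_pf: dict[str, int] = field(default_factory=dict)  # sample_id -> PF
    igr_bounds: str = "exclusive"
    drop_empty: bool = False
    pseudocount: float | None = None
    min_input_reads: int | None = None
    counting: CountingOptions = field(default_factory=CountingOptions)
    workers: int = 1
    scratch: Path | None = None

    def resolved(self) -> dict:
        d = {
            "version": __version__,
            "gff3": str(self.gff3),
            "genome": str(self.genome),
            "profile": str(self.profile),
            "pairs": [(str(p.input_path), str(p.ip_path)) for p in self.pairs],
            "untagged_pairs": [
                (str(p.input_path), str(p.ip_path)) for p in self.untagged_pairs
            ],
            "threshold": self.threshold,
            "clusters_pf": dict(self.clusters_pf),
            "igr_bounds": self.igr_bounds,
            "drop_empty": self.drop_empty,
            "pseudocount": self.pseudocount,
            "min_input_reads": self.min_input_reads,
            "counting": vars(self.counting).copy(),
            "workers": self.workers,
        }
        return d


def _sanitize(name: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", name)


def _normalization(cfg: RunConfig, sample_id: str, path: Path) -> SampleNormalization:
    """Depth denominator for one sample: user override, else alignment total."""
    if sample_id in cfg.clusters_pf:
        return SampleNormalization(sample_id, cfg.clusters_pf[sample_id],
                                   "user-supplied")
    role = "INPUT"
    total = total_sequences(AlignmentSource(path, role, sample_id))
    if total < 1:
        raise DataError(f"sample {sample_id}: no mapped reads to normalize by; "
                        f"supply a clusters-PF value")
    return SampleNormalization(sample_id, total, "alignment-total")


def _stage(name: str):
    def wrap(exc: Exception) -> ChipCompartError:
        return DataError(f"[stage {name}] {exc}")
    return wrap


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run all stages; returns the mapping of output name -> path."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    resolved = cfg.resolved()
    written: list[Path] = []

    def emit(df: pd.DataFrame, name: str) -> Path:
        path = outdir / name
        cio.write_csv(df, path, resolved)
        written.append(path)
        return path

    try:
        # --- stage: regions ---
        try:
            profile = load_definition_profile(cfg.profile)
            contigs = read_contig_table(cfg.genome)
            genes = extract_genic_regions(cfg.gff3, profile, contigs)
            igrs, negatives = derive_intergenic(
                genes, contigs, bounds=cfg.igr_bounds, drop_empty=cfg.drop_empty
            )
        except (ChipCompartError, OSError, ValueError) as exc:
            raise _stage("regions")(exc) from exc
        logger.info("regions: %d genic, %d intergenic, %d negative-gap exclusions",
                    len(genes), len(igrs), len(negatives))

        # --- stage: count ---
        def count_pairs(pairs: Sequence[SamplePair]):
            results = []
            for pair in pairs:
                src_in = AlignmentSource(pair.input_path, "INPUT", pair.input_id)
                src_ip = AlignmentSource(pair.ip_path, "IP", pair.ip_id)
                genic_counts = build_count_table(
                    src_in, src_ip, genes, cfg.counting, cfg.workers
                )
                igr_counts = build_count_table(
                    src_in, src_ip, igrs, cfg.counting, cfg.workers
                )
                results.append((pair, genic_counts, igr_counts))
            return results

        try:
            tagged_counts = count_pairs(cfg.pairs)
            untagged_counts = count_pairs(cfg.untagged_pairs)
        except (ChipCompartError, OSError, ValueError) as exc:
            raise _stage("count")(exc) from exc

        # --- stage: enrich ---
        try:
            norms: dict[str, SampleNormalization] = {}

            def norm_for(sample_id: str, path: Path) -> SampleNormalization:
                if sample_id not in norms:
                    norms[sample_id] = _normalization(cfg, sample_id, path)
                return norms[sample_id]

            def replicate_tables(counted):
                genic_reps, igr_reps = [], []
                for pair, genic_counts, igr_counts in counted:
                    n_in = norm_for(pair.input_id, pair.input_path)
                    n_ip = norm_for(pair.ip_id, pair.ip_path)
                    genic_reps.append(
                        replicate_enrichment(genic_counts, n_in, n_ip, cfg.pseudocount)
                    )
                    igr_reps.append(
                        replicate_enrichment(igr_counts, n_in, n_ip, cfg.pseudocount)
                    )
                return genic_reps, igr_reps

            tagged_genic, tagged_igr = replicate_tables(tagged_counts)
            untagged_genic, untagged_igr = replicate_tables(untagged_counts)

            genic_table = enrichment_table(
                tagged_genic, untagged_genic, cfg.threshold, "genic",
                cfg.min_input_reads,
            )
            igr_table = enrichment_table(
                tagged_igr, untagged_igr, cfg.threshold, "intergenic",
                cfg.min_input_reads,
            )
            summary = summarize_compartments(genic_table, igr_table)
        except (ChipCompartError, ValueError) as exc:
            raise _stage("enrich")(exc) from exc

        # --- stage: write ---
        outputs: dict[str, Path] = {}
        for pair, genic_counts, igr_counts in tagged_counts + untagged_counts:
            stem = f"FINAL.table.{_sanitize(pair.input_id)}-{_sanitize(pair.ip_id)}"
            outputs[f"{stem}.genic"] = emit(genic_counts, f"{stem}.genic.csv")
            outputs[f"{stem}.intergenic"] = emit(igr_counts, f"{stem}.intergenic.csv")
        outputs["genic_enrichment"] = emit(genic_table, "genic_enrichment.csv")
        outputs["intergenic_enrichment"] = emit(igr_table, "intergenic_enrichment.csv")
        outputs["negative_gaps"] = emit(
            cio.negative_gap_frame(negatives), "negative_gaps.csv"
        )
        outputs["summary"] = emit(summary, "compartment_summary.csv")

        meta = outdir / "run_metadata.txt"
        n_pass1 = int((genic_table["pass_filter1"].sum()
                       + igr_table["pass_filter1"].sum()))
        n_pass2 = int((genic_table["pass_filter2"].sum()
                       + igr_table["pass_filter2"].sum()))
        meta.write_text(
            "\n".join(
                [
                    f"chipcompart v{__version__}",
                    f"config_hash={cio.config_hash(resolved)}",
                    "config=" + json.dumps(resolved, sort_keys=True, default=str),
                    "clusters_pf="
                    + json.dumps(
                        {
                            s: {"value": n.clusters_pf, "provenance": n.provenance}
                            for s, n in norms.items()
                        },
                        sort_keys=True,
                    ),
                    f"n_genic_regions={len(genes)}",
                    f"n_intergenic_regions={len(igrs)}",
                    f"n_negative_gap_exclusions={len(negatives)}",
                    f"n_pass_filter1={n_pass1}",
                    f"n_pass_filter2={n_pass2}",
                ]
            )
            + "\n"
        )
        outputs["metadata"] = meta
        return outputs
    except Exception:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise
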