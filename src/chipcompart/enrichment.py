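"""Normalization, IP/INPUT enrichment, background filtering and summaries.

The post-processing model is deliberately a ratio-and-threshold scheme, not
a statistical test:

1. raw per-region counts are divided by the per-sample sequencing depth —
   the "clusters PF" total (clusters passing Illumina's Chastity filter),
   or an equivalent total-sequences value;
2. enrichment is normalized IP divided by normalized INPUT; a region with
   zero normalized INPUT has *undefined* enrichment (NaN) unless a
   pseudocount is requested;
3. Filter 1 subtracts the mean enrichment observed for the same region in
   untagged (mock-control) samples, removing nonspecific binding;
4. replicate enrichments are averaged (a region undefined in any tagged
   replicate stays undefined);
5. Filter 2 keeps regions whose final value is >= the threshold
   (default 1.5, boundary inclusive).

Because the background subtraction is linear, subtracting per replicate and
then averaging equals averaging and then subtracting; the pipeline subtracts
first, per replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

logger = logging.getLogger(__name__)

REGION_KEY = ["contig", "start", "end", "region_id"]

DEFAULT_THRESHOLD = 1.5

Provenance = Literal["user-supplied", "fastq-total", "alignment-total"]


@dataclass(frozen=True)
class SampleNormalization:
    """Per-sample depth denominator and where it came from."""

    sample_id: str
    clusters_pf: int
    provenance: Provenance = "user-supplied"

    def __post_init__(self) -> None:
        if self.clusters_pf < 1:
            raise DataError(
                f"clusters_pf for {self.sample_id!r} must be >= 1, "
                f"got {self.clusters_pf}"
            )


def normalize_count(raw: float, norm: SampleNormalization) -> float:
    """Depth-normalize a raw count: ``raw / clusters_pf`` (no million-scaling)."""
    if raw < 0:
        raise DataError(f"negative raw count {raw}")
    return raw / norm.clusters_pf


def compute_enrichment(norm_ip: float, norm_input: float) -> float:
    """IP/INPUT ratio; NaN (undefined) when normalized INPUT is zero."""
    if norm_ip < 0 or norm_input < 0:
        raise DataError("normalized counts must be non-negative")
    if norm_input == 0:
        return float("nan")
    return norm_ip / norm_input


def subtract_untagged(enrichment: float, untagged_mean: float) -> float:
    """Filter 1: remove the mock-control background (result may be negative)."""
    return enrichment - untagged_mean


def apply_threshold(values: pd.Series, threshold: float = DEFAULT_THRESHOLD) -> pd.Series:
    """Filter 2: boolean pass flags, ``value >= threshold``; NaN fails."""
    if threshold <= 0:
        raise DataError(f"threshold must be positive, got {threshold}")
    return values.ge(threshold).fillna(False).astype(bool)


def _check_same_regions(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    ref = tables[0][REGION_KEY]
    for t in tables[1:]:
        if len(t) != len(ref) or not t[REGION_KEY].reset_index(drop=True).equals(
            ref.reset_index(drop=True)
        ):
            a = set(map(tuple, ref.values))
            b = set(map(tuple, t[REGION_KEY].values))
            raise DataError(
                f"region sets differ between tables: "
                f"{len(a - b)} only in first, {len(b - a)} only in other"
            )
    return ref.reset_index(drop=True)


def replicate_enrichment(
    counts: pd.DataFrame,
    input_norm: SampleNormalization,
    ip_norm: SampleNormalization,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-region normalized counts and enrichment for one INPUT/IP pair.

    *counts* is a count table with ``input_count``/``ip_count`` columns.
    When *pseudocount* is set it is added to both normalized values, making
    every enrichment defined.
    """
    df = counts[REGION_KEY + ["input_count", "ip_count"]].copy()
    norm_input = counts["input_count"] / input_norm.clusters_pf
    norm_ip = counts["ip_count"] / ip_norm.clusters_pf
    if pseudocount is not None:
        norm_input = norm_input + pseudocount
        norm_ip = norm_ip + pseudocount
    df["norm_input"] = norm_input
    df["norm_ip"] = norm_ip
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = np.where(norm_input > 0, norm_ip / norm_input, np.nan)
    df["enrichment"] = enr
    df.attrs["input_sample"] = input_norm.sample_id
    df.attrs["ip_sample"] = ip_norm.sample_id
    df.attrs["clusters_pf"] = {
        input_norm.sample_id: (input_norm.clusters_pf, input_norm.provenance),
        ip_norm.sample_id: (ip_norm.clusters_pf, ip_norm.provenance),
    }
    return df


def untagged_background(untagged_tables: Sequence[pd.DataFrame]) -> pd.Series:
    """Per-region mean enrichment across untagged replicates.

    The mean is over the untagged replicates in which the region's
    enrichment is defined; a region with no defined value (or with no
    untagged samples at all) contributes background 0.
    """
    if not untagged_tables:
        return None  # arbitrary-cutoff mode: Filter 1 skipped
    _check_same_regions(untagged_tables)
    stacked = np.column_stack([t["enrichment"].to_numpy() for t in untagged_tables])
    defined = ~np.isnan(stacked)
    n_defined = defined.sum(axis=1)
    total = np.where(defined, stacked, 0.0).sum(axis=1)
    # all-undefined rows contribute background 0 (absent from the untagged table)
    mean = np.divide(total, n_defined, out=np.full(len(stacked), np.nan),
                     where=n_defined > 0)
    return pd.Series(np.nan_to_num(mean, nan=0.0), name="untagged_mean")


def average_replicates(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Arithmetic mean of per-replicate enrichments over identical regions.

    A region undefined in any replicate is undefined in the mean (logged).
    A single table averages to itself.
    """
    if not tables:
        raise DataError("average_replicates: no tables given")
    keys = _check_same_regions(tables)
    df = keys.copy()
    stacked = np.column_stack([t["enrichment"].to_numpy(float) for t in tables])
    mean = stacked.mean(axis=1)  # propagates NaN: undefined anywhere => undefined
    n_undef = int(np.isnan(mean).sum())
    if n_undef:
        logger.info("average_replicates: %d regions undefined in >=1 replicate", n_undef)
    df["enrichment"] = mean
    return df


def enrichment_table(
    tagged: Sequence[pd.DataFrame],
    untagged: Sequence[pd.DataFrame] = (),
    threshold: float = DEFAULT_THRESHOLD,
    compartment: str = "genic",
    min_input_reads: int | None = None,
) -> pd.DataFrame:
    """Full per-region post-processing table for one compartment.

    Parameters
    ----------
    tagged:
        One replicate-enrichment table (:func:`replicate_enrichment`) per
        tagged INPUT/IP pair, over identical regions.
    untagged:
        Same, for untagged (mock-control) pairs; empty switches to
        arbitrary-cutoff mode in which Filter 1 is skipped.
    threshold:
        Filter 2 cutoff on the final enrichment (inclusive).
    min_input_reads:
        Advisory only: flags regions whose raw INPUT count falls below this
        in any replicate (`low_input` column) because ratio estimates from
        very few reads can clear the threshold without being meaningfully
        enriched.  Never drops anything.

    Returns the table with per-replicate enrichment columns, the untagged
    background, the averaged and background-subtracted values, and the
    ``pass_filter1``/``pass_filter2`` flags.
    """
    if not tagged:
        raise DataError("enrichment_table: no tagged replicates")
    keys = _check_same_regions(list(tagged) + list(untagged))
    df = keys.copy()

    background = untagged_background(untagged)
    bg = background.to_numpy() if background is not None else np.zeros(len(df))
    df["untagged_mean"] = bg

    subtracted_cols = []
    for t in tagged:
        sid = t.attrs.get("ip_sample", f"rep{len(subtracted_cols) + 1}")
        df[f"norm_input_{sid}"] = t["norm_input"].to_numpy()
        df[f"norm_ip_{sid}"] = t["norm_ip"].to_numpy()
        df[f"enrichment_{sid}"] = t["enrichment"].to_numpy(float)
        df[f"enrichment_minus_untagged_{sid}"] = t["enrichment"].to_numpy(float) - bg
        subtracted_cols.append(f"enrichment_minus_untagged_{sid}")

    enr_cols = [c for c in df.columns if c.startswith("enrichment_") and
                not c.startswith("enrichment_minus")]
    df["enrichment_avg"] = df[enr_cols].to_numpy(float).mean(axis=1)
    df["final_enrichment"] = df[subtracted_cols].to_numpy(float).mean(axis=1)

    df["norm_ip_mean"] = df[[c for c in df.columns if c.startswith("norm_ip_") and
                             c != "norm_ip_mean"]].to_numpy(float).mean(axis=1)

    defined = ~df["enrichment_avg"].isna()
    if untagged:
        df["pass_filter1"] = defined & (df["final_enrichment"] > 0)
    else:
        df["pass_filter1"] = defined
    df["pass_filter2"] = apply_threshold(df["final_enrichment"], threshold)

    if min_input_reads is not None:
        low = np.zeros(len(df), dtype=bool)
        for t in tagged:
            low |= t["input_count"].to_numpy() < min_input_reads
        df["low_input"] = low
    df.attrs["threshold"] = threshold
    df.attrs["compartment"] = compartment
    df.attrs["untagged_samples"] = [t.attrs.get("ip_sample", "?") for t in untagged]
    return df


def summarize_compartments(
    genic: pd.DataFrame, intergenic: pd.DataFrame
) -> pd.DataFrame:
    """Genic vs intergenic localization summary.

    For each compartment: total regions, regions passing both filters, the
    summed mean normalized IP signal over passing regions (the quantity the
    localization fractions are computed from) and over all regions, plus
    the cross-compartment fractions of passing regions and of passing
    normalized IP signal.
    """
    rows = []
    for name, df in (("genic", genic), ("intergenic", intergenic)):
        passing = df["pass_filter1"] & df["pass_filter2"]
        rows.append(
            {
                "compartment": name,
                "n_regions": len(df),
                "n_pass": int(passing.sum()),
                "norm_ip_pass": float(df.loc[passing, "norm_ip_mean"].sum()),
                "norm_ip_total": float(df["norm_ip_mean"].sum()),
            }
        )
    out = pd.DataFrame(rows)
    n_pass_total = out["n_pass"].sum()
    ip_pass_total = out["norm_ip_pass"].sum()
    out["fraction_regions"] = (
        out["n_pass"] / n_pass_total if n_pass_total else np.nan
    )
    out["fraction_reads"] = (
        out["norm_ip_pass"] / ip_pass_total if ip_pass_total else np.nan
    )
    return out
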