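"""Feature aggregation, breadth of coverage, and normalizations.

Counts live in feature-by-sample data frames.  Library sizes are the
total reads per sample (supplied externally, e.g. from the design
table) and may exceed column sums when not all reads map.  The log2
normalizations use a pseudocount-then-log convention on the CPM/CPKM
scale: ``log2(cpm + pseudocount)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from rumivir.errors import InputError


@dataclass
class AbundanceBundle:
    """Raw counts plus optional lengths and a normalized matrix."""

    counts: pd.DataFrame  # features x samples, integers
    lib_sizes: pd.Series  # per sample
    lengths: pd.Series | None = None  # bp per feature
    normalized: pd.DataFrame | None = None
    norm_tag: str | None = None

    def __post_init__(self) -> None:
        self.lib_sizes = self.lib_sizes.reindex(self.counts.columns)
        if self.lib_sizes.isna().any():
            raise InputError("library size missing for some samples")
        if (self.counts.sum(axis=0) > self.lib_sizes + 1e-9).any():
            raise InputError("column sums exceed library sizes")
        if self.lengths is not None:
            self.lengths = self.lengths.reindex(self.counts.index)
            if self.lengths.isna().any():
                raise InputError("length missing for some features")


def _member_lists(populations: pd.DataFrame) -> dict[str, list[str]]:
    return {pid: row["contigs"].split(",") for pid, row in populations.iterrows()}


def population_counts(
    contig_counts: pd.DataFrame,
    populations: pd.DataFrame,
    lib_sizes: pd.Series | None = None,
) -> AbundanceBundle:
    """Sum member-contig counts into population counts.

    ``lib_sizes`` defaults to the column sums of the full contig matrix
    (total mapped reads); pass the per-sample sequencing depth for the
    stricter total-reads convention.
    """
    members = _member_lists(populations)
    missing = {c for ms in members.values() for c in ms} - set(contig_counts.index)
    if missing:
        raise InputError(f"contigs absent from count matrix: {sorted(missing)[:5]}")
    rows = {pid: contig_counts.loc[ms].sum(axis=0) for pid, ms in members.items()}
    counts = pd.DataFrame(rows).T.reindex(populations.index)
    if lib_sizes is None:
        lib_sizes = contig_counts.sum(axis=0)
    lengths = populations["cumulative_length_bp"].astype(float)
    return AbundanceBundle(counts=counts, lib_sizes=lib_sizes, lengths=lengths)


def normalize_log2cpm(bundle: AbundanceBundle, pseudocount: float = 1.0) -> AbundanceBundle:
    """log2(counts-per-million + pseudocount)."""
    if (bundle.lib_sizes <= 0).any():
        raise InputError("library sizes must be positive")
    cpm = bundle.counts / (bundle.lib_sizes / 1e6)
    return replace(bundle, normalized=np.log2(cpm + pseudocount), norm_tag="log2CPM")


def normalize_log2cpkm(bundle: AbundanceBundle, pseudocount: float = 1.0) -> AbundanceBundle:
    """log2(counts per kilobase per million + pseudocount).

    Invariant under jointly scaling a sample's counts and library size.
    """
    if bundle.lengths is None:
        raise InputError("feature lengths required for CPKM")
    if (bundle.lib_sizes <= 0).any():
        raise InputError("library sizes must be positive")
    cpm = bundle.counts / (bundle.lib_sizes / 1e6)
    cpkm = cpm.div(bundle.lengths / 1e3, axis=0)
    return replace(bundle, normalized=np.log2(cpkm + pseudocount), norm_tag="log2CPKM")


def relative_abundance(bundle: AbundanceBundle) -> AbundanceBundle:
    """Raw counts divided by total reads per sample."""
    rel = bundle.counts / bundle.lib_sizes
    return replace(bundle, normalized=rel, norm_tag="relative")


def breadth(
    covered_bases: pd.DataFrame,
    populations: pd.DataFrame,
    contig_lengths: pd.Series,
) -> pd.DataFrame:
    """Population breadth = summed member covered bases / cumulative length."""
    aligned = contig_lengths.reindex(covered_bases.index)
    if aligned.isna().any():
        raise InputError("length missing for some contigs in covered_bases")
    if (covered_bases.gt(aligned, axis=0)).any().any():
        raise InputError("covered bases exceed contig length")
    members = _member_lists(populations)
    missing = {c for ms in members.values() for c in ms} - set(covered_bases.index)
    if missing:
        raise InputError(f"contigs absent from coverage matrix: {sorted(missing)[:5]}")
    rows = {
        pid: covered_bases.loc[ms].sum(axis=0) / populations.at[pid, "cumulative_length_bp"]
        for pid, ms in members.items()
    }
    out = pd.DataFrame(rows).T.reindex(populations.index)
    return out.clip(0.0, 1.0)


def family_abundance(bundle: AbundanceBundle, populations: pd.DataFrame) -> AbundanceBundle:
    """Aggregate classified populations to families, then log2 CPKM.

    Family counts are sums of member-population counts; family length is
    the summed cumulative length of members, so merging identical
    populations leaves CPKM unchanged.
    """
    if "family" not in populations.columns:
        raise InputError("populations lack a family column; run assign_taxonomy first")
    fam = populations["family"].dropna()
    counts = bundle.counts.loc[fam.index].groupby(fam).sum()
    lengths = populations.loc[fam.index, "cumulative_length_bp"].groupby(fam).sum().astype(float)
    out = AbundanceBundle(counts=counts, lib_sizes=bundle.lib_sizes, lengths=lengths)
    return normalize_log2cpkm(out)


def reads_recruited(bundle: AbundanceBundle) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample recruited fraction and per-feature recruitment summary.

    Returns ``(per_sample, per_feature)`` where ``per_sample`` is the
    column sum over library size and ``per_feature`` holds the max and
    mean percentage of a sample's reads recruited by each feature.
    """
    per_sample = bundle.counts.sum(axis=0) / bundle.lib_sizes
    pct = bundle.counts.div(bundle.lib_sizes, axis=1) * 100.0
    per_feature = pd.DataFrame(
        {"max_pct_reads": pct.max(axis=1), "mean_pct_reads": pct.mean(axis=1)}
    )
    return per_sample, per_feature


def pc_filter(
    orf_counts: pd.Series, abundance: pd.DataFrame, min_samples: int = 3
) -> pd.Index:
    """Protein-cluster retention: >= 2 ORFs, or a singleton seen in
    at least ``min_samples`` samples."""
    orf_counts = orf_counts.reindex(abundance.index)
    present = (abundance > 0).sum(axis=1)
    keep = (orf_counts >= 2) | ((orf_counts == 1) & (present >= min_samples))
    return abundance.index[keep]


def summarize_fraction(numerator: int, denominator: int) -> float:
    """Percentage rounded to one decimal, as printed in summaries."""
    if denominator == 0:
        raise InputError("zero denominator")
    return round(100.0 * numerator / denominator, 1)
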