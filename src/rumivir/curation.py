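"""Delineate and decontaminate viral populations from binned contigs.

A contig catalog records per-contig length, a viral call, and marker
annotations (terL and bacterial single-copy-gene counts).  Candidate
binnings are scored by the number of bins carrying duplicate terL
genes; the curated population set applies, in order, multi-terL
removal with long-contig rescue, bacterial-SCG removal, and a
cumulative-length floor.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from rumivir.errors import InputError

CATALOG_COLUMNS = ("length_bp", "viral_flag", "terl_count", "scg_count")


def build_catalog(
    contigs: pd.DataFrame, markers: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble a contig catalog from a contig table and marker hits.

    ``contigs`` needs columns ``contig_id``/index, ``length_bp`` and
    ``viral_flag``; ``markers`` is long-format ``(contig_id,
    marker_type)`` with types ``terL`` and ``bacterial_scg``.
    """
    cat = contigs.copy()
    if "contig_id" in cat.columns:
        cat = cat.set_index("contig_id")
    if cat.index.duplicated().any():
        raise InputError("duplicate contig ids")
    if (cat["length_bp"] <= 0).any():
        raise InputError("contig lengths must be positive")
    if markers is not None:
        terl = markers.loc[markers["marker_type"] == "terL", "contig_id"].value_counts()
        scg = markers.loc[
            markers["marker_type"] == "bacterial_scg", "contig_id"
        ].value_counts()
        cat["terl_count"] = cat.index.map(terl).fillna(0).astype(int)
        cat["scg_count"] = cat.index.map(scg).fillna(0).astype(int)
    for col in ("terl_count", "scg_count"):
        if col not in cat.columns:
            cat[col] = 0
    return cat


def filter_viral_contigs(catalog: pd.DataFrame, min_length: int = 1000) -> pd.DataFrame:
    """Retain contigs strictly longer than ``min_length`` with a viral call."""
    keep = (catalog["length_bp"] > min_length) & catalog["viral_flag"].astype(bool)
    out = catalog.loc[keep]
    if out.empty:
        warnings.warn("no contigs passed the viral length filter", stacklevel=2)
    return out


def _bin_terl_profile(binning: Mapping[str, str], catalog: pd.DataFrame) -> tuple[int, int]:
    """(number of bins with >= 2 terL, number with exactly one)."""
    terl = catalog["terl_count"]
    totals: dict[str, int] = {}
    for contig, bin_id in binning.items():
        totals[bin_id] = totals.get(bin_id, 0) + int(terl.get(contig, 0))
    multi = sum(1 for t in totals.values() if t >= 2)
    single = sum(1 for t in totals.values() if t == 1)
    return multi, single


def score_binning(
    candidate_binnings: Sequence[Mapping[str, str]], catalog: pd.DataFrame
) -> tuple[Mapping[str, str], list[int]]:
    """Choose the binning that minimizes duplicate-terL bins.

    Returns the winning candidate and the per-candidate counts of bins
    containing two or more terL genes.  Ties go to the candidate with
    more single-terL bins, then to input order.
    """
    if not candidate_binnings:
        raise InputError("need at least one candidate binning")
    profiles = [_bin_terl_profile(b, catalog) for b in candidate_binnings]
    scores = [p[0] for p in profiles]
    best = min(range(len(profiles)), key=lambda i: (profiles[i][0], -profiles[i][1], i))
    return candidate_binnings[best], scores


def curate_bins(
    binning: Mapping[str, str],
    catalog: pd.DataFrame,
    rescue_min_length: int = 10000,
    min_population_length: int = 10000,
    scg_on_rescued: bool = True,
) -> pd.DataFrame:
    """Apply the population-delineation rules to a chosen binning.

    In order: (1) bins with two or more terL genes are removed, but each
    member contig at least ``rescue_min_length`` long becomes its own
    singleton population; (2) bins containing a bacterial single-copy
    gene are removed with no rescue (rescued singletons are also subject
    to this check when ``scg_on_rescued``); (3) populations shorter than
    ``min_population_length`` cumulative bp are removed.

    Returns a population table indexed by ``population_id`` with columns
    ``contigs`` (comma-joined), ``cumulative_length_bp`` and
    ``provenance`` (``bin`` or ``rescued_contig``).  The result is
    independent of input ordering.
    """
    missing = [c for c in binning if c not in catalog.index]
    if missing:
        raise InputError(f"binning references unknown contigs: {missing[:5]}")

    members: dict[str, list[str]] = {}
    for contig in sorted(binning):
        members.setdefault(binning[contig], []).append(contig)

    terl = catalog["terl_count"]
    scg = catalog["scg_count"]
    length = catalog["length_bp"]

    rows = []
    for bin_id in sorted(members):
        contigs = members[bin_id]
        n_terl = int(sum(terl[c] for c in contigs))
        if n_terl >= 2:
            for c in contigs:
                if length[c] < rescue_min_length or terl[c] >= 2:
                    continue
                if scg_on_rescued and scg[c] > 0:
                    continue
                rows.append(
                    {
                        "population_id": f"rescue_{c}",
                        "contigs": c,
                        "cumulative_length_bp": int(length[c]),
                        "provenance": "rescued_contig",
                    }
                )
            continue
        if int(sum(scg[c] for c in contigs)) >= 1:
            continue
        rows.append(
            {
                "population_id": bin_id,
                "contigs": ",".join(contigs),
                "cumulative_length_bp": int(sum(length[c] for c in contigs)),
                "provenance": "bin",
            }
        )

    pops = pd.DataFrame(
        rows, columns=["population_id", "contigs", "cumulative_length_bp", "provenance"]
    ).set_index("population_id")
    pops = pops.loc[pops["cumulative_length_bp"] >= min_population_length]
    validate_populations(pops, catalog, check_scg=scg_on_rescued)
    return pops


def validate_populations(
    populations: pd.DataFrame,
    catalog: pd.DataFrame | None = None,
    check_scg: bool = True,
) -> None:
    """Assert the population-set invariants; raise ``InputError`` on breach."""
    seen: set[str] = set()
    for pid, row in populations.iterrows():
        contigs = row["contigs"].split(",")
        if seen & set(contigs):
            raise InputError(f"contig shared between populations at {pid}")
        seen.update(contigs)
        if catalog is not None:
            if int(sum(catalog["terl_count"][c] for c in contigs)) > 1:
                raise InputError(f"population {pid} has multiple terL genes")
            if check_scg and int(sum(catalog["scg_count"][c] for c in contigs)) > 0:
                raise InputError(f"population {pid} contains a bacterial SCG")
            cum = int(sum(catalog["length_bp"][c] for c in contigs))
            if cum != int(row["cumulative_length_bp"]):
                raise InputError(f"population {pid} cumulative length mismatch")


def assign_taxonomy(
    populations: pd.DataFrame,
    hits: pd.DataFrame,
    catalog: pd.DataFrame,
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
) -> pd.DataFrame:
    """Assign population taxonomy via the longest classified contig.

    Hits failing ``evalue <= max_evalue`` or ``bitscore >=
    min_bitscore`` are discarded.  Per contig the best surviving hit
    wins (highest bit-score, then lowest E-value, then lexicographic
    taxon id); the population inherits the taxonomy of its longest
    contig that has any surviving hit.  Populations without surviving
    hits stay unclassified (NA taxon/family).
    """
    ok = hits.loc[(hits["evalue"] <= max_evalue) & (hits["bitscore"] >= min_bitscore)]
    best: dict[str, pd.Series] = {}
    for _, h in ok.sort_values(
        ["contig_id", "bitscore", "evalue", "ref_taxon"],
        ascending=[True, False, True, True],
    ).iterrows():
        best.setdefault(h["contig_id"], h)

    out = populations.copy()
    taxa, families = [], []
    for _, row in out.iterrows():
        contigs = row["contigs"].split(",")
        classified = [c for c in contigs if c in best]
        if not classified:
            taxa.append(np.nan)
            families.append(np.nan)
            continue
        longest = max(classified, key=lambda c: (catalog["length_bp"][c], c))
        taxa.append(best[longest]["ref_taxon"])
        families.append(best[longest]["family"])
    out["taxon"] = taxa
    out["family"] = families
    return out
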