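"""Detection of near-ubiquitous ("core") viral populations."""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from rumivir.abundance import AbundanceBundle
from rumivir.errors import InputError


@dataclass
class CoreCriterion:
    """Presence = breadth >= ``presence_breadth_min`` in a sample;
    core = present in at least ``prevalence_min`` of samples."""

    presence_breadth_min: float = 0.15
    prevalence_min: float = 0.80

    def __post_init__(self) -> None:
        if not (0.0 <= self.presence_breadth_min and 0.0 <= self.prevalence_min <= 1.0):
            raise InputError("criterion thresholds out of range")


def detect_core(
    breadth: pd.DataFrame,
    bundle: AbundanceBundle,
    criterion: CoreCriterion = CoreCriterion(),
) -> pd.DataFrame:
    """Core-population table from a breadth matrix and counts.

    A population is core iff the number of samples where its breadth
    meets the presence threshold is at least
    ``ceil(prevalence_min * n_samples)`` (boundary inclusive).  For each
    core population the maximum and mean percentage of a sample's reads
    recruited are reported.
    """
    if breadth.empty:
        raise InputError("empty breadth matrix")
    common = breadth.index.intersection(bundle.counts.index)
    if len(common) != len(breadth.index):
        raise InputError("breadth and counts disagree on populations")

    n = breadth.shape[1]
    # tiny slack so 0.8 * 20 == 16 despite binary rounding; at least one
    # sample so prevalence 0 means "present somewhere"
    needed = max(1, math.ceil(criterion.prevalence_min * n - 1e-9))
    present = (breadth >= criterion.presence_breadth_min).sum(axis=1)
    core_ids = breadth.index[present >= needed]

    pct = bundle.counts.div(bundle.lib_sizes, axis=1) * 100.0
    out = pd.DataFrame(
        {
            "n_present": present.loc[core_ids].astype(int),
            "max_pct_reads": pct.loc[core_ids].max(axis=1),
            "mean_pct_reads": pct.loc[core_ids].mean(axis=1),
        },
        index=core_ids,
    )
    out.index.name = "population_id"
    return out
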