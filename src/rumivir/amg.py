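"""Class-I auxiliary metabolic gene classification and differential tests.

A KO qualifies as a Class-I AMG when it belongs to at least one KEGG
metabolic pathway and is not confined to pathways commonly associated
with viral genomes — unless it is additionally involved in carbon
metabolism, nitrogen metabolism or the pentose phosphate pathway, which
rescues it.  Differential abundance between two diets uses a simplified
negative-binomial Wald test whose size factors come from the full ORF
matrix, not the AMG subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from rumivir.abundance import summarize_fraction
from rumivir.errors import InputError

#: Pathways whose functions are commonly viral and therefore excluded.
EXCLUDED_PATHWAYS = frozenset(
    {
        "ko03440",  # homologous recombination
        "ko03430",  # mismatch repair
        "ko00970",  # aminoacyl-tRNA biosynthesis
        "ko00230",  # purine metabolism
        "ko00240",  # pyrimidine metabolism
        "ko03030",  # DNA replication
        "ko00520",  # amino/nucleotide sugar metabolism
        "ko01230",  # biosynthesis of amino acids
        "ko03410",  # base excision repair
        "ko00270",  # cysteine and methionine metabolism
        "ko00330",  # arginine and proline metabolism
    }
)

#: Membership in any of these overrides the exclusion.
RESCUE_PATHWAYS = frozenset({"ko01200", "ko00910", "ko00030"})


@dataclass
class PathwayRule:
    excluded_pathways: frozenset = EXCLUDED_PATHWAYS
    rescue_pathways: frozenset = RESCUE_PATHWAYS
    require_metabolic: bool = True

    def __post_init__(self) -> None:
        if self.excluded_pathways & self.rescue_pathways:
            raise InputError("excluded and rescue pathway sets overlap")

    def is_class1(self, pathways: set, metabolic: set) -> bool:
        """Pure set-logic Class-I decision for one KO."""
        if self.require_metabolic and not (pathways & metabolic):
            return False
        if pathways & self.excluded_pathways and not (pathways & self.rescue_pathways):
            return False
        return True


@dataclass
class AmgClassification:
    table: pd.DataFrame  # KO x samples abundances, plus n_contigs column
    unmapped: list = field(default_factory=list)


def classify_class1(
    annotations: pd.DataFrame,
    ko_pathways: pd.DataFrame,
    orf_counts: pd.DataFrame,
    rule: PathwayRule | None = None,
    min_contig_length: int = 1500,
    max_evalue: float = 1e-5,
    min_bitscore: float = 50.0,
) -> AmgClassification:
    """Classify Class-I AMGs from ORF annotations on viral contigs.

    Keeps ORF hits passing the homology thresholds on bona-fide viral
    contigs strictly longer than ``min_contig_length``; per-KO abundance
    is the sum of its ORFs' counts.  KOs absent from ``ko_pathways`` go
    to the unmapped report rather than being classified.
    """
    rule = rule or PathwayRule()
    ok = annotations.loc[
        (annotations["evalue"] <= max_evalue)
        & (annotations["bitscore"] >= min_bitscore)
        & annotations["viral_bona_fide"].astype(bool)
        & (annotations["contig_length"] > min_contig_length)
    ]

    path_sets = ko_pathways.groupby("ko")["pathway"].agg(set)
    metabolic = set(ko_pathways.loc[ko_pathways["is_metabolic"].astype(bool), "pathway"])

    unmapped = sorted(set(ok["ko"]) - set(path_sets.index))
    mapped = ok.loc[ok["ko"].isin(path_sets.index)]

    rows = {}
    contig_support = {}
    for ko, grp in mapped.groupby("ko"):
        if not rule.is_class1(set(path_sets[ko]), metabolic):
            continue
        orfs = [o for o in grp["orf_id"] if o in orf_counts.index]
        if not orfs:
            continue
        rows[ko] = orf_counts.loc[orfs].sum(axis=0)
        contig_support[ko] = grp["contig_id"].nunique()

    if rows:
        table = pd.DataFrame(rows).T.sort_index()
        table.insert(0, "n_contigs", pd.Series(contig_support))
    else:
        table = pd.DataFrame(columns=["n_contigs", *orf_counts.columns])
    table.index.name = "ko"
    return AmgClassification(table=table, unmapped=unmapped)


def size_factors(orf_counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors from the full ORF matrix.

    For each ORF with an all-positive row, the geometric mean across
    samples is the reference; a sample's factor is the median ratio of
    its counts to the references.
    """
    mat = orf_counts.to_numpy(float)
    with np.errstate(divide="ignore"):
        logs = np.log(mat)
    finite = np.isfinite(logs).all(axis=1)
    if not finite.any():
        raise InputError("no ORF has nonzero counts in every sample")
    ref = np.exp(logs[finite].mean(axis=1))
    ratios = mat[finite] / ref[:, None]
    return pd.Series(np.median(ratios, axis=0), index=orf_counts.columns)


def diff_test(
    amg_counts: pd.DataFrame,
    factors: pd.Series,
    groups: pd.Series,
    fdr: float = 0.05,
    min_dispersion: float = 1e-8,
    shrink_dispersion: bool = False,
) -> pd.DataFrame:
    """Negative-binomial Wald test between two groups of samples.

    Counts are scaled by the size factors; per-feature dispersion is
    estimated by method of moments from within-group variability and
    floored at ``min_dispersion`` (optionally shrunk halfway toward the
    across-feature median).  The Wald statistic on
    the log fold-change is referred to a t distribution with
    ``n - 2`` degrees of freedom; P-values are Benjamini-Hochberg
    adjusted.

    Raises
    ------
    InputError
        Unless ``groups`` defines exactly two levels with at least two
        samples each.
    """
    groups = groups.loc[amg_counts.columns]
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise InputError(f"need exactly two groups, got {levels}")
    idx1 = groups.index[groups == levels[0]]
    idx2 = groups.index[groups == levels[1]]
    if len(idx1) < 2 or len(idx2) < 2:
        raise InputError("each group needs at least two samples")

    s = factors.loc[amg_counts.columns].to_numpy(float)
    q = amg_counts.to_numpy(float) / s[None, :]
    m1 = q[:, [amg_counts.columns.get_loc(c) for c in idx1]]
    m2 = q[:, [amg_counts.columns.get_loc(c) for c in idx2]]
    n1, n2 = m1.shape[1], m2.shape[1]
    mu1 = m1.mean(axis=1)
    mu2 = m2.mean(axis=1)

    # method-of-moments dispersion from pooled within-group variance:
    # Var(q) ~= mu/s + alpha mu^2
    inv_s_mean = float(np.mean(1.0 / s))
    ss_within = ((m1 - mu1[:, None]) ** 2).sum(axis=1) + ((m2 - mu2[:, None]) ** 2).sum(axis=1)
    var_within = ss_within / (n1 + n2 - 2)
    mu_bar = (n1 * mu1 + n2 * mu2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        alpha = (var_within - mu_bar * inv_s_mean) / mu_bar**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.maximum(alpha, min_dispersion)
    if shrink_dispersion and len(alpha) >= 3:
        common = float(np.median(alpha))
        alpha = np.sqrt(alpha * max(common, min_dispersion))  # halfway in log space

    eps = 1e-8
    log_fc = np.log(np.maximum(mu2, eps)) - np.log(np.maximum(mu1, eps))
    var_log1 = (1.0 / n1) * (inv_s_mean / np.maximum(mu1, eps) + alpha)
    var_log2 = (1.0 / n2) * (inv_s_mean / np.maximum(mu2, eps) + alpha)
    se = np.sqrt(var_log1 + var_log2)
    both_zero = (mu1 < eps) & (mu2 < eps)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(both_zero, 0.0, log_fc / se)
    df = n1 + n2 - 2
    pvals = 2.0 * scipy.stats.t.sf(np.abs(stat), df)
    pvals = np.where(both_zero, 1.0, pvals)
    padj = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "base_mean": mu_bar,
            "log2FC": log_fc / np.log(2.0),
            "dispersion": alpha,
            "stat": stat,
            "P": pvals,
            "P_adj": padj,
            "significant": padj < fdr,
        },
        index=amg_counts.index,
    )


def singleton_prevalence(amg_table: pd.DataFrame) -> tuple[int, int, float]:
    """(n AMGs, n present in exactly one sample, percentage).

    Accepts the classification table (ignores the ``n_contigs`` column).
    """
    counts = amg_table.drop(columns=["n_contigs"], errors="ignore")
    n_amgs = len(counts)
    if n_amgs == 0:
        return 0, 0, 0.0
    n_single = int(((counts > 0).sum(axis=1) == 1).sum())
    return n_amgs, n_single, summarize_fraction(n_single, n_amgs)
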