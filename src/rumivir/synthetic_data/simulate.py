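"""Generators for every table the analysis pipeline consumes.

Abundance model: the log2 expected abundance of population ``p`` in
sample ``j`` is ``a_p + beta_p * (TDN_j - mean TDN) + u_steer(j)`` plus
Gaussian noise; reads are then drawn per sample as a multinomial with
the drawn library size, so column sums equal library sizes exactly.
Breadth of coverage follows the ``1 - exp(-depth)`` saturation curve.

Each output table draws from its own random stream derived from the
master seed, so adding tables never perturbs existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from rumivir.errors import InputError
from rumivir.synthetic_data.design import StudyDesign

_FAMILIES = ("Myoviridae", "Siphoviridae", "Podoviridae", "Mimiviridae")

# Pathway ids used by the Class-I AMG rule plus invented neutral ones.
_EXCLUDED_PATHWAYS = {
    "ko03440": False,  # value: counts as a KEGG *metabolic* pathway
    "ko03430": False,
    "ko00970": False,
    "ko00230": True,
    "ko00240": True,
    "ko03030": False,
    "ko00520": True,
    "ko01230": True,
    "ko03410": False,
    "ko00270": True,
    "ko00330": True,
}
_RESCUE_PATHWAYS = {"ko01200": True, "ko00910": True, "ko00030": True}
_NEUTRAL_METABOLIC = {"ko00010": True, "ko00500": True, "ko00790": True, "ko00750": True}
_NON_METABOLIC = {"ko03010": False, "ko03070": False, "ko02010": False}


@dataclass
class SimTruth:
    """Ground truth of a simulated dataset.

    ``populations`` carries one row per planted population (baseline
    ``a``, slope ``beta`` on centered TDN, core/responder flags);
    ``bins`` one row per planted bin including contaminants and their
    rule violations; ``expected_populations`` is the exact population
    id set a correct curation must produce.
    """

    populations: pd.DataFrame
    bins: pd.DataFrame | None = None
    expected_populations: set = field(default_factory=set)
    steer_effects: pd.Series | None = None
    library_sizes: pd.Series | None = None
    sigma: float = 0.0
    seed: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class ViralSimData:
    """Bundle of simulated virome inputs (see module docstring)."""

    catalog: pd.DataFrame
    candidate_binnings: list
    markers: pd.DataFrame
    hits: pd.DataFrame
    counts: pd.DataFrame
    covered_bases: pd.DataFrame
    truth: SimTruth


@dataclass
class AmgSimData:
    orf_ko: pd.DataFrame
    orf_counts: pd.DataFrame
    ko_pathways: pd.DataFrame
    truth: SimTruth


def _streams(seed: int, names: list[str]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


def _contig_lengths(rng: np.random.Generator, k: int) -> np.ndarray:
    """Log-normal lengths, median ~15 kbp, truncated below at 1 kbp."""
    lengths = rng.lognormal(mean=np.log(15000.0), sigma=0.6, size=k)
    return np.maximum(lengths, 1001.0).round().astype(int)


def simulate_viral_metagenome(
    design: StudyDesign,
    n_populations: int = 300,
    n_core: int = 14,
    n_responders: int = 40,
    n_contaminant_bins: int = 20,
    effect_size: float = 0.3,
    libsize_range: tuple[int, int] = (25000, 35000),
    seed: int = 0,
    sigma: float = 0.5,
    steer_sd: float = 0.25,
    core_boost: float = 6.0,
    read_length: int = 30,
    n_decoys: int = 20,
    n_candidates: int = 3,
) -> ViralSimData:
    """Simulate contigs, binnings, markers, counts and coverage.

    Every true population emits 1-5 contigs with cumulative length
    >= 10 kbp, exactly one terL marker and no bacterial single-copy
    gene; contaminant bins carry >= 2 terL genes and/or a bacterial SCG.
    Core populations receive a baseline boost large enough that their
    expected breadth exceeds 15% in every sample.

    Raises
    ------
    InputError
        If ``n_core + n_responders > n_populations`` or
        ``effect_size < 0``.
    """
    if n_core + n_responders > n_populations:
        raise InputError("n_core + n_responders must not exceed n_populations")
    if effect_size < 0:
        raise InputError("effect_size must be non-negative")

    rngs = _streams(seed, ["contigs", "bins", "params", "counts", "hits", "candidates"])
    rc, rb, rp, rn, rh, rcand = (
        rngs["contigs"],
        rngs["bins"],
        rngs["params"],
        rngs["counts"],
        rngs["hits"],
        rngs["candidates"],
    )

    contig_rows: list[dict] = []
    pop_rows: list[dict] = []
    bin_rows: list[dict] = []
    true_binning: dict[str, str] = {}
    cid = 0

    def new_contig(length, terl, scg, bin_id, viral=True):
        nonlocal cid
        cid += 1
        name = f"c{cid:05d}"
        contig_rows.append(
            {
                "contig_id": name,
                "length_bp": int(length),
                "viral_flag": bool(viral),
                "terl_count": int(terl),
                "scg_count": int(scg),
                "bin_id": bin_id,
            }
        )
        if bin_id is not None:
            true_binning[name] = bin_id
        return name

    # --- clean populations ------------------------------------------------
    for p in range(n_populations):
        bin_id = f"pop{p + 1:04d}"
        k = int(rc.integers(1, 6))
        lengths = _contig_lengths(rc, k)
        if lengths.sum() < 10000:
            lengths[lengths.argmax()] += 10000 - lengths.sum() + int(rc.integers(200, 2000))
        terl_at = int(rc.integers(k))
        members = [
            new_contig(lengths[i], terl=1 if i == terl_at else 0, scg=0, bin_id=bin_id)
            for i in range(k)
        ]
        pop_rows.append(
            {
                "population_id": bin_id,
                "contigs": ",".join(members),
                "cumulative_length_bp": int(lengths.sum()),
            }
        )
        bin_rows.append(
            {"bin_id": bin_id, "kind": "clean", "contigs": ",".join(members), "expected_rescues": ""}
        )

    # --- contaminant bins -------------------------------------------------
    expected_rescues_all: list[str] = []
    for b in range(n_contaminant_bins):
        bin_id = f"bad{b + 1:03d}"
        kind = ("multi_terl", "scg", "both")[int(rb.integers(3))]
        k = int(rb.integers(2, 5))
        lengths = _contig_lengths(rb, k)
        terl = np.zeros(k, int)
        scg = np.zeros(k, int)
        if kind in ("multi_terl", "both"):
            terl[rb.choice(k, size=2, replace=False)] = 1
        if kind in ("scg", "both"):
            scg[int(rb.integers(k))] = 1
            if kind == "scg":
                terl[int(rb.integers(k))] = 1  # looks like one genome, still contaminated
        members = [
            new_contig(lengths[i], terl=terl[i], scg=scg[i], bin_id=bin_id) for i in range(k)
        ]
        rescues = []
        if kind in ("multi_terl", "both"):
            # multi-terL bins are removed but long clean members survive
            # as singleton populations
            rescues = [
                m
                for i, m in enumerate(members)
                if lengths[i] >= 10000 and scg[i] == 0 and terl[i] <= 1
            ]
        expected_rescues_all.extend(rescues)
        bin_rows.append(
            {
                "bin_id": bin_id,
                "kind": kind,
                "contigs": ",".join(members),
                "expected_rescues": ",".join(rescues),
            }
        )

    # --- decoy contigs that the viral filter must drop --------------------
    for i in range(n_decoys):
        if i % 2 == 0:
            new_contig(int(rc.integers(300, 1001)), 0, 0, None, viral=True)
        else:
            new_contig(_contig_lengths(rc, 1)[0], 0, 0, None, viral=False)

    catalog = pd.DataFrame(contig_rows).set_index("contig_id")
    populations = pd.DataFrame(pop_rows).set_index("population_id")

    # --- candidate binnings ------------------------------------------------
    # The true binning plus degraded versions in which clean populations
    # are merged pairwise, creating extra duplicate-terL bins.
    candidates = [dict(true_binning)]
    pop_ids = list(populations.index)
    for c in range(1, max(1, n_candidates)):
        merged = dict(true_binning)
        n_merge = c * 2
        picks = rcand.choice(len(pop_ids), size=min(n_merge * 2, len(pop_ids)), replace=False)
        for a, bb in zip(picks[::2], picks[1::2]):
            keep, absorb = pop_ids[a], pop_ids[bb]
            for contig, bid in list(merged.items()):
                if bid == absorb:
                    merged[contig] = keep
        candidates.append(merged)
    order = rcand.permutation(len(candidates))
    candidates = [candidates[i] for i in order]
    true_candidate_index = int(np.argwhere(order == 0)[0, 0])

    markers = _markers_table(catalog)

    # --- planted effects ---------------------------------------------------
    tdn = design.covariate("tdn")
    x = (tdn - tdn.mean()).to_numpy()
    steers = design.factor("steer")
    steer_ids = sorted(set(steers))
    u = pd.Series(rp.normal(0.0, steer_sd, len(steer_ids)), index=steer_ids)

    a = rp.normal(0.0, 0.4, n_populations)
    a[:n_core] = rp.normal(core_boost, 0.1, n_core)
    beta = np.zeros(n_populations)
    # balanced signs so responders cannot tilt per-sample totals with TDN
    signs = np.ones(n_responders)
    signs[: n_responders // 2] = -1.0
    rp.shuffle(signs)
    beta[n_core : n_core + n_responders] = effect_size * signs

    populations["a"] = a
    populations["beta"] = beta
    populations["is_core"] = np.arange(n_populations) < n_core
    populations["is_responder"] = beta != 0.0

    # --- counts -----------------------------------------------------------
    samples = design.sample_ids
    n_samples = len(samples)
    libsizes = pd.Series(
        rn.integers(libsize_range[0], libsize_range[1] + 1, n_samples), index=samples
    )

    cum_len = populations["cumulative_length_bp"].to_numpy(float)
    # per-population log2 mean for each sample
    u_j = np.array([u[s] for s in steers])
    eta = (
        a[:, None]
        + beta[:, None] * x[None, :]
        + u_j[None, :]
        + rn.normal(0.0, sigma, (n_populations, n_samples))
    )
    # length factor keeps per-base depth (and so breadth) independent of
    # genome length: longer populations recruit proportionally more reads
    pop_weight = np.exp2(eta) * (cum_len[:, None] / 15000.0)

    # spread population weight over member contigs by length
    contig_ids = list(catalog.index)
    weights = np.zeros((len(contig_ids), n_samples))
    pos = {c: i for i, c in enumerate(contig_ids)}
    lengths_all = catalog["length_bp"].to_numpy(float)
    for p, (pid, row) in enumerate(populations.iterrows()):
        members = row["contigs"].split(",")
        lens = np.array([catalog.at[m, "length_bp"] for m in members], float)
        share = lens / lens.sum()
        for m, s in zip(members, share):
            weights[pos[m], :] = pop_weight[p, :] * s
    # contaminant & decoy contigs: weak, diet-independent abundance
    unassigned = [c for c in contig_ids if weights[pos[c], :].sum() == 0]
    if unassigned:
        w0 = np.exp2(rn.normal(-2.0, 0.5, len(unassigned)))
        for c, w in zip(unassigned, w0):
            weights[pos[c], :] = w * lengths_all[pos[c]] / 15000.0

    counts = np.zeros((len(contig_ids), n_samples), dtype=int)
    for j, s in enumerate(samples):
        probs = weights[:, j] / weights[:, j].sum()
        counts[:, j] = rn.multinomial(libsizes[s], probs)
    counts_df = pd.DataFrame(counts, index=contig_ids, columns=samples)

    depth = counts * read_length / lengths_all[:, None]
    breadth = 1.0 - np.exp(-depth)
    covered = np.floor(breadth * lengths_all[:, None]).astype(int)
    covered_df = pd.DataFrame(covered, index=contig_ids, columns=samples)

    hits = _hits_table(rh, populations, catalog)

    bins_df = pd.DataFrame(bin_rows).set_index("bin_id")
    expected = set(populations.index) | {f"rescue_{c}" for c in expected_rescues_all}
    truth = SimTruth(
        populations=populations,
        bins=bins_df,
        expected_populations=expected,
        steer_effects=u,
        library_sizes=libsizes,
        sigma=sigma,
        seed=seed,
        extras={"read_length": read_length, "tdn_centered": pd.Series(x, index=samples)},
    )
    return ViralSimData(
        catalog=catalog,
        candidate_binnings=candidates,
        markers=markers,
        hits=hits,
        counts=counts_df,
        covered_bases=covered_df,
        truth=truth,
    )


def _markers_table(catalog: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for contig, r in catalog.iterrows():
        rows.extend({"contig_id": contig, "marker_type": "terL"} for _ in range(r["terl_count"]))
        rows.extend(
            {"contig_id": contig, "marker_type": "bacterial_scg"} for _ in range(r["scg_count"])
        )
    return pd.DataFrame(rows, columns=["contig_id", "marker_type"])


def _hits_table(
    rng: np.random.Generator, populations: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """Homology hits for ~8% of populations plus sub-threshold noise."""
    rows = []
    n_hit = max(2, int(0.08 * len(populations)))
    chosen = rng.choice(len(populations), size=n_hit, replace=False)
    for k, p in enumerate(chosen):
        members = populations.iloc[p]["contigs"].split(",")
        taxon = f"refvirus_{k + 1:03d}"
        family = _FAMILIES[int(rng.integers(len(_FAMILIES)))]
        for m in members:
            if rng.random() < 0.7:
                rows.append(
                    {
                        "contig_id": m,
                        "ref_taxon": taxon,
                        "family": family,
                        "evalue": 10.0 ** -rng.uniform(6.0, 30.0),
                        "bitscore": round(float(rng.uniform(60.0, 400.0)), 1),
                    }
                )
    # hits failing the thresholds; must never influence taxonomy
    for _ in range(max(3, n_hit // 2)):
        contig = catalog.index[int(rng.integers(len(catalog)))]
        rows.append(
            {
                "contig_id": contig,
                "ref_taxon": "refvirus_weak",
                "family": "Siphoviridae",
                "evalue": 10.0 ** -rng.uniform(1.0, 4.0),
                "bitscore": round(float(rng.uniform(20.0, 45.0)), 1),
            }
        )
    return pd.DataFrame(rows, columns=["contig_id", "ref_taxon", "family", "evalue", "bitscore"])


def simulate_otu_community(
    design: StudyDesign,
    n_otus: int = 200,
    n_responders: int = 30,
    effect_size: float = 0.3,
    seed: int = 0,
    libsize_range: tuple[int, int] = (20000, 40000),
    sigma: float = 0.5,
    steer_sd: float = 0.25,
) -> tuple[pd.DataFrame, str, SimTruth]:
    """Simulate an OTU count table with a random bifurcating phylogeny.

    Returns ``(otu_counts, newick, truth)``; branch lengths are
    exponential(1), counts follow the same log-normal/multinomial model
    as the virome simulator.  ``truth.extras['min_depth']`` records the
    minimum per-sample read depth.
    """
    if n_otus < 2:
        raise InputError("need at least 2 OTUs")
    if n_responders > n_otus:
        raise InputError("n_responders must not exceed n_otus")

    rngs = _streams(seed, ["tree", "params", "counts"])
    rt, rp, rn = rngs["tree"], rngs["params"], rngs["counts"]

    otus = [f"otu{i + 1:04d}" for i in range(n_otus)]
    newick = _random_bifurcating_newick(rt, otus)

    tdn = design.covariate("tdn")
    x = (tdn - tdn.mean()).to_numpy()
    steers = design.factor("steer")
    steer_ids = sorted(set(steers))
    u = pd.Series(rp.normal(0.0, steer_sd, len(steer_ids)), index=steer_ids)

    a = rp.normal(0.0, 1.0, n_otus)
    beta = np.zeros(n_otus)
    beta[:n_responders] = effect_size * rp.choice([-1.0, 1.0], n_responders)

    samples = design.sample_ids
    libsizes = pd.Series(
        rn.integers(libsize_range[0], libsize_range[1] + 1, len(samples)), index=samples
    )
    u_j = np.array([u[s] for s in steers])
    eta = (
        a[:, None]
        + beta[:, None] * x[None, :]
        + u_j[None, :]
        + rn.normal(0.0, sigma, (n_otus, len(samples)))
    )
    w = np.exp2(eta)
    counts = np.zeros((n_otus, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        counts[:, j] = rn.multinomial(libsizes[s], w[:, j] / w[:, j].sum())
    table = pd.DataFrame(counts, index=otus, columns=samples)

    truth_pop = pd.DataFrame(
        {"a": a, "beta": beta, "is_responder": beta != 0.0}, index=pd.Index(otus, name="otu_id")
    )
    truth = SimTruth(
        populations=truth_pop,
        steer_effects=u,
        library_sizes=libsizes,
        sigma=sigma,
        seed=seed,
        extras={"min_depth": int(table.sum().min())},
    )
    return table, newick, truth


def _random_bifurcating_newick(rng: np.random.Generator, tips: list[str]) -> str:
    """Join random subtree pairs until one root remains."""
    nodes = [f"{t}:{rng.exponential(1.0):.6f}" for t in tips]
    while len(nodes) > 2:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        i, j = (int(i), int(j)) if i < j else (int(j), int(i))
        merged = f"({nodes[i]},{nodes[j]}):{rng.exponential(1.0):.6f}"
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
    return f"({nodes[0]},{nodes[1]});"


def make_ko_catalog(
    n_kos: int = 60, include_rescue: bool = True, seed: int = 0
) -> pd.DataFrame:
    """A KO -> pathway table spanning excluded, rescue and neutral groups.

    Long format: one row per (ko, pathway) with an ``is_metabolic`` flag
    marking pathways that belong to the KEGG metabolism category.
    Roughly equal thirds of KOs map to excluded-only pathways, neutral
    metabolic pathways, and (when ``include_rescue``) excluded+rescue
    combinations; a few KOs map only to non-metabolic pathways.
    """
    if n_kos < 4:
        raise InputError("need at least 4 KOs")
    rng = np.random.default_rng(seed)
    excluded = list(_EXCLUDED_PATHWAYS)
    rescue = list(_RESCUE_PATHWAYS)
    neutral = list(_NEUTRAL_METABOLIC)
    nonmet = list(_NON_METABOLIC)
    is_met = {**_EXCLUDED_PATHWAYS, **_RESCUE_PATHWAYS, **_NEUTRAL_METABOLIC, **_NON_METABOLIC}

    rows = []
    for i in range(n_kos):
        ko = f"K{i + 1:05d}"
        r = i % 4
        if r == 0:  # excluded only
            paths = list(rng.choice(excluded, size=int(rng.integers(1, 3)), replace=False))
        elif r == 1:  # neutral metabolic
            paths = list(rng.choice(neutral, size=int(rng.integers(1, 3)), replace=False))
        elif r == 2 and include_rescue:  # excluded but rescued
            paths = [str(rng.choice(excluded)), str(rng.choice(rescue))]
        elif r == 2:
            paths = list(rng.choice(excluded, size=1))
        else:  # non-metabolic only
            paths = list(rng.choice(nonmet, size=1))
        for p in paths:
            rows.append({"ko": ko, "pathway": p, "is_metabolic": bool(is_met[p])})
    return pd.DataFrame(rows).drop_duplicates(ignore_index=True)


def simulate_amg_inputs(
    design: StudyDesign,
    n_orfs: int = 400,
    ko_catalog: pd.DataFrame | None = None,
    fraction_excluded: float = 0.25,
    seed: int = 0,
    mu: float = 200.0,
    dispersion: float = 0.1,
    planted_lfc: dict | None = None,
) -> AmgSimData:
    """Simulate ORF annotations and a count matrix for AMG analysis.

    ORFs sit on contigs that are mostly bona-fide viral and longer than
    1.5 kbp (a minority violate either gate to exercise the filter).
    Counts are negative binomial with mean ``mu`` (log-normal spread
    across ORFs) and the given dispersion; ``planted_lfc`` maps KO ids
    to a log2 fold-change applied to the second diet group.

    ``fraction_excluded`` is the probability an ORF is annotated with a
    KO whose pathways are all in the excluded (non-rescued) set.
    """
    if ko_catalog is None:
        ko_catalog = make_ko_catalog(seed=seed)
    if len(ko_catalog) == 0:
        raise InputError("empty KO catalog")
    planted_lfc = planted_lfc or {}

    rngs = _streams(seed, ["orfs", "counts"])
    ro, rn_ = rngs["orfs"], rngs["counts"]

    by_ko = ko_catalog.groupby("ko")
    excl_set = set(_EXCLUDED_PATHWAYS)
    rescue_set = set(_RESCUE_PATHWAYS)
    excluded_kos, other_kos = [], []
    for ko, grp in by_ko:
        paths = set(grp["pathway"])
        if paths & excl_set and not paths & rescue_set:
            excluded_kos.append(ko)
        else:
            other_kos.append(ko)
    if not excluded_kos:
        excluded_kos = other_kos

    samples = design.sample_ids
    diets = design.factor("diet")
    diet_levels = sorted(set(diets))
    group2 = set(diets[diets == diet_levels[-1]].index) if len(diet_levels) > 1 else set()

    rows = []
    n_contigs = max(1, n_orfs // 3)
    contig_len = np.maximum(ro.lognormal(np.log(8000.0), 0.8, n_contigs), 400).astype(int)
    bona = ro.random(n_contigs) < 0.9
    for o in range(n_orfs):
        ci = int(ro.integers(n_contigs))
        if ro.random() < fraction_excluded:
            ko = excluded_kos[int(ro.integers(len(excluded_kos)))]
        else:
            ko = other_kos[int(ro.integers(len(other_kos)))] if other_kos else excluded_kos[0]
        weak = ro.random() < 0.05
        rows.append(
            {
                "orf_id": f"orf{o + 1:05d}",
                "contig_id": f"vc{ci + 1:04d}",
                "contig_length": int(contig_len[ci]),
                "viral_bona_fide": bool(bona[ci]),
                "ko": ko,
                "evalue": 10.0 ** -ro.uniform(1.0, 4.0) if weak else 10.0 ** -ro.uniform(6.0, 40.0),
                "bitscore": float(ro.uniform(20.0, 45.0)) if weak else float(ro.uniform(55.0, 300.0)),
            }
        )
    orf_ko = pd.DataFrame(rows)

    mu_o = ro.lognormal(np.log(mu), 0.5, n_orfs)
    lfc = np.array([planted_lfc.get(k, 0.0) for k in orf_ko["ko"]])
    counts = np.zeros((n_orfs, len(samples)), dtype=int)
    for j, s in enumerate(samples):
        m = mu_o * np.exp2(lfc) if s in group2 else mu_o
        if dispersion > 0:
            n_param = 1.0 / dispersion
            counts[:, j] = rn_.negative_binomial(n_param, n_param / (n_param + m))
        else:
            counts[:, j] = rn_.poisson(m)
    orf_counts = pd.DataFrame(counts, index=orf_ko["orf_id"].to_numpy(), columns=samples)

    truth = SimTruth(
        populations=pd.DataFrame(
            {"ko": orf_ko["ko"], "mu": mu_o, "planted_lfc": lfc}, index=orf_counts.index
        ),
        seed=seed,
        extras={"dispersion": dispersion, "groups": diet_levels},
    )
    return AmgSimData(orf_ko=orf_ko, orf_counts=orf_counts, ko_pathways=ko_catalog, truth=truth)


def write_dataset(
    outdir,
    design: StudyDesign,
    viral: ViralSimData | None = None,
    otu: tuple[pd.DataFrame, str, SimTruth] | None = None,
    amg: AmgSimData | None = None,
) -> None:
    """Write all simulated tables as single-header TSV files."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    design.samples.to_csv(out / "design.tsv", sep="\t", index=False)
    design.diet_table.to_csv(out / "diet.tsv", sep="\t", index_label="covariate")
    if viral is not None:
        viral.catalog.to_csv(out / "contigs.tsv", sep="\t", index_label="contig_id")
        viral.markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        viral.hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        viral.counts.to_csv(out / "counts.tsv", sep="\t", index_label="contig_id")
        viral.covered_bases.to_csv(out / "covered_bases.tsv", sep="\t", index_label="contig_id")
        for i, cand in enumerate(viral.candidate_binnings):
            pd.Series(cand, name="bin_id").rename_axis("contig_id").to_csv(
                out / f"binning_candidate_{i}.tsv", sep="\t"
            )
        viral.truth.populations.to_csv(out / "truth.tsv", sep="\t", index_label="population_id")
        viral.truth.bins.to_csv(out / "truth_bins.tsv", sep="\t", index_label="bin_id")
    if otu is not None:
        table, newick, otruth = otu
        table.to_csv(out / "otus.tsv", sep="\t", index_label="otu_id")
        (out / "tree.nwk").write_text(newick + "\n")
        otruth.populations.to_csv(out / "truth_otus.tsv", sep="\t", index_label="otu_id")
    if amg is not None:
        amg.orf_ko.to_csv(out / "orf_ko.tsv", sep="\t", index=False)
        amg.orf_counts.to_csv(out / "orf_counts.tsv", sep="\t", index_label="orf_id")
        amg.ko_pathways.to_csv(out / "ko_pathways.tsv", sep="\t", index=False)
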