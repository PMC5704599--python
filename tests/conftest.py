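import numpy as np
import pandas as pd
import pytest

from rumivir import abundance as ab
from rumivir import curation as cur
from rumivir import synthetic_data as synth


@pytest.fixture(scope="session")
def design():
    return synth.builtin_design()


@pytest.fixture(scope="session")
def viral_sim(design):
    return synth.simulate_viral_metagenome(design, seed=11)


@pytest.fixture(scope="session")
def curated(viral_sim):
    """(catalog, populations) for the session's simulated dataset."""
    cat = cur.build_catalog(
        viral_sim.catalog.reset_index()[["contig_id", "length_bp", "viral_flag"]],
        viral_sim.markers,
    )
    chosen, _ = cur.score_binning(viral_sim.candidate_binnings, cat)
    pops = cur.curate_bins(chosen, cat)
    return cat, pops


@pytest.fixture(scope="session")
def pop_bundle(viral_sim, curated):
    _, pops = curated
    return ab.population_counts(
        viral_sim.counts, pops, lib_sizes=viral_sim.truth.library_sizes
    )


@pytest.fixture(scope="session")
def otu_sim(design):
    return synth.simulate_otu_community(design, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def toy_catalog(rows):
    """Build a contig catalog from (id, length, viral, terl, scg[, bin]) tuples."""
    recs = []
    for r in rows:
        rid, length, viral, terl, scg = r[:5]
        recs.append(
            {
                "contig_id": rid,
                "length_bp": length,
                "viral_flag": viral,
                "terl_count": terl,
                "scg_count": scg,
            }
        )
    return pd.DataFrame(recs).set_index("contig_id")
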