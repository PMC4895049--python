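import numpy as np
import pandas as pd
import pytest

from ecoscan.layout import GenomeLayout, default_layout
from ecoscan.simdata import build_paper_scenario, simulate_cohort
from ecoscan.sites import SiteTable


def make_sitetable(
    chrom="chr1",
    positions=(),
    genotypes=None,
    popmap=None,
    ref="A",
    alt="G",
    anc=None,
    category="intergenic",
    third_codon=False,
):
    """Build a small SiteTable from explicit per-site genotype lists.

    ``genotypes``: array-like (n_sites, n_individuals, 2) with 0=REF, 1=ALT,
    -1=missing. Scalar ref/alt/anc broadcast to all sites.
    """
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_ind = g.shape[0], g.shape[1]
    positions = list(positions) if len(positions) else list(range(n_sites))
    if popmap is None:
        popmap = {f"i{k}": "pop1" for k in range(n_ind)}
    individuals = list(popmap)

    def bcast(v):
        return [v] * n_sites if isinstance(v, str) else list(v)

    df = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": np.asarray(positions, dtype=np.int64),
            "ref": bcast(ref),
            "alt": bcast(alt),
            "anc": bcast(anc if anc is not None else ref),
            "category": bcast(category),
            "third_codon": [third_codon] * n_sites if isinstance(third_codon, bool) else list(third_codon),
        }
    )
    return SiteTable(df, g, individuals, popmap)


@pytest.fixture(scope="session")
def paper_model():
    return build_paper_scenario(1.0, 7)


@pytest.fixture(scope="session")
def small_dataset(paper_model):
    """Five-population cohort on a 5 x 400 kb genome; shared across tests."""
    return simulate_cohort(paper_model, default_layout(0.2), seed=11)


@pytest.fixture(scope="session")
def two_pop_layout():
    return GenomeLayout((("chr1", 1_000_000),))
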