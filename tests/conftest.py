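import numpy as np
import pandas as pd
import pytest

from germcore.datatypes import GenomeLayout, GenotypeMatrix, new_variant_table
from germcore.synthetic_data import fixture_suite, simulate_frequencies


def make_genotypes(dosages, chrom="chr1", spacing=1000, ids=None):
    """Wrap a dosage array in a GenotypeMatrix with evenly spaced sites."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    ids = ids or [f"A{i:03d}" for i in range(n)]
    refs = np.tile(["A", "C"], (m + 1) // 2)[:m]
    alts = np.tile(["G", "T"], (m + 1) // 2)[:m]
    sites = new_variant_table(
        pd.DataFrame(
            {
                "chrom": [chrom] * m,
                "pos": (np.arange(m) + 1) * spacing,
                "ref": refs,
                "alt": alts,
            }
        )
    )
    return GenotypeMatrix(ids, dosages, sites)


def balding_nichols_panel(
    n_per_pop, n_snps, fst, seed, pop_codes=("P1", "P2"), missing_rate=0.0
):
    """Pure-ancestry Balding-Nichols panel with known per-pop frequencies."""
    rng = np.random.default_rng(seed)
    k = len(pop_codes)
    p_anc, pop_freqs = simulate_frequencies(n_snps, k, fst, rng)
    dosages = []
    labels = []
    for i, code in enumerate(pop_codes):
        dosages.append(rng.binomial(2, pop_freqs[i], size=(n_per_pop, n_snps)).astype(float))
        labels.extend([code] * n_per_pop)
    dosages = np.vstack(dosages)
    if missing_rate:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    geno = make_genotypes(dosages)
    popmap = pd.Series(labels, index=geno.accession_ids)
    return geno, popmap, pop_freqs


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixtures")
    fixture_suite(str(outdir), seed=313)
    return outdir


@pytest.fixture(scope="session")
def layout_10kb():
    return GenomeLayout({"chr1": 10_000})
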