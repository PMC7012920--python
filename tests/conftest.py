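import numpy as np
import pandas as pd
import pytest

from poolmap import popsim


@pytest.fixture(scope="session")
def small_marker_set():
    """Two 1-Mb chromosomes with 50 markers each (every 20 kb)."""
    return popsim.default_marker_set(
        n_chromosomes=2, chrom_length=1_000_000, markers_per_chrom=50
    )


@pytest.fixture(scope="session")
def desk_marker_set():
    """Ten 30-Mb chromosomes with 200 markers each (every 150 kb)."""
    return popsim.default_marker_set(markers_per_chrom=200)


@pytest.fixture(scope="session")
def desk_population(desk_marker_set):
    """200 F2 individuals under the default six-locus architecture."""
    arch = popsim.default_architecture(desk_marker_set)
    eggs, erec = popsim.simulate_gametes(desk_marker_set, 200, seed=11)
    pollen, prec = popsim.simulate_gametes(desk_marker_set, 200, seed=12)
    pop = popsim.make_f2_population(
        desk_marker_set, eggs, pollen, seed=13,
        egg_crossovers=erec, pollen_crossovers=prec,
    )
    return popsim.assign_phenotypes(pop, arch)


def fixed_pool_depths(marker_set, high_geno, low_geno, depth=30):
    """Noise-free allele-depth table for pools fixed at one genotype each.

    high_geno/low_geno: parent-B dosage (0, 1 or 2) applied at every marker.
    """
    rows = []
    for label, g in (("high", high_geno), ("low", low_geno)):
        q = g / 2.0
        cb = int(round(depth * q))
        rows.append(
            pd.DataFrame(
                {
                    "chrom": marker_set.markers["chrom"].to_numpy(),
                    "pos": marker_set.markers["pos"].to_numpy(),
                    "pool": label,
                    "count_a": depth - cb,
                    "count_b": cb,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
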