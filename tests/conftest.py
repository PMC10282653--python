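"""Shared fixtures: small synthetic reference sets and abundance tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from twobrad.digest import DigestScheme, build_unique_tag_db
from twobrad.ecology import AbundanceTable
from twobrad.synth import SynthConfig, generate_reference_set

try:  # derandomise hypothesis wherever it is used
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:  # pragma: no cover
    pass


@pytest.fixture(scope="session")
def scheme() -> DigestScheme:
    return DigestScheme()


@pytest.fixture(scope="session")
def small_refset():
    """Five mock genomes (20 sites each), taxonomy, decoy and tag DB."""
    config = SynthConfig(
        n_species=5, genome_length=8_000, sites_per_genome=20,
        n_samples_per_group=(2, 2), reads_per_sample=500, seed=7,
    )
    genomes, taxonomy, decoy = generate_reference_set(config)
    db = build_unique_tag_db(genomes, config.scheme)
    return {"config": config, "genomes": genomes, "taxonomy": taxonomy,
            "decoy": decoy, "db": db}


def make_table(
    X: np.ndarray,
    groups: list[str],
    taxa: list[str] | None = None,
    counts: np.ndarray | None = None,
    taxonomy: pd.DataFrame | None = None,
) -> AbundanceTable:
    """Abundance table from a raw non-negative matrix (rows renormalised)."""
    X = np.asarray(X, dtype=float)
    sums = X.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    X = X / sums
    samples = [f"s{i:02d}" for i in range(X.shape[0])]
    taxa = taxa or [f"taxon{j:02d}" for j in range(X.shape[1])]
    return AbundanceTable(
        values=pd.DataFrame(X, index=samples, columns=taxa),
        groups=pd.Series(groups, index=samples),
        counts=(
            pd.DataFrame(counts, index=samples, columns=taxa)
            if counts is not None else None
        ),
        taxonomy=taxonomy,
    )


@pytest.fixture()
def two_group_table() -> AbundanceTable:
    """22-sample (15 vs 7) random compositional table, no group signal."""
    rng = np.random.default_rng(42)
    X = rng.dirichlet(np.ones(12), size=22)
    return make_table(X, ["MIBC"] * 15 + ["NMIBC"] * 7)
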