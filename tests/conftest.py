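"""Shared fixtures: tiny hand-built datasets and simulated scenario pools."""

from __future__ import annotations

import numpy as np
import pytest

from multibarcode.seqstore import Individual, LocusAlignment, MultilocusDataset


def ind(species: str, ident: str) -> Individual:
    return Individual(species, ident)


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def make_dataset(
    n_loci: int,
    individuals: list[Individual],
    length: int = 60,
    seed: int = 0,
    missing: set[tuple[str, Individual]] = frozenset(),
) -> MultilocusDataset:
    """Random-sequence dataset with an optional (locus_id, individual) mask."""
    rng = np.random.default_rng(seed)
    loci = []
    for k in range(n_loci):
        lid = f"loc{k:03d}"
        seqs = {
            i: random_seq(rng, length)
            for i in individuals
            if (lid, i) not in missing
        }
        loci.append(LocusAlignment(lid, seqs))
    return MultilocusDataset(loci, individuals=individuals)


@pytest.fixture(scope="session")
def two_species_inds() -> list[Individual]:
    return [ind("A", f"a{i}") for i in range(3)] + [
        ind("B", f"b{i}") for i in range(3)
    ]


@pytest.fixture(scope="session")
def deep_split_ds():
    """Simulated deep-divergence two-species dataset (split 700k gen, m=0)."""
    from multibarcode.cli import make_fixture

    return make_fixture("deep_split", seed=101, n_loci=150)


@pytest.fixture(scope="session")
def panmictic_ds():
    """Simulated panmictic dataset: one population labeled as two species."""
    from multibarcode.cli import make_fixture

    return make_fixture("panmictic", seed=103, n_loci=150)
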