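"""Two-species isolation-with-migration coalescent simulator.

Simulates gene genealogies backward in time under a structured coalescent
with two descendant demes that merge into a single ancestral deme at the
split time, then drops Jukes–Cantor finite-sites mutations on the genealogy
to produce per-locus alignments.  Population sizes are in gene copies
(haploid counts): a pair of lineages in a deme of size N coalesces at rate
1/N per generation, and each lineage in deme i migrates (backward in time)
to deme j at rate m_ij per generation.  The continuous-time exponential-rates
approximation to the discrete Wright–Fisher coalescent is used throughout.

A second, migration-free generator walks an arbitrary species tree (used for
multi-species pipeline fixtures).

The module also hosts the simulation "power study" experiments: success rate
of the all-species-barcodes criterion as a function of the number of loci,
and the single-long-locus versus many-short-loci contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .seqstore import (
    Individual,
    LocusAlignment,
    MultilocusDataset,
    decode_sequence,
    pair_counts,
)


@dataclass
class IMModel:
    """Parameters of the two-population isolation-with-migration model.

    Sizes (``N1``, ``N2``, ``N_anc``) are effective sizes in gene copies;
    ``t_split`` is the species splitting time in generations; ``m12``/``m21``
    are per-lineage per-generation migration probabilities (backward in
    time); ``mu`` is the substitution rate per site per generation and
    ``locus_length`` the locus size in bp.
    """

    t_split: float
    N1: float = 20_000.0
    N2: float = 20_000.0
    N_anc: float = 20_000.0
    m12: float = 0.0
    m21: float = 0.0
    mu: float = 2e-8
    locus_length: int = 300

    def __post_init__(self) -> None:
        if min(self.N1, self.N2, self.N_anc) <= 0:
            raise ValueError("population sizes must be positive")
        if self.t_split < 0:
            raise ValueError("t_split must be nonnegative")
        if not (0 <= self.m12 < 1 and 0 <= self.m21 < 1):
            raise ValueError("migration rates must be in [0, 1)")
        if self.mu <= 0:
            raise ValueError("mutation rate must be positive")
        if self.locus_length < 1:
            raise ValueError("locus_length must be >= 1")


class Node:
    """A node of a gene genealogy (times in generations, increasing rootward)."""

    __slots__ = ("time", "deme", "children", "name")

    def __init__(self, time: float, deme: int | str, children=(), name=None):
        self.time = time
        self.deme = deme
        self.children = list(children)
        self.name = name

    def is_tip(self) -> bool:
        return not self.children


@dataclass
class GeneGenealogy:
    root: Node
    tips: list[Node]

    def pairwise_tmrca(self) -> dict[frozenset, float]:
        """TMRCA (generations) for every pair of tip names."""
        out: dict[frozenset, float] = {}

        def walk(node: Node) -> list[str]:
            if node.is_tip():
                return [node.name]
            clades = [walk(c) for c in node.children]
            for i in range(len(clades)):
                for j in range(i + 1, len(clades)):
                    for a in clades[i]:
                        for b in clades[j]:
                            out[frozenset((a, b))] = node.time
            return [n for cl in clades for n in cl]

        walk(self.root)
        return out

    def total_branch_length(self) -> float:
        tot = 0.0
        stack = [self.root]
        while stack:
            node = stack.pop()
            for c in node.children:
                tot += node.time - c.time
                stack.append(c)
        return tot


def _coalesce(lineages: list[Node], t: float, rng: np.random.Generator,
              deme) -> None:
    i, j = rng.choice(len(lineages), size=2, replace=False)
    i, j = (int(i), int(j)) if i < j else (int(j), int(i))
    parent = Node(t, deme, children=[lineages[i], lineages[j]])
    lineages[i] = parent
    del lineages[j]


def simulate_genealogy(
    model: IMModel, n1: int, n2: int, rng: np.random.Generator
) -> GeneGenealogy:
    """Simulate one gene genealogy for n1 + n2 sampled gene copies.

    Tips are named ``A0..`` (deme 1) and ``B0..`` (deme 2).  With no
    migration, every between-deme coalescence necessarily happens in the
    ancestral deme, i.e. at a time >= ``t_split``.
    """
    if n1 + n2 < 2:
        raise ValueError("need at least two sampled lineages")
    tips = [Node(0.0, 0, name=f"A{i}") for i in range(n1)] + [
        Node(0.0, 1, name=f"B{i}") for i in range(n2)
    ]
    demes: list[list[Node]] = [list(tips[:n1]), list(tips[n1:])]
    t = 0.0
    merged = model.t_split <= 0.0
    if merged:
        pool = demes[0] + demes[1]
    while True:
        if not merged:
            k1, k2 = len(demes[0]), len(demes[1])
            if k1 + k2 == 1:
                break
            rates = [
                k1 * (k1 - 1) / 2.0 / model.N1,
                k2 * (k2 - 1) / 2.0 / model.N2,
                k1 * model.m12,
                k2 * model.m21,
            ]
            total = sum(rates)
            if total == 0.0:
                t = model.t_split
            else:
                dt = rng.exponential(1.0 / total)
                if t + dt >= model.t_split:
                    t = model.t_split
                else:
                    t += dt
                    u = rng.random() * total
                    if u < rates[0]:
                        _coalesce(demes[0], t, rng, deme=0)
                    elif u < rates[0] + rates[1]:
                        _coalesce(demes[1], t, rng, deme=1)
                    elif u < rates[0] + rates[1] + rates[2]:
                        k = int(rng.integers(k1))
                        demes[1].append(demes[0].pop(k))
                    else:
                        k = int(rng.integers(k2))
                        demes[0].append(demes[1].pop(k))
                    continue
            # reached the split: merge into the ancestral deme
            merged = True
            pool = demes[0] + demes[1]
        if len(pool) == 1:
            break
        k = len(pool)
        rate = k * (k - 1) / 2.0 / model.N_anc
        t += rng.exponential(1.0 / rate)
        _coalesce(pool, t, rng, deme="anc")
    root = pool[0] if merged else (demes[0] + demes[1])[0]
    return GeneGenealogy(root=root, tips=tips)


def drop_mutations(
    genealogy: GeneGenealogy,
    mu: float,
    locus_length: int,
    rng: np.random.Generator,
    locus_id: str = "locus",
    species_names: tuple[str, str] = ("speciesA", "speciesB"),
) -> LocusAlignment:
    """Drop Jukes–Cantor finite-sites mutations on a genealogy.

    The root sequence is uniform random; each branch receives a Poisson
    number of mutations with mean ``mu * locus_length * branch_length``; each
    mutation hits a uniform site and changes it to a uniform different base.
    """
    root_seq = rng.integers(0, 4, size=locus_length, dtype=np.uint8)
    sequences: dict[Individual, str] = {}
    stack = [(genealogy.root, root_seq)]
    while stack:
        node, seq = stack.pop()
        if node.is_tip():
            species = species_names[0] if node.name.startswith("A") else species_names[1]
            sequences[Individual(species, node.name)] = decode_sequence(seq)
            continue
        for child in node.children:
            n_mut = rng.poisson(mu * locus_length * (node.time - child.time))
            child_seq = seq
            if n_mut:
                child_seq = seq.copy()
                pos = rng.integers(0, locus_length, size=n_mut)
                shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
                for p, s in zip(pos, shift):
                    child_seq[p] = (child_seq[p] + s) % 4
            stack.append((child, child_seq))
    return LocusAlignment(locus_id, sequences)


@dataclass
class LocusPool:
    """A simulated pool of independent loci for two species."""

    dataset: MultilocusDataset
    model: IMModel
    seed: int
    n1: int = 5
    n2: int = 5


def simulate_pool(
    model: IMModel,
    n_loci: int,
    seed: int,
    n1: int = 5,
    n2: int = 5,
) -> LocusPool:
    """Simulate ``n_loci`` independent loci for n1 + n2 sampled sequences.

    Loci are unlinked (independent genealogies) with no recombination within
    a locus.  Deterministic under ``seed``.
    """
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_loci)))
    loci = []
    for i in range(n_loci):
        g = simulate_genealogy(model, n1, n2, rng)
        loci.append(
            drop_mutations(
                g, model.mu, model.locus_length, rng,
                locus_id=f"locus{i:0{width}d}",
            )
        )
    return LocusPool(
        dataset=MultilocusDataset(loci), model=model, seed=seed, n1=n1, n2=n2
    )


# ---------------------------------------------------------------------------
# Multi-deme, migration-free generator for pipeline fixtures.


def simulate_species_genealogy(
    samples: dict[str, int],
    merges: Sequence[tuple[float, str, str, str]],
    N: float,
    rng: np.random.Generator,
) -> GeneGenealogy:
    """Structured coalescent on an arbitrary species tree without migration.

    ``samples`` maps tip-deme name -> number of sampled gene copies; each
    merge event ``(time, a, b, parent)`` joins demes a and b into ``parent``
    at ``time`` generations (events must be sorted ascending and end with a
    single root deme).  All demes share size ``N`` gene copies.
    """
    tips: list[Node] = []
    demes: dict[str, list[Node]] = {}
    for name, n in samples.items():
        demes[name] = [Node(0.0, name, name=f"{name}_{i}") for i in range(n)]
        tips.extend(demes[name])
    t = 0.0
    schedule = list(merges)
    while True:
        n_lin = sum(len(v) for v in demes.values())
        if n_lin == 1 and not schedule:
            break
        next_merge = schedule[0][0] if schedule else math.inf
        rates = {d: len(v) * (len(v) - 1) / 2.0 / N for d, v in demes.items()}
        total = sum(rates.values())
        if total > 0:
            dt = rng.exponential(1.0 / total)
        else:
            dt = math.inf
        if t + dt >= next_merge:
            t, a, b, parent = schedule.pop(0)
            demes[parent] = demes.pop(a, []) + demes.pop(b, [])
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        for d, r in rates.items():
            acc += r
            if u < acc:
                _coalesce(demes[d], t, rng, deme=d)
                break
    (last,) = [v for v in demes.values() if v]
    return GeneGenealogy(root=last[0], tips=tips)


def simulate_species_pool(
    samples: dict[str, int],
    merges: Sequence[tuple[float, str, str, str]],
    N: float,
    mu: float,
    locus_length: int,
    n_loci: int,
    seed: int,
) -> MultilocusDataset:
    """Multi-species analogue of :func:`simulate_pool` (no migration)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_loci)))
    loci = []
    for i in range(n_loci):
        g = simulate_species_genealogy(samples, merges, N, rng)
        root_seq = rng.integers(0, 4, size=locus_length, dtype=np.uint8)
        sequences: dict[Individual, str] = {}
        stack = [(g.root, root_seq)]
        while stack:
            node, seq = stack.pop()
            if node.is_tip():
                species = node.name.rsplit("_", 1)[0]
                sequences[Individual(species, node.name)] = decode_sequence(seq)
                continue
            for child in node.children:
                n_mut = rng.poisson(mu * locus_length * (node.time - child.time))
                child_seq = seq
                if n_mut:
                    child_seq = seq.copy()
                    pos = rng.integers(0, locus_length, size=n_mut)
                    shift = rng.integers(1, 4, size=n_mut).astype(np.uint8)
                    for p, s in zip(pos, shift):
                        child_seq[p] = (child_seq[p] + s) % 4
                stack.append((child, child_seq))
        loci.append(LocusAlignment(f"locus{i:0{width}d}", sequences))
    return MultilocusDataset(loci)


# ---------------------------------------------------------------------------
# Power experiments.


def success_vs_loci(
    model: IMModel,
    levels: Sequence[int],
    pool_size: int,
    n_reps: int,
    seed: int,
    n1: int = 5,
    n2: int = 5,
) -> pd.DataFrame:
    """All-species-barcodes success rate per number-of-loci level.

    Simulates one pool of ``pool_size`` loci, then for each level draws
    ``n_reps`` without-replacement locus samples, scores every individual as
    a query against all others (leave-one-out), and averages.
    Returns a DataFrame with columns level, success_rate, n_reps.
    """
    from .identify import success_fraction_from_counts

    if max(levels) > pool_size:
        raise ValueError(
            f"level {max(levels)} exceeds pool size {pool_size}"
        )
    pool = simulate_pool(model, pool_size, seed, n1=n1, n2=n2)
    ds = pool.dataset
    inds, pairs, M, V = pair_counts(ds)
    species = np.array([i.species_label for i in inds])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    rows = []
    for level in levels:
        rates = []
        for _ in range(n_reps):
            idx = rng.choice(pool_size, size=level, replace=False)
            rates.append(
                success_fraction_from_counts(
                    M[idx].sum(axis=0), V[idx].sum(axis=0), pairs, species
                )
            )
        rows.append((level, float(np.mean(rates)), n_reps))
    return pd.DataFrame(rows, columns=["level", "success_rate", "n_reps"])


def single_vs_multi(
    model: IMModel,
    total_lengths: Sequence[int],
    seed: int,
    n_reps: int = 200,
    n1: int = 5,
    n2: int = 5,
) -> pd.DataFrame:
    """Success of one long locus vs. many independent 300-bp loci.

    For each total length L (a multiple of 300): the single-locus arm
    simulates one genealogy carrying an L-bp locus per replicate; the
    multilocus arm simulates L/300 independent 300-bp loci per replicate.
    Both are scored with the all-species-barcodes criterion.  At L=300 the
    two arms share the same simulated locus, so they are identical by
    construction.
    """
    from .identify import success_fraction_from_counts

    unit = 300
    for L in total_lengths:
        if L % unit != 0 or L < unit:
            raise ValueError(f"total length {L} is not a multiple of {unit}")
    rng = np.random.default_rng(seed)
    rows = []
    for L in total_lengths:
        k = L // unit
        single_rates = []
        multi_rates = []
        for _ in range(n_reps):
            short_model = IMModel(
                t_split=model.t_split, N1=model.N1, N2=model.N2,
                N_anc=model.N_anc, m12=model.m12, m21=model.m21,
                mu=model.mu, locus_length=unit,
            )
            multi = [
                drop_mutations(
                    simulate_genealogy(short_model, n1, n2, rng),
                    model.mu, unit, rng, locus_id=f"m{i}",
                )
                for i in range(k)
            ]
            if k == 1:
                single = [multi[0]]
            else:
                single = [
                    drop_mutations(
                        simulate_genealogy(short_model, n1, n2, rng),
                        model.mu, L, rng, locus_id="s0",
                    )
                ]
            for lst, sink in ((single, single_rates), (multi, multi_rates)):
                ds = MultilocusDataset(lst)
                inds, pairs, M, V = pair_counts(ds)
                species = np.array([i.species_label for i in inds])
                sink.append(
                    success_fraction_from_counts(
                        M.sum(axis=0), V.sum(axis=0), pairs, species
                    )
                )
        rows.append(
            (
                L,
                float(np.mean(single_rates)),
                float(np.mean(multi_rates)),
                float(np.std(single_rates, ddof=1) / math.sqrt(n_reps)),
                float(np.std(multi_rates, ddof=1) / math.sqrt(n_reps)),
                n_reps,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "total_length", "success_single", "success_multi",
            "se_single", "se_multi", "n_reps",
        ],
    )
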