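"""Species-identification criteria and success-rate estimation.

Two criteria are provided.  Under *all species barcodes*, a query is
correctly identified iff every conspecific reference ranks closer to it than
any heterospecific reference; exact distance ties are broken in favour of the
heterospecific (a conservative choice that biases against spurious
"correct" calls).  Under *best close match*, references within an optimized
distance threshold vote: unanimous conspecifics → correct, unanimous
heterospecifics → incorrect, a mixture → ambiguous, and an empty
neighbourhood → no identification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence
import warnings

import numpy as np

from .seqstore import (
    BarcodeError,
    Individual,
    MultilocusDataset,
    PDistance,
    UndefinedDistanceError,
    concat_distance,
    pair_counts,
)

Verdict = Literal["correct", "incorrect", "no_id", "ambiguous"]


@dataclass
class NeighborRanking:
    query: Individual
    ranked: list[tuple[Individual, PDistance]]


@dataclass
class IdentificationOutcome:
    criterion: Literal["all_species_barcodes", "best_close_match"]
    verdict: Verdict


def rank_neighbors(
    query: Individual,
    refs: MultilocusDataset,
    loci: Sequence[str] | None = None,
) -> NeighborRanking:
    """Rank all references by concatenated p-distance to the query.

    References sharing no locus with the query are dropped with a warning.
    Ties are ordered heterospecific-first, then by species label and
    individual id, making the ranking total and deterministic.
    """
    lids = list(loci) if loci is not None else refs.locus_ids
    others = [i for i in refs.individuals if i != query]
    if not others:
        raise BarcodeError("empty reference set")
    entries = []
    for ref in others:
        try:
            d = concat_distance(refs, lids, query, ref)
        except UndefinedDistanceError:
            warnings.warn(
                f"reference {ref} shares no usable locus with {query}; dropped",
                stacklevel=2,
            )
            continue
        entries.append((ref, d))
    entries.sort(
        key=lambda e: (
            e[1].value,
            e[0].species_label == query.species_label,  # heterospecific first
            e[0].species_label,
            e[0].individual_id,
        )
    )
    return NeighborRanking(query=query, ranked=entries)


def all_species_barcodes(
    query: Individual,
    refs: MultilocusDataset,
    loci: Sequence[str] | None = None,
) -> IdentificationOutcome:
    """All-species-barcodes criterion.

    Correct iff every conspecific of the query precedes every heterospecific
    in the distance ranking.  An exact tie with a heterospecific counts as
    incorrect (the heterospecific sorts first).  No conspecific reference
    → ``no_id``.
    """
    ranking = rank_neighbors(query, refs, loci)
    n_con = sum(
        1 for r, _ in ranking.ranked if r.species_label == query.species_label
    )
    if n_con == 0:
        return IdentificationOutcome("all_species_barcodes", "no_id")
    head_ok = all(
        r.species_label == query.species_label
        for r, _ in ranking.ranked[:n_con]
    )
    return IdentificationOutcome(
        "all_species_barcodes", "correct" if head_ok else "incorrect"
    )


def success_fraction_from_counts(
    mism: np.ndarray,
    valid: np.ndarray,
    pairs: Sequence[tuple[int, int]],
    species: np.ndarray,
) -> float:
    """Leave-one-out all-species-barcodes success from summed pair counts.

    ``mism``/``valid`` are per-pair totals over the chosen loci (as produced
    by summing rows of :func:`multibarcode.seqstore.pair_counts`).  Pairs
    with no valid site are treated as infinitely distant, and a tie between
    the furthest conspecific and nearest heterospecific counts as failure —
    both matching the ranking semantics above.
    """
    n = len(species)
    dist = np.full((n, n), np.inf)
    for p, (i, j) in enumerate(pairs):
        d = mism[p] / valid[p] if valid[p] > 0 else np.inf
        dist[i, j] = dist[j, i] = d
    n_correct = 0
    for q in range(n):
        same = species == species[q]
        same[q] = False
        if not same.any():
            continue  # no conspecific reference: no_id, never correct
        if dist[q, same].max() < dist[q, ~same].min():
            n_correct += 1
    return n_correct / n


def success_rate(
    ds: MultilocusDataset,
    species_pair: tuple[str, str],
    n_loci: int,
    n_reps: int,
    seed: int,
) -> float:
    """Mean identification success over locus-resampling replicates.

    Per replicate, ``n_loci`` loci are drawn without replacement; every
    individual of the two species is scored in turn as the query against all
    remaining individuals (leave-one-out) under the all-species-barcodes
    criterion.  The rate pools over individuals and replicates.
    """
    inds = [i for i in ds.individuals if i.species_label in species_pair]
    if n_loci > len(ds.loci):
        raise BarcodeError(
            f"n_loci={n_loci} exceeds the {len(ds.loci)} available loci"
        )
    inds_out, pairs, M, V = pair_counts(ds, individuals=inds)
    species = np.array([i.species_label for i in inds_out])
    rng = np.random.default_rng(seed)
    rates = []
    for _ in range(n_reps):
        idx = rng.choice(len(ds.loci), size=n_loci, replace=False)
        rates.append(
            success_fraction_from_counts(
                M[idx].sum(axis=0), V[idx].sum(axis=0), pairs, species
            )
        )
    return float(np.mean(rates))


def optimize_threshold(
    intra: Sequence[float], inter: Sequence[float]
) -> float:
    """Distance threshold minimizing cumulative identification error.

    Candidates are 0 plus all midpoints of consecutive distinct observed
    distances (intra and inter pooled); the error of a threshold T is
    ``#{intra > T} + #{inter <= T}``.  Ties are resolved toward the smallest
    threshold.
    """
    intra = np.asarray(intra, dtype=float)
    inter = np.asarray(inter, dtype=float)
    if intra.size == 0 or inter.size == 0:
        raise BarcodeError("both intra and inter distance lists must be nonempty")
    observed = np.unique(np.concatenate([intra, inter]))
    candidates = np.concatenate([[0.0], (observed[:-1] + observed[1:]) / 2.0])
    intra_sorted = np.sort(intra)
    inter_sorted = np.sort(inter)
    # intra > T  and  inter <= T via binary search on the sorted samples
    err = (
        intra.size
        - np.searchsorted(intra_sorted, candidates, side="right")
        + np.searchsorted(inter_sorted, candidates, side="right")
    )
    best = err.min()
    return float(candidates[np.argmax(err == best)])


def best_close_match(
    query: Individual,
    refs: MultilocusDataset,
    loci: Sequence[str] | None = None,
    threshold: float = 0.01,
) -> IdentificationOutcome:
    """Best-close-match criterion at a fixed distance threshold.

    References at distance <= threshold vote by species; an empty
    neighbourhood yields ``no_id``, agreement with the query's species
    ``correct``, unanimous other species ``incorrect``, several species
    ``ambiguous``.
    """
    ranking = rank_neighbors(query, refs, loci)
    within = {
        r.species_label for r, d in ranking.ranked if d.value <= threshold
    }
    if not within:
        verdict: Verdict = "no_id"
    elif within == {query.species_label}:
        verdict = "correct"
    elif len(within) == 1:
        verdict = "incorrect"
    else:
        verdict = "ambiguous"
    return IdentificationOutcome("best_close_match", verdict)
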