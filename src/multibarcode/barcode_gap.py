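"""Barcoding-gap analytics: distance distributions vs. number of loci.

Profiles the intra- and interspecific p-distance distributions for a species
pair as the number of concatenated loci grows, over seeded resampling
replicates, and summarises the "barcoding gap" (minimum interspecific minus
maximum intraspecific distance, pooled over replicates) per level.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqstore import BarcodeError, MultilocusDataset, pair_counts


@dataclass
class DistanceProfile:
    """Replicate distance distributions per number-of-loci level.

    ``replicates[level]`` is a list of ``(intra, inter)`` arrays, one entry
    per resampling replicate.
    """

    levels: list[int]
    n_reps: int
    seed: int
    replicates: dict[int, list[tuple[np.ndarray, np.ndarray]]]


@dataclass
class GapSummary:
    """Pooled per-level gap statistics: min_inter - max_intra and variances."""

    levels: list[int]
    min_inter: dict[int, float]
    max_intra: dict[int, float]
    gap: dict[int, float]
    intra_var: dict[int, float]
    inter_var: dict[int, float]


def distance_profile(
    ds: MultilocusDataset,
    species_pair: tuple[str, str],
    levels: Sequence[int],
    n_reps: int,
    seed: int,
) -> DistanceProfile:
    """Intra/interspecific distance distributions per number-of-loci level.

    Per replicate, loci are sampled uniformly without replacement; all
    pairwise concatenated distances among the two species' individuals are
    computed and split into intraspecific (same species) and interspecific
    (different species) sets.  Replicates are independent; the whole profile
    is reproducible from ``seed``.
    """
    levels = sorted(set(int(l) for l in levels))
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if max(levels) > len(ds.loci):
        raise BarcodeError(
            f"level {max(levels)} exceeds the {len(ds.loci)} available loci"
        )
    inds = [i for i in ds.individuals if i.species_label in species_pair]
    for sp in species_pair:
        if sum(1 for i in inds if i.species_label == sp) < 2:
            raise BarcodeError(f"species {sp!r} needs >= 2 individuals")
    inds, pairs, M, V = pair_counts(ds, individuals=inds)
    intra_mask = np.array(
        [inds[i].species_label == inds[j].species_label for i, j in pairs]
    )
    rng = np.random.default_rng(seed)
    replicates: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
    for level in levels:
        reps = []
        for _ in range(n_reps):
            idx = rng.choice(len(ds.loci), size=level, replace=False)
            mism = M[idx].sum(axis=0)
            valid = V[idx].sum(axis=0)
            with np.errstate(invalid="ignore"):
                dist = np.where(valid > 0, mism / np.maximum(valid, 1), np.nan)
            reps.append((dist[intra_mask], dist[~intra_mask]))
        replicates[level] = reps
    return DistanceProfile(
        levels=levels, n_reps=n_reps, seed=seed, replicates=replicates
    )


def gap_summary(profile: DistanceProfile) -> GapSummary:
    """Pooled gap statistics per level (all replicate distances together)."""
    min_inter, max_intra, gap, intra_var, inter_var = {}, {}, {}, {}, {}
    for level in profile.levels:
        reps = profile.replicates[level]
        intra = np.concatenate([r[0] for r in reps])
        inter = np.concatenate([r[1] for r in reps])
        intra = intra[~np.isnan(intra)]
        inter = inter[~np.isnan(inter)]
        if intra.size == 0 or inter.size == 0:
            raise BarcodeError(f"level {level}: empty distance distribution")
        min_inter[level] = float(inter.min())
        max_intra[level] = float(intra.max())
        gap[level] = min_inter[level] - max_intra[level]
        intra_var[level] = float(intra.var())
        inter_var[level] = float(inter.var())
    return GapSummary(
        levels=profile.levels,
        min_inter=min_inter,
        max_intra=max_intra,
        gap=gap,
        intra_var=intra_var,
        inter_var=inter_var,
    )


def profile_to_tsv(profile: DistanceProfile, path: str | Path) -> None:
    """Export `level<TAB>replicate<TAB>class<TAB>distance` for plotting."""
    rows = []
    for level in profile.levels:
        for rep, (intra, inter) in enumerate(profile.replicates[level]):
            rows.extend((level, rep, "intra", d) for d in intra)
            rows.extend((level, rep, "inter", d) for d in inter)
    pd.DataFrame(
        rows, columns=["level", "replicate", "class", "distance"]
    ).to_csv(path, sep="\t", index=False)
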