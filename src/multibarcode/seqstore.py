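"""Data model and I/O for multilocus alignment databases.

The central object is a :class:`MultilocusDataset`: an ordered collection of
per-locus multiple sequence alignments over a shared set of labeled
individuals, with a missing-data mask recording which individual is present at
which locus.  On top of it sit the distance primitives used throughout the
package: the uncorrected p-distance between two aligned sequences, and its
concatenated multilocus analogue (total mismatches over total valid sites
across loci).

Sites are compared under pairwise deletion: a column counts as valid for a
pair iff both characters are one of A, C, G, T.  Gaps, Ns and other ambiguity
codes are dropped per pair, not per column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO


class BarcodeError(Exception):
    """Base class for errors raised by this package."""


class FastaParseError(BarcodeError):
    """A FASTA record could not be interpreted (bad header, empty file...)."""


class AlignmentError(BarcodeError):
    """Sequences that must form an alignment have unequal lengths."""


class UndefinedDistanceError(BarcodeError):
    """No valid site is shared by the two sequences being compared."""


# A,C,G,T (either case) -> 0..3; everything else (gap, N, IUPAC codes) -> 255.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _CODE[_b] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (ACGT -> 0..3, other -> 255)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    if np.any(codes > 3):
        raise ValueError("cannot decode non-ACGT codes")
    return _DECODE[codes].tobytes().decode("ascii")


@dataclass(frozen=True, order=True)
class Individual:
    """A sampled individual: species label plus an individual identifier."""

    species_label: str
    individual_id: str

    def __str__(self) -> str:  # matches the FASTA header convention
        return f"{self.species_label}|{self.individual_id}"


@dataclass(frozen=True)
class PDistance:
    """An uncorrected p-distance together with the number of sites compared."""

    value: float
    valid_sites: int

    def __post_init__(self) -> None:
        if self.valid_sites < 0:
            raise ValueError("valid_sites must be nonnegative")
        if not 0.0 <= self.value <= 1.0:
            raise ValueError(f"p-distance {self.value} outside [0, 1]")


def mismatch_valid(a: str | np.ndarray, b: str | np.ndarray) -> tuple[int, int]:
    """Count (mismatches, valid sites) for two equal-length sequences.

    A site is valid iff both characters are in ACGT (pairwise deletion).
    """
    ca = encode_sequence(a) if isinstance(a, str) else a
    cb = encode_sequence(b) if isinstance(b, str) else b
    if ca.shape != cb.shape:
        raise AlignmentError(
            f"sequence lengths differ: {ca.size} vs {cb.size}"
        )
    valid = (ca != 255) & (cb != 255)
    mism = int(np.count_nonzero((ca != cb) & valid))
    return mism, int(np.count_nonzero(valid))


def p_distance(a: str | np.ndarray, b: str | np.ndarray) -> PDistance:
    """Uncorrected p-distance between two aligned sequences.

    Raises :class:`UndefinedDistanceError` when no valid site is shared and
    :class:`AlignmentError` on a length mismatch.  Symmetric in its arguments.
    """
    mism, valid = mismatch_valid(a, b)
    if valid == 0:
        raise UndefinedDistanceError("no shared valid (ACGT) site")
    return PDistance(value=mism / valid, valid_sites=valid)


class LocusAlignment:
    """A single-locus multiple sequence alignment over labeled individuals."""

    def __init__(self, locus_id: str, sequences: Mapping[Individual, str]):
        if not locus_id:
            raise ValueError("locus_id must be nonempty")
        if not sequences:
            raise AlignmentError(f"locus {locus_id!r}: no sequences")
        self.locus_id = locus_id
        self.sequences: dict[Individual, str] = dict(sequences)
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise AlignmentError(
                f"locus {locus_id!r}: ragged alignment, lengths {sorted(lengths)}"
            )
        self.length = lengths.pop()
        if self.length < 1:
            raise AlignmentError(f"locus {locus_id!r}: zero-length alignment")
        self._codes: dict[Individual, np.ndarray] = {}

    @property
    def individuals(self) -> list[Individual]:
        return list(self.sequences)

    def __contains__(self, ind: Individual) -> bool:
        return ind in self.sequences

    def codes(self, ind: Individual) -> np.ndarray:
        """Encoded sequence for an individual (cached)."""
        c = self._codes.get(ind)
        if c is None:
            c = encode_sequence(self.sequences[ind])
            self._codes[ind] = c
        return c

    def __repr__(self) -> str:
        return (
            f"LocusAlignment({self.locus_id!r}, n={len(self.sequences)}, "
            f"length={self.length})"
        )


class MultilocusDataset:
    """An ordered list of locus alignments over the union of their individuals.

    The missing-data mask is implicit: an individual is "present" at a locus
    iff the locus alignment holds a sequence for it.
    """

    def __init__(
        self,
        loci: Sequence[LocusAlignment],
        individuals: Sequence[Individual] | None = None,
    ):
        ids = [aln.locus_id for aln in loci]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise BarcodeError(f"duplicate locus ids: {dup}")
        self.loci: list[LocusAlignment] = list(loci)
        if individuals is None:
            seen: dict[Individual, None] = {}
            for aln in self.loci:
                for ind in aln.sequences:
                    seen.setdefault(ind, None)
            individuals = sorted(seen)
        else:
            individuals = list(individuals)
            covered = set(individuals)
            for aln in self.loci:
                extra = set(aln.sequences) - covered
                if extra:
                    raise BarcodeError(
                        f"locus {aln.locus_id!r} has individuals outside the "
                        f"dataset: {sorted(str(i) for i in extra)}"
                    )
        self.individuals: list[Individual] = individuals
        self._by_id = {aln.locus_id: aln for aln in self.loci}

    @property
    def locus_ids(self) -> list[str]:
        return [aln.locus_id for aln in self.loci]

    def locus(self, locus_id: str) -> LocusAlignment:
        try:
            return self._by_id[locus_id]
        except KeyError:
            raise KeyError(f"no locus {locus_id!r} in dataset") from None

    def is_present(self, locus_id: str, ind: Individual) -> bool:
        return ind in self.locus(locus_id)

    def missing_counts(self) -> dict[str, int]:
        """Number of dataset individuals absent from each locus."""
        n = len(self.individuals)
        return {
            aln.locus_id: n - sum(1 for i in self.individuals if i in aln)
            for aln in self.loci
        }

    def subset_loci(self, locus_ids: Iterable[str]) -> "MultilocusDataset":
        return MultilocusDataset(
            [self.locus(lid) for lid in locus_ids], individuals=self.individuals
        )

    def restrict_individuals(
        self, individuals: Sequence[Individual]
    ) -> "MultilocusDataset":
        keep = set(individuals)
        loci = []
        for aln in self.loci:
            sub = {i: s for i, s in aln.sequences.items() if i in keep}
            if sub:
                loci.append(LocusAlignment(aln.locus_id, sub))
        return MultilocusDataset(loci, individuals=list(individuals))

    def __len__(self) -> int:
        return len(self.loci)

    def __repr__(self) -> str:
        return (
            f"MultilocusDataset(n_loci={len(self.loci)}, "
            f"n_individuals={len(self.individuals)})"
        )


def concat_distance(
    ds: MultilocusDataset,
    loci: Sequence[str],
    a: Individual,
    b: Individual,
) -> PDistance:
    """p-distance on the concatenation of the listed loci.

    Equals total mismatches / total valid sites over loci where both
    individuals are present; raises :class:`UndefinedDistanceError` if no
    listed locus is shared (or no valid site survives pairwise deletion).
    """
    tot_m = 0
    tot_v = 0
    shared = False
    for lid in loci:
        aln = ds.locus(lid)
        if a in aln and b in aln:
            shared = True
            m, v = mismatch_valid(aln.codes(a), aln.codes(b))
            tot_m += m
            tot_v += v
    if not shared:
        raise UndefinedDistanceError(
            f"{a} and {b} share none of the listed loci"
        )
    if tot_v == 0:
        raise UndefinedDistanceError(
            f"{a} and {b} share no valid site over the listed loci"
        )
    return PDistance(value=tot_m / tot_v, valid_sites=tot_v)


def pair_counts(
    ds: MultilocusDataset,
    individuals: Sequence[Individual] | None = None,
    loci: Sequence[str] | None = None,
) -> tuple[list[Individual], list[tuple[int, int]], np.ndarray, np.ndarray]:
    """Per-locus mismatch/valid-site tables for all individual pairs.

    Returns ``(individuals, pairs, M, V)`` where ``pairs`` lists index pairs
    ``(i, j)`` with ``i < j`` into ``individuals``, and ``M``/``V`` are
    ``(n_loci, n_pairs)`` integer arrays of mismatches and valid sites (both 0
    when either individual is absent from the locus).  Summing rows over a
    subset of loci gives the concatenated distance for every pair at once;
    this is the kernel behind the resampling analytics.
    """
    inds = list(individuals) if individuals is not None else list(ds.individuals)
    lids = list(loci) if loci is not None else ds.locus_ids
    n = len(inds)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    M = np.zeros((len(lids), len(pairs)), dtype=np.int64)
    V = np.zeros_like(M)
    for li, lid in enumerate(lids):
        aln = ds.locus(lid)
        present = [k for k, ind in enumerate(inds) if ind in aln]
        if len(present) < 2:
            continue
        X = np.stack([aln.codes(inds[k]) for k in present])
        ok = X != 255
        diff = X[:, None, :] != X[None, :, :]
        valid = ok[:, None, :] & ok[None, :, :]
        mism = (diff & valid).sum(axis=2)
        nval = valid.sum(axis=2)
        pos = {k: r for r, k in enumerate(present)}
        for p, (i, j) in enumerate(pairs):
            if i in pos and j in pos:
                M[li, p] = mism[pos[i], pos[j]]
                V[li, p] = nval[pos[i], pos[j]]
    return inds, pairs, M, V


def filter_by_missing(
    ds: MultilocusDataset, individuals: Sequence[Individual]
) -> MultilocusDataset:
    """Keep exactly the loci where every listed individual is present."""
    if not individuals:
        raise ValueError("individuals subset must be nonempty")
    keep = [
        aln.locus_id
        for aln in ds.loci
        if all(ind in aln for ind in individuals)
    ]
    if not keep:
        warnings.warn(
            "no locus is complete for the requested individuals; "
            "returning an empty dataset",
            stacklevel=2,
        )
    return ds.subset_loci(keep)


def locus_mean_distances(ds: MultilocusDataset) -> dict[str, float]:
    """Mean pairwise p-distance per locus over present individuals.

    Loci with fewer than two present individuals are omitted (with a warning).
    """
    means: dict[str, float] = {}
    for aln in ds.loci:
        present = [i for i in ds.individuals if i in aln]
        if len(present) < 2:
            warnings.warn(
                f"locus {aln.locus_id!r} has <2 present individuals; "
                "excluded from ranking",
                stacklevel=2,
            )
            continue
        vals = []
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                m, v = mismatch_valid(
                    aln.codes(present[i]), aln.codes(present[j])
                )
                if v > 0:
                    vals.append(m / v)
        if vals:
            means[aln.locus_id] = float(np.mean(vals))
    return means


def rank_loci_by_divergence(
    ds: MultilocusDataset,
) -> list[tuple[str, float]]:
    """Loci sorted by mean pairwise p-distance, most divergent first.

    Ties are broken by locus id (lexicographic) so the ranking is invariant
    to the input order of loci.
    """
    means = locus_mean_distances(ds)
    return sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))


def select_panel(
    ds: MultilocusDataset,
    n_low_missing: int = 750,
    n_panel: int = 500,
) -> list[str]:
    """Two-step marker panel selection.

    Step 1 keeps the ``n_low_missing`` loci with the fewest missing
    individuals (ties: higher mean p-distance, then locus id); step 2 keeps
    the ``n_panel`` of those with the largest mean p-distance (ties: locus
    id).  Returns locus ids in decreasing divergence order.
    """
    if n_panel > len(ds.loci) or n_low_missing > len(ds.loci):
        raise BarcodeError(
            f"dataset has {len(ds.loci)} loci; requested "
            f"n_low_missing={n_low_missing}, n_panel={n_panel}"
        )
    if n_panel > n_low_missing:
        raise BarcodeError("n_panel cannot exceed n_low_missing")
    missing = ds.missing_counts()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        means = locus_mean_distances(ds)
    mean_of = lambda lid: means.get(lid, float("-inf"))
    step1 = sorted(
        ds.locus_ids, key=lambda lid: (missing[lid], -mean_of(lid), lid)
    )[:n_low_missing]
    step2 = sorted(step1, key=lambda lid: (-mean_of(lid), lid))[:n_panel]
    return step2


def sample_loci(ds: MultilocusDataset, n: int, seed: int) -> list[str]:
    """Uniform sample of ``n`` locus ids without replacement, seeded."""
    if n > len(ds.loci):
        raise BarcodeError(
            f"cannot sample {n} loci from a dataset of {len(ds.loci)}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ds.loci), size=n, replace=False)
    lids = ds.locus_ids
    return [lids[i] for i in idx]


# ---------------------------------------------------------------------------
# FASTA I/O.  One file per locus, headers ">species|individual".


def read_locus_fasta(path: str | Path) -> LocusAlignment:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sequences: dict[Individual, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.description:
            raise FastaParseError(
                f"{path.name}: header {rec.description!r} lacks the "
                "'species|individual' separator"
            )
        species, ind_id = rec.description.split("|", 1)
        ind = Individual(species.strip(), ind_id.strip())
        if ind in sequences:
            raise FastaParseError(f"{path.name}: duplicate record {ind}")
        sequences[ind] = str(rec.seq).upper()
    if not sequences:
        raise FastaParseError(f"{path.name}: no FASTA records")
    return LocusAlignment(path.stem, sequences)


def load_dataset(directory: str | Path) -> MultilocusDataset:
    """Load every ``*.fasta``/``*.fa`` file in a directory as one locus each."""
    directory = Path(directory)
    paths = sorted(
        p for p in directory.iterdir() if p.suffix in {".fasta", ".fa"}
    )
    if not paths:
        raise BarcodeError(f"no FASTA files in {directory}")
    loci = [read_locus_fasta(p) for p in paths]
    return MultilocusDataset(loci)


def write_locus_fasta(aln: LocusAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, seq in sorted(aln.sequences.items()):
            fh.write(f">{ind}\n{seq}\n")


def write_dataset(ds: MultilocusDataset, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for aln in ds.loci:
        write_locus_fasta(aln, directory / f"{aln.locus_id}.fasta")


def ranking_to_tsv(ds: MultilocusDataset, path: str | Path) -> None:
    """Write `locus_id<TAB>mean_p_distance<TAB>n_missing` for all ranked loci."""
    import pandas as pd

    ranking = rank_loci_by_divergence(ds)
    missing = ds.missing_counts()
    df = pd.DataFrame(
        [(lid, mean, missing[lid]) for lid, mean in ranking],
        columns=["locus_id", "mean_p_distance", "n_missing"],
    )
    df.to_csv(path, sep="\t", index=False)
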