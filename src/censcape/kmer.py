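"""GC-normalised k-mer enrichment z-scores with a base-shuffle null.

The null model randomises the order of the bases within a window: each
artificial sequence is a uniformly random permutation of the window's
letters, so mononucleotide composition -- and hence GC content -- is
preserved exactly. Observed k-mer counts are compared with the mean and
sample standard deviation of the counts across ``n_shuffles`` such
permutations:

    z[m] = (obs[m] - null_mean[m]) / null_sd[m]

with the convention z[m] = 0 when the null standard deviation is zero
(the composition then pins the count, so observed == mean). The
resulting vector of 4**k z-scores describes the k-mer usage of a window
normalised for its base composition.

K-mers are counted on the given strand as written (no canonical
collapsing); any k-mer containing a letter outside {A,C,G,T} is skipped
in observed and shuffled counting alike, and ambiguity letters are
permuted together with the rest.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._kernels import count_codes, shuffle_count
from .genome_io import Genome, Window

__all__ = [
    "KmerTable",
    "NullStats",
    "EnrichmentProfile",
    "count_kmers",
    "shuffle_null",
    "zscore_profile",
    "profile_matrix",
    "kmer_index",
    "KmerEnrichmentProfiler",
]

_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i

#: maximum k for which dense 4**k arrays are kept in memory
_MAX_K = 12

# target number of letter slots per compiled-kernel chunk (memory bound)
_CHUNK_BUDGET = 4_000_000


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A,C,G,T -> 0..3, other -> 4)."""
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def kmer_index(k: int) -> list[str]:
    """All 4**k k-mers in lexicographic (== code) order."""
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def _check_k(k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > _MAX_K:
        raise ValueError(f"k={k} too large for dense counting (max {_MAX_K})")


def _dense_counts(codes: np.ndarray, k: int) -> np.ndarray:
    out = np.zeros(4**k, dtype=np.int64)
    if codes.shape[0] >= k:
        count_codes(codes, k, out)
    return out


def gc_fraction(seq: str) -> float:
    """G+C fraction over the unambiguous (ACGT) letters of ``seq``."""
    codes = encode(seq)
    n_acgt = int((codes < 4).sum())
    if n_acgt == 0:
        return float("nan")
    n_gc = int(((codes == 1) | (codes == 2)).sum())
    return n_gc / n_acgt


@dataclass
class KmerTable:
    """Sparse k-mer counts of a single sequence (strand as written)."""

    k: int
    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())

    def as_vector(self) -> np.ndarray:
        idx = {m: i for i, m in enumerate(kmer_index(self.k))}
        v = np.zeros(4**self.k, dtype=np.int64)
        for m, c in self.counts.items():
            v[idx[m]] = c
        return v


@dataclass
class NullStats:
    """Per-k-mer mean and sample sd of counts across composition-preserving shuffles."""

    k: int
    n_shuffles: int
    mean: np.ndarray
    sd: np.ndarray
    seed: int | None = None


@dataclass
class EnrichmentProfile:
    """Vector of 4**k z-scores for one window, plus its GC fraction."""

    window_id: str
    z: np.ndarray
    gc: float


def count_kmers(seq: str, k: int) -> KmerTable:
    """Count overlapping k-mers of ``seq`` on the given strand.

    K-mers containing a non-ACGT letter are skipped.
    """
    _check_k(k)
    dense = _dense_counts(encode(seq), k)
    names = kmer_index(k)
    counts = {names[i]: int(c) for i, c in enumerate(dense) if c}
    return KmerTable(k=k, counts=counts)


def _null_moments(
    letters: np.ndarray, k: int, n_shuffles: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and sample sd (ddof=1) of k-mer counts over random permutations.

    Swap indices for the Fisher-Yates passes are drawn from ``rng`` as a
    float32 block per chunk, making the whole procedure a deterministic
    function of the generator state.
    """
    L = letters.shape[0]
    nbins = 4**k
    sums = np.zeros(nbins, dtype=np.float64)
    sumsq = np.zeros(nbins, dtype=np.float64)
    if L < 2:
        # nothing to permute; counts are constant
        base = _dense_counts(letters, k).astype(np.float64)
        return base, np.zeros(nbins)
    chunk_rows = max(1, min(n_shuffles, _CHUNK_BUDGET // L))
    ranges = np.arange(L, 1, -1, dtype=np.float32)  # i+1 for i = L-1 .. 1
    clip = np.arange(L - 1, 0, -1, dtype=np.int32)  # i for i = L-1 .. 1
    done = 0
    counts = np.empty((chunk_rows, nbins), dtype=np.int64)
    while done < n_shuffles:
        n = min(chunk_rows, n_shuffles - done)
        jmat = (rng.random((n, L - 1), dtype=np.float32) * ranges).astype(np.int32)
        np.minimum(jmat, clip, out=jmat)  # guard float32 rounding to i+1
        block = counts[:n]
        block[:] = 0
        shuffle_count(letters, jmat, k, block)
        sums += block.sum(axis=0)
        sumsq += (block.astype(np.float64) ** 2).sum(axis=0)
        done += n
    mean = sums / n_shuffles
    var = (sumsq - n_shuffles * mean**2) / (n_shuffles - 1)
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean, sd


def shuffle_null(
    seq: str, k: int, n_shuffles: int = 1000, seed: int | None = None
) -> NullStats:
    """Null k-mer count distribution under random permutation of the letters.

    Every artificial sequence has exactly the letter multiset of ``seq``
    (mononucleotide composition, hence GC, preserved). Returns the
    sample mean and sample standard deviation (denominator n-1) of each
    k-mer count across ``n_shuffles`` permutations.
    """
    _check_k(k)
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    mean, sd = _null_moments(encode(seq), k, n_shuffles, rng)
    return NullStats(k=k, n_shuffles=n_shuffles, mean=mean, sd=sd,
                     seed=seed if isinstance(seed, int) else None)


def _zscores(observed: np.ndarray, null: NullStats) -> np.ndarray:
    sd = null.sd
    z = np.zeros_like(null.mean)
    ok = sd > 0
    z[ok] = (observed[ok] - null.mean[ok]) / sd[ok]
    return z


def zscore_profile(
    seq: str,
    k: int = 5,
    n_shuffles: int = 1000,
    seed: int | None = None,
    window_id: str = "",
) -> EnrichmentProfile:
    """Composition-normalised k-mer enrichment z-scores of one sequence."""
    _check_k(k)
    if n_shuffles < 2:
        raise ValueError("n_shuffles must be >= 2")
    letters = encode(seq)
    observed = _dense_counts(letters, k).astype(np.float64)
    rng = np.random.default_rng(seed)
    mean, sd = _null_moments(letters, k, n_shuffles, rng)
    null = NullStats(k=k, n_shuffles=n_shuffles, mean=mean, sd=sd)
    return EnrichmentProfile(window_id=window_id, z=_zscores(observed, null),
                             gc=gc_fraction(seq))


def window_seed(
    master_seed: int | None, index: int, chrom: str | None = None
) -> np.random.SeedSequence:
    """Deterministic per-window seed stream from (master seed, window identity).

    The stream follows the window itself (chromosome and per-chromosome
    ordinal), not its position in a list, so permuting or chunking the
    window set never changes any window's profile.
    """
    if master_seed is None:
        master_seed = 0
    key = [int(master_seed)]
    if chrom is not None:
        key.append(zlib.crc32(chrom.encode()))
    key.append(int(index))
    return np.random.SeedSequence(entropy=tuple(key))


def profile_matrix(
    genome: Genome,
    windows: Sequence[Window],
    k: int = 5,
    n_shuffles: int = 1000,
    seed: int | None = 0,
) -> np.ndarray:
    """Z-score profile matrix (windows x 4**k) for a set of genome windows.

    Row order matches window order. Each window's shuffle stream is
    derived from (master seed, chromosome, per-chromosome window index),
    so serial, chunked and reordered runs agree row-for-row.
    """
    _check_k(k)
    encoded = {name: encode(seq) for name, seq in genome.chromosomes.items()}
    nbins = 4**k
    out = np.empty((len(windows), nbins), dtype=np.float64)
    for i, w in enumerate(windows):
        if w.chrom not in encoded:
            raise KeyError(f"window on unknown chromosome {w.chrom!r}")
        chrom = encoded[w.chrom]
        if w.end > chrom.shape[0] or w.start < 0:
            raise ValueError(f"window {w.name} outside chromosome bounds")
        letters = chrom[w.start : w.end]
        observed = _dense_counts(letters, k).astype(np.float64)
        rng = np.random.default_rng(window_seed(seed, w.index, w.chrom))
        mean, sd = _null_moments(letters, k, n_shuffles, rng)
        ok = sd > 0
        row = out[i]
        row[:] = 0.0
        row[ok] = (observed[ok] - mean[ok]) / sd[ok]
    return out


class KmerEnrichmentProfiler(TransformerMixin, BaseEstimator):
    """Transformer mapping DNA windows to k-mer enrichment z-score vectors.

    Parameters
    ----------
    k : int
        K-mer length (columns of the output are the 4**k k-mers in
        lexicographic order).
    n_shuffles : int
        Number of composition-preserving permutations per window.
    random_state : int or None
        Master seed; the stream for window ``i`` is derived from
        ``(random_state, i)``.
    """

    def __init__(self, k: int = 5, n_shuffles: int = 1000, random_state: int | None = 0):
        self.k = k
        self.n_shuffles = n_shuffles
        self.random_state = random_state

    def fit(self, X, y=None):
        _check_k(self.k)
        if self.n_shuffles < 2:
            raise ValueError("n_shuffles must be >= 2")
        self.n_features_out_ = 4**self.k
        self.feature_names_out_ = np.asarray(kmer_index(self.k))
        return self

    def transform(self, X) -> np.ndarray:
        """Profile a sequence collection.

        ``X`` is either a list of DNA strings or a ``(genome, windows)``
        pair; rows of the result follow the input order.
        """
        if not hasattr(self, "n_features_out_"):
            self.fit(X)
        if isinstance(X, tuple) and len(X) == 2 and isinstance(X[0], Genome):
            genome, windows = X
            return profile_matrix(
                genome, windows, k=self.k, n_shuffles=self.n_shuffles,
                seed=self.random_state,
            )
        out = np.empty((len(X), 4**self.k), dtype=np.float64)
        for i, seq in enumerate(X):
            letters = encode(seq)
            observed = _dense_counts(letters, self.k).astype(np.float64)
            rng = np.random.default_rng(window_seed(self.random_state, i))
            mean, sd = _null_moments(letters, self.k, self.n_shuffles, rng)
            ok = sd > 0
            row = out[i]
            row[:] = 0.0
            row[ok] = (observed[ok] - mean[ok]) / sd[ok]
        return out

    def get_feature_names_out(self, input_features=None):
        return self.feature_names_out_
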