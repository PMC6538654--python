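"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's compiled/vectorised code paths:
counting is dict-based over explicit substrings, permutations are
enumerated or simulated naively, and expectations are closed-form.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np

ACGT = "ACGT"


def naive_count(seq: str, k: int) -> Counter:
    """Dict-based overlapping k-mer count, skipping ambiguous k-mers."""
    out: Counter = Counter()
    for i in range(len(seq) - k + 1):
        m = seq[i : i + k]
        if set(m) <= set(ACGT):
            out[m] += 1
    return out


def exhaustive_null_moments(seq: str, k: int) -> tuple[dict, dict]:
    """Exact mean/sd of k-mer counts over all distinct permutations of seq.

    Feasible for short strings only (enumerates the multiset
    permutations).
    """
    perms = set(itertools.permutations(seq))
    counts_per_perm = [naive_count("".join(p), k) for p in perms]
    kmers = {m for c in counts_per_perm for m in c}
    mean, sd = {}, {}
    n = len(counts_per_perm)
    for m in kmers:
        vals = np.array([c.get(m, 0) for c in counts_per_perm], dtype=float)
        mean[m] = vals.mean()
        # population sd over the exact permutation distribution
        sd[m] = vals.std(ddof=0)
    return mean, sd


def closed_form_pair_mean(seq: str) -> dict:
    """Exact E[count of each 2-mer] under uniform permutation of ``seq``.

    By exchangeability, P(positions i, i+1 spell 'ab') is
    n_a * n_b / (L (L-1)) for a != b and n_a (n_a - 1) / (L (L-1)) for
    a == b; the expectation is (L-1) times that.
    """
    L = len(seq)
    counts = Counter(seq)
    out = {}
    for a in ACGT:
        for b in ACGT:
            na, nb = counts.get(a, 0), counts.get(b, 0)
            num = na * (na - 1) if a == b else na * nb
            out[a + b] = (L - 1) * num / (L * (L - 1)) if L >= 2 else 0.0
    return out


def naive_zscore(seq: str, k: int, n_shuffles: int, seed: int) -> np.ndarray:
    """Naive recomputation of the shuffle-null z-score profile.

    Consumes random numbers exactly like the library (a float32 block of
    Fisher-Yates swap targets per run), but shuffles and counts with
    plain Python data structures. Assumes a single RNG chunk
    (n_shuffles * len(seq) must be small).
    """
    L = len(seq)
    assert n_shuffles * L <= 4_000_000, "oracle assumes a single RNG chunk"
    rng = np.random.default_rng(seed)
    ranges = np.arange(L, 1, -1, dtype=np.float32)
    clip = np.arange(L - 1, 0, -1, dtype=np.int32)
    jmat = (rng.random((n_shuffles, L - 1), dtype=np.float32) * ranges).astype(np.int32)
    jmat = np.minimum(jmat, clip)
    kmers = ["".join(p) for p in itertools.product(ACGT, repeat=k)]
    counts = np.zeros((n_shuffles, len(kmers)), dtype=float)
    index = {m: i for i, m in enumerate(kmers)}
    for r in range(n_shuffles):
        buf = list(seq)
        for i in range(L - 1, 0, -1):
            j = int(jmat[r, L - 1 - i])
            buf[i], buf[j] = buf[j], buf[i]
        for m, c in naive_count("".join(buf), k).items():
            counts[r, index[m]] = c
    mean = counts.mean(axis=0)
    sd = counts.std(axis=0, ddof=1)
    obs = np.zeros(len(kmers))
    for m, c in naive_count(seq, k).items():
        obs[index[m]] = c
    z = np.zeros(len(kmers))
    ok = sd > 0
    z[ok] = (obs[ok] - mean[ok]) / sd[ok]
    return z


def mc_two_gene_cluster_prob(
    chrom_len: int, gene_len: int, gap_max: int, n_draws: int, seed: int
) -> float:
    """Monte-Carlo P(two uniformly placed genes cluster) on one chromosome.

    Genes are placed independently and draws with overlapping genes are
    rejected, matching the non-overlap constraint of the location
    shuffle.
    """
    rng = np.random.default_rng(seed)
    hits = 0
    total = 0
    span = chrom_len - gene_len + 1
    while total < n_draws:
        m = n_draws - total
        s1 = rng.integers(0, span, size=m)
        s2 = rng.integers(0, span, size=m)
        ok = np.abs(s1 - s2) >= gene_len  # non-overlapping
        gap = np.abs(s1 - s2) - gene_len
        hits += int(np.sum(ok & (gap < gap_max)))
        total += int(ok.sum())
    return hits / total
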