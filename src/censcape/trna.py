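"""tRNA-gene cluster detection and a genome-shuffle permutation test.

Genes closer than ``gap_max`` (end-to-start, strictly less than 1000 bp
by default) are chained into clusters by a single greedy pass per
chromosome. A cluster is summarised by its *signature*: the sequence of
(cognate amino acid, strand) pairs in genomic order, canonicalised as
the lexicographic minimum of the string and its orientation flip
(reversed order with strands inverted), so a cluster and its
reverse-orientation mirror share one signature.

Significance of recurrent signatures is assessed by shuffling the gene
locations across the genome: each gene is re-placed uniformly at random
(chromosome chosen proportional to its length), keeping gene lengths,
strands and identities, forbidding overlap. For each observed signature
the p-value is the raw proportion of permutations in which the
signature occurred at least as many times as observed; a p of 0 only
means "below the resolution of n_perm" and is flagged as such.
Benjamini-Hochberg q-values account for testing many signatures.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .genome_io import Genome, Interval

__all__ = [
    "TrnaGene",
    "TrnaCluster",
    "PermutationResult",
    "cluster_trna_genes",
    "cluster_signature",
    "shuffle_gene_locations",
    "cluster_permutation_test",
    "bh_qvalues",
    "centromere_frequency_matrix",
    "read_trna_genes",
    "ClusterPermutationTest",
]


@dataclass(frozen=True)
class TrnaGene:
    """A tRNA gene: stranded interval plus cognate amino acid and anticodon."""

    interval: Interval
    amino_acid: str
    anticodon: str

    def __post_init__(self) -> None:
        if self.interval.strand not in "+-":
            raise ValueError("tRNA gene strand must be '+' or '-'")
        if len(self.amino_acid) != 1:
            raise ValueError("amino_acid must be a single letter")
        if len(self.anticodon) != 3 or set(self.anticodon) - set("ACGT"):
            raise ValueError("anticodon must be 3 letters over ACGT")


@dataclass
class TrnaCluster:
    """A maximal run of tRNA genes with inter-gene gaps below gap_max."""

    genes: tuple[TrnaGene, ...]
    span: Interval
    signature: str

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class PermutationResult:
    signature: str
    observed_count: int
    null_counts: np.ndarray
    p: float
    below_resolution: bool
    q: float
    n_perm: int
    seed: int | None = None


def _flip(pairs: tuple[tuple[str, str], ...]) -> tuple[tuple[str, str], ...]:
    swap = {"+": "-", "-": "+"}
    return tuple((aa, swap[s]) for aa, s in reversed(pairs))


def _canonical(pairs: tuple[tuple[str, str], ...]) -> str:
    fwd = "".join(f"{aa}{s}" for aa, s in pairs)
    rev = "".join(f"{aa}{s}" for aa, s in _flip(pairs))
    return min(fwd, rev)


def cluster_signature(genes: Sequence[TrnaGene] | TrnaCluster) -> str:
    """Canonical signature of a gene run (orientation-normalised)."""
    if isinstance(genes, TrnaCluster):
        genes = genes.genes
    if not genes:
        raise ValueError("empty cluster has no signature")
    ordered = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    pairs = tuple((g.amino_acid, g.interval.strand) for g in ordered)
    return _canonical(pairs)


def cluster_trna_genes(
    genes: Sequence[TrnaGene], gap_max: int = 1000
) -> list[TrnaCluster]:
    """Greedy single-pass clustering of genes with gaps < ``gap_max``.

    Genes must be non-overlapping; singletons are emitted as one-gene
    clusters. The result is independent of the input order.
    """
    ordered = sorted(genes, key=lambda g: (g.interval.chrom, g.interval.start))
    for prev, nxt in zip(ordered, ordered[1:]):
        if prev.interval.chrom == nxt.interval.chrom and nxt.interval.start < prev.interval.end:
            raise ValueError(
                f"overlapping tRNA genes at {prev.interval.chrom}:"
                f"{prev.interval.start}-{prev.interval.end} and "
                f"{nxt.interval.start}-{nxt.interval.end}"
            )
    clusters: list[TrnaCluster] = []
    run: list[TrnaGene] = []

    def close_run() -> None:
        if run:
            span = Interval(
                run[0].interval.chrom, run[0].interval.start, run[-1].interval.end
            )
            pairs = tuple((g.amino_acid, g.interval.strand) for g in run)
            clusters.append(
                TrnaCluster(genes=tuple(run), span=span, signature=_canonical(pairs))
            )

    for g in ordered:
        if run and (
            g.interval.chrom != run[-1].interval.chrom
            or g.interval.start - run[-1].interval.end >= gap_max
        ):
            close_run()
            run = []
        run.append(g)
    close_run()
    return clusters


# ---------------------------------------------------------------------------
# fast array representation used inside the permutation loop


def _gene_arrays(genome: Genome, genes: Sequence[TrnaGene]):
    names = genome.names
    chrom_idx = {name: i for i, name in enumerate(names)}
    for g in genes:
        if g.interval.chrom not in chrom_idx:
            raise KeyError(f"gene on unknown chromosome {g.interval.chrom!r}")
    chrom_lens = np.array([genome.lengths[n] for n in names], dtype=np.int64)
    lengths = np.array([g.interval.length for g in genes], dtype=np.int64)
    # token per gene: (amino acid, strand) and its orientation flip
    tokens = [(g.amino_acid, g.interval.strand) for g in genes]
    return chrom_lens, lengths, tokens


def _place_uniform(
    rng: np.random.Generator,
    chrom_lens: np.ndarray,
    lengths: np.ndarray,
    max_rounds: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping uniform placement of gene lengths on a genome.

    Chromosome chosen proportional to chromosome length; start uniform
    over the positions where the gene fits. Overlaps are resolved by
    re-drawing the later gene of each overlapping pair (bounded
    rejection sampling).
    """
    n = lengths.shape[0]
    probs = chrom_lens / chrom_lens.sum()
    chrom = rng.choice(chrom_lens.shape[0], size=n, p=probs)
    span = chrom_lens[chrom] - lengths + 1
    start = np.floor(rng.random(n) * np.maximum(span, 0)).astype(np.int64)
    redo = span <= 0
    for _ in range(max_rounds):
        if redo.any():
            m = int(redo.sum())
            chrom[redo] = rng.choice(chrom_lens.shape[0], size=m, p=probs)
            span = chrom_lens[chrom[redo]] - lengths[redo] + 1
            start[redo] = np.floor(rng.random(m) * np.maximum(span, 0)).astype(np.int64)
            bad_fit = np.zeros(n, dtype=bool)
            bad_fit[np.flatnonzero(redo)] = span <= 0
            redo = bad_fit
            if redo.any():
                continue
        order = np.lexsort((start, chrom))
        s, c = start[order], chrom[order]
        e = s + lengths[order]
        clash = (c[1:] == c[:-1]) & (s[1:] < e[:-1])
        if not clash.any():
            return chrom, start
        redo = np.zeros(n, dtype=bool)
        redo[order[1:][clash]] = True
    raise RuntimeError("could not place genes without overlap (genome too crowded)")


def shuffle_gene_locations(
    genome: Genome, genes: Sequence[TrnaGene], seed=None
) -> list[TrnaGene]:
    """Re-place every gene uniformly at random across the genome.

    Lengths, strands and identities are preserved; placements are
    non-overlapping and within chromosome bounds; reproducible by seed.
    """
    chrom_lens, lengths, _ = _gene_arrays(genome, genes)
    if lengths.sum() >= chrom_lens.sum():
        raise ValueError("total gene length must be smaller than the genome")
    rng = np.random.default_rng(seed)
    chrom, start = _place_uniform(rng, chrom_lens, lengths)
    names = genome.names
    out = []
    for g, c, s, L in zip(genes, chrom, start, lengths):
        iv = Interval(names[int(c)], int(s), int(s + L), g.interval.strand, g.interval.label)
        out.append(TrnaGene(iv, g.amino_acid, g.anticodon))
    return out


def _count_signatures(
    chrom: np.ndarray,
    start: np.ndarray,
    lengths: np.ndarray,
    tokens: list[tuple[str, str]],
    gap_max: int,
    wanted: dict[str, int] | None = None,
) -> Counter:
    """Canonical-signature multiplicities of size>=2 clusters in a placement."""
    order = np.lexsort((start, chrom))
    s, c = start[order], chrom[order]
    e = s + lengths[order]
    n = s.shape[0]
    counts: Counter = Counter()
    i = 0
    while i < n:
        j = i + 1
        while j < n and c[j] == c[i] and s[j] - e[j - 1] < gap_max:
            j += 1
        if j - i >= 2:
            pairs = tuple(tokens[int(order[t])] for t in range(i, j))
            sig = _canonical(pairs)
            if wanted is None or sig in wanted:
                counts[sig] += 1
        i = j
    return counts


def bh_qvalues(p_list) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order preserved, capped at 1)."""
    p = np.asarray(p_list, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_permutation_test(
    genome: Genome,
    genes: Sequence[TrnaGene],
    n_perm: int = 1000,
    seed: int | None = 0,
    gap_max: int = 1000,
    extra_signatures: Sequence[str] = (),
) -> list[PermutationResult]:
    """Location-shuffle significance test for recurrent cluster signatures.

    Observed clusters of size >= 2 define the tested signatures (plus
    any ``extra_signatures``, which get observed_count 0 and hence
    p = 1). For each of ``n_perm`` permutations the genes are re-placed
    uniformly, re-clustered and signature multiplicities tallied;
    p = #{null >= observed} / n_perm. Permutation ``i`` uses a stream
    derived from ``(seed, i)``, so runs are reproducible and
    parallelisable. Results are sorted by (p, signature).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    chrom_lens, lengths, tokens = _gene_arrays(genome, genes)
    observed_clusters = cluster_trna_genes(genes, gap_max=gap_max)
    observed = Counter(
        cl.signature for cl in observed_clusters if len(cl) >= 2
    )
    for sig in extra_signatures:
        observed.setdefault(sig, 0)
    if not observed:
        return []
    sigs = sorted(observed)
    null_counts = {sig: np.zeros(n_perm, dtype=np.int64) for sig in sigs}
    wanted = dict.fromkeys(sigs, 0)
    for i in range(n_perm):
        rng = np.random.default_rng(np.random.SeedSequence((0 if seed is None else seed, i)))
        chrom, start = _place_uniform(rng, chrom_lens, lengths)
        counts = _count_signatures(chrom, start, lengths, tokens, gap_max, wanted)
        for sig, c in counts.items():
            null_counts[sig][i] = c
    ps = np.array(
        [(null_counts[sig] >= observed[sig]).mean() for sig in sigs], dtype=np.float64
    )
    qs = bh_qvalues(ps)
    results = [
        PermutationResult(
            signature=sig,
            observed_count=int(observed[sig]),
            null_counts=null_counts[sig],
            p=float(p),
            below_resolution=bool(p == 0.0),
            q=float(q),
            n_perm=n_perm,
            seed=seed,
        )
        for sig, p, q in zip(sigs, ps, qs)
    ]
    results.sort(key=lambda r: (r.p, r.signature))
    return results


def centromere_frequency_matrix(
    genes: Sequence[TrnaGene], centromeres: Sequence[Interval]
) -> pd.DataFrame:
    """Per-anticodon counts of tRNA genes inside vs outside centromeres.

    A gene is centromeric when its interval overlaps any centromere
    interval. The returned frame is indexed by (amino_acid, anticodon)
    with columns ``centromeric``, ``non_centromeric``, ``total`` and
    ``centromeric_fraction``, plus a final ("ALL", "ALL") totals row
    whose fraction is the overall centromeric fraction of tRNA genes.
    """
    rows: dict[tuple[str, str], list[int]] = {}
    cen_by_chrom: dict[str, list[Interval]] = {}
    for iv in centromeres:
        cen_by_chrom.setdefault(iv.chrom, []).append(iv)
    n_cen = 0
    for g in genes:
        key = (g.amino_acid, g.anticodon)
        inside = any(
            g.interval.overlaps(iv) for iv in cen_by_chrom.get(g.interval.chrom, ())
        )
        n_cen += inside
        cell = rows.setdefault(key, [0, 0])
        cell[0 if inside else 1] += 1
    index = pd.MultiIndex.from_tuples(
        sorted(rows) + [("ALL", "ALL")], names=["amino_acid", "anticodon"]
    )
    data = [rows[key] for key in sorted(rows)] + [[n_cen, len(genes) - n_cen]]
    df = pd.DataFrame(data, index=index, columns=["centromeric", "non_centromeric"])
    df["total"] = df["centromeric"] + df["non_centromeric"]
    with np.errstate(invalid="ignore"):
        df["centromeric_fraction"] = df["centromeric"] / df["total"]
    return df


def read_trna_genes(path, fmt: str = "bed") -> list[TrnaGene]:
    """Read tRNA genes from BED6 (name 'A-AGC': amino acid-anticodon) or GFF3.

    GFF3 records must carry ``amino_acid`` and ``anticodon`` attributes.
    """
    from .genome_io import read_intervals

    genes = []
    if fmt.lower() == "bed":
        for iv in read_intervals(path, "bed"):
            try:
                aa, anticodon = iv.label.split("-", 1)
            except ValueError as exc:
                raise ValueError(
                    f"tRNA BED name must be 'AminoAcid-Anticodon', got {iv.label!r}"
                ) from exc
            genes.append(TrnaGene(iv, aa, anticodon))
    else:
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                attrs = dict(
                    kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
                )
                try:
                    iv = Interval(f[0], int(f[3]) - 1, int(f[4]), f[6])
                    genes.append(
                        TrnaGene(iv, attrs["amino_acid"], attrs["anticodon"])
                    )
                except (KeyError, ValueError, IndexError) as exc:
                    raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return genes


class ClusterPermutationTest(BaseEstimator):
    """Estimator wrapper around :func:`cluster_permutation_test`.

    ``fit(genes, genome)`` runs the test; fitted attributes are
    ``results_`` (list of :class:`PermutationResult`), ``pvalues_``,
    ``qvalues_`` and ``signatures_``.
    """

    def __init__(
        self, n_perm: int = 1000, gap_max: int = 1000, random_state: int | None = 0
    ):
        self.n_perm = n_perm
        self.gap_max = gap_max
        self.random_state = random_state

    def fit(self, genes: Sequence[TrnaGene], genome: Genome):
        self.results_ = cluster_permutation_test(
            genome,
            genes,
            n_perm=self.n_perm,
            seed=self.random_state,
            gap_max=self.gap_max,
        )
        self.signatures_ = np.asarray([r.signature for r in self.results_])
        self.pvalues_ = np.asarray([r.p for r in self.results_])
        self.qvalues_ = np.asarray([r.q for r in self.results_])
        return self

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "signature": self.signatures_,
                "observed": [r.observed_count for r in self.results_],
                "p": self.pvalues_,
                "below_resolution": [r.below_resolution for r in self.results_],
                "q": self.qvalues_,
            }
        )
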