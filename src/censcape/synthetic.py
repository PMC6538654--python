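"""Synthetic genomes with planted centromere-like sequence structure.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised end to end without external
data:

* background sequence is drawn i.i.d. from a configurable base
  composition (defaults approximate the AT-rich fission-yeast genome);
* each chromosome carries one centromere-like domain whose sequence is
  drawn from a first-order Markov chain sharing the background's
  stationary base composition -- GC content is matched by construction,
  but dinucleotide (hence 5-mer) usage is biased, exactly the kind of
  signal a mononucleotide-shuffle null is designed to expose. The chain
  is the "sticky" perturbation of the i.i.d. kernel,
  ``T = (1 - eps) * 1 p' + eps * I``, whose stationary distribution is
  the base composition for every ``eps`` in [0, 1);
* CENP-A peaks cover the core of each planted centromere, H3K9 peaks
  cover its flanks and subtelomeric blocks, and one mating-type locus
  and one neocentromere-forming region are laid down, all aligned to
  the analysis window grid so truth labels are unambiguous;
* tRNA-gene annotations combine planted centromere-exclusive clusters
  (one copy of each configured signature per centromere, intra-cluster
  gaps well below 1 kb) with uniformly scattered decoy singletons kept
  >= 1 kb apart;
* colony counts for the minichromosome assays are binomially sampled.

All randomness flows from a single master seed with named substreams
per artifact, so genomes, annotations and counts are independently
reproducible.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Genome, Interval, Window, WindowingConfig, make_windows
from .trna import TrnaGene, _place_uniform

__all__ = [
    "SynthConfig",
    "SynthTruth",
    "SynthAnnotations",
    "transition_matrix",
    "synth_genome",
    "synth_annotations",
    "synth_colony_counts",
    "scatter_genes",
    "AA_TO_ANTICODON",
]

# named substreams off the master seed
_STREAM_SEQUENCE = 0
_STREAM_GENES = 1
_STREAM_COLONY = 2

#: one representative anticodon per cognate amino acid
AA_TO_ANTICODON = {
    "A": "AGC", "C": "GCA", "D": "GTC", "E": "TTC", "F": "GAA",
    "G": "GCC", "H": "GTG", "I": "AAT", "K": "CTT", "L": "CAA",
    "M": "CAT", "N": "GTT", "P": "AGG", "Q": "TTG", "R": "ACG",
    "S": "AGA", "T": "AGT", "V": "AAC", "W": "CCA", "Y": "GTA",
}

_DEFAULT_CLUSTER = ((("D", "+"), ("V", "+"), ("A", "+")),)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults define the standard study genome."""

    n_chromosomes: int = 3
    chromosome_length: int = 4_000_000
    base_composition: tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32)
    bias_epsilon: float = 0.15
    cenpa_core_width: int = 30_000
    h3k9_flank_width: int = 9_000
    subtel_block_width: int = 30_000
    mat_width: int = 15_000
    neocen_width: int = 12_000
    planted_cluster_signatures: tuple = _DEFAULT_CLUSTER
    decoy_gene_count: int = 150
    gene_length: int = 72
    decoy_min_gap: int = 1_000
    windowing: WindowingConfig = field(default_factory=WindowingConfig)
    p_establish: float = 0.94
    p_loss: float = 0.058
    n_transformants: int = 217
    n_colonies: int = 3_284
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=np.float64)
        if comp.shape != (4,) or not np.isclose(comp.sum(), 1.0) or (comp <= 0).any():
            raise ValueError("base_composition must be 4 positive probabilities summing to 1")
        if not (0 <= self.bias_epsilon < 1):
            raise ValueError("bias_epsilon must be in [0, 1)")
        if self.chromosome_length < 2 * self.subtel_block_width + self.cenpa_core_width:
            raise ValueError("chromosome too short for the requested layout")


@dataclass
class SynthLayout:
    """Deterministic feature placement derived from a config."""

    chrom_names: list[str]
    cores: dict[str, Interval]
    flanks: dict[str, list[Interval]]
    centromeres: dict[str, Interval]
    subtel_blocks: dict[str, list[Interval]]
    mat: Interval | None
    neocen: Interval | None


@dataclass
class SynthTruth:
    """Ground truth emitted alongside a synthetic genome."""

    window_labels: list[tuple[Window, str]]
    planted_clusters: list[Interval]
    layout: SynthLayout
    config: SynthConfig

    def labels_by_name(self) -> dict[str, str]:
        return {w.name: lab for w, lab in self.window_labels}


@dataclass
class SynthAnnotations:
    """Annotation tracks consistent with a genome's truth labels."""

    trna_genes: list[TrnaGene]
    cenpa_peaks: list[Interval]
    h3k9_peaks: list[Interval]
    mat_regions: list[Interval]
    neocen_regions: list[Interval]
    centromeres: list[Interval]


def transition_matrix(cfg: SynthConfig) -> np.ndarray:
    """Perturbed Markov kernel for centromere-like sequence.

    ``T = (1 - eps) * 1 p' + eps * I``: with probability ``eps`` the
    chain repeats the previous base, otherwise it draws fresh from the
    base composition. Rows sum to 1 and the stationary distribution is
    the base composition for every ``eps`` in [0, 1); both properties
    are verified numerically.
    """
    p = np.asarray(cfg.base_composition, dtype=np.float64)
    T = (1.0 - cfg.bias_epsilon) * np.tile(p, (4, 1)) + cfg.bias_epsilon * np.eye(4)
    if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("perturbed kernel rows do not sum to 1")
    if not np.allclose(p @ T, p, atol=1e-9):
        raise ValueError("perturbed kernel does not admit the base composition "
                         "as stationary distribution")
    return T


def _grid(pos: int, step: int) -> int:
    return (pos // step) * step


def _layout(cfg: SynthConfig) -> SynthLayout:
    step = cfg.windowing.step
    names = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    L = cfg.chromosome_length
    cores, flanks, centromeres, subtels = {}, {}, {}, {}
    for name in names:
        c = _grid(L // 2, step)
        core = Interval(name, c, c + cfg.cenpa_core_width, label="cenpa_core")
        fw = cfg.h3k9_flank_width
        fl = [
            Interval(name, core.start - fw, core.start, label="h3k9_flank"),
            Interval(name, core.end, core.end + fw, label="h3k9_flank"),
        ]
        cores[name] = core
        flanks[name] = fl
        centromeres[name] = Interval(name, core.start - fw, core.end + fw,
                                     label="centromere")
        sw = cfg.subtel_block_width
        subtels[name] = [
            Interval(name, 0, sw, label="subtel"),
            Interval(name, L - sw, L, label="subtel"),
        ]
    mat = None
    if cfg.n_chromosomes >= 2 and cfg.mat_width > 0:
        m = _grid(L // 4, step)
        mat = Interval(names[1], m, m + cfg.mat_width, label="mat")
    neocen = None
    if cfg.neocen_width > 0:
        n0 = _grid(3 * L // 4, step)
        neocen = Interval(names[-1], n0, n0 + cfg.neocen_width, label="neocen")
    # features must not collide
    placed = []
    for name in names:
        placed.extend([centromeres[name], *subtels[name]])
    if mat:
        placed.append(mat)
    if neocen:
        placed.append(neocen)
    by_chrom: dict[str, list[Interval]] = {}
    for iv in placed:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValueError("layout features collide; enlarge the chromosome")
    return SynthLayout(names, cores, flanks, centromeres, subtels, mat, neocen)


def _sticky_chain(rng: np.random.Generator, n: int, p: np.ndarray, eps: float) -> np.ndarray:
    """Vectorised simulation of the sticky Markov chain (codes 0..3)."""
    fresh = rng.choice(4, size=n, p=p)
    if eps == 0.0 or n == 1:
        return fresh
    keep = rng.random(n) < eps
    keep[0] = False
    pos = np.arange(n)
    last_fresh = np.maximum.accumulate(np.where(keep, -1, pos))
    return fresh[last_fresh]


_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def _truth_labels(cfg: SynthConfig, layout: SynthLayout, genome: Genome) -> list[tuple[Window, str]]:
    """Intended chromatin label per window, from the planted geometry."""
    windows = make_windows(genome, cfg.windowing)
    half = 0.5 * cfg.windowing.window_len
    out: list[tuple[Window, str]] = []
    # first pass: CENP-A core coverage
    prelim: list[str | None] = []
    for w in windows:
        core = layout.cores[w.chrom]
        prelim.append("CENPA" if w.interval.overlap_len(core) > 6000 else None)
    anchors: dict[str, list[Interval]] = {}
    for name in layout.chrom_names:
        anchors[name] = [layout.cores[name]]
    for w, lab in zip(windows, prelim):
        if lab == "CENPA":
            anchors[w.chrom].append(w.interval)
    lengths = genome.lengths
    for w, lab in zip(windows, prelim):
        if lab is None:
            iv = w.interval
            h3k9 = sum(iv.overlap_len(f) for f in layout.flanks[w.chrom])
            h3k9 += sum(iv.overlap_len(b) for b in layout.subtel_blocks[w.chrom])
            if layout.neocen and iv.overlaps(layout.neocen):
                lab = "NEOCEN"
            elif layout.mat and iv.overlap_len(layout.mat) > half:
                lab = "MAT"
            elif h3k9 > half and any(
                iv.distance(a) <= 1 for a in anchors[w.chrom]
            ):
                lab = "CEN_HET"
            elif h3k9 > half and min(iv.start, lengths[w.chrom] - iv.end) < 100_000:
                lab = "SUBTEL"
            else:
                lab = "OTHER"
        out.append((w, lab))
    return out


def synth_genome(cfg: SynthConfig | None = None) -> tuple[Genome, SynthTruth]:
    """Generate a synthetic genome with compositionally biased centromeres.

    Background sequence is i.i.d. from ``cfg.base_composition``; each
    planted centromere interval is overwritten with a sticky-chain
    segment at the same stationary composition, so GC is matched but
    higher-order composition is biased with strength ``bias_epsilon``.
    Deterministic for a fixed ``cfg.seed``.
    """
    cfg = cfg or SynthConfig()
    layout = _layout(cfg)
    T = transition_matrix(cfg)  # validates the kernel
    del T
    p = np.asarray(cfg.base_composition, dtype=np.float64)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, _STREAM_SEQUENCE)))
    chroms: dict[str, str] = {}
    for name in layout.chrom_names:
        codes = rng.choice(4, size=cfg.chromosome_length, p=p)
        cen = layout.centromeres[name]
        codes[cen.start : cen.end] = _sticky_chain(
            rng, cen.length, p, cfg.bias_epsilon
        )
        chroms[name] = _codes_to_str(codes.astype(np.uint8))
    genome = Genome(chroms)
    truth = SynthTruth(
        window_labels=_truth_labels(cfg, layout, genome),
        planted_clusters=[],
        layout=layout,
        config=cfg,
    )
    return genome, truth


def _planted_genes(cfg: SynthConfig, layout: SynthLayout) -> tuple[list[TrnaGene], list[Interval]]:
    genes: list[TrnaGene] = []
    spans: list[Interval] = []
    intra_gap = 300  # well under the 1 kb clustering threshold
    for name in layout.chrom_names:
        offset = layout.centromeres[name].start + 200
        for sig in cfg.planted_cluster_signatures:
            start = offset
            first = start
            for aa, strand in sig:
                iv = Interval(name, start, start + cfg.gene_length, strand,
                              f"{aa}-{AA_TO_ANTICODON[aa]}")
                genes.append(TrnaGene(iv, aa, AA_TO_ANTICODON[aa]))
                start += cfg.gene_length + intra_gap
            spans.append(Interval(name, first, start - intra_gap, label="planted_cluster"))
            offset = start + cfg.decoy_min_gap + 200
    return genes, spans


def _decoy_genes(
    cfg: SynthConfig,
    layout: SynthLayout,
    rng: np.random.Generator,
    existing: Sequence[TrnaGene],
) -> list[TrnaGene]:
    """Uniform singleton decoys outside centromeres, >= decoy_min_gap apart."""
    aa_pool = sorted(AA_TO_ANTICODON)
    occupied: dict[str, list[tuple[int, int]]] = {n: [] for n in layout.chrom_names}
    for g in existing:
        occupied[g.interval.chrom].append((g.interval.start, g.interval.end))
    for ivs in occupied.values():
        ivs.sort()
    lengths = {n: cfg.chromosome_length for n in layout.chrom_names}
    names = layout.chrom_names
    probs = np.full(len(names), 1.0 / len(names))
    out: list[TrnaGene] = []
    attempts = 0
    max_attempts = 200 * max(cfg.decoy_gene_count, 1)
    while len(out) < cfg.decoy_gene_count:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("could not place decoy genes (genome too crowded)")
        ci = int(rng.choice(len(names), p=probs))
        name = names[ci]
        start = int(rng.integers(0, lengths[name] - cfg.gene_length + 1))
        end = start + cfg.gene_length
        cen = layout.centromeres[name]
        if start < cen.end and end > cen.start:
            continue
        ivs = occupied[name]
        k = bisect_left(ivs, (start, end))
        gap = cfg.decoy_min_gap
        if k > 0 and start - ivs[k - 1][1] < gap:
            continue
        if k < len(ivs) and ivs[k][0] - end < gap:
            continue
        aa = str(rng.choice(aa_pool))
        strand = "+" if rng.random() < 0.5 else "-"
        iv = Interval(name, start, end, strand, f"{aa}-{AA_TO_ANTICODON[aa]}")
        out.append(TrnaGene(iv, aa, AA_TO_ANTICODON[aa]))
        insort(ivs, (start, end))
    return out


def synth_annotations(cfg: SynthConfig, truth: SynthTruth) -> SynthAnnotations:
    """Emit peak/region/gene annotations consistent with the truth labels.

    CENP-A peaks cover the planted cores, H3K9 peaks the flanks and
    subtelomeric blocks; planted tRNA clusters go inside the centromere
    intervals with intra-cluster gaps < 1 kb, decoy singletons outside.
    """
    layout = truth.layout
    planted, spans = _planted_genes(cfg, layout)
    truth.planted_clusters = spans
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, _STREAM_GENES)))
    decoys = _decoy_genes(cfg, layout, rng, planted)
    genes = sorted(planted + decoys, key=lambda g: (g.interval.chrom, g.interval.start))
    cenpa = [replace(layout.cores[n], label="cenpa_peak") for n in layout.chrom_names]
    h3k9 = []
    for n in layout.chrom_names:
        h3k9.extend(replace(f, label="h3k9_peak") for f in layout.flanks[n])
        h3k9.extend(replace(b, label="h3k9_peak") for b in layout.subtel_blocks[n])
    return SynthAnnotations(
        trna_genes=genes,
        cenpa_peaks=cenpa,
        h3k9_peaks=h3k9,
        mat_regions=[layout.mat] if layout.mat else [],
        neocen_regions=[layout.neocen] if layout.neocen else [],
        centromeres=[layout.centromeres[n] for n in layout.chrom_names],
    )


def scatter_genes(
    genome: Genome,
    n_genes: int,
    amino_acids: Sequence[str] = tuple(sorted(AA_TO_ANTICODON)),
    gene_length: int = 72,
    seed: int | None = 0,
    strands: Sequence[str] = ("+", "-"),
) -> list[TrnaGene]:
    """Uniformly scattered genes with no spacing constraint (null model).

    Unlike the decoy placement, genes may fall arbitrarily close to one
    another, so chance clusters form at the rate implied by gene density
    -- the appropriate null for calibrating the cluster permutation
    test.
    """
    rng = np.random.default_rng(seed)
    chrom_lens = np.array([genome.lengths[n] for n in genome.names], dtype=np.int64)
    lengths = np.full(n_genes, gene_length, dtype=np.int64)
    chrom, start = _place_uniform(rng, chrom_lens, lengths)
    names = genome.names
    out = []
    for i in range(n_genes):
        aa = str(rng.choice(list(amino_acids)))
        strand = str(rng.choice(list(strands)))
        iv = Interval(names[int(chrom[i])], int(start[i]), int(start[i] + gene_length),
                      strand, f"{aa}-{AA_TO_ANTICODON[aa]}")
        out.append(TrnaGene(iv, aa, AA_TO_ANTICODON[aa]))
    return out


def synth_colony_counts(
    p_establish: float = 0.94,
    p_loss: float = 0.058,
    n_transformants: int = 217,
    n_colonies: int = 3_284,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Binomially sampled colony counts for the minichromosome assays."""
    for p in (p_establish, p_loss):
        if not (0 <= p <= 1):
            raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence((0 if seed is None else seed,
                                                        _STREAM_COLONY)))
    n_white = int(rng.binomial(n_transformants, p_establish))
    n_half = int(rng.binomial(n_colonies, p_loss))
    return pd.DataFrame(
        [
            {
                "plasmid": "synthetic",
                "n_transformants": n_transformants,
                "n_white": n_white,
                "n_checked": 0,
                "n_integrants": 0,
                "n_colonies": n_colonies,
                "n_half_sectored": n_half,
            }
        ]
    )
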