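"""Genome containers, interval algebra and fixed-width sliding windows.

All coordinates are 0-based, half-open (BED convention). GFF3 input
(1-based, inclusive) is converted on read. Windows are anchored at
position 0 of each chromosome and partial terminal windows are dropped,
so every window has exactly the configured length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Genome",
    "Interval",
    "Window",
    "WindowingConfig",
    "read_fasta",
    "write_fasta",
    "read_intervals",
    "write_intervals",
    "make_windows",
    "interval_coverage",
]

#: IUPAC one-letter DNA codes accepted in genome sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")

_NON_IUPAC = re.compile("[^ACGTRYSWKMBDHVN]")

_STRANDS = (".", "+", "-")


@dataclass(frozen=True, order=True)
class Interval:
    """A genomic interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "Interval") -> int:
        """Gap between intervals on the same chromosome (0 if they touch/overlap)."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        return max(0, other.start - self.end, self.start - other.end)

    @property
    def name(self) -> str:
        return self.label or f"{self.chrom}:{self.start}-{self.end}"


class Genome:
    """Ordered collection of chromosome sequences.

    Sequences are stored upper-cased and validated against the IUPAC
    one-letter DNA alphabet. Chromosome order is the insertion order of
    the mapping (record order for FASTA input).
    """

    def __init__(self, chromosomes: Mapping[str, str]):
        if not chromosomes:
            raise ValueError("no records: genome must contain at least one chromosome")
        self._chromosomes: dict[str, str] = {}
        for name, seq in chromosomes.items():
            if name in self._chromosomes:
                raise ValueError(f"duplicate chromosome id {name!r}")
            if not seq:
                raise ValueError(f"chromosome {name!r} has empty sequence")
            seq = seq.upper()
            m = _NON_IUPAC.search(seq)
            if m:
                raise ValueError(
                    f"non-IUPAC character {m.group()!r} in chromosome {name!r} "
                    f"at position {m.start()}"
                )
            self._chromosomes[name] = seq

    @property
    def chromosomes(self) -> dict[str, str]:
        return dict(self._chromosomes)

    @property
    def names(self) -> list[str]:
        return list(self._chromosomes)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self._chromosomes.items()}

    @property
    def total_length(self) -> int:
        return sum(len(seq) for seq in self._chromosomes.values())

    def __contains__(self, name: str) -> bool:
        return name in self._chromosomes

    def __getitem__(self, name: str) -> str:
        return self._chromosomes[name]

    def __len__(self) -> int:
        return len(self._chromosomes)

    def __iter__(self) -> Iterator[str]:
        return iter(self._chromosomes)

    def fetch(self, interval: Interval) -> str:
        """Sequence under ``interval`` (clipped coordinates are an error)."""
        if interval.chrom not in self._chromosomes:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        seq = self._chromosomes[interval.chrom]
        if interval.end > len(seq):
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"extends past chromosome end ({len(seq)} bp)"
            )
        return seq[interval.start : interval.end]


def read_fasta(path) -> Genome:
    """Read a (multi-record) FASTA file into a :class:`Genome`.

    Record ids are parsed up to the first whitespace; sequences are
    upper-cased. Duplicate ids and non-IUPAC characters raise.
    """
    chromosomes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chromosomes:
            raise ValueError(f"duplicate chromosome id {rec.id!r} in {path}")
        chromosomes[rec.id] = str(rec.seq)
    if not chromosomes:
        raise ValueError(f"no records in FASTA file {path}")
    return Genome(chromosomes)


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.chromosomes.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_intervals(path, fmt: str = "bed") -> list[Interval]:
    """Read intervals from BED (3-6 column) or GFF3.

    BED is taken as-is (0-based half-open); GFF3 start/end (1-based
    inclusive) are converted to 0-based half-open. Strand column is
    honoured where present, with '.' allowed.
    """
    fmt = fmt.lower()
    if fmt not in ("bed", "gff3", "gff"):
        raise ValueError(f"unknown interval format {fmt!r}")
    out: list[Interval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("track"):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated BED
                fields = line.split()
            try:
                if fmt == "bed":
                    chrom = fields[0]
                    start, end = int(fields[1]), int(fields[2])
                    label = fields[3] if len(fields) > 3 else ""
                    strand = fields[5] if len(fields) > 5 else "."
                else:
                    chrom = fields[0]
                    start, end = int(fields[3]) - 1, int(fields[4])
                    strand = fields[6] if len(fields) > 6 and fields[6] in "+-" else "."
                    label = fields[2] if len(fields) > 2 else ""
                if start >= end:
                    raise ValueError("start >= end")
                out.append(Interval(chrom, start, end, strand, label))
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}, line {lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[Interval], path) -> None:
    """Write intervals as 6-column BED (score column fixed at 0)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


@dataclass(frozen=True)
class WindowingConfig:
    """Sliding-window geometry: 12 kb windows overlapping by 4.5 kb by default."""

    window_len: int = 12_000
    overlap: int = 4_500

    def __post_init__(self) -> None:
        if not (0 <= self.overlap < self.window_len):
            raise ValueError("require 0 <= overlap < window_len")

    @property
    def step(self) -> int:
        return self.window_len - self.overlap


@dataclass(frozen=True)
class Window:
    """A fixed-length genome window with its per-chromosome ordinal."""

    interval: Interval
    index: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def make_windows(genome: Genome, cfg: WindowingConfig | None = None) -> list[Window]:
    """Tile each chromosome with full-length sliding windows.

    Windows start at coordinate 0 and advance by ``cfg.step``; partial
    terminal windows are dropped. Order is deterministic: chromosome
    order, then start coordinate.
    """
    cfg = cfg or WindowingConfig()
    windows: list[Window] = []
    for chrom, seq in genome.chromosomes.items():
        L = len(seq)
        idx = 0
        for start in range(0, L - cfg.window_len + 1, cfg.step):
            iv = Interval(chrom, start, start + cfg.window_len)
            windows.append(Window(iv, idx))
            idx += 1
    return windows


def interval_coverage(window: Interval, peaks: Sequence[Interval]) -> int:
    """Base pairs of ``window`` covered by the union of ``peaks``.

    Peaks on other chromosomes are ignored; peaks are clipped to the
    window, then their union length is returned (overlapping peaks are
    not double-counted).
    """
    clipped = sorted(
        (max(p.start, window.start), min(p.end, window.end))
        for p in peaks
        if p.chrom == window.chrom and p.start < window.end and p.end > window.start
    )
    covered = 0
    cur_start = cur_end = None
    for s, e in clipped:
        if cur_end is None or s > cur_end:
            if cur_end is not None:
                covered += cur_end - cur_start
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start
    return covered
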