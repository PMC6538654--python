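"""Chromatin-group assignment of genome windows.

Each fixed-length window receives exactly one of six labels, by the
first matching rule in priority order:

1. ``CENPA``   -- CENP-A peak coverage strictly greater than
   ``cenpa_cov_min`` (default 6 kb of a 12 kb window);
2. ``NEOCEN``  -- the window overlaps a neocentromere-forming region;
3. ``MAT``     -- more than ``half_cov`` of the window lies in the
   mating-type locus;
4. ``CEN_HET`` -- more than ``half_cov`` of the window is covered by
   H3K9me2 peaks and the window abuts (gap <= ``adjacency_gap``) a
   CENP-A peak or a CENPA-labelled window;
5. ``SUBTEL``  -- more than ``half_cov`` of the window is covered by
   H3K9me2 peaks and the window lies within ``telomere_proximity`` of
   either chromosome end;
6. ``OTHER``   -- everything else.

The CENP-A rule runs first because it is the most specific; the
adjacency and telomere distances are configurable because no canonical
values exist for them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .genome_io import Genome, Interval, Window, interval_coverage

__all__ = [
    "GROUP_LABELS",
    "GroupAnnotation",
    "classify_windows",
    "top_enriched_windows",
    "random_control_windows",
    "WindowGroupClassifier",
]

#: the six chromatin group labels, in rule priority order
GROUP_LABELS = ("CENPA", "NEOCEN", "MAT", "CEN_HET", "SUBTEL", "OTHER")


@dataclass
class GroupAnnotation:
    """Peak/region inputs and thresholds for window classification."""

    cenpa_peaks: list[Interval] = field(default_factory=list)
    h3k9_peaks: list[Interval] = field(default_factory=list)
    mat_regions: list[Interval] = field(default_factory=list)
    neocen_regions: list[Interval] = field(default_factory=list)
    telomere_proximity: int = 100_000
    cenpa_cov_min: int = 6_000
    half_cov: float = 0.5
    adjacency_gap: int = 1

    def __post_init__(self) -> None:
        if self.telomere_proximity <= 0 or self.cenpa_cov_min <= 0:
            raise ValueError("thresholds must be positive")
        if not (0 < self.half_cov < 1):
            raise ValueError("half_cov must be in (0, 1)")


def _by_chrom(intervals: Sequence[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


def _check_resolvable(ann: GroupAnnotation, genome: Genome) -> None:
    for group in (ann.cenpa_peaks, ann.h3k9_peaks, ann.mat_regions, ann.neocen_regions):
        for iv in group:
            if iv.chrom not in genome:
                raise KeyError(f"interval on unknown chromosome {iv.chrom!r}")


def classify_windows(
    windows: Sequence[Window], ann: GroupAnnotation, genome: Genome
) -> list[tuple[Window, str]]:
    """Assign each window to exactly one chromatin group.

    See the module docstring for the rule cascade. Returns (window,
    label) pairs in the input window order.
    """
    _check_resolvable(ann, genome)
    lengths = genome.lengths
    cenpa = _by_chrom(ann.cenpa_peaks)
    h3k9 = _by_chrom(ann.h3k9_peaks)
    mat = _by_chrom(ann.mat_regions)
    neo = _by_chrom(ann.neocen_regions)

    # first pass: CENP-A coverage decides the CENPA group
    labels: list[str | None] = []
    for w in windows:
        if w.chrom not in lengths:
            raise KeyError(f"window on unknown chromosome {w.chrom!r}")
        cov = interval_coverage(w.interval, cenpa.get(w.chrom, ()))
        labels.append("CENPA" if cov > ann.cenpa_cov_min else None)

    # adjacency anchors: CENP-A peaks plus CENPA-labelled windows
    anchors = _by_chrom(
        list(ann.cenpa_peaks)
        + [w.interval for w, lab in zip(windows, labels) if lab == "CENPA"]
    )

    out: list[tuple[Window, str]] = []
    for w, label in zip(windows, labels):
        if label is None:
            half = ann.half_cov * w.interval.length
            if any(w.interval.overlaps(r) for r in neo.get(w.chrom, ())):
                label = "NEOCEN"
            elif interval_coverage(w.interval, mat.get(w.chrom, ())) > half:
                label = "MAT"
            else:
                h3k9_cov = interval_coverage(w.interval, h3k9.get(w.chrom, ()))
                near_cenpa = any(
                    w.interval.distance(a) <= ann.adjacency_gap
                    for a in anchors.get(w.chrom, ())
                )
                L = lengths[w.chrom]
                near_telomere = min(w.start, L - w.end) < ann.telomere_proximity
                if h3k9_cov > half and near_cenpa:
                    label = "CEN_HET"
                elif h3k9_cov > half and near_telomere:
                    label = "SUBTEL"
                else:
                    label = "OTHER"
        out.append((w, label))
    return out


def _overlaps_any(w: Window, excluded: dict[str, list[Interval]]) -> bool:
    return any(w.interval.overlaps(iv) for iv in excluded.get(w.chrom, ()))


def top_enriched_windows(
    windows: Sequence[Window],
    scores: Sequence[float] | Mapping[Window, float],
    n: int,
    exclude: Sequence[Interval] = (),
) -> list[Window]:
    """The ``n`` highest-scoring windows not overlapping ``exclude``.

    Ties are broken in favour of the genomically earlier window (input
    order is taken to be genomic order), making the selection
    deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(scores, Mapping):
        score_list = [float(scores[w]) for w in windows]
    else:
        score_list = [float(s) for s in scores]
        if len(score_list) != len(windows):
            raise ValueError("scores and windows length mismatch")
    if not all(np.isfinite(score_list)):
        raise ValueError("scores must be finite")
    excluded = _by_chrom(exclude)
    eligible = [
        (s, i, w)
        for i, (w, s) in enumerate(zip(windows, score_list))
        if not _overlaps_any(w, excluded)
    ]
    if n > len(eligible):
        raise ValueError(f"requested {n} windows but only {len(eligible)} eligible")
    eligible.sort(key=lambda t: (-t[0], t[1]))
    return [w for _, _, w in eligible[:n]]


def random_control_windows(
    windows: Sequence[Window],
    exclude: Sequence[Interval],
    n: int,
    seed: int | None = None,
) -> list[Window]:
    """``n`` windows sampled uniformly without replacement outside ``exclude``.

    Returned in genomic (input) order; reproducible for a fixed seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    excluded = _by_chrom(exclude)
    eligible_idx = [
        i for i, w in enumerate(windows) if not _overlaps_any(w, excluded)
    ]
    if n > len(eligible_idx):
        raise ValueError(
            f"requested {n} control windows but only {len(eligible_idx)} eligible"
        )
    if n == 0:
        return []
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible_idx), size=n, replace=False)
    return [windows[eligible_idx[i]] for i in sorted(chosen)]


class WindowGroupClassifier(BaseEstimator):
    """Rule-based chromatin-group classifier over genome windows.

    A scikit-learn-style estimator: parameters are the annotation
    intervals and thresholds, ``fit`` binds the genome (validating that
    all intervals are resolvable on it) and ``predict`` labels windows.
    """

    def __init__(
        self,
        cenpa_peaks: Sequence[Interval] = (),
        h3k9_peaks: Sequence[Interval] = (),
        mat_regions: Sequence[Interval] = (),
        neocen_regions: Sequence[Interval] = (),
        telomere_proximity: int = 100_000,
        cenpa_cov_min: int = 6_000,
        half_cov: float = 0.5,
        adjacency_gap: int = 1,
    ):
        self.cenpa_peaks = cenpa_peaks
        self.h3k9_peaks = h3k9_peaks
        self.mat_regions = mat_regions
        self.neocen_regions = neocen_regions
        self.telomere_proximity = telomere_proximity
        self.cenpa_cov_min = cenpa_cov_min
        self.half_cov = half_cov
        self.adjacency_gap = adjacency_gap

    def _annotation(self) -> GroupAnnotation:
        return GroupAnnotation(
            cenpa_peaks=list(self.cenpa_peaks),
            h3k9_peaks=list(self.h3k9_peaks),
            mat_regions=list(self.mat_regions),
            neocen_regions=list(self.neocen_regions),
            telomere_proximity=self.telomere_proximity,
            cenpa_cov_min=self.cenpa_cov_min,
            half_cov=self.half_cov,
            adjacency_gap=self.adjacency_gap,
        )

    def fit(self, genome: Genome, y=None):
        ann = self._annotation()
        _check_resolvable(ann, genome)
        self.genome_ = genome
        self.classes_ = np.asarray(GROUP_LABELS)
        return self

    def predict(self, windows: Sequence[Window]) -> np.ndarray:
        if not hasattr(self, "genome_"):
            raise RuntimeError("classifier is not fitted; call fit(genome) first")
        pairs = classify_windows(windows, self._annotation(), self.genome_)
        return np.asarray([label for _, label in pairs])
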