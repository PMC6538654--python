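"""Shared fixtures: small synthetic genomes and the full default pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from censcape import (
    EnrichmentPCA,
    GroupAnnotation,
    classify_windows,
    profile_matrix,
)
from censcape.synthetic import SynthConfig, synth_annotations, synth_genome


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down generator config for fast unit-level checks."""
    return SynthConfig(n_chromosomes=2, chromosome_length=400_000, seed=3)


@pytest.fixture(scope="session")
def small_synth(small_cfg):
    genome, truth = synth_genome(small_cfg)
    ann = synth_annotations(small_cfg, truth)
    return genome, truth, ann


@pytest.fixture(scope="session")
def default_synth():
    """The standard study genome: 3 chromosomes x 4 Mb, epsilon 0.15."""
    cfg = SynthConfig()
    genome, truth = synth_genome(cfg)
    ann = synth_annotations(cfg, truth)
    return cfg, genome, truth, ann


@pytest.fixture(scope="session")
def default_pipeline(default_synth):
    """Full profiling + PCA of the standard study genome (heavyweight)."""
    cfg, genome, truth, ann = default_synth
    windows = [w for w, _ in truth.window_labels]
    truth_labels = np.asarray([lab for _, lab in truth.window_labels])
    group_ann = GroupAnnotation(
        cenpa_peaks=ann.cenpa_peaks,
        h3k9_peaks=ann.h3k9_peaks,
        mat_regions=ann.mat_regions,
        neocen_regions=ann.neocen_regions,
    )
    predicted = np.asarray(
        [lab for _, lab in classify_windows(windows, group_ann, genome)]
    )
    matrix = profile_matrix(genome, windows, k=5, n_shuffles=1000, seed=cfg.seed)
    pca = EnrichmentPCA(n_components=2)
    scores = pca.fit_transform(matrix)
    return {
        "cfg": cfg,
        "genome": genome,
        "truth": truth,
        "ann": ann,
        "windows": windows,
        "truth_labels": truth_labels,
        "predicted_labels": predicted,
        "matrix": matrix,
        "scores": scores,
    }
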