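"""Synthetic multi-class expression profiles with planted marker genes.

The generator emulates the salient properties of large single-cell atlases
that the downstream selection stages must cope with: many classes, strong
class imbalance, a small set of class-specific informative genes hidden
among many uninformative ones, and sparse count-like values.  Counts are
drawn from a zero-inflated negative binomial; each class owns a disjoint
set of marker genes whose mean is shifted up by ``exp(effect_size)`` inside
that class.  The planted truth is returned alongside the data so recovery
of the markers can be scored exactly.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import ExpressionMatrix, LabelVector


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    ``class_sizes=None`` draws one size per class log-uniformly between
    ``size_min`` and ``size_max`` (heavy imbalance, mimicking cell-type
    abundance spread).  ``effect_size`` is the log-scale mean shift of a
    marker gene within its own class; ``dispersion`` is the negative
    binomial over-dispersion (variance = mean + dispersion·mean²);
    ``dropout_rate`` is the independent zero-inflation probability.
    """

    n_classes: int = 6
    class_sizes: list[int] | None = None
    size_min: int = 50
    size_max: int = 1000
    n_genes: int = 500
    markers_per_class: int = 5
    effect_size: float = 2.0
    baseline_mean: float = 1.0
    dispersion: float = 0.5
    dropout_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be ≥ 2")
        if self.markers_per_class * self.n_classes > self.n_genes:
            raise ValueError(
                f"markers_per_class × n_classes = "
                f"{self.markers_per_class * self.n_classes} exceeds n_genes = {self.n_genes}"
            )
        if self.class_sizes is not None:
            if len(self.class_sizes) != self.n_classes:
                raise ValueError("class_sizes length must equal n_classes")
            if any(s < 2 for s in self.class_sizes):
                raise ValueError("all class sizes must be ≥ 2")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.dispersion <= 0 or self.baseline_mean <= 0:
            raise ValueError("dispersion and baseline_mean must be > 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be ≥ 0")


@dataclass
class SynthTruth:
    """Planted ground truth: which genes mark which class."""

    marker_map: dict[str, set[str]]
    noise_genes: set[str]
    class_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def all_markers(self) -> set[str]:
        out: set[str] = set()
        for s in self.marker_map.values():
            out |= s
        return out


def _rng_for(config_seed: int, stream: str) -> np.random.Generator:
    """One named substream per operation so stages are individually stable."""
    h = np.random.SeedSequence([config_seed, sum(ord(c) for c in stream), len(stream)])
    return np.random.default_rng(h)


def _draw_class_sizes(cfg: SynthConfig, rng: np.random.Generator) -> list[int]:
    if cfg.class_sizes is not None:
        return [int(s) for s in cfg.class_sizes]
    lo, hi = math.log(cfg.size_min), math.log(cfg.size_max)
    return [max(2, int(round(math.exp(rng.uniform(lo, hi))))) for _ in range(cfg.n_classes)]


def simulate_profiles(config: SynthConfig) -> tuple[ExpressionMatrix, LabelVector, SynthTruth]:
    """Generate a labelled expression matrix with planted markers.

    Every gene in every cell is negative-binomial with mean
    ``baseline_mean`` except the markers of the cell's own class, whose
    mean is ``baseline_mean · exp(effect_size)``; each value is then zeroed
    independently with probability ``dropout_rate``.
    """
    config.validate()
    rng_sizes = _rng_for(config.seed, "class_sizes")
    rng_counts = _rng_for(config.seed, "counts")
    rng_drop = _rng_for(config.seed, "dropout")

    sizes = _draw_class_sizes(config, rng_sizes)
    classes = [f"type_{i:02d}" for i in range(config.n_classes)]
    gene_ids = [f"G{j:04d}" for j in range(config.n_genes)]

    labels = np.concatenate(
        [np.full(n, c, dtype=object) for c, n in zip(classes, sizes)]
    )
    n_cells = len(labels)
    cell_ids = [f"cell_{i:06d}" for i in range(n_cells)]

    # disjoint marker blocks at the front of the gene list
    marker_map: dict[str, set[str]] = {}
    marker_idx: dict[str, np.ndarray] = {}
    for k, c in enumerate(classes):
        cols = np.arange(k * config.markers_per_class, (k + 1) * config.markers_per_class)
        marker_map[c] = {gene_ids[j] for j in cols}
        marker_idx[c] = cols
    noise = set(gene_ids) - {g for s in marker_map.values() for g in s}

    # NB(mean mu, dispersion phi): size r = 1/phi, p = r / (r + mu)
    r = 1.0 / config.dispersion
    mu = np.full((n_cells, config.n_genes), config.baseline_mean)
    for c in classes:
        rows = np.flatnonzero(labels == c)
        mu[np.ix_(rows, marker_idx[c])] = config.baseline_mean * math.exp(config.effect_size)
    p = r / (r + mu)
    values = rng_counts.negative_binomial(r, p).astype(float)
    if config.dropout_rate > 0:
        values[rng_drop.random(values.shape) < config.dropout_rate] = 0.0

    matrix = ExpressionMatrix(values, gene_ids, cell_ids)
    lab = LabelVector(labels, classes=classes)
    truth = SynthTruth(
        marker_map=marker_map,
        noise_genes=noise,
        class_sizes={c: n for c, n in zip(classes, sizes)},
    )
    return matrix, lab, truth


def imbalance_profile(class_sizes: list[int]) -> float:
    """Max/min class-size ratio, the usual one-number imbalance summary."""
    if not class_sizes:
        raise ValueError("class_sizes must be non-empty")
    if min(class_sizes) <= 0:
        raise ValueError("class sizes must be positive")
    return max(class_sizes) / min(class_sizes)


def write_truth(truth: SynthTruth, path: str | os.PathLike) -> None:
    doc = {
        "marker_map": {c: sorted(g) for c, g in truth.marker_map.items()},
        "noise_genes": sorted(truth.noise_genes),
        "class_sizes": truth.class_sizes,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_truth(path: str | os.PathLike) -> SynthTruth:
    with open(Path(path)) as fh:
        doc = json.load(fh)
    return SynthTruth(
        marker_map={c: set(g) for c, g in doc["marker_map"].items()},
        noise_genes=set(doc["noise_genes"]),
        class_sizes={c: int(n) for c, n in doc.get("class_sizes", {}).items()},
    )
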