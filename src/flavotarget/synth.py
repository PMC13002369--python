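"""Synthetic multi-cohort expression data and compound-target fixtures.

The generator emulates the statistical structure that the downstream
harmonization/ML stages assume: several cohorts of log2-intensity
microarray-like profiles, a small set of condition-associated genes whose
disease means are shifted, and per-cohort additive location plus
multiplicative scale batch effects — exactly the location/scale model that
parametric empirical-Bayes batch correction (ComBat) is built on, so
parameter recovery is well-posed by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._seeds import child_seed
from .study import CONTROL, DISEASE, ExpressionStudy

#: Baseline per-gene mean distribution on the log2 scale; typical microarray
#: log2 intensities sit in roughly 4-12 with unit-order gene-to-gene spread.
BASELINE_MEAN = 7.0
BASELINE_SD = 1.5


class ConfigurationError(ValueError):
    """Raised when a synthetic configuration violates its invariants."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the multi-cohort generator.

    effect_size is the mean log2 shift added to informative genes in disease
    samples before batch effects; batch_shift_sd / batch_scale_sd set the
    scale of per-cohort per-gene additive (Normal) and multiplicative
    (log-normal sigma) batch effects; noise_sd is the residual Gaussian sd.
    """

    n_cohorts: int = 3
    samples_per_cohort: tuple[tuple[int, int], ...] = ((30, 30), (30, 30), (30, 30))
    n_genes: int = 2000
    n_informative: int = 5
    effect_size: float = 2.0
    batch_shift_sd: float = 1.0
    batch_scale_sd: float = 0.25
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "samples_per_cohort",
            tuple(tuple(int(x) for x in pair) for pair in self.samples_per_cohort),
        )
        if self.n_cohorts < 1:
            raise ConfigurationError("n_cohorts must be a positive integer")
        if len(self.samples_per_cohort) != self.n_cohorts:
            raise ConfigurationError(
                "samples_per_cohort must list one (n_disease, n_control) "
                f"pair per cohort; got {len(self.samples_per_cohort)} for "
                f"n_cohorts={self.n_cohorts}"
            )
        for pair in self.samples_per_cohort:
            if len(pair) != 2 or min(pair) < 0:
                raise ConfigurationError(
                    f"samples_per_cohort entries must be non-negative "
                    f"(n_disease, n_control) pairs; got {pair!r}"
                )
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be a positive integer")
        if not 0 <= self.n_informative <= self.n_genes:
            raise ConfigurationError("n_informative must satisfy 0 <= n_informative <= n_genes")
        if self.batch_shift_sd < 0:
            raise ConfigurationError("batch_shift_sd must be non-negative")
        if self.batch_scale_sd < 0:
            raise ConfigurationError("batch_scale_sd must be non-negative")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")


@dataclass
class TruthRecord:
    """Ground truth sufficient to score recovery of the planted signal."""

    informative_genes: list[str]
    effect_size: float
    #: cohort id -> per-gene additive location effect (length n_genes)
    batch_shift: dict[str, np.ndarray]
    #: cohort id -> per-gene multiplicative scale effect (length n_genes)
    batch_scale: dict[str, np.ndarray]
    baseline: np.ndarray = field(repr=False, default=None)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "informative_genes": self.informative_genes,
            "effect_size": self.effect_size,
            "batch_shift": {k: v.tolist() for k, v in self.batch_shift.items()},
            "batch_scale": {k: v.tolist() for k, v in self.batch_scale.items()},
            "baseline": self.baseline.tolist() if self.baseline is not None else None,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        payload = json.loads(Path(path).read_text())
        return cls(
            informative_genes=list(payload["informative_genes"]),
            effect_size=float(payload["effect_size"]),
            batch_shift={k: np.asarray(v) for k, v in payload["batch_shift"].items()},
            batch_scale={k: np.asarray(v) for k, v in payload["batch_scale"].items()},
            baseline=None if payload["baseline"] is None else np.asarray(payload["baseline"]),
        )


def gene_symbols(n_genes: int) -> list[str]:
    """Synthetic symbols G000001..., uppercased like every symbol here."""
    return [f"G{i + 1:06d}" for i in range(n_genes)]


def generate_cohorts(
    config: SyntheticConfig, cohort_prefix: str = "COHORT", stage: str = "synth.expression"
) -> tuple[ExpressionStudy, TruthRecord]:
    """Generate a multi-cohort study plus the ground-truth record.

    Disease samples have informative-gene means shifted by ``effect_size``
    before the per-cohort location/scale batch effects and Gaussian noise
    are applied:

        x = baseline + effect * informative * disease + gamma_c + delta_c * eps

    with gamma_c ~ N(0, batch_shift_sd) and delta_c ~ LogNormal(0,
    batch_scale_sd) drawn once per (cohort, gene), eps ~ N(0, noise_sd).
    Identical config and seed give bit-identical output.
    """
    rng = np.random.default_rng(child_seed(config.seed, stage))
    genes = gene_symbols(config.n_genes)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, config.n_genes)
    informative_idx = np.sort(
        rng.choice(config.n_genes, size=config.n_informative, replace=False)
    )
    informative = [genes[i] for i in informative_idx]
    effect = np.zeros(config.n_genes)
    effect[informative_idx] = config.effect_size

    samples: list[str] = []
    cohort_of: dict[str, str] = {}
    condition_of: dict[str, str] = {}
    columns: list[np.ndarray] = []
    batch_shift: dict[str, np.ndarray] = {}
    batch_scale: dict[str, np.ndarray] = {}

    for c, (n_dis, n_ctl) in enumerate(config.samples_per_cohort):
        cid = f"{cohort_prefix}{c + 1}"
        gamma = rng.normal(0.0, config.batch_shift_sd, config.n_genes) \
            if config.batch_shift_sd > 0 else np.zeros(config.n_genes)
        delta = np.exp(rng.normal(0.0, config.batch_scale_sd, config.n_genes)) \
            if config.batch_scale_sd > 0 else np.ones(config.n_genes)
        batch_shift[cid] = gamma
        batch_scale[cid] = delta
        for j in range(n_dis + n_ctl):
            is_disease = j < n_dis
            sid = f"{cid}S{j + 1:03d}"
            samples.append(sid)
            cohort_of[sid] = cid
            condition_of[sid] = DISEASE if is_disease else CONTROL
            eps = rng.normal(0.0, config.noise_sd, config.n_genes)
            col = baseline + (effect if is_disease else 0.0) + gamma + delta * eps
            columns.append(col)

    values = np.column_stack(columns) if columns else np.empty((config.n_genes, 0))
    study = ExpressionStudy(genes, samples, values, cohort_of, condition_of)
    truth = TruthRecord(
        informative_genes=informative,
        effect_size=config.effect_size,
        batch_shift=batch_shift,
        batch_scale=batch_scale,
        baseline=baseline,
    )
    return study, truth


def generate_target_fixture(
    truth: TruthRecord,
    all_genes: Sequence[str],
    n_compounds: int = 10,
    hit_fraction: float = 0.5,
    genes_per_compound: int = 10,
    seed: int = 0,
    stage: str = "synth.targets",
) -> pd.DataFrame:
    """Compound -> predicted-target table mixing planted genes with decoys.

    Stands in for a target-prediction export: each compound's gene list
    draws ``round(hit_fraction * genes_per_compound)`` entries from the
    informative genes (capped at their number, without replacement) and
    fills the rest with random decoy genes. Long format with columns
    ``compound_id``, ``gene_symbol``.
    """
    if not 0.0 <= hit_fraction <= 1.0:
        raise ConfigurationError("hit_fraction must lie in [0, 1]")
    if n_compounds < 1:
        raise ConfigurationError("n_compounds must be a positive integer")
    if hit_fraction > 0 and not truth.informative_genes:
        raise ConfigurationError(
            "hit_fraction > 0 requires a non-empty informative gene set"
        )
    rng = np.random.default_rng(child_seed(seed, stage))
    informative = list(truth.informative_genes)
    decoy_pool = [g for g in all_genes if g not in set(informative)]
    rows: list[tuple[str, str]] = []
    for c in range(n_compounds):
        cid = f"MOL{c + 1:02d}"
        n_hit = min(int(round(hit_fraction * genes_per_compound)), len(informative))
        hits = list(rng.choice(informative, size=n_hit, replace=False)) if n_hit else []
        n_decoy = min(genes_per_compound - n_hit, len(decoy_pool))
        decoys = list(rng.choice(decoy_pool, size=n_decoy, replace=False)) if n_decoy else []
        for g in hits + decoys:
            rows.append((cid, str(g)))
    return pd.DataFrame(rows, columns=["compound_id", "gene_symbol"])
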