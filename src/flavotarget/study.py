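"""The in-memory expression container shared by all pipeline stages.

An :class:`ExpressionStudy` is a gene x sample matrix of log2-scale
intensities together with per-sample cohort and condition labels, mirroring
how merged multi-cohort microarray series are handled in batch-correction
workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DISEASE = "disease"
CONTROL = "control"
CONDITIONS = (DISEASE, CONTROL)


class StudyError(ValueError):
    """Raised when an expression study violates its structural invariants."""


@dataclass
class ExpressionStudy:
    """Gene x sample expression matrix with sample metadata.

    Parameters
    ----------
    genes
        Ordered gene symbols, uppercased, no duplicates.
    samples
        Ordered sample identifiers, no duplicates.
    values
        ``(n_genes, n_samples)`` float matrix on a log2 intensity scale.
    cohort
        Mapping sample id -> cohort id.
    condition
        Mapping sample id -> ``"disease"`` or ``"control"``.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    cohort: dict[str, str]
    condition: dict[str, str]

    def __post_init__(self) -> None:
        self.genes = [str(g).upper() for g in self.genes]
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.genes)) != len(self.genes):
            raise StudyError("duplicate gene symbols")
        if len(set(self.samples)) != len(self.samples):
            raise StudyError("duplicate sample ids")
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise StudyError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.isfinite(self.values).all():
            raise StudyError("expression matrix contains non-finite values")
        for s in self.samples:
            if s not in self.cohort:
                raise StudyError(f"sample {s!r} missing cohort label")
            if self.condition.get(s) not in CONDITIONS:
                raise StudyError(
                    f"sample {s!r} condition must be one of {CONDITIONS}"
                )

    # -- convenience views -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def disease_mask(self) -> np.ndarray:
        """Boolean vector over samples, True for disease."""
        return np.array([self.condition[s] == DISEASE for s in self.samples])

    @property
    def labels(self) -> np.ndarray:
        """0/1 integer labels over samples (disease = 1)."""
        return self.disease_mask.astype(int)

    @property
    def cohort_labels(self) -> np.ndarray:
        return np.array([self.cohort[s] for s in self.samples])

    @property
    def cohort_ids(self) -> list[str]:
        """Distinct cohort ids in first-seen sample order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.cohort[s], None)
        return list(seen)

    def frame(self) -> pd.DataFrame:
        """Expression matrix as a genes x samples DataFrame."""
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)

    def feature_frame(self, genes: Sequence[str] | None = None) -> pd.DataFrame:
        """Samples x genes feature matrix (the ML orientation)."""
        df = self.frame().T
        return df if genes is None else df.loc[:, list(genes)]

    def with_values(self, values: np.ndarray) -> "ExpressionStudy":
        return ExpressionStudy(
            list(self.genes), list(self.samples), np.asarray(values, float),
            dict(self.cohort), dict(self.condition),
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionStudy":
        genes = [g.upper() for g in genes]
        missing = [g for g in genes if g not in set(self.genes)]
        if missing:
            raise StudyError(f"genes absent from study: {missing}")
        idx = [self.genes.index(g) for g in genes]
        return ExpressionStudy(
            genes, list(self.samples), self.values[idx],
            dict(self.cohort), dict(self.condition),
        )

    # -- plain-text round trip --------------------------------------------

    def to_tsv(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        """Write the matrix and sample metadata as tab-separated text.

        Matrix: first column ``gene``, one column per sample.
        Metadata: columns ``sample_id``, ``cohort``, ``condition``.
        """
        mat = self.frame()
        mat.index.name = "gene"
        mat.to_csv(matrix_path, sep="\t", lineterminator="\n")
        meta = pd.DataFrame(
            {
                "sample_id": self.samples,
                "cohort": [self.cohort[s] for s in self.samples],
                "condition": [self.condition[s] for s in self.samples],
            }
        )
        meta.to_csv(metadata_path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(
        cls, matrix_path: str | Path, metadata_path: str | Path
    ) -> "ExpressionStudy":
        mat = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
        cohort = dict(zip(meta["sample_id"], meta["cohort"]))
        condition = dict(zip(meta["sample_id"], meta["condition"]))
        return cls(
            list(mat.index), list(mat.columns), mat.to_numpy(float),
            cohort, condition,
        )


def merge_studies(studies: Sequence[ExpressionStudy]) -> ExpressionStudy:
    """Column-concatenate studies sharing an identical gene axis."""
    if not studies:
        raise StudyError("no studies to merge")
    genes = studies[0].genes
    for st in studies[1:]:
        if st.genes != genes:
            raise StudyError("studies do not share a gene axis")
    samples: list[str] = []
    cohort: dict[str, str] = {}
    condition: dict[str, str] = {}
    for st in studies:
        samples.extend(st.samples)
        cohort.update(st.cohort)
        condition.update(st.condition)
    values = np.concatenate([st.values for st in studies], axis=1)
    return ExpressionStudy(list(genes), samples, values, cohort, condition)
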