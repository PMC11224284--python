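"""Sample-level feature representations.

Three feature views feed the classifiers:

* six diversity indices per sample;
* two-dimensional counts (total clonotypes, associated clonotypes present);
* a 0/1 presence matrix over a screened clonotype list.

The associated set is always screened on the training split only; test-split
features are built against that same list (leakage guard).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .diversity import DiversityProfile, diversity_profile
from .repertoire_io import ConfigurationError, Repertoire

LABEL_COLUMN = "phenotype"


@dataclass
class FeatureMatrix:
    """Samples × features numeric grid with per-sample phenotype labels."""

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.sample_ids), len(self.feature_names))
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"grid shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("labels length mismatch")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.values, other.values)
            and self.labels == other.labels
        )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def y(self) -> np.ndarray:
        """Binary labels, case = 1 (the positive class throughout)."""
        if self.labels is None:
            raise ValueError("matrix carries no labels")
        return np.asarray([1 if lab == "case" else 0 for lab in self.labels])

    def select_features(self, names: Sequence[str]) -> "FeatureMatrix":
        idx = [self.feature_names.index(n) for n in names]
        values = self.values[:, idx] if idx else np.empty((self.n_samples, 0))
        return FeatureMatrix(list(self.sample_ids), list(names), values, self.labels)

    def to_frame(self) -> pd.DataFrame:
        integral = self.values.size > 0 and np.all(self.values == np.round(self.values))
        vals = self.values.astype(int) if integral else self.values
        df = pd.DataFrame(vals, index=self.sample_ids, columns=self.feature_names)
        if self.labels is not None:
            df[LABEL_COLUMN] = self.labels
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        labels = None
        if LABEL_COLUMN in df.columns:
            labels = df[LABEL_COLUMN].tolist()
            df = df.drop(columns=[LABEL_COLUMN])
        return cls(
            sample_ids=[str(i) for i in df.index],
            feature_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            labels=labels,
        )


def two_dim_features(repertoire: Repertoire, associated: set[str]) -> tuple[int, int]:
    """(total clonotypes, associated clonotypes present) for one sample."""
    return repertoire.richness, len(repertoire.keys() & associated)


def two_dim_matrix(cohort: Sequence[Repertoire], associated: set[str]) -> FeatureMatrix:
    values = np.array([two_dim_features(r, associated) for r in cohort], dtype=float)
    return FeatureMatrix(
        sample_ids=[r.sample_id for r in cohort],
        feature_names=["total_clonotypes", "associated_clonotypes"],
        values=values,
        labels=[r.phenotype for r in cohort],
    )


def presence_matrix(cohort: Sequence[Repertoire], associated: Sequence[str]) -> FeatureMatrix:
    """0/1 matrix: entry (s, k) is 1 iff clonotype key k occurs in sample s."""
    associated = list(associated)
    if not associated:
        raise ConfigurationError("associated key list is empty")
    if len(set(associated)) != len(associated):
        raise ConfigurationError("duplicate keys in associated list")
    values = np.array(
        [[1.0 if k in r.records else 0.0 for k in associated] for r in cohort]
    )
    return FeatureMatrix(
        sample_ids=[r.sample_id for r in cohort],
        feature_names=associated,
        values=values,
        labels=[r.phenotype for r in cohort],
    )


def diversity_feature_table(
    cohort: Sequence[Repertoire], include_richness: bool = False
) -> FeatureMatrix:
    """Six diversity indices per sample, columns in the fixed profile order."""
    names = list(DiversityProfile.FIELDS)
    if include_richness:
        names.append("richness")
    rows = []
    for r in cohort:
        prof = diversity_profile(r)
        rows.append([getattr(prof, n) for n in names])
    return FeatureMatrix(
        sample_ids=[r.sample_id for r in cohort],
        feature_names=names,
        values=np.array(rows, dtype=float),
        labels=[r.phenotype for r in cohort],
    )
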