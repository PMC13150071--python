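"""Shared in-memory containers for omics matrices and ground truth.

Samples are rows, features are columns, mirroring the delimited-text layout
(first column = sample id) used by every stage of the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

MODALITIES = ("metabolome", "transcriptome", "proteome")

#: Label conventions: the anemic RA group is the positive class everywhere.
GROUP_NEGATIVE = "RA"
GROUP_POSITIVE = "RA_ane"


@dataclass
class OmicsMatrix:
    """A sample x feature numeric table with a modality tag.

    ``values`` is a pandas DataFrame indexed by sample id with feature ids as
    columns. Metabolome matrices may contain NaN (missing intensities);
    transcriptome matrices hold non-negative integers.
    """

    values: pd.DataFrame
    modality: str
    group_labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.group_labels is not None:
            self.group_labels = self.group_labels.reindex(self.values.index)
            if self.group_labels.isna().any():
                raise ValueError("group labels missing for some samples")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame) -> "OmicsMatrix":
        labels = None
        if self.group_labels is not None:
            labels = self.group_labels.loc[values.index]
        return OmicsMatrix(values=values, modality=self.modality, group_labels=labels)

    def binary_labels(self) -> np.ndarray:
        """0/1 vector with the anemic group (RA_ane) coded 1."""
        if self.group_labels is None:
            raise ValueError("matrix carries no group labels")
        return binary_labels(self.group_labels)

    def to_tsv(self, path) -> None:
        out = self.values.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, modality: str, labels: Optional[pd.Series] = None) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=df, modality=modality, group_labels=labels)


def binary_labels(groups: pd.Series | np.ndarray) -> np.ndarray:
    """Map group labels to 0/1 with RA_ane (or the lexicographically larger
    of exactly two labels) as the positive class."""
    arr = np.asarray(groups)
    uniq = sorted(pd.unique(arr))
    if len(uniq) != 2:
        raise ValueError(f"expected exactly 2 groups, got {uniq}")
    if GROUP_POSITIVE in uniq:
        pos = GROUP_POSITIVE
    else:
        pos = uniq[1]
    return (arr == pos).astype(int)


def read_labels_tsv(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError("labels TSV needs sample_id and group columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_labels_tsv(labels: pd.Series, path) -> None:
    out = pd.DataFrame({"sample_id": labels.index, "group": labels.values})
    out.to_csv(path, sep="\t", index=False)


@dataclass
class GroundTruth:
    """Planted signal bookkeeping emitted by every synthetic generator."""

    planted_feature_ids: list
    effect_sizes: pd.Series  # per feature; 0 for non-planted
    group_assignment: pd.Series  # sample id -> group label

    def __post_init__(self) -> None:
        planted = set(self.planted_feature_ids)
        if not planted.issubset(set(self.effect_sizes.index)):
            raise ValueError("planted features must be a subset of generated features")
        nonplanted = self.effect_sizes.drop(index=list(planted))
        if (nonplanted != 0).any():
            raise ValueError("non-planted features must have zero effect size")

    def to_json_dict(self) -> dict:
        return {
            "planted_feature_ids": list(self.planted_feature_ids),
            "effect_sizes": {k: float(v) for k, v in self.effect_sizes.items() if v != 0},
            "group_assignment": {str(k): str(v) for k, v in self.group_assignment.items()},
        }
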