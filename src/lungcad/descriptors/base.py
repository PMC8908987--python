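"""Common descriptor interface.

Each descriptor is a scikit-learn transformer over lists of
:class:`~lungcad.phantoms.NoduleRecord`: ``fit`` learns whatever the descriptor
needs from training nodules (only the MGRF energy model actually does),
``transform`` maps records to a fixed-length feature matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

DESCRIPTOR_TAGS = ("albp", "hog3d", "mgrf", "pscss", "spharm", "geometric")


@dataclass
class DescriptorVector:
    """Fixed-length real feature vector with a descriptor tag."""

    values: np.ndarray
    tag: str
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.tag not in DESCRIPTOR_TAGS:
            raise ValueError(f"unknown descriptor tag {self.tag!r}")
        if self.names and len(self.names) != self.values.size:
            raise ValueError("names must match vector length")

    def __len__(self) -> int:
        return self.values.size


class NoduleDescriptor(BaseEstimator, TransformerMixin):
    """Base transformer: subclasses implement :meth:`describe`."""

    tag: str = ""

    def fit(self, records, y=None):
        self.n_features_in_ = 1  # records, not columns; kept for sklearn clone checks
        return self

    def describe(self, record) -> DescriptorVector:
        raise NotImplementedError

    def transform(self, records) -> np.ndarray:
        rows = [self.describe(r).values for r in records]
        return np.vstack(rows) if rows else np.empty((0, 0))

    def feature_names(self, record=None) -> list[str]:
        if record is None:
            raise ValueError("a sample record is required to enumerate feature names")
        return self.describe(record).names
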