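"""Presence/absence Jaccard similarity between sampling sites.

Two sites are compared through their species lists only: the Jaccard
coefficient J = 100 * |A intersect B| / |A union B| ignores abundance.
Site lists are formed by pooling all seasons and tissues (any CF > 0
counts as present).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .data import CFMatrix, presence_absence

__all__ = ["SimilarityMatrix", "jaccard", "pairwise_jaccard", "site_jaccard"]


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """Percent Jaccard similarity of two species sets.

    Two empty sets are identical communities, so the coefficient is 100
    by convention (avoids 0/0 while preserving reflexivity).
    """
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 100.0
    return 100.0 * len(a & b) / len(union)


@dataclass
class SimilarityMatrix:
    """Symmetric percent-similarity matrix with a 100 diagonal."""

    labels: list[str]
    values: np.ndarray  # integer percent, shape (n, n)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def lower_triangular(self) -> pd.DataFrame:
        """Lower-triangular view (upper entries blank), the printed layout."""
        frame = self.to_frame().astype(object)
        n = len(self.labels)
        for i in range(n):
            for j in range(i + 1, n):
                frame.iat[i, j] = ""
        return frame

    def __getitem__(self, pair: tuple[str, str]) -> int:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return int(self.values[i, j])


def pairwise_jaccard(presence: Mapping[object, Iterable[str]]) -> SimilarityMatrix:
    """Full Jaccard matrix over labelled species sets.

    Values are rounded to the nearest integer percent, the grain of the
    printed site-similarity table.
    """
    if not presence:
        raise ValueError("need at least one labelled species set")
    labels = [str(k) for k in presence]
    sets = [set(v) for v in presence.values()]
    n = len(labels)
    values = np.full((n, n), 100, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            v = int(round(jaccard(sets[i], sets[j])))
            values[i, j] = values[j, i] = v
    return SimilarityMatrix(labels, values)


def site_jaccard(survey: CFMatrix) -> SimilarityMatrix:
    """Inter-site similarity from a full survey.

    Each site's species list is the union over all seasons and tissues
    sampled there (threshold CF > 0).
    """
    presence = presence_absence(survey, by="site")
    ordered = {f"site{k}": presence[k] for k in sorted(presence)}
    return pairwise_jaccard(ordered)
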