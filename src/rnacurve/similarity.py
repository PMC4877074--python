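"""Pairwise similarity quotient and distance matrices.

The quotient between two 36D descriptors is the Euclidean distance
between the vectors' end-points divided by the cosine of the angle
between them.  Identical descriptors score exactly 0; the smaller the
quotient, the more similar the structures.  The measure is a
non-negative dissimilarity only: a near-zero or negative cosine is an
error, not a sign-flipped score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .descriptor import Descriptor36, describe
from .structure_io import CharacteristicSequence, SecondaryStructure

DEFAULT_COS_EPS = 1e-9


class DegenerateAngleError(ValueError):
    """Cosine of the angle between the descriptors is ≤ epsilon."""


def quotient_similarity(u: Descriptor36 | np.ndarray, v: Descriptor36 | np.ndarray, *, cos_eps: float = DEFAULT_COS_EPS) -> float:
    """Distance/cosine quotient between two 36D descriptors.

    Returns 0 for identical vectors; raises ``ValueError`` on a
    zero-magnitude vector and :class:`DegenerateAngleError` when the
    cosine is ≤ ``cos_eps``.
    """
    a = u.components if isinstance(u, Descriptor36) else np.asarray(u, dtype=float)
    b = v.components if isinstance(v, Descriptor36) else np.asarray(v, dtype=float)
    norm_a, norm_b = np.linalg.norm(a), np.linalg.norm(b)
    if norm_a == 0.0 or norm_b == 0.0:
        raise ValueError("zero-magnitude descriptor")
    dist = float(np.linalg.norm(a - b))
    if dist == 0.0:
        return 0.0
    cos = float(a @ b) / (norm_a * norm_b)
    if cos <= cos_eps:
        raise DegenerateAngleError(f"degenerate angle: cos = {cos:.3e} <= {cos_eps:.0e}")
    return dist / cos


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative matrix with a zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        m = len(self.labels)
        if arr.shape != (m, m):
            raise ValueError(f"matrix shape {arr.shape} does not match {m} labels")
        if len(set(self.labels)) != m:
            raise ValueError("duplicate labels")
        if not np.all(np.isfinite(arr)):
            raise ValueError("non-finite matrix entries")
        if not np.allclose(arr, arr.T):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(arr) != 0.0):
            raise ValueError("diagonal must be exactly zero")
        if np.any(arr < 0.0):
            raise ValueError("negative matrix entries")
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return len(self.labels)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def off_diagonal(self) -> Iterator[tuple[str, str, float]]:
        for i in range(len(self.labels)):
            for j in range(i + 1, len(self.labels)):
                yield self.labels[i], self.labels[j], float(self.values[i, j])

    def to_phylip(self, precision: int = 6) -> str:
        """Square PHYLIP distance-matrix text."""
        lines = [f"{len(self.labels):5d}"]
        width = max(10, max(len(l) for l in self.labels) + 1)
        for label, row in zip(self.labels, self.values):
            cells = "  ".join(f"{v:.{precision}f}" for v in row)
            lines.append(f"{label:<{width}}{cells}")
        return "\n".join(lines) + "\n"

    def to_csv(self, precision: int = 4) -> str:
        """CSV rendering rounded to ``precision`` decimals (4 by default)."""
        lines = ["name," + ",".join(self.labels)]
        for label, row in zip(self.labels, self.values):
            lines.append(label + "," + ",".join(f"{v:.{precision}f}" for v in row))
        return "\n".join(lines) + "\n"

    @classmethod
    def from_phylip(cls, text: str) -> "DistanceMatrix":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        m = int(lines[0].split()[0])
        labels, rows = [], []
        for ln in lines[1 : 1 + m]:
            fields = ln.split()
            labels.append(fields[0])
            rows.append([float(v) for v in fields[1:]])
        return cls(labels=tuple(labels), values=np.array(rows))


def pairwise_matrix(
    items: Sequence[SecondaryStructure | CharacteristicSequence | Descriptor36],
    *,
    cos_eps: float = DEFAULT_COS_EPS,
) -> DistanceMatrix:
    """Quotient-similarity matrix over the descriptors of ``items``.

    Labels are item names and must be unique; any pairwise error is
    re-raised with the offending pair named.
    """
    if len(items) < 2:
        raise ValueError("need at least 2 items")
    descriptors = [it if isinstance(it, Descriptor36) else describe(it) for it in items]
    labels = tuple(d.name for d in descriptors)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate labels: {dupes}")
    m = len(descriptors)
    values = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                s = quotient_similarity(descriptors[i], descriptors[j], cos_eps=cos_eps)
            except ValueError as exc:
                raise ValueError(f"pair ({labels[i]}, {labels[j]}): {exc}") from exc
            values[i, j] = values[j, i] = s
    return DistanceMatrix(labels=labels, values=values)
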