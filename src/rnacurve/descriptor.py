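"""36-dimensional geometric-center descriptor of the three curves.

For map ``k`` and group-set ``j`` the component triple is the sum of
(x, y, z) over the curve points whose symbol belongs to that group-set,
divided by the full sequence length ``n`` (not the group size, so an
absent group contributes an exact (0, 0, 0)).  Components are ordered
(k=1, j=1..4), (k=2, j=1..4), (k=3, j=1..4) with (x, y, z) per group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import SCHEMES, Curve3D, all_curves
from .structure_io import CharacteristicSequence, SecondaryStructure, encode

COMPONENT_NAMES = tuple(f"{c}{k}{j}" for k in (1, 2, 3) for j in (1, 2, 3, 4) for c in ("x", "y", "z"))


@dataclass(frozen=True)
class Descriptor36:
    """The 36-component geometric-center vector of one structure."""

    name: str
    components: np.ndarray  # shape (36,)

    def __post_init__(self) -> None:
        arr = np.asarray(self.components, dtype=float)
        if arr.shape != (36,):
            raise ValueError(f"descriptor must have 36 components, got shape {arr.shape}")
        object.__setattr__(self, "components", arr)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(COMPONENT_NAMES, self.components.tolist()))

    def __getitem__(self, name: str) -> float:
        return float(self.components[COMPONENT_NAMES.index(name)])


@dataclass(frozen=True)
class CompositionSummary:
    """Relative frequencies of the 8 symbols plus the paired fraction."""

    frequencies: dict[str, float]
    paired_fraction: float


def geometric_centers(curves: tuple[Curve3D, Curve3D, Curve3D], n: int, name: str = "") -> Descriptor36:
    """Collapse the three curves into the 36D descriptor.

    ``curves`` must come from one characteristic sequence of length
    ``n``; a mismatch in curve lengths is an error.
    """
    if any(len(c) != n for c in curves):
        raise ValueError(f"curve lengths {[len(c) for c in curves]} do not match n={n}")
    components = np.zeros(36)
    for idx_k, curve in enumerate(curves):
        groups = np.asarray(curve.group_of_point)
        for j in (1, 2, 3, 4):
            mask = groups == j
            offset = idx_k * 12 + (j - 1) * 3
            if mask.any():
                components[offset : offset + 3] = curve.points[mask].sum(axis=0) / n
    return Descriptor36(name=name, components=components)


def describe(item: SecondaryStructure | CharacteristicSequence) -> Descriptor36:
    """Full pipeline: encode (if needed), build curves, take centers."""
    cs = encode(item) if isinstance(item, SecondaryStructure) else item
    return geometric_centers(all_curves(cs), len(cs), name=cs.name)


def composition_summary(cs: CharacteristicSequence) -> CompositionSummary:
    """Exact symbol frequencies and paired (primed) fraction of ``cs``."""
    n = len(cs)
    freqs = {s: 0 for s in SCHEMES[1].positive_unpaired | SCHEMES[1].negative_unpaired
             | SCHEMES[1].positive_paired | SCHEMES[1].negative_paired}
    for sym in cs.symbols:
        freqs[sym] += 1
    frequencies = {s: c / n for s, c in freqs.items()}
    paired = sum(v for s, v in frequencies.items() if s.endswith("'"))
    return CompositionSummary(frequencies=frequencies, paired_fraction=paired)
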