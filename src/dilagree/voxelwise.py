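"""Boolean sum volume and voxel-wise fractional-rank Spearman correlation.

The common sampling region for voxel-wise comparison of two parametric maps
is the Boolean sum volume (BSV): the voxel-wise union of the lesion contours
drawn on all available sequences.  Using the union guarantees that the same
set of voxels — and hence an equal number of observations per sequence —
enters the correlation regardless of which pair is being compared.

Spearman's ρ is computed as the Pearson correlation of fractional ranks
(average ranks for ties, divided by n).  A map that is constant inside the
BSV has degenerate ranks; such a pair is reported as *undefined* rather than
silently zero, which is the mechanism by which uninformative Ktrans cases
are flagged and later excluded from cohort averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .grids import BinaryMask, GridError, ScalarVolume
from .metrics import UndefinedMetricError

__all__ = [
    "PAIRS",
    "CorrelationResult",
    "boolean_sum_volume",
    "fractional_ranks",
    "spearman_in_bsv",
    "patient_voxelwise",
]

#: Canonical sequence-pair names used throughout the pipeline.
PAIRS = ("T2-ADC", "T2-Ktrans", "ADC-Ktrans")

_PAIR_MODALITIES = {
    "T2-ADC": ("T2W", "ADC"),
    "T2-Ktrans": ("T2W", "KTRANS"),
    "ADC-Ktrans": ("ADC", "KTRANS"),
}


@dataclass(frozen=True)
class CorrelationResult:
    """Voxel-wise Spearman ρ inside a BSV, with its defined/undefined flag."""

    rho: float
    n_voxels: int
    defined: bool

    def __float__(self) -> float:
        return self.rho


def boolean_sum_volume(masks: Sequence[BinaryMask]) -> BinaryMask:
    """Voxel-wise union of contours from all sequences, labelled "BSV"."""
    if len(masks) == 0:
        raise ValueError("boolean_sum_volume needs at least one mask")
    geom = masks[0].geometry
    for m in masks[1:]:
        if m.geometry != geom:
            raise GridError("all masks must share one geometry")
    union = np.zeros(geom.shape, dtype=bool)
    for m in masks:
        union |= m.voxels
    return BinaryMask(geometry=geom, voxels=union, label="BSV")


def fractional_ranks(values: Iterable[float]) -> np.ndarray:
    """Average-tie ranks divided by n; output lies in (0, 1]."""
    values = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    if values.size == 0:
        raise UndefinedMetricError("fractional ranks of an empty sequence")
    return stats.rankdata(values, method="average") / values.size


def spearman_in_bsv(
    vol_a: ScalarVolume, vol_b: ScalarVolume, bsv: BinaryMask
) -> CorrelationResult:
    """Spearman ρ of two co-registered maps over the BSV voxels.

    Returns an undefined (flagged) result when either map is constant inside
    the BSV, since ranks are then degenerate.
    """
    if vol_a.geometry != bsv.geometry or vol_b.geometry != bsv.geometry:
        raise GridError("volumes and BSV must share one geometry")
    n = bsv.n_voxels
    if n < 2:
        raise UndefinedMetricError("correlation needs at least 2 BSV voxels")
    va = vol_a.values[bsv.voxels]
    vb = vol_b.values[bsv.voxels]
    if np.all(va == va[0]) or np.all(vb == vb[0]):
        return CorrelationResult(rho=float("nan"), n_voxels=n, defined=False)
    ra = fractional_ranks(va)
    rb = fractional_ranks(vb)
    rho = float(np.corrcoef(ra, rb)[0, 1])
    return CorrelationResult(rho=rho, n_voxels=n, defined=True)


def patient_voxelwise(
    pair: str,
    volumes: dict[str, ScalarVolume],
    masks: Sequence[BinaryMask],
) -> CorrelationResult:
    """One patient's voxel-wise ρ for one sequence pair.

    The BSV is always built from *all* supplied per-sequence masks (three in
    the standard pipeline), then the two maps of the requested pair are
    sampled inside it.  ``volumes`` is keyed by modality (T2W/ADC/KTRANS).
    """
    if pair not in _PAIR_MODALITIES:
        raise ValueError(f"unknown pair {pair!r}; expected one of {PAIRS}")
    mod_a, mod_b = _PAIR_MODALITIES[pair]
    for mod in (mod_a, mod_b):
        if mod not in volumes:
            raise KeyError(f"volume for modality {mod} missing")
    bsv = boolean_sum_volume(masks)
    return spearman_in_bsv(volumes[mod_a], volumes[mod_b], bsv)
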