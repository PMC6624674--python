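"""Batch drivers joining the per-patient stages into cohort tables.

These functions run the contour-agreement and voxel-wise stages over a whole
cohort — either in memory (a list of :class:`~dilagree.synthetic.SyntheticCase`)
or from a cohort directory of NIfTI files — and emit the tidy per-patient
record frames that :mod:`dilagree.cohort` aggregates.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import PatientMeta
from .metrics import UndefinedMetricError, pair_metrics
from .synthetic import SEQUENCES, SyntheticCase, load_cohort_case
from .voxelwise import PAIRS, patient_voxelwise

__all__ = [
    "agreement_records",
    "voxelwise_records",
    "cohort_patient_ids",
    "load_cohort",
]

_PAIR_SEQS = {"T2-ADC": ("T2W", "ADC"), "T2-Ktrans": ("T2W", "KTRANS"),
              "ADC-Ktrans": ("ADC", "KTRANS")}


def agreement_records(
    cases: Iterable[SyntheticCase],
    observer: str = "obs1",
    pairs: Sequence[str] = PAIRS,
    hd_percentile: float = 95.0,
) -> pd.DataFrame:
    """Per-patient agreement metrics for each sequence pair.

    One row per patient × pair with columns ``patient_id, pair, dice,
    jaccard, hd95_mm, mda_mm``.  Pairs whose metrics are undefined (e.g. an
    empty contour) are skipped rather than emitted as NaN; explicit
    accounting happens at the CLI layer.
    """
    rows = []
    for case in cases:
        seq_masks = case.masks.get(observer)
        if not seq_masks:
            continue
        for pair in pairs:
            sa, sb = _PAIR_SEQS[pair]
            try:
                m = pair_metrics(seq_masks[sa], seq_masks[sb], q=hd_percentile)
            except UndefinedMetricError:
                continue
            rows.append(
                {"patient_id": case.meta.patient_id, "pair": pair,
                 "dice": m.dice, "jaccard": m.jaccard,
                 "hd95_mm": m.hd95, "mda_mm": m.mda}
            )
    return pd.DataFrame(rows, columns=["patient_id", "pair", "dice", "jaccard",
                                       "hd95_mm", "mda_mm"])


def voxelwise_records(
    cases: Iterable[SyntheticCase],
    observer: str = "obs1",
    pairs: Sequence[str] = PAIRS,
) -> pd.DataFrame:
    """Per-patient voxel-wise Spearman ρ inside the three-contour BSV.

    One row per patient × pair with columns ``patient_id, pair, rho,
    n_voxels, defined``.  A Ktrans-involved pair of a patient whose Ktrans
    map is flagged unusable is reported with ``defined = False``, mirroring
    the exclusion of uninformative Ktrans cases from cohort averages.
    """
    rows = []
    for case in cases:
        seq_masks = case.masks.get(observer)
        if not seq_masks:
            continue
        masks = [seq_masks[s] for s in SEQUENCES if s in seq_masks]
        for pair in pairs:
            res = patient_voxelwise(pair, case.volumes, masks)
            defined = res.defined
            if "Ktrans" in pair and not case.meta.ktrans_usable:
                defined = False
            rows.append(
                {"patient_id": case.meta.patient_id, "pair": pair,
                 "rho": res.rho, "n_voxels": res.n_voxels, "defined": defined}
            )
    return pd.DataFrame(rows, columns=["patient_id", "pair", "rho",
                                       "n_voxels", "defined"])


def cohort_patient_ids(cohort_dir: str | Path) -> list[str]:
    meta = pd.read_csv(Path(cohort_dir) / "metadata.csv")
    return [str(p) for p in meta["patient_id"]]


def load_cohort(
    cohort_dir: str | Path, observers: Sequence[str] = ("obs1",)
) -> list[SyntheticCase]:
    """Load every patient of an on-disk cohort."""
    cases = []
    for pid in cohort_patient_ids(cohort_dir):
        case = load_cohort_case(cohort_dir, pid, observers=observers)
        if case is not None:
            cases.append(case)
    return cases


def metadata_from_cases(cases: Iterable[SyntheticCase]) -> list[PatientMeta]:
    return [case.meta for case in cases]
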