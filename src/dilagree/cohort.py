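"""Cohort-level aggregation of per-patient agreement and correlation results.

Per-patient agreement records (Dice, Jaccard, HD95, MDA per sequence pair)
and voxel-wise Spearman results are joined to patient metadata and summarised
as mean ± SD tables stratified by lesion zone or by Gleason grade group, in
the layout clinicians use for such studies: zones reported as AFS,
Peripheral, and a pooled Central/Transition column, grade groups as 1, 2, 3
and pooled 4+5, plus a Total column.

Two exclusion rules are applied during aggregation and surfaced in counts
rather than silently: patients whose Ktrans map is uninformative
(``ktrans_usable == False``) are dropped from Ktrans-involved pairs only,
and voxel-wise rows flagged undefined never enter Spearman averages.

All standard deviations are sample SDs (n−1 denominator); a stratum with
fewer than two contributors reports SD as NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import BinaryMask, GridError, ScalarVolume
from .metrics import UndefinedMetricError

__all__ = [
    "ZONES",
    "GRADE_GROUPS",
    "PatientMeta",
    "IntensityStats",
    "contour_intensity_stats",
    "lesion_volume_ml",
    "stratified_table",
    "wide_table",
    "interobserver_report",
    "cohort_composition",
    "intensity_table",
]

ZONES = ("AFS", "CZ", "PZ", "TZ")
GRADE_GROUPS = ("1", "2", "3", "4+5")

#: Display pooling of zones for stratified tables.
_ZONE_DISPLAY = {"AFS": "AFS", "PZ": "Peripheral", "CZ": "Cent/Tran", "TZ": "Cent/Tran"}
ZONE_COLUMNS = ("AFS", "Peripheral", "Cent/Tran", "Total")
GRADE_COLUMNS = ("1", "2", "3", "4+5", "Total")

#: Metric display names mapped to record columns.
_METRIC_COLS = {
    "HD95": "hd95_mm",
    "MDA": "mda_mm",
    "Dice": "dice",
    "Jaccard": "jaccard",
    "Spearman": "rho",
}


@dataclass(frozen=True)
class PatientMeta:
    """One patient's stratification labels and Ktrans usability flag.

    Gleason grade groups 4 and 5 are pooled at ingest and never reported
    separately.
    """

    patient_id: str
    zone: str
    grade_group: str
    observer_id: str = "obs1"
    ktrans_usable: bool = True

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")
        gg = str(self.grade_group)
        if gg in ("4", "5"):
            gg = "4+5"
        if gg not in GRADE_GROUPS:
            raise ValueError(
                f"grade group must normalise to one of {GRADE_GROUPS}, got {gg!r}"
            )
        object.__setattr__(self, "grade_group", gg)


@dataclass(frozen=True)
class IntensityStats:
    """Summary of map values inside one contour, in the map's units."""

    mean: float
    min: float
    max: float
    sd: float


def contour_intensity_stats(vol: ScalarVolume, mask: BinaryMask) -> IntensityStats:
    """Mean/min/max/SD of voxel values inside a contour.

    SD uses the n−1 denominator; a single-voxel contour reports SD = 0.
    """
    if vol.geometry != mask.geometry:
        raise GridError("volume and mask must share one geometry")
    if mask.n_voxels == 0:
        raise UndefinedMetricError("intensity statistics of an empty contour")
    vals = vol.values[mask.voxels]
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return IntensityStats(
        mean=float(vals.mean()), min=float(vals.min()), max=float(vals.max()), sd=sd
    )


def lesion_volume_ml(mask: BinaryMask) -> float:
    """Contour volume in mL (empty mask → 0)."""
    return mask.volume_ml()


def _is_ktrans_pair(pair: str) -> bool:
    return "Ktrans" in pair


def metadata_frame(meta: list[PatientMeta] | pd.DataFrame) -> pd.DataFrame:
    """Normalise metadata to a DataFrame with pooled grade groups."""
    if isinstance(meta, pd.DataFrame):
        df = meta.copy()
        df["grade_group"] = (
            df["grade_group"].astype(str).replace({"4": "4+5", "5": "4+5"})
        )
        if "ktrans_usable" in df:
            df["ktrans_usable"] = df["ktrans_usable"].astype(bool)
        else:
            df["ktrans_usable"] = True
        return df
    return pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in meta],
            "zone": [m.zone for m in meta],
            "grade_group": [m.grade_group for m in meta],
            "observer_id": [m.observer_id for m in meta],
            "ktrans_usable": [m.ktrans_usable for m in meta],
        }
    )


def _joined_long(
    records: pd.DataFrame,
    meta: pd.DataFrame,
    voxelwise: pd.DataFrame | None,
) -> pd.DataFrame:
    """Join records to metadata and melt to (patient, pair, metric, value)."""
    missing = set(records["patient_id"]) - set(meta["patient_id"])
    if missing:
        raise ValueError(f"records with no metadata row: {sorted(missing)}")
    value_cols = [c for c in _METRIC_COLS.values() if c in records.columns]
    long = records.melt(
        id_vars=["patient_id", "pair"],
        value_vars=value_cols,
        var_name="column",
        value_name="value",
    )
    if voxelwise is not None:
        vw = voxelwise.copy()
        if "defined" in vw.columns:
            vw = vw[vw["defined"].astype(bool)]
        vw = vw[["patient_id", "pair", "rho"]].melt(
            id_vars=["patient_id", "pair"], var_name="column", value_name="value"
        )
        long = pd.concat([long, vw], ignore_index=True)
    col_to_metric = {v: k for k, v in _METRIC_COLS.items()}
    long["metric"] = long["column"].map(col_to_metric)
    long = long.drop(columns="column").dropna(subset=["value"])
    long = long.merge(
        meta[["patient_id", "zone", "grade_group", "ktrans_usable"]],
        on="patient_id",
        how="left",
    )
    # Uninformative-Ktrans patients leave Ktrans-involved pairs only.
    drop = long["pair"].map(_is_ktrans_pair) & ~long["ktrans_usable"]
    return long[~drop].reset_index(drop=True)


def stratified_table(
    records: pd.DataFrame,
    meta: list[PatientMeta] | pd.DataFrame,
    by: str,
    voxelwise: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Mean ± SD per stratum × pair × metric, with a Total stratum.

    Parameters
    ----------
    records
        Per-patient agreement rows with columns ``patient_id, pair, dice,
        jaccard, hd95_mm, mda_mm``.
    meta
        Patient metadata (list of :class:`PatientMeta` or equivalent frame).
    by
        ``"zone"`` (columns AFS / Peripheral / Cent/Tran) or
        ``"grade_group"`` (columns 1 / 2 / 3 / 4+5).
    voxelwise
        Optional per-patient Spearman rows (``patient_id, pair, rho,
        defined``); defined rows contribute the Spearman metric.

    Returns a tidy frame with columns
    ``stratum, pair, metric, mean, sd, n``.
    """
    if by not in ("zone", "grade_group"):
        raise ValueError(f"by must be 'zone' or 'grade_group', got {by!r}")
    meta_df = metadata_frame(meta)
    long = _joined_long(records, meta_df, voxelwise)
    if by == "zone":
        long["stratum"] = long["zone"].map(_ZONE_DISPLAY)
    else:
        long["stratum"] = long["grade_group"]
    total = long.copy()
    total["stratum"] = "Total"
    both = pd.concat([long, total], ignore_index=True)
    grouped = (
        both.groupby(["stratum", "pair", "metric"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan, n="size")
        .reset_index()
    )
    grouped["n"] = grouped["n"].astype(int)
    return grouped


def wide_table(stratified: pd.DataFrame, by: str) -> pd.DataFrame:
    """Pivot a stratified table into the publication layout.

    Rows are (pair, metric); columns are the strata in canonical order; cells
    are ``mean ± sd`` strings rounded to two decimals.
    """
    columns = ZONE_COLUMNS if by == "zone" else GRADE_COLUMNS
    df = stratified.copy()
    df["cell"] = df.apply(
        lambda r: f"{r['mean']:.2f} ± {r['sd']:.2f}"
        if np.isfinite(r["sd"])
        else f"{r['mean']:.2f}",
        axis=1,
    )
    wide = df.pivot_table(
        index=["pair", "metric"], columns="stratum", values="cell", aggfunc="first"
    )
    metric_order = ["HD95", "MDA", "Dice", "Jaccard", "Spearman"]
    pair_order = [p for p in ("T2-ADC", "T2-Ktrans", "ADC-Ktrans") if p in df["pair"].unique()]
    wide = wide.reindex(
        pd.MultiIndex.from_product([pair_order, metric_order], names=["pair", "metric"])
    )
    return wide.reindex(columns=[c for c in columns if c in wide.columns])


def interobserver_report(
    records_obs1: pd.DataFrame, records_obs2: pd.DataFrame
) -> pd.DataFrame:
    """Side-by-side per-patient metrics for two observers' contour sets.

    Both inputs are per-patient agreement frames restricted to the pairs of
    interest (T2-ADC and T2-Ktrans in the standard analysis).  The output is
    a long frame with one row per patient × pair × observer and the four
    metrics as columns, suitable for a grouped bar chart; per-observer,
    per-pair means are appended as ``patient_id == "MEAN"`` rows.
    """
    ids1 = set(records_obs1["patient_id"])
    ids2 = set(records_obs2["patient_id"])
    if ids1 != ids2:
        raise ValueError(
            f"observers cover different patients: only-obs1={sorted(ids1 - ids2)}, "
            f"only-obs2={sorted(ids2 - ids1)}"
        )
    frames = []
    for obs, rec in (("obs1", records_obs1), ("obs2", records_obs2)):
        df = rec.copy()
        df["observer"] = obs
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    metric_cols = [c for c in ("dice", "jaccard", "hd95_mm", "mda_mm") if c in out]
    means = (
        out.groupby(["observer", "pair"])[metric_cols].mean().reset_index()
    )
    means["patient_id"] = "MEAN"
    out = pd.concat([out, means], ignore_index=True)
    cols = ["patient_id", "pair", "observer", *metric_cols]
    return out[cols].sort_values(["pair", "observer", "patient_id"]).reset_index(drop=True)


def cohort_composition(meta: list[PatientMeta] | pd.DataFrame) -> pd.DataFrame:
    """Percentage of patients per zone and per grade group.

    Percentages are computed over patients with a known label for each axis;
    the number of unlabeled patients is reported in its own row with NaN
    percentage.
    """
    df = metadata_frame(meta)
    if len(df) == 0:
        raise ValueError("empty cohort")
    rows = []
    for axis, vocab in (("zone", ZONES), ("grade_group", GRADE_GROUPS)):
        labeled = df[df[axis].isin(vocab)]
        n_lab = len(labeled)
        for level in vocab:
            count = int((labeled[axis] == level).sum())
            pct = 100.0 * count / n_lab if n_lab else np.nan
            rows.append({"axis": axis, "level": level, "n": count, "percent": pct})
        n_unlab = len(df) - n_lab
        if n_unlab:
            rows.append(
                {"axis": axis, "level": "unlabeled", "n": n_unlab, "percent": np.nan}
            )
    return pd.DataFrame(rows)


def intensity_table(
    stats: pd.DataFrame, meta: list[PatientMeta] | pd.DataFrame
) -> pd.DataFrame:
    """Within-contour intensity summary by grade group.

    ``stats`` carries one row per patient × modality with columns
    ``patient_id, modality, mean, min, max`` (per-patient contour statistics,
    e.g. from :func:`contour_intensity_stats`).  The output reports, per
    grade group and modality, the cohort mean of the per-patient means, the
    cohort min/max of the per-patient extremes, and the SD of the per-patient
    means — the layout used for threshold recommendations.
    """
    meta_df = metadata_frame(meta)
    df = stats.merge(
        meta_df[["patient_id", "grade_group", "ktrans_usable"]], on="patient_id"
    )
    df = df[~((df["modality"] == "KTRANS") & ~df["ktrans_usable"])]
    out = (
        df.groupby(["grade_group", "modality"])
        .agg(
            mean=("mean", "mean"),
            min=("min", "min"),
            max=("max", "max"),
            sd=("mean", lambda v: v.std(ddof=1) if len(v) > 1 else np.nan),
            n=("mean", "size"),
        )
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out
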