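"""Per-cell translocation ratios and their well/sample aggregation.

The per-cell statistic is the mean GFP reporter intensity over the nucleus
mask divided by the mean over the cytoplasm ring region — a ratio that rises
as the reporter translocates into the nucleus. Aggregation follows the
assay's design: the field value is the mean of its cells' ratios, the well
value is the unweighted mean of its field values, and each sample's
normalized translocation y is its replicate-well mean divided by the mean of
its matched solvent-control (vehicle) wells, so vehicle y = 1 by
construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import GFP_CHANNEL, ImageField, as_labels
from .segment import paired_labels

CELL_COLUMNS = [
    "plate",
    "well",
    "field",
    "cell",
    "nuc_area",
    "ring_area",
    "nuc_mean_gfp",
    "ring_mean_gfp",
    "ratio",
]


def measure_cells(
    field: ImageField,
    nuclei,
    rings,
    background_mode: str = "none",
    eps: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Per-cell nucleus/ring mean GFP and their ratio.

    ``background_mode``: ``"none"`` (default) measures raw intensities;
    ``"field_median"`` subtracts the median of non-cell pixels from the GFP
    channel first, flooring at zero. Cells whose ring mean is <= ``eps``
    counts are discarded and tallied in the returned QC dict rather than
    producing unstable ratios.

    Returns ``(cells, qc)`` where ``cells`` has one row per retained cell.
    """
    nuc = as_labels(nuclei)
    ring = as_labels(rings)
    if nuc.shape != field.shape or ring.shape != field.shape:
        raise ValueError("mask shape does not match field shape")
    if background_mode not in ("none", "field_median"):
        raise ValueError(f"unknown background_mode {background_mode!r}")

    gfp = field.channel(GFP_CHANNEL).astype(float)
    if background_mode == "field_median":
        bg_pixels = gfp[(nuc == 0) & (ring == 0)]
        if bg_pixels.size:
            gfp = np.maximum(gfp - np.median(bg_pixels), 0.0)

    labels = paired_labels(nuc, ring)
    qc = {
        "n_nuclei": int(len(np.unique(nuc)) - (1 if (nuc == 0).any() else 0)),
        "n_paired": int(labels.size),
        "n_dropped_low_ring": 0,
    }
    if labels.size == 0:
        return pd.DataFrame(columns=CELL_COLUMNS), qc

    idx = labels.astype(int)
    nuc_mean = ndimage.mean(gfp, labels=nuc, index=idx)
    ring_mean = ndimage.mean(gfp, labels=ring, index=idx)
    nuc_area = ndimage.sum_labels(np.ones_like(gfp), labels=nuc, index=idx)
    ring_area = ndimage.sum_labels(np.ones_like(gfp), labels=ring, index=idx)

    keep = ring_mean > eps
    qc["n_dropped_low_ring"] = int((~keep).sum())
    cells = pd.DataFrame(
        {
            "plate": field.plate,
            "well": field.well,
            "field": field.field_index,
            "cell": idx[keep],
            "nuc_area": nuc_area[keep].astype(int),
            "ring_area": ring_area[keep].astype(int),
            "nuc_mean_gfp": nuc_mean[keep],
            "ring_mean_gfp": ring_mean[keep],
            "ratio": nuc_mean[keep] / ring_mean[keep],
        },
        columns=CELL_COLUMNS,
    )
    return cells, qc


def aggregate(
    cells: pd.DataFrame, layout, min_cells_per_well: int = 50
) -> pd.DataFrame:
    """Field means -> well values (fields weighted equally, not cell-weighted).

    The well value is the arithmetic mean of its field means and the SEM is
    taken across field means. Wells with fewer than ``min_cells_per_well``
    cells in total are flagged ``low_count``. Every measured well must appear
    in the layout.
    """
    by_well = layout.well_map()
    if len(cells):
        unknown = sorted(set(cells["well"]) - set(by_well))
        if unknown:
            raise ValueError(f"wells not in layout: {unknown}")

    rows = []
    if len(cells):
        field_means = (
            cells.groupby(["well", "field"], sort=True)["ratio"]
            .agg(["mean", "size"])
            .reset_index()
        )
        for well, grp in field_means.groupby("well", sort=True):
            spec = by_well[well]
            fm = grp["mean"].to_numpy()
            n_cells = int(grp["size"].sum())
            sem = (
                float(np.std(fm, ddof=1) / np.sqrt(len(fm))) if len(fm) > 1 else np.nan
            )
            rows.append(
                {
                    "well": well,
                    "sample": spec.sample,
                    "treatment": spec.treatment,
                    "concentration": spec.concentration,
                    "timepoint": spec.timepoint,
                    "vehicle_group": spec.vehicle_group,
                    "is_vehicle": spec.is_vehicle,
                    "n_fields": int(len(fm)),
                    "n_cells": n_cells,
                    "well_value": float(np.mean(fm)),
                    "sem": sem,
                    "low_count": n_cells < min_cells_per_well,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "well",
            "sample",
            "treatment",
            "concentration",
            "timepoint",
            "vehicle_group",
            "is_vehicle",
            "n_fields",
            "n_cells",
            "well_value",
            "sem",
            "low_count",
        ],
    )


def normalize(wells: pd.DataFrame, layout) -> pd.DataFrame:
    """Sample-level normalized translocation y against matched vehicle wells.

    y_sample = mean(sample well values) / mean(vehicle-group well values);
    the vehicle mean is treated as a constant divisor when propagating the
    SEM from the sample's replicate wells. The vehicle sample itself gets
    y = 1 exactly.
    """
    if not len(wells):
        return pd.DataFrame(
            columns=[
                "sample",
                "treatment",
                "concentration",
                "timepoint",
                "vehicle_group",
                "y",
                "sem",
                "n_wells",
            ]
        )
    vehicle_means = {}
    for group, grp in wells[wells["is_vehicle"]].groupby("vehicle_group"):
        m = float(grp["well_value"].mean())
        if m <= 0:
            raise ValueError(f"vehicle group {group!r} has non-positive mean {m}")
        vehicle_means[group] = m

    rows = []
    for sample, grp in wells.groupby("sample", sort=True):
        group = grp["vehicle_group"].iloc[0]
        if group not in vehicle_means:
            raise ValueError(
                f"sample {sample!r} references vehicle group {group!r} "
                "with no measured vehicle wells"
            )
        vm = vehicle_means[group]
        vals = grp["well_value"].to_numpy()
        y = float(np.mean(vals)) / vm
        sem = (
            float(np.std(vals, ddof=1) / np.sqrt(len(vals)) / vm)
            if len(vals) > 1
            else np.nan
        )
        rows.append(
            {
                "sample": sample,
                "treatment": grp["treatment"].iloc[0],
                "concentration": grp["concentration"].iloc[0],
                "timepoint": grp["timepoint"].iloc[0],
                "vehicle_group": group,
                "y": y,
                "sem": sem,
                "n_wells": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)
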