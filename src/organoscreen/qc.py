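"""Plate quality control: masking localized groups of aberrant wells.

Screening plates accumulate spatially clustered artifacts — dispenser
misfires, evaporation patches, debris — that corrupt whole groups of
neighboring wells.  This module automates the masking step that is usually
done by eye: each well's intensity is compared against the robust
median/MAD statistics of its local neighborhood (restricted to wells of the
same cell line and treatment, so controls and compound fields are judged
against their own kind), and wells whose robust z-score exceeds a threshold
AND that form 4-connected clusters of a minimum size are masked.  Isolated
single-well outliers are deliberately left alone — the curve fit's
residuals absorb those.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import QCError
from .model import N_COLS, N_ROWS, PlateSet

MAD_FLOOR = 1e-9
_MAD_SCALE = 1.4826  # consistent with a normal sd


@dataclass
class MaskReport:
    plate_id: str
    masked_wells: list = field(default_factory=list)  # (row, col, reason)

    @property
    def n_masked(self) -> int:
        return len(self.masked_wells)


def _neighborhood_z(grid, group, masked, window):
    """Robust z-score of each well vs its window x window neighborhood.

    The neighborhood is restricted to unmasked wells of the same group id,
    excluding the well itself.  Wells with fewer than 3 usable neighbors get
    z = 0.
    """
    half = window // 2
    z = np.zeros_like(grid, dtype=float)
    for r in range(N_ROWS):
        for c in range(N_COLS):
            if masked[r, c] or group[r, c] < 0:
                continue
            r0, r1 = max(0, r - half), min(N_ROWS, r + half + 1)
            c0, c1 = max(0, c - half), min(N_COLS, c + half + 1)
            patch = grid[r0:r1, c0:c1]
            ok = (group[r0:r1, c0:c1] == group[r, c]) & ~masked[r0:r1, c0:c1]
            ok[r - r0, c - c0] = False
            vals = patch[ok]
            if vals.size < 3:
                continue
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            z[r, c] = (grid[r, c] - med) / max(_MAD_SCALE * mad, MAD_FLOOR)
    return z


def mask_local_artifacts(
    plates: PlateSet,
    window: int = 5,
    z_threshold: float = 5.0,
    min_cluster: int = 3,
) -> tuple[PlateSet, list[MaskReport]]:
    """Mask clustered aberrant wells on every plate of a campaign.

    Returns a new PlateSet (input untouched) and one MaskReport per plate.
    Wells already masked on input are reported with reason MANUAL and kept
    masked; they are excluded from neighborhood statistics so the operation
    is idempotent.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if z_threshold <= 0:
        raise ValueError("z_threshold must be > 0")
    if min_cluster < 1:
        raise ValueError("min_cluster must be >= 1")

    out = plates.copy()
    df = out.wells
    reports = []
    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])  # 4-connectivity

    for pid in out.plate_ids:
        sel = df["plate_id"] == pid
        sub = df[sel]
        if (~sub["masked"]).sum() < window * window:
            raise QCError(
                f"plate {pid!r}: fewer unmasked wells than the {window}x{window} "
                "neighborhood needs"
            )
        rows = sub["row"].to_numpy()
        cols = sub["col"].to_numpy()

        group = np.full((N_ROWS, N_COLS), -1, dtype=int)
        keys = (sub["cell_line"].astype(str) + "|" + sub["treatment"].astype(str)).to_numpy()
        codes = {k: i for i, k in enumerate(np.unique(keys))}
        group[rows, cols] = [codes[k] for k in keys]

        masked0 = np.zeros((N_ROWS, N_COLS), dtype=bool)
        masked0[rows, cols] = sub["masked"].to_numpy()

        report = MaskReport(plate_id=pid)
        for r, c in zip(*np.nonzero(masked0)):
            report.masked_wells.append((int(r), int(c), "MANUAL"))

        flag_high = np.zeros((N_ROWS, N_COLS), dtype=bool)
        flag_low = np.zeros((N_ROWS, N_COLS), dtype=bool)
        for channel in ("gfp", "dapi"):
            grid = np.zeros((N_ROWS, N_COLS))
            grid[rows, cols] = sub[channel].to_numpy()
            z = _neighborhood_z(grid, group, masked0, window)
            flag_high |= z > z_threshold
            flag_low |= z < -z_threshold

        new_mask = np.zeros((N_ROWS, N_COLS), dtype=bool)
        for flags, reason in ((flag_high, "LOCAL_HIGH"), (flag_low, "LOCAL_LOW")):
            labels, n_lab = ndimage.label(flags, structure=struct)
            for lab in range(1, n_lab + 1):
                members = np.argwhere(labels == lab)
                if len(members) >= min_cluster:
                    for r, c in members:
                        if not new_mask[r, c] and not masked0[r, c]:
                            new_mask[r, c] = True
                            report.masked_wells.append((int(r), int(c), reason))

        if new_mask.any():
            well_mask = new_mask[rows, cols]
            df.loc[sub.index[well_mask], "masked"] = True
        reports.append(report)

    return out, reports


def mask_report_frame(reports: list[MaskReport]):
    """Flatten reports to a DataFrame with columns plate_id,row,col,reason."""
    import pandas as pd

    rows = [
        (rep.plate_id, r, c, reason)
        for rep in reports
        for (r, c, reason) in rep.masked_wells
    ]
    return pd.DataFrame(rows, columns=["plate_id", "row", "col", "reason"])
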