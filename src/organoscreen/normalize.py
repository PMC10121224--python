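"""Intra-plate normalization of raw intensities to percent scores.

Each plate's raw channel intensities are converted into three percent
scales anchored on that plate's own DMSO control wells:

* efficacy      = 100 * (GFP_rd16+c - mean GFP_rd16+dmso)
                      / (mean GFP_wt+dmso - mean GFP_rd16+dmso)
* toxicity      = -100 * (DAPI_rd16+c - mean DAPI_rd16+dmso)
                       / mean DAPI_rd16+dmso
* fluorescence  = 100 * (GFP_parental+c - mean GFP_parental+dmso)
                      / (mean GFP_wt+dmso - mean GFP_parental+dmso)

so a compound well at the disease baseline scores 0 efficacy, one at the WT
level scores 100, full cell loss scores 100 toxicity, and counter-screen
autofluorescence is expressed on the same 0-100 scale as rescue.  Scores are
deliberately NOT clipped to [0, 100]: noise and super-WT rescue legitimately
exceed the anchors and clipping would bias the curve fits.  Masked wells
never contribute — neither to control means nor as scored observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .model import AssayKind, CellLine, PlateSet, Treatment

SCORE_COLUMNS = [
    "compound_id",
    "concentration_molar",
    "replicate",
    "efficacy",
    "toxicity",
    "fluorescence",
]


@dataclass(frozen=True)
class ControlStats:
    """Per-plate DMSO control means (unmasked wells only)."""

    plate_id: str
    mean_gfp_wt_dmso: float
    mean_gfp_rd16_dmso: float | None
    mean_dapi_rd16_dmso: float | None
    mean_gfp_parental_dmso: float | None
    n_wt: int
    n_rd16: int
    n_parental: int


def _group_mean(sub: pd.DataFrame, line: CellLine, channel: str) -> tuple[float, int]:
    sel = (
        (sub["cell_line"] == line.value)
        & (sub["treatment"] == Treatment.DMSO.value)
        & ~sub["masked"]
    )
    vals = sub.loc[sel, channel]
    return (float(vals.mean()) if len(vals) else math.nan), int(len(vals))


def control_stats(
    plates: PlateSet, trimmed: float = 0.0
) -> dict[str, ControlStats]:
    """Compute per-plate control statistics.

    Plates without WT+DMSO wells (typically counter-screen plates) borrow
    the WT mean from the campaign's designated control plate: the first
    (by plate id) plate of the same replicate index that has WT wells.
    ``trimmed`` optionally trims that fraction from each tail before
    averaging (off by default).
    """

    def agg(values: pd.Series) -> float:
        v = np.sort(values.to_numpy())
        if trimmed > 0 and len(v) > 2:
            k = int(trimmed * len(v))
            v = v[k : len(v) - k] if k > 0 else v
        return float(v.mean())

    raw: dict[str, dict] = {}
    for pid in plates.plate_ids:
        sub = plates.plate(pid)
        d: dict = {}
        for line, channel, key in (
            (CellLine.WT, "gfp", "wt_gfp"),
            (CellLine.RD16, "gfp", "rd16_gfp"),
            (CellLine.RD16, "dapi", "rd16_dapi"),
            (CellLine.PARENTAL, "gfp", "parental_gfp"),
        ):
            sel = (
                (sub["cell_line"] == line.value)
                & (sub["treatment"] == Treatment.DMSO.value)
                & ~sub["masked"]
            )
            vals = sub.loc[sel, channel]
            d[key] = agg(vals) if len(vals) else None
            d[f"n_{key}"] = len(vals)
        raw[pid] = d

    # designated WT donors per replicate: first plate id carrying WT controls
    donors: dict[int, str] = {}
    for pid in plates.plate_ids:
        rep = plates.plate_info[pid].replicate_index
        if raw[pid]["wt_gfp"] is not None and rep not in donors:
            donors[rep] = pid

    out: dict[str, ControlStats] = {}
    for pid in plates.plate_ids:
        d = raw[pid]
        kind = plates.plate_info[pid].assay_kind
        rep = plates.plate_info[pid].replicate_index
        wt = d["wt_gfp"]
        if wt is None:
            donor = donors.get(rep)
            if donor is None:
                raise NormalizationError(
                    f"plate {pid!r}: no WT+DMSO wells on this plate and no "
                    f"control plate available for replicate {rep}"
                )
            wt = raw[donor]["wt_gfp"]
        if kind == AssayKind.DISEASE_ASSAY:
            for key, group in (("rd16_gfp", "RD16+DMSO GFP"), ("rd16_dapi", "RD16+DMSO DAPI")):
                if d[key] is None:
                    raise NormalizationError(
                        f"plate {pid!r}: zero unmasked {group} control wells"
                    )
            if wt <= d["rd16_gfp"]:
                raise NormalizationError(
                    f"plate {pid!r}: degenerate efficacy window "
                    f"(WT mean {wt:.3g} <= RD16 mean {d['rd16_gfp']:.3g})"
                )
        if kind == AssayKind.COUNTER_SCREEN:
            if d["parental_gfp"] is None:
                raise NormalizationError(
                    f"plate {pid!r}: zero unmasked PARENTAL+DMSO control wells"
                )
            if wt <= d["parental_gfp"]:
                raise NormalizationError(
                    f"plate {pid!r}: degenerate fluorescence window"
                )
        out[pid] = ControlStats(
            plate_id=pid,
            mean_gfp_wt_dmso=wt,
            mean_gfp_rd16_dmso=d["rd16_gfp"],
            mean_dapi_rd16_dmso=d["rd16_dapi"],
            mean_gfp_parental_dmso=d["parental_gfp"],
            n_wt=d["n_wt_gfp"],
            n_rd16=d["n_rd16_gfp"],
            n_parental=d["n_parental_gfp"],
        )
    return out


def efficacy_score(gfp_c: float, stats: ControlStats) -> float:
    """Percent GFP rescue of a disease-assay compound well."""
    if stats.mean_gfp_rd16_dmso is None:
        raise NormalizationError(f"plate {stats.plate_id!r}: no RD16 controls")
    window = stats.mean_gfp_wt_dmso - stats.mean_gfp_rd16_dmso
    return 100.0 * (gfp_c - stats.mean_gfp_rd16_dmso) / window


def toxicity_score(dapi_c: float, stats: ControlStats) -> float:
    """Percent viability loss (positive = cell death)."""
    if stats.mean_dapi_rd16_dmso is None:
        raise NormalizationError(f"plate {stats.plate_id!r}: no RD16 DAPI controls")
    if stats.mean_dapi_rd16_dmso <= 0:
        raise NormalizationError(
            f"plate {stats.plate_id!r}: zero RD16+DMSO DAPI control mean"
        )
    return -100.0 * (dapi_c - stats.mean_dapi_rd16_dmso) / stats.mean_dapi_rd16_dmso


def fluorescence_score(gfp_parental_c: float, stats: ControlStats) -> float:
    """Percent compound autofluorescence on the rescue scale."""
    if stats.mean_gfp_parental_dmso is None:
        raise NormalizationError(
            f"plate {stats.plate_id!r}: no PARENTAL controls"
        )
    window = stats.mean_gfp_wt_dmso - stats.mean_gfp_parental_dmso
    return 100.0 * (gfp_parental_c - stats.mean_gfp_parental_dmso) / window


def normalize_campaign(
    plates: PlateSet, stats: dict[str, ControlStats] | None = None
) -> pd.DataFrame:
    """Score every unmasked compound well of a campaign.

    Disease-assay wells yield efficacy (GFP) and toxicity (DAPI);
    counter-screen wells yield fluorescence.  The three are joined by
    (compound_id, concentration, replicate) into one row per observation,
    ordered by compound then descending concentration.  Compounds present
    only in the counter-screen are emitted with null efficacy and a warning.
    """
    if stats is None:
        stats = control_stats(plates)

    df = plates.wells
    cpd = df[(df["treatment"] == Treatment.COMPOUND.value) & ~df["masked"]].copy()
    if cpd.empty:
        return pd.DataFrame(columns=SCORE_COLUMNS)

    cpd["replicate"] = [
        plates.plate_info[p].replicate_index for p in cpd["plate_id"]
    ]
    cpd["assay_kind"] = [
        plates.plate_info[p].assay_kind.value for p in cpd["plate_id"]
    ]

    disease = cpd[cpd["assay_kind"] == AssayKind.DISEASE_ASSAY.value]
    counter = cpd[cpd["assay_kind"] == AssayKind.COUNTER_SCREEN.value]

    def score_rows(sub: pd.DataFrame, fn, channel: str, name: str) -> pd.DataFrame:
        if sub.empty:
            return pd.DataFrame(
                columns=["compound_id", "concentration_molar", "replicate", name]
            )
        vals = [
            fn(getattr(t, channel), stats[t.plate_id])
            for t in sub.itertuples(index=False)
        ]
        out = sub[["compound_id", "concentration_molar", "replicate"]].copy()
        out[name] = vals
        # one observation per key: average duplicate wells (same compound,
        # concentration, replicate on one assay kind)
        return (
            out.groupby(["compound_id", "concentration_molar", "replicate"])
            .mean()
            .reset_index()
        )

    eff = score_rows(disease, efficacy_score, "gfp", "efficacy")
    tox = score_rows(disease, toxicity_score, "dapi", "toxicity")
    flr = score_rows(counter, fluorescence_score, "gfp", "fluorescence")

    key = ["compound_id", "concentration_molar", "replicate"]
    merged = eff.merge(tox, on=key, how="outer").merge(flr, on=key, how="outer")

    has_eff = merged.groupby("compound_id")["efficacy"].transform(
        lambda s: s.notna().any()
    )
    orphans = merged.loc[~has_eff, "compound_id"].unique()
    if len(orphans):
        warnings.warn(
            "compounds present in the counter-screen but missing from the "
            f"disease assay (efficacy null, excluded from fitting): "
            f"{sorted(map(str, orphans))[:10]}",
            stacklevel=2,
        )

    merged = merged.sort_values(
        ["compound_id", "concentration_molar"], ascending=[True, False]
    ).reset_index(drop=True)
    for col in SCORE_COLUMNS:
        if col not in merged.columns:
            merged[col] = np.nan
    return merged[SCORE_COLUMNS]
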