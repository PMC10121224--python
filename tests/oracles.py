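"""Independent reference implementations used only to check the package.

These deliberately re-derive results through different routes than the
library code: the normalization oracle is a literal well-by-well
transcription of the percent-score formulas, and the Hill oracle is an
exhaustive grid search over (log AC50, slope) with the two linear
parameters profiled out by a closed-form box-constrained solve.
"""

from __future__ import annotations

import numpy as np


def normalization_oracle(wells: list[dict], wt_mean: float | None = None) -> list[dict]:
    """Literal transcription of the three percent-score formulas.

    ``wells`` are dicts with keys cell_line, treatment, gfp, dapi, masked,
    plate (one plate at a time), compound fields optional.  Returns scored
    compound wells with efficacy/toxicity (disease wells need RD16) and
    fluorescence (parental wells).  ``wt_mean`` supplies the positive-control
    GFP mean for plates that carry no WT wells of their own.
    """

    def mean(vals):
        return sum(vals) / len(vals)

    wt_wells = [
        w["gfp"] for w in wells
        if w["cell_line"] == "WT" and w["treatment"] == "DMSO" and not w["masked"]
    ]
    gfp_wt = mean(wt_wells) if wt_wells else wt_mean
    rd_dmso = [w for w in wells
               if w["cell_line"] == "RD16" and w["treatment"] == "DMSO" and not w["masked"]]
    par_dmso = [w for w in wells
                if w["cell_line"] == "PARENTAL" and w["treatment"] == "DMSO" and not w["masked"]]
    gfp_rd = mean([w["gfp"] for w in rd_dmso]) if rd_dmso else None
    dapi_rd = mean([w["dapi"] for w in rd_dmso]) if rd_dmso else None
    gfp_par = mean([w["gfp"] for w in par_dmso]) if par_dmso else None

    out = []
    for w in wells:
        if w["treatment"] != "COMPOUND" or w["masked"]:
            continue
        rec = dict(w)
        if w["cell_line"] == "RD16":
            rec["efficacy"] = 100.0 * (w["gfp"] - gfp_rd) / (gfp_wt - gfp_rd)
            rec["toxicity"] = -100.0 * (w["dapi"] - dapi_rd) / dapi_rd
        if w["cell_line"] == "PARENTAL":
            rec["fluorescence"] = 100.0 * (w["gfp"] - gfp_par) / (gfp_wt - gfp_par)
        out.append(rec)
    return out


def hill_grid_search_sse(
    conc: np.ndarray,
    score: np.ndarray,
    log_ac50_range: tuple[float, float],
    n_range: tuple[float, float] = (0.1, 10.0),
    log_ac50_step: float = 0.01,
    n_step: float = 0.1,
    a_box: tuple[float, float] = (-100.0, 200.0),
) -> float:
    """Best SSE over an exhaustive (log AC50, n) grid.

    At each grid node the model is linear in (A0, Ainf); the box-constrained
    linear least-squares solution is computed in closed form (interior
    solution if feasible, else the best of the four clamped-edge solutions).
    """
    conc = np.asarray(conc, float)
    y = np.asarray(score, float)
    logc = np.log10(conc)
    lacs = np.arange(log_ac50_range[0], log_ac50_range[1] + 1e-12, log_ac50_step)
    ns = np.arange(n_range[0], n_range[1] + 1e-12, n_step)
    lo, hi = a_box
    yty = float(y @ y)

    best = np.inf
    for n in ns:
        # w: (L, P) occupancy for every log_ac50 at this slope
        t = np.clip(n * (lacs[:, None] - logc[None, :]), -300, 300)
        w = 1.0 / (1.0 + 10.0**t)
        u = 1.0 - w
        S11 = (u * u).sum(axis=1)
        S12 = (u * w).sum(axis=1)
        S22 = (w * w).sum(axis=1)
        b1 = u @ y
        b2 = w @ y

        def sse_of(a0, ai):
            return (
                a0 * a0 * S11 + 2 * a0 * ai * S12 + ai * ai * S22
                - 2 * a0 * b1 - 2 * ai * b2 + yty
            )

        det = S11 * S22 - S12 * S12
        with np.errstate(divide="ignore", invalid="ignore"):
            a0_int = np.where(det > 0, (b1 * S22 - b2 * S12) / det, np.nan)
            ai_int = np.where(det > 0, (S11 * b2 - S12 * b1) / det, np.nan)
        feasible = (
            (a0_int >= lo) & (a0_int <= hi) & (ai_int >= lo) & (ai_int <= hi)
        )
        cand = np.where(feasible, sse_of(a0_int, ai_int), np.inf)

        for a0_edge in (lo, hi):
            with np.errstate(divide="ignore", invalid="ignore"):
                ai = np.where(S22 > 0, (b2 - a0_edge * S12) / S22, 0.0)
            ai = np.clip(ai, lo, hi)
            cand = np.minimum(cand, sse_of(np.full_like(ai, a0_edge), ai))
        for ai_edge in (lo, hi):
            with np.errstate(divide="ignore", invalid="ignore"):
                a0 = np.where(S11 > 0, (b1 - ai_edge * S12) / S11, 0.0)
            a0 = np.clip(a0, lo, hi)
            cand = np.minimum(cand, sse_of(a0, np.full_like(a0, ai_edge)))

        best = min(best, float(np.nanmin(cand)))
    return best
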