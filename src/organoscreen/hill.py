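"""Four-parameter logistic (Hill) concentration-response fitting.

The model, in log10 concentration, is

    A(C) = A0 + (Ainf - A0) / (1 + 10^(n * (log10 AC50 - log10 C)))

with A0 the zero-concentration asymptote, Ainf the infinite-concentration
asymptote, AC50 the concentration giving the half-way response
(A(AC50) = (A0 + Ainf)/2 identically), and n > 0 the Hill slope.  Fitting is
bounded nonlinear least squares on normalized percent scores with a
deterministic multistart around a heuristic initial guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

N_MAX = 10.0
N_MIN = 1e-2
MIN_DISTINCT_CONC = 4


@dataclass(frozen=True)
class HillParams:
    a0: float
    ainf: float
    log_ac50: float  # log10 mol/L
    n: float

    def __post_init__(self):
        if not (self.n > 0):
            raise ValueError("Hill coefficient must be > 0")
        if not np.isfinite([self.a0, self.ainf, self.log_ac50]).all():
            raise ValueError("parameters must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.a0, self.ainf, self.log_ac50, self.n])


@dataclass(frozen=True)
class FitBounds:
    """Box constraints for the optimizer, in (a0, ainf, log_ac50, n) order."""

    a0: tuple[float, float] = (-100.0, 200.0)
    ainf: tuple[float, float] = (-100.0, 200.0)
    log_ac50: tuple[float, float] = (-np.inf, np.inf)  # set from data if infinite
    n: tuple[float, float] = (N_MIN, N_MAX)

    def resolved(self, conc: np.ndarray) -> "FitBounds":
        """Replace infinite AC50 bounds by the tested range widened 2 decades."""
        lo, hi = self.log_ac50
        if not np.isfinite(lo):
            lo = float(np.log10(conc.min())) - 2.0
        if not np.isfinite(hi):
            hi = float(np.log10(conc.max())) + 2.0
        return replace(self, log_ac50=(lo, hi))

    def lower(self) -> np.ndarray:
        return np.array([self.a0[0], self.ainf[0], self.log_ac50[0], self.n[0]])

    def upper(self) -> np.ndarray:
        return np.array([self.a0[1], self.ainf[1], self.log_ac50[1], self.n[1]])


@dataclass(frozen=True)
class HillFit:
    """Result of fitting one compound/score-type concentration series."""

    compound_id: str
    score_type: str  # EFFICACY | TOXICITY | FLUORESCENCE
    params: HillParams | None
    sse: float
    r2: float
    n_points: int
    converged: bool
    curve_class: object = None  # filled in by curve classification

    @property
    def ac50(self) -> float | None:
        return None if self.params is None else 10.0 ** self.params.log_ac50


def hill_response(params: HillParams, conc) -> np.ndarray | float:
    """Evaluate the model at concentration(s) ``conc`` (mol/L, > 0)."""
    c = np.asarray(conc, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be > 0")
    return _hill(params.a0, params.ainf, params.log_ac50, params.n, c)


def _hill(a0, ainf, log_ac50, n, conc):
    x = n * (log_ac50 - np.log10(conc))
    # clip the exponent so extreme slopes cannot overflow
    return a0 + (ainf - a0) / (1.0 + 10.0 ** np.clip(x, -300, 300))


def ac50(fit: HillFit) -> float | None:
    """AC50 in mol/L for a converged fit; None when unconverged."""
    if not fit.converged or fit.params is None:
        return None
    return 10.0 ** fit.params.log_ac50


def initial_guess(points: Sequence[tuple[float, float]]) -> HillParams:
    """Heuristic starting parameters from the data.

    A0 is the mean score at the two lowest concentrations, Ainf at the two
    highest; log AC50 is where the concentration-mean response first crosses
    the half-way level (linear interpolation in log concentration), falling
    back to the midpoint of the tested log-range; the slope starts at 1.
    """
    conc = np.array([p[0] for p in points], dtype=float)
    score = np.array([p[1] for p in points], dtype=float)
    if len(np.unique(conc)) < MIN_DISTINCT_CONC:
        raise ValueError(
            f"need >= {MIN_DISTINCT_CONC} distinct concentrations, "
            f"got {len(np.unique(conc))}"
        )
    uconc = np.unique(conc)  # ascending
    means = np.array([score[conc == u].mean() for u in uconc])
    a0 = means[:2].mean()
    ainf = means[-2:].mean()
    half = 0.5 * (a0 + ainf)
    logc = np.log10(uconc)
    log_ac50 = 0.5 * (logc[0] + logc[-1])
    rising = ainf >= a0
    for i in range(len(uconc) - 1):
        y0, y1 = means[i], means[i + 1]
        crosses = (y0 - half) * (y1 - half) <= 0 and y0 != y1
        if crosses and ((y1 > y0) == rising or y0 == half):
            frac = (half - y0) / (y1 - y0)
            log_ac50 = logc[i] + frac * (logc[i + 1] - logc[i])
            break
    return HillParams(a0=float(a0), ainf=float(ainf), log_ac50=float(log_ac50), n=1.0)


def _coarse_profile_start(conc, score, lo, hi):
    """Best coarse-lattice candidate over (log_ac50, n).

    At each lattice node the model is linear in (A0, Ainf); the
    box-constrained least-squares solution is closed-form (interior if
    feasible, else best clamped edge).  The winner seeds one multistart
    leg, giving the local optimizer a foothold in the global basin even
    when the data-driven guess starts in a poor one.
    """
    logc = np.log10(conc)
    lacs = np.arange(lo[2], hi[2] + 1e-9, 0.1)
    ns = np.array([0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 10.0])
    ns = ns[(ns >= lo[3]) & (ns <= hi[3])]
    y = score
    yty = float(y @ y)
    a_lo, a_hi = lo[0], hi[0]

    best = (np.inf, None)
    for n in ns:
        t = np.clip(n * (lacs[:, None] - logc[None, :]), -300, 300)
        w = 1.0 / (1.0 + 10.0**t)
        u = 1.0 - w
        S11, S12, S22 = (u * u).sum(1), (u * w).sum(1), (w * w).sum(1)
        b1, b2 = u @ y, w @ y

        def sse_of(a0, ai):
            return (
                a0 * a0 * S11 + 2 * a0 * ai * S12 + ai * ai * S22
                - 2 * a0 * b1 - 2 * ai * b2 + yty
            )

        det = S11 * S22 - S12 * S12
        with np.errstate(divide="ignore", invalid="ignore"):
            a0_i = np.where(det > 0, (b1 * S22 - b2 * S12) / det, np.nan)
            ai_i = np.where(det > 0, (S11 * b2 - S12 * b1) / det, np.nan)
        ok = (a0_i >= a_lo) & (a0_i <= a_hi) & (ai_i >= a_lo) & (ai_i <= a_hi)
        cand_sse = np.where(ok, sse_of(a0_i, ai_i), np.inf)
        cand_a0, cand_ai = np.where(ok, a0_i, 0.0), np.where(ok, ai_i, 0.0)
        for edge_a0 in (a_lo, a_hi):
            with np.errstate(divide="ignore", invalid="ignore"):
                ai = np.clip(np.where(S22 > 0, (b2 - edge_a0 * S12) / S22, 0.0), a_lo, a_hi)
            s = sse_of(np.full_like(ai, edge_a0), ai)
            better = s < cand_sse
            cand_sse = np.where(better, s, cand_sse)
            cand_a0 = np.where(better, edge_a0, cand_a0)
            cand_ai = np.where(better, ai, cand_ai)
        for edge_ai in (a_lo, a_hi):
            with np.errstate(divide="ignore", invalid="ignore"):
                a0 = np.clip(np.where(S11 > 0, (b1 - edge_ai * S12) / S11, 0.0), a_lo, a_hi)
            s = sse_of(a0, np.full_like(a0, edge_ai))
            better = s < cand_sse
            cand_sse = np.where(better, s, cand_sse)
            cand_a0 = np.where(better, a0, cand_a0)
            cand_ai = np.where(better, edge_ai, cand_ai)

        j = int(np.argmin(cand_sse))
        if cand_sse[j] < best[0]:
            best = (
                float(cand_sse[j]),
                np.array([cand_a0[j], cand_ai[j], lacs[j], n]),
            )
    return best[1]


def _aicc(sse: float, k: int, n: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit."""
    base = n * math.log(max(sse, 1e-30) / n) + 2 * k
    return base + 2 * k * (k + 1) / max(n - k - 1, 0.5)


def _baseline_selection(best_x, best_sse, starts, lo, hi, n_obs, minimize):
    """Let a zero-baseline fit compete against the free-baseline optimum."""
    lo0, hi0 = lo.copy(), hi.copy()
    lo0[0], hi0[0] = 0.0, 1e-12  # pin A0 at zero
    starts0 = [np.clip(s, lo0 + 1e-13, hi0 - 1e-13) for s in starts]
    x0, sse0 = minimize(starts0, lo0, hi0)
    if x0 is None:
        return best_x
    if _aicc(sse0, 3, n_obs) <= _aicc(best_sse, 4, n_obs):
        x0 = x0.copy()
        x0[0] = 0.0
        return x0
    return best_x


def fit_hill(
    points: Sequence[tuple[float, float]],
    compound_id: str = "",
    score_type: str = "EFFICACY",
    bounds: FitBounds = FitBounds(),
    multistart: int = 5,
    seed: int = 0,
    select_baseline: bool = False,
) -> HillFit:
    """Bounded least-squares fit of the four-parameter logistic.

    Replicate observations enter as individual residuals.  ``multistart - 1``
    deterministically jittered restarts guard against local minima; the
    lowest-SSE converged solution wins.  Fewer than four distinct
    concentrations yields an unconverged placeholder fit.

    With ``select_baseline=True``, a zero-baseline (A0 = 0) fit competes
    against the free-baseline fit by small-sample AIC whenever the free
    baseline drifts away from zero.  Short series whose AC50 sits near the
    bottom of the tested range leave A0 nearly unidentifiable — the
    free-baseline fit then trades A0 against AC50 and can run to the bound
    with barely lower SSE; on percent-normalized scores the zero baseline is
    the natural null and AICc arbitrates.  Off by default so the plain fit
    remains the exact least-squares minimizer.
    """
    conc = np.array([p[0] for p in points], dtype=float)
    score = np.array([p[1] for p in points], dtype=float)
    n_points = len(conc)

    if len(np.unique(conc)) < MIN_DISTINCT_CONC:
        return HillFit(
            compound_id=compound_id,
            score_type=score_type,
            params=None,
            sse=np.nan,
            r2=np.nan,
            n_points=n_points,
            converged=False,
        )
    if np.any(conc <= 0):
        raise ValueError("concentrations must be > 0")

    b = bounds.resolved(conc)
    lo, hi = b.lower(), b.upper()
    guess = initial_guess(points)
    x0 = np.clip(guess.as_array(), lo + 1e-12, hi - 1e-12)

    rng = np.random.default_rng(seed)
    starts = [x0]
    coarse = _coarse_profile_start(conc, score, lo, hi)
    if coarse is not None and multistart > 1:
        starts.append(np.clip(coarse, lo + 1e-12, hi - 1e-12))
    while len(starts) < multistart:
        jitter = np.array(
            [
                rng.normal(0.0, 10.0),
                rng.normal(0.0, 10.0),
                rng.normal(0.0, 0.5),
                rng.normal(0.0, 0.3),
            ]
        )
        base = starts[(len(starts) - 2) % 2]  # alternate guess / coarse
        starts.append(np.clip(base + jitter, lo + 1e-12, hi - 1e-12))

    logc = np.log10(conc)

    def resid(x):
        return _hill(x[0], x[1], x[2], x[3], conc) - score

    def jac(x):
        a0, ainf, log_ac50, n = x
        t = np.clip(n * (log_ac50 - logc), -300, 300)
        u = 10.0**t
        w = 1.0 / (1.0 + u)  # occupancy in [0, 1]
        dw = -np.log(10.0) * u * w**2
        J = np.empty((len(conc), 4))
        J[:, 0] = 1.0 - w
        J[:, 1] = w
        J[:, 2] = (ainf - a0) * dw * n
        J[:, 3] = (ainf - a0) * dw * (log_ac50 - logc)
        return J

    # an essentially perfect fit makes further restarts pointless, as does a
    # consensus: two independent starts landing on the same SSE
    good_enough = 1e-12 * max(1.0, float(np.sum(score**2)))

    def _minimize(starts, lo, hi):
        best_x, best_sse = None, np.inf
        candidate_sses: list[float] = []
        for s in starts:
            sol = None
            trf_start = s
            try:
                # unbounded Levenberg-Marquardt is much cheaper; keep its
                # answer when it lands inside the box, otherwise restart the
                # bounded solver from its projection onto the box
                lm = least_squares(resid, s, jac=jac, method="lm")
                if lm.success:
                    if np.all(lm.x >= lo - 1e-9) and np.all(lm.x <= hi + 1e-9):
                        sol = lm
                        sol.x = np.clip(sol.x, lo, hi)
                    else:
                        trf_start = np.clip(lm.x, lo + 1e-12, hi - 1e-12)
            except Exception:
                pass
            if sol is None:
                try:
                    sol = least_squares(
                        resid, trf_start, jac=jac, bounds=(lo, hi),
                        method="trf", max_nfev=300,
                    )
                except Exception:
                    continue
                if not sol.success:
                    continue
            sse = float(np.sum(sol.fun**2))
            candidate_sses.append(sse)
            if sse < best_sse:
                best_sse, best_x = sse, sol.x
            if best_sse <= good_enough:
                break
            if len(candidate_sses) >= 2:
                second = sorted(candidate_sses)[1]
                if second <= best_sse * (1.0 + 1e-3) + 1e-12:
                    break
        if best_x is not None and best_sse > good_enough:
            # final tight polish from the winner
            try:
                sol = least_squares(
                    resid, np.clip(best_x, lo + 1e-12, hi - 1e-12), jac=jac,
                    bounds=(lo, hi), method="trf",
                    ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=200,
                )
                sse = float(np.sum(sol.fun**2))
                if sse < best_sse:
                    best_sse, best_x = sse, sol.x
            except Exception:
                pass
        return best_x, best_sse

    best_x, best_sse = _minimize(starts, lo, hi)

    if best_x is None:
        return HillFit(
            compound_id=compound_id,
            score_type=score_type,
            params=None,
            sse=np.nan,
            r2=np.nan,
            n_points=n_points,
            converged=False,
        )

    if select_baseline and abs(best_x[0]) > 10.0:
        best_x = _baseline_selection(
            best_x, best_sse, starts, lo, hi, n_points, _minimize
        )
        best_sse = float(np.sum(resid(best_x) ** 2))

    params = HillParams(
        a0=float(best_x[0]),
        ainf=float(best_x[1]),
        log_ac50=float(best_x[2]),
        n=float(best_x[3]),
    )
    sst = float(np.sum((score - score.mean()) ** 2))
    if sst > 0:
        r2 = 1.0 - best_sse / sst
        if abs(r2) < 1e-12:  # cancellation noise when the fit ties the mean
            r2 = 0.0
    else:
        r2 = 1.0 if best_sse < 1e-12 else 0.0
    return HillFit(
        compound_id=compound_id,
        score_type=score_type,
        params=params,
        sse=best_sse,
        r2=r2,
        n_points=n_points,
        converged=True,
    )
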