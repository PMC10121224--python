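"""Ground-truth-labeled synthetic screening campaigns.

Emulates the statistical structure of an organoid qHTS campaign on
well-summary intensities: a disease assay in which RD16 cells sit at a
reduced GFP and viability baseline relative to WT (defaults: 40% of the WT
GFP level and 50% of the WT viability, the disease phenotype the screen is
built around), a reporter-negative parental counter-screen, and compound
classes that separate exactly along the axes the triage rules test —
efficacious (Hill-shaped GFP rescue toward the WT level), toxic (Hill-shaped
kill that removes DAPI signal and, because dead cells lose reporter, GFP
proportionally), and autofluorescent (Hill-shaped additive GFP that appears
identically in the counter-screen).  Per-well noise is multiplicative
lognormal; plate artifacts are an additive separable row/column gradient
plus an edge-well offset.

Everything is deterministic for a fixed seed, and every compound carries its
generating parameters so downstream calls can be scored against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .model import (
    N_COLS,
    N_ROWS,
    WELL_COLUMNS,
    AssayKind,
    CellLine,
    PlateInfo,
    PlateSet,
    Treatment,
    dilution_series,
)

COMPOUND_CLASSES = (
    "inactive",
    "efficacious",
    "toxic",
    "autofluorescent",
    "efficacious+toxic",
    "efficacious+autofluorescent",
)

#: Concentration-series presets: (top nominal concentration mol/L, dilution
#: factor, points, replicates).  Both mirror the screening libraries'
#: preparation — 1:3 serial dilutions starting from the 10 mM stock — with
#: the seven-point single-replicate series for the primary screen and the
#: 11-point triplicate series for the confirmatory screen.  Concentrations
#: are nominal (source-series) values, as supplied by the layout.
PRESETS = {
    "primary-7pt": (10e-3, 3.0, 7, 1),
    "confirmatory-11pt-x3": (10e-3, 3.0, 11, 3),
}


@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for one simulated compound."""

    compound_id: str
    compound_class: str
    is_efficacious: bool
    is_toxic: bool
    is_autofluorescent: bool
    # efficacy: fraction of the WT-RD16 GFP window restored at saturation
    a0_e: float | None = None
    ainf_e: float | None = None
    ac50_e: float | None = None
    n_e: float | None = None
    # toxicity: fraction of cells killed at saturation
    ac50_t: float | None = None
    n_t: float | None = None
    max_kill: float | None = None
    # autofluorescence: additive GFP intensity at saturation
    ac50_f: float | None = None
    n_f: float | None = None
    added_intensity: float | None = None

    def __post_init__(self):
        if self.is_efficacious != (self.ac50_e is not None):
            raise ValueError("eff params present iff is_efficacious")
        if self.is_toxic != (self.ac50_t is not None):
            raise ValueError("tox params present iff is_toxic")
        if self.is_autofluorescent != (self.ac50_f is not None):
            raise ValueError("fluor params present iff is_autofluorescent")
        for v in (self.ac50_e, self.ac50_t, self.ac50_f):
            if v is not None and v <= 0:
                raise ValueError("AC50 must be > 0")
        for v in (self.n_e, self.n_t, self.n_f):
            if v is not None and v <= 0:
                raise ValueError("Hill coefficient must be > 0")
        if self.max_kill is not None and not (0 < self.max_kill <= 1):
            raise ValueError("max_kill must be in (0, 1]")


@dataclass
class SimConfig:
    """Study conditions for a simulated campaign."""

    n_compounds: int = 600
    class_probabilities: dict = field(
        default_factory=lambda: {
            "inactive": 0.60,
            "efficacious": 0.12,
            "toxic": 0.10,
            "autofluorescent": 0.08,
            "efficacious+toxic": 0.05,
            "efficacious+autofluorescent": 0.05,
        }
    )
    wt_gfp_mean: float = 1000.0
    dapi_mean: float = 1000.0  # WT/parental viability baseline
    parental_gfp_mean: float = 50.0  # reporter-negative background
    rd16_gfp_fraction: float = 0.4  # "almost 60% fewer GFP+ rods"
    rd16_viability_fraction: float = 0.5  # "as much as 50% lower viability"
    noise_cv: float = 0.10
    gradient_amplitude: float = 0.05  # fraction of channel baseline across plate
    edge_amplitude: float = 0.05  # fractional signal loss on edge rows/cols
    seed: int = 1
    preset: str = "primary-7pt"
    n_rd16_dmso: int = 32
    n_wt_dmso: int = 16
    n_parental_dmso: int = 32

    def validate(self) -> None:
        total = sum(self.class_probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"class probabilities sum to {total}, not 1")
        unknown = set(self.class_probabilities) - set(COMPOUND_CLASSES)
        if unknown:
            raise ConfigError(f"unknown compound classes: {sorted(unknown)}")
        if any(p < 0 for p in self.class_probabilities.values()):
            raise ConfigError("class probabilities must be >= 0")
        for name in ("rd16_gfp_fraction", "rd16_viability_fraction"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigError(f"{name} must be in (0, 1]")
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be >= 0")
        if self.preset not in PRESETS:
            raise ConfigError(f"unknown preset {self.preset!r}")
        if self.n_compounds < 1:
            raise ConfigError("n_compounds must be >= 1")

    @property
    def series(self) -> list[float]:
        top, factor, n_points, _ = PRESETS[self.preset]
        return dilution_series(top, factor, n_points)

    @property
    def n_replicates(self) -> int:
        return PRESETS[self.preset][3]


def _hill_frac(conc: np.ndarray, ac50: float, n: float) -> np.ndarray:
    """Unit-amplitude rising Hill curve, 0 at zero concentration."""
    return 1.0 / (1.0 + (ac50 / conc) ** n)


def draw_truth(config: SimConfig, rng: np.random.Generator) -> list[GroundTruth]:
    """Draw compound classes and their generating parameters.

    AC50s are log-uniform over the central 80% of the tested log-range so
    every active curve has its inflection inside the series; saturating
    amplitudes are large relative to assay noise, the regime a screen is
    powered for.
    """
    series = np.array(config.series)
    lo, hi = math.log10(series.min()), math.log10(series.max())
    span = hi - lo
    ac_lo, ac_hi = lo + 0.1 * span, hi - 0.1 * span
    window = config.wt_gfp_mean - config.parental_gfp_mean

    classes = list(config.class_probabilities)
    probs = np.array([config.class_probabilities[c] for c in classes])
    width = len(str(max(config.n_compounds - 1, 1)))
    out = []
    for i in range(config.n_compounds):
        cls = classes[rng.choice(len(classes), p=probs)]
        eff = "efficacious" in cls
        tox = "toxic" in cls
        fluor = "autofluorescent" in cls
        kw = {}
        if eff:
            kw.update(
                a0_e=0.0,
                ainf_e=float(rng.uniform(0.5, 1.0)),
                ac50_e=float(10 ** rng.uniform(ac_lo, ac_hi)),
                n_e=float(rng.uniform(0.8, 3.0)),
            )
        if tox:
            kw.update(
                ac50_t=float(10 ** rng.uniform(ac_lo, ac_hi)),
                n_t=float(rng.uniform(0.8, 3.0)),
                max_kill=float(rng.uniform(0.5, 1.0)),
            )
        if fluor:
            kw.update(
                ac50_f=float(10 ** rng.uniform(ac_lo, ac_hi)),
                n_f=float(rng.uniform(0.8, 3.0)),
                added_intensity=float(rng.uniform(0.3, 1.0) * window),
            )
        out.append(
            GroundTruth(
                compound_id=f"CPD{i:0{width}d}",
                compound_class=cls,
                is_efficacious=eff,
                is_toxic=tox,
                is_autofluorescent=fluor,
                **kw,
            )
        )
    return out


def truth_table(truths: Sequence[GroundTruth]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in truths])


def _expected_intensities(
    truth: GroundTruth, conc: np.ndarray, config: SimConfig, assay: AssayKind
) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless expected (gfp, dapi) for one compound's wells."""
    g_wt = config.wt_gfp_mean
    g_rd = config.rd16_gfp_fraction * g_wt
    g_par = config.parental_gfp_mean
    d_wt = config.dapi_mean
    d_rd = config.rd16_viability_fraction * d_wt

    e = (
        truth.ainf_e * _hill_frac(conc, truth.ac50_e, truth.n_e)
        if truth.is_efficacious
        else np.zeros_like(conc)
    )
    kill = (
        truth.max_kill * _hill_frac(conc, truth.ac50_t, truth.n_t)
        if truth.is_toxic
        else np.zeros_like(conc)
    )
    fluor = (
        truth.added_intensity * _hill_frac(conc, truth.ac50_f, truth.n_f)
        if truth.is_autofluorescent
        else np.zeros_like(conc)
    )
    if assay == AssayKind.DISEASE_ASSAY:
        gfp = (g_rd + e * (g_wt - g_rd)) * (1.0 - kill) + fluor
        dapi = d_rd * (1.0 - kill)
    else:  # counter-screen on parental cells
        gfp = g_par * (1.0 - kill) + fluor
        dapi = d_wt * (1.0 - kill)
    return gfp, dapi


def _baseline(config: SimConfig, cell_line: CellLine) -> tuple[float, float]:
    if cell_line == CellLine.WT:
        return config.wt_gfp_mean, config.dapi_mean
    if cell_line == CellLine.RD16:
        return (
            config.rd16_gfp_fraction * config.wt_gfp_mean,
            config.rd16_viability_fraction * config.dapi_mean,
        )
    return config.parental_gfp_mean, config.dapi_mean


def simulate_campaign(config: SimConfig) -> tuple[PlateSet, pd.DataFrame]:
    """Simulate a full campaign: disease-assay plus counter-screen plates.

    Returns the PlateSet and the ground-truth table.  Control wells are
    scattered across each plate so spatial artifacts average out of control
    statistics the way interleaved DMSO fields do on real qHTS plates.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truths = draw_truth(config, rng)
    series = np.array(config.series)
    n_points = len(series)

    rows: list[tuple] = []
    plate_info: dict[str, PlateInfo] = {}

    for assay, prefix, dmso_line, n_dmso, extra_wt in (
        (AssayKind.DISEASE_ASSAY, "D", CellLine.RD16, config.n_rd16_dmso, config.n_wt_dmso),
        (AssayKind.COUNTER_SCREEN, "C", CellLine.PARENTAL, config.n_parental_dmso, 0),
    ):
        n_controls = n_dmso + extra_wt
        capacity = (N_ROWS * N_COLS - n_controls) // n_points
        n_plates = -(-len(truths) // capacity)
        for rep in range(config.n_replicates):
            for p in range(n_plates):
                plate_id = f"{prefix}{rep}-{p:02d}"
                plate_info[plate_id] = PlateInfo(assay_kind=assay, replicate_index=rep)
                chunk = truths[p * capacity : (p + 1) * capacity]
                positions = rng.permutation(N_ROWS * N_COLS)
                pos_iter = iter(positions)
                # scattered DMSO controls
                for line, count in ((dmso_line, n_dmso), (CellLine.WT, extra_wt)):
                    g0, d0 = _baseline(config, line)
                    for _ in range(count):
                        idx = next(pos_iter)
                        rows.append(
                            (plate_id, idx // N_COLS, idx % N_COLS, line.value,
                             Treatment.DMSO.value, None, math.nan, g0, d0)
                        )
                cpd_line = (
                    CellLine.RD16 if assay == AssayKind.DISEASE_ASSAY else CellLine.PARENTAL
                )
                for truth in chunk:
                    gfp, dapi = _expected_intensities(truth, series, config, assay)
                    for j in range(n_points):
                        idx = next(pos_iter)
                        rows.append(
                            (plate_id, idx // N_COLS, idx % N_COLS, cpd_line.value,
                             Treatment.COMPOUND.value, truth.compound_id,
                             float(series[j]), float(gfp[j]), float(dapi[j]))
                        )

    df = pd.DataFrame(
        rows,
        columns=[
            "plate_id", "row", "col", "cell_line", "treatment",
            "compound_id", "concentration_molar", "gfp", "dapi",
        ],
    )

    # spatial artifacts: additive separable gradient + edge offset, then noise
    r_norm = df["row"].to_numpy() / (N_ROWS - 1) - 0.5
    c_norm = df["col"].to_numpy() / (N_COLS - 1) - 0.5
    grad = config.gradient_amplitude * (r_norm + c_norm)
    edge = (
        (df["row"].isin([0, N_ROWS - 1]) | df["col"].isin([0, N_COLS - 1]))
        .to_numpy()
        .astype(float)
        * config.edge_amplitude
    )
    gfp = df["gfp"].to_numpy() + (grad - edge) * config.wt_gfp_mean
    dapi = df["dapi"].to_numpy() + (grad - edge) * config.dapi_mean
    gfp = np.maximum(gfp, 0.0)
    dapi = np.maximum(dapi, 0.0)

    if config.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
        mu = -0.5 * sigma**2
        gfp = gfp * np.exp(rng.normal(mu, sigma, size=len(df)))
        dapi = dapi * np.exp(rng.normal(mu, sigma, size=len(df)))
    df["gfp"] = gfp
    df["dapi"] = dapi
    df["masked"] = False
    df = df[WELL_COLUMNS]

    plates = PlateSet(wells=df, plate_info=plate_info)
    plates.validate()
    return plates, truth_table(truths)


def truth_to_expected_calls(
    truth: pd.DataFrame, triage_config, config: SimConfig
) -> pd.DataFrame:
    """Analytic hit/non-hit expectations from generating parameters.

    Applies the triage logic directly to the ground truth — no simulation,
    no noise, no curve fitting — producing the reference labels for
    confusion-matrix scoring.  The oracle evaluates the *apparent* noiseless
    efficacy curve a compound produces in the disease assay, because two
    mechanisms confound the GFP readout there: autofluorescence adds
    reporter-like signal (an artifact false positive the counter-screen must
    catch), and toxicity within the tested range depresses the top of the
    curve (the data cannot support a rising curve, whatever the nominal
    AC50 ratio says).  Concretely, per compound:

    * the apparent efficacy score at each tested concentration is computed
      in closed form;
    * the curve counts as usable activity when it rises by at least the
      classification amplitude threshold and its downturn past the peak
      stays within the plateau tolerance;
    * its apparent AC50 is the log-interpolated half-rise concentration;
    * selectivity ratios against the toxicity / autofluorescence AC50s are
      then thresholded exactly like :func:`organoscreen.triage.triage_compound`.
    """
    g_wt = config.wt_gfp_mean
    g_rd = config.rd16_gfp_fraction * g_wt
    window_fluor = g_wt - config.parental_gfp_mean
    amp_thr = triage_config.amplitude_threshold
    # plateau tolerance of the curve classifier; the downturn a fit tolerates
    plateau_tol = 10.0
    series = np.sort(np.array(config.series))  # ascending

    out = []
    for t in truth.itertuples(index=False):
        tr = GroundTruth(
            compound_id=t.compound_id,
            compound_class=t.compound_class,
            is_efficacious=bool(t.is_efficacious),
            is_toxic=bool(t.is_toxic),
            is_autofluorescent=bool(t.is_autofluorescent),
            **{
                k: (None if pd.isna(getattr(t, k)) else float(getattr(t, k)))
                for k in (
                    "a0_e", "ainf_e", "ac50_e", "n_e",
                    "ac50_t", "n_t", "max_kill",
                    "ac50_f", "n_f", "added_intensity",
                )
            },
        )
        gfp, _ = _expected_intensities(tr, series, config, AssayKind.DISEASE_ASSAY)
        a_app = 100.0 * (gfp - g_rd) / (g_wt - g_rd)

        peak = float(a_app.max())
        bottom = float(a_app[0])
        top = float(a_app[-1])
        amplitude = peak - bottom
        downturn = peak - top

        if amplitude < amp_thr:
            verdict = "INACTIVE"
        elif downturn > plateau_tol:
            # toxicity wrecks the top of the curve: no well-behaved rise
            verdict = "TOXIC" if tr.is_toxic else "INACTIVE"
        elif top < triage_config.min_ainf_efficacy:
            verdict = "INACTIVE"
        else:
            # apparent AC50: log-interpolated half-rise concentration
            half = 0.5 * (bottom + top)
            ac50_app = float(series[-1])
            for i in range(len(series) - 1):
                if (a_app[i] - half) * (a_app[i + 1] - half) <= 0 and a_app[i] != a_app[i + 1]:
                    frac = (half - a_app[i]) / (a_app[i + 1] - a_app[i])
                    ac50_app = 10 ** (
                        math.log10(series[i])
                        + frac * (math.log10(series[i + 1]) - math.log10(series[i]))
                    )
                    break
            tox_active = tr.is_toxic and 100.0 * tr.max_kill >= amp_thr
            fluor_active = (
                tr.is_autofluorescent
                and 100.0 * tr.added_intensity / window_fluor >= amp_thr
            )
            ratio_tox = (tr.ac50_t / ac50_app) if tox_active else math.inf
            ratio_fluor = (tr.ac50_f / ac50_app) if fluor_active else math.inf
            if ratio_tox < triage_config.min_ratio:
                verdict = "TOXIC"
            elif ratio_fluor < triage_config.min_ratio:
                verdict = "AUTOFLUORESCENT"
            else:
                verdict = "HIT"
        out.append(
            {
                "compound_id": t.compound_id,
                "expected_verdict": verdict,
                "expected_hit": verdict == "HIT",
            }
        )
    return pd.DataFrame(out)
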