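"""End-to-end pipeline: qc -> normalize -> fit -> classify -> triage.

One declarative YAML config drives the whole funnel; every stage writes its
tabular output as CSV under the configured output directory, and a run log
records the config hash and seeds so a rerun with identical config and
inputs reproduces identical tables byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifyThresholds, classify_curve
from .errors import ConfigError
from .hill import FitBounds, HillFit, fit_hill
from .model import PlateSet, read_plate_table
from .normalize import control_stats, normalize_campaign
from .qc import mask_local_artifacts, mask_report_frame
from .triage import TriageConfig, triage_campaign

SCORE_TYPES = ("EFFICACY", "TOXICITY", "FLUORESCENCE")
_SCORE_COLUMN = {
    "EFFICACY": "efficacy",
    "TOXICITY": "toxicity",
    "FLUORESCENCE": "fluorescence",
}


@dataclass
class QCOptions:
    enabled: bool = True
    window: int = 5
    z_threshold: float = 5.0
    min_cluster: int = 3


@dataclass
class FitOptions:
    multistart: int = 5
    seed: int = 0
    baseline_selection: bool = True
    a0_bounds: tuple[float, float] = (-100.0, 200.0)
    ainf_bounds: tuple[float, float] = (-100.0, 200.0)
    n_bounds: tuple[float, float] = (1e-2, 10.0)

    def bounds(self) -> FitBounds:
        return FitBounds(
            a0=tuple(self.a0_bounds),
            ainf=tuple(self.ainf_bounds),
            n=tuple(self.n_bounds),
        )


@dataclass
class PipelineConfig:
    plate_table: str = ""
    layout: str = ""
    plate_meta: str | None = None
    outdir: str = "results"
    preset: str = "primary-7pt"
    qc: QCOptions = field(default_factory=QCOptions)
    trimmed_controls: float = 0.0
    fit: FitOptions = field(default_factory=FitOptions)
    classify: ClassifyThresholds = field(default_factory=ClassifyThresholds)
    triage: TriageConfig = field(default_factory=TriageConfig)

    def validate(self) -> None:
        if self.qc.window < 3 or self.qc.window % 2 == 0:
            raise ConfigError("qc.window must be odd and >= 3")
        if self.qc.z_threshold <= 0:
            raise ConfigError("qc.z_threshold must be > 0")
        if self.qc.min_cluster < 1:
            raise ConfigError("qc.min_cluster must be >= 1")
        if not (0 <= self.trimmed_controls < 0.5):
            raise ConfigError("trimmed_controls must be in [0, 0.5)")
        if self.fit.multistart < 1:
            raise ConfigError("fit.multistart must be >= 1")
        try:
            self.classify.validate()
            self.triage.validate()
        except ValueError as e:
            raise ConfigError(str(e)) from e

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, typ in (
            ("qc", QCOptions),
            ("fit", FitOptions),
            ("classify", ClassifyThresholds),
            ("triage", TriageConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = d[key]
                for f in dataclasses.fields(typ):
                    if f.name in sub and isinstance(sub[f.name], list):
                        sub[f.name] = tuple(sub[f.name])
                d[key] = typ(**sub)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _fit_seed(base: int, compound_id: str, score_type: str) -> int:
    h = zlib.crc32(f"{compound_id}:{score_type}".encode())
    return (base * 1_000_003 + h) % (2**31)


def fit_campaign(
    scores: pd.DataFrame,
    fit_options: FitOptions = FitOptions(),
    classify_thresholds: ClassifyThresholds = ClassifyThresholds(),
) -> list[HillFit]:
    """Fit and classify every (compound, score type) concentration series."""
    bounds = fit_options.bounds()
    fits: list[HillFit] = []
    for cid, sub in scores.groupby("compound_id", sort=True):
        for stype in SCORE_TYPES:
            col = _SCORE_COLUMN[stype]
            obs = sub[["concentration_molar", col]].dropna()
            if obs.empty:
                continue
            points = list(
                zip(obs["concentration_molar"].tolist(), obs[col].tolist())
            )
            fit = fit_hill(
                points,
                compound_id=str(cid),
                score_type=stype,
                bounds=bounds,
                multistart=fit_options.multistart,
                seed=_fit_seed(fit_options.seed, str(cid), stype),
                select_baseline=fit_options.baseline_selection,
            )
            cc = classify_curve(fit, points, classify_thresholds)
            fits.append(dataclasses.replace(fit, curve_class=cc))
    return fits


def fits_frame(fits: list[HillFit]) -> pd.DataFrame:
    rows = []
    for f in fits:
        p = f.params
        rows.append(
            {
                "compound_id": f.compound_id,
                "score_type": f.score_type,
                "a0": p.a0 if p else np.nan,
                "ainf": p.ainf if p else np.nan,
                "log_ac50": p.log_ac50 if p else np.nan,
                "n": p.n if p else np.nan,
                "sse": f.sse,
                "r2": f.r2,
                "n_points": f.n_points,
                "converged": f.converged,
                "curve_class": f.curve_class.value.value if f.curve_class else "",
                "class_reasons": ";".join(f.curve_class.reasons)
                if f.curve_class
                else "",
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig, plates: PlateSet | None = None
) -> dict:
    """Execute the full funnel and write the report bundle.

    Returns a dict with the in-memory stage outputs and the paths written.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    if plates is None:
        t0 = time.perf_counter()
        plates = read_plate_table(
            config.plate_table, config.layout, config.plate_meta
        )
        timings["read"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.qc.enabled:
        plates, reports = mask_local_artifacts(
            plates,
            window=config.qc.window,
            z_threshold=config.qc.z_threshold,
            min_cluster=config.qc.min_cluster,
        )
        mask_df = mask_report_frame(reports)
    else:
        mask_df = pd.DataFrame(columns=["plate_id", "row", "col", "reason"])
    timings["qc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats = control_stats(plates, trimmed=config.trimmed_controls)
    scores = normalize_campaign(plates, stats)
    timings["normalize"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits = fit_campaign(scores, config.fit, config.classify)
    timings["fit"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    verdicts, hits = triage_campaign(fits, config.triage)
    timings["triage"] = time.perf_counter() - t0

    fits_df = fits_frame(fits)
    stats_df = pd.DataFrame(
        [dataclasses.asdict(s) for s in stats.values()]
    ).sort_values("plate_id")

    paths = {}
    for name, df in (
        ("mask_report", mask_df),
        ("control_stats", stats_df),
        ("scores", scores),
        ("fits", fits_df),
        ("verdicts", verdicts),
        ("hits", hits),
    ):
        p = outdir / f"{name}.csv"
        # fixed 9-significant-digit serialization: full float repr would
        # expose ULP-level noise from allocation-dependent summation order
        # and break the byte-identical rerun contract
        df.to_csv(p, index=False, float_format="%.9g")
        paths[name] = p

    log = {
        "config_hash": config.config_hash(),
        "fit_seed": config.fit.seed,
        "n_plates": len(plates.plate_info),
        "n_wells": int(len(plates.wells)),
        "n_masked": int(plates.wells["masked"].sum()),
        "n_compounds": int(verdicts["compound_id"].nunique()),
        "verdict_counts": verdicts["verdict"].value_counts().to_dict(),
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))
    config.to_yaml(outdir / "config.yaml")

    return {
        "plates": plates,
        "mask_report": mask_df,
        "control_stats": stats,
        "scores": scores,
        "fits": fits,
        "verdicts": verdicts,
        "hits": hits,
        "paths": paths,
        "log": log,
        "outdir": outdir,
    }


def summarize(bundle: dict, plots: bool = False, top: int = 10) -> str:
    """Render a human-readable summary of a completed run.

    With ``plots=True`` writes one concentration-response PNG per ranked hit
    into ``<outdir>/plots``.
    """
    lines = ["organoscreen run summary", "=" * 24]
    log = bundle.get("log", {})
    lines.append(f"config hash : {log.get('config_hash', 'n/a')}")
    lines.append(f"plates      : {log.get('n_plates', 'n/a')}")
    lines.append(
        f"wells       : {log.get('n_wells', 'n/a')} "
        f"({log.get('n_masked', 0)} masked by QC)"
    )
    lines.append("")
    lines.append("verdict counts")
    counts = log.get("verdict_counts", {})
    if counts:
        for k in sorted(counts):
            lines.append(f"  {k:<16}{counts[k]}")
    else:
        lines.append("  (none)")
    lines.append("")

    hits = bundle.get("hits")
    if hits is None or len(hits) == 0:
        lines.append("no hits")
    else:
        lines.append(f"top hits (of {len(hits)})")
        lines.append(
            f"  {'rank':<5}{'compound':<12}{'Ainf%':>8}{'AC50 (uM)':>12}"
            f"{'tox ratio':>11}{'fluor ratio':>13}"
        )
        for t in hits.head(top).itertuples(index=False):
            lines.append(
                f"  {t.rank:<5}{t.compound_id:<12}{t.ainf_efficacy:>8.1f}"
                f"{t.ac50_efficacy * 1e6:>12.2f}"
                f"{t.ratio_tox:>11.1f}{t.ratio_fluor:>13.1f}"
            )

    scores = bundle.get("scores")
    fluor_assessed = scores is not None and scores["fluorescence"].notna().any()
    if not fluor_assessed:
        lines.append("")
        lines.append(
            "fluorescence: not assessed (no counter-screen data); "
            "hits are not artifact-cleared"
        )

    text = "\n".join(lines) + "\n"
    outdir = bundle.get("outdir")
    if outdir is not None:
        Path(outdir, "summary.txt").write_text(text)

    if plots and hits is not None and len(hits) and scores is not None:
        _plot_hits(bundle, top)
    return text


def _plot_hits(bundle: dict, top: int) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .hill import hill_response

    outdir = Path(bundle["outdir"], "plots")
    outdir.mkdir(exist_ok=True)
    fits_by_key = {(f.compound_id, f.score_type): f for f in bundle["fits"]}
    scores = bundle["scores"]
    for t in bundle["hits"].head(top).itertuples(index=False):
        sub = scores[scores["compound_id"] == t.compound_id]
        fig, ax = plt.subplots(figsize=(5, 4))
        colors = {"efficacy": "tab:green", "toxicity": "tab:red", "fluorescence": "tab:blue"}
        for col, color in colors.items():
            obs = sub[["concentration_molar", col]].dropna()
            if obs.empty:
                continue
            ax.semilogx(obs["concentration_molar"], obs[col], "o", ms=4, color=color, label=col)
            fit = fits_by_key.get((t.compound_id, col.upper()))
            if fit and fit.converged:
                grid = np.logspace(
                    np.log10(sub["concentration_molar"].min()),
                    np.log10(sub["concentration_molar"].max()),
                    100,
                )
                ax.semilogx(grid, hill_response(fit.params, grid), "-", color=color, lw=1)
        ax.set_xlabel("concentration (mol/L)")
        ax.set_ylabel("score (%)")
        ax.set_title(t.compound_id)
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / f"{t.compound_id}.png", dpi=100)
        plt.close(fig)
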