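"""End-to-end orchestration of the three analysis chains.

:func:`run_all` drives, from one :class:`RunConfig`:

1. data acquisition — either simulated from a scenario preset or loaded
   from spectra / leakage / E-nose CSV files;
2. exploratory PCA on checkpoint-mean spectra (boxcar + Norris gap chain);
3. PLS regression of the leaf-damage index on bag-mean spectra (SNV +
   second-derivative chain) with cross-validated metrics;
4. aquagram construction (second derivative + MSC + column normalization)
   grouped by treatment and storage day, with radar-chart rendering;
5. leakage and E-nose group statistics (ANOVA with LSD / Tukey HSD).

Every quantitative artifact is written as CSV or JSON (plots are side
artifacts), and a run manifest records the configuration hash, seed and
per-stage timings.  Re-running with the same config and seed reproduces
every numeric artifact bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import aquaphotomics, chemometrics, damage_stats, pretreatment, spectra_io
from . import synthetic_data
from .dataset import SpectralDataError


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full analysis run."""

    outdir: str
    seed: int = 0
    scenario: Optional[str] = "trial1"     # preset name, or None to load files
    spectra_path: Optional[str] = None
    leakage_path: Optional[str] = None
    enose_path: Optional[str] = None
    reference_path: Optional[str] = None   # packaging-film spectra to subtract
    pca_preset: str = "pca_prep"
    pls_preset: str = "pls_prep"
    aqua_preset: str = "aqua_prep"
    group_keys: tuple[str, ...] = ("treatment", "day")
    alpha: float = 0.05
    n_pls_components: int = 4
    wab_mode: str = "default"              # "default" | "select"
    flip_aquagram_sign: bool = False
    render_plots: bool = True

    def semantic_dict(self) -> dict:
        d = asdict(self)
        d.pop("outdir")            # where artifacts land is not semantic
        d.pop("render_plots")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)


def run_all(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk).

    Any stage error aborts with a stage-tagged message; artifacts written by
    earlier stages are retained and a failure marker records the stage.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.semantic_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "artifacts": {},
        "timings_s": {},
        "versions": _versions(),
    }
    stage = "setup"
    try:
        stage = "acquire"
        t0 = time.perf_counter()
        absorb, leakage, enose_rows = _acquire(cfg, out, manifest)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "pca"
        t0 = time.perf_counter()
        _stage_pca(cfg, absorb, out, manifest)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "pls"
        t0 = time.perf_counter()
        _stage_pls(cfg, absorb, leakage, out, manifest)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "aquagram"
        t0 = time.perf_counter()
        _stage_aquagram(cfg, absorb, out, manifest)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)

        stage = "stats"
        t0 = time.perf_counter()
        _stage_stats(cfg, leakage, enose_rows, out, manifest)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(out / "manifest.json", manifest)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    _write_json(out / "manifest.json", manifest)
    return manifest


def _versions() -> dict:
    import sklearn
    import scipy

    from . import __version__

    return {
        "aquarocket": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "scikit-learn": sklearn.__version__,
    }


def _acquire(cfg: RunConfig, out: Path, manifest: dict):
    if cfg.scenario is not None:
        sc = synthetic_data.PRESET_SCENARIOS.get(cfg.scenario)
        if sc is None:
            raise SpectralDataError(
                f"unknown scenario preset {cfg.scenario!r}; "
                f"available: {sorted(synthetic_data.PRESET_SCENARIOS)}"
            )
        sc = sc.replace(seed=cfg.seed)
        refl, truth = synthetic_data.generate_spectra(sc)
        leakage, _ = synthetic_data.generate_leakage(sc)
        enose_rows, _ = synthetic_data.generate_enose(sc)
        truth.to_json(out / "scenario_truth.json")
        manifest["artifacts"]["scenario_truth"] = "scenario_truth.json"
        absorb = spectra_io.reflectance_to_absorbance(refl)
    else:
        if cfg.spectra_path is None:
            raise SpectralDataError("no scenario and no spectra_path given")
        ds = spectra_io.read_spectra(cfg.spectra_path)
        absorb = (
            spectra_io.reflectance_to_absorbance(ds)
            if ds.mode == "reflectance"
            else ds
        )
        if cfg.reference_path:
            ref = spectra_io.read_spectra(cfg.reference_path)
            if ref.mode == "reflectance":
                ref = spectra_io.reflectance_to_absorbance(ref)
            absorb = spectra_io.subtract_reference(absorb, ref)
        leakage = (
            damage_stats.read_leakage(cfg.leakage_path) if cfg.leakage_path else None
        )
        enose_rows = (
            pd.read_csv(cfg.enose_path).to_dict("records") if cfg.enose_path else None
        )
    spectra_io.write_spectra(absorb, out / "spectra_absorbance.csv")
    manifest["artifacts"]["spectra"] = "spectra_absorbance.csv"
    if leakage is not None:
        damage_stats.leakage_frame(leakage).to_csv(out / "leakage.csv", index=False)
        manifest["artifacts"]["leakage"] = "leakage.csv"
    if enose_rows is not None:
        pd.DataFrame(enose_rows).to_csv(out / "enose.csv", index=False)
        manifest["artifacts"]["enose"] = "enose.csv"
    return absorb, leakage, enose_rows


def _stage_pca(cfg: RunConfig, absorb, out: Path, manifest: dict) -> None:
    checkpoints = spectra_io.checkpoint_means(absorb)
    prepped, _ = pretreatment.apply_pipeline(checkpoints, cfg.pca_preset)
    n_comp = min(2, prepped.n_spectra - 1)
    res = chemometrics.fit_pca(prepped, n_components=n_comp)
    res.scores_frame(prepped.samples).to_csv(out / "pca_scores.csv", index=False)
    res.loadings_frame().to_csv(out / "pca_loadings.csv", index=False)
    _write_json(
        out / "pca_metrics.json",
        {"explained_variance_pct": res.explained_variance_pct.tolist()},
    )
    manifest["artifacts"]["pca"] = [
        "pca_scores.csv", "pca_loadings.csv", "pca_metrics.json",
    ]
    if cfg.render_plots:
        _plot_pca(res, prepped, out / "pca_scores.png")
        manifest["artifacts"]["pca_plot"] = "pca_scores.png"


def _stage_pls(cfg: RunConfig, absorb, leakage, out: Path, manifest: dict) -> None:
    if leakage is None:
        raise SpectralDataError(
            "PLS stage requires leakage data: provide leakage_path or a scenario"
        )
    bag_spectra = spectra_io.bag_means(absorb)
    prepped, _ = pretreatment.apply_pipeline(bag_spectra, cfg.pls_preset)
    ild = (
        damage_stats.leakage_frame(leakage)
        .groupby(["treatment", "day", "bag"])["ild"]
        .mean()
    )
    y = np.array(
        [ild.loc[(s.treatment, s.day, s.bag)] for s in prepped.samples]
    )
    res = chemometrics.fit_pls(
        prepped, y, n_components=cfg.n_pls_components, seed=cfg.seed
    )
    _write_json(out / "pls_metrics.json", res.metrics())
    pd.DataFrame(
        {
            "treatment": [s.treatment for s in prepped.samples],
            "day": [s.day for s in prepped.samples],
            "bag": [s.bag for s in prepped.samples],
            "ild": y,
            "fitted": res.fitted,
            "cv_prediction": res.cv_predictions,
        }
    ).to_csv(out / "pls_predictions.csv", index=False)
    table = chemometrics.cross_validate(
        prepped, y, max_components=max(cfg.n_pls_components, 6), seed=cfg.seed
    )
    table.to_csv(out / "pls_component_selection.csv", index=False)
    manifest["artifacts"]["pls"] = [
        "pls_metrics.json", "pls_predictions.csv", "pls_component_selection.csv",
    ]


def _stage_aquagram(cfg: RunConfig, absorb, out: Path, manifest: dict) -> None:
    prepped, side = pretreatment.apply_pipeline(absorb, cfg.aqua_preset)
    if cfg.wab_mode == "select":
        wabs = aquaphotomics.select_wabs(prepped, group_keys=cfg.group_keys)
    else:
        wabs = aquaphotomics.default_wabs()
    aq = aquaphotomics.compute_aquagram(prepped, wabs, group_keys=cfg.group_keys)
    aq.to_frame().to_csv(out / "aquagram.csv", index=False)
    _write_json(
        out / "aquagram.json",
        {
            "group_keys": list(aq.group_keys),
            "groups": [list(g) for g in aq.groups],
            "wabs": [
                {"wavelength": w.wavelength, "wamac": w.wamac, "assignment": w.assignment}
                for w in aq.wabs
            ],
            "values": aq.values.tolist(),
        },
    )
    manifest["artifacts"]["aquagram"] = ["aquagram.csv", "aquagram.json"]
    if cfg.render_plots:
        aquaphotomics.render_aquagram(
            aq, out / "aquagram.png", flip_sign=cfg.flip_aquagram_sign
        )
        manifest["artifacts"]["aquagram_plot"] = "aquagram.png"


def _stage_stats(cfg: RunConfig, leakage, enose_rows, out: Path, manifest: dict) -> None:
    artifacts = []
    if leakage is not None:
        comparisons = damage_stats.ild_day_comparisons(
            leakage, posthoc="lsd", alpha=cfg.alpha
        )
        payload = {
            t: {
                "F": c.f_statistic,
                "p": c.p_value,
                "significant_pairs": [list(p) for p in c.significant_pairs()],
            }
            for t, c in comparisons.items()
        }
        _write_json(out / "ild_anova.json", payload)
        artifacts.append("ild_anova.json")
    if enose_rows is not None:
        df = pd.DataFrame(enose_rows)
        table = damage_stats.sensorwise_day_comparisons(df, alpha=cfg.alpha)
        table.to_csv(out / "enose_anova.csv", index=False)
        artifacts.append("enose_anova.csv")
        res, mean_table = damage_stats.enose_pca(df)
        mean_table.to_csv(out / "enose_means.csv", index=False)
        artifacts.append("enose_means.csv")
        if cfg.render_plots:
            damage_stats.render_enose_biplot(res, mean_table, out / "enose_biplot.png")
            manifest["artifacts"]["enose_plot"] = "enose_biplot.png"
    manifest["artifacts"]["stats"] = artifacts


def _plot_pca(res, ds, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    colors = {"A": "tab:blue", "B": "tab:green", "C": "tab:red"}
    for (x, y), s in zip(res.scores[:, :2], ds.samples):
        ax.scatter(x, y, color=colors.get(s.treatment, "grey"), s=18)
        ax.annotate(f"{s.treatment}{s.day}", (x, y), fontsize=7)
    ax.set_xlabel(f"PC1 ({res.explained_variance_pct[0]:.1f}%)")
    if res.scores.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({res.explained_variance_pct[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
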