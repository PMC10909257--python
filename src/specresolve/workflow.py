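"""End-to-end pipeline: simulate → preprocess → calibrate ×4 → predict → diagnose.

One :func:`run_pipeline` call produces a self-contained run directory holding
the design and spectra CSVs, the four fitted models, per-engine prediction
CSVs, a diagnostics report (recovery table, regression figures of merit,
EJCR, cross-engine t/F comparison) in JSON and Markdown, the greenness
report, and a manifest with the configuration, seeds and file hashes. All
randomness flows from the named seeds in the config, so a repeated run is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ann import ANNConfig, predict_ann, train_ann
from .diagnostics import compare_methods, ejcr, recovery_stats, regression_fom, rmse
from .factor_models import fit_pcr, fit_pls, loo_cross_validate, predict
from .greenness import (agree_score, eco_scale, load_agree_fixture,
                        proposed_method_items, reference_method_items)
from .mcr_als import MCRConfig, fit_mcr_als, predict_mcr
from .preprocessing import DEFAULT_WINDOW, select_window
from .synthetic_data import (default_pure_spectra, generate_design,
                             simulate_spectra)

__all__ = ["RunConfig", "run_pipeline", "compare_report"]

log = logging.getLogger("specresolve")

ENGINES = ("PCR", "PLS", "MCR-ALS", "ANN")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "specresolve_run"
    design_source: str = "table1"          # or "cyclic"
    noise_sd: float = 0.002
    seed: int = 1
    window: tuple[float, float] = DEFAULT_WINDOW
    engines: tuple[str, ...] = ENGINES
    n_lv: int | str = "auto"               # latent variables, or "auto" for LOO-CV
    max_lv: int = 8
    ann_hidden: int = 5
    ann_epochs: int = 100
    mcr_tol: float = 0.1
    mcr_max_iter: int = 100
    dw_permutations: int = 10_000
    reference_engine: str = "ANN"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        cfg.window = tuple(cfg.window)
        cfg.engines = tuple(cfg.engines)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["window"] = list(self.window)
        d["engines"] = list(self.engines)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _dump(payload: dict, path: Path) -> None:
    path.write_text(json.dumps(payload, indent=2, default=_json_default))


def _fit_engines(cfg: RunConfig, Xcal, Ycal, design):
    """Fit every requested engine on the windowed calibration block."""
    models = {}
    extras = {"cv": None}
    n_lv = cfg.n_lv
    if n_lv == "auto":
        cv = loo_cross_validate(Xcal.absorbance, Ycal, cfg.max_lv, kind="PLS")
        extras["cv"] = cv
        n_lv = cv.selected_lv
        log.info("stage=calibrate lv_selection=loo selected_lv=%d", n_lv)
    for engine in cfg.engines:
        if engine == "PCR":
            models[engine] = fit_pcr(Xcal.absorbance, Ycal, int(n_lv))
        elif engine == "PLS":
            models[engine] = fit_pls(Xcal.absorbance, Ycal, int(n_lv))
        elif engine == "MCR-ALS":
            mcr_cfg = MCRConfig(convergence_tol=cfg.mcr_tol, max_iter=cfg.mcr_max_iter)
            models[engine] = fit_mcr_als(Xcal.absorbance, Ycal, mcr_cfg)
        elif engine == "ANN":
            ann_cfg = ANNConfig(n_hidden=cfg.ann_hidden, max_epochs=cfg.ann_epochs,
                                seed=cfg.seed + 2)
            models[engine] = train_ann(Xcal.absorbance, Ycal, ann_cfg)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        log.info("stage=calibrate engine=%s status=fitted", engine)
    return models, extras


def _predict_engine(engine, model, X, Ycal, Xcal):
    if engine in ("PCR", "PLS"):
        return predict(model, X.absorbance)
    if engine == "ANN":
        return predict_ann(model, X.absorbance)
    if engine == "MCR-ALS":
        rows = [
            predict_mcr(model, X.absorbance[i:i + 1], Ycal, Xcal.absorbance)
            for i in range(len(X))
        ]
        return np.vstack(rows)
    raise ValueError(engine)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the whole workflow; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        design = generate_design(source=config.design_source, seed=config.seed)
        pure = default_pure_spectra()
        spectra = simulate_spectra(design, pure, noise_sd=config.noise_sd,
                                   seed=config.seed)
        design.to_csv(out / "design.csv")
        spectra.to_csv(out / "spectra.csv")
        log.info("stage=simulate n_samples=%d noise_sd=%g", len(spectra), config.noise_sd)

        stage = "preprocess"
        windowed = select_window(spectra, *config.window)
        cal_mask = design.role == "calibration"
        Xcal = windowed.subset(np.nonzero(cal_mask)[0])
        Xval = windowed.subset(np.nonzero(~cal_mask)[0])
        Ycal = design.calibration.nominal
        Yval = design.validation.nominal

        stage = "calibrate"
        models, extras = _fit_engines(config, Xcal, Ycal, design)

        stage = "predict"
        predictions = {}
        for engine, model in models.items():
            pred = _predict_engine(engine, model, Xval, Ycal, Xcal)
            predictions[engine] = pred
            df = pd.DataFrame(pred, columns=list(design.analytes))
            df.insert(0, "sample_id", design.validation.sample_ids)
            df.to_csv(out / f"predictions_{engine.lower().replace('-', '_')}.csv",
                      index=False, float_format="%.6f")
            log.info("stage=predict engine=%s n=%d", engine, pred.shape[0])

        stage = "diagnose"
        report = {"engines": {}, "n_validation": int(Yval.shape[0]),
                  "analytes": list(design.analytes)}
        if extras["cv"] is not None:
            report["cv"] = {
                "lv_counts": extras["cv"].lv_counts.tolist(),
                "mean_rmsecv": extras["cv"].mean_rmsecv.tolist(),
                "selected_lv": extras["cv"].selected_lv,
            }
        for engine, pred in predictions.items():
            cal_pred = _predict_engine(engine, models[engine], Xcal, Ycal, Xcal) \
                if engine != "MCR-ALS" else models[engine].C
            rec = recovery_stats(pred, Yval, design.analytes)
            per_analyte = {}
            for j, name in enumerate(design.analytes):
                fom = regression_fom(
                    pred[:, j], Yval[:, j],
                    calibration_errors=cal_pred[:, j] - Ycal[:, j],
                    dw_permutations=config.dw_permutations,
                    dw_seed=config.seed + 10,
                )
                per_analyte[name] = {
                    "slope": fom.slope, "intercept": fom.intercept, "r": fom.r,
                    "rmsec": fom.rmsec, "rmsep": fom.rmsep,
                    "dw": fom.dw, "dw_p": fom.dw_p,
                    "recovery_mean": float(rec.mean[j]),
                    "recovery_sd": float(rec.sd[j]),
                }
            region = ejcr(pred.ravel(), Yval.ravel())
            report["engines"][engine] = {
                "recovery": rec.recovery.tolist(),
                "per_analyte": per_analyte,
                "ejcr": {
                    "intercept": region.intercept, "slope": region.slope,
                    "s2": region.s2, "f_crit": region.f_crit,
                    "contains_ideal": bool(region.contains_ideal),
                },
            }
        report["comparison"] = _comparison_table(predictions, Yval, design.analytes,
                                                 config.reference_engine)
        _dump(report, out / "diagnostics.json")
        (out / "diagnostics.md").write_text(_markdown_report(report))
        log.info("stage=diagnose engines=%d", len(predictions))

        stage = "greenness"
        green = {
            "eco_scale": {
                "proposed": eco_scale(proposed_method_items()).to_dict(),
                "reference": eco_scale(reference_method_items()).to_dict(),
            },
            "agree": agree_score(load_agree_fixture()[0]).to_dict(),
        }
        _dump(green, out / "greenness.json")

        stage = "manifest"
        files = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "package": "specresolve",
            "version": __version__,
            "config": config.to_dict(),
            "files": {name: _sha256(out / name) for name in files},
        }
        _dump(manifest, out / "manifest.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def _comparison_table(predictions, Yval, analytes, reference_engine):
    """Cross-engine t/F of recovery sets against the reference engine."""
    if reference_engine not in predictions:
        reference_engine = next(iter(predictions))
    ref_rec = recovery_stats(predictions[reference_engine], Yval).recovery
    table = {"reference": reference_engine, "rows": {}}
    for engine, pred in predictions.items():
        rec = recovery_stats(pred, Yval).recovery
        rows = {}
        for j, name in enumerate(analytes):
            if engine == reference_engine:
                rows[name] = {"t": 0.0, "t_crit": None, "F": 1.0, "F_crit": None,
                              "t_significant": False, "f_significant": False}
                continue
            cmp = compare_methods(rec[:, j], ref_rec[:, j])
            rows[name] = {"t": cmp.t_stat, "t_crit": cmp.t_crit,
                          "F": cmp.f_stat, "F_crit": cmp.f_crit,
                          "t_significant": cmp.t_significant,
                          "f_significant": cmp.f_significant}
        table["rows"][engine] = rows
    return table


def _markdown_report(report: dict) -> str:
    lines = ["# Validation diagnostics", ""]
    analytes = report["analytes"]
    lines.append("## Recovery (%) of the validation set")
    lines.append("")
    header = "| Engine | " + " | ".join(
        f"{a} mean ± SD" for a in analytes) + " |"
    lines += [header, "|" + "---|" * (len(analytes) + 1)]
    for engine, block in report["engines"].items():
        cells = []
        for a in analytes:
            pa = block["per_analyte"][a]
            cells.append(f"{pa['recovery_mean']:.2f} ± {pa['recovery_sd']:.2f}")
        lines.append(f"| {engine} | " + " | ".join(cells) + " |")
    lines += ["", "## Regression figures of merit", ""]
    lines += ["| Engine | Analyte | Slope | Intercept | r | RMSEC | RMSEP | DW | DW p |",
              "|---|---|---|---|---|---|---|---|---|"]
    for engine, block in report["engines"].items():
        for a in analytes:
            pa = block["per_analyte"][a]
            dw = "–" if pa["dw"] is None else f"{pa['dw']:.3f}"
            dwp = "–" if pa["dw_p"] is None else f"{pa['dw_p']:.3f}"
            rmsec = "–" if pa["rmsec"] is None else f"{pa['rmsec']:.4f}"
            lines.append(
                f"| {engine} | {a} | {pa['slope']:.4f} | {pa['intercept']:.4f} | "
                f"{pa['r']:.4f} | {rmsec} | {pa['rmsep']:.4f} | {dw} | {dwp} |"
            )
    lines += ["", "## EJCR accuracy test (pooled over analytes)", ""]
    lines += ["| Engine | Intercept | Slope | contains (0, 1) |", "|---|---|---|---|"]
    for engine, block in report["engines"].items():
        e = block["ejcr"]
        lines.append(f"| {engine} | {e['intercept']:.4f} | {e['slope']:.4f} | "
                     f"{'yes' if e['contains_ideal'] else 'no'} |")
    cmp_tab = report.get("comparison")
    if cmp_tab:
        lines += ["", f"## t/F comparison vs {cmp_tab['reference']}", ""]
        lines += ["| Engine | Analyte | t | F |", "|---|---|---|---|"]
        for engine, rows in cmp_tab["rows"].items():
            for a, r in rows.items():
                lines.append(f"| {engine} | {a} | {r['t']:.3f} | {r['F']:.3f} |")
    return "\n".join(lines) + "\n"


def compare_report(run_dir) -> dict:
    """Reload a run directory's diagnostics and return the comparison block."""
    report = json.loads((Path(run_dir) / "diagnostics.json").read_text())
    summary = {"reference": report["comparison"]["reference"], "engines": {}}
    for engine, block in report["engines"].items():
        summary["engines"][engine] = {
            "recovery_mean": {a: block["per_analyte"][a]["recovery_mean"]
                              for a in report["analytes"]},
            "rmsep": {a: block["per_analyte"][a]["rmsep"] for a in report["analytes"]},
            "ejcr_contains_ideal": block["ejcr"]["contains_ideal"],
            "vs_reference": report["comparison"]["rows"][engine],
        }
    return summary
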