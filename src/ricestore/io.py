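"""Delimited-text I/O, configuration and the end-to-end pipeline.

All tabular artifacts are comma-separated UTF-8 with '.' decimals.  The
residue table schema is ``pesticide,temperature_C,rh_pct,day,conc_mgkg``.
A run writes a machine-readable manifest (seed, config echo, package
versions) so it can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .grading import build_m_index, grade_clusters, kmeans, select_k
from .pipeline import (evaluate_metrics, make_windows, persistence_baseline,
                       predict_windows, split_windows, train)
from .quatformer import Quatformer, QuatformerConfig
from .stats import (coded_levels, duncan_mrt, fit_first_order,
                    full_factorial_design, response_surface_fit)
from .synthetic import (DEFAULT_PROFILES, PesticideProfile, ResidueSeries,
                        StorageCondition, StudyDesign, generate_study_dataset,
                        noiseless, simulate_series)

__all__ = [
    "RESIDUE_COLUMNS",
    "PipelineConfig",
    "write_residue_table",
    "read_residue_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

RESIDUE_COLUMNS = ["pesticide", "temperature_C", "rh_pct", "day", "conc_mgkg"]


def write_residue_table(series_list, path) -> None:
    rows = []
    for s in series_list:
        for d, c in zip(s.days, s.conc):
            rows.append((s.pesticide, s.condition.temperature_C,
                         s.condition.rh_pct, int(d), c))
    df = pd.DataFrame(rows, columns=RESIDUE_COLUMNS)
    df.to_csv(path, index=False)


def read_residue_table(path) -> list[ResidueSeries]:
    """Read and validate a residue table, grouped into per-condition series."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in RESIDUE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for col in ("temperature_C", "rh_pct", "day", "conc_mgkg"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        nonnum = numeric.isna()
        if nonnum.any():
            row = int(np.flatnonzero(nonnum)[0]) + 2  # header is line 1
            raise ValueError(f"non-numeric value in column {col!r} at line {row}")
        df[col] = numeric
    neg = df["conc_mgkg"] < 0
    if neg.any():
        row = int(np.flatnonzero(neg)[0]) + 2
        raise ValueError(f"negative concentration at line {row}")
    out = []
    for (pest, T, H), grp in df.groupby(
            ["pesticide", "temperature_C", "rh_pct"], sort=True):
        grp = grp.sort_values("day", kind="stable")
        counts = grp["day"].value_counts()
        if (counts == 1).all():
            copies = 1
        elif (counts == 2).all() and len(counts) >= 2:
            # the reference condition belongs to both sweep arms and is
            # written once per arm; split it back into its two series
            copies = 2
        else:
            day = counts[counts > 1].index[0]
            row = int(np.flatnonzero(
                df.duplicated(subset=["pesticide", "temperature_C",
                                      "rh_pct", "day"]))[0]) + 2
            raise ValueError(
                f"duplicate (series, day) row at line {row} (day {day})")
        for copy in range(copies):
            sub = grp.groupby("day", sort=True).nth(copy)
            out.append(ResidueSeries(
                pesticide=str(pest),
                condition=StorageCondition(float(T), float(H)),
                days=sub["day"].to_numpy(dtype=int),
                conc=sub["conc_mgkg"].to_numpy(dtype=float)))
    return out


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; loadable from a YAML file."""

    out_dir: str = "results/run"
    data_path: str | None = None      # load instead of simulate when set
    seed: int = 0
    noise_sd: float | None = None     # override generator noise when set
    design: StudyDesign = field(default_factory=StudyDesign)
    model: QuatformerConfig = field(default_factory=QuatformerConfig)
    k_range: tuple[int, ...] = (3, 4, 5, 6, 7)
    restarts: int = 10
    alpha: float = 0.05
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "design" in kwargs:
            d = dict(kwargs["design"])
            if "pesticides" in d:
                d["pesticides"] = tuple(
                    PesticideProfile(**p) for p in d["pesticides"])
            for key in ("temperatures_at_ref_rh", "humidities_at_ref_T"):
                if key in d:
                    d[key] = tuple(d[key])
            kwargs["design"] = StudyDesign(**d)
        if "model" in kwargs:
            kwargs["model"] = QuatformerConfig(**kwargs["model"])
        if "k_range" in kwargs:
            kwargs["k_range"] = tuple(kwargs["k_range"])
        return cls(**kwargs)


def _manifest(cfg: PipelineConfig) -> dict:
    def plain(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [plain(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return obj

    return {
        "seed": cfg.seed,
        "config": plain(cfg),
        "versions": {
            "ricestore": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }


def _pesticide_seed(root: int, idx: int) -> int:
    return (root * 1000 + idx * 17 + 1) % (2**31 - 1)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Simulate (or load) -> train -> forecast -> grade -> kinetics/stats.

    Writes every artifact under ``cfg.out_dir`` and returns a summary dict
    with the headline numbers (forecast metrics, chosen K per pesticide,
    grade tables, half-life surface coefficients).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        if cfg.data_path:
            series_list = read_residue_table(cfg.data_path)
        else:
            design = cfg.design
            if cfg.noise_sd is not None:
                design = dataclasses.replace(design, pesticides=tuple(
                    dataclasses.replace(p, noise_sd=cfg.noise_sd)
                    for p in design.pesticides))
            series_list = generate_study_dataset(design, seed=cfg.seed)
            write_residue_table(series_list, out / "residues.csv")

        pesticides = sorted({s.pesticide for s in series_list})
        mcfg = cfg.model
        summary: dict = {"pesticides": {}, "n_records":
                         int(sum(len(s) for s in series_list))}
        all_true, all_pred, all_persist = [], [], []
        grade_rows, interval_rows, cluster_rows, halflife_rows = [], [], [], []
        duncan_lines = []

        for pi, pest in enumerate(pesticides):
            stage = f"train[{pest}]"
            p_series = [s for s in series_list if s.pesticide == pest]
            windows = make_windows(p_series, mcfg.input_len, mcfg.horizon)
            tr, va, te = split_windows(windows)
            pcfg = dataclasses.replace(
                mcfg, seed=_pesticide_seed(cfg.seed, pi))
            model, history = train(pcfg, tr, va)
            model.save(out / f"model_{pest}.json")

            stage = f"forecast[{pest}]"
            y_true = np.stack([w.target for w in te])
            y_pred = predict_windows(model, te)
            y_persist = np.stack([persistence_baseline(w) for w in te])
            all_true.append(y_true.ravel())
            all_pred.append(y_pred.ravel())
            all_persist.append(y_persist.ravel())
            rep = evaluate_metrics(y_true, y_pred)
            rep_persist = evaluate_metrics(y_true, y_persist)

            stage = f"grade[{pest}]"
            m_points = np.stack([
                build_m_index(w.inputs[-1, 0], yp, pest).as_array()
                for w, yp in zip(te, y_pred[:, 0])])
            best_k, sil_by_k = select_k(
                m_points, cfg.k_range, seed=cfg.seed, restarts=cfg.restarts)
            cres = kmeans(m_points, best_k, seed=cfg.seed,
                          restarts=cfg.restarts)
            try:
                gm = grade_clusters(cres, m_points)
                for name, interval in gm.intervals():
                    interval_rows.append((pest, interval, name))
                for gidx in range(gm.K):
                    cluster_rows.append(
                        (pest, gidx + 1, gm.centers[gidx, 0],
                         gm.centers[gidx, 1], int(gm.counts[gidx]),
                         gm.grade_names[gidx]))
                for w, yp, lab in zip(te, y_pred[:, 0], cres.labels):
                    grade_rows.append(
                        (pest, w.series_id, w.anchor_day, w.inputs[-1, 0], yp,
                         gm.grade_names[gm.cluster_to_grade[lab]]))
                grade_info = {"K": best_k, "silhouette_by_k": sil_by_k,
                              "breakpoints": gm.breakpoints.tolist(),
                              "counts": gm.counts.tolist()}
            except ValueError as exc:  # overlapping clusters on this axis
                log.warning("grading skipped for %s: %s", pest, exc)
                grade_info = {"K": best_k, "silhouette_by_k": sil_by_k,
                              "error": str(exc)}

            stage = f"stats[{pest}]"
            for s in p_series:
                fit = fit_first_order(s)
                halflife_rows.append(
                    (pest, s.condition.temperature_C, s.condition.rh_pct,
                     fit.k_hat, fit.t_half, fit.r_squared))
            groups, names = [], []
            seen = set()
            for s in p_series:
                key = (s.condition.temperature_C, s.condition.rh_pct)
                if key in seen:
                    continue
                seen.add(key)
                groups.append(s.conc)
                names.append(f"{key[0]:g}C/{key[1]:g}%")
            dres = duncan_mrt(groups, alpha=cfg.alpha)
            duncan_lines.append(f"{pest}: " + "; ".join(dres.format_rows(names)))

            # quadratic half-life surface over the 3x3 factorial (noiseless
            # series at the coded levels; half-life fitted over the first
            # week — the active dissipation phase — so the slow tail does
            # not dominate the log-linear slope)
            profile = next(p for p in DEFAULT_PROFILES if p.name == pest) \
                if any(p.name == pest for p in DEFAULT_PROFILES) else None
            surface = None
            if profile is not None:
                design_pts = full_factorial_design()
                resp = []
                for a, b in design_pts:
                    cond = StorageCondition(35.0 + 5.0 * a, 75.0 + 5.0 * b)
                    s = simulate_series(noiseless(profile), cond, 8, seed=0)
                    resp.append(fit_first_order(s).t_half)
                sfit = response_surface_fit(design_pts, resp)
                surface = {"beta": sfit.beta.tolist(),
                           "residual_sd": sfit.residual_sd}

            summary["pesticides"][pest] = {
                "metrics": rep.as_dict(),
                "persistence_metrics": rep_persist.as_dict(),
                "epochs_run": len(history.epochs),
                "grading": grade_info,
                "surface": surface,
            }

        stage = "reports"
        overall = evaluate_metrics(np.concatenate(all_true),
                                   np.concatenate(all_pred))
        overall_persist = evaluate_metrics(np.concatenate(all_true),
                                           np.concatenate(all_persist))
        summary["overall_metrics"] = overall.as_dict()
        summary["overall_persistence_metrics"] = overall_persist.as_dict()

        pd.DataFrame(grade_rows, columns=[
            "pesticide", "series", "anchor_day", "d_current", "d_predicted",
            "grade"]).to_csv(out / "sample_grades.csv", index=False)
        pd.DataFrame(interval_rows, columns=[
            "pesticide", "conc_interval_mgkg", "quality_level"]).to_csv(
            out / "grade_intervals.csv", index=False)
        pd.DataFrame(cluster_rows, columns=[
            "pesticide", "cluster", "center_d_current", "center_d_predicted",
            "sample_size", "quality_level"]).to_csv(
            out / "cluster_summary.csv", index=False)
        pd.DataFrame(halflife_rows, columns=[
            "pesticide", "temperature_C", "rh_pct", "k_per_day", "t_half_days",
            "r_squared"]).to_csv(out / "halflife.csv", index=False)
        (out / "duncan.txt").write_text("\n".join(duncan_lines) + "\n")
        (out / "metrics.json").write_text(json.dumps({
            "overall": overall.as_dict(),
            "overall_persistence": overall_persist.as_dict(),
            "per_pesticide": {p: summary["pesticides"][p]["metrics"]
                              for p in summary["pesticides"]}}, indent=2))
        manifest = _manifest(cfg)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True))
    except Exception as exc:
        # mark whatever was already written as not belonging to a complete run
        (out / "STALE").write_text(
            f"run aborted at stage {stage!r}; outputs are partial\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    stale = out / "STALE"
    if stale.exists():
        stale.unlink()
    return summary
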