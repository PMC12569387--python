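"""Configured simulate -> analyze -> report orchestration.

CSV is the interchange format at every boundary, so real trial exports
can be mapped onto the same schema by a thin adapter and fed to
``analyze`` without touching the simulator. The simulator writes a
ground-truth manifest next to its tables; the analysis stages never
read it (strict simulate/analyze firewall).
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distance as dist_mod
from . import inference, localization, psychometrics
from . import synthetic_data as synth

log = logging.getLogger("somacross")

TASK_FILES = {"2PDT": "2pdt.csv", "TMT": "tmt.csv", "TDJT": "tdjt.csv", "TLT": "tlt.csv"}


@dataclass
class RunConfig:
    """Everything a pipeline run needs, round-trippable through YAML."""

    seed: int = 0
    n_participants: int = 33
    rss_effects: dict = field(
        default_factory=lambda: dict(synth.DEFAULT_RSS_EFFECTS)
    )
    miss_rate_tlt: float = 0.002
    exclude_outliers: bool = False
    stim_duration: float = synth.RSS_DURATION_S
    emm_family: str = "postpre_by_intervention"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def cmd_simulate(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the four task tables, stimulation trains and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = synth.simulate_study(
        n_participants=config.n_participants,
        seed=config.seed,
        rss_effects=config.rss_effects,
    )
    paths: dict[str, Path] = {}
    for task, fname in TASK_FILES.items():
        table = study.tables[task]
        if task == "TLT" and config.miss_rate_tlt > 0:
            table = synth.inject_missing_and_outliers(
                table, miss_rate=config.miss_rate_tlt, seed=config.seed + 1
            )
        path = out / fname
        table.to_csv(path, index=False, float_format="%.6f")
        paths[task] = path
        log.info("wrote %s (%d trials)", path, len(table))

    trains = []
    for protocol in ("RSS", "sham"):
        train = synth.generate_stim_train(protocol, config.stim_duration, config.seed)
        trains.append(
            pd.DataFrame(
                {"protocol": protocol, "pulse_time_s": np.round(train.pulse_times, 6)}
            )
        )
    pd.concat(trains, ignore_index=True).to_csv(out / "stim_trains.csv", index=False)

    manifest = {
        "seed": config.seed,
        "design": {
            pid: order
            for pid, order in zip(
                study.design.as_frame()["participant"], study.design.order_assignment
            )
        },
        "finger_lengths": study.finger_lengths,
        "observers": {
            pid: {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(obs).items()
                if not isinstance(v, dict)
            }
            | {
                "rss_effects": obs.rss_effects,
                "localization_bias": {
                    ph: b.tolist() for ph, b in obs.localization_bias.items()
                },
            }
            for pid, obs in study.observers.items()
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    config.to_yaml(out / "config.yaml")
    return paths


def _analyze_pse_task(table: pd.DataFrame, measure: str) -> dict:
    fits = psychometrics.fit_cells(table)
    pses = psychometrics.pse_table(fits)
    out: dict = {"pse_table": pses, "n_retained": pses["participant"].nunique()}
    if out["n_retained"] < 2:
        out["error"] = "fewer than 2 fittable participants"
        return out
    spec = inference.LmmSpec(response="pse", random=("intercept", "intervention"))
    fit = inference.fit_lmm(pses, spec)
    out["wald"] = inference.wald_type2(fit)
    out["emm"] = inference.emm_contrasts(fit, inference.postpre_family(fit))
    out["slopes"] = inference.postpre_slopes(fit)
    out["random_structure"] = fit.random_structure
    wide = pses.pivot_table(index="participant", columns=["intervention", "session"],
                            values="pse")
    out["bf10"] = {
        i: inference.jzs_bf_paired(wide[(i, "post")].to_numpy(),
                                   wide[(i, "pre")].to_numpy())
        for i in ("RSS", "sham")
    }
    return out


def _analyze_tdjt(table: pd.DataFrame) -> dict:
    summary = dist_mod.summarize_distance(table)
    spec = inference.LmmSpec(
        response="mean_judged",
        fixed=("session", "intervention", "position", "true_distance"),
        random=("intercept", "session", "intervention"),
    )
    data = summary.copy()
    data["true_distance"] = data["true_distance"].map(lambda v: f"{v:g}mm")
    fit = inference.fit_lmm(data, spec)
    wide = (
        summary.groupby(["participant", "intervention", "session"], observed=True)[
            "mean_judged"
        ]
        .mean()
        .unstack(["intervention", "session"])
    )
    return {
        "summary": summary,
        "wald": inference.wald_type2(fit),
        "slopes": inference.postpre_slopes(fit),
        "bias_tests": dist_mod.distance_bias_tests(summary),
        "random_structure": fit.random_structure,
        "bf10": {
            i: inference.jzs_bf_paired(wide[(i, "post")].to_numpy(),
                                       wide[(i, "pre")].to_numpy())
            for i in ("RSS", "sham")
        },
    }


def _analyze_tlt(table: pd.DataFrame, exclude_outliers: bool) -> dict:
    clean, report = localization.filter_tlt(table)
    if exclude_outliers and report.group_outliers:
        clean = clean[~clean["group_outlier"]]
    summary = localization.localization_summary(clean)
    out: dict = {
        "filter_report": report,
        "summary": summary,
        "bias_tests": localization.axis_bias_tests(summary),
    }
    for measure, response in (("constant_error", "delta_jr"),
                              ("variable_error", "ellipse_area")):
        random = (
            ("intercept", "intervention")
            if measure == "constant_error"
            else ("intercept", "session", "intervention")
        )
        spec = inference.LmmSpec(
            response=response,
            fixed=("session", "intervention", "phalanx", "position"),
            random=random,
        )
        data = summary.dropna(subset=[response]).copy()
        data["position"] = data["position"].astype(str)
        fit = inference.fit_lmm(data, spec)
        out[measure] = {
            "wald": inference.wald_type2(fit),
            "phalanx_emm": inference.emm_contrasts(
                fit, inference.pairwise_family(fit, "phalanx")
            ),
            "slopes": inference.postpre_slopes(fit),
            "random_structure": fit.random_structure,
        }
    # circular two-way ANOVA on the constant-error direction, per location
    hk = {}
    for (phalanx, position), g in summary.dropna(subset=["theta_jr"]).groupby(
        ["phalanx", "position"], observed=True
    ):
        try:
            hk[f"{phalanx}_{position}"] = inference.harrison_kanji(
                g["theta_jr"].to_numpy(),
                g["intervention"].to_numpy(),
                g["session"].to_numpy(),
            )
        except ValueError as exc:
            log.warning("Harrison-Kanji skipped for %s/%s: %s", phalanx, position, exc)
    out["direction_hk"] = hk
    out["direction_alpha_bonf"] = 0.05 / max(len(hk), 1)
    return out


def cmd_analyze(
    config: RunConfig, in_dir: str | Path, out_dir: str | Path
) -> dict:
    """Run the full analysis chain on a directory of task CSVs.

    Missing task files degrade gracefully: the corresponding stages are
    skipped with a warning and everything else completes.
    """
    in_dir, out = Path(in_dir), Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    for task, fname in TASK_FILES.items():
        path = in_dir / fname
        if not path.exists():
            log.warning("missing %s: skipping %s analysis", path, task)
            continue
        table = pd.read_csv(path)
        _validate_schema(table, task, path)
        if task in ("2PDT", "TMT"):
            results[task] = _analyze_pse_task(table, task)
        elif task == "TDJT":
            results[task] = _analyze_tdjt(table)
        else:
            results[task] = _analyze_tlt(table, config.exclude_outliers)
    _write_report(results, out)
    return results


_REQUIRED_COLUMNS = {
    "2PDT": ["participant", "intervention", "session", "separation", "response"],
    "TMT": ["participant", "intervention", "session", "distortion", "response"],
    "TDJT": ["participant", "intervention", "session", "position",
             "true_distance", "judged_length"],
    "TLT": ["participant", "intervention", "session", "phalanx", "position",
            "real_x", "real_y", "judged_x", "judged_y", "finger_length"],
}


def _validate_schema(table: pd.DataFrame, task: str, path: Path) -> None:
    missing = [c for c in _REQUIRED_COLUMNS[task] if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} for task {task}")


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.ndarray, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, localization.FilterReport):
        return {
            "n_input": obj.n_input,
            "n_missing_removed": obj.n_missing_removed,
            "n_trial_outliers_removed": obj.n_trial_outliers_removed,
            "removal_fraction": obj.removal_fraction,
            "group_outliers": obj.group_outliers,
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    return obj


def _write_report(results: dict, out: Path) -> None:
    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(results), fh, indent=1, default=str)
    for task, res in results.items():
        for key in ("pse_table", "summary", "bias_tests", "wald", "emm", "slopes"):
            if key in res and isinstance(res[key], pd.DataFrame):
                res[key].to_csv(out / f"{task.lower()}_{key}.csv", index=False)


def cmd_report(report_dir: str | Path, out_dir: str | Path | None = None) -> list[Path]:
    """Render summary figures and a text digest from an analyze directory."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    report_dir = Path(report_dir)
    out = Path(out_dir) if out_dir else report_dir
    out.mkdir(parents=True, exist_ok=True)
    report_path = report_dir / "report.json"
    if not report_path.exists():
        raise FileNotFoundError(f"no report.json in {report_dir}; run analyze first")
    with open(report_path) as fh:
        report = json.load(fh)
    artifacts: list[Path] = []

    for task in ("2PDT", "TMT"):
        csv = report_dir / f"{task.lower()}_pse_table.csv"
        if not csv.exists():
            continue
        pses = pd.read_csv(csv)
        fig, axes = plt.subplots(1, 2, figsize=(8, 3.5), sharey=True)
        for ax, intervention in zip(axes, ("sham", "RSS")):
            sub = pses[pses["intervention"] == intervention]
            means = sub.groupby("session")["pse"].mean().reindex(["pre", "post"])
            for _, grp in sub.groupby("participant"):
                vals = grp.set_index("session")["pse"].reindex(["pre", "post"])
                ax.plot([0, 1], vals, color="0.8", lw=0.6)
            ax.plot([0, 1], means, "o-", color="crimson", lw=2)
            ax.set_xticks([0, 1], ["pre", "post"])
            ax.set_title(f"{task} {intervention}")
        axes[0].set_ylabel("PSE")
        fig.tight_layout()
        path = out / f"{task.lower()}_pse.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        artifacts.append(path)

    csv = report_dir / "tlt_summary.csv"
    if csv.exists():
        summary = pd.read_csv(csv)
        grand = summary.groupby(["phalanx", "position"], observed=True)[
            ["mean_dx", "mean_dy", "ellipse_area"]
        ].mean().reset_index()
        fig, ax = plt.subplots(figsize=(4, 6))
        theta = np.linspace(0, 2 * np.pi, 100)
        for _, row in grand.iterrows():
            y0 = {"proximal": 0, "middle": 1, "distal": 2}[row["phalanx"]] / 3 + row[
                "position"
            ] / 12
            radius = np.sqrt(row["ellipse_area"] / np.pi)
            ax.plot(row["mean_dx"] + radius * np.cos(theta),
                    y0 + row["mean_dy"] + radius * np.sin(theta), lw=1)
            ax.plot(row["mean_dx"], y0 + row["mean_dy"], "k+")
            ax.plot(0, y0, "ko", mfc="none")
        ax.set_xlabel("ulnar-radial (finger lengths)")
        ax.set_ylabel("proximo-distal (finger lengths)")
        ax.set_title("judged vs real touch locations")
        fig.tight_layout()
        path = out / "tlt_ellipses.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        artifacts.append(path)

    lines = ["# somacross run summary", ""]
    for task, res in report.items():
        lines.append(f"## {task}")
        for key in ("bf10", "random_structure", "direction_alpha_bonf"):
            if key in res:
                lines.append(f"- {key}: {res[key]}")
        if "emm" in res:
            for row in res["emm"]:
                lines.append(
                    f"- contrast {row['contrast']}: est={row['estimate']:.3f}, "
                    f"t({row['df']})={row['t']:.2f}, p={row['p']:.4f}, "
                    f"alpha_bonf={row['alpha_bonf']:.3f}, d={row['cohens_d']:.2f}"
                )
        if "slopes" in res:
            for row in res["slopes"]:
                lines.append(
                    f"- post-pre slope {row['intervention']}: "
                    f"{row['estimate']:.3f} CI ({row['ci_low']:.3f}, "
                    f"{row['ci_high']:.3f})"
                    + (" *" if row["excludes_zero"] else "")
                )
        lines.append("")
    digest = out / "summary.md"
    digest.write_text("\n".join(lines))
    artifacts.append(digest)
    return artifacts
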