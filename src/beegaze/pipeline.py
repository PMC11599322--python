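"""End-to-end orchestration: ingest -> filter -> label -> summarise -> model.

A run is driven by a single YAML config naming the track files, the arena /
calibration file, the optional wall-ceiling masks and the choices table.
Outputs are tidy CSVs (facing summaries, bouts, transitions), position /
heading histograms (NPZ + PNG), model results as JSON, and a plain-text
report mirroring the analysis narrative; every number in the report traces
to a JSON field.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arena import ArenaSpec, FlowerSpec, default_arena
from .metrics import (
    FacingSummary,
    label_session,
    preceding_category_counts,
    segment_bouts,
    spatial_heading_histograms,
    summarize_facing,
    DEFAULT_MAX_BRIDGE_FRAMES,
)
from .pose_io import (
    Calibration,
    FilterConfig,
    apply_filters,
    load_exclusion_mask,
    load_pose_tracks,
)
from .stats import (
    ChoiceRecord,
    ContingencyTable,
    compare_groups,
    facing_effect_model,
    facing_time_difference_test,
    freeman_halton_test,
    test_vs_chance,
    transition_frequency_test,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_run_config",
           "load_arena_yaml", "load_choices", "write_report"]

log = logging.getLogger("beegaze")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Source of truth for one analysis run (mirrors the run YAML)."""

    tracks_dir: Path
    arena_file: Path
    out_dir: Path
    choices_file: Path | None = None
    masks_dir: Path | None = None
    groups_file: Path | None = None  # optional bee -> group/colony table
    likelihood_threshold: float = 0.99
    min_body_axis: float = 0.05
    occupancy_radius: float = 1.0
    max_bridge_frames: int = DEFAULT_MAX_BRIDGE_FRAMES
    alpha: float = 0.05
    adjust: str = "none"
    use_random_effects: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("tracks_dir", "arena_file", "out_dir", "choices_file",
                     "masks_dir", "groups_file"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, Path(v))


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    base = Path(path).parent
    kwargs = {}
    for key, value in raw.items():
        if key.endswith(("_dir", "_file")) and value is not None:
            value = (base / value) if not Path(value).is_absolute() else Path(value)
        kwargs[key] = value
    return RunConfig(**kwargs)


def load_arena_yaml(path: str | Path) -> tuple[ArenaSpec, Calibration]:
    """Arena + calibration from the YAML dialect make_fixture_suite writes.

    Reward roles are assigned per session from the choices table's group,
    so the flowers here carry colour only.
    """
    raw = yaml.safe_load(Path(path).read_text())
    a = raw.get("arena", {})
    flowers = tuple(
        FlowerSpec(flower_id=f["flower_id"], center_x=float(f["center_x"]),
                   colour=f["colour"], rewarding=False)
        for f in a.get("flowers", [])
    )
    spec = ArenaSpec(
        arena_width=float(a.get("arena_width", 15.2)),
        arena_depth=float(a.get("arena_depth", 12.8)),
        screen_offset=float(a.get("screen_offset", 2.8)),
        flower_width=float(a.get("flower_width", 2.4)),
        flower_depth=float(a.get("flower_depth", 0.8)),
        flower_gap=float(a.get("flower_gap", 1.6)),
        flowers=flowers,
        fps=float(a.get("fps", 100.0)),
    )
    c = raw.get("calibration", {})
    calib = Calibration(px_per_cm=float(c.get("px_per_cm", 1.0)),
                        origin_x_px=float(c.get("origin_x_px", 0.0)),
                        origin_y_px=float(c.get("origin_y_px", 0.0)))
    return spec, calib


def load_choices(path: str | Path) -> list[ChoiceRecord]:
    df = pd.read_csv(path)
    return [
        ChoiceRecord(bee_id=str(r.bee_id), group=str(r.group),
                     colony_id=str(r.colony_id), n_choices=int(r.n_choices),
                     n_yellow=int(r.n_yellow),
                     first_choice=str(r.first_choice))
        for r in df.itertuples(index=False)
    ]


def _reward_arena(arena: ArenaSpec, demonstrated_colour: str) -> ArenaSpec:
    flowers = tuple(
        FlowerSpec(f.flower_id, f.center_x, f.colour,
                   rewarding=(f.colour == demonstrated_colour))
        for f in arena.flowers
    )
    return arena.with_flowers(flowers)


def _model_to_dict(res) -> dict:
    return {
        "coefficients": res.coefficients,
        "standard_errors": res.standard_errors,
        "z_values": res.z_values,
        "p_values": res.p_values,
        "loglik": res.loglik,
        "random_effect_variances": res.random_effect_variances,
        "random_effects_dropped": res.random_effects_dropped,
        "converged": res.convergence_flag,
        "n": res.n_obs,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every observation-phase and test-phase stage and write the bundle.

    Observation stages need the track files; test-phase models additionally
    need the choices file and are marked "skipped" without it.  Returns the
    results dictionary that is also serialised to ``results.json``.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    stale = out / "STALE"
    stale.write_text("run in progress; outputs incomplete\n")

    try:
        arena_base, calibration = load_arena_yaml(cfg.arena_file)
    except (OSError, yaml.YAMLError, ValueError) as exc:
        raise PipelineError("config", f"cannot read arena file: {exc}") from exc

    records: list[ChoiceRecord] = []
    if cfg.choices_file is not None and Path(cfg.choices_file).exists():
        records = load_choices(cfg.choices_file)
    group_of = {r.bee_id: r.group for r in records}
    colony_of = {r.bee_id: r.colony_id for r in records}

    filter_cfg = FilterConfig(likelihood_threshold=cfg.likelihood_threshold,
                              min_body_axis=cfg.min_body_axis)
    summaries: list[FacingSummary] = []
    bout_rows = []
    transition_rows = []
    excluded_fractions = {}
    hist_store = {}

    track_files = sorted(Path(cfg.tracks_dir).glob("*.csv")) if cfg.tracks_dir else []
    for path in track_files:
        bee_id = path.stem
        group = group_of.get(bee_id, "")
        colour = group.lower() if group.lower() in ("blue", "yellow") else "blue"
        arena = _reward_arena(arena_base, colour)
        try:
            tracks = load_pose_tracks(path, calibration, fps=arena.fps)
        except Exception as exc:
            raise PipelineError("ingest", f"{path.name}: {exc}") from exc
        if "observer" not in tracks:
            raise PipelineError("ingest", f"{path.name}: no observer track")
        observer_track = tracks["observer"]
        if cfg.masks_dir is not None:
            mask_path = Path(cfg.masks_dir) / f"{bee_id}.csv"
            if mask_path.exists():
                observer_track.excluded_flag |= load_exclusion_mask(
                    mask_path, observer_track.n_frames)
        observer = apply_filters(observer_track, filter_cfg)
        demonstrator = (apply_filters(tracks["demonstrator"], filter_cfg)
                        if "demonstrator" in tracks else None)
        excluded_fractions[bee_id] = 1.0 - observer.valid_fraction
        log.info("bee %s: %.1f%% of frames excluded", bee_id,
                 100 * excluded_fractions[bee_id])

        labels = label_session(observer, demonstrator, arena,
                               occupancy_radius=cfg.occupancy_radius)
        summary = summarize_facing(labels, arena.fps, bee_id=bee_id,
                                   group=group, colony_id=colony_of.get(bee_id, ""))
        summaries.append(summary)
        bouts = segment_bouts(labels, cfg.max_bridge_frames)
        for b in bouts:
            bout_rows.append({"bee_id": bee_id, "label": b.label.name,
                              "start_frame": b.start_frame,
                              "end_frame": b.end_frame})
        tc = preceding_category_counts(bouts, bee_id=bee_id)
        transition_rows.append({
            "bee_id": bee_id, "group": group,
            "colony_id": colony_of.get(bee_id, ""),
            "n_preceded_by_nonreward": tc.n_preceded_by_nonreward,
            "n_preceded_by_occ_reward": tc.n_preceded_by_occ_reward,
            "n_preceded_by_other": tc.n_preceded_by_other,
        })
        pos_hist, head_hist, edges = spatial_heading_histograms(observer, arena)
        hist_store[f"{bee_id}_position"] = pos_hist
        hist_store[f"{bee_id}_heading"] = head_hist

    summary_df = pd.DataFrame([
        {"bee_id": s.bee_id, "group": s.group, "colony_id": s.colony_id,
         "t_occ_reward": s.t_occ_reward, "t_unocc_reward": s.t_unocc_reward,
         "t_occ_nonreward": s.t_occ_nonreward,
         "t_unocc_nonreward": s.t_unocc_nonreward,
         "t_no_flower": s.t_no_flower, "t_invalid": s.t_invalid,
         "session_duration": s.session_duration}
        for s in summaries
    ])
    summary_df.to_csv(out / "facing_summaries.csv", index=False)
    pd.DataFrame(bout_rows).to_csv(out / "bouts.csv", index=False)
    transitions_df = pd.DataFrame(transition_rows)
    transitions_df.to_csv(out / "transitions.csv", index=False)
    if hist_store:
        np.savez(out / "histograms.npz", **hist_store)
        _plot_histograms(out, hist_store)

    results: dict = {
        "meta": {
            "beegaze_version": __version__,
            "python": platform.python_version(),
            "seed": cfg.seed,
            "n_sessions": len(summaries),
            "excluded_frame_fractions": excluded_fractions,
        },
        "models": {},
    }

    # --- test-phase models ---------------------------------------------
    if not records:
        results["models"]["test_phase"] = "skipped"
    else:
        by_group: dict[str, list[ChoiceRecord]] = {}
        for r in records:
            by_group.setdefault(r.group, []).append(r)
        vs_chance = {}
        for group, recs in sorted(by_group.items()):
            if len([r for r in recs if r.n_choices > 0]) >= 2:
                vs_chance[group] = _model_to_dict(test_vs_chance(
                    recs, use_random_effects=cfg.use_random_effects))
        results["models"]["vs_chance"] = vs_chance
        if len(by_group) >= 2:
            lrt, contrasts = compare_groups(
                records, adjust=cfg.adjust,
                use_random_effects=cfg.use_random_effects)
            results["models"]["group_comparison"] = {
                "lrt": {"statistic": lrt.statistic, "df": lrt.df,
                        "p_value": lrt.p_value},
                "contrasts": contrasts.to_dict(orient="records"),
            }
        counted = [r for r in records if r.n_choices > 0]
        first_levels = sorted({r.first_choice for r in counted})
        groups_lv = sorted({r.group for r in counted})
        if len(groups_lv) >= 2 and len(first_levels) >= 2:
            table = np.array([
                [sum(1 for r in counted
                     if r.group == g and r.first_choice == f)
                 for f in first_levels]
                for g in groups_lv
            ])
            results["models"]["first_choice"] = {
                "rows": groups_lv, "cols": first_levels,
                "counts": table.tolist(),
                "freeman_halton_p": freeman_halton_test(
                    ContingencyTable(tuple(groups_lv), tuple(first_levels),
                                     table)),
            }

    # --- observation-phase models --------------------------------------
    # without a choices table there are no group labels; pool all sessions
    obs_summaries = ([s for s in summaries if s.group in ("Blue", "Yellow")]
                     or summaries)
    if len(obs_summaries) >= 2:
        results["models"]["facing_time_difference"] = _model_to_dict(
            facing_time_difference_test(
                obs_summaries, use_random_effects=cfg.use_random_effects))
    if records and obs_summaries:
        effects = {}
        for group in ("Blue", "Yellow"):
            rows = [s for s in obs_summaries if s.group == group]
            try:
                model, ame = facing_effect_model(
                    rows, records, group,
                    use_random_effects=cfg.use_random_effects,
                    alpha=cfg.alpha)
            except ValueError:
                continue
            effects[group] = {"model": _model_to_dict(model),
                              "ame": ame.to_dict(orient="records")}
        if effects:
            results["models"]["facing_effects"] = effects
    if len(transition_rows) >= 2:
        from .metrics import TransitionCounts

        trans = {}
        t_groups = sorted({t["group"] for t in transition_rows if t["group"]}
                          or {""})
        for group in t_groups:
            tcs = [TransitionCounts(t["bee_id"], t["n_preceded_by_nonreward"],
                                    t["n_preceded_by_occ_reward"],
                                    t["n_preceded_by_other"])
                   for t in transition_rows
                   if not group or t["group"] == group]
            try:
                trans[group or "all"] = _model_to_dict(
                    transition_frequency_test(tcs))
            except ValueError:
                continue
        if trans:
            results["models"]["transition_frequency"] = trans

    (out / "results.json").write_text(json.dumps(results, indent=1,
                                                 sort_keys=True, default=float))
    write_report(results, out / "report.txt")
    stale.unlink()
    return results


def _plot_histograms(out: Path, hist_store: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pos = [v for k, v in hist_store.items() if k.endswith("_position")]
    head = [v for k, v in hist_store.items() if k.endswith("_heading")]
    if not pos:
        return
    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].imshow(np.mean(pos, axis=0).T, origin="lower", aspect="auto",
                   cmap="viridis")
    axes[0].set_title("mean chamber occupancy")
    axes[0].set_xlabel("x bin")
    axes[0].set_ylabel("y bin (screen at bottom)")
    mean_head = np.mean(head, axis=0)
    centers = np.linspace(-np.pi, np.pi, len(mean_head), endpoint=False)
    axes[1].bar(centers, mean_head, width=2 * np.pi / len(mean_head))
    axes[1].set_title("mean heading distribution")
    axes[1].set_xlabel("heading (rad)")
    fig.tight_layout()
    fig.savefig(out / "histograms.png", dpi=120)
    plt.close(fig)


def _fmt_model(name: str, d: dict) -> list[str]:
    lines = [f"{name}:"]
    for coef, est in d["coefficients"].items():
        lines.append(
            f"  {coef}: estimate={est:+.4f}  SE={d['standard_errors'][coef]:.4f}"
            f"  Z={d['z_values'][coef]:+.3f}  p={d['p_values'][coef]:.4g}")
    if d.get("random_effects_dropped"):
        lines.append("  (random intercept at boundary; fixed-effects fit)")
    return lines


def write_report(results: dict, path: str | Path) -> None:
    """Render the human-readable report from the results dictionary only."""
    lines = [
        "beegaze analysis report",
        f"version {results['meta']['beegaze_version']}, "
        f"seed {results['meta']['seed']}, "
        f"{results['meta']['n_sessions']} observation sessions",
        "",
    ]
    excl = results["meta"]["excluded_frame_fractions"]
    if excl:
        mean_excl = float(np.mean(list(excl.values())))
        lines.append(f"Mean excluded-frame fraction: {mean_excl:.1%}")
        lines.append("")
    models = results.get("models", {})
    if models.get("test_phase") == "skipped":
        lines.append("Test-phase models: skipped (no choices file).")
    if "vs_chance" in models:
        lines.append("Choice proportion vs chance (logit scale, 0 = 50:50):")
        for group, d in models["vs_chance"].items():
            lines.extend("  " + s for s in _fmt_model(group, d))
    if "group_comparison" in models:
        gc = models["group_comparison"]
        lines.append(
            f"Group effect LRT: chi2={gc['lrt']['statistic']:.3f} "
            f"(df={gc['lrt']['df']}), p={gc['lrt']['p_value']:.4g}")
        for c in gc["contrasts"]:
            lines.append(f"  {c['contrast']}: Z={c['z']:+.3f}, "
                         f"p={c['p_value']:.4g}")
    if "first_choice" in models:
        fc = models["first_choice"]
        lines.append(f"First choice (Freeman-Halton exact): "
                     f"p={fc['freeman_halton_p']:.4g}")
    if "facing_time_difference" in models:
        lines.append("Facing-time difference (rewarding - non-rewarding, s):")
        lines.extend("  " + s for s in _fmt_model(
            "difference", models["facing_time_difference"]))
    if "facing_effects" in models:
        for group, d in models["facing_effects"].items():
            lines.append(f"Facing-time effects on choice, {group} group:")
            for row in d["ame"]:
                lines.append(
                    f"  {row['predictor']}: beta={row['coefficient']:+.4f}/s, "
                    f"AME={row['ame_pct_per_s']:+.2f} pct-pts/s, "
                    f"LRT p={row['p_lrt']:.4g}"
                    f"{' (retained)' if row['retained'] else ''}")
    if "transition_frequency" in models:
        lines.append("Predecessors of unoccupied-rewarding facing "
                     "(nonreward share vs 0.5):")
        for group, d in models["transition_frequency"].items():
            lines.extend("  " + s for s in _fmt_model(group, d))
    Path(path).write_text("\n".join(lines) + "\n")
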