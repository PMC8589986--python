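"""End-to-end orchestration: simulate -> detect -> extract -> events ->
statistics -> classifiers.

Two routes produce the click-level feature table:

* :func:`detection_run` renders each event's active region into noisy
  samples and runs the energy detector before extraction (the full
  waveform route; silent stretches of the timeline are never
  materialised).
* :func:`snippet_run` skips the detector scan and extracts features from
  per-click noisy snippets directly (fast route for classifier studies,
  where detection recall is not the quantity under test).
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .banter import BanterConfig, encounter_similarity, fit_banter
from .detect import DetectorConfig, assign_detector_code, detect_clicks
from .events import build_event_table
from .features import FEATURE_COLUMNS, compute_click_features
from .forest import ForestConfig, fit_balanced_forest
from .simulate import (
    SimConfig,
    SyntheticDataset,
    default_templates,
    generate_dataset,
    render_click_snippet,
    render_event_region,
)
from .stats import group_dispersion, pca_broken_stick, permanova, permdisp, zscore_and_distance

__all__ = ["detection_run", "snippet_run", "click_table_to_events", "run_pipeline"]

META_COLUMNS = ("time_s", "detector_code", "event_id", "species", "encounter", "snr_db")


def _finalize_click_table(rows: list[dict]) -> pd.DataFrame:
    cols = list(FEATURE_COLUMNS) + list(META_COLUMNS)
    return pd.DataFrame(rows, columns=cols)


def detection_run(
    dataset: SyntheticDataset,
    detector_config: DetectorConfig = DetectorConfig(),
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Full waveform route: render, detect, extract, label.

    Detections are labelled with the event whose window contains them;
    each event region is rendered and scanned independently.
    """
    if rng is None:
        rng = np.random.default_rng(dataset.config.seed)
    if noise_sd is None:
        noise_sd = dataset.config.noise_sd
    fs = dataset.sample_rate
    rows: list[dict] = []
    for ev in dataset.events:
        t0, block = render_event_region(dataset, ev, noise_sd, rng)
        detections = detect_clicks(block, detector_config, fs, time_offset_s=t0)
        prev_time = None
        for det in detections:
            if not (ev.window_start_s <= det.time_s < ev.window_start_s + ev.window_length_s):
                continue
            try:
                feats = compute_click_features(
                    det.snippet, fs, click_time_s=det.time_s, previous_click_time_s=prev_time
                )
            except ValueError:
                continue
            prev_time = det.time_s
            feats.update(
                time_s=det.time_s,
                detector_code=assign_detector_code(feats["peak"]),
                event_id=ev.event_id,
                species=ev.species,
                encounter=ev.encounter_id,
                snr_db=det.snr_db,
            )
            rows.append(feats)
    return _finalize_click_table(rows)


def snippet_run(
    dataset: SyntheticDataset,
    noise_sd: float | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Fast route: per-click noisy snippets, no detector scan."""
    if rng is None:
        rng = np.random.default_rng(dataset.config.seed)
    if noise_sd is None:
        noise_sd = dataset.config.noise_sd
    fs = dataset.sample_rate
    rows: list[dict] = []
    for ev in dataset.events:
        prev_time = None
        for c in ev.clicks:
            snippet = render_click_snippet(c, noise_sd, rng, fs)
            feats = compute_click_features(
                snippet, fs, click_time_s=c.time_s, previous_click_time_s=prev_time
            )
            prev_time = c.time_s
            feats.update(
                time_s=c.time_s,
                detector_code=assign_detector_code(feats["peak"]),
                event_id=ev.event_id,
                species=ev.species,
                encounter=ev.encounter_id,
                snr_db=c.snr_db,
            )
            rows.append(feats)
    return _finalize_click_table(rows)


def click_table_to_events(click_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate clicks to the events x 20-parameter table."""
    return build_event_table(click_table)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(
    config: dict,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the configured stages and return (and optionally write) a
    machine-readable summary.

    ``config`` keys (all optional): ``seed``, ``sim`` (SimConfig field
    overrides), ``route`` ('snippet' | 'detect'), ``stages`` (subset of
    {'stats', 'rf', 'banter', 'encounters'}), ``rf`` (mtry/sampsize/
    ntree), ``banter`` (stage sizes/ntrees), ``encounters``
    (pair_ntree).  All randomness derives from ``seed``.
    """
    seed = int(config.get("seed", 0))
    stages = set(config.get("stages", {"stats", "rf", "banter", "encounters"}))
    sim_over = dict(config.get("sim", {}))
    sim_config = SimConfig(**sim_over, seed=seed) if "seed" not in sim_over else SimConfig(**sim_over)
    templates = default_templates(sim_config.sample_rate)
    rng = np.random.default_rng(seed)
    dataset = generate_dataset(sim_config, templates, rng)
    route = config.get("route", "snippet")
    if route == "detect":
        click_table = detection_run(dataset, rng=rng)
    else:
        click_table = snippet_run(dataset, rng=rng)
    event_table = click_table_to_events(click_table)
    summary: dict = {
        "provenance": {
            "package_version": __version__,
            "seed": seed,
            "config_hash": _config_hash(config),
            "route": route,
        },
        "n_clicks": int(len(click_table)),
        "n_events": int(len(event_table)),
        "events_per_species": event_table["species"].value_counts().to_dict(),
        "encounters_per_species": event_table.groupby("species")["encounter"].nunique().to_dict(),
    }
    if "stats" in stages:
        dist = zscore_and_distance(event_table)
        labels = event_table["species"].to_numpy()
        pm = permanova(dist, labels, rng=np.random.default_rng(seed + 1))
        pdp = permdisp(dist, labels, rng=np.random.default_rng(seed + 2))
        pca = pca_broken_stick(event_table)
        summary["stats"] = {
            "permanova": {"F": pm.statistic, "p": pm.p_value, "df": [pm.df_between, pm.df_within]},
            "permdisp": {"F": pdp.statistic, "p": pdp.p_value, "df": [pdp.df_between, pdp.df_within]},
            "dispersion": group_dispersion(dist, labels),
            "pca": {
                "proportions": pca.proportions[:5].tolist(),
                "broken_stick": pca.broken_stick[:5].tolist(),
                "n_significant": int(pca.significant.sum()),
            },
        }
    if "rf" in stages:
        rf_over = dict(config.get("rf", {}))
        rf_cfg = ForestConfig(
            mtry=rf_over.get("mtry"),
            sampsize=rf_over.get("sampsize"),
            ntree=int(rf_over.get("ntree", 10_000)),
            seed=seed + 3,
        )
        _, rf_summary, importance, trace = fit_balanced_forest(event_table, rf_cfg)
        summary["rf"] = rf_summary.to_dict()
        summary["rf"]["top_features"] = importance["feature"].head(5).tolist()
        summary["rf"]["final_oob_error"] = float(trace["oob_error"].iloc[-1])
    banter_model = None
    if "banter" in stages or "encounters" in stages:
        b_over = dict(config.get("banter", {}))
        b_cfg = BanterConfig(
            stage1_sampsize=int(b_over.get("stage1_sampsize", 50)),
            stage1_ntree=int(b_over.get("stage1_ntree", 20_000)),
            stage2_sampsize=int(b_over.get("stage2_sampsize", 9)),
            stage2_ntree=int(b_over.get("stage2_ntree", 20_000)),
            seed=seed + 4,
        )
    if "banter" in stages:
        banter_model = fit_banter(click_table, b_cfg)
        summary["banter"] = {
            "retained_detectors": banter_model.retained_detectors,
            "event": banter_model.stage2_summary.to_dict(),
            "call": {str(d): m.summary.to_dict() for d, m in banter_model.stage1.items()},
        }
    if "encounters" in stages:
        enc_over = dict(config.get("encounters", {}))
        sim_table = encounter_similarity(
            click_table, b_cfg, pair_ntree=int(enc_over.get("pair_ntree", 10_000))
        )
        summary["encounters"] = {
            "n_pairs": int(len(sim_table)),
            "n_similar": int(sim_table["similar"].sum()),
            "pairs": sim_table.to_dict(orient="records"),
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        click_table.to_csv(out / "clicks.csv", index=False)
        event_table.to_csv(out / "events.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=float)
    return summary
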