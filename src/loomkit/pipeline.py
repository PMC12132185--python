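"""End-to-end orchestration: simulate -> extract -> classify -> rhythm -> stats.

A run is configured by a single YAML file, schema-checked against the keys
documented in :data:`CONFIG_SCHEMA`.  Every stage writes tidy CSVs with a
fixed float precision (9 significant digits) so a rerun from the same
config and seed reproduces the stage outputs bit-for-bit.  A JSON run
manifest records the config hash, the seed, the package version and a
SHA-256 inventory of the outputs; its wall-clock timestamp is the one
field that differs between otherwise identical runs.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .arena import ArenaConfig, ZoneSet, write_session
from .classify import classify_trial, cohort_summary
from .events import detect_bouts, extract_trial_features
from .kinematics import speed_from_positions
from .rhythm import (
    bout_matrix,
    detrend_linear,
    mean_spectrum,
    peak_frequency,
    power_spectrum,
    stimulus_indicator,
    xcorr_bouts_vs_onsets,
    xcorr_speed_vs_sine,
)
from .simulate import DEFAULT_MIX, CohortConfig, simulate_cohort
from .stats import fit_linear_model, permutation_test

__all__ = ["run_pipeline", "load_config", "CONFIG_SCHEMA", "PipelineError"]

FLOAT_FORMAT = "%.9g"

CONFIG_SCHEMA: dict = {
    "seed": int,
    "cohort": {
        "n_per_condition": int,
        "species": list,
        "lights": list,
        "rate_hz": (int, float),
        "pre_stimulus_s": (int, float),
        "post_stimulus_s": (int, float),
    },
    "mix": dict,
    "stimulus": {"kind": str},
    "stats": {"formula": str, "n_permutations": int},
    "rhythm": {"band_hz": list},
    "write_sessions": bool,
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_per_condition": 5,
        "species": ["Mm", "Pp"],
        "lights": ["dim", "bright"],
        "rate_hz": 30.0,
        "pre_stimulus_s": 10.0,
        "post_stimulus_s": 2.0,
    },
    "mix": dict(DEFAULT_MIX),
    "stimulus": {"kind": "black_loom"},
    "stats": {"formula": "pre_stim_median_speed ~ light + species", "n_permutations": 2000},
    "rhythm": {"band_hz": [0.2, 5.0]},
    "write_sessions": False,
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


def _check_schema(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise PipelineError(f"config: unknown key {where!r}")
        want = schema[key]
        if isinstance(want, dict):
            if not isinstance(val, dict):
                raise PipelineError(f"config: {where!r} must be a mapping")
            _check_schema(val, want, where)
        elif not isinstance(val, want):
            raise PipelineError(f"config: {where!r} has wrong type {type(val).__name__}")


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge a YAML config (and overrides) over the defaults, schema-checked."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for extra in (None if path is None else yaml.safe_load(Path(path).read_text()), overrides):
        if extra:
            _check_schema(extra, CONFIG_SCHEMA)
            _merge(cfg, extra)
    _check_schema(cfg, CONFIG_SCHEMA)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _merge(base[k], v)
        else:
            base[k] = v


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)


def run_pipeline(config: dict | str | Path, out_dir, stages: tuple[str, ...] | None = None) -> Path:
    """Run the full pipeline, returning the output directory.

    Stage outputs: ``sessions/`` (optional), ``features.csv``,
    ``labels.csv``, ``label_summary.csv``, ``spectra.csv``, ``xcorr.csv``,
    ``stats.csv`` and ``manifest.json``.
    """
    cfg = config if isinstance(config, dict) else load_config(config)
    _check_schema(cfg, CONFIG_SCHEMA)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    all_stages = ("simulate", "extract", "classify", "rhythm", "stats")
    if stages is None:
        last = len(all_stages) - 1
    else:
        unknown = set(stages) - set(all_stages)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        last = max(all_stages.index(s) for s in stages)

    # stages form a chain; run every prerequisite up to the latest requested
    state: dict = {}
    for stage in all_stages[: last + 1]:
        try:
            _STAGES[stage](cfg, out, state)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - reported with the stage name
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": cfg["seed"],
        "loomkit_version": __version__,
        "outputs": {str(p.relative_to(out)): _sha256(p) for p in files},
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _stage_simulate(cfg: dict, out: Path, state: dict) -> None:
    c = cfg["cohort"]
    cohort_cfg = CohortConfig(
        n_per_condition=c["n_per_condition"],
        species=tuple(c["species"]),
        lights=tuple(c["lights"]),
        rate_hz=float(c["rate_hz"]),
        pre_stimulus_s=float(c["pre_stimulus_s"]),
        post_stimulus_s=float(c["post_stimulus_s"]),
        seed=cfg["seed"],
    )
    trials, truth = simulate_cohort(
        cohort_cfg, mix=cfg["mix"], schedule_kind=cfg["stimulus"]["kind"]
    )
    state["trials"] = trials
    state["truth"] = truth
    _write_csv(truth, out / "ground_truth.csv")
    if cfg["write_sessions"]:
        sess_dir = out / "sessions"
        sess_dir.mkdir(exist_ok=True)
        for i, trial in enumerate(trials):
            write_session(trial.recording, sess_dir / f"session_{i:04d}.csv")


def _stage_extract(cfg: dict, out: Path, state: dict) -> None:
    zones = ZoneSet.from_arena(ArenaConfig())
    rows = []
    traces, bouts_all = [], []
    for i, trial in enumerate(state["trials"]):
        trace = speed_from_positions(trial.recording)
        bouts = detect_bouts(trace)
        feats = extract_trial_features(
            trial.recording, trace, trial.schedule, zones, bouts=bouts
        )
        traces.append(trace)
        bouts_all.append(bouts)
        row = {"trial": i, **feats.to_row()}
        rows.append(row)
    state["traces"] = traces
    state["bouts"] = bouts_all
    state["features"] = pd.DataFrame(rows)
    merged = state["truth"].merge(state["features"], on="trial")
    state["table"] = merged
    _write_csv(state["features"], out / "features.csv")


def _stage_classify(cfg: dict, out: Path, state: dict) -> None:
    from .events import TrialFeatures

    zones = ZoneSet.from_arena(ArenaConfig())
    labels = []
    feats_df = state["features"].set_index("trial")
    for i, trial in enumerate(state["trials"]):
        feats = TrialFeatures(**{
            k: (None if pd.isna(v) else v)
            for k, v in feats_df.loc[i].items()
        })
        label = classify_trial(
            feats, state["bouts"][i], trial.recording, zones, trial.schedule,
            state["traces"][i],
        )
        labels.append(
            {
                "trial": i,
                "species": trial.recording.species_tag,
                "light": trial.recording.light_condition,
                "stimulus": trial.schedule.kind,
                "label": label.value,
                "confidence": label.confidence,
                "rules": " | ".join(label.rules),
            }
        )
    df = pd.DataFrame(labels)
    state["labels"] = df
    _write_csv(df, out / "labels.csv")
    _write_csv(cohort_summary(df), out / "label_summary.csv")


def _stage_rhythm(cfg: dict, out: Path, state: dict) -> None:
    band = tuple(cfg["rhythm"]["band_hz"])
    spectra_by_label: dict[str, list] = {}
    xcorr_rows = []
    for i, trial in enumerate(state["trials"]):
        sched = trial.schedule
        trace = state["traces"][i]
        vals = trace.window_values(sched.onset_s, sched.onset_s + sched.n_reps * sched.cycle_s)
        if len(vals) < 4:
            continue
        spec = power_spectrum(detrend_linear(vals), trace.rate_hz, source=f"trial_{i}")
        label = state["labels"].loc[state["labels"]["trial"] == i, "label"].iloc[0]
        spectra_by_label.setdefault(label, []).append(spec)
    spec_rows = []
    for label, specs in sorted(spectra_by_label.items()):
        L = min(s.L for s in specs)
        specs = [s for s in specs if s.L == L]
        ms = mean_spectrum(specs)
        for f, p in zip(ms.freqs_hz, ms.power):
            spec_rows.append({"label": label, "freq_hz": f, "power": p})
        xcorr_rows.append(
            {"label": label, "peak_freq_hz": peak_frequency(ms, band), "n_trials": len(specs)}
        )
    _write_csv(pd.DataFrame(spec_rows), out / "spectra.csv")
    _write_csv(pd.DataFrame(xcorr_rows), out / "spectral_peaks.csv")

    # bout-train vs onset-train cross-correlation per label
    trial0 = state["trials"][0]
    ind = stimulus_indicator(trial0.schedule, state["traces"][0].rate_hz)
    rows = []
    for label in sorted(state["labels"]["label"].unique()):
        ids = state["labels"].loc[state["labels"]["label"] == label, "trial"]
        mats = bout_matrix([state["bouts"][i] for i in ids], ind)
        lags, r = xcorr_bouts_vs_onsets(mats, ind)
        keep = np.abs(lags) <= 10.0
        for lag, v in zip(lags[keep], r[keep]):
            rows.append({"label": label, "lag_s": lag, "r": v})
    _write_csv(pd.DataFrame(rows), out / "xcorr.csv")


def _stage_stats(cfg: dict, out: Path, state: dict) -> None:
    table = state["table"].merge(state["labels"][["trial", "label"]], on="trial")
    rows = []
    model = fit_linear_model(table, cfg["stats"]["formula"])
    for term, p in model.term_pvalues.items():
        rows.append({"analysis": "linear_model", "term": term, "value": p, "detail": model.formula})
    lights = sorted(table["light"].unique())
    if len(lights) == 2:
        a = table.loc[table["light"] == lights[0], "pre_stim_median_speed"].dropna().to_numpy()
        b = table.loc[table["light"] == lights[1], "pre_stim_median_speed"].dropna().to_numpy()
        if len(a) >= 2 and len(b) >= 2:
            res = permutation_test(
                a, b, n_perm=cfg["stats"]["n_permutations"], seed=cfg["seed"]
            )
            rows.append(
                {
                    "analysis": "permutation_prestim_speed",
                    "term": f"{lights[0]}-{lights[1]}",
                    "value": res.observed_effect,
                    "detail": f"p={res.p_value:.6g}",
                }
            )
    _write_csv(pd.DataFrame(rows), out / "stats.csv")


_STAGES = {
    "simulate": _stage_simulate,
    "extract": _stage_extract,
    "classify": _stage_classify,
    "rhythm": _stage_rhythm,
    "stats": _stage_stats,
}
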