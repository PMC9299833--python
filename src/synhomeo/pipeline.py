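"""Workflow orchestration: simulate -> detect -> quantify -> test.

A run is described by a JSON (or YAML) config with a global seed, an output
directory and a list of stages, each with its own parameter block. Stage
seeds are derived from the global seed by a stable hash so adding a stage
does not shift the random streams of the others. Every run writes a
manifest of its outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as shio
from . import minidetect, proximics, quantal, screenstats, synthgen

__all__ = ["stage_seed", "load_config", "run_pipeline"]

KNOWN_STAGES = ("simulate", "detect", "quantal", "screen", "nnd", "morpho")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31)


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def _validate(config: dict) -> None:
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ValueError("config error at 'stages': a list of stage names is required")
    for s in config["stages"]:
        if s not in KNOWN_STAGES:
            raise ValueError(f"config error at 'stages': unknown stage '{s}'")


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"dependency error: missing input file {path}")
    return path


def _stage_simulate(block: dict, out: Path, seed: int) -> list[str]:
    outputs = []
    if "minis" in block:
        p = synthgen.MiniSimParams(**{**block["minis"], "seed": block["minis"].get("seed", seed)})
        trace, truth = synthgen.simulate_minis(p)
        shio.write_trace(out / "trace.csv", trace, params=asdict(p))
        pd.DataFrame({"time_s": truth.times, "amplitude": truth.amplitudes}).to_csv(
            out / "trace_truth.csv", index=False
        )
        outputs += ["trace.csv", "trace.json", "trace_truth.csv"]
    if "trains" in block:
        p = synthgen.QuantalModelParams(**{**block["trains"], "seed": block["trains"].get("seed", seed)})
        trains, truth = synthgen.simulate_trains(p)
        trains.to_csv(out / "trains.csv", index=False)
        (out / "trains_truth.json").write_text(json.dumps(asdict(truth), indent=2))
        outputs += ["trains.csv", "trains_truth.json"]
    if "screen" in block:
        p = synthgen.ScreenSimParams(**{**block["screen"], "seed": block["screen"].get("seed", seed)})
        table, truth = synthgen.simulate_screen(p)
        table.to_csv(out / "screen.csv", index=False)
        truth.to_csv(out / "screen_truth.csv", index=False)
        outputs += ["screen.csv", "screen_truth.csv"]
    if "boutons" in block:
        b = dict(block["boutons"])
        b.setdefault("seed", seed)
        boutons = synthgen.simulate_nnd_dataset(**b)
        shio.write_boutons(out / "boutons.json", boutons)
        outputs += ["boutons.json"]
    return outputs


def _stage_detect(block: dict, out: Path, seed: int) -> list[str]:
    trace = shio.read_trace(_require(Path(block.get("trace", out / "trace.csv"))))
    tpl = minidetect.build_template(
        rise_tau=block.get("rise_tau", 0.5),
        decay_tau=block.get("decay_tau", 5.0),
        dt=trace.dt,
    )
    events = minidetect.cb_detect(
        trace,
        tpl,
        threshold=block.get("threshold", minidetect.DEFAULT_THRESHOLD),
        min_separation=block.get("min_separation"),
    )
    events.to_csv(out / "events.csv", index=False)
    return ["events.csv"]


def _stage_quantal(block: dict, out: Path, seed: int) -> list[str]:
    trains = pd.read_csv(_require(Path(block.get("trains", out / "trains.csv"))))
    group_mepsc = block.get("group_mepsc")
    if group_mepsc is None:
        minis = pd.read_csv(_require(Path(block["minis_group"])))
        group_mepsc = quantal.group_mean_mepsc(minis["value"])
    metrics = quantal.cell_metrics(
        trains, group_mepsc, freq=block.get("freq", 60.0), last_k=block.get("last_k", 15)
    )
    metrics.to_csv(out / "metrics.csv", index=False)
    return ["metrics.csv"]


def _stage_screen(block: dict, out: Path, seed: int) -> list[str]:
    table = pd.read_csv(_require(Path(block.get("table", out / "screen.csv"))))
    volcano = screenstats.volcano_screen(table, alpha_flag=block.get("alpha", 0.01))
    volcano.to_csv(out / "volcano.csv", index=False)
    n_smaller = int((volcano["flag"] == "smaller").sum())
    summary = {
        "n_lines": len(volcano),
        "n_smaller": n_smaller,
        "n_larger": int((volcano["flag"] == "larger").sum()),
        "hit_rate_percent": screenstats.hit_rate_percent(n_smaller, len(volcano)),
    }
    (out / "volcano_summary.json").write_text(json.dumps(summary, indent=2))
    return ["volcano.csv", "volcano_summary.json"]


def _stage_nnd(block: dict, out: Path, seed: int) -> list[str]:
    boutons = shio.read_boutons(_require(Path(block.get("boutons", out / "boutons.json"))))
    results, p = proximics.mc_nnd_test(
        boutons,
        n_rand=block.get("n_rand", 100),
        seed=block.get("seed", seed),
        paired=block.get("paired", True),
    )
    pd.DataFrame([asdict(r) for r in results]).to_csv(out / "nnd.csv", index=False)
    (out / "nnd_summary.json").write_text(
        json.dumps(
            {
                "p": p,
                "test": "paired_t" if block.get("paired", True) else "student_t",
                "n_rand": block.get("n_rand", 100),
                "seed": block.get("seed", seed),
                "n_boutons": len(results),
            },
            indent=2,
        )
    )
    return ["nnd.csv", "nnd_summary.json"]


def _stage_morpho(block: dict, out: Path, seed: int) -> list[str]:
    from . import morphoquant

    img, px = shio.read_image(_require(Path(block["image"])))
    pixel_size = block.get("pixel_size", px)
    if pixel_size is None:
        raise ValueError("config error at 'morpho.pixel_size': pixel size unknown")
    if img.ndim == 2:
        img = img[None]
    brp = img[block.get("brp_channel", 0)]
    hrp = img[block.get("hrp_channel", 1)] if img.shape[0] > 1 else brp
    rows = []
    for frac in block.get("thresholds", [0.15, 0.35]):
        filt, unfilt = morphoquant.preprocess_projection(brp, pixel_size)
        hf, _ = morphoquant.preprocess_projection(hrp, pixel_size)
        mask = morphoquant.threshold_mask(filt, frac)
        hrp_mask = morphoquant.threshold_mask(hf, frac)
        res = morphoquant.count_and_measure(mask, unfilt, hrp_mask, pixel_size)
        rows.append(
            {
                "threshold": frac,
                "count": res.object_count,
                "area_um2": res.mask_area_um2,
                "density_per_um2": res.density_per_um2,
                "mean_intensity": float(np.mean(res.object_mean_intensities))
                if len(res.object_mean_intensities)
                else np.nan,
            }
        )
    pd.DataFrame(rows).to_csv(out / "morpho.csv", index=False)
    return ["morpho.csv"]


_STAGE_FN = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "quantal": _stage_quantal,
    "screen": _stage_screen,
    "nnd": _stage_nnd,
    "morpho": _stage_morpho,
}


def run_pipeline(config: dict | str | Path, out_dir=None) -> dict:
    """Execute the configured stages in order and return the run report.

    On stage failure the run aborts with an error naming the failed stage.
    The report manifests every output file and echoes the config.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    _validate(config)
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "synhomeo_run"))
    out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    manifest: dict[str, list[str]] = {}
    for stage in config["stages"]:
        block = config.get(stage, {})
        try:
            manifest[stage] = _STAGE_FN[stage](block, out, stage_seed(seed, stage))
        except Exception as exc:
            raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    report = {
        "version": __version__,
        "seed": seed,
        "out_dir": str(out),
        "manifest": manifest,
        "config": {k: v for k, v in config.items()},
        "wall_time_s": time.time() - t0,
    }
    (out / "run_report.json").write_text(json.dumps(report, indent=2))
    for files in manifest.values():
        for f in files:
            assert (out / f).exists(), f"declared output missing: {f}"
    return report
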