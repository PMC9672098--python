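"""Table formats, configuration, seed management and the pipeline driver.

All tables are delimited text (tab-separated) with a commented ``# key=value``
header block carrying schema/provenance metadata; floats are written with 17
significant digits so write→read round trips are lossless.  Images use TIFF.

A single master seed drives every stochastic stage; child seeds are spawned
with ``numpy.random.SeedSequence`` in a fixed order (documented in
:func:`child_seeds`), so reruns with the same configuration are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .model import ModelParams
from .synth import EmbryoSpec, generate_embryo_tracks
from .tracks import EdgeTrack
from . import feedback as fb
from . import predict as pr

__all__ = [
    "TRACK_COLUMNS",
    "write_tracks",
    "read_tracks",
    "write_table",
    "read_table",
    "RunConfig",
    "load_config",
    "child_seeds",
    "run_pipeline",
]

log = logging.getLogger("mechanofeedback")

TRACK_COLUMNS = ["edge_id", "time_s", "length_um", "myosin_density",
                 "dv_position_um", "ap_position_um", "orientation_deg"]
_FLOAT_FMT = "%.17g"
_SCHEMA = "mechanofeedback-tracks-1"


def _write_header(handle, meta: dict) -> None:
    for key, value in meta.items():
        handle.write(f"# {key}={value}\n")


def _read_header(path: Path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    return meta


def write_table(frame: pd.DataFrame, path: str | Path,
                meta: dict | None = None) -> None:
    """Write a DataFrame as tab-separated text with a commented header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _write_header(fh, meta or {})
        frame.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_table(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta = _read_header(path)
    frame = pd.read_csv(path, sep="\t", comment="#",
                        float_precision="round_trip")
    return frame, meta


def write_tracks(tracks: Sequence[EdgeTrack], path: str | Path,
                 meta: dict | None = None) -> None:
    """Write an edge-track collection in the standard table dialect."""
    frames = []
    for t in tracks:
        frames.append(pd.DataFrame({
            "edge_id": t.edge_id,
            "time_s": t.times,
            "length_um": t.lengths,
            "myosin_density": t.myosin_density,
            "dv_position_um": t.dv_position,
            "ap_position_um": t.ap_position,
            "orientation_deg": t.orientation,
        }))
    table = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=TRACK_COLUMNS))
    header = {"schema": _SCHEMA, "n_edges": len(tracks)}
    header.update(meta or {})
    write_table(table, path, header)


def read_tracks(path: str | Path) -> list[EdgeTrack]:
    """Read a track table, validating each edge with row-numbered diagnostics."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table, meta = read_table(path)
    if table.empty:
        log.warning("%s: empty track file", path)
        return []
    missing = [c for c in TRACK_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = table.index[table["length_um"] <= 0]
    if len(bad):
        raise ValueError(
            f"{path}: non-positive length at data row {int(bad[0])}")
    tracks = []
    for eid, grp in table.groupby("edge_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        dts = np.diff(times)
        if len(dts) and (np.any(dts <= 0)
                         or np.max(np.abs(dts - dts[0])) > 1e-6 * abs(dts[0])):
            row = int(grp.index[0])
            raise ValueError(
                f"{path}: non-uniform time grid for edge {eid} "
                f"(starting at data row {row})")
        tracks.append(EdgeTrack(
            edge_id=int(eid),
            times=times,
            lengths=grp["length_um"].to_numpy(dtype=float),
            myosin_density=grp["myosin_density"].to_numpy(dtype=float),
            dv_position=float(grp["dv_position_um"].iloc[0]),
            ap_position=float(grp["ap_position_um"].iloc[0]),
            orientation=float(grp["orientation_deg"].iloc[0]),
        ))
    return tracks


# ---------------------------------------------------------------------------
# configuration

_ANALYSIS_DEFAULTS = {"sigma": 10.0, "window": (10.0, 20.0)}
_FIT_DEFAULTS = {"n_bins": 10, "cone_halfwidth": 30.0, "min_edges": 30}
_PREDICT_DEFAULTS = {"fit_window": None, "metric": "l1",
                     "coefficient_source": "fitted"}


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run."""

    embryo: EmbryoSpec
    analysis: dict
    fit: dict
    predict: dict
    mutant_scale: float | None
    seed: int
    out: Path
    log_level: str = "INFO"


def _build_block(cls_or_defaults, block: dict, name: str):
    if isinstance(cls_or_defaults, dict):
        merged = dict(cls_or_defaults)
        unknown = set(block) - set(merged)
        if unknown:
            raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
        merged.update(block)
        if "window" in merged and merged["window"] is not None:
            merged["window"] = tuple(merged["window"])
        if "fit_window" in merged and merged["fit_window"] is not None:
            merged["fit_window"] = tuple(merged["fit_window"])
        return merged
    known = {f.name for f in dataclasses.fields(cls_or_defaults)}
    unknown = set(block) - known
    if unknown:
        raise ValueError(f"unknown keys in '{name}' block: {sorted(unknown)}")
    return block


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys anywhere are rejected.  ``overrides`` (e.g. from the command
    line) take precedence over the file.
    """
    raw: dict = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    if overrides:
        raw = {**raw, **{k: v for k, v in overrides.items() if v is not None}}

    top_known = {"embryo", "model", "analysis", "fit", "predict",
                 "mutant_scale", "seed", "out", "log_level"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")

    model_block = _build_block(ModelParams, dict(raw.get("model") or {}), "model")
    embryo_block = dict(raw.get("embryo") or {})
    _build_block(EmbryoSpec, embryo_block, "embryo")
    if "ramp_window" in embryo_block:
        embryo_block["ramp_window"] = tuple(embryo_block["ramp_window"])
    if model_block:
        base = EmbryoSpec(**embryo_block).oscillator
        embryo_block["oscillator"] = dataclasses.replace(base, **model_block)
    seed = int(raw.get("seed", 0))
    embryo_block.setdefault("seed", seed)
    embryo = EmbryoSpec(**embryo_block)

    mutant_scale = raw.get("mutant_scale")
    return RunConfig(
        embryo=embryo,
        analysis=_build_block(_ANALYSIS_DEFAULTS,
                              dict(raw.get("analysis") or {}), "analysis"),
        fit=_build_block(_FIT_DEFAULTS, dict(raw.get("fit") or {}), "fit"),
        predict=_build_block(_PREDICT_DEFAULTS,
                             dict(raw.get("predict") or {}), "predict"),
        mutant_scale=float(mutant_scale) if mutant_scale is not None else None,
        seed=seed,
        out=Path(raw.get("out", "mechanofeedback-run")),
        log_level=str(raw.get("log_level", "INFO")),
    )


def child_seeds(master: int, n: int) -> list[int]:
    """Deterministic child seeds: entropy stream of SeedSequence(master).

    Order: 0 = wild-type embryo, 1 = mutant embryo, 2+ = reserved.
    """
    return [int(s) for s in np.random.SeedSequence(master).generate_state(n)]


# ---------------------------------------------------------------------------
# pipeline driver

def run_pipeline(config: RunConfig) -> dict:
    """generate → analyze → fit → predict (→ mutant comparison).

    Returns a JSON-serializable report of seeds, counts at each filter, key
    results and output paths; all outputs are written under ``config.out``.
    Identical configurations produce byte-identical outputs.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    seeds = child_seeds(config.seed, 2)
    report: dict = {"seed": config.seed, "child_seeds": seeds,
                    "stages": [], "outputs": {}}

    def fail(stage, exc):
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    # -- generate ----------------------------------------------------------
    try:
        spec = dataclasses.replace(config.embryo, seed=seeds[0])
        tracks, truth = generate_embryo_tracks(spec)
        write_tracks(tracks, out / "tracks_wt.tsv",
                     {"condition": "wild_type", "seed": seeds[0]})
        gt = pd.DataFrame({
            "edge_id": np.arange(len(tracks)),
            "feedback_c": truth.feedback_c,
            "dv_position_um": truth.dv_position,
            "orientation_deg": truth.orientation,
        })
        write_table(gt, out / "ground_truth_wt.tsv",
                    {"schema": "mechanofeedback-truth-1"})
        report["stages"].append({"stage": "generate", "n_edges": len(tracks)})
        report["outputs"]["tracks_wt"] = str(out / "tracks_wt.tsv")
    except Exception as exc:  # noqa: BLE001 - fail-fast with stage name
        fail("generate", exc)

    mutant_tracks = None
    if config.mutant_scale is not None:
        try:
            # paired design: same geometry and noise streams as wild type,
            # only the strain field is attenuated
            mspec = dataclasses.replace(config.embryo, seed=seeds[0],
                                        mutant_scale=config.mutant_scale)
            mutant_tracks, _ = generate_embryo_tracks(mspec)
            write_tracks(mutant_tracks, out / "tracks_mutant.tsv",
                         {"condition": "mutant", "seed": seeds[0],
                          "mutant_scale": config.mutant_scale})
            report["outputs"]["tracks_mutant"] = str(out / "tracks_mutant.tsv")
        except Exception as exc:  # noqa: BLE001
            fail("generate-mutant", exc)

    # -- analyze + fit -----------------------------------------------------
    try:
        ana = config.analysis
        fit_cfg = config.fit
        bins = fb.bin_edges(tracks, fit_cfg["n_bins"],
                            window=tuple(ana["window"]), sigma=ana["sigma"],
                            cone_halfwidth=fit_cfg["cone_halfwidth"],
                            min_edges=fit_cfg["min_edges"],
                            dv_max=spec.dv_halfcircumference)
        profile = fb.feedback_profile(bins)
        bin_table = pd.DataFrame({
            "dv_lo": [b.dv_range[0] for b in bins],
            "dv_hi": [b.dv_range[1] for b in bins],
            "n_edges": [b.n_edges for b in bins],
            "mean_strain_rate": [b.mean_strain_rate for b in bins],
            "sd_strain_rate": [b.sd_strain_rate for b in bins],
            "mean_myosin_rate": [b.mean_myosin_rate for b in bins],
            "sd_myosin_rate": [b.sd_myosin_rate for b in bins],
            "usable": [b.usable for b in bins],
        })
        write_table(bin_table, out / "bins_wt.tsv",
                    {"schema": "mechanofeedback-bins-1"})
        write_table(profile.table, out / "feedback_profile.tsv",
                    {"schema": "mechanofeedback-profile-1",
                     "slope_per_um": profile.slope,
                     "intercept": profile.intercept})
        report["stages"].append({
            "stage": "fit",
            "usable_bins": int(sum(b.usable for b in bins)),
            "profile_slope_per_um": profile.slope,
        })
        report["outputs"]["feedback_profile"] = str(out / "feedback_profile.tsv")
    except Exception as exc:  # noqa: BLE001
        fail("fit", exc)

    # -- predict -----------------------------------------------------------
    try:
        pcfg = config.predict
        if pcfg["coefficient_source"] == "fitted":
            c_of_dv = profile.coefficient_at
        elif pcfg["coefficient_source"] == "imposed":
            cv, cd = spec.feedback_c_ventral, spec.feedback_c_dorsal
            c_of_dv = lambda dv: cv + (cd - cv) * np.asarray(dv) / spec.dv_halfcircumference  # noqa: E731
        else:
            raise ValueError("coefficient_source must be 'fitted' or 'imposed'")
        pred = pr.predict_myosin(tracks, c_of_dv, n_bins=fit_cfg["n_bins"],
                                 dv_max=spec.dv_halfcircumference,
                                 fit_window=pcfg["fit_window"])
        acc = pd.DataFrame({"time_s": pred.times, "accuracy": pred.accuracy})
        write_table(acc, out / "accuracy.tsv",
                    {"schema": "mechanofeedback-accuracy-1",
                     "global_constant": pred.global_constant})
        prof_rows = []
        for bi, dvc in enumerate(pred.dv_centers):
            for ti in range(0, pred.times.size, max(1, pred.times.size // 50)):
                prof_rows.append({"dv_center": dvc, "time_s": pred.times[ti],
                                  "predicted": pred.predicted[bi, ti],
                                  "measured": pred.measured[bi, ti]})
        write_table(pd.DataFrame(prof_rows), out / "myosin_prediction.tsv",
                    {"schema": "mechanofeedback-prediction-1"})
        report["stages"].append({
            "stage": "predict",
            "global_constant": pred.global_constant,
            "final_accuracy": float(pred.accuracy[-1]),
        })
        report["outputs"]["accuracy"] = str(out / "accuracy.tsv")
    except Exception as exc:  # noqa: BLE001
        fail("predict", exc)

    # -- mutant comparison -------------------------------------------------
    if mutant_tracks is not None:
        try:
            mbins = fb.bin_edges(mutant_tracks, fit_cfg["n_bins"],
                                 window=tuple(ana["window"]),
                                 sigma=ana["sigma"],
                                 cone_halfwidth=fit_cfg["cone_halfwidth"],
                                 min_edges=fit_cfg["min_edges"],
                                 dv_max=spec.dv_halfcircumference)
            comp = pr.condition_comparison(bins, mbins)
            write_table(comp.table, out / "condition_comparison.tsv",
                        {"schema": "mechanofeedback-comparison-1",
                         "reference_coefficient": comp.reference_fit.coefficient})
            ok = comp.table[~comp.table["flagged"]]
            report["stages"].append({
                "stage": "compare",
                "mean_strain_ratio": float(ok["strain_ratio"].mean()),
                "mean_myosin_ratio": float(ok["myosin_ratio"].mean()),
            })
            report["outputs"]["condition_comparison"] = str(
                out / "condition_comparison.tsv")
        except Exception as exc:  # noqa: BLE001
            fail("compare", exc)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    report["outputs"]["report"] = str(out / "report.json")
    return report
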