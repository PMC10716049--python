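"""Readers/writers: TIFF stacks with pixel-size metadata, CSV traces and
curves, YAML ground-truth sidecars, and the config-driven pipeline runner.

CSV dialect: comma separator, dot decimal, UTF-8, mandatory header row.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .datatypes import Curve, GroundTruth, ImageStack, TimeTrace

logger = logging.getLogger(__name__)

__all__ = [
    "read_image_stack",
    "write_image_stack",
    "write_sidecar",
    "read_sidecar",
    "write_traces_csv",
    "read_traces_csv",
    "write_curve_csv",
    "read_curve_csv",
    "RunConfig",
    "run_pipeline",
]


def write_image_stack(path: str | Path, stack: ImageStack) -> Path:
    """Write a (t,z,y,x,c) stack as ImageJ-style TIFF with pixel size."""
    path = Path(path)
    px_um = stack.pixel_size / 1000.0
    # ImageJ axis order TZCYX; move channel before y,x
    data = np.moveaxis(stack.pixels, 4, 2)
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px_um, 1.0 / px_um),
        metadata={"axes": "TZCYX", "unit": "um", "spacing": 1.0},
    )
    return path


def read_image_stack(path: str | Path, pixel_size: float | None = None) -> ImageStack:
    """Read a TIFF into the canonical (t,z,y,x,channel) layout.

    Pixel size (nm) is taken from the TIFF resolution metadata; pass
    ``pixel_size`` to override. Raises if neither is available, since the
    physical-unit quantifications need it.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. 'YX', 'TZCYX'
        if pixel_size is None:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = None
            if tf.imagej_metadata:
                unit = tf.imagej_metadata.get("unit")
            res_unit = page.tags.get("ResolutionUnit")
            has_units = unit is not None or (
                res_unit is not None and getattr(res_unit.value, "value", res_unit.value) not in (1,)
            )
            if res is not None and res.value[0] != 0 and has_units:
                px_per_unit = res.value[0] / res.value[1]
                size_unit = 1.0 / px_per_unit
                if unit in ("um", "micron", "µm", None):
                    pixel_size = size_unit * 1000.0  # um -> nm
                elif unit == "nm":
                    pixel_size = size_unit
    if pixel_size is None:
        raise ValueError(
            f"{path}: no pixel size in TIFF metadata; pass pixel_size= override"
        )
    # normalize axes to TZYXC
    order = {"T": 0, "Z": 1, "Y": 2, "X": 3, "C": 4, "S": 4}
    arr = data
    have = list(axes)
    for ax in "TZYXC":
        if ax not in have and not (ax == "C" and "S" in have):
            arr = np.expand_dims(arr, axis=0)
            have.insert(0, ax)
    perm = sorted(range(len(have)), key=lambda i: order[have[i]])
    arr = np.transpose(arr, perm)
    bit_depth = 8 if arr.dtype == np.uint8 else 16
    return ImageStack(arr, pixel_size, bit_depth)


def write_sidecar(path: str | Path, gt: GroundTruth) -> Path:
    """Write the scalar ground-truth parameters as a YAML sidecar."""
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(gt.to_sidecar(), fh, sort_keys=True)
    return path


def read_sidecar(path: str | Path) -> GroundTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    seed = int(data.pop("seed", 0))
    return GroundTruth(params=data, seed=seed)


def write_traces_csv(path: str | Path, traces: dict[str, TimeTrace]) -> Path:
    """Long-format t,roi,value CSV for FRAP-style ROI traces."""
    rows = []
    for roi, tr in traces.items():
        for t, v in zip(tr.t, tr.value):
            rows.append({"t": t, "roi": roi, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def read_traces_csv(path: str | Path) -> dict[str, TimeTrace]:
    df = pd.read_csv(path)
    out = {}
    for roi, sub in df.groupby("roi"):
        sub = sub.sort_values("t")
        out[str(roi)] = TimeTrace(sub["t"].to_numpy(), sub["value"].to_numpy(), str(roi))
    return out


def write_curve_csv(path: str | Path, curve: Curve, xname: str = "x", yname: str = "y") -> Path:
    cols = {xname: curve.x, yname: curve.y}
    if curve.replicate is not None:
        cols["replicate"] = curve.replicate
    pd.DataFrame(cols).to_csv(path, index=False)
    return Path(path)


def read_curve_csv(path: str | Path, xname: str = "x", yname: str = "y") -> Curve:
    df = pd.read_csv(path)
    rep = df["replicate"].to_numpy() if "replicate" in df.columns else None
    return Curve(df[xname].to_numpy(), df[yname].to_numpy(), replicate=rep)


_KNOWN_KEYS = {"stage", "inputs", "params", "seed", "outdir", "log_level"}


class RunConfig:
    """Validated run configuration: stage, inputs, params, seed, outdir."""

    def __init__(self, mapping: dict):
        unknown = set(mapping) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage" not in mapping or "outdir" not in mapping:
            raise ValueError("config requires 'stage' and 'outdir'")
        self.stage = str(mapping["stage"])
        self.inputs = dict(mapping.get("inputs", {}))
        self.params = dict(mapping.get("params", {}))
        self.seed = int(mapping.get("seed", 0))
        self.outdir = Path(mapping["outdir"])
        self.log_level = str(mapping.get("log_level", "INFO"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def resolved(self) -> dict:
        return {
            "stage": self.stage,
            "inputs": {k: str(v) for k, v in self.inputs.items()},
            "params": self.params,
            "seed": self.seed,
            "outdir": str(self.outdir),
            "log_level": self.log_level,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_simulate_turbidity(cfg: RunConfig) -> list[Path]:
    from .synthetic import gen_turbidity_curve

    curve, gt = gen_turbidity_curve(seed=cfg.seed, **cfg.params)
    out = [
        write_curve_csv(cfg.outdir / "turbidity.csv", curve, xname="T", yname="A340"),
        write_sidecar(cfg.outdir / "turbidity.truth.yaml", gt),
    ]
    return out


def _stage_simulate_frap(cfg: RunConfig) -> list[Path]:
    from .synthetic import gen_frap_trace

    traces, gt = gen_frap_trace(seed=cfg.seed, **cfg.params)
    return [
        write_traces_csv(cfg.outdir / "frap.csv", traces),
        write_sidecar(cfg.outdir / "frap.truth.yaml", gt),
    ]


def _stage_simulate_nuclei(cfg: RunConfig) -> list[Path]:
    from .synthetic import gen_nuclei_field

    params = dict(cfg.params)
    params.setdefault("n_nuclei", 5)
    stack, gt = gen_nuclei_field(seed=cfg.seed, **params)
    return [
        write_image_stack(cfg.outdir / "nuclei.tif", stack),
        write_sidecar(cfg.outdir / "nuclei.truth.yaml", gt),
    ]


def _stage_simulate_dose_response(cfg: RunConfig) -> list[Path]:
    from .synthetic import gen_dose_response

    curve, gt = gen_dose_response(seed=cfg.seed, **cfg.params)
    return [
        write_curve_csv(cfg.outdir / "dose_response.csv", curve, xname="dose", yname="response"),
        write_sidecar(cfg.outdir / "dose_response.truth.yaml", gt),
    ]


def _stage_frap_fit(cfg: RunConfig) -> list[Path]:
    from .frap import FRAPTrace, FrapRecoveryModel, normalize_double

    trace = FRAPTrace.from_csv(cfg.inputs["traces"])
    norm = normalize_double(trace)
    res = FrapRecoveryModel(norm).fit()
    out_csv = cfg.outdir / "frap_fit.csv"
    pd.DataFrame(
        [
            {
                "mobile_fraction": res.mobile_fraction,
                "t_half_s": res.t_half,
                "k_per_s": res.k,
                "I0_norm": res.I0_norm,
                "plateau_norm": res.plateau_norm,
                "rmse": res.rmse,
            }
        ]
    ).to_csv(out_csv, index=False)
    norm_csv = cfg.outdir / "frap_normalized.csv"
    pd.DataFrame({"t": norm.t, "normalized": norm.value}).to_csv(norm_csv, index=False)
    return [out_csv, norm_csv]


def _stage_phase_tc(cfg: RunConfig) -> list[Path]:
    from .phase import cloud_point

    curve = read_curve_csv(cfg.inputs["curve"], xname="T", yname="A340")
    cp = cloud_point(curve, smooth_window=int(cfg.params.get("smooth_window", 5)))
    out = cfg.outdir / "cloud_point.csv"
    pd.DataFrame([{"Tc": cp.Tc, "peak_height": cp.peak_height, "flag": cp.flag}]).to_csv(
        out, index=False
    )
    return [out]


def _stage_stats_drc(cfg: RunConfig) -> list[Path]:
    from .stats import LogLogisticModel

    curve = read_curve_csv(cfg.inputs["curve"], xname="dose", yname="response")
    res = LogLogisticModel(curve.x, curve.y).fit()
    out = cfg.outdir / "dose_response_fit.csv"
    pd.DataFrame(
        [{"b": res.b, "d": res.d, "e": res.e, "IC50": res.ic50, "IC10": res.ic10}]
    ).to_csv(out, index=False)
    return [out]


_STAGES = {
    "simulate_turbidity": _stage_simulate_turbidity,
    "simulate_frap": _stage_simulate_frap,
    "simulate_nuclei": _stage_simulate_nuclei,
    "simulate_dose_response": _stage_simulate_dose_response,
    "frap_fit": _stage_frap_fit,
    "phase_tc": _stage_phase_tc,
    "stats_drc": _stage_stats_drc,
}


def run_pipeline(config: RunConfig | dict) -> dict:
    """Run one configured stage; returns a manifest of outputs with hashes.

    Deterministic given the config: all randomness flows from ``seed``.
    The resolved config is written next to the outputs. On stage failure a
    ``.failed`` marker is left in the output directory and the exception
    re-raised after recording partial outputs.
    """
    if isinstance(config, dict):
        config = RunConfig(config)
    if config.stage not in _STAGES:
        raise ValueError(f"unknown stage {config.stage!r}; known: {sorted(_STAGES)}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    resolved = config.outdir / "config.resolved.yaml"
    with open(resolved, "w") as fh:
        yaml.safe_dump(config.resolved(), fh, sort_keys=True)
    cfg_hash = _sha256(resolved)
    logger.info(
        "condensakit %s stage=%s config_hash=%s", __version__, config.stage, cfg_hash
    )
    try:
        outputs = _STAGES[config.stage](config)
    except Exception:
        (config.outdir / f"{config.stage}.failed").touch()
        raise
    manifest = {
        "package_version": __version__,
        "stage": config.stage,
        "config_hash": cfg_hash,
        "input_hashes": {
            k: _sha256(Path(v)) for k, v in config.inputs.items() if Path(v).is_file()
        },
        "outputs": {str(p.name): _sha256(p) for p in outputs},
    }
    with open(config.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
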