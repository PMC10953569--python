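"""End-to-end analysis pipeline: filter -> detect -> sort -> metrics.

The pipeline is pure orchestration over the library modules; every number in
its reports can be reproduced by calling the module operations directly with
the parameters recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .io import Recording, read_raw_binary, spiketrains_to_csv, write_hdf5
from .layouts import ElectrodeLayout, load_layout
from .metrics import (
    active_channels,
    bin_spiketrains,
    box_summary,
    correlation_matrix,
    detect_bursts,
    firing_map,
    firing_rates,
    snr,
)
from .plotting import plot_corr, plot_heatmap, plot_raster
from .preprocess import FilterSpec, apply_filter
from .spikes import DetectionConfig, detect_spikes, sort_spikes

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs, serializable to YAML."""

    input_path: str | None = None
    layout_path: str | None = None
    output_dir: str = "meakit_out"
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    bin_s: float = 0.010
    burst_max_isi_s: float = 0.1
    burst_min_spikes: int = 3
    active_threshold_hz: float = 0.5
    sort_components: int = 2
    seed: int = 0
    make_figures: bool = True

    def to_dict(self) -> dict:
        d = {
            "input_path": self.input_path,
            "layout_path": self.layout_path,
            "output_dir": self.output_dir,
            "filter": self.filter_spec.to_dict(),
            "detection": {
                "multiplier": self.detection.multiplier,
                "noise_divisor": self.detection.noise_divisor,
                "polarity": self.detection.polarity,
                "dead_time_s": self.detection.dead_time_s,
                "pre_s": self.detection.pre_s,
                "post_s": self.detection.post_s,
            },
            "bin_s": self.bin_s,
            "burst_max_isi_s": self.burst_max_isi_s,
            "burst_min_spikes": self.burst_min_spikes,
            "active_threshold_hz": self.active_threshold_hz,
            "sort_components": self.sort_components,
            "seed": self.seed,
            "make_figures": self.make_figures,
        }
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        det = d.get("detection", {})
        return cls(
            input_path=d.get("input_path"),
            layout_path=d.get("layout_path"),
            output_dir=d.get("output_dir", "meakit_out"),
            filter_spec=FilterSpec.from_dict(d.get("filter", {})),
            detection=DetectionConfig(
                multiplier=det.get("multiplier", 5.0),
                noise_divisor=det.get("noise_divisor", 0.6745),
                polarity=det.get("polarity", "negative"),
                dead_time_s=det.get("dead_time_s", 0.001),
                pre_s=det.get("pre_s", 0.001),
                post_s=det.get("post_s", 0.002),
            ),
            bin_s=d.get("bin_s", 0.010),
            burst_max_isi_s=d.get("burst_max_isi_s", 0.1),
            burst_min_spikes=d.get("burst_min_spikes", 3),
            active_threshold_hz=d.get("active_threshold_hz", 0.5),
            sort_components=d.get("sort_components", 2),
            seed=d.get("seed", 0),
            make_figures=d.get("make_figures", True),
        )


def _param_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(
    config: PipelineConfig,
    recording: Recording | None = None,
    layout: ElectrodeLayout | None = None,
) -> dict:
    """Run the full analysis chain and write its report bundle.

    Inputs may be passed in memory or referenced by path in the config.
    Outputs (under ``config.output_dir``): filtered recording and spike
    trains as HDF5, spike timestamps and per-channel metrics as CSV, the
    correlation matrix as CSV, a JSON report, figures, and a manifest
    recording the package version, seed, and parameter hash.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if recording is None:
        if config.input_path is None:
            raise ConfigError("no recording given and no input_path configured")
        if not Path(config.input_path).exists():
            raise ConfigError(f"input file not found: {config.input_path}")
        recording = read_raw_binary(config.input_path)
    if layout is None and config.layout_path is not None:
        if not Path(config.layout_path).exists():
            raise ConfigError(f"layout file not found: {config.layout_path}")
        layout = load_layout(config.layout_path)

    stages = []

    filtered = apply_filter(recording, config.filter_spec)
    stages.append("filter")

    trains, cutouts = detect_spikes(filtered, config.detection)
    stages.append("detect")

    sort_info = None
    if cutouts.n_events >= 2 * config.sort_components:
        result = sort_spikes(cutouts, n_components=config.sort_components, seed=config.seed)
        sort_info = {"n_units": result.n_units, "n_events": cutouts.n_events}
        stages.append("sort")

    rates = firing_rates(trains)
    active = active_channels(rates, config.active_threshold_hz)
    snrs = snr(filtered, cutouts)
    counts, chan_ids = bin_spiketrains(trains, config.bin_s)
    corr = correlation_matrix(counts, config.bin_s, chan_ids)
    bursts = {
        ch: detect_bursts(ts, config.burst_max_isi_s, config.burst_min_spikes)
        for ch, ts in trains.trains.items()
    }
    rate_box = box_summary(list(rates.values()))
    stages.append("metrics")

    # ---- outputs -----------------------------------------------------------
    metrics_df = pd.DataFrame(
        {
            "channel": list(rates.keys()),
            "rate_hz": list(rates.values()),
            "active": [active[ch] for ch in rates],
            "snr": [snrs.get(ch, float("nan")) for ch in rates],
            "n_bursts": [len(bursts[ch]) for ch in rates],
        }
    )
    metrics_df.to_csv(out / "channel_metrics.csv", index=False)
    spiketrains_to_csv(trains, out / "spikes.csv")
    write_hdf5(trains, out / "spikes.h5")
    pd.DataFrame(corr.values, index=corr.channel_ids, columns=corr.channel_ids).to_csv(
        out / "correlation.csv"
    )

    report = {
        "n_channels": recording.n_channels,
        "duration_s": recording.duration,
        "n_spikes": trains.n_spikes(),
        "n_active_channels": int(sum(active.values())),
        "mean_rate_hz": float(np.mean(list(rates.values()))) if rates else 0.0,
        "rate_box": {
            "median": rate_box.median,
            "q1": rate_box.q1,
            "q3": rate_box.q3,
            "whisker_low": rate_box.whisker_low,
            "whisker_high": rate_box.whisker_high,
            "n_outliers": int(len(rate_box.outliers)),
        },
        "sorting": sort_info,
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1)

    if config.make_figures:
        plot_raster(trains, out / "raster.png")
        plot_corr(corr, out / "correlation.png")
        if layout is not None and layout.n_electrodes == len(rates):
            fmap = firing_map(rates, layout)
            plot_heatmap(fmap, out / "firing_map.png")
            fmap.to_csv(out / "firing_map.csv", index=False)
        stages.append("figures")

    manifest = {
        "package": "meakit",
        "version": __version__,
        "seed": config.seed,
        "param_hash": _param_hash(config),
        "parameters": config.to_dict(),
        "stages": stages,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return {"report": report, "manifest": manifest, "metrics": metrics_df, "output_dir": str(out)}
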