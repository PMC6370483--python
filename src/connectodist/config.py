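"""Run configuration: validated, serializable parameters for the CLI workflow."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """All parameters of one end-to-end run.

    Defaults follow the study conditions the framework was designed around:
    Pearson binning of width 0.2 on [-1, 1] (unpaired) and 0.1 on [-2, 2]
    (paired differences), a pooled 95th-percentile threshold, a rest band-pass
    of [0.001, 0.08] Hz against a more liberal [0.001, 0.25] Hz for task runs,
    and 100 null realizations.
    """

    rest_manifest: str = ""
    task_manifests: tuple[str, ...] = ()
    partition_path: str = ""
    sc_path: str = ""
    out_dir: str = "connectodist_out"
    mode: str = "unpaired"                   # unpaired | paired
    unpaired_range: tuple[float, float] = (-1.0, 1.0)
    unpaired_width: float = 0.2
    paired_range: tuple[float, float] = (-2.0, 2.0)
    paired_width: float = 0.1
    percentile: float = 95.0
    rest_band_hz: tuple[float, float] = (0.001, 0.08)
    task_band_hz: tuple[float, float] = (0.001, 0.25)
    n_realizations: int = 100
    seed: int = 0
    sampling_interval: float = 0.72

    def validate(self, require_inputs: bool = True) -> None:
        if self.mode not in ("unpaired", "paired"):
            raise ValueError(f"mode must be unpaired|paired, got {self.mode!r}")
        if not 0 < self.percentile < 100:
            raise ValueError(f"percentile must be in (0, 100), got "
                             f"{self.percentile}")
        for name, (lo, hi) in (("unpaired_range", self.unpaired_range),
                               ("paired_range", self.paired_range)):
            if not hi > lo:
                raise ValueError(f"{name} must be increasing, got ({lo}, {hi})")
        for name, band in (("rest_band_hz", self.rest_band_hz),
                           ("task_band_hz", self.task_band_hz)):
            if not 0 < band[0] < band[1]:
                raise ValueError(f"{name} must satisfy 0 < low < high")
        if self.n_realizations < 1:
            raise ValueError("n_realizations must be >= 1")
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if require_inputs:
            for label, p in [("rest_manifest", self.rest_manifest),
                             ("partition_path", self.partition_path),
                             *[("task_manifest", t) for t in self.task_manifests]]:
                if not p:
                    raise ValueError(f"{label} is required")
                if not Path(p).exists():
                    raise FileNotFoundError(f"{label}: {p} does not exist")
            if self.sc_path and not Path(self.sc_path).exists():
                raise FileNotFoundError(f"sc_path: {self.sc_path} does not exist")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["task_manifests"] = list(self.task_manifests)
        for k in ("unpaired_range", "paired_range", "rest_band_hz",
                  "task_band_hz"):
            d[k] = list(d[k])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for k in ("task_manifests", "unpaired_range", "paired_range",
              "rest_band_hz", "task_band_hz"):
        if k in raw and isinstance(raw[k], list):
            raw[k] = tuple(raw[k])
    return RunConfig(**raw)
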