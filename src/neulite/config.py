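"""JSON run configuration.

A run is described by one JSON file giving the time grid, the network file
set, the components directory (morphologies and dynamics-parameter files),
external spike-train inputs, and the list of reports to record.  Unknown
keys are rejected everywhere — silent typos in config files are the
dominant user error.  All relative paths resolve against the directory of
the config file.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Any, Dict, List, Mapping, Optional

__all__ = ["ReportConfig", "RunConfig", "parse_config", "ConfigError"]

REPORT_VARIABLES = ("spikes", "v_soma", "extracellular")


class ConfigError(ValueError):
    pass


@dataclass
class ReportConfig:
    variable: str
    file_name: str
    node_ids: Any = "all"            # "all" or list of gids
    electrode_file: Optional[str] = None
    buffer_steps: int = 1000

    def __post_init__(self):
        if self.variable not in REPORT_VARIABLES:
            raise ConfigError(f"unknown report variable {self.variable!r}; "
                              f"valid: {REPORT_VARIABLES}")
        if self.buffer_steps < 1:
            raise ConfigError("buffer_steps must be >= 1")
        if self.variable == "extracellular" and not self.electrode_file:
            raise ConfigError("extracellular report requires electrode_file")


@dataclass
class RunConfig:
    tstop: float                     # ms
    network_name: str
    network_dir: str
    components_dir: str
    output_dir: str
    dt: float = 0.1                  # ms
    seed: int = 0
    ranks: int = 1
    max_seg_len: float = 20.0        # μm
    inputs: List[Dict[str, str]] = field(default_factory=list)
    reports: List[ReportConfig] = field(default_factory=list)

    def __post_init__(self):
        if self.dt <= 0 or self.tstop <= 0:
            raise ConfigError("dt and tstop must be > 0")
        if self.ranks < 1:
            raise ConfigError("ranks must be >= 1")


_TOP_KEYS = {"run", "network", "components_dir", "inputs", "reports",
             "output_dir"}
_RUN_KEYS = {"dt", "tstop", "seed", "ranks", "max_seg_len"}
_NETWORK_KEYS = {"name", "dir"}
_INPUT_KEYS = {"population", "spikes_file"}
_REPORT_KEYS = {"variable", "file_name", "node_ids", "electrode_file",
                "buffer_steps"}


def _check_keys(d: Mapping, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}; "
                          f"allowed: {sorted(allowed)}")


def parse_config(path: str) -> RunConfig:
    """Parse and validate a run configuration file.

    Referenced network files, components directory, spike files and
    electrode layouts must exist at parse time.
    """
    if not os.path.exists(path):
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigError(f"{path}: invalid JSON: {exc}") from None
    base = os.path.dirname(os.path.abspath(path))

    def resolve(p: str) -> str:
        return p if os.path.isabs(p) else os.path.join(base, p)

    _check_keys(raw, _TOP_KEYS, "top level")
    for key in ("run", "network", "output_dir"):
        if key not in raw:
            raise ConfigError(f"missing mandatory key {key!r}")
    run = dict(raw["run"])
    _check_keys(run, _RUN_KEYS, '"run"')
    if "tstop" not in run:
        raise ConfigError('missing mandatory key "tstop" in "run"')
    network = dict(raw["network"])
    _check_keys(network, _NETWORK_KEYS, '"network"')
    for key in ("name", "dir"):
        if key not in network:
            raise ConfigError(f'missing mandatory key {key!r} in "network"')

    inputs = []
    for i, item in enumerate(raw.get("inputs", [])):
        item = dict(item)
        _check_keys(item, _INPUT_KEYS, f"inputs[{i}]")
        for key in _INPUT_KEYS:
            if key not in item:
                raise ConfigError(f"missing key {key!r} in inputs[{i}]")
        item["spikes_file"] = resolve(item["spikes_file"])
        inputs.append(item)

    reports = []
    for i, item in enumerate(raw.get("reports", [])):
        item = dict(item)
        _check_keys(item, _REPORT_KEYS, f"reports[{i}]")
        for key in ("variable", "file_name"):
            if key not in item:
                raise ConfigError(f"missing key {key!r} in reports[{i}]")
        if item.get("electrode_file"):
            item["electrode_file"] = resolve(item["electrode_file"])
        reports.append(ReportConfig(**item))

    cfg = RunConfig(
        tstop=float(run["tstop"]),
        dt=float(run.get("dt", 0.1)),
        seed=int(run.get("seed", 0)),
        ranks=int(run.get("ranks", 1)),
        max_seg_len=float(run.get("max_seg_len", 20.0)),
        network_name=network["name"],
        network_dir=resolve(network["dir"]),
        components_dir=resolve(raw.get("components_dir", base)),
        output_dir=resolve(raw["output_dir"]),
        inputs=inputs,
        reports=reports,
    )
    _check_paths(cfg)
    return cfg


def _check_paths(cfg: RunConfig) -> None:
    from .netio import NetworkFileSet

    fs = NetworkFileSet.in_directory(cfg.network_dir, cfg.network_name)
    for p in (fs.nodes_file, fs.node_types_file, fs.edges_file,
              fs.edge_types_file):
        if not os.path.exists(p):
            raise ConfigError(f"network file does not exist: {p}")
    if not os.path.isdir(cfg.components_dir):
        raise ConfigError(
            f"components_dir does not exist: {cfg.components_dir}")
    for item in cfg.inputs:
        if not os.path.exists(item["spikes_file"]):
            raise ConfigError(
                f"spikes file does not exist: {item['spikes_file']}")
    for rc in cfg.reports:
        if rc.electrode_file and not os.path.exists(rc.electrode_file):
            raise ConfigError(
                f"electrode file does not exist: {rc.electrode_file}")


def write_config(path: str, cfg_dict: Dict[str, Any]) -> str:
    """Serialize a raw config mapping to JSON (used by fixture emitters)."""
    with open(path, "w") as fh:
        json.dump(cfg_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
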