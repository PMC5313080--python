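"""File formats: raster TSV, edge-list CSV, LFP CSV, run manifests.

All formats are plain text.  Spike rasters are two-column tab-separated
(gid, time in ms, 3 decimal places); edge lists are CSV with a fixed header;
run manifests are YAML documents carrying the configuration digest, seeds and
perturbation description so any result directory can be regenerated.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .builder import EDGE_COLUMNS, EdgeList
from .config import NetworkConfig, config_to_dict, load_config


class FormatError(ValueError):
    pass


# -- spike rasters -----------------------------------------------------------

def write_raster(path, gids: np.ndarray, times_ms: np.ndarray):
    with open(path, "w") as fh:
        for g, t in zip(gids, times_ms):
            fh.write(f"{int(g)}\t{t:.3f}\n")


def read_raster(path) -> tuple[np.ndarray, np.ndarray]:
    gids, times = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{ln}: expected 2 tab-separated "
                                  f"fields, got {len(parts)}")
            try:
                gids.append(int(parts[0]))
                times.append(float(parts[1]))
            except ValueError as e:
                raise FormatError(f"{path}:{ln}: {e}") from None
    return np.asarray(gids, dtype=np.int64), np.asarray(times)


# -- edge lists ---------------------------------------------------------------

def write_edges(path, edges: EdgeList):
    df = edges.to_frame()
    df.columns = ["pre_gid", "post_gid", "n_syn", "dist_um", "zone",
                  "weight", "delay_ms"]
    df.to_csv(path, index=False, float_format="%.6g")


def read_edges(path) -> EdgeList:
    df = pd.read_csv(path)
    missing = [c for c in EDGE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return EdgeList(
        pre_gid=df["pre_gid"].to_numpy(np.int64),
        post_gid=df["post_gid"].to_numpy(np.int64),
        n_syn=df["n_syn"].to_numpy(np.int32),
        dist_um=df["dist_um"].to_numpy(float),
        zone=df["zone"].to_numpy(object),
        weight=df["weight"].to_numpy(float),
        delay_ms=df["delay_ms"].to_numpy(float),
        pair_labels=np.full(len(df), "", dtype=object),
    )


# -- LFP traces ---------------------------------------------------------------

def write_lfp(path, t_ms: np.ndarray, values: np.ndarray):
    pd.DataFrame({"time_ms": t_ms, "value": values}).to_csv(path, index=False)


def read_lfp(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    for c in ("time_ms", "value"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    return df["time_ms"].to_numpy(float), df["value"].to_numpy(float)


# -- manifests ----------------------------------------------------------------

@dataclass
class RunManifest:
    config_digest: str
    seed: int
    scale_fraction: float
    perturbation: str
    tool_version: str
    created: str

    @classmethod
    def for_run(cls, cfg: NetworkConfig, seed: int, perturbation: str = "none"
                ) -> "RunManifest":
        from . import __version__
        return cls(config_digest=cfg.digest(), seed=seed,
                   scale_fraction=cfg.scale_fraction, perturbation=perturbation,
                   tool_version=__version__,
                   created=datetime.datetime.now().isoformat(timespec="seconds"))

    def write(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def roundtrip_config(cfg: NetworkConfig) -> NetworkConfig:
    """Serialize and reparse a configuration (semantic identity check)."""
    return load_config(yaml.safe_dump(config_to_dict(cfg)))
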