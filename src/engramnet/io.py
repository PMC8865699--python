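"""Configuration schema, artifact readers/writers, run manifest.

Experiment configurations are human-editable YAML with explicit units in
the key names (``_ms``, ``_s``, ``_hz``, ``_mv``); unknown keys are
rejected with their full path.  All randomness is controlled by an
explicit seed block (construction / drive / rewiring / analysis).  Every
output artifact carries the configuration hash in a comment header so
that analysis steps can refuse silently mismatched inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .network import (ConnectivityMatrix, LIFParams, SpikeRecord,
                      SpikingNetwork, build_static_network)
from .plasticity import PlasticityParams, plastic_run
from .protocols import StimulusProtocol

__all__ = [
    "ExperimentConfig", "SeedBlock", "NetworkSection", "PlasticitySection",
    "ProtocolSection", "EnsembleSpec", "EpisodeSpec",
    "load_config", "config_hash", "run_experiment",
    "write_spikes", "read_spikes", "write_connectivity_triplets",
    "read_connectivity_triplets", "write_table", "read_table",
    "get_logger", "log_event",
]

logger = logging.getLogger("engramnet")


def get_logger() -> logging.Logger:
    if not logger.handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(message)s", "%Y-%m-%dT%H:%M:%S"))
        logger.addHandler(h)
        logger.setLevel(logging.INFO)
    return logger


def log_event(event: str, **kv) -> None:
    """Machine-parseable log line: ``event key=value ...``."""
    get_logger().info("%s %s", event,
                      " ".join(f"{k}={v}" for k, v in kv.items()))


# ----------------------------------------------------------------------
# configuration schema
# ----------------------------------------------------------------------

class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SeedBlock(_Strict):
    construction: int = 1
    drive: int = 2
    rewiring: int = 3
    analysis: int = 4


class NetworkSection(_Strict):
    n_excitatory: int = 1000
    n_inhibitory: int = 250
    n_extra: int = 0
    tau_m_ms: float = 20.0
    v_th_mv: float = 20.0
    v_reset_mv: float = 10.0
    t_ref_ms: float = 2.0
    delay_ms: float = 1.5
    j_mv: float = 0.1
    g_ratio: float = 8.0
    nu_ext_hz: float = 15000.0
    dt_ms: float = 0.1
    k_inh_contacts: Optional[int] = None
    k_exc_contacts: Optional[int] = None

    def lif(self) -> LIFParams:
        return LIFParams(tau_m=self.tau_m_ms, V_th=self.v_th_mv,
                         V_r=self.v_reset_mv, t_ref=self.t_ref_ms,
                         D=self.delay_ms, J=self.j_mv, g=self.g_ratio,
                         nu_ext=self.nu_ext_hz)


class PlasticitySection(_Strict):
    tau_ca_s: float = 10.0
    beta_a: float = 2.0
    beta_d: float = 2.0
    nu_target_hz: float = 8.0
    delta_t_s_ms: float = 100.0
    record_every_s: float = 1.0
    frozen: bool = False

    def params(self) -> PlasticityParams:
        return PlasticityParams(**self.model_dump())


class EnsembleSpec(_Strict):
    indices: Optional[List[int]] = None
    fraction: Optional[float] = None

    @model_validator(mode="after")
    def _one_of(self):
        if (self.indices is None) == (self.fraction is None):
            raise ValueError("give exactly one of 'indices' or 'fraction'")
        return self


class EpisodeSpec(_Strict):
    duration_s: float
    stim: Dict[str, float] = {}


class ProtocolSection(_Strict):
    ensembles: Dict[str, EnsembleSpec] = {}
    episodes: List[EpisodeSpec] = []


class ExperimentConfig(_Strict):
    name: str = "experiment"
    network: NetworkSection = NetworkSection()
    plasticity: PlasticitySection = PlasticitySection()
    protocol: ProtocolSection = ProtocolSection()
    seeds: SeedBlock = SeedBlock()
    record_spikes: bool = False
    output_dir: str = "runs"


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML experiment configuration.

    Schema violations are reported exhaustively (every offending key path)
    before aborting.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        return ExperimentConfig.model_validate(raw)
    except ValidationError as exc:
        msgs = [f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}"
                for e in exc.errors()]
        raise ValueError("invalid configuration:\n  " + "\n  ".join(msgs))


def config_hash(cfg: ExperimentConfig) -> str:
    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ----------------------------------------------------------------------
# artifact formats
# ----------------------------------------------------------------------

def _header(tag: Optional[str]) -> str:
    return f"# config_hash={tag}\n" if tag else ""


def write_spikes(path, spikes: SpikeRecord, tag: Optional[str] = None) -> None:
    """Two-column ASCII spike file (time_ms, neuron_id), time-sorted."""
    with open(path, "w") as fh:
        fh.write(_header(tag))
        for t, i in zip(spikes.times_ms, spikes.ids):
            fh.write(f"{t:.3f}\t{i}\n")


def _read_tagged(path):
    tag = None
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# config_hash="):
            tag = first.strip().split("=", 1)[1]
            body = fh.read()
        else:
            body = first + fh.read()
    return tag, body


def read_spikes(path) -> SpikeRecord:
    tag, body = _read_tagged(path)
    rows = [line.split() for line in body.splitlines() if line.strip()]
    if not rows:
        return SpikeRecord(np.empty(0), np.empty(0, dtype=np.int64))
    arr = np.array(rows, dtype=float)
    rec = SpikeRecord(arr[:, 0], arr[:, 1].astype(np.int64))
    rec.config_hash = tag
    return rec


def write_connectivity_triplets(path, conn: ConnectivityMatrix,
                                tag: Optional[str] = None) -> None:
    """Sparse triplet text: one ``pre post count`` line per connection."""
    pre, post = np.nonzero(conn.W)
    with open(path, "w") as fh:
        fh.write(_header(tag))
        fh.write(f"# shape={conn.N_E},{conn.N_I},{conn.n_extra}\n")
        for j, i in zip(pre, post):
            fh.write(f"{j}\t{i}\t{conn.W[j, i]}\n")


def read_connectivity_triplets(path) -> ConnectivityMatrix:
    tag, body = _read_tagged(path)
    lines = [ln for ln in body.splitlines() if ln.strip()]
    shape_line = [ln for ln in lines if ln.startswith("# shape=")][0]
    N_E, N_I, n_extra = (int(x) for x in shape_line.split("=")[1].split(","))
    conn = ConnectivityMatrix(N_E, N_I, n_extra)
    for ln in lines:
        if ln.startswith("#"):
            continue
        j, i, c = (int(x) for x in ln.split())
        conn.W[j, i] = c
    conn.config_hash = tag
    return conn


def write_table(path, df: pd.DataFrame, tag: Optional[str] = None) -> None:
    """Columnar text output with provenance header."""
    with open(path, "w") as fh:
        fh.write(_header(tag))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    tag, body = _read_tagged(path)
    from io import StringIO
    df = pd.read_csv(StringIO(body))
    df.attrs["config_hash"] = tag
    return df


def check_same_provenance(*objs) -> None:
    tags = {getattr(o, "config_hash", None) or o.attrs.get("config_hash")
            for o in objs}
    tags.discard(None)
    if len(tags) > 1:
        raise ValueError(f"inputs come from different runs: {sorted(tags)}")


# ----------------------------------------------------------------------
# experiment runner
# ----------------------------------------------------------------------

def build_network_from_config(cfg: ExperimentConfig) -> SpikingNetwork:
    net_cfg = cfg.network
    lif = net_cfg.lif()
    conn = build_static_network(net_cfg.n_excitatory, net_cfg.n_inhibitory,
                                lif, cfg.seeds.construction,
                                n_extra=net_cfg.n_extra,
                                k_inh=net_cfg.k_inh_contacts,
                                k_exc=net_cfg.k_exc_contacts)
    return SpikingNetwork(conn, lif, cfg.plasticity.params(),
                          dt_ms=net_cfg.dt_ms,
                          drive_seed=cfg.seeds.drive,
                          rewire_seed=cfg.seeds.rewiring,
                          init_seed=cfg.seeds.construction + 1)


def resolve_ensembles(cfg: ExperimentConfig) -> Dict[str, np.ndarray]:
    rng = np.random.default_rng(cfg.seeds.analysis)
    fixed = {k: np.asarray(v.indices, dtype=np.int64)
             for k, v in cfg.protocol.ensembles.items()
             if v.indices is not None}
    fracs = {k: v.fraction for k, v in cfg.protocol.ensembles.items()
             if v.fraction is not None}
    sampled = {}
    if fracs:
        taken = (np.concatenate(list(fixed.values()))
                 if fixed else np.empty(0, dtype=np.int64))
        pool = np.setdiff1d(np.arange(cfg.network.n_excitatory), taken)
        pool = rng.permutation(pool)
        k = 0
        for label, f in fracs.items():
            n = int(round(f * cfg.network.n_excitatory))
            sampled[label] = np.sort(pool[k:k + n])
            k += n
    return {**fixed, **sampled}


def run_experiment(config_path, output_dir=None) -> Path:
    """Run a configured experiment and write a deterministic artifact set.

    Artifacts: ``manifest.json`` (config hash, seeds, package version),
    ``blocks.csv`` (time series of rate, calcium and block connectivity
    means), ``connectivity_final.txt`` (sparse triplets) and optionally
    ``spikes.gdf``.
    """
    from . import __version__
    cfg = load_config(config_path)
    tag = config_hash(cfg)
    out = Path(output_dir or cfg.output_dir) / f"{cfg.name}-{tag}"
    out.mkdir(parents=True, exist_ok=True)
    log_event("run_start", name=cfg.name, config_hash=tag)

    net = build_network_from_config(cfg)
    ens = resolve_ensembles(cfg)
    proto = StimulusProtocol(
        episodes=[(e.duration_s, e.stim) for e in cfg.protocol.episodes],
        ensembles=ens)

    frames = []
    spikes_t, spikes_i = [], []
    t_off = 0.0
    for dur, stim in proto.episodes:
        mult = proto.multipliers(stim, net.conn.N)
        res = plastic_run(net, dur * 1000.0, multipliers=mult,
                          ensembles=ens or None,
                          record_spikes=cfg.record_spikes)
        df = pd.DataFrame({"time_s": res.time_s + t_off,
                           "rate_hz": res.rate_hz, "phi_hz": res.phi_hz,
                           "mean_ee": res.mean_ee})
        for k, v in res.block_means.items():
            df[f"C_{k}"] = v
        frames.append(df)
        if cfg.record_spikes and res.spikes is not None:
            spikes_t.append(res.spikes.times_ms)
            spikes_i.append(res.spikes.ids)
        t_off += dur
    blocks = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame())
    write_table(out / "blocks.csv", blocks, tag)
    write_connectivity_triplets(out / "connectivity_final.txt", net.conn, tag)
    if cfg.record_spikes:
        rec = SpikeRecord(
            np.concatenate(spikes_t) if spikes_t else np.empty(0),
            np.concatenate(spikes_i) if spikes_i else np.empty(0, int))
        write_spikes(out / "spikes.gdf", rec, tag)
    manifest = {"config_hash": tag, "version": __version__,
                "seeds": cfg.seeds.model_dump(),
                "config": cfg.model_dump()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log_event("run_done", name=cfg.name, output=str(out))
    return out
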