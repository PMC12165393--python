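"""Plain-text file formats and run configuration.

Spike tables (``neuron_id,spike_time_s``), trajectories (``t,x,y``),
barcodes (``dimension,birth,death``) and tidy result tables are CSV with
documented headers; configurations and summaries are YAML/JSON.  All
numeric round-trips are lossless at full double precision.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .barcodes import Barcode, BarcodeSet
from .gridsim import SpikeData, Trajectory
from .pipeline import TdaConfig

__all__ = [
    "read_spikes", "write_spikes",
    "read_trajectory", "write_trajectory",
    "read_barcodes", "write_barcodes",
    "RunConfig", "load_config", "save_config",
]

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def write_spikes(spikes: SpikeData, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# span={float(spikes.span[0])!r},{float(spikes.span[1])!r}\n")
        fh.write("neuron_id,spike_time_s\n")
        for i, s in enumerate(spikes.spikes):
            for t in s:
                fh.write(f"{i},{float(t)!r}\n")


def read_spikes(path, n_neurons: int | None = None) -> SpikeData:
    path = Path(path)
    span = None
    with path.open() as fh:
        first = fh.readline()
        if first.startswith("# span="):
            a, b = first.strip().split("=", 1)[1].split(",")
            span = (float(a), float(b))
        else:
            fh.seek(0)
        df = pd.read_csv(fh, float_precision="round_trip")
    if list(df.columns) != ["neuron_id", "spike_time_s"]:
        raise ValueError(f"{path}: expected header neuron_id,spike_time_s")
    n = n_neurons or (int(df.neuron_id.max()) + 1 if len(df) else 0)
    trains = [df.spike_time_s[df.neuron_id == i].to_numpy() for i in range(n)]
    if span is None:
        tmax = df.spike_time_s.max() if len(df) else 0.0
        span = (0.0, float(tmax))
    return SpikeData(trains, span)


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({"t": traj.times, "x": traj.positions[:, 0],
                       "y": traj.positions[:, 1]})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_trajectory(path, arena: float = 1.5) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["t", "x", "y"]:
        raise ValueError(f"{path}: expected header t,x,y")
    t = df.t.to_numpy()
    dts = np.diff(t)
    traj = Trajectory(t, df[["x", "y"]].to_numpy(), arena)
    if len(dts) and not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
        warnings.warn("non-uniform trajectory time step; resampling to the "
                      "median step")
        traj = traj.resampled(float(np.median(dts)))
    return traj


def write_barcodes(bset: BarcodeSet, path) -> None:
    path = Path(path)
    if path.suffix == ".json":
        obj = {f"h{d}": [[float(b), float(dd)] for b, dd in bset[d].array]
               for d in (0, 1, 2)}
        obj["max_filtration"] = bset.max_filtration
        path.write_text(json.dumps(obj))
        return
    rows = []
    for d in (0, 1, 2):
        for b, dd in bset[d].array:
            rows.append((d, b, dd))
    with path.open("w") as fh:
        fh.write("dimension,birth,death\n")
        for d, b, dd in rows:
            fh.write(f"{int(d)},{float(b)!r},{float(dd)!r}\n")


def read_barcodes(path, max_filtration: float | None = None) -> BarcodeSet:
    """Read a barcode table or JSON; ``inf`` deaths are truncated to the
    max filtration value (or the largest finite death) with a warning."""
    path = Path(path)
    if path.suffix == ".json":
        obj = json.loads(path.read_text())
        arrs = {d: np.asarray(obj.get(f"h{d}", []), dtype=float).reshape(-1, 2)
                for d in (0, 1, 2)}
        max_filtration = max_filtration or obj.get("max_filtration")
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns) != ["dimension", "birth", "death"]:
            raise ValueError(f"{path}: expected header dimension,birth,death")
        arrs = {d: df[df.dimension == d][["birth", "death"]]
                .to_numpy(dtype=float) for d in (0, 1, 2)}
    truncated = {d: False for d in arrs}
    finite_max = max((a[np.isfinite(a)].max() for a in arrs.values()
                      if a.size and np.isfinite(a).any()), default=0.0)
    cap = max_filtration if max_filtration is not None else finite_max
    for d, a in arrs.items():
        inf_mask = np.isinf(a[:, 1])
        if inf_mask.any():
            warnings.warn(f"H{d}: truncating {inf_mask.sum()} infinite "
                          f"death(s) to {cap}")
            a[inf_mask, 1] = cap
            truncated[d] = True
    return BarcodeSet(
        h0=Barcode(0, arrs[0], truncated[0]),
        h1=Barcode(1, arrs[1], truncated[1]),
        h2=Barcode(2, arrs[2], truncated[2]),
        max_filtration=cap,
    )


@dataclass
class RunConfig:
    """Everything a simulation + analysis run needs, serializable to YAML."""

    # simulator
    N: int = 75
    spacing: float = 0.85
    lattice_kind: str = "hexagonal"
    sigma: float = 0.12
    lambda0: float = 0.05
    G0: float = 1.5
    x0: float = 0.4
    oscillations: str = "methods_default"  # or "none" / "single"
    single_freq: float | None = None
    displacement: float = 0.0
    duration: float = 1800.0
    sim_dt: float = 0.010
    mean_speed: float = 0.15
    # pipeline
    tda: TdaConfig = field(default_factory=TdaConfig)
    # bookkeeping
    seed: int = 0
    out_dir: str = "."

    def asdict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def fromdict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        tda = d.pop("tda", {})
        cfg = cls(**d)
        cfg.tda = TdaConfig(**tda) if isinstance(tda, dict) else tda
        return cfg


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.asdict(), sort_keys=False))


def load_config(path) -> RunConfig:
    return RunConfig.fromdict(yaml.safe_load(Path(path).read_text()))
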