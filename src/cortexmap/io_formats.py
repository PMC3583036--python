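"""Readers/writers for simulator and analysis artifacts.

* Snapshots: HDF5 container with groups ``/populations/{name}/...``,
  ``/projections/{name}/...`` (full-precision weights and adjacency),
  ``/meta`` (config document, step, RNG states, config hash).  A reloaded
  snapshot continues bit-identically under the same seed stream.
* Spikes and traces: plain CSV via pandas.
* Maps: PNG images (cyclic colormap for orientation preference, grayscale
  for selectivity/gradient, green/red/blue for left/right/binocular eye
  labels) always accompanied by the raw arrays as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .config import SimConfig
from .network_core import Network

__all__ = [
    "write_snapshot",
    "read_snapshot",
    "write_events_csv",
    "read_events_csv",
    "export_maps",
]


def _rng_state(rng) -> str:
    return json.dumps(rng.bit_generator.state)


def _set_rng_state(rng, state: str) -> None:
    rng.bit_generator.state = json.loads(state)


def write_snapshot(net: Network, step: int, path) -> None:
    """Append the full network state at ``step`` to an HDF5 archive."""
    with h5py.File(path, "a") as f:
        meta = f.require_group("meta")
        cfg_yaml = net.config.to_yaml()
        if "config" not in meta:
            meta.create_dataset("config", data=cfg_yaml)
            meta.create_dataset("config_hash", data=net.config.config_hash())
            meta.create_dataset("master_seed", data=net.master_seed)
        g = f.require_group(f"snapshots/{step}")
        g.attrs["step"] = step
        for name, pop in net.populations.items():
            pg = g.require_group(f"populations/{name}")
            for key, arr in pop.state_arrays().items():
                pg.create_dataset(key, data=arr)
            pg.create_dataset("spiked", data=pop.spiked)
        for proj in net.projections:
            jg = g.require_group(f"projections/{proj.name}")
            jg.create_dataset("weights", data=proj.w)
            jg.create_dataset("pre_idx", data=proj.pre_idx)
            jg.create_dataset("post_idx", data=proj.post_idx)
        prev = g.require_group("prev_spikes")
        for name, arr in net._prev_spikes.items():
            prev.create_dataset(name, data=np.asarray(arr, dtype=np.int64))
        rg = g.require_group("rngs")
        for key in ("rng_inject", "rng_stim_left", "rng_stim_right", "rng_misc"):
            rg.create_dataset(key, data=_rng_state(getattr(net, key)))


def read_snapshot(path, step: int) -> Network:
    """Rebuild a network from an archived snapshot.

    Raises ``KeyError`` naming the available steps when ``step`` is missing.
    The archive's config hash is verified against the stored document.
    """
    with h5py.File(path, "r") as f:
        cfg = SimConfig.from_yaml(f["meta/config"][()].decode())
        stored_hash = f["meta/config_hash"][()].decode()
        if cfg.config_hash() != stored_hash:
            raise ValueError("archive config hash mismatch: corrupted archive")
        key = f"snapshots/{step}"
        if key not in f:
            avail = sorted(int(k) for k in f["snapshots"].keys())
            raise KeyError(f"no snapshot at step {step}; available steps: {avail}")
        g = f[key]
        net = Network(cfg, master_seed=int(f["meta/master_seed"][()]))
        net.step_count = int(g.attrs["step"])
        for name, pop in net.populations.items():
            pg = g[f"populations/{name}"]
            for field, arr in pop.state_arrays().items():
                arr[:] = pg[field][()]
            pop.spiked[:] = pg["spiked"][()]
        for proj in net.projections:
            jg = g[f"projections/{proj.name}"]
            proj.pre_idx = jg["pre_idx"][()]
            proj.post_idx = jg["post_idx"][()]
            proj.w = jg["weights"][()]
            proj._csr_pre = proj._csr_post = None
        net._prev_spikes = {name: g["prev_spikes"][name][()]
                            for name in g["prev_spikes"].keys()}
        for key2 in ("rng_inject", "rng_stim_left", "rng_stim_right", "rng_misc"):
            _set_rng_state(getattr(net, key2), g[f"rngs/{key2}"][()].decode())
    return net


def write_events_csv(events, path) -> None:
    """Spike event list: one record per spike (step, population, neuron)."""
    df = pd.DataFrame(events, columns=["step", "population", "neuron"])
    df.to_csv(path, index=False)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def export_maps(maps: dict, out_dir) -> list[Path]:
    """Write PNG + raw-CSV files for a dict of named maps.

    Recognized keys: ``odm`` (an OdmMap: green/red/blue for left/right/
    binocular), ``preference`` (cyclic 0-180 colormap), ``selectivity`` and
    ``gradient`` (grayscale).  Raw values are always written alongside the
    images.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _save_csv(name, arr):
        p = out_dir / f"{name}.csv"
        np.savetxt(p, np.asarray(arr, dtype=float), delimiter=",")
        written.append(p)

    for name, obj in maps.items():
        if name == "odm":
            label = obj.label
            rgb = np.zeros(label.shape + (3,))
            rgb[label > 0] = (0.0, 0.8, 0.0)   # left: green
            rgb[label < 0] = (0.8, 0.0, 0.0)   # right: red
            rgb[label == 0] = (0.0, 0.0, 0.8)  # binocular: blue
            p = out_dir / "odm.png"
            plt.imsave(p, rgb)
            written.append(p)
            _save_csv("odm_label", label)
            _save_csv("odm_sum_left", obj.sum_left)
            _save_csv("odm_sum_right", obj.sum_right)
        elif name == "preference":
            p = out_dir / "preference.png"
            plt.imsave(p, np.asarray(obj) % 180.0, cmap="hsv", vmin=0.0, vmax=180.0)
            written.append(p)
            _save_csv("preference", obj)
        elif name in ("selectivity", "gradient"):
            p = out_dir / f"{name}.png"
            arr = np.asarray(obj, dtype=float)
            plt.imsave(p, arr, cmap="gray")
            written.append(p)
            _save_csv(name, arr)
        else:
            _save_csv(name, obj)
    return written
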