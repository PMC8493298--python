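"""Artifact persistence: HDF5 snapshot container, VTK export, reports.

One HDF5 file per pipeline run holds every stage's artifacts (design,
trajectories, POD bases, network parameters, evaluation report), so any
stage can be resumed from the container.  Field snapshots are exported for
visualization as legacy-ASCII VTK structured grids of point samples on a
uniform evaluation grid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .nn import MLP
from .pod import PODBasis
from .rom import MinMaxStats, ROMNetworks
from .solver import Trajectory
from .splines import SplineSpace, evaluate_basis

__all__ = [
    "save_design", "load_design",
    "save_trajectories", "load_trajectories",
    "save_basis", "load_basis",
    "save_networks", "load_networks",
    "save_report", "load_report",
    "write_vtk_grid", "write_report_csv",
]


# --------------------------------------------------------------------------
# HDF5 stages
# --------------------------------------------------------------------------

def save_design(f: h5py.File, mus_train: np.ndarray, mus_test: np.ndarray) -> None:
    g = f.require_group("design")
    for name, arr in (("mu_train", mus_train), ("mu_test", mus_test)):
        if name in g:
            del g[name]
        g.create_dataset(name, data=arr)


def load_design(f: h5py.File):
    g = f["design"]
    return g["mu_train"][()], g["mu_test"][()]


def save_trajectories(f: h5py.File, group: str, trajs: Sequence[Trajectory]) -> None:
    if group in f:
        del f[group]
    g = f.create_group(group)
    for i, tr in enumerate(trajs):
        sub = g.create_group(f"{i:04d}")
        sub.create_dataset("u", data=tr.u)
        sub.create_dataset("ue", data=tr.ue)
        sub.create_dataset("times", data=tr.times)
        if "w_quad" in tr.meta:
            sub.create_dataset("w_quad", data=tr.meta["w_quad"])
        if tr.mu is not None:
            sub.create_dataset("mu", data=tr.mu)


def load_trajectories(f: h5py.File, group: str) -> list[Trajectory]:
    out = []
    for key in sorted(f[group]):
        sub = f[group][key]
        out.append(Trajectory(
            mu=sub["mu"][()] if "mu" in sub else None,
            times=sub["times"][()],
            u=sub["u"][()],
            ue=sub["ue"][()],
        ))
    return out


def save_basis(f: h5py.File, basis: PODBasis) -> None:
    g = f.require_group(f"pod/{basis.channel}")
    for name, arr in (("V", basis.V), ("sigma", basis.sigma)):
        if name in g:
            del g[name]
        g.create_dataset(name, data=arr)
    g.attrs.update(N=basis.N, seed=basis.seed, channel=basis.channel,
                   oversampling=basis.oversampling, n_power_iter=basis.n_power_iter)


def load_basis(f: h5py.File, channel: str) -> PODBasis:
    g = f[f"pod/{channel}"]
    return PODBasis(
        V=g["V"][()], sigma=g["sigma"][()], channel=channel,
        oversampling=int(g.attrs["oversampling"]),
        n_power_iter=int(g.attrs["n_power_iter"]), seed=int(g.attrs["seed"]),
    )


def _save_mlp(g: h5py.Group, name: str, net: MLP) -> None:
    sub = g.create_group(name)
    sub.attrs["sizes"] = net.sizes
    for i, (w, b) in enumerate(zip(net.weights, net.biases)):
        sub.create_dataset(f"W{i}", data=w)
        sub.create_dataset(f"b{i}", data=b)


def _load_mlp(g: h5py.Group, name: str) -> MLP:
    sub = g[name]
    net = MLP(tuple(int(s) for s in sub.attrs["sizes"]), np.random.default_rng(0))
    for i in range(len(net.weights)):
        net.weights[i][...] = sub[f"W{i}"][()]
        net.biases[i][...] = sub[f"b{i}"][()]
    return net


def save_networks(f: h5py.File, nets: ROMNetworks, history: dict | None = None) -> None:
    if "networks" in f:
        del f["networks"]
    g = f.create_group("networks")
    g.attrs.update(n=nets.n, N=nets.N, d=nets.d,
                   decoder_fourier_modes=nets.decoder_fourier_modes)
    g.attrs["channels"] = list(nets.channel_names)
    for name, net in (("encoder", nets.encoder), ("dfnn", nets.dfnn),
                      ("decoder", nets.decoder)):
        _save_mlp(g, name, net)
    g.create_dataset("input_mins", data=nets.input_stats.mins)
    g.create_dataset("input_maxs", data=nets.input_stats.maxs)
    for ch in nets.channel_names:
        g.create_dataset(f"out_mins_{ch}", data=nets.output_stats[ch].mins)
        g.create_dataset(f"out_maxs_{ch}", data=nets.output_stats[ch].maxs)
    if history is not None:
        g.create_dataset("loss_train", data=np.asarray(history["train"]))
        g.create_dataset("loss_val", data=np.asarray(history["val"]))
        g.attrs["best_epoch"] = history.get("best_epoch", -1)


def load_networks(f: h5py.File) -> ROMNetworks:
    g = f["networks"]
    channels = tuple(str(c) for c in g.attrs["channels"])
    return ROMNetworks(
        encoder=_load_mlp(g, "encoder"),
        dfnn=_load_mlp(g, "dfnn"),
        decoder=_load_mlp(g, "decoder"),
        n=int(g.attrs["n"]), N=int(g.attrs["N"]), d=int(g.attrs["d"]),
        decoder_fourier_modes=int(g.attrs.get("decoder_fourier_modes", 0)),
        channel_names=channels,
        input_stats=MinMaxStats(mins=g["input_mins"][()], maxs=g["input_maxs"][()]),
        output_stats={
            ch: MinMaxStats(mins=g[f"out_mins_{ch}"][()], maxs=g[f"out_maxs_{ch}"][()])
            for ch in channels
        },
    )


def save_report(f: h5py.File, report: dict) -> None:
    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer, np.bool_)):
            return obj.item()
        return obj

    payload = json.dumps(_clean(report))
    if "report" in f.attrs:
        del f.attrs["report"]
    f.attrs["report"] = payload


def load_report(f: h5py.File) -> dict:
    return json.loads(f.attrs["report"])


# --------------------------------------------------------------------------
# VTK and CSV exports
# --------------------------------------------------------------------------

def write_vtk_grid(
    path: str | Path,
    space: SplineSpace,
    fields: dict,
    resolution: tuple[int, int] = (101, 21),
) -> None:
    """Sample coefficient vectors on a uniform grid; write legacy-ASCII VTK.

    ``fields`` maps names to coefficient vectors of length N_h.
    """
    nx, ny = resolution
    (x0, x1), (y0, y1) = space.extents
    xs = np.linspace(x0, x1, nx)
    ys = np.linspace(y0, y1, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel()])
    B, _, _ = evaluate_basis(space, pts)
    lines = [
        "# vtk DataFile Version 3.0",
        "cardiorom field export",
        "ASCII",
        "DATASET STRUCTURED_POINTS",
        f"DIMENSIONS {nx} {ny} 1",
        f"ORIGIN {x0} {y0} 0",
        f"SPACING {(x1 - x0) / max(nx - 1, 1)} {(y1 - y0) / max(ny - 1, 1)} 1",
        f"POINT_DATA {nx * ny}",
    ]
    for name, coeffs in fields.items():
        vals = (B @ np.asarray(coeffs)).reshape(nx, ny)
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        # VTK structured points expect x varying fastest
        lines.extend(" ".join(f"{v:.9g}" for v in vals[:, j]) for j in range(ny))
    Path(path).write_text("\n".join(lines) + "\n")


def write_report_csv(path: str | Path, report: dict) -> None:
    """Flat CSV summary: one row per (channel, quantity)."""
    rows = ["channel,quantity,value"]
    for ch, v in report.get("epsilon_rel", {}).items():
        rows.append(f"{ch},epsilon_rel,{v}")
    for ch, v in report.get("projection_epsilon_rel", {}).items():
        rows.append(f"{ch},projection_epsilon_rel,{v}")
    for ch, means in report.get("epsilon_k_mean", {}).items():
        rows.append(f"{ch},epsilon_k_mean_max,{np.max(means)}")
        rows.append(f"{ch},epsilon_k_mean_avg,{np.mean(means)}")
    Path(path).write_text("\n".join(rows) + "\n")
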