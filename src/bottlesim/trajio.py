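"""Plain-text trajectory files and run manifests.

Format: header lines prefixed with ``#`` carrying the time step, frame
stride, geometry, model parameters, seed and the interpolated exit times,
followed by whitespace-separated data rows ``id frame x y`` (frames
0-based, positions in metres, fixed 4-decimal precision). The same dialect
is read back into a :class:`~bottlesim.dynamics.Trajectory`, so every
measurement can be run on files as well as on in-process runs.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np

from .dynamics import ModelParams, Trajectory

_FMT_VERSION = 1

_FLOAT_KEYS = {
    "dt",
    "b",
    "l_c",
    "w_e",
    "exit_depth",
    "v0",
    "l",
    "T",
    "sigma",
    "dh",
    "d_w",
    "g",
    "rho_i",
}
_INT_KEYS = {"stride", "seed", "n_agents", "format"}
_BOOL_KEYS = {"sigma_is_variance"}


class TrajectoryFormatError(ValueError):
    pass


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    p = traj.params
    lines = [f"# bottlesim trajectory format {_FMT_VERSION}"]
    kv: dict = {
        "dt": p.dt,
        "stride": traj.stride,
        "n_agents": traj.n_agents,
        "v0": p.v0,
        "l": p.l,
        "T": p.T,
        "sigma": p.sigma,
        "sigma_is_variance": int(p.sigma_is_variance),
    }
    if traj.seed is not None:
        kv["seed"] = traj.seed
    kv.update(traj.geometry_config)
    kv.update(traj.meta)
    for key, val in kv.items():
        lines.append(f"# {key} {val}")
    for i, t in enumerate(traj.exit_times):
        if np.isfinite(t):
            lines.append(f"# exit {i} {t:.6f}")
    lines.append("# columns id frame x y")
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        for f in range(len(traj.times)):
            pos = traj.positions[f]
            for i in np.nonzero(~np.isnan(pos[:, 0]))[0]:
                fh.write(f"{i} {f} {pos[i, 0]:.4f} {pos[i, 1]:.4f}\n")


def read_trajectory(path: str | Path) -> Trajectory:
    """Parse a trajectory file; corrupt rows are reported with line numbers."""
    path = Path(path)
    meta: dict = {}
    exit_list: list[tuple[int, float]] = []
    rows: list[tuple[int, int, float, float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if not parts:
                    continue
                if parts[0] == "exit" and len(parts) == 3:
                    exit_list.append((int(parts[1]), float(parts[2])))
                elif len(parts) == 2:
                    key, val = parts
                    if key in _FLOAT_KEYS:
                        meta[key] = float(val)
                    elif key in _INT_KEYS:
                        meta[key] = int(val)
                    elif key in _BOOL_KEYS:
                        meta[key] = bool(int(val))
                    else:
                        meta[key] = val
                continue
            parts = line.split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"{path}:{lineno}: expected 'id frame x y', got {line!r}"
                )
            try:
                rows.append(
                    (int(parts[0]), int(parts[1]), float(parts[2]), float(parts[3]))
                )
            except ValueError as exc:
                raise TrajectoryFormatError(f"{path}:{lineno}: {exc}") from exc
    if "dt" not in meta:
        raise TrajectoryFormatError(f"{path}: missing dt header")
    dt = meta["dt"]
    stride = int(meta.get("stride", 1))
    n_frames = max(r[1] for r in rows) + 1 if rows else 0
    n_agents = int(meta.get("n_agents", (max(r[0] for r in rows) + 1) if rows else 0))
    positions = np.full((n_frames, n_agents, 2), np.nan)
    for i, f, x, y in rows:
        if i >= n_agents or f >= n_frames:
            raise TrajectoryFormatError(f"{path}: id/frame out of range ({i}, {f})")
        positions[f, i] = (x, y)
    exit_times = np.full(n_agents, np.nan)
    for i, t in exit_list:
        exit_times[i] = t
    params = ModelParams(
        v0=meta.get("v0", 1.34),
        l=meta.get("l", 0.35),
        T=meta.get("T", 1.3),
        sigma=meta.get("sigma", 0.7),
        dt=dt,
        sigma_is_variance=meta.get("sigma_is_variance", True),
    )
    geometry_config = {
        k: meta[k] for k in ("variant", "b", "l_c", "w_e", "exit_depth") if k in meta
    }
    extra = {
        k: v
        for k, v in meta.items()
        if k
        not in {
            "dt",
            "stride",
            "n_agents",
            "seed",
            "v0",
            "l",
            "T",
            "sigma",
            "sigma_is_variance",
            "columns",
            "bottlesim",
            "format",
        }
        and k not in geometry_config
    }
    times = np.arange(n_frames) * dt * stride
    return Trajectory(
        dt=dt,
        stride=stride,
        times=times,
        positions=positions,
        exit_times=exit_times,
        params=params,
        geometry_config=geometry_config,
        seed=meta.get("seed"),
        meta=extra,
    )


def config_hash(config_dict: dict) -> str:
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(
    path: str | Path,
    config_dict: dict,
    seed: int | None,
    outputs: list[str],
    geometry_summary: dict | None = None,
    extra: dict | None = None,
) -> dict:
    """JSON manifest tying outputs to the exact configuration that made them."""
    from . import __version__

    manifest = {
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "seed": seed,
        "code_version": __version__,
        "geometry": geometry_summary or {},
        "outputs": outputs,
        "written_at_unix": time.time(),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
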