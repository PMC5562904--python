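"""Reading and writing phase series and simulation configs.

Phase series travel as delimited text: a header row of channel names, one
row per observation.  The sampling step delta is not stored in the table
itself but in a JSON metadata sidecar (``<file>.meta.json``) written next
to the data, or supplied explicitly by the caller.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .sim import OscillatorSystemSpec, PhaseTrajectory

__all__ = ["read_phase_file", "write_trajectory", "load_config", "spec_from_config"]


def read_phase_file(path, delta: Optional[float] = None, delimiter: Optional[str] = None):
    """Read a delimited multichannel series; returns (DataFrame, delta or None).

    delta is taken from the argument if given, else from a metadata sidecar.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, engine="python" if delimiter is None else "c")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if delta is None and meta_path.exists():
        delta = json.loads(meta_path.read_text()).get("delta")
    return df, delta


def write_trajectory(path, traj: PhaseTrajectory, channel_names=None,
                     metadata: Optional[dict] = None, delimiter: str = ",") -> None:
    """Write a trajectory as delimited text plus a JSON metadata sidecar."""
    path = Path(path)
    names = channel_names or [f"phi{k + 1}" for k in range(traj.p)]
    cols = {n: traj.phi[:, k] for k, n in enumerate(names)}
    if traj.gamma is not None:
        for k, n in enumerate(names):
            cols[n.replace("phi", "gamma") if "phi" in n else f"gamma_{n}"] = traj.gamma[:, k]
    pd.DataFrame(cols).to_csv(path, sep=delimiter, index=False)
    meta = {"delta": traj.delta, "t0": traj.t0}
    if metadata:
        meta.update(metadata)
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def spec_from_config(cfg: Union[dict, str, Path]) -> OscillatorSystemSpec:
    """Build an :class:`OscillatorSystemSpec` from a config mapping or file.

    Keys: either ``pi`` (matrix) or ``alpha`` + ``beta`` (factor form);
    ``mu`` or ``kappa``; optional ``omega``, ``sigma_phi``, ``sigma_gamma``,
    ``dt_fine``, ``dt_obs``, ``T``, ``seed``, ``z0``.
    """
    if not isinstance(cfg, dict):
        cfg = load_config(cfg)
    if "pi" in cfg:
        Pi = np.asarray(cfg["pi"], dtype=float)
    elif "alpha" in cfg and "beta" in cfg:
        a = np.atleast_2d(np.asarray(cfg["alpha"], dtype=float))
        b = np.atleast_2d(np.asarray(cfg["beta"], dtype=float))
        if a.shape[0] == 1:
            a = a.T
        if b.shape[0] == 1:
            b = b.T
        Pi = a @ b.T
    else:
        raise ValueError("config must declare 'pi' or both 'alpha' and 'beta'")
    p = Pi.shape[0]
    kwargs = dict(
        p=p, Pi=Pi,
        kappa=cfg.get("kappa"), mu=cfg.get("mu"), omega=cfg.get("omega"),
        sigma_phi=cfg.get("sigma_phi", 0.0), sigma_gamma=cfg.get("sigma_gamma", 0.0),
        dt_fine=cfg.get("dt_fine", 2e-4), dt_obs=cfg.get("dt_obs", 0.1),
        T=cfg.get("T", 200.0), seed=cfg.get("seed", 0),
    )
    if "z0" in cfg:
        z0 = np.asarray(cfg["z0"], dtype=float).reshape(p, 2)
        kwargs["phi0"] = np.arctan2(z0[:, 1], z0[:, 0])
        kwargs["gamma0"] = np.hypot(z0[:, 0], z0[:, 1])
    return OscillatorSystemSpec(**kwargs)
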