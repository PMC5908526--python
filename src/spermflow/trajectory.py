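"""Trajectory persistence (HDF5) and bit-exact checkpoint/restart.

Layout of a trajectory file:

    /bodies/pos      (n_t, S, B, 2)   body positions, head first
    /bodies/theta    (n_t, S, B)      orientation angles
    /swimmers/com    (n_t, S, 2)      centres of mass
    /swimmers/Phi    (n_t, S)         integrated drive phases
    /swimmers/omega  (n_t, S)         current frequencies
    /swimmers/phi    (S,)             static phase offsets
    /forces/fluid    (n_t, S, B, 2)   forces exerted on the fluid (optional)
    /diag/*          per-frame solver diagnostics
    /meta            config TOML, seeds, schema version, code version

Checkpoints additionally hold the one-step BDF2 history and the frequency
RNG state, so a restarted run continues bit-exactly for deterministic
backends.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from . import __version__
from .system import PlanarSystem

__all__ = ["TrajectoryWriter", "read_trajectory", "save_checkpoint",
           "load_checkpoint"]

SCHEMA_VERSION = 1


class TrajectoryWriter:
    """Incremental trajectory writer; usable as a run observer."""

    def __init__(self, path, system: PlanarSystem, *,
                 store_forces: bool = True, config_text: str = ""):
        self.path = path
        self.store_forces = store_forces
        self._fh = h5py.File(path, "w")
        S, B = system.S, system.B
        m = self._fh.create_group("meta")
        m.attrs["schema_version"] = SCHEMA_VERSION
        m.attrs["code_version"] = __version__
        m.attrs["config"] = config_text
        self._fh.create_dataset("swimmers/phi", data=system.phi)
        self._fh.create_dataset("time", shape=(0,), maxshape=(None,),
                                dtype="f8")
        spec = {
            "bodies/pos": (S, B, 2), "bodies/theta": (S, B),
            "swimmers/com": (S, 2), "swimmers/Phi": (S,),
            "swimmers/omega": (S,),
            "diag/iterations": (), "diag/constraint_max": (),
        }
        if store_forces:
            spec["forces/fluid"] = (S, B, 2)
            spec["forces/torque_z"] = (S, B)
        self._ds = {}
        for name, shape in spec.items():
            self._ds[name] = self._fh.create_dataset(
                name, shape=(0,) + shape, maxshape=(None,) + shape,
                dtype="f8", chunks=(64,) + shape if shape else (1024,))

    def append(self, system: PlanarSystem, diag=None) -> None:
        n = self._fh["time"].shape[0]
        self._fh["time"].resize(n + 1, axis=0)
        self._fh["time"][n] = system.t
        vals = {
            "bodies/pos": system.x, "bodies/theta": system.th,
            "swimmers/com": system.com(), "swimmers/Phi": system.Phi,
            "swimmers/omega": system.omega,
            "diag/iterations": diag.iterations if diag else 0,
            "diag/constraint_max": diag.constraint_max if diag else np.nan,
        }
        if self.store_forces and diag is not None:
            vals["forces/fluid"] = diag.F_fluid
            vals["forces/torque_z"] = diag.Tz_fluid
        for name, v in vals.items():
            ds = self._ds[name]
            ds.resize(n + 1, axis=0)
            ds[n] = v

    # observer protocol
    def __call__(self, system, diag) -> None:
        self.append(system, diag)

    def close(self) -> None:
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def read_trajectory(path) -> dict:
    """Load a trajectory file into arrays; refuses mismatched schemas."""
    out = {}
    with h5py.File(path, "r") as fh:
        ver = fh["meta"].attrs.get("schema_version", -1)
        if ver != SCHEMA_VERSION:
            raise ValueError(
                f"trajectory schema version {ver} != {SCHEMA_VERSION}")
        out["config"] = fh["meta"].attrs.get("config", "")
        out["code_version"] = fh["meta"].attrs.get("code_version", "")

        def visit(name, obj):
            if isinstance(obj, h5py.Dataset):
                out[name] = obj[...]
        fh.visititems(visit)
    return out


def save_checkpoint(path, system: PlanarSystem, stepper=None,
                    freq_rng: np.random.Generator | None = None) -> None:
    """Full restartable state: configuration, multipliers, BDF2 history."""
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["t"] = system.t
        fh.attrs["nstep"] = system.nstep
        for name in ("x", "th", "phi", "Phi", "omega", "Lam", "mu"):
            fh.create_dataset(name, data=getattr(system, name))
        if stepper is not None and stepper._prev is not None:
            fh.create_dataset("prev_x", data=stepper._prev[0])
            fh.create_dataset("prev_th", data=stepper._prev[1])
        if stepper is not None:
            # quasi-Newton internals: required for bit-exact continuation,
            # since the converged state depends (within tolerance) on the
            # iteration path
            if stepper._lu is not None:
                fh.create_dataset("jac_lu", data=np.stack(
                    [lu for lu, _ in stepper._lu]))
                fh.create_dataset("jac_piv", data=np.stack(
                    [piv for _, piv in stepper._lu]))
            us, ys = stepper._memory
            if us:
                fh.create_dataset("secant_u", data=np.stack(us))
                fh.create_dataset("secant_y", data=np.stack(ys))
        if freq_rng is not None:
            fh.attrs["rng_state"] = json.dumps(
                freq_rng.bit_generator.state)


def load_checkpoint(path, params, grid):
    """Restore (system, prev_history, freq_rng, solver_state).

    ``solver_state`` holds the quasi-Newton seed Jacobian factors and
    secant memory when present; assign them onto a fresh Stepper to
    continue bit-exactly.
    """
    with h5py.File(path, "r") as fh:
        if fh.attrs["schema_version"] != SCHEMA_VERSION:
            raise ValueError("checkpoint schema version mismatch")
        system = PlanarSystem(
            params=params, grid=grid,
            x=fh["x"][...], th=fh["th"][...], phi=fh["phi"][...],
            Phi=fh["Phi"][...], omega=fh["omega"][...],
            Lam=fh["Lam"][...], mu=fh["mu"][...],
            t=float(fh.attrs["t"]), nstep=int(fh.attrs["nstep"]))
        prev = None
        if "prev_x" in fh:
            prev = (fh["prev_x"][...], fh["prev_th"][...])
        solver_state = {}
        if "jac_lu" in fh:
            solver_state["lu"] = [
                (fh["jac_lu"][s], fh["jac_piv"][s])
                for s in range(fh["jac_lu"].shape[0])]
        if "secant_u" in fh:
            solver_state["memory"] = (list(fh["secant_u"][...]),
                                      list(fh["secant_y"][...]))
        rng = None
        if "rng_state" in fh.attrs:
            rng = np.random.default_rng()
            rng.bit_generator.state = json.loads(fh.attrs["rng_state"])
    return system, prev, rng, solver_state
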