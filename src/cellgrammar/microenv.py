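"""Reaction–diffusion microenvironment on a regular 2-D voxel mesh.

Each substrate obeys  ∂ρ/∂t = D ∇²ρ − λρ  plus cell-coupled secretion
and uptake at agent positions. Diffusion is advanced by operator
splitting: implicit (backward-Euler) tridiagonal solves along each axis
followed by an exact exponential decay factor — unconditionally stable
for any time step, mass-conserving under no-flux boundaries, and
non-negativity-preserving.

The mesh is 2-D (the z direction is collapsed to one voxel of the given
thickness); concentrations are stored as (ny, nx) arrays indexed
[row=y, col=x].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import solve_banded

__all__ = ["Substrate", "Microenvironment"]


@dataclass
class Substrate:
    """One diffusing, decaying extracellular substrate."""

    name: str
    diffusion: float            # um^2/min
    decay: float                # 1/min
    initial: float = 0.0
    boundary: str = "no-flux"   # "no-flux" or "dirichlet"
    boundary_value: Optional[float] = None
    secretion_saturation: float = 1.0  # default target density rho* for secretion
    dt: Optional[float] = None  # per-substrate sub-step for stiff uptake (min)

    def __post_init__(self) -> None:
        if self.boundary not in ("no-flux", "dirichlet"):
            raise ValueError(f"unknown boundary condition {self.boundary!r}")
        if self.boundary == "dirichlet" and self.boundary_value is None:
            self.boundary_value = self.initial


class Microenvironment:
    """Rectangular voxel mesh of diffusing substrates.

    Parameters
    ----------
    bounds : (xmin, xmax, ymin, ymax) in um.
    voxel_size : um; the mesh is (ny, nx) voxels of this pitch (default 20).
    thickness : um; collapsed z extent used for voxel volume.
    """

    def __init__(self, bounds, voxel_size: float = 20.0, thickness: float = 20.0):
        if voxel_size <= 0:
            raise ValueError(f"voxel size must be positive, got {voxel_size}")
        self.xmin, self.xmax, self.ymin, self.ymax = map(float, bounds)
        if self.xmax <= self.xmin or self.ymax <= self.ymin:
            raise ValueError("empty domain")
        self.voxel_size = float(voxel_size)
        self.thickness = float(thickness)
        self.nx = max(1, int(round((self.xmax - self.xmin) / voxel_size)))
        self.ny = max(1, int(round((self.ymax - self.ymin) / voxel_size)))
        self.substrates: dict[str, Substrate] = {}
        self.fields: dict[str, np.ndarray] = {}
        self._banded_cache: dict = {}

    @property
    def voxel_volume(self) -> float:
        return self.voxel_size**2 * self.thickness

    def add_substrate(self, sub: Substrate) -> None:
        if sub.name in self.substrates:
            raise ValueError(f"duplicate substrate {sub.name!r}")
        self.substrates[sub.name] = sub
        self.fields[sub.name] = np.full((self.ny, self.nx), float(sub.initial))

    # -- position <-> voxel ------------------------------------------------

    def voxel_index(self, position) -> tuple[int, int]:
        """(row, col) of the voxel containing the position; errors outside."""
        x, y = float(position[0]), float(position[1])
        if not (self.xmin <= x <= self.xmax and self.ymin <= y <= self.ymax):
            raise ValueError(f"position {position} outside domain")
        i = min(int((y - self.ymin) / self.voxel_size), self.ny - 1)
        j = min(int((x - self.xmin) / self.voxel_size), self.nx - 1)
        return i, j

    def voxel_indices(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized voxel lookup; positions are clipped into the domain."""
        p = np.asarray(positions, dtype=float)
        j = np.clip(((p[:, 0] - self.xmin) / self.voxel_size).astype(int), 0, self.nx - 1)
        i = np.clip(((p[:, 1] - self.ymin) / self.voxel_size).astype(int), 0, self.ny - 1)
        return i, j

    def sample(self, position) -> dict[str, float]:
        """Per-substrate concentration at the containing voxel."""
        i, j = self.voxel_index(position)
        return {name: float(f[i, j]) for name, f in self.fields.items()}

    def sample_field(self, name: str, positions: np.ndarray) -> np.ndarray:
        i, j = self.voxel_indices(positions)
        return self.fields[name][i, j]

    def gradient(self, position) -> dict[str, np.ndarray]:
        """Per-substrate (d/dx, d/dy) by central differences (one-sided at
        the boundary)."""
        i, j = self.voxel_index(position)
        out = {}
        for name, f in self.fields.items():
            gy, gx = np.gradient(f, self.voxel_size)
            out[name] = np.array([gx[i, j], gy[i, j]])
        return out

    def gradient_field(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """Full-mesh (gx, gy) arrays for one substrate."""
        gy, gx = np.gradient(self.fields[name], self.voxel_size)
        return gx, gy

    # -- diffusion ---------------------------------------------------------

    def _banded(self, n: int, alpha: float, boundary: str) -> np.ndarray:
        """Banded (ab) form of I - alpha * L for one 1-D sweep."""
        key = (n, alpha, boundary)
        ab = self._banded_cache.get(key)
        if ab is not None:
            return ab
        ab = np.zeros((3, n))
        ab[0, 1:] = -alpha          # upper diagonal
        ab[1, :] = 1.0 + 2.0 * alpha
        ab[2, :-1] = -alpha         # lower diagonal
        if boundary == "no-flux":
            ab[1, 0] = 1.0 + alpha
            ab[1, -1] = 1.0 + alpha
        else:  # dirichlet: boundary rows pinned to their current value
            ab[1, 0] = 1.0
            ab[0, 1] = 0.0
            ab[1, -1] = 1.0
            ab[2, -2] = 0.0
        self._banded_cache[key] = ab
        return ab

    def step_substrate(self, name: str, dt: float) -> None:
        """One operator-split diffusion-decay step for one substrate."""
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        sub = self.substrates[name]
        f = self.fields[name]
        h2 = self.voxel_size**2
        if sub.boundary == "dirichlet":
            f[0, :] = f[-1, :] = sub.boundary_value
            f[:, 0] = f[:, -1] = sub.boundary_value
        if sub.diffusion > 0 and (self.nx > 1 or self.ny > 1):
            alpha = sub.diffusion * dt / h2
            if self.nx > 1:
                ab = self._banded(self.nx, alpha, sub.boundary)
                f[:] = solve_banded((1, 1), ab, f.T).T
            if self.ny > 1:
                ab = self._banded(self.ny, alpha, sub.boundary)
                f[:] = solve_banded((1, 1), ab, f)
        if sub.decay > 0:
            f *= np.exp(-sub.decay * dt)
        if sub.boundary == "dirichlet":
            f[0, :] = f[-1, :] = sub.boundary_value
            f[:, 0] = f[:, -1] = sub.boundary_value
        np.maximum(f, 0.0, out=f)

    def step_diffusion(self, dt: float) -> None:
        """One operator-split diffusion-decay step for every substrate."""
        if dt <= 0:
            raise ValueError(f"dt must be positive, got {dt}")
        for name in self.substrates:
            self.step_substrate(name, dt)

    # -- cell coupling -----------------------------------------------------

    def apply_sources_sinks_arrays(self, positions, volumes, secretion, uptake,
                                   saturation, dt: float) -> None:
        """Vectorized per-voxel implicit secretion/uptake update.

        ``secretion``, ``uptake``, ``saturation`` map substrate name ->
        per-agent arrays (1/min, 1/min, concentration). Per voxel the
        agent terms are pooled and the update is
        rho <- (rho + dt f Σ S_k rho*_k) / (1 + dt f Σ (S_k + U_k)),
        with f = V_cell/V_voxel — monotone and never negative.
        """
        if len(positions) == 0:
            return
        i, j = self.voxel_indices(np.asarray(positions, dtype=float))
        flat = i * self.nx + j
        fvol = np.asarray(volumes, dtype=float) / self.voxel_volume
        for name in self.substrates:
            self.apply_sources_sinks_one(
                name, flat, fvol, secretion.get(name), uptake.get(name),
                saturation.get(name), dt)

    def apply_sources_sinks_one(self, name: str, flat_voxels, volume_fraction,
                                S, U, rho_star, dt: float) -> None:
        """Pooled implicit secretion/uptake update for one substrate.

        ``flat_voxels`` are the agents' flattened voxel indices and
        ``volume_fraction`` their V_cell/V_voxel ratios.
        """
        if S is None and U is None:
            return
        n = len(flat_voxels)
        S = np.zeros(n) if S is None else np.asarray(S, dtype=float)
        U = np.zeros(n) if U is None else np.asarray(U, dtype=float)
        if not (np.any(S) or np.any(U)):
            return
        if rho_star is None:
            rho_star = np.full(n, self.substrates[name].secretion_saturation)
        else:
            rho_star = np.asarray(rho_star, dtype=float)
        nvox = self.nx * self.ny
        num = np.bincount(flat_voxels, weights=volume_fraction * S * rho_star,
                          minlength=nvox)
        den = np.bincount(flat_voxels, weights=volume_fraction * (S + U),
                          minlength=nvox)
        f = self.fields[name]
        f[:] = ((f.ravel() + dt * num) / (1.0 + dt * den)).reshape(f.shape)

    def apply_sources_sinks(self, agents, dt: float) -> None:
        """Per-agent secretion/uptake from the agents' working phenotypes."""
        agents = list(agents)
        if not agents:
            return
        positions = np.array([a.position for a in agents], dtype=float)
        volumes = np.array([a.volume for a in agents], dtype=float)
        secretion, uptake, saturation = {}, {}, {}
        for name, sub in self.substrates.items():
            secretion[name] = np.array(
                [a.get_phenotype(f"{name} secretion", 0.0) for a in agents])
            uptake[name] = np.array(
                [a.get_phenotype(f"{name} uptake", 0.0) for a in agents])
            saturation[name] = np.array(
                [a.get_phenotype(f"{name} secretion target", sub.secretion_saturation)
                 for a in agents])
        self.apply_sources_sinks_arrays(positions, volumes, secretion, uptake,
                                        saturation, dt)

    # -- output ------------------------------------------------------------

    def total_mass(self, name: str) -> float:
        return float(self.fields[name].sum() * self.voxel_volume)

    def save_grids(self, directory, tag: str) -> list[str]:
        """Write each substrate field as a dense CSV grid; returns paths."""
        import os

        paths = []
        os.makedirs(directory, exist_ok=True)
        for name, f in self.fields.items():
            safe = name.replace(" ", "_").replace("/", "-")
            path = os.path.join(directory, f"substrate_{safe}_{tag}.csv")
            np.savetxt(path, f, delimiter=",")
            paths.append(path)
        return paths
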