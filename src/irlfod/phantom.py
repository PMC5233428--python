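"""Multi-tensor crossing-fiber phantoms with an isotropic compartment.

Each voxel mixes axially symmetric Gaussian-tensor fiber signals with a free
isotropic compartment and magnitude (Rician) noise:

    S(g) = S0 [ sum_k w_k exp(-b g^T D_k g) + w_iso exp(-b MD) ],

with the fiber tensors sharing eigenvalues (default (1.7, 0.2, 0.2)e-3
mm^2/s, mean diffusivity 0.7e-3) and ``sum_k w_k + w_iso = 1``.  Noise is
applied to the mixed signal: |S + n_re + i n_im| with n ~ N(0, sigma^2) and
sigma = S0 / SNR.

The two standard experiment layouts are homogeneous patches (one noise draw
per voxel, standing in for noise repetitions while letting spatial
regularizers act as on an image) and the 11x11 grid sweeping isotropic
fraction 0.1..1.0 along x against SNR 10..30 along y.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .dwio import DwiVolume, GradientTable
from .sphere import gradient_scheme_81

__all__ = [
    "PhantomSpec",
    "NoiseSpec",
    "GroundTruth",
    "tensor_signal",
    "axial_tensor",
    "simulate_voxel",
    "add_rician_noise",
    "make_patch",
    "make_pve_snr_grid",
    "make_angle_series",
    "default_gradient_table",
]

DEFAULT_MD = 0.7e-3                      # mm^2/s, fixed by the simulation design
DEFAULT_EIGENVALUES = (1.7e-3, 0.2e-3, 0.2e-3)
NOISE_FREE_SNR = 1e12


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth configuration of a single simulated voxel."""

    fiber_directions: np.ndarray          # (K, 3) unit vectors
    fiber_weights: np.ndarray             # (K,) nonnegative
    iso_fraction: float
    b_value: float = 3000.0               # s/mm^2
    mean_diffusivity: float = DEFAULT_MD  # mm^2/s
    anisotropic_eigenvalues: tuple = DEFAULT_EIGENVALUES
    S0: float = 1.0

    def __post_init__(self):
        dirs = np.atleast_2d(np.asarray(self.fiber_directions, dtype=float))
        if dirs.size:
            dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        w = np.atleast_1d(np.asarray(self.fiber_weights, dtype=float))
        if np.any(w < 0) or self.iso_fraction < 0:
            raise ValueError("volume fractions must be nonnegative")
        if abs(w.sum() + self.iso_fraction - 1.0) > 1e-9:
            raise ValueError("fiber weights and iso fraction must sum to 1")
        ev = np.asarray(self.anisotropic_eigenvalues, dtype=float)
        if ev.shape != (3,) or np.any(ev < 0):
            raise ValueError("anisotropic eigenvalues must be 3 nonnegative values")
        if abs(ev[1] - ev[2]) > 1e-15:
            raise ValueError("fiber tensors must be axially symmetric (l2 == l3)")
        if abs(ev.mean() - self.mean_diffusivity) > 1e-12:
            raise ValueError("eigenvalues must average to mean_diffusivity")
        object.__setattr__(self, "fiber_directions", dirs)
        object.__setattr__(self, "fiber_weights", w)


@dataclass(frozen=True)
class NoiseSpec:
    snr: float
    seed: int = 0

    def __post_init__(self):
        if not self.snr > 0:
            raise ValueError("snr must be positive")


def axial_tensor(direction, eigenvalues) -> np.ndarray:
    """Axially symmetric tensor with principal axis ``direction``."""
    v = np.asarray(direction, dtype=float)
    v = v / np.linalg.norm(v)
    lpar, lperp = eigenvalues[0], eigenvalues[1]
    return lperp * np.eye(3) + (lpar - lperp) * np.outer(v, v)


def tensor_signal(D, b, g):
    """Gaussian-tensor attenuation exp(-b g^T D g)."""
    if np.any(np.asarray(b) < 0):
        raise ValueError("b-value must be nonnegative")
    D = np.asarray(D, dtype=float)
    g = np.asarray(g, dtype=float)
    quad = np.einsum("...i,ij,...j->...", g, D, g)
    return np.exp(-np.asarray(b) * quad)


def simulate_voxel(spec: PhantomSpec, gtab: GradientTable) -> np.ndarray:
    """Noise-free multi-tensor signal for every volume of the gradient table."""
    S = np.empty(len(gtab))
    b0 = gtab.b0_mask
    S[b0] = spec.S0
    b = gtab.bvals[~b0]
    g = gtab.bvecs[~b0]
    sig = spec.iso_fraction * np.exp(-b * spec.mean_diffusivity)
    for w, d in zip(spec.fiber_weights, spec.fiber_directions):
        D = axial_tensor(d, spec.anisotropic_eigenvalues)
        sig = sig + w * tensor_signal(D, b, g)
    S[~b0] = spec.S0 * sig
    return S


def add_rician_noise(S, noise: NoiseSpec, S0: float = 1.0) -> np.ndarray:
    """Magnitude of the complex-Gaussian-corrupted signal, sigma = S0/snr."""
    S = np.asarray(S, dtype=float)
    sigma = S0 / noise.snr
    rng = np.random.default_rng(noise.seed)
    n_re = rng.normal(0.0, sigma, S.shape)
    n_im = rng.normal(0.0, sigma, S.shape)
    return np.hypot(S + n_re, n_im)


# ---------------------------------------------------------------------------
# ground truth container
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Per-voxel true fiber directions and fractions for a phantom image."""

    directions: np.ndarray    # (nx, ny, nz, K, 3); zero rows where fewer fibers
    weights: np.ndarray       # (nx, ny, nz, K)
    iso_fraction: np.ndarray  # (nx, ny, nz)
    snr: np.ndarray           # (nx, ny, nz)

    def voxel_directions(self, idx) -> np.ndarray:
        """True directions at a voxel, dropping zero-weight entries."""
        w = self.weights[idx]
        return self.directions[idx][w > 0]

    def to_json(self, path) -> None:
        payload = {
            "directions": self.directions.tolist(),
            "weights": self.weights.tolist(),
            "iso_fraction": self.iso_fraction.tolist(),
            "snr": self.snr.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**{k: np.asarray(v, dtype=float) for k, v in payload.items()})


def default_gradient_table(b: float = 3000.0) -> GradientTable:
    """One b=0 volume followed by the packaged 81-direction shell."""
    dirs = gradient_scheme_81()
    bvals = np.concatenate([[0.0], np.full(len(dirs), float(b))])
    bvecs = np.vstack([np.zeros(3), dirs])
    return GradientTable(bvals, bvecs)


def crossing_directions(crossing_angle: float) -> np.ndarray:
    """Two in-plane fibers symmetric about e_x, separated by crossing_angle."""
    half = np.radians(crossing_angle) / 2.0
    return np.array(
        [[np.cos(half), np.sin(half), 0.0], [np.cos(half), -np.sin(half), 0.0]]
    )


# ---------------------------------------------------------------------------
# experiment layouts
# ---------------------------------------------------------------------------

def _patch_shape(n_voxels: int):
    side = int(np.ceil(np.sqrt(n_voxels)))
    return side, side


def make_patch(spec: PhantomSpec, gtab: GradientTable, snr: float,
               n_voxels: int, seed: int):
    """Homogeneous patch: one configuration, independent noise per voxel.

    Voxels are laid out on the smallest square grid holding ``n_voxels``
    (z-depth 1); surplus grid cells are masked out.
    """
    nx, ny = _patch_shape(n_voxels)
    S = simulate_voxel(spec, gtab)
    noisy = add_rician_noise(
        np.broadcast_to(S, (nx, ny, 1) + S.shape).copy(),
        NoiseSpec(snr=snr, seed=seed), S0=spec.S0,
    )
    mask = np.zeros((nx, ny, 1), dtype=bool)
    mask.flat[:n_voxels] = True
    noisy[~mask] = 0.0
    vol = DwiVolume(noisy, np.eye(4), mask=mask)
    K = max(1, len(spec.fiber_weights))
    dirs = np.zeros((nx, ny, 1, K, 3))
    w = np.zeros((nx, ny, 1, K))
    dirs[mask] = spec.fiber_directions if len(spec.fiber_weights) else 0.0
    w[mask] = spec.fiber_weights
    truth = GroundTruth(
        directions=dirs, weights=w,
        iso_fraction=np.where(mask, spec.iso_fraction, 0.0),
        snr=np.where(mask, snr, 0.0),
    )
    return vol, truth


def make_pve_snr_grid(crossing_angle: float, b: float = 3000.0, seed: int = 0,
                      gtab: GradientTable | None = None):
    """The 11x11 sweep: iso fraction 0.1..1.0 (x) against SNR 10..30 (y).

    Every voxel holds two equal-weight fibers crossing at ``crossing_angle``
    (in-plane, symmetric about e_x) and its own independent noise draw.
    """
    if not 0.0 < crossing_angle <= 90.0:
        raise ValueError("crossing_angle must be in (0, 90] degrees")
    if gtab is None:
        gtab = default_gradient_table(b)
    iso_values = np.linspace(0.1, 1.0, 11)
    snr_values = np.arange(10.0, 31.0, 2.0)
    dirs2 = crossing_directions(crossing_angle)
    nx, ny = len(iso_values), len(snr_values)
    data = np.zeros((nx, ny, 1, len(gtab)))
    truth_dirs = np.zeros((nx, ny, 1, 2, 3))
    truth_w = np.zeros((nx, ny, 1, 2))
    truth_iso = np.zeros((nx, ny, 1))
    truth_snr = np.zeros((nx, ny, 1))
    rng = np.random.default_rng(seed)
    for ix, iso in enumerate(iso_values):
        w_ani = (1.0 - iso) / 2.0
        spec = PhantomSpec(dirs2, [w_ani, w_ani], iso_fraction=iso, b_value=b)
        S = simulate_voxel(spec, gtab)
        for iy, snr in enumerate(snr_values):
            voxel_seed = int(rng.integers(0, 2**31 - 1))
            data[ix, iy, 0] = add_rician_noise(S, NoiseSpec(snr, voxel_seed))
            truth_dirs[ix, iy, 0] = dirs2
            truth_w[ix, iy, 0] = [w_ani, w_ani]
            truth_iso[ix, iy, 0] = iso
            truth_snr[ix, iy, 0] = snr
    vol = DwiVolume(data, np.eye(4), mask=np.ones((nx, ny, 1), dtype=bool))
    truth = GroundTruth(truth_dirs, truth_w, truth_iso, truth_snr)
    return vol, truth, gtab


def make_angle_series(angles: Sequence[float], iso_fraction: float = 0.5,
                      b: float = 3000.0, snr: float = 20.0, n_reps: int = 100,
                      seed: int = 0, gtab: GradientTable | None = None) -> List[tuple]:
    """One homogeneous two-fiber patch per crossing angle.

    Returns a list of ``(angle, DwiVolume, GroundTruth)`` tuples; each patch
    holds ``n_reps`` voxels with independent noise.
    """
    if np.any((np.asarray(angles) <= 0) | (np.asarray(angles) > 90)):
        raise ValueError("crossing angles must be in (0, 90] degrees")
    if gtab is None:
        gtab = default_gradient_table(b)
    rng = np.random.default_rng(seed)
    out = []
    for angle in angles:
        dirs = crossing_directions(angle)
        w_ani = (1.0 - iso_fraction) / 2.0
        spec = PhantomSpec(dirs, [w_ani, w_ani], iso_fraction=iso_fraction, b_value=b)
        patch_seed = int(rng.integers(0, 2**31 - 1))
        vol, truth = make_patch(spec, gtab, snr=snr, n_voxels=n_reps, seed=patch_seed)
        out.append((float(angle), vol, truth))
    return out
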