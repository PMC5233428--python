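"""Response matrices, the over-complete fODF dictionary, and the forward map.

The discrete deconvolution model is

    S = R_hat f,        R_hat = [R_ani  R_iso]  (I x (J+1)),
    f  = Phi c,         Phi block-diagonal      ((J+1) x (L+1)),

so the composed forward operator on coefficients is ``A = R_hat Phi``
(I x (L+1)).  ``R_ani[:, j]`` is the attenuation profile of a maximally
anisotropic fiber (FA = 1, i.e. eigenvalues ``(3 MD, 0, 0)``) along sampling
direction ``v_j``; ``R_iso`` is the free-diffusion profile ``exp(-b MD)``
(FA = 0), both with MD = 0.7e-3 mm^2/s.

The dictionary atoms are antipodally symmetric double-lobe kernels
``d(v, u_l) = k(theta_{v,u_l})`` placed on L >= J directions, peak-normalized
to 1 (kappa_1).  The isotropic entry of Phi is scaled by the mean anisotropic
atom mass so that a unit of anisotropic coefficient and a unit of isotropic
coefficient account for the same amount of fODF mass — this is what makes the
isotropy index P_iso = c_iso / (sum c) read as a volume fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dwio import CalibrationError, DwiVolume, GradientTable
from .sphere import Tessellation, angle_between_lines

__all__ = [
    "ResponseMatrices",
    "DictionaryBasis",
    "ForwardOperator",
    "MODEL_MD",
    "build_response",
    "build_dictionary",
    "assemble_operator",
    "estimate_response_from_data",
    "fit_tensors",
]

MODEL_MD = 0.7e-3  # mm^2/s, shared by the FA=1 and FA=0 response tensors
DEFAULT_KERNEL = "cosine_power"
DEFAULT_TAU = {"cosine_power": 256.0, "eq5_fraction": 2.0}
DEFAULT_KAPPA2 = 0.9


@dataclass(frozen=True)
class ResponseMatrices:
    """Single-fiber and isotropic response profiles on a gradient scheme."""

    R_ani: np.ndarray          # (I, J) attenuations
    R_iso: np.ndarray          # (I,)
    d1_eigenvalues: tuple      # anisotropic response tensor (lpar, lperp, lperp)
    d2_eigenvalues: tuple      # isotropic response tensor (MD, MD, MD)
    sampling: Tessellation = None

    @property
    def n_gradients(self) -> int:
        return self.R_ani.shape[0]

    @property
    def n_sampling(self) -> int:
        return self.R_ani.shape[1]

    def augmented(self) -> np.ndarray:
        """R_hat = [R_ani  R_iso], shape (I, J+1)."""
        return np.hstack([self.R_ani, self.R_iso[:, None]])


@dataclass(frozen=True)
class DictionaryBasis:
    """Over-complete double-lobe atom basis plus the augmented block matrix."""

    phi: np.ndarray            # (J, L) atom values d(v_j, u_l)
    Phi: np.ndarray            # (J+1, L+1) block matrix
    kernel_shape: str
    kappa1: float
    kappa2: float
    tau: float
    atom_directions: np.ndarray  # (L, 3)
    iso_scale: float           # Phi[-1, -1]: mean anisotropic atom mass

    @property
    def n_atoms(self) -> int:
        return self.phi.shape[1]

    def evaluate_atoms(self, render_vertices) -> np.ndarray:
        """Atom kernel values at arbitrary unit directions, shape (N, L)."""
        theta = angle_between_lines(
            np.asarray(render_vertices)[:, None, :], self.atom_directions[None, :, :]
        )
        return kernel_value(theta, self.kernel_shape, self.kappa1, self.kappa2, self.tau)


@dataclass(frozen=True)
class ForwardOperator:
    """The composed linear map A = R_hat Phi from coefficients to signal."""

    A: np.ndarray                  # (I, L+1), nonnegative
    column_directions: np.ndarray  # (L, 3) atom directions (iso column is last)
    response: ResponseMatrices
    basis: DictionaryBasis

    @property
    def n_coeffs(self) -> int:
        return self.A.shape[1]


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------

def build_response(gtab: GradientTable, sampling: Tessellation,
                   md: float = MODEL_MD) -> ResponseMatrices:
    """Analytic FA=1 / FA=0 response pair on every entry of ``gtab``.

    ``R_ani[i, j] = exp(-b_i (3 md) (g_i . v_j)^2)`` — the unique axially
    symmetric tensor with FA = 1 and the stated mean diffusivity has
    eigenvalues ``(3 md, 0, 0)``, so only the parallel component attenuates.

    The b=0 rows (all ones, matching the unit b=0 attenuation) are kept in
    the operator on purpose: they pin the total compartment volume, which is
    what makes an isotropic compartment distinguishable from an orientation-
    dispersed spread of sticks on single-shell data.
    """
    v = np.asarray(sampling.vertices if isinstance(sampling, Tessellation)
                   else sampling, dtype=float)
    if v.size == 0:
        raise ValueError("empty sampling direction set")
    b = gtab.bvals
    g = gtab.bvecs
    lpar = 3.0 * md
    R_ani = np.exp(-b[:, None] * lpar * (g @ v.T) ** 2)
    R_iso = np.exp(-b * md)
    return ResponseMatrices(
        R_ani, R_iso,
        d1_eigenvalues=(lpar, 0.0, 0.0),
        d2_eigenvalues=(md, md, md),
        sampling=sampling if isinstance(sampling, Tessellation) else None,
    )


def _axial_response(gtab: GradientTable, sampling, lpar: float, lperp: float):
    v = np.asarray(sampling.vertices if isinstance(sampling, Tessellation)
                   else sampling, dtype=float)
    b = gtab.bvals
    g = gtab.bvecs
    return np.exp(-b[:, None] * (lperp + (lpar - lperp) * (g @ v.T) ** 2))


# ---------------------------------------------------------------------------
# tensor fitting (for response calibration from data)
# ---------------------------------------------------------------------------

def _design_matrix(gtab: GradientTable) -> np.ndarray:
    dw = gtab.dwi_mask
    b = gtab.bvals[dw]
    g = gtab.bvecs[dw]
    x, y, z = g.T
    # log S/S0 = -b (Dxx x^2 + Dyy y^2 + Dzz z^2 + 2 Dxy xy + 2 Dxz xz + 2 Dyz yz)
    return -b[:, None] * np.column_stack(
        [x * x, y * y, z * z, 2 * x * y, 2 * x * z, 2 * y * z]
    )


def fit_tensors(volume: DwiVolume, gtab: GradientTable):
    """Linear least-squares diffusion-tensor fit on log-attenuations.

    Returns ``(eigenvalues (n, 3) descending, eigenvectors (n, 3, 3) columns,
    valid mask over the volume's masked voxels, voxel indices)``.
    """
    att, mask = volume.attenuations(gtab, include_b0=False)
    idx = np.argwhere(mask)
    sig = att[mask]
    valid = np.all(sig > 0, axis=1)
    X = _design_matrix(gtab)
    coef, *_ = np.linalg.lstsq(X, np.log(np.clip(sig, 1e-12, None)).T, rcond=None)
    Dxx, Dyy, Dzz, Dxy, Dxz, Dyz = coef
    tensors = np.empty((len(sig), 3, 3))
    tensors[:, 0, 0], tensors[:, 1, 1], tensors[:, 2, 2] = Dxx, Dyy, Dzz
    tensors[:, 0, 1] = tensors[:, 1, 0] = Dxy
    tensors[:, 0, 2] = tensors[:, 2, 0] = Dxz
    tensors[:, 1, 2] = tensors[:, 2, 1] = Dyz
    evals, evecs = np.linalg.eigh(tensors)
    order = np.argsort(evals, axis=1)[:, ::-1]
    evals = np.take_along_axis(evals, order, axis=1)
    evecs = np.stack([np.take_along_axis(evecs[i], order[i][None, :], axis=1)
                      for i in range(len(evecs))])
    return evals, evecs, valid, idx


def _fa_from_evals(evals: np.ndarray) -> np.ndarray:
    lam = np.asarray(evals, dtype=float)
    mean = lam.mean(axis=-1, keepdims=True)
    num = np.sum((lam - mean) ** 2, axis=-1)
    den = np.sum(lam ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(1.5) * np.sqrt(num / den)


def estimate_response_from_data(volume: DwiVolume, gtab: GradientTable,
                                sampling: Tessellation, n_select: int = 50
                                ) -> ResponseMatrices:
    """Calibrate the response pair from the data itself.

    Fits a diffusion tensor per masked voxel; the ``n_select`` highest-FA
    voxels (coherent single-fiber, corpus-callosum-like) are aligned on their
    principal axis and their axially symmetrized eigenvalues averaged to give
    the anisotropic profile, re-oriented to every sampling direction; the
    ``n_select`` lowest-FA voxels give the isotropic profile through their
    mean diffusivity.
    """
    evals, _evecs, valid, _idx = fit_tensors(volume, gtab)
    evals = evals[valid]
    if len(evals) < n_select:
        raise CalibrationError(
            f"response calibration needs >= {n_select} valid voxels, got {len(evals)}"
        )
    fa = _fa_from_evals(evals)
    hi = np.argsort(fa)[-n_select:]
    lo = np.argsort(fa)[:n_select]
    lpar = float(np.mean(evals[hi, 0]))
    lperp = float(np.mean(evals[hi, 1:]))
    md_iso = float(np.mean(evals[lo]))
    R_ani = _axial_response(gtab, sampling, lpar, lperp)
    R_iso = np.exp(-gtab.bvals * md_iso)
    return ResponseMatrices(
        R_ani, R_iso,
        d1_eigenvalues=(lpar, lperp, lperp),
        d2_eigenvalues=(md_iso, md_iso, md_iso),
        sampling=sampling,
    )


# ---------------------------------------------------------------------------
# dictionary
# ---------------------------------------------------------------------------

def kernel_value(theta_deg, kernel_shape: str, kappa1: float, kappa2: float,
                 tau: float) -> np.ndarray:
    """Atom kernel k(theta) for a line angle in degrees."""
    th = np.radians(np.asarray(theta_deg, dtype=float))
    if kernel_shape == "cosine_power":
        return kappa1 * np.abs(np.cos(th)) ** tau
    if kernel_shape == "eq5_fraction":
        return kappa1 * (np.sin(th) / (1.0 - kappa2 * np.cos(2.0 * th) ** 2)) ** tau
    raise ValueError(f"unknown kernel_shape {kernel_shape!r}")


def _kappa1(kernel_shape: str, kappa2: float, tau: float) -> float:
    """Peak normalization: choose kappa1 so that max_theta k(theta) = 1."""
    if kernel_shape == "cosine_power":
        return 1.0
    grid = np.linspace(0.0, 90.0, 9001)
    peak = kernel_value(grid, kernel_shape, 1.0, kappa2, tau).max()
    return 1.0 / peak


def build_dictionary(sampling: Tessellation, atoms: Tessellation | None = None,
                     kernel_shape: str = DEFAULT_KERNEL,
                     kappa2: float = DEFAULT_KAPPA2,
                     tau: float | None = None) -> DictionaryBasis:
    """Assemble phi (J x L atom table) and the augmented Phi block matrix.

    Phi = [[phi, 0], [0, mu]] with mu the mean column mass of phi: the
    isotropic coefficient feeds only the isotropic fODF entry, on the same
    mass scale as the anisotropic coefficients.
    """
    if atoms is None:
        atoms = sampling
    v = sampling.vertices if isinstance(sampling, Tessellation) else np.asarray(sampling)
    u = atoms.vertices if isinstance(atoms, Tessellation) else np.asarray(atoms)
    J, L = len(v), len(u)
    if L < J:
        raise ValueError(f"dictionary must be over-complete: L={L} < J={J}")
    if tau is None:
        tau = DEFAULT_TAU[kernel_shape]
    kappa1 = _kappa1(kernel_shape, kappa2, tau)
    theta = angle_between_lines(v[:, None, :], u[None, :, :])
    phi = kernel_value(theta, kernel_shape, kappa1, kappa2, tau)
    iso_scale = float(phi.sum(axis=0).mean())
    Phi = np.zeros((J + 1, L + 1))
    Phi[:J, :L] = phi
    Phi[J, L] = iso_scale
    return DictionaryBasis(
        phi=phi, Phi=Phi, kernel_shape=kernel_shape, kappa1=kappa1,
        kappa2=kappa2, tau=float(tau), atom_directions=np.asarray(u, dtype=float),
        iso_scale=iso_scale,
    )


def assemble_operator(resp: ResponseMatrices, basis: DictionaryBasis
                      ) -> ForwardOperator:
    """Compose A = R_hat Phi (I x (L+1)); last column is iso_scale * R_iso."""
    if resp.n_sampling != basis.phi.shape[0]:
        raise ValueError(
            f"response has J={resp.n_sampling} sampling directions but the "
            f"dictionary was built on J={basis.phi.shape[0]}"
        )
    A = resp.augmented() @ basis.Phi
    if np.any(A.max(axis=0) <= 0):
        raise ValueError("forward operator has a zero column")
    return ForwardOperator(
        A=A, column_directions=basis.atom_directions, response=resp, basis=basis
    )
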