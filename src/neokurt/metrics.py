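"""Scalar metrics of the diffusion and kurtosis tensors.

DTI scalars use the standard definitions: AD = lambda_1, RD = (lambda_2 +
lambda_3)/2, MD = mean eigenvalue, FA = sqrt(3/2) ||lambda - MD|| /
||lambda||.  Directional kurtosis follows the apparent-kurtosis convention

    K(n) = (MD / D(n))^2 * W(n),    W(n) = sum n_i n_j n_k n_l W_ijkl,

which along diffusion-tensor eigenvector i reduces to
K_i = (MD / lambda_i)^2 * What_iiii with What the kurtosis tensor rotated
into the eigenframe.  Radial kurtosis is the mean of K(n) over directions
equally spaced in the plane perpendicular to the principal eigenvector; it
doubles as the practical estimator of the maximum directional kurtosis
K_max (an exhaustive grid-search mode exists as the theoretical
alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dki import D_IDX, DKIFitResults, W_IDX, quartic_design

__all__ = [
    "TensorEigenSystem",
    "ScalarMaps",
    "eigendecompose",
    "dti_scalars",
    "w15_to_full",
    "full_to_w15",
    "rotate_kurtosis",
    "directional_kurtosis",
    "radial_kurtosis",
    "max_kurtosis",
    "compute_scalar_maps",
]

#: relative eigenvalue gap below which a voxel is flagged near-degenerate
DEGENERACY_TOL = 1e-3


@dataclass
class TensorEigenSystem:
    """Descending eigenvalues and a right-handed orthonormal eigenframe."""

    eigenvalues: np.ndarray  # (..., 3), descending
    eigenvectors: np.ndarray  # (..., 3, 3), rows are e1, e2, e3
    degenerate: np.ndarray  # (...,) bool


def d6_to_matrix(d6: np.ndarray) -> np.ndarray:
    out = np.empty(d6.shape[:-1] + (3, 3))
    for k, (i, j) in enumerate(D_IDX):
        out[..., i, j] = d6[..., k]
        out[..., j, i] = d6[..., k]
    return out


def matrix_to_d6(D: np.ndarray) -> np.ndarray:
    return np.stack([D[..., i, j] for (i, j) in D_IDX], axis=-1)


def eigendecompose(D) -> TensorEigenSystem:
    """Eigen-decompose symmetric tensors (3x3, 6-vector, or batches thereof).

    Deterministic conventions: eigenvalues descending; each eigenvector's
    largest-magnitude component made positive (ties broken by the first
    such component); e3 flipped if needed to make the frame right-handed.
    Near-degenerate pairs (|l2 - l3| / MD < 1e-3) are flagged — any in-plane
    frame is equally valid there and downstream radial averages are
    rotation-invariant in-plane.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[-1] == 6:
        D = d6_to_matrix(D)
    if not np.all(np.isfinite(D)):
        raise ValueError("non-finite tensor entries")
    evals, evecs = np.linalg.eigh(D)  # ascending, columns
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    vecs = np.swapaxes(evecs, -1, -2).copy()  # rows = eigenvectors
    # sign convention on e1, e2: largest-magnitude component positive;
    # e3 then fixed as e1 x e2 so the frame is right-handed and deterministic
    idx = np.argmax(np.abs(vecs), axis=-1, keepdims=True)
    lead = np.take_along_axis(vecs, idx, axis=-1)
    vecs = vecs * np.where(lead < 0, -1.0, 1.0)
    vecs[..., 2, :] = np.cross(vecs[..., 0, :], vecs[..., 1, :])
    md = evals.mean(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        gap = np.abs(evals[..., 1] - evals[..., 2]) / np.where(md != 0, md, np.nan)
    degenerate = ~(gap > DEGENERACY_TOL)
    return TensorEigenSystem(evals, vecs, degenerate)


def dti_scalars(eig: TensorEigenSystem):
    """(FA, MD, AD, RD) from an eigen-system; FA of an all-zero tensor is 0."""
    lam = eig.eigenvalues
    MD = lam.mean(axis=-1)
    AD = lam[..., 0]
    RD = (lam[..., 1] + lam[..., 2]) / 2.0
    norm2 = (lam ** 2).sum(axis=-1)
    dev2 = ((lam - MD[..., None]) ** 2).sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        FA = np.sqrt(1.5 * dev2 / norm2)
    FA = np.where(norm2 > 0, FA, 0.0)
    return FA, MD, AD, RD


# ---------------------------------------------------------------------------
# kurtosis tensor algebra

def w15_to_full(w15: np.ndarray) -> np.ndarray:
    """Expand 15 unique components to the full symmetric (..., 3,3,3,3)."""
    from itertools import permutations

    out = np.zeros(w15.shape[:-1] + (3, 3, 3, 3))
    for k, idx in enumerate(W_IDX):
        for perm in set(permutations(idx)):
            out[(...,) + perm] = w15[..., k]
    return out


def full_to_w15(W: np.ndarray) -> np.ndarray:
    return np.stack([W[(...,) + idx] for idx in W_IDX], axis=-1)


def rotate_kurtosis(w15: np.ndarray, eig: TensorEigenSystem | np.ndarray) -> np.ndarray:
    """Rotate the kurtosis tensor into a new frame.

    ``eig`` may be a :class:`TensorEigenSystem` (rows of the rotation are
    its eigenvectors, so component iiii of the result is the kurtosis form
    along eigenvector i) or a raw rotation matrix with the same row
    convention.  Full index symmetry is preserved structurally.
    """
    R = eig.eigenvectors if isinstance(eig, TensorEigenSystem) else np.asarray(eig)
    W = w15_to_full(np.asarray(w15, dtype=float))
    Wr = np.einsum("...ia,...jb,...kc,...ld,...abcd->...ijkl", R, R, R, R, W,
                   optimize=True)
    return full_to_w15(Wr)


def directional_kurtosis(d6, w15, n) -> np.ndarray:
    """Apparent kurtosis K(n) = (MD / D(n))^2 W(n) for unit direction(s) n.

    Broadcasts a single voxel over many directions or many voxels over a
    single direction.  D(n) <= 0 yields NaN (undefined kurtosis).
    """
    d6 = np.asarray(d6, dtype=float)
    w15 = np.asarray(w15, dtype=float)
    n = np.atleast_2d(np.asarray(n, dtype=float))
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    md = d6[..., :3].mean(axis=-1)
    from .dki import quadratic_design
    q = quadratic_design(n)  # (K, 6)
    t = quartic_design(n)  # (K, 15)
    Dn = np.einsum("...c,kc->...k", d6, q)
    Wn = np.einsum("...c,kc->...k", w15, t)
    with np.errstate(invalid="ignore", divide="ignore"):
        K = (md[..., None] / Dn) ** 2 * Wn
    K = np.where(Dn > 0, K, np.nan)
    return K.squeeze()


def radial_kurtosis(d6, w15, eig: TensorEigenSystem | None = None,
                    n_samples: int = 64) -> float | np.ndarray:
    """Mean apparent kurtosis over ``n_samples`` directions equally spaced in
    the plane perpendicular to the principal eigenvector (single voxel)."""
    if eig is None:
        eig = eigendecompose(np.asarray(d6))
    e2, e3 = eig.eigenvectors[..., 1, :], eig.eigenvectors[..., 2, :]
    theta = np.pi * np.arange(n_samples) / n_samples
    dirs = (np.cos(theta)[:, None] * e2[None, :]
            + np.sin(theta)[:, None] * e3[None, :])
    K = directional_kurtosis(d6, w15, dirs)
    return float(np.mean(K))


def max_kurtosis(d6, w15, eig: TensorEigenSystem | None = None,
                 mode: str = "practical_rk", n_samples: int = 64,
                 n_grid: int = 1000) -> float:
    """Maximum directional kurtosis of one voxel.

    ``practical_rk`` (default) returns the radial kurtosis — the practical
    estimator when the largest kurtosis lies perpendicular to the fiber.
    ``grid_search`` maximizes K(n) over an ``n_grid``-point sphere grid with
    local Nelder-Mead refinement.
    """
    if mode == "practical_rk":
        return radial_kurtosis(d6, w15, eig, n_samples=n_samples)
    if mode != "grid_search":
        raise ValueError(f"unknown mode {mode!r}")
    from scipy.optimize import minimize

    i = np.arange(n_grid) + 0.5
    phi = np.arccos(1 - 2 * i / n_grid)
    lam = np.pi * (1 + 5 ** 0.5) * i
    grid = np.column_stack([np.cos(lam) * np.sin(phi),
                            np.sin(lam) * np.sin(phi), np.cos(phi)])
    K = directional_kurtosis(d6, w15, grid)
    j = int(np.nanargmax(K))
    n0 = grid[j]
    th0 = np.array([np.arccos(np.clip(n0[2], -1, 1)), np.arctan2(n0[1], n0[0])])

    def neg_k(t):
        n = np.array([np.sin(t[0]) * np.cos(t[1]),
                      np.sin(t[0]) * np.sin(t[1]), np.cos(t[0])])
        val = directional_kurtosis(d6, w15, n)
        return -float(val) if np.isfinite(val) else np.inf

    res = minimize(neg_k, th0, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12})
    return max(float(K[j]), -float(res.fun))


# ---------------------------------------------------------------------------
# map-level driver

@dataclass
class ScalarMaps:
    """DTI and kurtosis scalar maps on the acquisition grid."""

    FA: np.ndarray
    MD: np.ndarray
    AD: np.ndarray
    RD: np.ndarray
    RK: np.ndarray
    K_max: np.ndarray
    degenerate: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    def as_dict(self) -> dict:
        return {"FA": self.FA, "MD": self.MD, "AD": self.AD, "RD": self.RD,
                "RK": self.RK, "K_max": self.K_max}


def compute_scalar_maps(fit: DKIFitResults, n_radial_samples: int = 64,
                        kmax_mode: str = "practical_rk") -> ScalarMaps:
    """Derive FA/MD/AD/RD and radial/maximum kurtosis maps from a DKI fit.

    Radial kurtosis is computed for all voxels at once: for each of the
    ``n_radial_samples`` in-plane angles the per-voxel direction is built
    from e2, e3 and the apparent kurtosis evaluated vectorized.
    """
    shape = fit.mask.shape
    sel = fit.mask & fit.converged
    d6 = fit.D6[sel]
    w15 = fit.W15[sel]
    eig = eigendecompose(d6)
    FA, MD, AD, RD = dti_scalars(eig)

    # vectorized radial average
    from .dki import quadratic_design
    e2 = eig.eigenvectors[:, 1, :]
    e3 = eig.eigenvectors[:, 2, :]
    theta = np.pi * np.arange(n_radial_samples) / n_radial_samples
    Ksum = np.zeros(d6.shape[0])
    md = MD
    for t in theta:
        n = np.cos(t) * e2 + np.sin(t) * e3  # (N, 3)
        q = quadratic_design(n)
        tq = quartic_design(n)
        Dn = np.einsum("vc,vc->v", d6, q)
        Wn = np.einsum("vc,vc->v", w15, tq)
        with np.errstate(invalid="ignore", divide="ignore"):
            Ksum += np.where(Dn > 0, (md / Dn) ** 2 * Wn, np.nan)
    RK = Ksum / n_radial_samples

    if kmax_mode == "practical_rk":
        Kmax = RK.copy()
    else:
        Kmax = np.array([
            max_kurtosis(d6[v], w15[v], mode="grid_search")
            for v in range(d6.shape[0])
        ])

    def expand(arr, fill=np.nan):
        out = np.full(shape + arr.shape[1:], fill, dtype=float)
        out[sel] = arr
        return out

    deg = np.zeros(shape, dtype=bool)
    deg[sel] = eig.degenerate
    return ScalarMaps(
        FA=expand(FA), MD=expand(MD), AD=expand(AD), RD=expand(RD),
        RK=expand(RK), K_max=expand(Kmax), degenerate=deg,
        eigenvalues=expand(eig.eigenvalues),
        eigenvectors=expand(eig.eigenvectors),
    )
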