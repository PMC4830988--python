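"""Inversion of the two-compartment white-matter model (WMTI).

Given the fitted diffusion and kurtosis tensors of a single-fiber voxel, the
non-exchanging stick-plus-zeppelin model can be inverted in closed form:

1. axonal water fraction from the maximum directional kurtosis,

       f = K_max / (K_max + 3),

   with K_max estimated in practice by the radial kurtosis (the maximum lies
   perpendicular to the fiber when the intra-axonal radial diffusivity is
   the smallest diffusivity in the system);

2. per-direction compartment diffusivities,

       D_a(n) = D(n) [1 - sqrt(K(n) (1 - f) / (3 f))]
       D_e(n) = D(n) [1 + sqrt(K(n) f / (3 (1 - f)))],

   the minus/plus branch assignment being forced by the model assumption
   D_e(n) >= D_a(n);

3. intra- and extra-axonal tensors by least squares over a direction set
   (n^T D_hat n = directional diffusivity), and the headline metrics

       D_a = tr(D_a_tensor),  D_e,par = lambda_e1,
       D_e,perp = (lambda_e2 + lambda_e3) / 2.

Step 2 conserves the mixture mean, f D_a(n) + (1 - f) D_e(n) = D(n),
identically; on exact (noise-free) cumulants the whole chain recovers the
generating parameters to machine precision, which is the module's primary
correctness surface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dki import DKIFitResults, quadratic_design, quartic_design
from .metrics import d6_to_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "awf_from_kmax",
    "compartment_diffusivities",
    "build_compartment_tensors",
    "wmti_metrics",
    "invert_from_directional",
    "WhiteMatterModel",
    "WMTIResults",
    "run_wmti",
]

#: AWF below which the compartment split is numerically unstable; such
#: voxels get NaN metrics and a flag rather than unreliable numbers.
F_MIN_DEFAULT = 0.05


def awf_from_kmax(K_max):
    """Axonal water fraction f = K_max / (K_max + 3).

    Monotone in K_max, maps [0, inf) onto [0, 1).  Negative inputs (noise)
    are clipped to 0; the caller can detect clipping from the second return.
    """
    K = np.asarray(K_max, dtype=float)
    clipped = K < 0
    K = np.clip(K, 0.0, None)
    f = K / (K + 3.0)
    if np.ndim(K_max) == 0:
        return float(f), bool(clipped)
    return f, clipped


def compartment_diffusivities(D_n, K_n, f):
    """Split directional diffusivity into intra-/extra-axonal parts.

    Returns ``(D_a_n, D_e_n, flags)`` where flags marks voxels whose
    intra-axonal value was clipped at 0.  Requires 0 < f < 1 and K >= 0
    (negative K is clipped to 0 before the square roots).
    """
    D_n = np.asarray(D_n, dtype=float)
    K_n = np.clip(np.asarray(K_n, dtype=float), 0.0, None)
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("compartment split undefined at f = 0 or f = 1")
    Da_n = D_n * (1.0 - np.sqrt(K_n * (1.0 - f) / (3.0 * f)))
    De_n = D_n * (1.0 + np.sqrt(K_n * f / (3.0 * (1.0 - f))))
    flags = Da_n < 0
    Da_n = np.clip(Da_n, 0.0, None)
    return Da_n, De_n, flags


def build_compartment_tensors(directions: np.ndarray, Da_n: np.ndarray,
                              De_n: np.ndarray):
    """Least-squares tensors from directional compartment diffusivities.

    Solves n^T D n = value over the direction set for each compartment;
    requires >= 6 directions spanning a rank-6 quadratic design.
    Returns the two symmetric 3x3 tensors.  Supports batches when ``Da_n``
    and ``De_n`` are (V, K).
    """
    dirs = np.atleast_2d(np.asarray(directions, dtype=float))
    B = quadratic_design(dirs)  # (K, 6)
    if dirs.shape[0] < 6 or np.linalg.matrix_rank(B) < 6:
        raise ValueError(
            "direction set is rank-deficient: need >= 6 non-coplanar directions"
        )
    pinv = np.linalg.pinv(B)
    da6 = np.einsum("ck,...k->...c", pinv, np.asarray(Da_n, dtype=float))
    de6 = np.einsum("ck,...k->...c", pinv, np.asarray(De_n, dtype=float))
    return d6_to_matrix(da6), d6_to_matrix(de6)


def wmti_metrics(D_a_tensor: np.ndarray, D_e_tensor: np.ndarray):
    """Headline metrics from the compartment tensors.

    D_a = trace of the intra-axonal tensor (equals the stick's axial
    diffusivity since its radial diffusivity is ~0); D_e,par and D_e,perp
    from the extra-axonal eigenvalues.  Returns a dict of scalars (or
    arrays for batched input).
    """
    Da = np.trace(D_a_tensor, axis1=-2, axis2=-1)
    ev = np.linalg.eigvalsh(D_e_tensor)[..., ::-1]
    return {
        "D_a": Da,
        "De_par": ev[..., 0],
        "De_perp": (ev[..., 1] + ev[..., 2]) / 2.0,
        "lambda_e": ev,
    }


def invert_from_directional(directions: np.ndarray, D_n: np.ndarray,
                            K_n: np.ndarray, K_max) -> dict:
    """Full inversion chain from directional cumulants of one voxel (or a
    batch): K_max -> f -> per-direction split -> tensors -> metrics.

    This is the fitting-free entry point: feeding it exact analytic D(n),
    K(n) recovers the generating two-compartment parameters exactly.
    """
    f, f_clipped = awf_from_kmax(K_max)
    Da_n, De_n, clip = compartment_diffusivities(D_n, K_n, f)
    Da_t, De_t = build_compartment_tensors(directions, Da_n, De_n)
    out = wmti_metrics(Da_t, De_t)
    out.update({"f": f, "Da_tensor": Da_t, "De_tensor": De_t,
                "clipped": np.any(clip, axis=-1) | np.asarray(f_clipped)})
    return out


# ---------------------------------------------------------------------------
# map-level model

@dataclass
class WMTIResults:
    """Per-voxel white-matter model maps (diffusivities in mm^2/s)."""

    f: np.ndarray
    D_a: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    lambda_e: np.ndarray  # (..., 3) descending extra-axonal eigenvalues
    valid: np.ndarray
    flags: np.ndarray  # bitmask: 1 = f below floor, 2 = negative radicand clip
    f_min: float
    kmax_mode: str

    def as_dict(self) -> dict:
        return {"awf": self.f, "da": self.D_a, "de_par": self.De_par,
                "de_perp": self.De_perp}

    def plot(self, path=None, z: int | None = None):
        """QC figure: mid-axial slice of the four white-matter maps.

        Returns the matplotlib figure; writes a PNG when ``path`` is given.
        """
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if z is None:
            z = self.f.shape[2] // 2
        fig, axes = plt.subplots(1, 4, figsize=(12, 3.2))
        titles = {"awf": "AWF f", "da": "D_a", "de_par": "D_e,par",
                  "de_perp": "D_e,perp"}
        for ax, (key, arr) in zip(axes, self.as_dict().items()):
            im = ax.imshow(arr[:, :, z].T, origin="lower", cmap="magma")
            ax.set_title(titles[key])
            ax.axis("off")
            fig.colorbar(im, ax=ax, shrink=0.8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=110)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        v = self.valid
        def med(x):
            return np.nanmedian(x[v])
        return "\n".join([
            "White-matter model (WMTI) maps",
            "==============================",
            f"K_max estimator: {self.kmax_mode}   f floor: {self.f_min}",
            f"valid voxels: {int(v.sum())} / {int(np.isfinite(self.f).sum())} with f computed",
            f"median AWF f: {med(self.f):.3f}",
            f"median D_a:     {med(self.D_a):.3e} mm^2/s",
            f"median D_e,par: {med(self.De_par):.3e} mm^2/s",
            f"median D_e,perp:{med(self.De_perp):.3e} mm^2/s",
        ])


class WhiteMatterModel:
    """Two-compartment white-matter model over a DKI fit.

    Parameters
    ----------
    fit : DKIFitResults
    kmax_mode : "rk" (radial kurtosis, the practical default) or "grid"
        (exhaustive directional search).
    f_min : voxels with AWF below this are flagged and emit NaN metrics.
    n_radial_samples : quadrature size of the radial kurtosis average.
    """

    def __init__(self, fit: DKIFitResults, kmax_mode: str = "rk",
                 f_min: float = F_MIN_DEFAULT, n_radial_samples: int = 64):
        if kmax_mode not in ("rk", "grid"):
            raise ValueError(f"unknown kmax_mode {kmax_mode!r}")
        self.fit = fit
        self.kmax_mode = kmax_mode
        self.f_min = f_min
        self.n_radial_samples = n_radial_samples

    def fit_maps(self) -> WMTIResults:
        fit = self.fit
        scal = fit.scalar_maps(
            n_radial_samples=self.n_radial_samples) if self.kmax_mode == "rk" \
            else fit.scalar_maps(kmax_mode="grid_search")
        shape = fit.mask.shape
        sel = fit.mask & fit.converged & np.isfinite(scal.K_max)
        d6 = fit.D6[sel]
        w15 = fit.W15[sel]
        md = fit.MD[sel]
        kmax = scal.K_max[sel]
        evecs = scal.eigenvectors[sel]  # (V, 3, 3) rows e1..e3

        f, _ = awf_from_kmax(kmax)
        usable = f >= self.f_min

        # direction set: the scheme's unique gradient directions plus the
        # per-voxel diffusion-tensor eigenvectors
        base_dirs = fit.scheme.unique_directions()  # (K, 3)
        nb = base_dirs.shape[0]
        V = d6.shape[0]
        dirs = np.concatenate(
            [np.broadcast_to(base_dirs, (V, nb, 3)), evecs], axis=1
        )  # (V, K+3, 3)

        q = quadratic_design(dirs.reshape(-1, 3)).reshape(V, nb + 3, 6)
        t = quartic_design(dirs.reshape(-1, 3)).reshape(V, nb + 3, 15)
        Dn = np.einsum("vkc,vc->vk", q, d6)
        Wn = np.einsum("vkc,vc->vk", t, w15)
        with np.errstate(invalid="ignore", divide="ignore"):
            Kn = np.where(Dn > 0, (md[:, None] / Dn) ** 2 * Wn, np.nan)

        out = {k: np.full(V, np.nan) for k in ("D_a", "De_par", "De_perp")}
        lam = np.full((V, 3), np.nan)
        clip = np.zeros(V, dtype=bool)
        idx = np.flatnonzero(usable & np.isfinite(Kn).all(axis=1))
        if idx.size:
            Da_n, De_n, cl = compartment_diffusivities(
                Dn[idx], Kn[idx], f[idx, None])
            clip[idx] = cl.any(axis=1)
            # batched per-voxel tensor solves (direction sets differ by voxel)
            Bi = q[idx]
            AtA = np.einsum("vkc,vkd->vcd", Bi, Bi)
            Da6 = np.linalg.solve(
                AtA, np.einsum("vkc,vk->vc", Bi, Da_n)[..., None])[..., 0]
            De6 = np.linalg.solve(
                AtA, np.einsum("vkc,vk->vc", Bi, De_n)[..., None])[..., 0]
            m = wmti_metrics(d6_to_matrix(Da6), d6_to_matrix(De6))
            for k in ("D_a", "De_par", "De_perp"):
                out[k][idx] = m[k]
            lam[idx] = m["lambda_e"]

        flags = (~usable).astype(np.uint8) | (clip.astype(np.uint8) << 1)

        def expand(arr, fill=np.nan, dtype=float):
            full = np.full(shape + arr.shape[1:], fill, dtype=dtype)
            full[sel] = arr
            return full

        return WMTIResults(
            f=expand(f), D_a=expand(out["D_a"]), De_par=expand(out["De_par"]),
            De_perp=expand(out["De_perp"]), lambda_e=expand(lam),
            valid=expand(usable, False, bool),
            flags=expand(flags, 0, np.uint8),
            f_min=self.f_min, kmax_mode=self.kmax_mode,
        )

    # statsmodels-flavoured alias
    fit = fit_maps


def run_wmti(fit: DKIFitResults, kmax_mode: str = "rk",
             f_min: float = F_MIN_DEFAULT) -> WMTIResults:
    """Functional entry point: DKI fit -> WMTI maps."""
    return WhiteMatterModel(fit, kmax_mode=kmax_mode, f_min=f_min).fit_maps()
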