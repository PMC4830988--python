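"""Diffusion and kurtosis tensor estimation by constrained weighted linear
least squares (CWLLS).

The log-linearized signal model per measurement (b, n) is

    ln S(b, n) = ln S0 - b * sum_ij n_i n_j D_ij + (b^2 / 6) * sum_ijkl n_i n_j n_k n_l V_ijkl

with D the symmetric diffusion tensor (6 unique components) and
V = MD^2 * W the kurtosis-tensor contraction fitted linearly (15 unique
components of the fully symmetric rank-4 W); 22 parameters in all.  W is
recovered by dividing the fitted V by the squared mean diffusivity of the
same fit.

The constrained fit enforces, at every measured gradient direction,

    K(n) >= 0            <=>  V(n) >= 0
    K(n) <= 3/(b_max D(n))  <=>  3 D(n) - b_max V(n) >= 0
    D(n) >= 0

all of which are *linear* in the 22 parameters, so each voxel is an
inequality-constrained least-squares problem.  It is solved exactly by the
Lawson–Hanson LSI -> LDP -> NNLS reduction; weights are the predicted
signals of the previous iterate (two reweighting passes by default), the
standard published recipe.  Published CWLLS descriptions vary in weights,
iteration count and constraint bounds, so these defaults are declared
package policy and every one of them is switchable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations_with_replacement

import numpy as np
from scipy.optimize import nnls

from .io import DWIVolume, GradientScheme, SchemeError

logger = logging.getLogger(__name__)

# unique index tuples and multinomial multiplicities for the symmetric tensors
D_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]
D_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])
W_IDX = list(combinations_with_replacement(range(3), 4))  # 15 tuples, sorted


def _w_mult(idx):
    from math import factorial
    counts = [idx.count(a) for a in set(idx)]
    m = factorial(4)
    for c in counts:
        m //= factorial(c)
    return float(m)


W_MULT = np.array([_w_mult(i) for i in W_IDX])

#: ceiling constant C in K(n) <= C / (b_max * D(n))
KMAX_CONSTRAINT_C = 3.0
#: voxels with fitted MD below this (mm^2/s) cannot yield a stable W
MD_FLOOR = 1e-7
#: minimum usable measurements per voxel for the 22-parameter fit
MIN_MEASUREMENTS = 22


def quadratic_design(directions: np.ndarray) -> np.ndarray:
    """(M, 6) rows q(n) such that q(n) . D6 = n^T D n."""
    n = np.atleast_2d(directions)
    cols = [D_MULT[k] * n[:, i] * n[:, j] for k, (i, j) in enumerate(D_IDX)]
    return np.column_stack(cols)


def quartic_design(directions: np.ndarray) -> np.ndarray:
    """(M, 15) rows t(n) such that t(n) . W15 = sum n_i n_j n_k n_l W_ijkl."""
    n = np.atleast_2d(directions)
    cols = [
        W_MULT[k] * n[:, i] * n[:, j] * n[:, kk] * n[:, l]
        for k, (i, j, kk, l) in enumerate(W_IDX)
    ]
    return np.column_stack(cols)


def design_rows(scheme: GradientScheme) -> np.ndarray:
    """The M x 22 log-signal design matrix (no acquisition validation)."""
    b = scheme.bvalues[:, None]
    q = quadratic_design(scheme.directions)
    t = quartic_design(scheme.directions)
    return np.hstack([np.ones((len(scheme), 1)), -b * q, (b ** 2 / 6.0) * t])


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """Validated design matrix for kurtosis fitting.

    Requires >= 3 distinct nonzero shells (the b and b^2 columns of a
    single shell are collinear) and full column rank 22.
    """
    scheme.validate_for_kurtosis()
    A = design_rows(scheme)
    rank = np.linalg.matrix_rank(A)
    if rank < 22:
        raise SchemeError(
            f"design matrix rank {rank} < 22: the scheme cannot identify all "
            "diffusion and kurtosis components (need >= 15 distinct directions "
            "over >= 3 nonzero shells)"
        )
    return A


def constraint_matrix(scheme: GradientScheme) -> np.ndarray:
    """Linear constraint rows G with G x >= 0 encoding, at each measured
    direction: D(n) >= 0, V(n) >= 0 and 3 D(n) - b_max V(n) >= 0."""
    dirs = scheme.unique_directions()
    q = quadratic_design(dirs)
    t = quartic_design(dirs)
    k = dirs.shape[0]
    z1 = np.zeros((k, 1))
    g_d = np.hstack([z1, q, np.zeros((k, 15))])
    g_v = np.hstack([z1, np.zeros((k, 6)), t])
    g_k = KMAX_CONSTRAINT_C * g_d - scheme.bmax * g_v
    return np.vstack([g_d, g_v, g_k])


# ---------------------------------------------------------------------------
# inequality-constrained least squares (Lawson & Hanson)

def solve_ldp(G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Least-distance programming: min ||z|| s.t. G z >= h, via NNLS."""
    m, n = G.shape
    E = np.vstack([G.T, h[None, :]])  # (n+1, m)
    f = np.zeros(n + 1)
    f[-1] = 1.0
    u, _ = nnls(E, f)
    r = E @ u - f
    if abs(r[-1]) < 1e-12:
        raise RuntimeError("LDP infeasible")
    return -r[:n] / r[-1]


def solve_lsi(E: np.ndarray, f: np.ndarray, G: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Inequality-constrained LS: min ||E x - f|| s.t. G x >= h.

    E must have full column rank (true for every validated scheme).
    """
    Q, R = np.linalg.qr(E)
    qtf = Q.T @ f
    GRinv = np.linalg.solve(R.T, G.T).T  # G R^{-1}
    z = solve_ldp(GRinv, h - GRinv @ qtf)
    return np.linalg.solve(R, z + qtf)


# ---------------------------------------------------------------------------
# results container

@dataclass
class DKIFitResults:
    """Per-voxel DKI estimates on the acquisition grid.

    ``params`` stacks [ln S0 | 6 D components (mm^2/s) | 15 W components
    (dimensionless)] per voxel; NaN outside the mask and in failed voxels.
    """

    params: np.ndarray  # (X, Y, Z, 22): lnS0, D6, W15
    scheme: GradientScheme
    mask: np.ndarray
    residual_rms: np.ndarray
    converged: np.ndarray
    constrained: np.ndarray  # voxels where an inequality constraint was active
    method: str = "cwlls"
    n_iter: int = 2

    @property
    def lnS0(self) -> np.ndarray:
        return self.params[..., 0]

    @property
    def S0(self) -> np.ndarray:
        return np.exp(self.params[..., 0])

    @property
    def D6(self) -> np.ndarray:
        return self.params[..., 1:7]

    @property
    def W15(self) -> np.ndarray:
        return self.params[..., 7:22]

    @property
    def MD(self) -> np.ndarray:
        return self.D6[..., :3].mean(axis=-1)

    def D_matrix(self) -> np.ndarray:
        """Full symmetric 3x3 per voxel, shape (..., 3, 3)."""
        d = self.D6
        out = np.empty(d.shape[:-1] + (3, 3))
        for k, (i, j) in enumerate(D_IDX):
            out[..., i, j] = d[..., k]
            out[..., j, i] = d[..., k]
        return out

    def predict(self, scheme: GradientScheme | None = None) -> np.ndarray:
        """Model-predicted signals, exp(A . params), per voxel."""
        scheme = scheme or self.scheme
        A = design_rows(scheme)
        p = self.params.copy()
        md = self.MD
        v = p[..., 7:22] * np.where(np.abs(md) > 0, md, np.nan)[..., None] ** 2
        theta = np.concatenate([p[..., :7], v], axis=-1)
        return np.exp(np.einsum("mk,...k->...m", A, theta))

    def scalar_maps(self, n_radial_samples: int = 64):
        from .metrics import compute_scalar_maps
        return compute_scalar_maps(self, n_radial_samples=n_radial_samples)

    def save(self, path) -> None:
        """Persist as a multi-volume NIfTI (22 parameter maps + diagnostics)."""
        import nibabel as nib
        stack = np.concatenate(
            [
                self.params,
                self.residual_rms[..., None],
                self.converged[..., None].astype(float),
                self.constrained[..., None].astype(float),
                self.mask[..., None].astype(float),
            ],
            axis=-1,
        )
        nib.Nifti1Image(stack, np.eye(4)).to_filename(str(path))

    def summary(self) -> str:
        n = int(self.mask.sum())
        ok = int(self.converged[self.mask].sum())
        act = int(self.constrained[self.mask].sum())
        md = self.MD[self.mask & self.converged]
        lines = [
            "Diffusion kurtosis fit",
            "======================",
            f"method: {self.method} (iterations={self.n_iter})",
            f"voxels in mask: {n}   converged: {ok}   constraint-active: {act}",
            f"median MD: {np.nanmedian(md):.3e} mm^2/s",
            f"median residual RMS (log-signal): {np.nanmedian(self.residual_rms[self.mask]):.3e}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# model

class DiffusionKurtosisModel:
    """Voxel-wise DKI model for a multi-shell :class:`~neokurt.io.DWIVolume`.

    Examples
    --------
    >>> fit = DiffusionKurtosisModel(dwi).fit()      # doctest: +SKIP
    >>> fit.scalar_maps().FA                         # doctest: +SKIP
    """

    def __init__(self, dwi: DWIVolume):
        self.dwi = dwi
        self.scheme = dwi.scheme
        self.design = design_matrix(dwi.scheme)
        self.constraints = constraint_matrix(dwi.scheme)

    # -- internals ---------------------------------------------------------

    def _solve_unweighted(self, logy: np.ndarray, usable: np.ndarray) -> np.ndarray:
        """OLS on log-signal; per-voxel measurement dropping where needed."""
        A = self.design
        theta = np.full((logy.shape[0], 22), np.nan)
        full = usable.all(axis=1)
        if full.any():
            pinv = np.linalg.pinv(A)
            theta[full] = logy[full] @ pinv.T
        for v in np.flatnonzero(~full):
            u = usable[v]
            if u.sum() < MIN_MEASUREMENTS:
                continue
            Av = A[u]
            if np.linalg.matrix_rank(Av) < 22:
                continue
            theta[v] = np.linalg.lstsq(Av, logy[v, u], rcond=None)[0]
        return theta

    def _solve_weighted(self, logy, usable, weights, constrained):
        """One WLS pass with row-weights ``weights``; constraint projection
        per violating voxel via LSI."""
        A = self.design
        G = self.constraints
        n_vox = logy.shape[0]
        theta = np.full((n_vox, 22), np.nan)
        active = np.zeros(n_vox, dtype=bool)
        w = np.where(usable, weights, 0.0)
        # batched normal equations: (A^T W^2 A) x = A^T W^2 y
        w2 = w ** 2
        AtWA = np.einsum("mi,vm,mj->vij", A, w2, A, optimize=True)
        AtWy = np.einsum("mi,vm->vi", A, w2 * np.nan_to_num(logy), optimize=True)
        try:
            theta = np.linalg.solve(AtWA, AtWy[..., None])[..., 0]
        except np.linalg.LinAlgError:
            for v in range(n_vox):
                try:
                    theta[v] = np.linalg.solve(AtWA[v], AtWy[v])
                except np.linalg.LinAlgError:
                    theta[v] = np.nan
        if not constrained:
            return theta, active
        slack = theta @ G.T
        viol = np.nanmin(slack, axis=1) < -1e-12
        for v in np.flatnonzero(viol):
            u = usable[v]
            Ev = A[u] * w[v, u, None]
            fv = logy[v, u] * w[v, u]
            try:
                theta[v] = solve_lsi(Ev, fv, G, np.zeros(G.shape[0]))
                active[v] = True
            except RuntimeError:
                logger.warning("constrained solve failed in voxel %d; "
                               "falling back to clipped OLS", v)
                active[v] = True
        return theta, active

    # -- public API --------------------------------------------------------

    def fit(self, method: str = "cwlls", n_iter: int = 2,
            constrained: bool = True) -> DKIFitResults:
        """Fit every masked voxel.

        method : "lls" (single unweighted log-linear pass, unconstrained) or
        "cwlls" (``n_iter`` signal-weighted passes with the directional
        kurtosis/diffusivity constraints).
        """
        dwi = self.dwi
        y = dwi.masked_signal()
        usable = y > 0
        n_dropped = int((~usable).sum())
        if n_dropped:
            logger.info("dropping %d nonpositive measurements (log undefined)",
                        n_dropped)
        with np.errstate(divide="ignore", invalid="ignore"):
            logy = np.where(usable, np.log(np.where(usable, y, 1.0)), np.nan)

        theta = self._solve_unweighted(logy, usable)
        active = np.zeros(theta.shape[0], dtype=bool)
        if method == "cwlls":
            for _ in range(n_iter):
                pred = np.exp(self.design @ np.nan_to_num(theta).T).T
                bad = ~np.isfinite(theta).all(axis=1)
                pred[bad] = 0.0
                theta_new, act = self._solve_weighted(logy, usable, pred, constrained)
                keep = np.isfinite(theta_new).all(axis=1)
                theta[keep] = theta_new[keep]
                active |= act
        elif method != "lls":
            raise ValueError(f"unknown method {method!r}")

        return self._package(theta, logy, usable, active, method, n_iter)

    def _package(self, theta, logy, usable, active, method, n_iter):
        dwi = self.dwi
        shape = dwi.spatial_shape
        # recover W = V / MD^2 and positivity-repair D
        finite = np.isfinite(theta).all(axis=1)
        d6 = theta[:, 1:7]
        md = d6[:, :3].mean(axis=1)
        good_md = md > MD_FLOOR
        W = np.full_like(theta[:, 7:22], np.nan)
        np.divide(theta[:, 7:22], md[:, None] ** 2, out=W,
                  where=(good_md & finite)[:, None])
        eigclip = np.zeros(theta.shape[0], dtype=bool)
        if method == "cwlls" and finite.any():
            Dm = np.zeros((theta.shape[0], 3, 3))
            for k, (i, j) in enumerate(D_IDX):
                Dm[:, i, j] = np.nan_to_num(d6[:, k])
                Dm[:, j, i] = np.nan_to_num(d6[:, k])
            evals, evecs = np.linalg.eigh(Dm)
            neg = finite & (evals[:, 0] < 0)
            if neg.any():  # clip tiny negative eigenvalues to PSD
                ev = np.clip(evals[neg], 0.0, None)
                Dr = np.einsum("vab,vb,vcb->vac", evecs[neg], ev, evecs[neg])
                for k, (i, j) in enumerate(D_IDX):
                    d6[neg, k] = Dr[:, i, j]
                eigclip[neg] = True
        theta = np.concatenate([theta[:, :1], d6, W], axis=1)

        pred_log = self.design @ np.where(np.isfinite(theta).all(axis=1)[:, None],
                                          np.concatenate(
                                              [theta[:, :7],
                                               theta[:, 7:22] * md[:, None] ** 2],
                                              axis=1),
                                          0.0).T
        resid = np.where(usable, np.nan_to_num(logy) - pred_log.T, 0.0)
        rms = np.sqrt((resid ** 2).sum(axis=1) / np.maximum(usable.sum(axis=1), 1))

        conv = finite & good_md
        out = {}
        for name, arr, fill in (
            ("params", theta, np.nan),
            ("residual_rms", rms, np.nan),
            ("converged", conv, False),
            ("constrained", active | eigclip, False),
        ):
            full = np.full(shape + arr.shape[1:] if arr.ndim > 1 else shape,
                           fill, dtype=arr.dtype if arr.dtype != bool else bool)
            full[dwi.mask] = arr
            out[name] = full
        return DKIFitResults(
            params=out["params"], scheme=dwi.scheme, mask=dwi.mask,
            residual_rms=out["residual_rms"], converged=out["converged"],
            constrained=out["constrained"], method=method, n_iter=n_iter,
        )


def fit_lls(dwi: DWIVolume) -> DKIFitResults:
    """Unconstrained ordinary least squares on the log-signal."""
    return DiffusionKurtosisModel(dwi).fit(method="lls")


def fit_cwlls(dwi: DWIVolume, max_iter: int = 2, constrained: bool = True) -> DKIFitResults:
    """Constrained weighted linear least squares (the default estimator)."""
    return DiffusionKurtosisModel(dwi).fit(method="cwlls", n_iter=max_iter,
                                           constrained=constrained)


def predict_signal(fit: DKIFitResults, scheme: GradientScheme | None = None) -> np.ndarray:
    return fit.predict(scheme)


# ---------------------------------------------------------------------------
# artifact rejection

def reject_artifacts(dwi: DWIVolume, z_threshold: float = 3.5):
    """Drop whole measurement volumes whose within-mask mean log-signal is a
    shell-wise robust-z outlier.

    This is an explicit simplified stand-in for automated artifact rejection:
    a volume is dropped when |0.6745 (x - median) / MAD| of its shell group
    exceeds ``z_threshold``.  Refuses to drop anything that would leave a
    shell with < 6 directions or a rank-deficient design.
    """
    y = dwi.masked_signal()
    pos = y > 0
    with np.errstate(divide="ignore"):
        logs = np.where(pos, np.log(np.where(pos, y, 1.0)), np.nan)
    mean_log = np.nanmean(logs, axis=0)  # per measurement volume

    bvals = dwi.scheme.bvalues
    drop = np.zeros(len(dwi.scheme), dtype=bool)
    zscores = np.zeros(len(dwi.scheme))
    for b in np.unique(bvals):
        sel = bvals == b
        x = mean_log[sel]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad < 1e-12:
            z = np.where(np.abs(x - med) < 1e-9, 0.0, np.inf)
        else:
            z = 0.6745 * (x - med) / mad
        zscores[sel] = z
        drop[sel] = np.abs(z) > z_threshold

    report = {
        "dropped_indices": np.flatnonzero(drop).tolist(),
        "z_scores": zscores,
        "threshold": z_threshold,
    }
    if not drop.any():
        return dwi, report

    keep = ~drop
    sub = GradientScheme(bvals[keep], dwi.scheme.directions[keep])
    for b in sub.shells:
        shell = GradientScheme(
            np.concatenate([[0.0], sub.bvalues[sub.bvalues == b]]),
            np.vstack([[0.0, 0.0, 0.0], sub.directions[sub.bvalues == b]]),
        )
        if shell.unique_directions().shape[0] < 6:
            raise SchemeError(
                f"rejection would leave shell b={b:g} with <6 directions; "
                "nothing dropped"
            )
    if np.linalg.matrix_rank(design_rows(sub)) < 22:
        raise SchemeError("rejection would leave a rank-deficient design; "
                          "nothing dropped")
    clean = DWIVolume(dwi.signal[..., keep], sub, mask=dwi.mask,
                      voxel_size_mm=dwi.voxel_size_mm)
    logger.info("artifact rejection dropped volumes %s", report["dropped_indices"])
    return clean, report
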