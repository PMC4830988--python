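"""Synthetic neonatal diffusion data with known two-compartment ground truth.

The tissue model is the non-exchanging single-fiber white-matter model: an
intra-axonal "stick" compartment (axial diffusivity ``Da_axial``, radial
diffusivity exactly zero) holding a signal fraction ``f`` (the axonal water
fraction), plus an axially symmetric extra-axonal "zeppelin" tensor with
eigenvalues (``De_par``, ``De_perp``, ``De_perp``).  Along a unit direction
``n`` the normalized signal is

    S(b, n) / S0 = f * exp(-b * Da(n)) + (1 - f) * exp(-b * De(n))

with Da(n) = Da_axial * (n . axis)^2 and De(n) = n^T D_e n.  The module also
provides the exact direction-wise cumulants of this mixture,

    D(n) = f * Da(n) + (1 - f) * De(n)
    K(n) = 3 f (1 - f) (Da(n) - De(n))^2 / D(n)^2,

which serve as the analytic oracle for the fitting and inversion stages, and
a cumulant-form signal generator (exactly within the DKI model class) for
truncation-free end-to-end validation.

Tissue regimes emulate three neonatal conditions — normal control, simple T2
hyperintensity (delayed myelination: extra-axonal diffusivities raised,
intra-axonal unchanged) and complex T2h with hypoxic-ischemic encephalopathy
(axonal damage: intra-axonal diffusivity lowered, extra-axonal radial raised)
— in four white-matter ROIs (PLIC, SCR, CC, EC).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import DWIVolume, GradientScheme, LabelAtlas, SchemeError, validate_cohort

__all__ = [
    "CompartmentParams",
    "TissueRegime",
    "PhantomTruth",
    "make_scheme",
    "forward_signal",
    "signal_from_cumulants",
    "analytic_cumulants",
    "generate_phantom",
    "generate_cohort",
    "default_regimes",
    "covariate_params",
    "metric_regimes",
    "TABLE_METRICS",
    "TABLE_COVARIATES",
    "DEFAULT_SNR",
]

#: Default b=0 signal-to-noise ratio of the simulated magnitude images.
#: The source acquisition does not state its SNR; 30 is a typical value for
#: neonatal 3T EPI at b=0 and is simulator policy (see docs/methods.md).
DEFAULT_SNR = 30.0


@dataclass(frozen=True)
class CompartmentParams:
    """Ground-truth two-compartment parameters of one voxel/tissue.

    Diffusivities in mm^2/s; ``f`` is the axonal water fraction.
    The model's branch assumption requires ``De_par >= Da_axial`` and
    ``De_par >= De_perp``.
    """

    f: float
    Da_axial: float
    De_par: float
    De_perp: float
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    S0: float = 1000.0

    def __post_init__(self):
        if not 0.0 <= self.f < 1.0:
            raise ValueError(f"f must be in [0, 1), got {self.f}")
        for name in ("Da_axial", "De_par", "De_perp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.De_par < self.De_perp - 1e-15:
            raise ValueError("De_par must be >= De_perp")
        if self.De_par < self.Da_axial - 1e-15:
            raise ValueError("branch assumption requires De_par >= Da_axial")
        axis = np.asarray(self.axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        object.__setattr__(self, "axis", axis)

    @property
    def De_tensor(self) -> np.ndarray:
        """Extra-axonal 3x3 tensor (zeppelin about ``axis``)."""
        a = self.axis
        return self.De_perp * np.eye(3) + (self.De_par - self.De_perp) * np.outer(a, a)

    @property
    def Da_tensor(self) -> np.ndarray:
        """Intra-axonal 3x3 tensor (stick along ``axis``)."""
        a = self.axis
        return self.Da_axial * np.outer(a, a)

    @property
    def mixture_tensor(self) -> np.ndarray:
        """Overall diffusion tensor f*Da + (1-f)*De."""
        return self.f * self.Da_tensor + (1.0 - self.f) * self.De_tensor


@dataclass(frozen=True)
class TissueRegime:
    """A named tissue condition: mean parameters plus between-subject spread."""

    name: str
    param_mean: CompartmentParams
    param_sd: dict = field(default_factory=dict)  # per-field SD for subject draws


@dataclass
class PhantomTruth:
    """Per-voxel ground-truth maps accompanying a generated phantom."""

    f: np.ndarray
    Da_axial: np.ndarray
    De_par: np.ndarray
    De_perp: np.ndarray
    axis: np.ndarray  # (X, Y, Z, 3)
    atlas: LabelAtlas
    regimes: list[TissueRegime]

    def map_for(self, metric: str) -> np.ndarray:
        key = {"awf": "f", "f": "f", "D_a": "Da_axial", "da": "Da_axial",
               "de_par": "De_par", "De_par": "De_par",
               "de_perp": "De_perp", "De_perp": "De_perp"}[metric]
        return getattr(self, key)


# ---------------------------------------------------------------------------
# acquisition scheme

def _fibonacci_hemisphere(n: int) -> np.ndarray:
    """Deterministic, roughly uniform points on the upper hemisphere."""
    i = np.arange(n) + 0.5
    golden = (1 + 5 ** 0.5) / 2
    z = i / n  # upper hemisphere only
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z ** 2, 0, None))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _repel(points: np.ndarray, n_iter: int = 400, step: float = 2e-3) -> np.ndarray:
    """Antipodally symmetric electrostatic repulsion on the sphere.

    Fixed iteration count and step so the layout is reproducible bit-for-bit
    without stored direction tables.
    """
    p = points.copy()
    for _ in range(n_iter):
        diff_m = p[:, None, :] - p[None, :, :]
        diff_p = p[:, None, :] + p[None, :, :]
        dm = np.linalg.norm(diff_m, axis=-1)
        dp = np.linalg.norm(diff_p, axis=-1)
        np.fill_diagonal(dm, np.inf)
        np.fill_diagonal(dp, np.inf)
        force = (diff_m / dm[..., None] ** 3).sum(axis=1) + (
            diff_p / dp[..., None] ** 3
        ).sum(axis=1)
        # project onto tangent plane, take a bounded step
        force -= (force * p).sum(axis=1, keepdims=True) * p
        norm = np.linalg.norm(force, axis=1, keepdims=True)
        norm = np.maximum(norm, 1.0)
        p = p + step * force / norm * np.minimum(norm, 50.0)
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    # canonical hemisphere and ordering for reproducibility
    flip = p[:, 2] < 0
    p[flip] *= -1
    order = np.lexsort((p[:, 1], p[:, 0], -p[:, 2]))
    return p[order]


def make_scheme(n_directions: int, shells=(500.0, 1000.0, 2000.0)) -> GradientScheme:
    """Build a multi-shell scheme: one b=0 plus each shell over a shared
    electrostatic-repulsion direction set (deterministic given ``n_directions``).
    """
    if n_directions < 6:
        raise SchemeError(
            "at least 6 directions are required for the diffusion tensor"
        )
    dirs = _repel(_fibonacci_hemisphere(n_directions))
    shells = sorted(float(b) for b in shells)
    if any(b <= 0 for b in shells):
        raise SchemeError("shell b-values must be positive")
    bvals = [0.0]
    directions = [np.array([0.0, 0.0, 0.0])]
    for b in shells:
        bvals.extend([b] * n_directions)
        directions.extend(dirs)
    return GradientScheme(np.array(bvals), np.vstack(directions))


# ---------------------------------------------------------------------------
# forward models

def _directional_diffusivities(params: CompartmentParams, n: np.ndarray):
    n = np.atleast_2d(np.asarray(n, dtype=float))
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    # zero vectors only ever appear as b=0 placeholders; any unit stand-in works
    n = np.where(norm > 0, n / np.where(norm > 0, norm, 1.0), [1.0, 0.0, 0.0])
    ca = n @ params.axis
    Da_n = params.Da_axial * ca ** 2
    De_n = params.De_perp + (params.De_par - params.De_perp) * ca ** 2
    return Da_n, De_n


def forward_signal(params: CompartmentParams, scheme: GradientScheme) -> np.ndarray:
    """Exact biexponential stick-plus-zeppelin signal for every scheme entry."""
    Da_n, De_n = _directional_diffusivities(params, scheme.directions)
    b = scheme.bvalues
    s = params.S0 * (
        params.f * np.exp(-b * Da_n) + (1.0 - params.f) * np.exp(-b * De_n)
    )
    return s


def analytic_cumulants(params: CompartmentParams, direction) -> tuple:
    """Exact directional diffusivity and kurtosis of the two-compartment model.

    Returns ``(D_n, K_n)`` with D in mm^2/s and K dimensionless.  These are
    the second and (excess, scaled) fourth cumulants of the Gaussian-mixture
    displacement distribution projected on ``direction``.
    """
    Da_n, De_n = _directional_diffusivities(params, direction)
    f = params.f
    D_n = f * Da_n + (1.0 - f) * De_n
    scalar = D_n.size == 1
    with np.errstate(divide="ignore", invalid="ignore"):
        K_n = 3.0 * f * (1.0 - f) * (Da_n - De_n) ** 2 / D_n ** 2
    K_n = np.where((f == 0) | (Da_n == De_n), 0.0, K_n)
    undefined = (D_n <= 0) & (f * (1 - f) > 0) & (Da_n != De_n)
    if np.any(undefined):
        raise ZeroDivisionError(
            "kurtosis undefined: zero mean diffusivity with differing compartments"
        )
    if scalar:
        return float(D_n[0]), float(K_n[0])
    return D_n, K_n


def signal_from_cumulants(params: CompartmentParams, scheme: GradientScheme) -> np.ndarray:
    """Signal generated *exactly* from the truncated cumulant form,

        S = S0 exp(-b D(n) + b^2 D(n)^2 K(n) / 6),

    i.e. exactly within the 22-parameter DKI model class — no truncation
    error against the tensor fit (used for end-to-end exactness checks).
    """
    D_n, K_n = analytic_cumulants(params, scheme.directions)
    b = scheme.bvalues
    return params.S0 * np.exp(-b * D_n + b ** 2 * D_n ** 2 * K_n / 6.0)


# ---------------------------------------------------------------------------
# the study's printed summary statistics, used as simulation conditions
#
# Metric regime table: per (ROI, term status, group) means and SDs of the
# seven reported metrics, diffusivities in 1e-3 mm^2/s.  (The source tables
# print the diffusivity unit as "x10^-3 mm/s^2", an evident typographical
# variant of x10^-3 mm^2/s; and one SD — full-term control CC De_par — as
# 0.90 where every neighbouring value is ~0.1, read here as 0.09.)

TABLE_COVARIATES = {
    # (term_status, group): {covariate: (mean, sd)}
    ("preterm", "control"): {"GA_weeks": (35.87, 1.99), "PMA_weeks": (38.85, 2.31), "BW_grams": (2490, 505)},
    ("preterm", "simple_T2h"): {"GA_weeks": (35.21, 1.66), "PMA_weeks": (38.47, 1.39), "BW_grams": (2150, 469)},
    ("fullterm", "control"): {"GA_weeks": (39.75, 1.02), "PMA_weeks": (41.08, 1.36), "BW_grams": (3243, 545)},
    ("fullterm", "simple_T2h"): {"GA_weeks": (38.96, 1.45), "PMA_weeks": (40.44, 1.52), "BW_grams": (3136, 530)},
    ("fullterm", "complex_T2h_HIE"): {"GA_weeks": (39.20, 1.87), "PMA_weeks": (40.51, 2.01), "BW_grams": (3236, 498)},
}

_M = ("FA", "MD", "AD", "RD", "D_a", "De_par", "De_perp")


def _row(*vals):
    return {m: v for m, v in zip(_M, vals)}


TABLE_METRICS = {
    ("PLIC", "preterm", "control"): _row((0.38, 0.02), (1.16, 0.07), (1.68, 0.08), (0.90, 0.06), (1.06, 0.17), (1.93, 0.12), (1.09, 0.11)),
    ("PLIC", "preterm", "simple_T2h"): _row((0.37, 0.03), (1.18, 0.07), (1.70, 0.07), (0.92, 0.08), (1.21, 0.19), (1.95, 0.10), (1.08, 0.09)),
    ("PLIC", "fullterm", "control"): _row((0.39, 0.02), (1.14, 0.05), (1.67, 0.05), (0.87, 0.05), (1.04, 0.09), (1.93, 0.07), (1.07, 0.07)),
    ("PLIC", "fullterm", "simple_T2h"): _row((0.38, 0.03), (1.16, 0.05), (1.68, 0.05), (0.90, 0.06), (1.07, 0.17), (1.93, 0.08), (1.08, 0.09)),
    ("PLIC", "fullterm", "complex_T2h_HIE"): _row((0.33, 0.04), (1.21, 0.06), (1.68, 0.08), (0.97, 0.07), (0.87, 0.09), (1.94, 0.08), (1.19, 0.07)),
    ("SCR", "preterm", "control"): _row((0.22, 0.02), (1.41, 0.09), (1.75, 0.09), (1.24, 0.09), (1.21, 0.22), (1.95, 0.09), (1.40, 0.09)),
    ("SCR", "preterm", "simple_T2h"): _row((0.20, 0.03), (1.58, 0.11), (1.92, 0.10), (1.41, 0.12), (1.47, 0.30), (2.10, 0.10), (1.53, 0.12)),
    ("SCR", "fullterm", "control"): _row((0.25, 0.02), (1.35, 0.07), (1.72, 0.07), (1.16, 0.07), (1.18, 0.13), (1.91, 0.07), (1.34, 0.07)),
    ("SCR", "fullterm", "simple_T2h"): _row((0.22, 0.03), (1.46, 0.09), (1.80, 0.08), (1.28, 0.10), (1.31, 0.24), (1.98, 0.07), (1.45, 0.10)),
    ("SCR", "fullterm", "complex_T2h_HIE"): _row((0.20, 0.03), (1.51, 0.08), (1.83, 0.08), (1.35, 0.09), (1.03, 0.06), (2.03, 0.07), (1.53, 0.09)),
    ("CC", "preterm", "control"): _row((0.26, 0.02), (1.71, 0.06), (2.18, 0.06), (1.47, 0.06), (1.33, 0.15), (2.51, 0.11), (1.74, 0.08)),
    ("CC", "preterm", "simple_T2h"): _row((0.25, 0.01), (1.75, 0.06), (2.23, 0.07), (1.51, 0.07), (1.48, 0.24), (2.56, 0.13), (1.75, 0.08)),
    ("CC", "fullterm", "control"): _row((0.28, 0.02), (1.62, 0.06), (2.12, 0.07), (1.38, 0.06), (1.30, 0.11), (2.43, 0.09), (1.64, 0.07)),
    ("CC", "fullterm", "simple_T2h"): _row((0.26, 0.02), (1.68, 0.07), (2.15, 0.07), (1.44, 0.07), (1.36, 0.17), (2.43, 0.11), (1.68, 0.08)),
    ("CC", "fullterm", "complex_T2h_HIE"): _row((0.23, 0.03), (1.75, 0.08), (2.18, 0.08), (1.53, 0.09), (1.19, 0.15), (2.46, 0.08), (1.78, 0.09)),
    ("EC", "preterm", "control"): _row((0.21, 0.01), (1.29, 0.08), (1.57, 0.07), (1.15, 0.08), (1.21, 0.20), (1.73, 0.08), (1.27, 0.09)),
    ("EC", "preterm", "simple_T2h"): _row((0.20, 0.02), (1.38, 0.08), (1.67, 0.08), (1.24, 0.09), (1.39, 0.25), (1.83, 0.10), (1.35, 0.10)),
    ("EC", "fullterm", "control"): _row((0.23, 0.01), (1.24, 0.05), (1.54, 0.05), (1.09, 0.05), (1.18, 0.12), (1.70, 0.06), (1.22, 0.05)),
    ("EC", "fullterm", "simple_T2h"): _row((0.21, 0.02), (1.29, 0.07), (1.57, 0.06), (1.15, 0.08), (1.23, 0.22), (1.73, 0.07), (1.27, 0.09)),
    ("EC", "fullterm", "complex_T2h_HIE"): _row((0.19, 0.02), (1.36, 0.05), (1.62, 0.04), (1.23, 0.05), (1.08, 0.09), (1.79, 0.04), (1.37, 0.06)),
}

_SCALE = 1e-3  # printed diffusivities are in 1e-3 mm^2/s

_REGIME_AXES = {  # distinct fiber orientations per ROI so rotation code is exercised
    "PLIC": np.array([0.0, 0.0, 1.0]),
    "SCR": np.array([0.0, 1.0, 1.0]) / np.sqrt(2.0),
    "CC": np.array([1.0, 0.0, 0.0]),
    "EC": np.array([0.0, 1.0, 0.0]),
}


def _awf_from_row(MD, D_a, De_par, De_perp):
    """Solve the mixture-mean identity MD = [f*Da + (1-f)*tr(De)] / 3 for f."""
    tre3 = (De_par + 2.0 * De_perp) / 3.0
    return (tre3 - MD) / (tre3 - D_a / 3.0)


def default_regimes(term_status: str = "fullterm") -> dict:
    """Two-compartment ground-truth regimes per (group, ROI).

    Means come from the study's printed ROI tables.  Within each ROI the
    intra-axonal diffusivity of the simple-T2h regime is pinned to the
    control value, encoding the delayed-myelination hypothesis (extra-axonal
    change only); the HIE regime takes its own, lower D_a.  The AWF is back-
    computed from each row's MD via the mixture-mean identity since no f is
    printed.  Returns {group: {roi: TissueRegime}}.
    """
    groups = ["control", "simple_T2h"]
    if term_status == "fullterm":
        groups.append("complex_T2h_HIE")
    out: dict[str, dict[str, TissueRegime]] = {}
    for group in groups:
        out[group] = {}
        for roi in ("PLIC", "SCR", "CC", "EC"):
            row = TABLE_METRICS[(roi, term_status, group)]
            Da = (
                TABLE_METRICS[(roi, term_status, "control")]["D_a"][0]
                if group == "simple_T2h"
                else row["D_a"][0]
            )
            De_par, De_perp = row["De_par"][0], row["De_perp"][0]
            f = _awf_from_row(row["MD"][0], Da, De_par, De_perp)
            mean = CompartmentParams(
                f=float(f),
                Da_axial=Da * _SCALE,
                De_par=De_par * _SCALE,
                De_perp=De_perp * _SCALE,
                axis=_REGIME_AXES[roi],
            )
            sd = {
                "f": 0.02,
                "Da_axial": row["D_a"][1] * _SCALE,
                "De_par": row["De_par"][1] * _SCALE,
                "De_perp": row["De_perp"][1] * _SCALE,
            }
            out[group][roi] = TissueRegime(f"{group}:{roi}", mean, sd)
    return out


def covariate_params(term_status: str, group: str) -> dict:
    return TABLE_COVARIATES[(term_status, group)]


def metric_regimes(term_status: str = "fullterm") -> dict:
    """{group: {roi: {metric: (mean, sd)}}} on the printed 1e-3 mm^2/s scale."""
    out: dict = {}
    for (roi, term, group), row in TABLE_METRICS.items():
        if term != term_status:
            continue
        out.setdefault(group, {})[roi] = row
    return out


# ---------------------------------------------------------------------------
# image phantoms

def _add_rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator):
    """Magnitude-MRI noise: |signal + complex Gaussian|."""
    e1 = rng.standard_normal(signal.shape)
    e2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + sigma * e1) ** 2 + (sigma * e2) ** 2)


def generate_phantom(
    regimes,
    grid_shape,
    scheme: GradientScheme,
    snr: float | None = DEFAULT_SNR,
    seed: int = 0,
    signal_model: str = "compartment",
) -> tuple[DWIVolume, PhantomTruth]:
    """Render a block phantom: the grid is tiled along z into one slab per
    regime, each voxel carrying that regime's mean parameters.

    ``snr`` is S0 / sigma of the Rician noise; ``None`` (or ``numpy.inf``)
    yields noise-free signals.  ``signal_model`` selects the biexponential
    compartment model ("compartment") or the exact cumulant form
    ("cumulant", in-class for the DKI fit).
    """
    if isinstance(regimes, dict):
        regimes = list(regimes.values())
    regimes = list(regimes)
    if not regimes:
        raise ValueError("need at least one regime")
    if snr is not None and not np.isinf(snr) and snr <= 0:
        raise ValueError("snr must be positive")
    gen = {"compartment": forward_signal, "cumulant": signal_from_cumulants}[signal_model]

    shape = tuple(int(s) for s in grid_shape)
    labels = np.zeros(shape, dtype=np.int32)
    edges = np.linspace(0, shape[2], len(regimes) + 1).astype(int)
    truth = PhantomTruth(
        f=np.zeros(shape), Da_axial=np.zeros(shape), De_par=np.zeros(shape),
        De_perp=np.zeros(shape), axis=np.zeros(shape + (3,)),
        atlas=None, regimes=regimes,
    )
    signal = np.zeros(shape + (len(scheme),))
    for i, reg in enumerate(regimes):
        sl = np.s_[:, :, edges[i]: edges[i + 1]]
        labels[sl] = i + 1
        p = reg.param_mean
        signal[sl] = gen(p, scheme)
        truth.f[sl] = p.f
        truth.Da_axial[sl] = p.Da_axial
        truth.De_par[sl] = p.De_par
        truth.De_perp[sl] = p.De_perp
        truth.axis[sl] = p.axis
    truth.atlas = LabelAtlas(labels, {i + 1: r.name for i, r in enumerate(regimes)})

    if snr is not None and np.isfinite(snr):
        sigma = float(np.mean([r.param_mean.S0 for r in regimes])) / snr
        rng = np.random.default_rng(seed)
        signal = _add_rician_noise(signal, sigma, rng)
    dwi = DWIVolume(signal, scheme, mask=labels > 0)
    return dwi, truth


# ---------------------------------------------------------------------------
# cohorts

def _truncated_normal(rng, mean, sd, n, low=None, high=None):
    out = np.empty(n)
    todo = np.arange(n)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = np.ones(todo.size, bool)
        if low is not None:
            ok &= draw > low
        if high is not None:
            ok &= draw < high
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _draw_covariates(rng, term_status, group, n):
    cp = TABLE_COVARIATES[(term_status, group)]
    # GA and PMA drawn jointly, pair rejected while PMA < GA (the scan
    # happens after birth); the rejection shifts both marginal means a few
    # tenths of a week from the nominal targets
    ga = np.empty(n)
    pma = np.empty(n)
    for i in range(n):
        while True:
            g = rng.normal(*cp["GA_weeks"])
            p = rng.normal(*cp["PMA_weeks"])
            if 22.0 < g <= p:
                ga[i], pma[i] = g, p
                break
    bw = _truncated_normal(rng, *cp["BW_grams"], n, low=0.0)
    return ga, pma, bw


def generate_cohort(
    group_sizes: dict,
    seed: int,
    term_status: str = "fullterm",
    mode: str = "metric_level",
    regimes: dict | None = None,
    rois=("PLIC", "SCR", "CC", "EC"),
    metrics=("FA", "MD", "AD", "RD", "D_a", "De_par", "De_perp"),
    image_level_kwargs: dict | None = None,
):
    """Simulate a per-subject cohort table with the study's covariate and
    metric structure.

    ``metric_level`` draws each (ROI, metric) value from its regime Gaussian;
    ``image_level`` renders one small phantom per subject, runs the full
    fit + inversion chain and summarizes per ROI (slow; used for pipeline
    validation at reduced grids).  Diffusivity columns are on the printed
    1e-3 mm^2/s scale.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if regimes is None:
        regimes = metric_regimes(term_status) if mode == "metric_level" else default_regimes(term_status)
    rows = []
    sid = 0
    for group, n in group_sizes.items():
        if n <= 0:
            raise ValueError(f"group size must be positive, got {group}: {n}")
        if group not in regimes:
            raise KeyError(f"unknown regime/group name {group!r}")
        ga, pma, bw = _draw_covariates(rng, term_status, group, n)
        for i in range(n):
            row = {
                "subject_id": f"sub-{sid:03d}",
                "group": group,
                "term_status": term_status,
                "GA_weeks": round(float(ga[i]), 2),
                "PMA_weeks": round(float(pma[i]), 2),
                "BW_grams": round(float(bw[i]), 0),
            }
            if mode == "metric_level":
                for roi in rois:
                    dists = regimes[group][roi]
                    for metric in metrics:
                        if metric not in dists:
                            continue
                        m, s = dists[metric]
                        row[f"{roi}_{metric}"] = rng.normal(m, s)
            elif mode == "image_level":
                row.update(
                    _image_level_metrics(
                        regimes[group], rng, rois, **(image_level_kwargs or {})
                    )
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            rows.append(row)
            sid += 1
    return validate_cohort(pd.DataFrame(rows))


def _perturbed(reg: TissueRegime, rng) -> TissueRegime:
    p = reg.param_mean
    sd = reg.param_sd
    for _ in range(100):
        try:
            q = replace(
                p,
                f=float(np.clip(rng.normal(p.f, sd.get("f", 0.0)), 0.01, 0.95)),
                Da_axial=max(rng.normal(p.Da_axial, sd.get("Da_axial", 0.0)), 1e-5),
                De_par=max(rng.normal(p.De_par, sd.get("De_par", 0.0)), 1e-5),
                De_perp=max(rng.normal(p.De_perp, sd.get("De_perp", 0.0)), 1e-5),
            )
            return replace(reg, param_mean=q)
        except ValueError:  # ordering constraint violated by the draw; retry
            continue
    return reg


def _image_level_metrics(roi_regimes, rng, rois, grid_shape=(6, 6, 8), snr=DEFAULT_SNR):
    """Render one phantom for a subject and run the full estimation chain."""
    from .dki import DiffusionKurtosisModel
    from .stats import roi_summary
    from .wmti import WhiteMatterModel

    scheme = make_scheme(18)
    regs = [_perturbed(roi_regimes[r], rng) for r in rois]
    seed = int(rng.integers(2 ** 31))
    dwi, truth = generate_phantom(regs, grid_shape, scheme, snr=snr, seed=seed)
    fit = DiffusionKurtosisModel(dwi).fit()
    wm = WhiteMatterModel(fit).fit()
    scal = fit.scalar_maps()
    maps = {
        "FA": scal.FA, "MD": scal.MD / _SCALE, "AD": scal.AD / _SCALE,
        "RD": scal.RD / _SCALE, "D_a": wm.D_a / _SCALE,
        "De_par": wm.De_par / _SCALE, "De_perp": wm.De_perp / _SCALE,
    }
    atlas = LabelAtlas(truth.atlas.labels, {i + 1: r for i, r in enumerate(rois)})
    out = {}
    summ = roi_summary(maps, atlas)
    for _, r in summ.iterrows():
        out[f"{r['roi']}_{r['metric']}"] = r["mean"]
    return out
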