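"""Estimating Ising energies from measured curves and comparing models.

Force-distance fits run the full equilibrium engine inside a bounded
trust-region least-squares loop: the state space, folded extensions and
mechanical force/energy tables depend only on geometry and elasticity,
so they are computed once per fit problem and every parameter evaluation
only re-weights the configurations.  Model variants (homopolymer vs
heteropolymer helix, with or without next-nearest-neighbour coupling)
are ranked by the Gaussian-residual Akaike information criterion.
Chemical-denaturation curves are fitted globally across array lengths
with a repeat-level homopolymer chain and linear denaturant dependence
of the intrinsic energy.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .elasticity import ElasticNetwork
from .engine import EnsembleModel, ForceDistanceCurve
from .ising import (
    Approximation,
    HelixIsingParams,
    ModelVariant,
    RepeatParams,
    config_fold_energy,
    helix_params_from_repeat,
    total_free_energy,
)
from .presets import DEFAULT_HELIX_BIAS
from .synthetic import DenaturationCurve, denaturation_fraction_folded

#: the repeat-level reading of the helix energies recorded in fit reports
ENERGY_CONVENTION = "dG_unit = g_A + g_B + g_AB; dG_nn = g_BA"


@dataclass(frozen=True)
class FdcModelSpec:
    """What to fit: array size, state space, geometry, elasticity."""

    n_repeats: int
    geom: object
    network: ElasticNetwork
    variant: ModelVariant = ModelVariant.heteropolymer_helix
    approximation: Approximation = Approximation.zipper
    parameterization: str = "repeat"  # "repeat" or "helix"
    helix_bias: float = DEFAULT_HELIX_BIAS
    interface_split: float = 0.0
    flank_residues: int = 0

    def parameter_names(self) -> list[str]:
        if self.parameterization == "repeat":
            return ["dG_unit", "dG_nn"]
        if self.variant is ModelVariant.homopolymer_helix:
            return ["g", "g_nn"]
        names = ["g_A", "g_B", "g_AB", "g_BA"]
        if self.variant is ModelVariant.heteropolymer_helix_nnn:
            names += ["g_AA", "g_BB"]
        return names

    def params_from_vector(self, theta) -> HelixIsingParams:
        theta = np.asarray(theta, dtype=float)
        if self.parameterization == "repeat":
            return helix_params_from_repeat(
                RepeatParams(theta[0], theta[1], self.n_repeats),
                helix_bias=self.helix_bias,
                interface_split=self.interface_split,
            )
        if self.variant is ModelVariant.homopolymer_helix:
            return HelixIsingParams(
                theta[0], theta[0], theta[1], theta[1], model_variant=self.variant
            )
        g_aa, g_bb = (theta[4], theta[5]) if len(theta) == 6 else (0.0, 0.0)
        return HelixIsingParams(
            theta[0], theta[1], theta[2], theta[3], g_aa, g_bb, model_variant=self.variant
        )

    def default_x0(self) -> np.ndarray:
        if self.parameterization == "repeat":
            return np.array([0.0, -10.0])
        if self.variant is ModelVariant.homopolymer_helix:
            return np.array([5.0, -10.0])
        x0 = [5.0, 5.0, -10.0, -10.0]
        if self.variant is ModelVariant.heteropolymer_helix_nnn:
            x0 += [0.0, 0.0]
        return np.array(x0)

    def default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        k = len(self.parameter_names())
        return (np.full(k, -30.0), np.full(k, 30.0))


class FdcFitProblem:
    """Cached forward model of one FDC on its own separation grid."""

    def __init__(self, fdc: ForceDistanceCurve, spec: FdcModelSpec):
        self.spec = spec
        curve = fdc.sorted()
        self.separations = curve.separation
        self.observed = curve.force
        # weighted residuals when the curve carries per-point standard
        # errors (cycle averages do); the noise is strongly
        # heteroscedastic - plateau and dip fluctuate, branches do not -
        # and unweighted fits let flexible variants harvest the dip
        if curve.force_stderr is not None and np.any(curve.force_stderr > 1e-12):
            sigma = curve.force_stderr.copy()
            fill = np.median(sigma[sigma > 1e-12])
            self.sigma = np.where(sigma > 1e-12, sigma, fill)
        else:
            self.sigma = np.ones_like(self.observed)
        # any parameter values work here: only state geometry is reused
        placeholder = spec.params_from_vector(spec.default_x0())
        self.model = EnsembleModel(
            placeholder,
            spec.geom,
            spec.network,
            spec.n_repeats,
            spec.approximation,
            flank_residues=spec.flank_residues,
        )
        self.force_groups, energy = self.model.group_mechanics(self.separations)
        self._neg_energy_kt = -energy / spec.network.thermal_energy
        self._group_members = [
            np.flatnonzero(self.model.group_of_state == g)
            for g in range(self.model.n_groups)
        ]

    def model_force(self, theta) -> np.ndarray:
        params = self.spec.params_from_vector(theta)
        g_fold = np.atleast_1d(config_fold_energy(self.model.states, params))
        log_group = np.array(
            [logsumexp(-g_fold[m]) for m in self._group_members]
        )
        logw = log_group[:, None] + self._neg_energy_kt
        w = np.exp(logw - logsumexp(logw, axis=0))
        return np.sum(w * self.force_groups, axis=0)

    def residuals(self, theta) -> np.ndarray:
        return (self.model_force(theta) - self.observed) / self.sigma


@dataclass
class FdcFit:
    """Result of a force-distance fit."""

    spec: FdcModelSpec
    names: list[str]
    values: np.ndarray
    stderr: np.ndarray
    rss: float
    n_points: int
    n_params: int
    success: bool
    convention: str = ENERGY_CONVENTION

    @property
    def aic(self) -> float:
        return akaike_information(self.rss, self.n_points, self.n_params)

    @property
    def params(self) -> dict:
        return dict(zip(self.names, map(float, self.values)))

    @property
    def errors(self) -> dict:
        return dict(zip(self.names, map(float, self.stderr)))

    def repeat_params(self) -> RepeatParams:
        helix = self.spec.params_from_vector(self.values)
        return RepeatParams(
            helix.g_A + helix.g_B + helix.g_AB, helix.g_BA, self.spec.n_repeats
        )

    def to_dict(self) -> dict:
        return {
            "variant": self.spec.variant.value,
            "approximation": self.spec.approximation.value,
            "parameterization": self.spec.parameterization,
            "params": self.params,
            "stderr": self.errors,
            "rss": self.rss,
            "n_points": self.n_points,
            "aic": self.aic,
            "convention": self.convention,
        }


def akaike_information(rss: float, n: int, k: int) -> float:
    """Gaussian-residual AIC: n ln(RSS/n) + 2k."""
    if n <= 0 or rss <= 0:
        raise ValueError("need positive n and RSS")
    return float(n * np.log(rss / n) + 2 * k)


def _covariance(result) -> np.ndarray:
    jac = result.jac
    n, k = jac.shape
    dof = max(n - k, 1)
    s2 = 2.0 * result.cost / dof  # cost = RSS/2
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    return cov


def fit_fdc(
    fdc: ForceDistanceCurve,
    spec: FdcModelSpec,
    x0=None,
    bounds=None,
    fixed: dict | None = None,
) -> FdcFit:
    """Nonlinear least squares of the equilibrium model against one FDC.

    ``fixed`` maps parameter names to frozen values; the rest are fitted
    with a bounded trust-region algorithm.  Standard errors come from
    the residual-scaled curvature at the optimum.
    """
    problem = FdcFitProblem(fdc, spec)
    names = spec.parameter_names()
    x0_full = np.asarray(x0, dtype=float) if x0 is not None else spec.default_x0()
    lo_full, hi_full = bounds if bounds is not None else spec.default_bounds()
    fixed = fixed or {}
    free = [i for i, n in enumerate(names) if n not in fixed]
    if not free:
        raise ValueError("no free parameters")
    template = x0_full.copy()
    for i, n in enumerate(names):
        if n in fixed:
            template[i] = fixed[n]

    def expand(theta_free):
        theta = template.copy()
        theta[free] = theta_free
        return theta

    result = least_squares(
        lambda t: problem.residuals(expand(t)),
        x0=x0_full[free],
        bounds=(np.asarray(lo_full)[free], np.asarray(hi_full)[free]),
        method="trf",
        x_scale="jac",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    if not result.success:
        raise RuntimeError(f"FDC fit did not converge: {result.message}")
    values = expand(result.x)
    stderr = np.zeros(len(names))
    cov = _covariance(result)
    stderr_free = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    for j, i in enumerate(free):
        stderr[i] = stderr_free[j]
    rss = float(2.0 * result.cost)
    return FdcFit(
        spec=spec,
        names=names,
        values=values,
        stderr=stderr,
        rss=rss,
        n_points=len(problem.observed),
        n_params=len(free),
        success=True,
    )


def bootstrap_errors(
    fdc: ForceDistanceCurve,
    spec: FdcModelSpec,
    fit: FdcFit,
    n_boot: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Residual-bootstrap standard errors of the fitted parameters."""
    problem = FdcFitProblem(fdc, spec)
    model = problem.model_force(fit.values)
    residuals = problem.observed - model
    rng = np.random.default_rng(seed)
    draws = []
    lo, hi = spec.default_bounds()
    for _ in range(n_boot):
        resampled = model + rng.choice(residuals, size=residuals.size, replace=True)
        boot = least_squares(
            lambda t: (problem.model_force(t) - resampled) / problem.sigma,
            x0=fit.values,
            bounds=(lo, hi),
            method="trf",
        )
        draws.append(boot.x)
    return np.std(np.array(draws), axis=0, ddof=1)


def fit_variant_suite(
    fdc: ForceDistanceCurve,
    base_spec: FdcModelSpec,
    variants=(
        ModelVariant.homopolymer_helix,
        ModelVariant.heteropolymer_helix,
        ModelVariant.heteropolymer_helix_nnn,
    ),
) -> list[FdcFit]:
    """Fit nested helix-level variants with warm starts.

    A robust two-parameter repeat-level fit seeds the homopolymer helix
    fit, whose solution seeds the heteropolymer fit, whose solution seeds
    the next-nearest-neighbour fit; nested warm starts keep richer
    variants from losing to their own sub-model through a poor local
    optimum.
    """
    repeat_fit = fit_fdc(fdc, replace(base_spec, parameterization="repeat"))
    dgu, dgn = repeat_fit.values[0], repeat_fit.values[1]
    warm = {
        ModelVariant.homopolymer_helix: np.array([(dgu - dgn) / 2.0, dgn]),
    }
    fits = []
    for variant in variants:
        spec = replace(base_spec, variant=variant, parameterization="helix")
        if variant is ModelVariant.homopolymer_helix:
            x0 = warm[variant]
        elif variant is ModelVariant.heteropolymer_helix:
            g, gnn = warm[ModelVariant.homopolymer_helix]
            prev = next(
                (f for f in fits if f.spec.variant is ModelVariant.homopolymer_helix),
                None,
            )
            if prev is not None:
                g, gnn = prev.values
            x0 = np.array([g, g, gnn, gnn])
        else:  # nnn extends the heteropolymer solution
            prev = next(
                (f for f in fits if f.spec.variant is ModelVariant.heteropolymer_helix),
                None,
            )
            base = (
                prev.values
                if prev is not None
                else np.array([(dgu - dgn) / 2, (dgu - dgn) / 2, dgn, dgn])
            )
            x0 = np.concatenate([base, [0.0, 0.0]])
        fits.append(fit_fdc(fdc, spec, x0=x0))
    # back-projection pass: a nested sub-model can never fit worse than the
    # restriction of its super-model, so if it does the sub-model fit sat
    # on a degeneracy ridge - refit it from the projected solution
    order = {
        ModelVariant.homopolymer_helix: 0,
        ModelVariant.heteropolymer_helix: 1,
        ModelVariant.heteropolymer_helix_nnn: 2,
    }
    by_variant = {f.spec.variant: i for i, f in enumerate(fits)}
    for sub, sup, project in (
        (
            ModelVariant.heteropolymer_helix,
            ModelVariant.heteropolymer_helix_nnn,
            lambda v: v[:4],
        ),
        (
            ModelVariant.homopolymer_helix,
            ModelVariant.heteropolymer_helix,
            lambda v: np.array([(v[0] + v[1]) / 2.0, (v[2] + v[3]) / 2.0]),
        ),
    ):
        if sub in by_variant and sup in by_variant:
            i, j = by_variant[sub], by_variant[sup]
            if fits[i].rss > fits[j].rss * (1 + 1e-9):
                retry = fit_fdc(
                    fdc,
                    replace(base_spec, variant=sub, parameterization="helix"),
                    x0=project(fits[j].values),
                )
                if retry.rss < fits[i].rss:
                    fits[i] = retry
    return fits


def compare_models(fits: list[FdcFit]) -> pd.DataFrame:
    """Rank fits of the same data by AIC (ascending; best first)."""
    if not fits:
        raise ValueError("no fits to compare")
    n_points = {f.n_points for f in fits}
    if len(n_points) != 1:
        raise ValueError("fits must be on identical data (n_points differ)")
    rows = [
        {
            "variant": f.spec.variant.value,
            "parameterization": f.spec.parameterization,
            "k": f.n_params,
            "rss": f.rss,
            "aic": f.aic,
        }
        for f in fits
    ]
    table = pd.DataFrame(rows).sort_values("aic", ignore_index=True)
    table["delta_aic"] = table["aic"] - table["aic"].iloc[0]
    return table


@dataclass
class DenaturationFit:
    """Global chemical-denaturation fit across array lengths."""

    dG_unit_water: float
    m_unit: float
    dG_nn: float
    baselines: dict[int, dict[str, float]]
    stderr: dict[str, float]
    rss: float
    n_points: int

    def total_free_energy(self, n_repeats: int) -> float:
        return total_free_energy(
            RepeatParams(self.dG_unit_water, self.dG_nn, n_repeats)
        )


def fit_denaturation(curves: list[DenaturationCurve], x0=None) -> DenaturationFit:
    """Global Ising fit of denaturation curves of several array lengths.

    Shared parameters: intrinsic repeat energy in water, its linear
    denaturant dependence (m-value, destabilising) and the
    denaturant-independent coupling; per-curve linear folded/unfolded
    baselines.  A single length leaves dG_unit and dG_nn degenerate, so
    at least two lengths are required (a warning-grade degeneracy the
    caller must avoid).
    """
    if len(curves) < 2:
        raise ValueError(
            "need curves for >= 2 array lengths; with one length dG_unit "
            "and dG_nn are degenerate"
        )
    lengths = [c.n_repeats for c in curves]

    def unpack(theta):
        dg, m, gnn = theta[:3]
        baselines = theta[3:].reshape(len(curves), 4)
        return dg, m, gnn, baselines

    def residuals(theta):
        dg, m, gnn, baselines = unpack(theta)
        out = []
        for curve, (bf, sf, bu, su) in zip(curves, baselines):
            theta_f = denaturation_fraction_folded(
                dg, m, gnn, curve.n_repeats, curve.denaturant
            )
            model = (bf + sf * curve.denaturant) * theta_f + (
                bu + su * curve.denaturant
            ) * (1 - theta_f)
            out.append(model - curve.signal)
        return np.concatenate(out)

    if x0 is None:
        base = []
        for c in curves:
            base += [float(c.signal[0]), 0.0, float(c.signal[-1]), 0.0]
        x0 = np.array([0.0, 1.5, -8.0] + base)
    k = len(x0)
    lo = np.full(k, -np.inf)
    hi = np.full(k, np.inf)
    lo[1] = 0.0  # m-value destabilises
    result = least_squares(residuals, x0=x0, bounds=(lo, hi), method="trf")
    if not result.success:
        raise RuntimeError(f"denaturation fit did not converge: {result.message}")
    dg, m, gnn, baselines = unpack(result.x)
    cov = _covariance(result)
    err = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    return DenaturationFit(
        dG_unit_water=float(dg),
        m_unit=float(m),
        dG_nn=float(gnn),
        baselines={
            n: dict(zip(["folded_intercept", "folded_slope", "unfolded_intercept", "unfolded_slope"], map(float, b)))
            for n, b in zip(lengths, baselines)
        },
        stderr={"dG_unit_water": float(err[0]), "m_unit": float(err[1]), "dG_nn": float(err[2])},
        rss=float(2.0 * result.cost),
        n_points=int(sum(len(c.signal) for c in curves)),
    )
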