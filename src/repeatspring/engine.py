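"""Equilibrium force-distance curves and configuration ensembles.

For a fixed trap separation d each fold configuration c stores the total
free energy

    E(c, d) = G_fold(c) * kT + G_mech(c, d),

where G_fold is the Ising fold energy (kT units) and G_mech the work held
in traps, handle and unfolded chain at the tension F*(c, d) that balances
the serial network, with the folded remainder contributing its superhelix
chord to the extension budget.  Boltzmann weighting over an enumerated
configuration set then yields the average force at every separation (the
theoretical FDC), per-helix fold probabilities, ranked configuration
snapshots, and the zero-crossing statistics of the unfolded state (seed
size).

States sharing unfolded contour length and folded extension are
mechanically identical, so all Boltzmann sums are collapsed onto those
groups; a 26-repeat zipper ensemble costs tens of groups rather than
thousands of states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .elasticity import ElasticNetwork, MechanicalTable, series_force_balance, stretch_free_energy
from .ising import (
    Approximation,
    Configuration,
    HelixIsingParams,
    RESIDUES_PER_HELIX,
    RESIDUES_PER_REPEAT,
    RepeatParams,
    config_fold_energy,
    enumerate_configurations,
    segment_ranges,
)
from .superhelix import BeadsOnString, beads_on_string_extension, extension_for_configuration, folded_extension


@dataclass
class ForceDistanceCurve:
    """Paired trap-separation / force arrays with sweep metadata."""

    separation: np.ndarray
    force: np.ndarray
    pulling_speed: float | None = None
    cycle: int | None = None
    direction: str | None = None
    force_stderr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.separation.shape != self.force.shape:
            raise ValueError("separation and force must have equal length")
        if self.force_stderr is not None:
            self.force_stderr = np.asarray(self.force_stderr, dtype=float)
            if self.force_stderr.shape != self.force.shape:
                raise ValueError("force_stderr must match force length")

    def __len__(self) -> int:
        return len(self.separation)

    def sorted(self) -> "ForceDistanceCurve":
        order = np.argsort(self.separation)
        return ForceDistanceCurve(
            self.separation[order],
            self.force[order],
            self.pulling_speed,
            self.cycle,
            self.direction,
            None if self.force_stderr is None else self.force_stderr[order],
        )


@dataclass
class EnsembleSnapshot:
    """Ranked configuration ensemble at one trap separation."""

    trap_separation: float
    configurations: list[tuple[str, float]]
    helix_fold_probability: np.ndarray
    p_unfolded: float

    def to_dict(self) -> dict:
        return {
            "trap_separation_nm": self.trap_separation,
            "p_unfolded": self.p_unfolded,
            "configurations": [
                {"fold_state": s, "probability": p} for s, p in self.configurations
            ],
            "helix_fold_probability": list(map(float, self.helix_fold_probability)),
        }


class EnsembleModel:
    """Configuration ensemble of one repeat array in one elastic network.

    Enumerates the state space once, precomputes fold energies, folded
    extensions and unfolded contour lengths, and groups mechanically
    equivalent states.  All separation-dependent quantities are then
    obtained from the dense mechanical table.
    """

    def __init__(
        self,
        params: HelixIsingParams,
        geom,
        network: ElasticNetwork,
        n_repeats: int,
        approximation=Approximation.zipper,
        flank_residues: int = 0,
        table: MechanicalTable | None = None,
    ):
        if n_repeats < 0:
            raise ValueError("n_repeats must be >= 0")
        self.params = params
        self.geom = geom
        self.network = network
        self.n_repeats = n_repeats
        self.approximation = Approximation(approximation)
        # a RepeatParams instance selects the repeat-level lattice
        # (homopolymer repeat model): one two-state unit per repeat
        self.repeat_units = isinstance(params, RepeatParams)
        if self.repeat_units:
            self.n_units = n_repeats
            residues_per_unit = RESIDUES_PER_REPEAT
        else:
            self.n_units = 2 * n_repeats
            residues_per_unit = RESIDUES_PER_HELIX
        self.n_helices = self.n_units  # lattice size (helices or repeats)
        self.table = table if table is not None else MechanicalTable(network)

        if n_repeats == 0:
            self.states = np.zeros((1, 0), dtype=np.uint8)
            self.g_fold = np.zeros(1)
            self.xi = np.zeros(1)
        else:
            self.states = enumerate_configurations(self.n_units, self.approximation)
            self.g_fold = np.atleast_1d(self._fold_energies(self.states, params))
            self.xi = np.atleast_1d(self._folded_extensions(self.states, geom))
        n_folded = self.states.sum(axis=1).astype(int)
        self.n_folded = n_folded
        self.contour_unfolded = (
            (self.n_units - n_folded) * residues_per_unit + flank_residues
        ) * network.nm_per_residue

        # mechanical groups: identical (contour, xi) -> identical F(d), E(d)
        keys = np.stack(
            [np.round(self.contour_unfolded, 9), np.round(self.xi, 9)], axis=1
        )
        _, group_index, inverse = np.unique(
            keys, axis=0, return_index=True, return_inverse=True
        )
        self.group_of_state = inverse
        self.group_contour = self.contour_unfolded[group_index]
        self.group_xi = self.xi[group_index]
        self.group_n_folded = n_folded[group_index].astype(float)
        self.n_groups = len(group_index)

        # per-group Boltzmann fold-weight sums, kept in log space: the fold
        # energies span hundreds of kT, so raw exponentials over/underflow
        self.log_group_weight = np.empty(self.n_groups)
        self.group_helix_fraction = np.zeros((self.n_groups, self.n_helices))
        for g in range(self.n_groups):
            members = np.flatnonzero(inverse == g)
            logs = -self.g_fold[members]
            self.log_group_weight[g] = logsumexp(logs)
            w = np.exp(logs - logs.max())
            self.group_helix_fraction[g] = (
                w @ self.states[members].astype(float)
            ) / w.sum()
        # index of the fully unfolded state's group (n_folded == 0)
        unf = np.flatnonzero(self.group_n_folded == 0)
        self._unfolded_group = int(unf[0]) if len(unf) else None

    def _fold_energies(self, states, params):
        if not self.repeat_units:
            return config_fold_energy(states, params)
        energy = states.sum(axis=1).astype(float) * float(params.dG_unit)
        if states.shape[1] > 1:
            adj = (states[:, :-1] * states[:, 1:]).sum(axis=1).astype(float)
            energy = energy + adj * float(params.dG_nn)
        return energy

    def _folded_extensions(self, states, geom):
        if not self.repeat_units:
            return extension_for_configuration(states, geom)
        if isinstance(geom, BeadsOnString):
            return np.atleast_1d(
                beads_on_string_extension(
                    states.sum(axis=1), geom.n_total_helices, geom.xi_max
                )
            )
        # repeat units span whole repeats along the superhelical arc
        n = states.shape[1]
        chord_by_len = folded_extension(np.arange(n + 1, dtype=float), geom)
        out = np.zeros(states.shape[0])
        for i, row in enumerate(states):
            for start, stop in segment_ranges(row):
                out[i] += chord_by_len[stop - start]
        return out

    # -- mechanics ---------------------------------------------------------

    def group_mechanics(self, separations):
        """Balanced force and stored energy per group: (n_groups, n_d)."""
        separations = np.asarray(separations, dtype=float)
        F = np.empty((self.n_groups, separations.size))
        E = np.empty_like(F)
        for g in range(self.n_groups):
            F[g], E[g] = self.table.solve(
                separations, self.group_contour[g], self.group_xi[g]
            )
        return F, E

    def _log_group_weights(self, separations):
        """log of unnormalised group Boltzmann weights at each separation."""
        F, E = self.group_mechanics(separations)
        kt = self.network.thermal_energy
        logw = self.log_group_weight[:, None] - E / kt
        return logw, F

    # -- observables -------------------------------------------------------

    def force_curve(self, separations, method: str = "average") -> ForceDistanceCurve:
        """Equilibrium FDC over a separation grid.

        ``method='average'`` Boltzmann-averages the per-configuration
        balanced forces; ``method='derivative'`` differentiates the total
        system free energy -kT ln Z with respect to separation.  The two
        agree at equilibrium on dense grids.
        """
        separations = np.asarray(separations, dtype=float)
        if np.any(np.diff(separations) <= 0):
            raise ValueError("separations must be strictly increasing")
        logw, F = self._log_group_weights(separations)
        if method == "average":
            logz = logsumexp(logw, axis=0)
            w = np.exp(logw - logz)
            force = np.sum(w * F, axis=0)
        elif method == "derivative":
            kt = self.network.thermal_energy
            free_energy = -kt * logsumexp(logw, axis=0)
            force = np.gradient(free_energy, separations)
        else:
            raise ValueError("method must be 'average' or 'derivative'")
        return ForceDistanceCurve(separations, force, direction="model")

    def force_statistics(self, separations):
        """Ensemble mean and variance of the balanced force at each separation.

        The variance is the equilibrium force fluctuation of the
        configuration mixture (large on plateau and dip, where states of
        different extension coexist; near zero on the pure WLC branches).
        """
        logw, F = self._log_group_weights(separations)
        logz = logsumexp(logw, axis=0)
        w = np.exp(logw - logz)
        mean = np.sum(w * F, axis=0)
        var = np.sum(w * (F - mean) ** 2, axis=0)
        return mean, var

    def plateau_window(self, separations, p_unfolded_max: float = 0.5) -> np.ndarray:
        """Boolean mask of the sequential-unfolding plateau region.

        The plateau spans separations where unfolding is in progress (at
        least one helix predominantly unzipped) but the terminal dip has
        not yet been reached; the dip's characteristic point is where the
        fully unfolded conformation holds half the population.
        """
        separations = np.asarray(separations, dtype=float)
        nbar = self.helix_fold_profile(separations).sum(axis=0)
        punf = self.p_unfolded(separations)
        return (nbar <= self.n_helices - 1) & (punf < p_unfolded_max)

    def helix_fold_profile(self, separations) -> np.ndarray:
        """P(helix folded) matrix, shape (n_helices, n_separations).

        Rows are ordered C-terminal helix first (index 0).
        """
        logw, _ = self._log_group_weights(separations)
        logz = logsumexp(logw, axis=0)
        w = np.exp(logw - logz)  # (n_groups, n_d)
        return self.group_helix_fraction.T @ w

    def p_unfolded(self, separations) -> np.ndarray:
        """Probability of the fully unfolded configuration."""
        separations = np.atleast_1d(np.asarray(separations, dtype=float))
        logw, _ = self._log_group_weights(separations)
        logz = logsumexp(logw, axis=0)
        if self._unfolded_group is None:
            return np.zeros(separations.size)
        # the unfolded state is alone in its group and has g_fold = 0, so
        # its log weight is just -E_g/kT
        g = self._unfolded_group
        log_state = logw[g] - self.log_group_weight[g]
        return np.exp(log_state - logz)

    def snapshot(self, trap_separation: float, k: int = 10) -> EnsembleSnapshot:
        """Top-k configurations and helix marginals at one separation."""
        if k < 1:
            raise ValueError("k must be >= 1")
        d = np.array([float(trap_separation)])
        logw, _ = self._log_group_weights(d)
        logz = float(logsumexp(logw[:, 0]))
        # per-state log weights: -g_fold - E_group/kT
        mech_log = logw[self.group_of_state, 0] - self.log_group_weight[
            self.group_of_state
        ]
        probs = np.exp(-self.g_fold + mech_log - logz)
        # rank by probability; ties by n_folded descending, then
        # lexicographic fold-state string (C terminus first)
        lex = self.states.astype(np.float64) @ (
            2.0 ** np.arange(self.n_helices - 1, -1, -1)
        )
        order = np.lexsort((lex, -self.n_folded, -probs))
        ranked = [
            (Configuration(self.states[i]).to_string(), float(probs[i]))
            for i in order[:k]
        ]
        marginals = self.states.T.astype(float) @ probs
        p_unf = float(probs[self.n_folded == 0][0]) if np.any(self.n_folded == 0) else 0.0
        return EnsembleSnapshot(float(trap_separation), ranked, marginals, p_unf)

    def unfolded_crossing(
        self, d_lo: float | None = None, d_hi: float | None = None, tol: float = 0.01
    ) -> float:
        """Separation where the fully unfolded state reaches P = 0.5."""
        if self._unfolded_group is None:
            raise RuntimeError("model has no fully unfolded state")
        lo, hi = self.default_separation_span()
        d_lo = lo if d_lo is None else d_lo
        d_hi = hi if d_hi is None else d_hi

        def gap(d):
            return float(self.p_unfolded([d])[0]) - 0.5

        g_lo, g_hi = gap(d_lo), gap(d_hi)
        if g_lo * g_hi > 0:
            raise RuntimeError(
                "P(unfolded) = 0.5 is not bracketed in "
                f"[{d_lo:.1f}, {d_hi:.1f}] nm (values {g_lo + 0.5:.3g}, {g_hi + 0.5:.3g})"
            )
        return brentq(gap, d_lo, d_hi, xtol=tol)

    def seed_size(self, tol: float = 0.01) -> float:
        """Mean folded-helix count of the folded ensemble at the 50% point.

        At the separation where the fully unfolded state is half the
        population, returns the expectation of n_folded over all other
        (folded) configurations - the size of the marginally stable
        ensemble that exchanges with the unfolded state at the force dip.
        """
        d_star = self.unfolded_crossing(tol=tol)
        logw, _ = self._log_group_weights(np.array([d_star]))
        w = np.exp(logw[:, 0] - logsumexp(logw[:, 0]))
        folded = np.ones(self.n_groups, dtype=bool)
        if self._unfolded_group is not None:
            folded[self._unfolded_group] = False
        return float(
            np.sum(w[folded] * self.group_n_folded[folded]) / np.sum(w[folded])
        )

    # -- grids -------------------------------------------------------------

    def default_separation_span(
        self, f_onset: float = 1.0, f_max: float = 25.0
    ) -> tuple[float, float]:
        """Separation window from folded-branch onset to unfolded f_max."""
        table = self.table
        folded = np.flatnonzero(self.group_n_folded == self.group_n_folded.max())[0]
        s_folded = (
            table.fixed_extension
            + self.group_contour[folded] * table.chain_fraction
            + self.group_xi[folded]
        )
        d_lo = float(np.interp(f_onset, table.force_grid, s_folded))
        contour_max = float(self.contour_unfolded.max())
        s_unfolded = table.fixed_extension + contour_max * table.chain_fraction
        d_hi = float(np.interp(f_max, table.force_grid, s_unfolded))
        return d_lo, d_hi

    def default_separations(self, step: float = 0.25, **kwargs) -> np.ndarray:
        lo, hi = self.default_separation_span(**kwargs)
        return np.arange(lo, hi, step)


def configuration_total_energy(
    config,
    trap_separation: float,
    params: HelixIsingParams,
    geom,
    network: ElasticNetwork,
    flank_residues: int = 0,
) -> float:
    """Total stored free energy (pN*nm) of one configuration at one separation.

    Fold free energy plus the work held in traps, handle and unfolded
    chain at the balanced tension.  Solved with the exact bracketed root
    finder rather than the tabulated fast path.
    """
    config = config if isinstance(config, Configuration) else Configuration(config)
    g_fold = config_fold_energy(config, params)
    xi = extension_for_configuration(config, geom)
    n_unfolded_res = (
        len(config.fold_state) - config.n_folded
    ) * RESIDUES_PER_HELIX + flank_residues
    contour = n_unfolded_res * network.nm_per_residue
    force = series_force_balance(trap_separation, network, xi, contour)
    mech = 0.0
    for element in network.elements(contour):
        if getattr(element, "contour_length", None) == 0:
            continue
        mech += float(stretch_free_energy(force, element))
    return g_fold * network.thermal_energy + mech


def equilibrium_fdc(
    params: HelixIsingParams,
    geom,
    network: ElasticNetwork,
    separations,
    approximation=Approximation.zipper,
    n_repeats: int | None = None,
    method: str = "average",
    **model_kwargs,
) -> ForceDistanceCurve:
    """Equilibrium force-distance curve of an N-repeat array."""
    model = EnsembleModel(
        params, geom, network, _infer_n(n_repeats), approximation, **model_kwargs
    )
    return model.force_curve(separations, method=method)


def _infer_n(n_repeats):
    if n_repeats is None:
        raise ValueError("n_repeats is required")
    return int(n_repeats)


def ensemble_snapshot(
    params,
    geom,
    network,
    trap_separation: float,
    approximation=Approximation.skip,
    k: int = 10,
    n_repeats: int | None = None,
    **model_kwargs,
) -> EnsembleSnapshot:
    """Top-k configuration ensemble at one separation (skip by default)."""
    model = EnsembleModel(
        params, geom, network, _infer_n(n_repeats), approximation, **model_kwargs
    )
    return model.snapshot(trap_separation, k=k)


def seed_size(
    params,
    geom,
    network,
    approximation=Approximation.skip,
    n_repeats: int | None = None,
    **model_kwargs,
) -> float:
    """Average folded-helix count where P(fully unfolded) = 50%."""
    model = EnsembleModel(
        params, geom, network, _infer_n(n_repeats), approximation, **model_kwargs
    )
    return model.seed_size()


def helix_fold_profile(
    params,
    geom,
    network,
    separations,
    approximation=Approximation.zipper,
    n_repeats: int | None = None,
    **model_kwargs,
) -> np.ndarray:
    """Fold-probability matrix (helix x separation), C-terminal row first."""
    model = EnsembleModel(
        params, geom, network, _infer_n(n_repeats), approximation, **model_kwargs
    )
    return model.helix_fold_profile(separations)


def simulate_apparatus_stiffness(
    params,
    geom,
    stiff_network: ElasticNetwork,
    n_repeats: int = 5,
    separations=None,
    approximation=Approximation.zipper,
    **model_kwargs,
) -> ForceDistanceCurve:
    """FDC of the same protein in a stiffer apparatus (AFM-like regime).

    With a compliant dumbbell the repeats unfold at a flat equilibrium
    plateau; when the apparatus stiffness is raised ~100-fold the ensemble
    re-equilibrates locally and every repeat unfolds with its own force
    peak, reproducing the sawtooth pattern familiar from AFM.
    """
    model = EnsembleModel(
        params, geom, stiff_network, n_repeats, approximation, **model_kwargs
    )
    if separations is None:
        separations = model.default_separations(step=0.1)
    return model.force_curve(separations)
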