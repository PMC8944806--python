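"""Polymer elasticity and the serial force balance of the tweezers dumbbell.

The passive mechanical elements of a dual-trap optical tweezers assay are
modelled here: the two harmonic traps, the double-stranded DNA handle
(extensible worm-like chain), the unfolded polypeptide (inextensible
worm-like chain) and a rigid extension standing in for the folded part of
the protein.  At mechanical equilibrium all elements in series carry the
same tension, and their extensions add up to the trap separation.  The
module provides force-extension laws, their inversions, stretching free
energies (the work stored in each element at a given tension) and a
bracketed root finder for the common tension at a given trap separation.

Units follow single-molecule conventions throughout: lengths in nm, forces
in pN, energies in pN*nm.  The thermal energy defaults to kT = 4.114 pN*nm
(25 C).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import brentq

KT_ROOM = 4.114
"""Thermal energy at 25 C in pN*nm."""

#: default bracket (pN) for tension root finding
_FORCE_BRACKET = (0.0, 200.0)
_FORCE_TOL = 1e-6


@dataclass(frozen=True)
class WormLikeChain:
    """Inextensible worm-like chain (Marko-Siggia interpolation).

    Parameters
    ----------
    persistence_length : float
        Bending persistence length in nm (> 0).
    contour_length : float
        Contour length in nm (>= 0).
    thermal_energy : float
        kT in pN*nm.
    """

    persistence_length: float
    contour_length: float
    thermal_energy: float = KT_ROOM

    def __post_init__(self) -> None:
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.contour_length < 0:
            raise ValueError("contour_length must be >= 0")
        if self.thermal_energy <= 0:
            raise ValueError("thermal_energy must be > 0")

    def force(self, extension):
        return wlc_force(extension, self)

    def extension(self, force):
        return wlc_extension(force, self)

    def stretch_energy(self, force):
        return stretch_free_energy(force, self)


@dataclass(frozen=True)
class ExtensibleWormLikeChain(WormLikeChain):
    """Worm-like chain with a linear enthalpic stretch term.

    The extension at tension F is the inextensible-chain extension plus
    (F / stretch_modulus) * contour_length, the standard eWLC used for
    double-stranded DNA handles.
    """

    stretch_modulus: float = 1200.0

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.stretch_modulus <= 0:
            raise ValueError("stretch_modulus must be > 0")

    def extension(self, force):
        return ewlc_extension(force, self)

    def force(self, extension):
        return _invert_extension(extension, self)

    def stretch_energy(self, force):
        return stretch_free_energy(force, self)


@dataclass(frozen=True)
class HarmonicElement:
    """Hookean element (an optical trap): extension = force / stiffness."""

    stiffness: float

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise ValueError("stiffness must be > 0")

    def extension(self, force):
        force = _check_nonneg_force(force)
        return force / self.stiffness

    def force(self, extension):
        return np.asarray(extension, dtype=float) * self.stiffness

    def stretch_energy(self, force):
        force = _check_nonneg_force(force)
        return force**2 / (2.0 * self.stiffness)


@dataclass(frozen=True)
class ElasticNetwork:
    """Serial arrangement of the dumbbell's passive elements.

    Two traps, one handle and the unfolded-polypeptide chain law.  The
    chain's contour length is configuration dependent, so the network
    stores only its persistence length and contour-per-residue; the folded
    part of the protein enters as a rigid extension term in the balance.
    """

    trap_stiffness: float = 0.30
    handle: ExtensibleWormLikeChain = field(
        default_factory=lambda: ExtensibleWormLikeChain(
            persistence_length=40.0, contour_length=350.0, stretch_modulus=1200.0
        )
    )
    chain_persistence_length: float = 0.9
    nm_per_residue: float = 0.365
    thermal_energy: float = KT_ROOM

    @property
    def traps(self) -> tuple[HarmonicElement, HarmonicElement]:
        k = HarmonicElement(self.trap_stiffness)
        return (k, k)

    def chain(self, contour_length: float) -> WormLikeChain:
        return WormLikeChain(
            persistence_length=self.chain_persistence_length,
            contour_length=contour_length,
            thermal_energy=self.thermal_energy,
        )

    def elements(self, unfolded_contour: float):
        return (*self.traps, self.handle, self.chain(unfolded_contour))

    def stiffened(self, factor: float) -> "ElasticNetwork":
        """Network with every compliant element stiffened by ``factor``.

        Trap stiffness and the handle stretch modulus are multiplied by
        ``factor`` and the handle persistence length is raised (shortening
        the entropic compliance) to emulate a stiff AFM-like apparatus.
        """
        if factor < 1:
            raise ValueError("stiffening factor must be >= 1")
        handle = replace(
            self.handle,
            stretch_modulus=self.handle.stretch_modulus * factor,
            persistence_length=self.handle.persistence_length * factor,
            contour_length=self.handle.contour_length / factor,
        )
        return replace(self, trap_stiffness=self.trap_stiffness * factor, handle=handle)

    @classmethod
    def from_config(cls, config: dict) -> "ElasticNetwork":
        """Build a network from flat config keys.

        Recognised keys: ``kT_pNnm``, ``trap_stiffness_pN_per_nm``,
        ``handle.Lc_nm``, ``handle.Lp_nm``, ``handle.K_pN``,
        ``chain.Lp_nm``, ``chain.nm_per_residue``.  Nested dicts
        (``{"handle": {"Lc_nm": ...}}``) are accepted as well.
        """
        flat = _flatten(config)
        kt = float(flat.get("kT_pNnm", KT_ROOM))
        handle = ExtensibleWormLikeChain(
            persistence_length=float(flat.get("handle.Lp_nm", 40.0)),
            contour_length=float(flat.get("handle.Lc_nm", 350.0)),
            stretch_modulus=float(flat.get("handle.K_pN", 1200.0)),
            thermal_energy=kt,
        )
        return cls(
            trap_stiffness=float(flat.get("trap_stiffness_pN_per_nm", 0.30)),
            handle=handle,
            chain_persistence_length=float(flat.get("chain.Lp_nm", 0.9)),
            nm_per_residue=float(flat.get("chain.nm_per_residue", 0.365)),
            thermal_energy=kt,
        )


def _flatten(config: dict, prefix: str = "") -> dict:
    out = {}
    for key, value in config.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, prefix=f"{name}."))
        else:
            out[name] = value
    return out


def _check_nonneg_force(force):
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("force must be >= 0")
    return force


def wlc_force(extension, chain: WormLikeChain):
    """Marko-Siggia interpolation tension of an inextensible WLC.

    F(x) = (kT/Lp) * [ 1/(4 (1 - x/Lc)^2) - 1/4 + x/Lc ]

    Strictly increasing in extension with F(0) = 0; extensions at or
    beyond the contour length are a domain error.
    """
    extension = np.asarray(extension, dtype=float)
    if np.any(extension < 0):
        raise ValueError("extension must be >= 0")
    if np.any(extension >= chain.contour_length):
        raise ValueError("extension must be < contour_length")
    x = extension / chain.contour_length
    scale = chain.thermal_energy / chain.persistence_length
    result = scale * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
    return result if result.ndim else float(result)


def wlc_extension_fraction(force, persistence_length, thermal_energy=KT_ROOM):
    """Fractional extension x/Lc of a Marko-Siggia WLC at a given tension.

    Inverted numerically by bracketed root finding; vectorised over
    ``force``.  This is the contour-length-independent quantity that makes
    the chain extension linear in Lc.
    """
    force = _check_nonneg_force(force)
    scalar = force.ndim == 0
    f = np.atleast_1d(force)
    scale = thermal_energy / persistence_length
    out = np.empty_like(f)
    for i, fi in enumerate(f):
        if fi == 0:
            out[i] = 0.0
            continue
        # F is strictly increasing in x on [0, 1)
        out[i] = brentq(
            lambda x: scale * (0.25 / (1.0 - x) ** 2 - 0.25 + x) - fi,
            0.0,
            1.0 - 1e-9,
            xtol=1e-12,
        )
    return float(out[0]) if scalar else out


def _fraction_table(force, persistence_length, thermal_energy):
    """Vectorised Marko-Siggia inversion by interpolation on a dense x grid.

    Accurate to ~1e-9 in x; used for the pre-tabulated mechanics where a
    per-point root find would dominate the runtime.
    """
    x = np.concatenate(
        [
            np.linspace(0.0, 0.98, 20000, endpoint=False),
            1.0 - np.geomspace(0.02, 1e-10, 20000),
        ]
    )
    scale = thermal_energy / persistence_length
    fx = scale * (0.25 / (1.0 - x) ** 2 - 0.25 + x)
    return np.interp(force, fx, x)


def wlc_extension(force, chain: WormLikeChain):
    """Extension of an inextensible WLC at tension ``force`` (nm)."""
    frac = wlc_extension_fraction(
        force, chain.persistence_length, chain.thermal_energy
    )
    return frac * chain.contour_length


def ewlc_extension(force, chain: ExtensibleWormLikeChain):
    """Extension of an extensible WLC: entropic part plus F/K * Lc."""
    force = _check_nonneg_force(force)
    frac = wlc_extension_fraction(
        force, chain.persistence_length, chain.thermal_energy
    )
    return chain.contour_length * (frac + force / chain.stretch_modulus)


def _invert_extension(extension, element, bracket=_FORCE_BRACKET):
    """Tension at which ``element.extension`` equals ``extension``."""
    extension = np.asarray(extension, dtype=float)
    scalar = extension.ndim == 0
    ext = np.atleast_1d(extension)
    out = np.empty_like(ext)
    for i, xi in enumerate(ext):
        if xi <= 0:
            out[i] = 0.0
            continue
        out[i] = brentq(
            lambda F: float(element.extension(F)) - xi,
            bracket[0],
            bracket[1],
            xtol=_FORCE_TOL,
        )
    return float(out[0]) if scalar else out


def stretch_free_energy(force, element, n_quad: int = 4001):
    """Work stored in an element held at tension ``force`` (pN*nm).

    Computed as the quadrature integral of F dx from zero extension to the
    extension at ``force``; equivalently F*x(F) - integral of x dF.  For a
    harmonic element this reduces to F^2 / (2 k) exactly.
    """
    force = _check_nonneg_force(force)
    if isinstance(element, HarmonicElement):
        return element.stretch_energy(force)
    scalar = force.ndim == 0
    f = np.atleast_1d(force)
    out = np.empty_like(f)
    for i, fi in enumerate(f):
        if fi == 0:
            out[i] = 0.0
            continue
        grid = np.linspace(0.0, fi, n_quad)
        x = np.asarray(element.extension(grid))
        out[i] = fi * x[-1] - np.trapezoid(x, grid)
    return float(out[0]) if scalar else out


def series_force_balance(
    trap_separation: float,
    network: ElasticNetwork,
    folded_extension: float = 0.0,
    unfolded_contour: float = 0.0,
    tol: float = _FORCE_TOL,
) -> float:
    """Common tension of all elements at a given trap separation.

    Finds the unique F* with
    sum_elements extension(F*) + folded_extension = trap_separation
    by bracketed root finding on [0, 200] pN.  Separations at or below the
    slack point (folded extension alone) return exactly 0.

    Raises
    ------
    ValueError
        If the separation is below the folded extension.
    RuntimeError
        If no bracket is found (separation beyond the 200 pN envelope);
        the message carries the diagnostic state.
    """
    if trap_separation < folded_extension:
        raise ValueError("trap_separation must be >= folded_extension")
    elements = network.elements(unfolded_contour)

    def gap(F: float) -> float:
        total = folded_extension
        for el in elements:
            if isinstance(el, WormLikeChain) and el.contour_length == 0:
                continue
            total += float(el.extension(F))
        return total - trap_separation

    if gap(0.0) >= 0.0:
        return 0.0
    lo, hi = _FORCE_BRACKET
    if gap(hi) < 0.0:
        raise RuntimeError(
            "no tension bracket in [0, 200] pN for "
            f"separation={trap_separation} nm, folded={folded_extension} nm, "
            f"unfolded contour={unfolded_contour} nm"
        )
    force = brentq(gap, lo, hi, xtol=tol)
    # below-slack separations: residual tensions under 1e-3 pN are
    # indistinguishable from a slack tether
    return 0.0 if force < 1e-3 else force


class MechanicalTable:
    """Pre-tabulated force-extension-energy relations of the fixed elements.

    The trap-plus-handle extension and stored energy are functions of the
    tension alone, and the unfolded chain contributes contour-length times
    a tabulated fractional extension (and energy per nm of contour).  The
    total extension at tension F is therefore

        s(F) = a(F) + Lc_unfolded * b(F) + xi_folded,

    monotone in F, which the ensemble engine inverts for thousands of
    configurations at once by interpolation on a dense grid.
    """

    def __init__(self, network: ElasticNetwork, f_max: float = 200.0, n_grid: int = 40001):
        self.network = network
        self.force_grid = np.linspace(0.0, f_max, n_grid)
        F = self.force_grid
        trap_ext = 2.0 * F / network.trap_stiffness
        handle_frac = _fraction_table(
            F, network.handle.persistence_length, network.handle.thermal_energy
        )
        handle_ext = network.handle.contour_length * (
            handle_frac + F / network.handle.stretch_modulus
        )
        self.fixed_extension = trap_ext + handle_ext
        self.chain_fraction = _fraction_table(
            F, network.chain_persistence_length, network.thermal_energy
        )
        # stored energy: W(F) = F x(F) - int_0^F x dF'
        self.fixed_energy = F * self.fixed_extension - cumulative_trapezoid(
            self.fixed_extension, F, initial=0.0
        )
        self.chain_energy_per_nm = F * self.chain_fraction - cumulative_trapezoid(
            self.chain_fraction, F, initial=0.0
        )

    def solve(self, separations, unfolded_contour: float, folded_extension: float):
        """Tension and stored mechanical energy at each separation.

        Returns ``(force, energy)`` arrays; below the slack separation both
        are exactly zero.
        """
        separations = np.asarray(separations, dtype=float)
        s = (
            self.fixed_extension
            + unfolded_contour * self.chain_fraction
            + folded_extension
        )
        force = np.interp(separations, s, self.force_grid)
        energy = np.interp(
            force,
            self.force_grid,
            self.fixed_energy + unfolded_contour * self.chain_energy_per_nm,
        )
        return force, energy
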