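"""Synthetic instrument data with known ground truth.

Emulates what the optical tweezers record for a repeat array at
equilibrium: repeated stretch/relax force-distance cycles consisting of
the model equilibrium force plus (i) instrument noise, (ii) thermal force
fluctuations of the configuration mixture - largest on the plateau and
dip, where states of different extension exchange - and (iii) per-cycle
rigid force/distance offsets that mimic calibration drift between
molecules/cycles.  Also generates ensemble chemical-denaturation curves
(fraction folded of the repeat-level Ising chain mapped through sloping
baselines).  Everything is driven by one seeded generator, so identical
seeds give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .elasticity import ElasticNetwork
from .engine import EnsembleModel, ForceDistanceCurve
from .ising import Approximation, HelixIsingParams, RepeatParams, repeat_partition_statistics


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise description for synthetic FDC cycles.

    instrument_sigma : measurement noise floor (pN).
    thermal_from_stiffness : add the equilibrium force variance of the
        configuration mixture on top of the instrument floor.
    cycle_force_sigma / cycle_distance_sigma : per-cycle rigid offsets
        (pN, nm) drawn once per cycle.
    """

    instrument_sigma: float = 0.3
    thermal_from_stiffness: bool = True
    seed: int = 0
    cycle_force_sigma: float = 0.2
    cycle_distance_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.instrument_sigma < 0:
            raise ValueError("instrument_sigma must be >= 0")


def generate_fdc_cycles(
    params: HelixIsingParams,
    geom,
    network: ElasticNetwork,
    noise: NoiseModel,
    n_repeats: int,
    n_cycles: int = 30,
    pulling_speed: float = 10.0,
    separations=None,
    approximation=Approximation.zipper,
    model: EnsembleModel | None = None,
) -> list[ForceDistanceCurve]:
    """Stretch and relax FDC cycles of one synthetic molecule.

    Returns 2*n_cycles curves (stretch then relax per cycle).  At the
    pulling speeds modelled here the system is at equilibrium, so stretch
    and relax share the same underlying curve and differ only in noise.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if model is None:
        model = EnsembleModel(params, geom, network, n_repeats, approximation)
    if separations is None:
        separations = model.default_separations(step=0.5)
    separations = np.asarray(separations, dtype=float)
    mean, var = model.force_statistics(separations)
    sigma = np.sqrt(
        noise.instrument_sigma**2
        + (var if noise.thermal_from_stiffness else 0.0)
    )
    rng = np.random.default_rng(noise.seed)
    cycles: list[ForceDistanceCurve] = []
    for c in range(n_cycles):
        df = rng.normal(0.0, noise.cycle_force_sigma)
        dd = rng.normal(0.0, noise.cycle_distance_sigma)
        for direction in ("stretch", "relax"):
            f = mean + rng.normal(0.0, 1.0, size=separations.size) * sigma + df
            d = separations + dd
            if direction == "relax":
                d, f = d[::-1], f[::-1]
            cycles.append(
                ForceDistanceCurve(d, f, pulling_speed, cycle=c, direction=direction)
            )
    return cycles


@dataclass
class DenaturationCurve:
    """Normalised ensemble signal vs denaturant for one array length."""

    n_repeats: int
    denaturant: np.ndarray
    signal: np.ndarray


def denaturation_fraction_folded(
    dG_unit_water: float, m_unit: float, dG_nn: float, n_repeats: int, denaturant
) -> np.ndarray:
    """Fraction of folded repeats vs denaturant concentration.

    Repeat-level homopolymer Ising chain whose intrinsic energy rises
    linearly with denaturant, dG_unit(D) = dG_unit(water) + m_unit * D
    (m_unit >= 0 destabilises); the coupling is denaturant independent.
    """
    denaturant = np.asarray(denaturant, dtype=float)
    out = np.empty_like(denaturant)
    for i, conc in enumerate(denaturant):
        rp = RepeatParams(dG_unit_water + m_unit * conc, dG_nn, n_repeats)
        _, frac = repeat_partition_statistics(rp)
        out[i] = frac
    return out


DEFAULT_BASELINES = {"folded": (1.0, -0.01), "unfolded": (0.05, 0.005)}


def generate_denaturation(
    dG_unit_water: float,
    m_unit: float,
    dG_nn: float,
    lengths,
    denaturant=None,
    sigma: float = 0.0,
    seed: int = 0,
    baselines: dict | None = None,
) -> list[DenaturationCurve]:
    """Synthetic chemical-denaturation curves for several array lengths.

    The observable is baseline_folded(D) * theta + baseline_unfolded(D)
    * (1 - theta) with linear (intercept, slope) baselines, plus Gaussian
    noise of standard deviation ``sigma``.
    """
    if not len(lengths):
        raise ValueError("lengths must be non-empty")
    if denaturant is None:
        denaturant = np.arange(0.0, 6.01, 0.25)
    denaturant = np.asarray(denaturant, dtype=float)
    baselines = baselines or DEFAULT_BASELINES
    bf, sf = baselines["folded"]
    bu, su = baselines["unfolded"]
    rng = np.random.default_rng(seed)
    curves = []
    for n in lengths:
        theta = denaturation_fraction_folded(dG_unit_water, m_unit, dG_nn, int(n), denaturant)
        signal = (bf + sf * denaturant) * theta + (bu + su * denaturant) * (1 - theta)
        if sigma > 0:
            signal = signal + rng.normal(0.0, sigma, size=signal.size)
        curves.append(DenaturationCurve(int(n), denaturant.copy(), signal))
    return curves
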