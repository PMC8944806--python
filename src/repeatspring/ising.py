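"""Nearest-neighbour Ising energetics of helical repeat arrays.

A consensus TPR array of N repeats is a lattice of 2N helix units (each
repeat contributes an A and a B helix).  A configuration assigns each helix
folded (1) or unfolded (0); an unfolded helix contributes zero free energy,
a folded helix its intrinsic energy, and every pair of adjacent folded
helices an interfacial energy.  Helices are indexed from the C terminus
(index 0 = C-terminal B helix), so even indices are B helices and odd
indices A helices, and the interface between helices j and j+1 is the
intra-repeat A-B interface for even j and the inter-repeat B-A interface
for odd j.

All energies are folding free energies in units of kT (folded minus
unfolded; negative = stable).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

RESIDUES_PER_REPEAT = 34
RESIDUES_PER_HELIX = 17

#: largest helix count for exhaustive (full / skip) enumeration
FULL_ENUMERATION_CAP = 24

NO_STABLE_UNIT = -1
"""Sentinel returned by :func:`minimal_stable_unit` when no block is stable."""


class ModelVariant(str, enum.Enum):
    homopolymer_repeat = "homopolymer_repeat"
    homopolymer_helix = "homopolymer_helix"
    heteropolymer_helix = "heteropolymer_helix"
    heteropolymer_helix_nnn = "heteropolymer_helix_nnn"


class Approximation(str, enum.Enum):
    full = "full"
    skip = "skip"
    zipper = "zipper"


@dataclass(frozen=True)
class HelixIsingParams:
    """Intrinsic and interfacial helix free energies (kT).

    ``g_A``/``g_B`` are the intrinsic energies of the A and B helices,
    ``g_AB`` the intra-repeat interface, ``g_BA`` the inter-repeat
    interface; ``g_AA``/``g_BB`` are the optional next-nearest-neighbour
    couplings used only by the ``heteropolymer_helix_nnn`` variant.
    """

    g_A: float
    g_B: float
    g_AB: float
    g_BA: float
    g_AA: float = 0.0
    g_BB: float = 0.0
    model_variant: ModelVariant = ModelVariant.heteropolymer_helix

    def intrinsic_energies(self, n_helices: int) -> np.ndarray:
        """Per-helix intrinsic energies, C terminus first (even = B)."""
        g = np.empty(n_helices)
        g[0::2] = self.g_B
        g[1::2] = self.g_A
        return g

    def interface_energies(self, n_helices: int) -> np.ndarray:
        """Energies of the n-1 nearest-neighbour interfaces."""
        gi = np.empty(max(n_helices - 1, 0))
        gi[0::2] = self.g_AB
        gi[1::2] = self.g_BA
        return gi


@dataclass(frozen=True)
class RepeatParams:
    """Repeat-level Ising parameters (kT).

    ``dG_unit`` is the intrinsic free energy of one repeat, ``dG_nn`` the
    coupling between adjacent folded repeats.  Both signs occur in
    practice: consensus arrays combine marginally (un)stable repeats with
    strongly stabilising interfaces.
    """

    dG_unit: float
    dG_nn: float
    N_repeats: int = 1


@dataclass(frozen=True)
class Configuration:
    """Binary fold state of all helices, C-terminal helix first."""

    fold_state: np.ndarray

    def __post_init__(self) -> None:
        state = np.asarray(self.fold_state, dtype=np.uint8)
        if state.ndim != 1 or not np.all((state == 0) | (state == 1)):
            raise ValueError("fold_state must be a 1-d 0/1 vector")
        object.__setattr__(self, "fold_state", state)

    @property
    def n_folded(self) -> int:
        return int(self.fold_state.sum())

    @property
    def folded_segments(self) -> list[tuple[int, int]]:
        """Maximal folded runs as (start, stop) index ranges (stop exclusive)."""
        return segment_ranges(self.fold_state)

    def to_string(self) -> str:
        return "".join("1" if s else "0" for s in self.fold_state)

    @classmethod
    def from_string(cls, text: str) -> "Configuration":
        return cls(np.array([int(c) for c in text], dtype=np.uint8))


def segment_ranges(fold_state: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[0], np.asarray(fold_state, dtype=np.int8), [0]])
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _as_state_matrix(configs) -> np.ndarray:
    if isinstance(configs, Configuration):
        return configs.fold_state[None, :]
    arr = np.asarray(configs, dtype=np.uint8)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def config_fold_energy(config, params: HelixIsingParams):
    """Fold free energy (kT) of one or many helix configurations.

    Sum of intrinsic energies of folded helices plus interface energies of
    adjacent folded pairs (plus next-nearest-neighbour terms for the nnn
    variant).  The all-unfolded state is the zero of energy.
    """
    states = _as_state_matrix(config)
    n = states.shape[1]
    if n % 2 != 0:
        raise ValueError("helix count must be even (A/B pairs per repeat)")
    g = params.intrinsic_energies(n)
    gi = params.interface_energies(n)
    energy = states @ g + (states[:, :-1] * states[:, 1:]) @ gi
    if params.model_variant is ModelVariant.heteropolymer_helix_nnn and n >= 3:
        pair = states[:, :-2] * states[:, 2:]
        gnnn = np.empty(n - 2)
        gnnn[0::2] = params.g_BB  # even j with even j+2: B-B
        gnnn[1::2] = params.g_AA
        energy = energy + pair @ gnnn
    return float(energy[0]) if isinstance(config, Configuration) or np.asarray(
        config
    ).ndim == 1 else energy


def repeat_params_from_helix(params: HelixIsingParams, n_repeats: int = 1) -> RepeatParams:
    """Collapse helix-level energies to repeat-level (dG_unit, dG_nn).

    Adopted decomposition: dG_unit = g_A + g_B + g_AB (one repeat fully
    folded in isolation) and dG_nn = g_BA (the inter-repeat interface).
    """
    return RepeatParams(
        dG_unit=params.g_A + params.g_B + params.g_AB,
        dG_nn=params.g_BA,
        N_repeats=n_repeats,
    )


def helix_params_from_repeat(
    rp: RepeatParams,
    helix_bias: float = 0.0,
    interface_split: float = 0.0,
    model_variant: ModelVariant = ModelVariant.heteropolymer_helix,
) -> HelixIsingParams:
    """Distribute repeat-level energies over helices.

    The uniform-interface split assigns every adjacent-helix interface the
    repeat coupling (g_AB = g_BA = dG_nn) and splits the remainder evenly
    over the two helices: g_A = g_B = (dG_unit - dG_nn)/2.  Two optional
    asymmetries refine it without changing the repeat-level energies under
    the adopted convention (dG_unit = g_A + g_B + g_AB, dG_nn = g_BA):

    ``helix_bias`` shifts the intrinsic energies antisymmetrically
    (g_B = mean + bias, g_A = mean - bias); a positive value makes the
    exposed C-terminal B helix the least stable unit, which breaks the
    C/N symmetry of the unfolding pathway.

    ``interface_split`` weakens the intra-repeat interface relative to
    the inter-repeat one (g_AB = dG_nn + split) while the intrinsic
    energies compensate so dG_unit is preserved; a nonzero split makes
    the helix chain observably heteropolymeric (even/odd alternation of
    unzipping costs) rather than degenerate with a homopolymer chain.
    """
    g_ab = rp.dG_nn + interface_split
    mean = (rp.dG_unit - g_ab) / 2.0
    return HelixIsingParams(
        g_A=mean - helix_bias,
        g_B=mean + helix_bias,
        g_AB=g_ab,
        g_BA=rp.dG_nn,
        model_variant=model_variant,
    )


def total_free_energy(rp: RepeatParams, n_repeats: int | None = None) -> float:
    """Total fold free energy of an N-repeat array: N dG_unit + (N-1) dG_nn."""
    n = rp.N_repeats if n_repeats is None else n_repeats
    if n < 1:
        raise ValueError("N_repeats must be >= 1")
    return n * rp.dG_unit + (n - 1) * rp.dG_nn


def fraction_unfolded(dG_fold: float) -> float:
    """Unfolded population of a two-state unit with fold energy dG_fold (kT).

    P_unfolded = 1 / (1 + exp(-dG_fold)); a marginally stable repeat
    (dG_fold = -1.9 kT) is ~13% unfolded at equilibrium.
    """
    return 1.0 / (1.0 + np.exp(-float(dG_fold)))


def minimal_stable_unit(params: HelixIsingParams, max_helices: int = 64) -> int:
    """Smallest number of consecutive folded helices with negative energy.

    Scans contiguous blocks of increasing length m (over both frame
    alignments, A-first and B-first) and returns the first m whose fold
    energy is below zero; returns :data:`NO_STABLE_UNIT` if no block up to
    ``max_helices`` is stable.
    """
    lattice = 2 * ((max_helices + 1) // 2) + 2
    g = params.intrinsic_energies(lattice)
    gi = params.interface_energies(lattice)
    for m in range(1, max_helices + 1):
        best = np.inf
        for start in (0, 1):
            stop = start + m
            if stop > lattice:
                continue
            e = g[start:stop].sum() + gi[start : stop - 1].sum()
            best = min(best, e)
        if best < 0:
            return m
    return NO_STABLE_UNIT


def _zipper_states(n: int) -> np.ndarray:
    states = [np.zeros(n, dtype=np.uint8)]
    for length in range(1, n + 1):
        for start in range(0, n - length + 1):
            s = np.zeros(n, dtype=np.uint8)
            s[start : start + length] = 1
            states.append(s)
    return np.array(states)


def _skip_states(n: int) -> np.ndarray:
    """Enumerate skip-approximation states by depth-first construction.

    A state is admitted unless it contains a maximal folded run of length
    1 or 2 that touches neither end of the array (an isolated short
    island).  Terminal short runs survive, so end-unzipped intermediates
    are retained while transient internal nuclei are pruned; the state
    count grows like 1.62^n instead of 2^n.
    """
    states: list[list[int]] = []
    prefix: list[int] = []

    def recurse(i: int, run: int) -> None:
        if i == n:
            states.append(prefix.copy())
            return
        # place an unfolded helix: closes any current run
        if run == 0 or run >= 3 or run == i:  # run == i -> run touches start
            prefix.append(0)
            recurse(i + 1, 0)
            prefix.pop()
        # place a folded helix
        prefix.append(1)
        recurse(i + 1, run + 1)
        prefix.pop()

    recurse(0, 0)
    return np.array(states, dtype=np.uint8)


def enumerate_configurations(n_helices: int, approximation=Approximation.full) -> np.ndarray:
    """All fold states of an n-helix lattice under a state-space restriction.

    Returns a (n_states, n_helices) 0/1 matrix, C-terminal helix in
    column 0.  ``full`` is every one of the 2^n states; ``zipper`` keeps
    the empty state plus every single contiguous folded block
    (n(n+1)/2 + 1 states); ``skip`` removes from the full set every state
    containing an internal folded run of length 1 or 2 (see
    :func:`_skip_states`).

    Full and skip enumeration are capped at 24 helices; longer arrays
    must use the zipper approximation.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    approximation = Approximation(approximation)
    if approximation is Approximation.zipper:
        return _zipper_states(n_helices)
    if n_helices > FULL_ENUMERATION_CAP:
        raise ValueError(
            f"{approximation.value} enumeration is capped at "
            f"{FULL_ENUMERATION_CAP} helices; use the zipper approximation "
            "for longer arrays"
        )
    if approximation is Approximation.full:
        codes = np.arange(2**n_helices, dtype=np.uint64)
        return (
            (codes[:, None] >> np.arange(n_helices, dtype=np.uint64)) & 1
        ).astype(np.uint8)
    return _skip_states(n_helices)


def repeat_partition_statistics(
    rp: RepeatParams, n_repeats: int | None = None
) -> tuple[float, float]:
    """Zero-force partition function and mean folded fraction.

    Repeat-level homopolymer Ising chain evaluated by transfer matrix;
    returns (ln Z, <n_folded>/N).  Used by the chemical-denaturation
    model, where each repeat is the two-state unit.
    """
    n = rp.N_repeats if n_repeats is None else n_repeats
    if n < 1:
        raise ValueError("N_repeats must be >= 1")
    w = np.exp(-rp.dG_unit)
    c = np.exp(-rp.dG_nn)
    # transfer matrix over (previous state) with numerical scaling
    log_scale = 0.0
    # state vectors: z[s], m[s] = sum over states ending in s of (weight * n_folded)
    z = np.array([1.0, w])  # first repeat: unfolded, folded
    m = np.array([0.0, w])
    for _ in range(1, n):
        z_new = np.array([z[0] + z[1], w * (z[0] + c * z[1])])
        m_new = np.array(
            [m[0] + m[1], w * (m[0] + c * m[1]) + w * (z[0] + c * z[1])]
        )
        scale = z_new.max()
        z, m = z_new / scale, m_new / scale
        log_scale += np.log(scale)
    Z = z.sum()
    mean_n = m.sum() / Z
    return float(np.log(Z) + log_scale), float(mean_n / n)
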