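"""End-to-end extension of the folded part of a repeat-protein superhelix.

Stacked TPR repeats trace a circular helix (the superhelix) with a rise
and an azimuthal phase advance per repeat.  Under tension the folded
remainder contributes its end-to-end chord, not its arc length, to the
pulling axis; as repeats unfold one by one the chord shortens
non-monotonically (flattening once per superhelical turn), which is what
imprints periodic force oscillations on the unfolding plateau.  A
beads-on-a-string alternative - extension simply proportional to the
folded fraction - is provided as the rejected reference model that
produces a featureless plateau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ising import Configuration, segment_ranges, _as_state_matrix


@dataclass(frozen=True)
class SuperhelixGeometry:
    """Circular-helix parameters of the folded array.

    radius and rise_per_repeat in nm, phase_per_repeat in degrees
    (360 / repeats-per-turn), terminal_offset the rigid end-to-end
    contribution of the termini/attachment geometry in nm.

    The radius is that of the helix traced by the repeat centroids (the
    path the pulled termini sit on), not the outer envelope of the
    solenoid: adjacent repeat centroids in a TPR stack are ~1.0-1.1 nm
    apart, which with ~8 repeats per turn fixes the centroid radius near
    1 nm even though the solenoid is several nm wide.
    """

    radius: float = 1.0
    rise_per_repeat: float = 0.90
    phase_per_repeat: float = 45.0
    terminal_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.rise_per_repeat <= 0:
            raise ValueError("rise_per_repeat must be > 0")
        if not 0 < self.phase_per_repeat <= 360:
            raise ValueError("phase_per_repeat must be in (0, 360]")


#: CTPRa geometry: ~8 repeats per superhelical turn (2HYZ-like solenoid)
CTPRA_GEOMETRY = SuperhelixGeometry()

#: CTPRrv geometry: wider, shorter superhelix (interface redesign)
CTPRRV_GEOMETRY = SuperhelixGeometry(radius=1.3, rise_per_repeat=0.80)

GEOMETRY_PRESETS = {"ctpra": CTPRA_GEOMETRY, "ctprrv": CTPRRV_GEOMETRY}


def folded_extension(folded_repeat_equivalents, geom: SuperhelixGeometry):
    """Chord length of a helical arc spanning m repeats (m may be fractional).

    sqrt((m * rise)^2 + (2 R sin(m * phi / 2))^2) + terminal_offset for
    m > 0; exactly zero for m = 0.  A lone folded helix counts as half a
    repeat.
    """
    m = np.asarray(folded_repeat_equivalents, dtype=float)
    if np.any(m < 0):
        raise ValueError("folded repeat count must be >= 0")
    phi = np.deg2rad(geom.phase_per_repeat)
    chord = np.sqrt(
        (m * geom.rise_per_repeat) ** 2
        + (2.0 * geom.radius * np.sin(m * phi / 2.0)) ** 2
    )
    out = chord + np.where(m > 0, geom.terminal_offset, 0.0)
    return float(out) if out.ndim == 0 else out


def beads_on_string_extension(n_folded, n_total: int, xi_max: float):
    """Folded extension proportional to the folded fraction.

    xi = (n_folded / n_total) * xi_max.  This is the geometry-free
    alternative that reproduces the final force dip but flattens the
    plateau; it is kept for model comparison.
    """
    if n_total == 0:
        raise ValueError("n_total must be > 0")
    n = np.asarray(n_folded, dtype=float)
    out = n / n_total * xi_max
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BeadsOnString:
    """Drop-in replacement for the superhelix geometry in the FDC engine."""

    n_total_helices: int
    xi_max: float


def extension_for_configuration(config, geom) -> np.ndarray:
    """End-to-end folded extension of one or many configurations (nm).

    Each maximal folded segment is an independent helical arc whose chord
    is given by :func:`folded_extension` with helices counted as half
    repeats; segments add.  With a :class:`BeadsOnString` geometry the
    extension is proportional to the total folded helix count instead.
    """
    states = _as_state_matrix(config)
    scalar = isinstance(config, Configuration) or np.asarray(config).ndim == 1
    if isinstance(geom, BeadsOnString):
        out = beads_on_string_extension(
            states.sum(axis=1), geom.n_total_helices, geom.xi_max
        )
        out = np.atleast_1d(out)
        return float(out[0]) if scalar else out
    n = states.shape[1]
    # chord for every possible segment length (in helices)
    chord_by_len = folded_extension(np.arange(n + 1) / 2.0, geom)
    out = np.zeros(states.shape[0])
    for i, row in enumerate(states):
        for start, stop in segment_ranges(row):
            out[i] += chord_by_len[stop - start]
    return float(out[0]) if scalar else out
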