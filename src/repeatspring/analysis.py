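"""Turning raw stretch/relax cycles into equilibrium observables.

Repeated pulling cycles at low speed are binned into one equilibrium FDC
per molecule, aligned against each other in force and distance to remove
common instrumental offsets, and reduced to scalar observables: the
plateau force (Gaussian fit to the force histogram of the plateau
window), the protein's unfolding work W_F (area between the measured
curve and the always-unfolded reference), and the contour-length gain of
full unfolding (composite worm-like-chain fits before and after the
transition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit, least_squares, minimize
from scipy.signal import find_peaks

from .elasticity import ElasticNetwork, MechanicalTable
from .engine import ForceDistanceCurve


def average_cycles(cycles, bin_width: float = 1.0) -> ForceDistanceCurve:
    """Bin repeated stretch/relax cycles into one equilibrium FDC.

    All samples from all cycles and both sweep directions are pooled and
    averaged in separation bins of ``bin_width`` nm; empty bins are
    dropped.  Each bin also records the standard error of its mean force
    (``force_stderr``), which downstream fits use as weights.
    """
    if not cycles:
        raise ValueError("need at least one cycle")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    sep = np.concatenate([c.separation for c in cycles])
    force = np.concatenate([c.force for c in cycles])
    edges = np.arange(sep.min(), sep.max() + bin_width, bin_width)
    idx = np.digitize(sep, edges) - 1
    counts = np.bincount(idx, minlength=len(edges))
    sums_f = np.bincount(idx, weights=force, minlength=len(edges))
    sums_d = np.bincount(idx, weights=sep, minlength=len(edges))
    sums_f2 = np.bincount(idx, weights=force**2, minlength=len(edges))
    keep = counts > 0
    n = counts[keep]
    mean_f = sums_f[keep] / n
    var = np.clip(sums_f2[keep] / n - mean_f**2, 0.0, np.inf)
    stderr = np.where(n > 1, np.sqrt(var / np.maximum(n - 1, 1)), np.nan)
    if np.any(np.isfinite(stderr)):
        fill = np.nanmedian(stderr)
        stderr = np.where(np.isfinite(stderr), stderr, fill)
    else:
        stderr = None
    return ForceDistanceCurve(
        sums_d[keep] / n, mean_f, direction="average", force_stderr=stderr
    ).sorted()


def _alignment_cost(curve, reference, df, dd):
    lo = max(reference.separation.min(), curve.separation.min() + dd)
    hi = min(reference.separation.max(), curve.separation.max() + dd)
    if hi <= lo:
        return None
    mask = (reference.separation >= lo) & (reference.separation <= hi)
    if mask.sum() < 3:
        return None
    d = reference.separation[mask]
    f_interp = np.interp(d - dd, curve.separation, curve.force) + df
    return float(np.sum((f_interp - reference.force[mask]) ** 2))


def align_fdcs(
    fdcs,
    force_range: float = 1.5,
    distance_range: float = 6.0,
    force_step: float = 0.05,
    distance_step: float = 0.5,
    reference: ForceDistanceCurve | None = None,
):
    """Rigid (force, distance) offsets aligning each curve to the first.

    Returns one ``(force_offset, distance_offset)`` pair per curve (the
    reference gets (0, 0)); adding the offsets to a curve superimposes it
    on the reference.  A coarse grid search over +-force_range pN and
    +-distance_range nm is refined by local optimisation.  An external
    ``reference`` curve (e.g. a pooled average) may replace the first
    curve as the target; every input is then aligned against it.
    """
    external_ref = reference is not None
    if not external_ref and len(fdcs) < 2:
        raise ValueError("need at least two curves to align")
    reference = (reference if external_ref else fdcs[0]).sorted()
    offsets = [] if external_ref else [(0.0, 0.0)]
    for curve in fdcs if external_ref else fdcs[1:]:
        curve = curve.sorted()
        best = None
        for dd in np.arange(-distance_range, distance_range + 1e-9, distance_step):
            for df in np.arange(-force_range, force_range + 1e-9, force_step):
                cost = _alignment_cost(curve, reference, df, dd)
                if cost is not None and (best is None or cost < best[0]):
                    best = (cost, df, dd)
        if best is None:
            raise ValueError("curves share no overlapping separation range")

        def cost_vec(x):
            c = _alignment_cost(curve, reference, x[0], x[1])
            return c if c is not None else 1e12

        res = minimize(cost_vec, x0=[best[1], best[2]], method="Nelder-Mead")
        offsets.append((float(res.x[0]), float(res.x[1])))
    return offsets


def apply_alignment(fdcs, offsets):
    """Shift each curve by its (force, distance) offset."""
    out = []
    for curve, (df, dd) in zip(fdcs, offsets):
        out.append(
            ForceDistanceCurve(
                curve.separation + dd,
                curve.force + df,
                curve.pulling_speed,
                curve.cycle,
                curve.direction,
            )
        )
    return out


def align_and_average(
    cycles, bin_width: float = 1.0, center: bool = True
) -> ForceDistanceCurve:
    """Align cycles against their pooled average and bin into one FDC.

    The pooled (unaligned) average serves as a low-noise alignment
    target; per-cycle rigid offsets against it are re-centred to zero
    mean before being applied (``center=True``), so the result stays in
    the ensemble frame instead of inheriting any single cycle's
    calibration error, and is then re-binned.
    """
    if len(cycles) < 2:
        return average_cycles(cycles, bin_width=bin_width)
    pooled = average_cycles(cycles, bin_width=bin_width)
    offsets = align_fdcs(cycles, reference=pooled)
    if center:
        mean_df = float(np.mean([o[0] for o in offsets]))
        mean_dd = float(np.mean([o[1] for o in offsets]))
        offsets = [(df - mean_df, dd - mean_dd) for df, dd in offsets]
    return average_cycles(apply_alignment(cycles, offsets), bin_width=bin_width)


def detect_plateau_window(
    fdc: ForceDistanceCurve,
    slope_threshold: float = 0.02,
    smooth_nm: float = 15.0,
    min_width_nm: float = 25.0,
    min_force: float = 2.0,
):
    """Longest low-slope run of the curve: (d_start, d_stop).

    The force is smoothed over ``smooth_nm`` and the longest run with
    |dF/dd| below ``slope_threshold`` (pN/nm) is taken; if no run reaches
    ``min_width_nm`` the threshold is relaxed stepwise (model plateaus
    tilt by a few hundredths of pN/nm, real plateaus carry noise).
    Points below ``min_force`` are excluded - the slack toe of the tether
    is flat too, but it is not a plateau.
    """
    curve = fdc.sorted()
    keep = curve.force >= min_force
    if keep.sum() < 4:
        raise RuntimeError("no data above the minimum plateau force")
    d, f = curve.separation[keep], curve.force[keep]
    step = float(np.median(np.diff(d)))
    width = max(int(round(smooth_nm / step)), 1)
    slope = np.abs(np.gradient(uniform_filter1d(f, width, mode="nearest"), d))
    threshold = slope_threshold
    for _ in range(8):
        best = (0, 0)
        i = 0
        ok = slope < threshold
        while i < len(ok):
            if not ok[i]:
                i += 1
                continue
            j = i
            while j < len(ok) and ok[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        if best[1] > best[0] and d[best[1] - 1] - d[best[0]] >= min_width_nm:
            return float(d[best[0]]), float(d[best[1] - 1])
        threshold *= 2.0
    raise RuntimeError("no plateau window found (curve has no low-slope region)")


@dataclass
class PlateauFit:
    center: float
    sigma: float
    window: tuple[float, float]


def _gaussian(x, amplitude, center, sigma):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def plateau_force(
    fdc: ForceDistanceCurve,
    window: tuple[float, float] | None = None,
    bin_width: float = 0.1,
    **window_kwargs,
) -> PlateauFit:
    """Plateau force as the centre of a Gaussian fit to the force histogram.

    The histogram is restricted to the plateau window (auto-detected via
    :func:`detect_plateau_window` unless given) and binned at 0.1 pN; a
    single Gaussian is fitted to the bin counts by nonlinear least
    squares.
    """
    curve = fdc.sorted()
    if window is None:
        window = detect_plateau_window(curve, **window_kwargs)
    lo, hi = window
    mask = (curve.separation >= lo) & (curve.separation <= hi)
    if not np.any(mask):
        raise ValueError("plateau window does not overlap the data")
    forces = curve.force[mask]
    # bin grid centred on the force values so a near-constant plateau
    # lands mid-bin instead of on an edge
    start = forces.min() - 3 * bin_width - bin_width / 2
    edges = np.arange(start, forces.max() + 4 * bin_width, bin_width)
    counts, edges = np.histogram(forces, bins=edges)
    centers = 0.5 * (edges[1:] + edges[:-1])
    p0 = (counts.max(), float(forces.mean()), max(float(forces.std()), bin_width))
    try:
        popt, _ = curve_fit(_gaussian, centers, counts, p0=p0, maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(
            f"Gaussian fit of the plateau histogram failed; counts={counts.tolist()}"
        ) from err
    return PlateauFit(float(popt[1]), abs(float(popt[2])), (lo, hi))


def unfolded_reference_curve(
    separations,
    network: ElasticNetwork,
    total_residues: int,
    table: MechanicalTable | None = None,
) -> ForceDistanceCurve:
    """Model response of the always-unfolded construct (handle + full chain)."""
    table = table if table is not None else MechanicalTable(network)
    contour = total_residues * network.nm_per_residue
    force, _ = table.solve(np.asarray(separations, dtype=float), contour, 0.0)
    return ForceDistanceCurve(np.asarray(separations, dtype=float), force, direction="model")


def unfolding_work(
    fdc: ForceDistanceCurve,
    network: ElasticNetwork,
    total_residues: int,
    span: tuple[float, float] | None = None,
    thermal_units: bool = True,
) -> float:
    """Protein folding work W_F from the area under the curve.

    Trapezoidal integral of the measured force minus the same integral
    for the model curve of the always-unfolded construct over the same
    separation span; the linker contribution cancels and the protein's
    share remains.  Sign convention: work done *by* the protein on
    folding, so stable proteins give negative W_F.  Returned in kT by
    default (``thermal_units=False`` for pN*nm).
    """
    curve = fdc.sorted()
    if span is None:
        span = (float(curve.separation[0]), float(curve.separation[-1]))
    lo, hi = span
    mask = (curve.separation >= lo) & (curve.separation <= hi)
    if mask.sum() < 2:
        raise ValueError("separation span does not cover the transition")
    d = curve.separation[mask]
    reference = unfolded_reference_curve(d, network, total_residues)
    area = np.trapezoid(curve.force[mask] - reference.force, d)
    work = -float(area)
    return work / network.thermal_energy if thermal_units else work


def contour_length_gain(
    fdc: ForceDistanceCurve,
    network: ElasticNetwork,
    pre_window: tuple[float, float],
    post_window: tuple[float, float],
    n_repeats: int | None = None,
    pre_force_max: float = 4.0,
):
    """Unfolded-chain contour gained across the transition (nm).

    The pre-transition branch is fitted with the fixed handle/trap model
    plus a free chain contour and a free rigid offset (the folded
    protein's extension); the post-transition branch with a free chain
    contour and zero rigid offset.  The gain is the contour difference;
    with ``n_repeats`` the per-repeat gain is returned as well.

    The pre-branch fit only uses points below ``pre_force_max`` (pN):
    close to the plateau the terminal helices already unzip gradually,
    which would otherwise leak protein contour into the folded-branch
    fit.
    """
    curve = fdc.sorted()
    table = MechanicalTable(network)

    def branch_fit(window, with_offset, force_max=None):
        lo, hi = window
        mask = (curve.separation >= lo) & (curve.separation <= hi)
        if force_max is not None:
            mask &= curve.force <= force_max
        if mask.sum() < 4:
            raise ValueError(f"branch window {window} holds too few points")
        d_obs, f_obs = curve.separation[mask], curve.force[mask]

        def residual(theta):
            contour, offset = theta[0], (theta[1] if with_offset else 0.0)
            d_model = (
                np.interp(f_obs, table.force_grid, table.fixed_extension)
                + contour * np.interp(f_obs, table.force_grid, table.chain_fraction)
                + offset
            )
            return d_model - d_obs

        x0 = [50.0, 5.0] if with_offset else [50.0]
        res = least_squares(residual, x0=x0, bounds=(0, np.inf))
        if not res.success:
            raise RuntimeError(f"branch fit failed for window {window}")
        return res.x[0]

    pre = branch_fit(pre_window, with_offset=True, force_max=pre_force_max)
    post = branch_fit(post_window, with_offset=False)
    gain = float(post - pre)
    if n_repeats:
        return gain, gain / n_repeats
    return gain


def detrended_plateau(fdc: ForceDistanceCurve, window: tuple[float, float], degree: int = 2):
    """Plateau force with a low-order polynomial trend removed."""
    curve = fdc.sorted()
    lo, hi = window
    mask = (curve.separation >= lo) & (curve.separation <= hi)
    d, f = curve.separation[mask], curve.force[mask]
    if len(d) < degree + 2:
        raise ValueError("window too small to detrend")
    trend = np.polyval(np.polyfit(d, f, degree), d)
    return d, f - trend


def count_plateau_oscillations(
    fdc: ForceDistanceCurve,
    window: tuple[float, float],
    prominence: float = 0.05,
    degree: int = 2,
) -> int:
    """Number of oscillation periods (detrended force maxima) on the plateau."""
    _, residual = detrended_plateau(fdc, window, degree)
    peaks, _ = find_peaks(residual, prominence=prominence)
    return int(len(peaks))


def oscillation_amplitude(
    fdc: ForceDistanceCurve, window: tuple[float, float], degree: int = 2
) -> float:
    """Peak-to-peak amplitude of the detrended plateau force (pN)."""
    _, residual = detrended_plateau(fdc, window, degree)
    return float(residual.max() - residual.min())


def count_force_peaks(
    fdc: ForceDistanceCurve,
    window: tuple[float, float] | None = None,
    prominence: float = 0.5,
) -> int:
    """Local force maxima of the raw curve (sawtooth events).

    Used for the stiff-apparatus simulation, where each repeat unfolds
    with its own force rip of ~pN prominence.
    """
    curve = fdc.sorted()
    d, f = curve.separation, curve.force
    if window is not None:
        mask = (d >= window[0]) & (d <= window[1])
        d, f = d[mask], f[mask]
    peaks, _ = find_peaks(f, prominence=prominence)
    return int(len(peaks))
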