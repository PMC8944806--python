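"""Configuration-driven desk-scale analysis pipeline.

One call runs simulate -> average -> align -> fit -> model comparison ->
ensemble statistics for a named preset (or explicit parameters) and
returns a JSON-serialisable report with the fitted energies, total free
energies, unfolding work, plateau force, oscillation count, seed size
and minimal stable unit.  Reports are deterministic given (config,
seed).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import analysis
from .elasticity import ElasticNetwork
from .engine import EnsembleModel
from .fitting import (
    ENERGY_CONVENTION,
    FdcModelSpec,
    compare_models,
    fit_fdc,
)
from .ising import (
    Approximation,
    ModelVariant,
    RESIDUES_PER_REPEAT,
    RepeatParams,
    helix_params_from_repeat,
    minimal_stable_unit,
    total_free_energy,
)
from .presets import PRESETS, Preset, get_preset
from .superhelix import GEOMETRY_PRESETS, SuperhelixGeometry
from .synthetic import NoiseModel, generate_fdc_cycles

REPORT_SCHEMA_VERSION = "1"

_ALLOWED_KEYS = {
    "preset",
    "variant",
    "n_repeats",
    "dG_unit",
    "dG_nn",
    "helix_bias",
    "geometry",
    "elasticity",
    "seed",
    "cycles",
    "molecules",
    "noise",
    "bin_width_nm",
    "grid_step_nm",
    "approximation",
    "compare_variants",
    "ensemble_top_k",
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}': {message}")
        self.stage = stage


def _build_preset(config: dict) -> Preset:
    if "preset" in config:
        return get_preset(str(config["preset"]))
    required = {"n_repeats", "dG_unit", "dG_nn"}
    if not required.issubset(config):
        raise ValueError(
            "config must name a 'preset' or give n_repeats, dG_unit, dG_nn"
        )
    geometry = config.get("geometry", "ctpra")
    if isinstance(geometry, str):
        geom = GEOMETRY_PRESETS[geometry]
    else:
        geom = SuperhelixGeometry(**geometry)
    return Preset(
        name="custom",
        variant=str(config.get("variant", "custom")),
        n_repeats=int(config["n_repeats"]),
        dG_unit=float(config["dG_unit"]),
        dG_nn=float(config["dG_nn"]),
        geometry=geom,
        helix_bias=float(config.get("helix_bias", 0.5)),
    )


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ValueError("config must be a mapping")
    unknown = set(config) - _ALLOWED_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    _build_preset(config)


def run_pipeline(config: dict) -> dict:
    """Execute the full simulate/analyze/fit chain for one construct."""
    validate_config(config)
    preset = _build_preset(config)
    seed = int(config.get("seed", 0))
    n_cycles = int(config.get("cycles", 20))
    n_molecules = int(config.get("molecules", 1))
    bin_width = float(config.get("bin_width_nm", 1.0))
    grid_step = float(config.get("grid_step_nm", 0.5))
    approximation = Approximation(config.get("approximation", "zipper"))
    network = ElasticNetwork.from_config(config.get("elasticity", {}))
    noise_cfg = config.get("noise", {})
    helix_params = preset.helix_params()

    try:
        model = EnsembleModel(
            helix_params, preset.geometry, network, preset.n_repeats, approximation
        )
        separations = model.default_separations(step=grid_step)
        molecules = []
        for mol in range(n_molecules):
            noise = NoiseModel(seed=seed + 1000 * mol, **noise_cfg)
            cycles = generate_fdc_cycles(
                helix_params,
                preset.geometry,
                network,
                noise,
                preset.n_repeats,
                n_cycles=n_cycles,
                separations=separations,
                model=model,
            )
            molecules.append(analysis.average_cycles(cycles, bin_width=bin_width))
    except Exception as err:  # noqa: BLE001
        raise PipelineError("simulate", str(err)) from err

    try:
        if len(molecules) > 1:
            offsets = analysis.align_fdcs(molecules)
            molecules = analysis.apply_alignment(molecules, offsets)
            averaged = analysis.average_cycles(molecules, bin_width=bin_width)
        else:
            averaged = molecules[0]
    except Exception as err:  # noqa: BLE001
        raise PipelineError("align", str(err)) from err

    try:
        window_mask = model.plateau_window(separations)
        window = (
            float(separations[window_mask][0]),
            float(separations[window_mask][-1]),
        )
        plateau = analysis.plateau_force(averaged, window=window)
        # oscillations are counted on the sequential-unfolding stretch,
        # before the dip region distorts the detrend
        osc_mask = model.plateau_window(separations, p_unfolded_max=0.05)
        try:
            periods = analysis.count_plateau_oscillations(
                model.force_curve(separations),
                (float(separations[osc_mask][0]), float(separations[osc_mask][-1])),
            )
        except (ValueError, IndexError):
            periods = None  # plateau too short to resolve oscillations
        total_residues = 2 * preset.n_repeats * (RESIDUES_PER_REPEAT // 2)
        work = analysis.unfolding_work(averaged, network, total_residues)
    except Exception as err:  # noqa: BLE001
        raise PipelineError("analyze", str(err)) from err

    try:
        spec = FdcModelSpec(
            n_repeats=preset.n_repeats,
            geom=preset.geometry,
            network=network,
            approximation=approximation,
            parameterization="repeat",
            helix_bias=preset.helix_bias,
        )
        fit = fit_fdc(averaged, spec)
        fitted_rp = RepeatParams(
            fit.params["dG_unit"], fit.params["dG_nn"], preset.n_repeats
        )
        aic_table = None
        if bool(config.get("compare_variants", False)):
            fits = [fit]
            for variant in (
                ModelVariant.homopolymer_helix,
                ModelVariant.heteropolymer_helix,
                ModelVariant.heteropolymer_helix_nnn,
            ):
                fits.append(
                    fit_fdc(
                        averaged,
                        replace(spec, variant=variant, parameterization="helix"),
                    )
                )
            aic_table = compare_models(fits).to_dict(orient="records")
    except Exception as err:  # noqa: BLE001
        raise PipelineError("fit", str(err)) from err

    try:
        snap_model = model
        if 2 * preset.n_repeats <= 20 and approximation is not Approximation.skip:
            snap_model = EnsembleModel(
                helix_params,
                preset.geometry,
                network,
                preset.n_repeats,
                Approximation.skip,
            )
        mid = float(np.mean(window))
        snapshot = snap_model.snapshot(mid, k=int(config.get("ensemble_top_k", 10)))
        seed_helices = snap_model.seed_size()
        msu = minimal_stable_unit(
            helix_params_from_repeat(preset.repeat_params, helix_bias=0.0)
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("ensemble", str(err)) from err

    return {
        "schema_version": REPORT_SCHEMA_VERSION,
        "convention": ENERGY_CONVENTION,
        "config": {
            "preset": preset.name,
            "variant": preset.variant,
            "n_repeats": preset.n_repeats,
            "seed": seed,
            "cycles": n_cycles,
            "molecules": n_molecules,
            "approximation": approximation.value,
        },
        "input_energies": {
            "dG_unit_kT": preset.dG_unit,
            "dG_nn_kT": preset.dG_nn,
            "dG_tot_kT": total_free_energy(preset.repeat_params),
        },
        "fit": fit.to_dict(),
        "fitted_energies": {
            "dG_unit_kT": fitted_rp.dG_unit,
            "dG_nn_kT": fitted_rp.dG_nn,
            "dG_tot_kT": total_free_energy(fitted_rp),
        },
        "unfolding_work_kT": work,
        "plateau": {
            "force_pN": plateau.center,
            "sigma_pN": plateau.sigma,
            "window_nm": list(plateau.window),
        },
        "oscillation_periods": periods,
        "seed_size_helices": seed_helices,
        "minimal_stable_unit_helices": msu,
        "ensemble_snapshot": snapshot.to_dict(),
        "aic_table": aic_table,
    }


def simulated_plateau_force(
    repeat_params: RepeatParams,
    geometry: SuperhelixGeometry,
    network: ElasticNetwork | None = None,
    helix_bias: float = 0.5,
    approximation=Approximation.zipper,
    grid_step: float = 0.25,
):
    """Gaussian-fit plateau force of the model FDC for one construct.

    Computes the equilibrium zipper-model FDC, restricts it to the
    plateau window (unfolding in progress, before the dip at
    P(unfolded) = 50%), and fits a Gaussian to the 0.1 pN force
    histogram.  Returns the :class:`~repeatspring.analysis.PlateauFit`.
    """
    network = network if network is not None else ElasticNetwork.from_config({})
    helix = helix_params_from_repeat(repeat_params, helix_bias=helix_bias)
    model = EnsembleModel(
        helix, geometry, network, repeat_params.N_repeats, approximation
    )
    d = model.default_separations(step=grid_step)
    mask = model.plateau_window(d)
    window = (float(d[mask][0]), float(d[mask][-1]))
    return analysis.plateau_force(model.force_curve(d), window=window)


def table1_style_report(preset_names=None) -> list[dict]:
    """Energy table over presets: dG_unit, dG_nn, dG_tot per construct."""
    rows = []
    for name in preset_names or sorted(PRESETS):
        p = get_preset(name)
        rows.append(
            {
                "preset": name,
                "variant": p.variant,
                "N": p.n_repeats,
                "dG_unit_kT": p.dG_unit,
                "dG_nn_kT": p.dG_nn,
                "dG_tot_kT": total_free_energy(p.repeat_params),
            }
        )
    return rows
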