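"""Parameter presets for the two consensus TPR variants.

Repeat-level energies are the published zipper-approximation fits per
array length, plus the pooled per-variant means; geometry presets describe
the CTPRa superhelix (~8 repeats per turn) and the wider, shorter CTPRrv
redesign.  The helix-level decomposition used by the presets assigns every
adjacent-helix interface the repeat coupling and splits the intrinsic
remainder with a 0.5 kT bias towards a less stable B helix (the exposed
C-terminal unit), which reproduces the C-to-N asymmetry of the unfolding
pathway without changing repeat-level energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .elasticity import ElasticNetwork
from .ising import HelixIsingParams, RepeatParams, helix_params_from_repeat
from .superhelix import CTPRA_GEOMETRY, CTPRRV_GEOMETRY, SuperhelixGeometry

#: default A/B intrinsic-energy asymmetry of the presets (kT)
DEFAULT_HELIX_BIAS = 0.5


@dataclass(frozen=True)
class Preset:
    """One measured construct: repeat count, energies, geometry."""

    name: str
    variant: str  # "rv" or "a"
    n_repeats: int
    dG_unit: float
    dG_nn: float
    geometry: SuperhelixGeometry
    helix_bias: float = DEFAULT_HELIX_BIAS
    interface_split: float = 0.0

    @property
    def repeat_params(self) -> RepeatParams:
        return RepeatParams(self.dG_unit, self.dG_nn, self.n_repeats)

    def helix_params(
        self,
        bias: float | None = None,
        interface_split: float | None = None,
    ) -> HelixIsingParams:
        b = self.helix_bias if bias is None else bias
        s = self.interface_split if interface_split is None else interface_split
        return helix_params_from_repeat(
            self.repeat_params, helix_bias=b, interface_split=s
        )


def _rv(name, n, dG_unit, dG_nn):
    return Preset(name, "rv", n, dG_unit, dG_nn, CTPRRV_GEOMETRY)


def _a(name, n, dG_unit, dG_nn):
    return Preset(name, "a", n, dG_unit, dG_nn, CTPRA_GEOMETRY)


#: zipper-fit energies per construct; *_mean are the pooled variant values
PRESETS: dict[str, Preset] = {
    p.name: p
    for p in [
        _rv("ctprrv3", 3, 1.0, -10.0),
        _rv("ctprrv5", 5, 1.5, -11.8),
        _rv("ctprrv10", 10, 1.2, -11.0),
        _rv("ctprrv20", 20, 1.0, -10.2),
        _rv("ctprrv26", 26, 0.5, -10.0),
        _a("ctpra5", 5, -2.4, -12.4),
        _a("ctpra9", 9, -1.3, -13.3),
        _rv("ctprrv_mean10", 10, 1.1, -11.0),
        _a("ctpra_mean9", 9, -1.9, -12.7),
    ]
}

#: pooled per-variant repeat energetics (ensemble of all array lengths)
VARIANT_MEANS = {"rv": RepeatParams(1.1, -11.0), "a": RepeatParams(-1.9, -12.7)}

#: pooled per-variant energetics from equilibrium chemical denaturation
DENATURATION_MEANS = {"rv": RepeatParams(0.20, -6.8), "a": RepeatParams(-1.0, -10.3)}


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def default_network(config: dict | None = None) -> ElasticNetwork:
    return ElasticNetwork.from_config(config or {})
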