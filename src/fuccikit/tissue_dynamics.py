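"""Flux calculus linking stem-cell cycle times to tissue output.

The germarium buds one egg chamber roughly every 12 h (720 min). A ring of
about eight layer-1 follicle stem cells (FSCs) supplies 5-6 proliferative
follicle cells (FCs) per budding cycle; the six layer-2 FSCs (with their two
slow layer-3 neighbors) supply quiescent escort cells (ECs) at about one
quarter the FC rate. Production per layer per budding cycle is simply
``n_cells * period / cycle_time``; comparing production with the known FC/EC
consumption reveals whether stem cells must flow between layers (net A/P
flux) or whether exchange is balanced.

Differentiation loss per FSC per budding cycle is F = f * p, where f is the
fraction of FSCs in layer 1 and p the probability a layer-1 FSC becomes an
FC per cycle; the wild-type baseline is F = 0.48 * 0.64 = 0.307.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .errors import InvalidParameterError

#: Wild-type loss of FSCs to FC differentiation per budding cycle (f*p = 0.48*0.64).
WILD_TYPE_LOSS_PER_CYCLE = 0.307


@dataclass(frozen=True)
class TissueParams:
    """Layer cell counts, budding period and derivative-output constants."""

    cells_per_layer: Mapping[str, int] = field(
        default_factory=lambda: {"1": 8, "2": 6, "3": 2}
    )
    budding_period_min: float = 720.0
    fc_per_cycle: float = 5.5
    ec_to_fc_ratio: float = 0.25

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.cells_per_layer.values()):
            raise InvalidParameterError("cell counts must be >= 0")
        if not self.budding_period_min > 0:
            raise InvalidParameterError("budding_period_min must be > 0")
        if not self.fc_per_cycle > 0:
            raise InvalidParameterError("fc_per_cycle must be > 0")
        if not 0 < self.ec_to_fc_ratio <= 1:
            raise InvalidParameterError("ec_to_fc_ratio must be in (0, 1]")


@dataclass(frozen=True)
class DifferentiationMetrics:
    """FSC loss to FC conversion per budding cycle and its change vs wild type."""

    f: float
    p: float
    loss_per_cycle: float
    delta_vs_wild_type: float
    percent_change_vs_wild_type: float


def production_rate(n_cells: int, cycle_time_min: float, period_min: float = 720.0) -> float:
    """New cells produced per budding period: n * period / cycle_time.

    Report to one decimal (``round(production_rate(...), 1)``).
    """
    if not cycle_time_min > 0:
        raise InvalidParameterError("cycle_time_min must be > 0")
    if not period_min > 0:
        raise InvalidParameterError("period_min must be > 0")
    if n_cells < 0:
        raise InvalidParameterError("n_cells must be >= 0")
    return n_cells * period_min / cycle_time_min


def required_cycle_time(
    n_cells: int, output_per_period: float, period_min: float = 720.0
) -> float:
    """Cycle time needed for ``n_cells`` to yield ``output_per_period`` per period.

    Exact inverse of :func:`production_rate`.
    """
    if not output_per_period > 0:
        raise InvalidParameterError("output_per_period must be > 0")
    if not period_min > 0:
        raise InvalidParameterError("period_min must be > 0")
    if n_cells < 0:
        raise InvalidParameterError("n_cells must be >= 0")
    return period_min * n_cells / output_per_period


def required_cycle_ratio(params: TissueParams | None = None) -> float:
    """Layer-2 : layer-1 cycle-time ratio needed to balance EC vs FC output.

    ECs are produced at ``ec_to_fc_ratio`` times the FC rate by ``n2`` cells
    instead of ``n1``, so their cycles must be (1/ratio) * n2/n1 longer.
    """
    params = params or TissueParams()
    n1 = params.cells_per_layer.get("1", 0)
    n2 = params.cells_per_layer.get("2", 0)
    if n1 <= 0:
        raise InvalidParameterError("layer 1 must contain cells")
    return (1.0 / params.ec_to_fc_ratio) * n2 / n1


def conversion_loss(
    f: float, p: float, baseline: float = WILD_TYPE_LOSS_PER_CYCLE
) -> DifferentiationMetrics:
    """Loss of FSCs to FC conversion per budding cycle, F = f * p.

    ``delta_vs_wild_type`` is F minus the wild-type baseline;
    ``percent_change_vs_wild_type`` expresses it relative to the baseline.
    """
    if not 0 <= f <= 1 or not 0 <= p <= 1:
        raise InvalidParameterError("f and p must be in [0, 1]")
    loss = f * p
    delta = loss - baseline
    return DifferentiationMetrics(
        f=f,
        p=p,
        loss_per_cycle=loss,
        delta_vs_wild_type=delta,
        percent_change_vs_wild_type=100.0 * delta / baseline,
    )


def flux_report(
    cycle_times_min: Mapping[str, float],
    params: TissueParams | None = None,
) -> dict:
    """Per-layer production vs differentiation balance and net A/P flow.

    ``cycle_times_min`` maps layer labels to estimated total cycle times for
    at least layers "1" and "2". Consumption is FC output for layer 1 and EC
    output (``ec_to_fc_ratio * fc_per_cycle``) for layer 2; layer-3
    production, when a cycle time is supplied, is reported separately but
    not folded into the layer-2 balance because layer-3 cells divide much
    more slowly and their output is unquantified. The residual
    production - consumption per layer is the net flux; production =
    consumption + net flux by construction (stem-cell pool assumed constant).
    """
    params = params or TissueParams()
    if len([l for l in cycle_times_min if l in ("1", "2")]) < 2:
        raise InvalidParameterError("cycle estimates required for layers '1' and '2'")
    consumption = {
        "1": params.fc_per_cycle,
        "2": params.ec_to_fc_ratio * params.fc_per_cycle,
    }
    layers = {}
    for layer, cycle in cycle_times_min.items():
        n = params.cells_per_layer.get(layer, 0)
        produced = production_rate(n, cycle, params.budding_period_min)
        entry = {
            "n_cells": n,
            "cycle_time_min": cycle,
            "production_per_cycle": round(produced, 1),
            "production_per_cycle_unrounded": produced,
        }
        if layer in consumption:
            entry["consumption_per_cycle"] = consumption[layer]
            entry["net_flux_per_cycle"] = round(produced - consumption[layer], 1)
            entry["net_flux_per_cycle_unrounded"] = produced - consumption[layer]
        layers[layer] = entry
    total_production = round(
        sum(layers[l]["production_per_cycle"] for l in ("1", "2")), 1
    )
    total_consumption = consumption["1"] + consumption["2"]
    report = {
        "layers": layers,
        "total_production_per_cycle_layers_1_2": total_production,
        "total_consumption_per_cycle_layers_1_2": total_consumption,
        "net_flux_per_cycle_layers_1_2": round(total_production - total_consumption, 1),
        "measured_cycle_ratio_2_to_1": round(
            cycle_times_min["2"] / cycle_times_min["1"], 1
        ),
        "required_cycle_ratio_2_to_1": round(required_cycle_ratio(params), 1),
        "required_layer1_cycle_time_min": round(
            required_cycle_time(
                params.cells_per_layer.get("1", 0),
                params.fc_per_cycle,
                params.budding_period_min,
            )
        ),
    }
    return report
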