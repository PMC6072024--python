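"""Registries for pluggable callables.

Weight functions modulate the synaptic strength of an edge at simulation
setup: the effective weight of a connection is
``syn_weight * weight_function(edge_props, source_node, target_node)``.
Names are resolved here both at build time (fail fast on typos) and at
simulation setup.
"""

from __future__ import annotations

from typing import Callable, Dict

WeightFunction = Callable[..., float]

_WEIGHT_FUNCTIONS: Dict[str, WeightFunction] = {}


def register_weight_function(name: str, fn: WeightFunction | None = None):
    """Register ``fn`` under ``name``; usable as a decorator."""
    if fn is None:
        def _decorator(f: WeightFunction) -> WeightFunction:
            _WEIGHT_FUNCTIONS[name] = f
            return f
        return _decorator
    _WEIGHT_FUNCTIONS[name] = fn
    return fn


def get_weight_function(name: str) -> WeightFunction:
    try:
        return _WEIGHT_FUNCTIONS[name]
    except KeyError:
        raise KeyError(
            f"unknown weight_function {name!r}; registered: "
            f"{sorted(_WEIGHT_FUNCTIONS)}"
        ) from None


def has_weight_function(name: str) -> bool:
    return name in _WEIGHT_FUNCTIONS


@register_weight_function("identity")
def _identity(edge_props, source, target) -> float:
    return 1.0


@register_weight_function("gaussian_tuning_difference")
def _gaussian_tuning_difference(edge_props, source, target) -> float:
    """Like-to-like example: weight falls off with preferred-angle difference.

    Expects ``tuning_angle`` (deg) on both nodes and ``weight_sigma`` (deg)
    in the edge properties; angle difference wraps at 180 degrees.
    """
    import numpy as np

    da = abs(float(source["tuning_angle"]) - float(target["tuning_angle"]))
    da = min(da % 360.0, 360.0 - da % 360.0)
    sigma = float(edge_props.get("weight_sigma", 50.0))
    return float(np.exp(-(da * da) / (2.0 * sigma * sigma)))
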