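"""One-way, scenario, and probabilistic sensitivity analysis.

Engines are callables ``engine(params, seed) -> result`` where
``params`` is any (possibly nested) dataclass. Parameters are addressed
by dotted path (``"qaly_weight_mean"``, ``"survival_params.shape"``).
Each evaluation is re-seeded with a deterministic hash of the base seed
and the overrides, so Monte Carlo noise is decoupled from the parameter
being swept and repeated invocations are bit-identical.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass
from typing import Any, Callable, Iterable

__all__ = ["SweepSpec", "one_way", "scenario", "set_path", "derive_seed"]


@dataclass(frozen=True)
class SweepSpec:
    """A one-way sweep: dotted parameter path, values to visit, and the
    name of the result attribute (or key) to tabulate."""

    parameter_path: str
    values: tuple
    output_metric: str | None = None


def _get_attr_or_key(obj, name: str):
    if isinstance(obj, dict):
        return obj[name]
    return getattr(obj, name)


def set_path(params, path: str, value):
    """Return a copy of a (nested) dataclass with ``path`` replaced."""
    head, _, rest = path.partition(".")
    if not dataclasses.is_dataclass(params):
        raise ValueError(f"cannot descend into non-dataclass at {head!r}")
    if not hasattr(params, head):
        raise AttributeError(f"parameter path {head!r} not found on {type(params).__name__}")
    if rest:
        value = set_path(getattr(params, head), rest, value)
    return dataclasses.replace(params, **{head: value})


def derive_seed(base_seed: int, overrides: dict) -> int:
    """Deterministic per-evaluation seed from the base seed and the
    override set (stable across processes, unlike ``hash``)."""
    text = repr(sorted((str(k), repr(v)) for k, v in overrides.items()))
    return (base_seed * 1_000_003 + zlib.crc32(text.encode())) % (2**31)


def _extract(result, metric: str | None):
    if metric is None:
        return result
    out = result
    for part in metric.split("."):
        out = _get_attr_or_key(out, part)
    return out


def scenario(
    base_params,
    overrides: dict[str, Any],
    engine: Callable,
    seed: int = 0,
    metric: str | None = None,
):
    """A single run with all overrides applied atomically.

    Empty overrides reproduce the base run exactly (same derived seed).
    Raises on conflicting overrides of the same path.
    """
    paths = list(overrides)
    if len(set(paths)) != len(paths):
        raise ValueError("conflicting overrides of the same parameter path")
    params = base_params
    for path, value in overrides.items():
        params = set_path(params, path, value)
    result = engine(params, derive_seed(seed, overrides))
    return _extract(result, metric)


def one_way(
    base_params,
    spec: SweepSpec,
    engine: Callable,
    seed: int = 0,
) -> list[tuple]:
    """Evaluate the engine at each value of one parameter, all others
    fixed; returns ``[(value, metric), ...]`` (tornado-ready)."""
    rows = []
    for value in spec.values:
        rows.append((
            value,
            scenario(
                base_params,
                {spec.parameter_path: value},
                engine,
                seed=seed,
                metric=spec.output_metric,
            ),
        ))
    return rows
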