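"""Power grids and sample-size solving for the planner surface."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from itertools import product
from typing import Any, Mapping, Sequence

import pandas as pd

from . import __version__
from .design import Comparison, MultiVariantDesign, SingleVariantDesign
from .errors import ParameterError, UnachievablePowerError
from .mv import mv_power_gain, mv_recall_power
from .sv import sv_power_gain, sv_recall_power

__all__ = ["PowerGrid", "power_grid", "solve_sample_size"]

_POWER_COLUMNS = ("power_recall", "power_random", "gain")


@dataclass(frozen=True)
class PowerGrid:
    """Tabulated power surface over a parameter sweep.

    ``cells`` holds one row per parameter combination, with the design
    parameters first and ``power_recall``, ``power_random``, ``gain`` last.
    Serialization (CSV and JSON) keeps full shortest-round-trip float
    precision so grids reload losslessly.
    """

    axes: Mapping[str, Sequence[Any]]
    cells: pd.DataFrame
    metadata: Mapping[str, Any]

    def to_csv(self, path) -> None:
        # shortest-round-trip formatting; read back with
        # pd.read_csv(..., float_precision="round_trip") for exact reload
        self.cells.to_csv(path, index=False, float_format=lambda v: repr(float(v)))

    def to_json(self, path) -> None:
        payload = {
            "axes": {k: list(v) for k, v in self.axes.items()},
            "metadata": dict(self.metadata),
            "cells": self.cells.to_dict(orient="records"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "PowerGrid":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            axes=payload["axes"],
            cells=pd.DataFrame(payload["cells"]),
            metadata=payload["metadata"],
        )


def _template_fields(template) -> set[str]:
    return {f.name for f in dataclasses.fields(template)}


def power_grid(
    design_template: SingleVariantDesign | MultiVariantDesign,
    sweep: Mapping[str, Sequence[Any]],
) -> PowerGrid:
    """Evaluate the analytic power gain at every point of a parameter sweep.

    ``sweep`` maps field names of the template design to value sequences;
    the grid is their Cartesian product and the cell count is the product
    of the axis lengths. Deterministic: no randomness is involved.
    """
    valid = _template_fields(design_template)
    for name in sweep:
        if name not in valid:
            raise ParameterError(
                "sweep", f"unknown axis {name!r}; valid axes: {sorted(valid)}"
            )
    is_sv = isinstance(design_template, SingleVariantDesign)
    gain_fn = sv_power_gain if is_sv else mv_power_gain

    names = list(sweep)
    rows = []
    for combo in product(*(sweep[n] for n in names)):
        design = dataclasses.replace(design_template, **dict(zip(names, combo)))
        result = gain_fn(design)
        row = {f.name: getattr(design, f.name) for f in dataclasses.fields(design)}
        if "comparison" in row:
            row["comparison"] = row["comparison"].value
        row["power_recall"] = result.power_recall
        row["power_random"] = result.power_random
        row["gain"] = result.gain
        rows.append(row)
    cells = pd.DataFrame(rows)
    metadata = {
        "design": "sv" if is_sv else "mv",
        "alpha": design_template.alpha,
        "method": "analytic",
        "tool_version": __version__,
    }
    return PowerGrid(axes={n: list(sweep[n]) for n in names}, cells=cells, metadata=metadata)


def solve_sample_size(
    design_template: SingleVariantDesign | MultiVariantDesign,
    target_power: float,
) -> int:
    """Smallest even total sample size whose analytic recall power meets the target.

    Exponential bracketing followed by bisection over even ``n``; the
    returned ``n`` satisfies ``power(n) >= target_power > power(n - 2)``
    (unless ``n`` is already the minimum allowed, 4). Raises
    :class:`UnachievablePowerError` for a null effect, where power never
    exceeds ``alpha``.
    """
    if not 0.0 < target_power < 1.0:
        raise ParameterError("target_power", "must be in (0, 1)")
    if isinstance(design_template, SingleVariantDesign):
        if design_template.beta == 0.0:
            raise UnachievablePowerError("beta is 0; power never exceeds alpha")
        power = lambda n: sv_recall_power(dataclasses.replace(design_template, n_total=n))
    else:
        if design_template.r2_xg * design_template.r2_yx == 0.0:
            raise UnachievablePowerError("r2_xg*r2_yx is 0; power never exceeds alpha")
        power = lambda n: mv_recall_power(dataclasses.replace(design_template, n_total=n))

    lo = 4
    if power(lo) >= target_power:
        return lo
    hi = lo
    while power(hi) < target_power:
        hi *= 2
        if hi > 10**9:
            raise UnachievablePowerError(
                f"target power {target_power} not reached by n = {hi // 2}"
            )
    lo = hi // 2
    # invariant: power(lo) < target <= power(hi); both even
    while hi - lo > 2:
        mid = lo + (hi - lo) // 2
        mid -= mid % 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return hi


def comparison_from_cli(value: str) -> Comparison:
    return Comparison.parse(value)
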