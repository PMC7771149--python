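"""Treatment-coded factorial design matrices with bounded interaction order.

Factors are categorical with a reference level (alphabetically first by
default, matching treatment-contrast coding); boolean factors are coded
0/1 with ``False`` as reference. Interaction columns are products of the
main-effect indicator columns, generated in ``itertools.combinations``
order, so the column layout is deterministic and auditable by name.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "build_design_matrix"]


@dataclass(frozen=True)
class DesignSpec:
    """Factors (name -> ordered levels, reference first) and max interaction order."""

    factors: Mapping[str, tuple]
    max_interaction_order: int = 1

    def __post_init__(self) -> None:
        if not self.factors:
            raise ValueError("DesignSpec requires at least one factor")
        if not 1 <= self.max_interaction_order <= len(self.factors):
            raise ValueError(
                f"max_interaction_order must be in 1..{len(self.factors)}, "
                f"got {self.max_interaction_order}"
            )
        for name, levels in self.factors.items():
            if len(levels) < 2:
                raise ValueError(f"factor {name!r} needs >= 2 levels, got {levels}")

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        factor_names: Sequence[str],
        max_interaction_order: int = 1,
        levels: Mapping[str, Sequence] | None = None,
    ) -> "DesignSpec":
        """Infer levels from the data (sorted, so the reference is alphabetically first)."""
        levels = dict(levels or {})
        factors: dict[str, tuple] = {}
        for name in factor_names:
            if name in levels:
                factors[name] = tuple(levels[name])
            else:
                vals = frame[name].unique().tolist()
                factors[name] = tuple(sorted(vals, key=lambda v: (str(v).lower(), str(v))))
        return cls(factors=factors, max_interaction_order=max_interaction_order)


def _main_effect_columns(frame: pd.DataFrame, name: str, levels: tuple) -> list[tuple[str, np.ndarray]]:
    observed = set(frame[name].unique().tolist())
    unknown = observed - set(levels)
    if unknown:
        raise ValueError(f"unknown level(s) {sorted(map(str, unknown))} for factor {name!r}")
    cols = []
    boolean = len(levels) == 2 and all(lv in (False, True, 0, 1) for lv in levels)
    for level in levels[1:]:
        label = name if boolean else f"{name}[{level}]"
        cols.append((label, (frame[name] == level).to_numpy(dtype=float)))
    return cols


def build_design_matrix(
    data, spec: DesignSpec
) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded main effects + interaction products.

    ``data`` may be a DataFrame or an iterable of objects with the factor
    names as attributes. Returns the n x p matrix and its column names.
    """
    if isinstance(data, pd.DataFrame):
        frame = data
    else:
        rows = list(data)
        frame = pd.DataFrame({name: [getattr(r, name) for r in rows] for name in spec.factors})

    per_factor: list[list[tuple[str, np.ndarray]]] = []
    for name, levels in spec.factors.items():
        per_factor.append(_main_effect_columns(frame, name, tuple(levels)))

    n = len(frame)
    names: list[str] = ["Intercept"]
    columns: list[np.ndarray] = [np.ones(n)]
    for cols in per_factor:
        for label, col in cols:
            names.append(label)
            columns.append(col)
    for order in range(2, spec.max_interaction_order + 1):
        for combo in itertools.combinations(range(len(per_factor)), order):
            for parts in itertools.product(*(per_factor[i] for i in combo)):
                label = ":".join(p[0] for p in parts)
                col = np.prod(np.stack([p[1] for p in parts]), axis=0)
                names.append(label)
                columns.append(col)
    return np.column_stack(columns), names
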