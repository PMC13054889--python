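"""Weighted geometric-mean combination of reward components.

The combined multi-parameter score of components with values v_i in
[0, 1] and non-negative weights w_i is ``(prod v_i^w_i)^(1/sum w_i)``
over the positively weighted components.  Zero-weight components are
excluded from the product but stay in the record, so a reward can be
logged without influencing optimization (the "control" configuration).
A zero value with positive weight annihilates the whole score — there
is deliberately no epsilon flooring, matching hard-filter semantics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable


class MpoError(ValueError):
    pass


@dataclass(frozen=True)
class ComponentScore:
    name: str
    value: float
    weight: float


def combine(components: Iterable[ComponentScore]) -> float:
    """Weighted geometric mean of the positively weighted components."""
    comps = list(components)
    values = []
    weights = []
    for c in comps:
        if not math.isfinite(c.value) or not math.isfinite(c.weight):
            raise MpoError(f"non-finite component {c.name!r}")
        if c.weight < 0:
            raise MpoError(f"negative weight on component {c.name!r}")
        if c.weight == 0:
            continue
        # tolerate tiny numeric overshoot, reject genuinely bad values
        if c.value < -1e-9 or c.value > 1.0 + 1e-9:
            raise MpoError(f"component {c.name!r} value {c.value} outside [0, 1]")
        values.append(min(1.0, max(0.0, c.value)))
        weights.append(c.weight)
    total = sum(weights)
    if total <= 0:
        raise MpoError("at least one component must have positive weight")
    if any(v == 0.0 for v in values):
        return 0.0
    log_mean = sum(w * math.log(v) for v, w in zip(values, weights)) / total
    return math.exp(log_mean)
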