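"""Foraging/moulting habitat class from bulk carbon isotope values.

Bulk δ13C separates polar from temperate water masses; the standard
cut-off is −21‰, with values strictly below it classified polar. A record
at exactly the threshold is temperate (the comparison is a strict "<"); a
``boundary_polar`` flag flips that convention if desired.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .errors import ValidationError
from .io import SampleRecord

DEFAULT_THRESHOLD = -21.0


@dataclass(frozen=True)
class HabitatCall:
    """Habitat assignment for one sample; habitat is None when δ13C is absent."""

    sample_id: str
    habitat: str | None
    d13C_used: float | None
    threshold: float


def classify_habitat(records: Sequence[SampleRecord],
                     threshold: float = DEFAULT_THRESHOLD,
                     boundary_polar: bool = False) -> list:
    """Classify each record as polar (δ13C < threshold) or temperate.

    Records lacking a bulk δ13C value are returned with habitat None
    rather than dropped, so counts always reconcile with the input.
    """
    calls = []
    for r in records:
        v = r.d13C_bulk
        if v is None:
            calls.append(HabitatCall(r.sample_id, None, None, threshold))
            continue
        v = float(v)
        if not math.isfinite(v):
            raise ValidationError(f"non-finite δ13C for sample {r.sample_id!r}")
        polar = v < threshold or (boundary_polar and v == threshold)
        calls.append(
            HabitatCall(r.sample_id, "polar" if polar else "temperate", v, threshold)
        )
    return calls
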