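"""Mass-spectral similarity on the 0-1000 scale.

The score is the cosine between square-root-transformed intensity vectors
laid out on the union m/z grid, scaled by 1000 and rounded to an integer:
1000 for proportional spectra, 0 when no m/z is shared.  Square-root
weighting damps the dominance of the base peak so that diagnostic minor
fragments contribute; alternative weightings can be passed through
``weight``.
"""

from __future__ import annotations

from typing import Callable

import math

from .models import Spectrum


def similarity(
    a: Spectrum,
    b: Spectrum,
    weight: Callable[[float], float] = math.sqrt,
) -> int:
    """Scaled cosine similarity between two spectra (symmetric, 0-1000)."""
    wa = {mz: weight(inten) for mz, inten in a.peaks if inten > 0}
    wb = {mz: weight(inten) for mz, inten in b.peaks if inten > 0}
    dot = sum(wa[mz] * wb[mz] for mz in wa.keys() & wb.keys())
    if dot == 0.0:
        return 0
    na = math.sqrt(sum(v * v for v in wa.values()))
    nb = math.sqrt(sum(v * v for v in wb.values()))
    return int(round(1000.0 * dot / (na * nb)))
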