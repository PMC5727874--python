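"""Small shared helpers: rounding, percentages, seeded RNG streams."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, as percentages are printed in tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``ndigits``."""
    if denominator == 0:
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for substream ``stream`` of a master ``seed``.

    Keeps every stage of a simulation reproducible while letting optional
    augmentation stages draw without perturbing earlier stages.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(stream),)))
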