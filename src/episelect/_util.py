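"""Small shared helpers: rounding, RNG streams, error types."""

from __future__ import annotations

import decimal

import numpy as np

#: Spawn keys for per-operation independent RNG streams derived from one root seed.
STREAM_F2 = 0
STREAM_F3 = 1
STREAM_EMERGENCE = 2
STREAM_REVERSION = 3


class ParameterError(ValueError):
    """Invalid parameter value (bad mixture fractions, unknown environment, ...)."""


class DataError(ValueError):
    """Invalid or insufficient data for an operation."""


class SchemaError(DataError):
    """A table failed schema validation; message names the column/row."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as in printed reports.

    Python's builtin ``round`` is banker's rounding; reported percents use
    half-up to match common presentation (e.g. 0.145 -> 0.15 at 2 digits).
    """
    if not np.isfinite(x):
        return float(x)
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def stream(seed: int, key: int) -> np.random.Generator:
    """Independent generator for operation ``key`` derived from the root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(key),)))
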