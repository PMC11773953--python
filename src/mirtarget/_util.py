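"""Shared helpers: errors, percentage formatting, seed derivation."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


class MirtargetError(Exception):
    """Base class for all package-specific errors."""


class UndefinedCorrelationError(MirtargetError):
    """Pearson correlation is undefined (constant vector or length < 2)."""


class DegenerateTrainingError(MirtargetError):
    """A training subset contains only one class."""


def pct(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Percentage ``100 * numerator / denominator`` rounded half-up.

    Half-up rounding (not banker's) so printed rates are stable and match
    the conventional presentation of validation/overlap percentages.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    raw = Decimal(str(100.0 * numerator / denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(raw.quantize(quantum, rounding=ROUND_HALF_UP))


def stage_seed(global_seed: int, offset: int) -> int:
    """Derive a stage seed from the global seed by a fixed offset, mod 2**31."""
    return (int(global_seed) + int(offset)) % (2**31 - 1)
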