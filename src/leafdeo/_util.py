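"""Small shared helpers: errors, rounding, sample-name parsing."""

from __future__ import annotations

from decimal import ROUND_HALF_EVEN, Decimal

import pandas as pd


class LeafdeoError(Exception):
    """Base class for all package errors."""


class InputError(LeafdeoError, ValueError):
    """Malformed or inconsistent input data."""


class ConfigurationError(LeafdeoError, ValueError):
    """Invalid configuration value; the message names the offending field."""


class FormatError(InputError):
    """A file does not follow its documented layout."""


def round1(x: float) -> float:
    """Round to one decimal, half to even, working in decimal digits.

    Plain ``round()`` operates on the binary float and can mis-round values
    such as 46.15 whose decimal halves are not representable; percentages
    are therefore quantized through :class:`decimal.Decimal`.
    """
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def percentage1(numerator: int, denominator: int) -> float:
    """Exact ``100 * numerator / denominator`` rounded half-to-even to one decimal."""
    numerator, denominator = int(numerator), int(denominator)
    if denominator == 0:
        return 0.0
    q = Decimal(100 * numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


def sample_name(species: str, segment: str, replicate: int | str) -> str:
    return f"{species}_{segment}_r{replicate}"


def parse_sample_names(columns) -> pd.DataFrame:
    """Parse ``species_segment_rN`` column names into a metadata frame.

    Returns a DataFrame indexed by sample name with columns
    ``species``, ``segment``, ``replicate``.
    """
    rows = {}
    for col in columns:
        parts = str(col).split("_")
        if len(parts) != 3 or not parts[2].startswith("r"):
            raise FormatError(
                f"sample column {col!r} does not follow the species_segment_rN convention"
            )
        rows[col] = {"species": parts[0], "segment": parts[1], "replicate": int(parts[2][1:])}
    return pd.DataFrame.from_dict(rows, orient="index")
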