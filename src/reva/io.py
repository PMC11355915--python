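"""Bit-stable CSV helpers shared by the pipeline and the CLI.

Floats are written with their shortest round-trip representation so that a
written table reads back bit-identical and re-runs produce byte-identical
artifacts.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["write_csv", "read_csv"]


def _round_trip_float(v) -> str:
    return repr(float(v))


def write_csv(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a table with lossless float formatting."""
    frame.to_csv(path, index=index, float_format=_round_trip_float)


def read_csv(path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_csv`, bit-exact for floats."""
    kwargs.setdefault("float_precision", "round_trip")
    return pd.read_csv(path, **kwargs)
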