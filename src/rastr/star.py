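"""STAR-format metadata tables, read and written through gemmi's CIF layer.

Tables use RELION-style column naming where a standard name exists
(``rlnAnglePsi``, ``rlnOriginX``, ...); package-specific columns carry the
``rastr`` prefix.  One loop per block; values roundtrip through text with at
least 8 significant digits.
"""

from __future__ import annotations

import os

import gemmi
import numpy as np
import pandas as pd


def write_star(path: str | os.PathLike, df: pd.DataFrame, block_name: str = "particles") -> None:
    doc = gemmi.cif.Document()
    block = doc.add_new_block(block_name)
    tags = [str(c) for c in df.columns]
    loop = block.init_loop("_", tags)
    for _, row in df.iterrows():
        loop.add_row([_fmt(v) for v in row])
    doc.write_file(str(path))


def read_star(path: str | os.PathLike, block_name: str | None = None) -> pd.DataFrame:
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block() if block_name is None else doc.find_block(block_name)
    if block is None:
        raise ValueError(f"{path}: no block named {block_name!r}")
    tags = [item.loop.tags for item in block if item.loop is not None]
    if not tags:
        raise ValueError(f"{path}: no loop found in block {block.name!r}")
    columns = {}
    for tag in tags[0]:
        values = [gemmi.cif.as_string(v) for v in block.find_loop(tag)]
        series = pd.Series(values, dtype=object)
        try:
            series = pd.to_numeric(series)
        except (ValueError, TypeError):
            pass
        columns[tag.lstrip("_")] = series
    df = pd.DataFrame(columns)
    return df


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return f"{value:.8g}"
    if isinstance(value, (bool, np.bool_)):
        return "1" if value else "0"
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    s = str(value)
    return s if s else "''"
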