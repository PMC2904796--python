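"""Loaders for externally published screen tables.

The original screen's processed data (per-strain aging profiles with both
replicates, and pool CFU counts) were published as supplementary
spreadsheets.  These helpers read a TSV export of those tables into the
package's in-memory containers so the QC and time-course stages can be
replayed on the published numbers.  Expected profile layout: one row per
strain with a ``strain_id`` column and per-day columns named
``rep1_day<D>`` / ``rep2_day<D>`` holding the log2 ratios versus the
reference day.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .errors import ParseError
from .tagio import AgingProfileMatrix, _average_layers

__all__ = ["load_published_profiles"]

_COL_RE = re.compile(r"^rep(\d+)_day(\d+)$")


def load_published_profiles(path, reference_day: int = 3) -> AgingProfileMatrix:
    """Read a TSV of published replicate log2-ratio profiles."""
    table = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
    if "strain_id" not in table.columns:
        raise ParseError("published profile table needs a strain_id column")
    layers: dict[int, dict[int, pd.Series]] = {}
    for col in table.columns:
        m = _COL_RE.match(col)
        if m:
            rep, day = int(m.group(1)), int(m.group(2))
            layers.setdefault(rep, {})[day] = table[col]
    if not layers:
        raise ParseError("no rep<R>_day<D> columns found")
    reps = {}
    idx = pd.Index(table["strain_id"], name="strain_id")
    for rep, cols in layers.items():
        days = sorted(cols)
        mat = pd.DataFrame({d: cols[d].to_numpy(dtype=float) for d in days}, index=idx)
        if reference_day not in days:
            mat[reference_day] = 0.0
            mat = mat[sorted(mat.columns)]
        reps[rep] = mat
    if np.any([m.index.duplicated().any() for m in reps.values()]):
        raise ParseError("duplicate strain ids in published profile table")
    return AgingProfileMatrix(
        replicates=reps,
        averaged=_average_layers(reps),
        reference_day=reference_day,
    )
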