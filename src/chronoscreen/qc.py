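"""Quality-control exclusions for pooled-screen aging profiles.

Two filters are applied before clustering, in this order: (1) strains whose
tag signal sits at hybridization background at every sampled time point in
either replicate (slow growers, poorly hybridizing tags) are dropped; (2)
among the survivors, strains whose two replicate aging profiles disagree —
root squared mean error (RSME) above the 90th percentile — are dropped.
What remains is averaged across replicates for clustering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .tagio import AgingProfileMatrix, _average_layers

__all__ = [
    "QCReport",
    "flag_background_tags",
    "detect_background_strains",
    "replicate_rsme",
    "filter_high_rsme",
    "average_replicates",
    "apply_qc",
]


@dataclass
class QCReport:
    excluded_background: list[str]
    excluded_rsme: list[str]
    rsme_per_strain: pd.Series
    rsme_threshold: float
    retained: list[str]
    k_factor: float = 2.0
    percentile: float = 90.0
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_excluded_background": len(self.excluded_background),
            "n_excluded_rsme": len(self.excluded_rsme),
            "n_retained": len(self.retained),
            "rsme_threshold": self.rsme_threshold,
            "k_factor": self.k_factor,
            "percentile": self.percentile,
            "excluded_background": list(self.excluded_background),
            "excluded_rsme": list(self.excluded_rsme),
            **self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def flag_background_tags(
    table: pd.DataFrame, background_level: float, k_factor: float = 2.0
) -> set[tuple[str, str, int]]:
    """Tags whose intensity stays below ``k_factor * background_level`` at every day.

    Returns a set of ``(strain_id, tag, replicate)`` keys, suitable for
    :func:`chronoscreen.tagio.combine_tags`.
    """
    if background_level <= 0:
        raise ConfigurationError("background_level must be > 0")
    threshold = k_factor * background_level
    below = (
        table.assign(below=table["intensity"] < threshold)
        .groupby(["strain_id", "tag", "replicate"])["below"]
        .all()
    )
    return set(below.index[below])


def detect_background_strains(
    combined: pd.DataFrame, background_level: float, k_factor: float = 2.0
) -> list[str]:
    """Strains at background level across the whole time course.

    A strain is excluded when, in either replicate, its combined (tag-
    averaged) intensity is below ``k_factor * background_level`` at EVERY
    sampled time point — one day of clear signal rescues the strain.
    ``combined`` is the output of :func:`chronoscreen.tagio.combine_tags`.
    """
    if background_level <= 0:
        raise ConfigurationError("background_level must be > 0")
    threshold = k_factor * background_level
    below_all = (
        combined.assign(below=combined["intensity"] < threshold)
        .groupby(["strain_id", "replicate"])["below"]
        .all()
    )
    excluded = below_all.groupby(level="strain_id").any()
    return sorted(excluded.index[excluded])


def replicate_rsme(profiles: AgingProfileMatrix) -> pd.Series:
    """Root squared mean error between the two replicate aging profiles.

    ``RSME_s = sqrt(mean_t (r1[s,t] - r2[s,t])^2)`` over non-reference days
    shared by both replicates (the reference column is identically zero in
    both and would dilute the statistic).  NaN flags strains with no shared
    non-reference day (uncomputable).
    """
    reps = sorted(profiles.replicates)
    if len(reps) != 2:
        raise InputError(f"RSME requires exactly two replicates, got {len(reps)}")
    days = profiles.non_reference_days
    r1 = profiles.replicates[reps[0]][days].to_numpy(dtype=float)
    r2 = profiles.replicates[reps[1]][days].to_numpy(dtype=float)
    diff2 = (r1 - r2) ** 2
    shared = ~np.isnan(diff2)
    n_shared = shared.sum(axis=1)
    with np.errstate(invalid="ignore"):
        rsme = np.sqrt(np.nansum(diff2, axis=1) / n_shared)
    rsme[n_shared < 1] = np.nan
    return pd.Series(rsme, index=profiles.replicates[reps[0]].index, name="rsme")


def filter_high_rsme(rsme: pd.Series, percentile: float = 90.0) -> tuple[list[str], float]:
    """Exclude strains whose RSME exceeds the nearest-rank percentile.

    The threshold is the value at position ``ceil(percentile/100 * n)`` of
    the sorted computable RSMEs (nearest-rank definition — a reproducible
    integer cutoff); strains strictly above it are excluded, so ties at the
    threshold are retained.
    """
    values = rsme.dropna()
    if values.empty:
        raise InputError("no computable RSME values")
    n = len(values)
    rank = max(1, math.ceil(percentile / 100.0 * n))
    threshold = float(np.sort(values.to_numpy())[rank - 1])
    excluded = sorted(values.index[values > threshold])
    return excluded, threshold


def average_replicates(profiles: AgingProfileMatrix, retained) -> AgingProfileMatrix:
    """Averaged profile matrix restricted to the retained strains."""
    kept = profiles.restrict(retained)
    kept.averaged = _average_layers(kept.replicates)
    return kept


def apply_qc(
    combined: pd.DataFrame,
    profiles: AgingProfileMatrix,
    background_level: float,
    k_factor: float = 2.0,
    percentile: float = 90.0,
) -> tuple[AgingProfileMatrix, QCReport]:
    """Run both exclusion rules and return (averaged retained profiles, report).

    Order: background exclusion first, then the RSME percentile rule on the
    survivors.  Strains whose RSME is uncomputable are also dropped (recorded
    in the report).
    """
    background = detect_background_strains(combined, background_level, k_factor)
    after_bg = profiles.strain_ids.difference(background)
    rsme = replicate_rsme(profiles.restrict(after_bg))
    uncomputable = sorted(rsme.index[rsme.isna()])
    excluded_rsme, threshold = filter_high_rsme(rsme, percentile)
    retained = sorted(after_bg.difference(excluded_rsme).difference(uncomputable))
    report = QCReport(
        excluded_background=sorted(background),
        excluded_rsme=excluded_rsme,
        rsme_per_strain=rsme,
        rsme_threshold=threshold,
        retained=retained,
        k_factor=k_factor,
        percentile=percentile,
        extra={"excluded_rsme_uncomputable": uncomputable},
    )
    return average_replicates(profiles, retained), report
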