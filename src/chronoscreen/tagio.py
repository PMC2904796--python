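"""Read/write the screen's tabular formats and build per-strain aging profiles.

All tables are plain TSV (tab-separated, '.' decimal, header required).
The central product is the :class:`AgingProfileMatrix`: per-strain log2
intensity ratios at each sampled day relative to the reference day (day 3 by
convention, where pool survival is defined as 100%), one layer per replicate
pool plus an averaged layer.  Missing data propagate as NaN masks with
recorded reason codes, never silent drops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ChronoscreenError, ParseError

__all__ = [
    "AgingProfileMatrix",
    "read_tag_intensities",
    "write_tag_intensities",
    "read_pool_cfu",
    "write_pool_cfu",
    "mean_normalize",
    "combine_tags",
    "compute_profiles",
]

_TAG_COLUMNS = ["strain_id", "tag", "replicate", "day", "intensity"]
_CFU_COLUMNS = ["replicate", "day", "cfu_per_ml"]
_FLOAT_FMT = "%.12g"  # lossless round-trip at 12 significant digits


def _validate_tag_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _TAG_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"tag intensity table missing column(s): {missing}")
    table = table[_TAG_COLUMNS].copy()
    bad_tag = ~table["tag"].isin(["up", "down"])
    if bad_tag.any():
        raise ParseError(f"invalid tag value at row {int(np.flatnonzero(bad_tag)[0])}")
    neg = table["intensity"] < 0
    if neg.any():
        raise ParseError(f"negative intensity at row {int(np.flatnonzero(neg)[0])}")
    dup = table.duplicated(subset=["strain_id", "tag", "replicate", "day"])
    if dup.any():
        row = table.loc[dup].iloc[0]
        raise ParseError(
            "duplicate (strain, tag, replicate, day) key: "
            f"({row.strain_id}, {row.tag}, {row.replicate}, {row.day})"
        )
    days_by_rep = table.groupby("replicate")["day"].agg(lambda d: tuple(sorted(set(d))))
    if days_by_rep.nunique() > 1:
        raise ParseError("replicates do not share the same day set")
    return table.sort_values(["strain_id", "tag", "replicate", "day"], ignore_index=True)


def read_tag_intensities(path) -> pd.DataFrame:
    """Read and validate a per-tag intensity TSV.

    Expected header: strain_id, tag, replicate, day, intensity.  Raises
    :class:`ParseError` naming the offending row for duplicate keys, negative
    intensities or missing columns.
    """
    table = pd.read_csv(path, sep="\t", dtype={"strain_id": str, "tag": str})
    return _validate_tag_table(table)


def write_tag_intensities(table: pd.DataFrame, path) -> None:
    _validate_tag_table(table).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_pool_cfu(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in _CFU_COLUMNS if c not in table.columns]
    if missing:
        raise ParseError(f"pool CFU table missing column(s): {missing}")
    if (table["cfu_per_ml"] <= 0).any():
        raise ParseError("cfu_per_ml must be positive")
    return table[[c for c in table.columns if c in _CFU_COLUMNS + ["percent_survival"]]].copy()


def write_pool_cfu(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def mean_normalize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean-normalize each array to the grand mean across arrays.

    One hybridization array corresponds to one (replicate, day) pair; every
    intensity on it is rescaled by (grand mean of per-array means) / (its own
    array mean), so all array means coincide afterwards while within-array
    relative intensities are untouched.  The common target keeps values in
    input units; any common target gives identical downstream log2 ratios.
    """
    table = _validate_tag_table(table)
    means = table.groupby(["replicate", "day"])["intensity"].mean()
    if (means == 0).any():
        rep, day = means.index[means == 0][0]
        raise ChronoscreenError(f"array (replicate={rep}, day={day}) has all-zero intensities")
    grand = means.mean()
    factors = grand / means
    key = pd.MultiIndex.from_frame(table[["replicate", "day"]])
    out = table.copy()
    out["intensity"] = table["intensity"].to_numpy() * factors.reindex(key).to_numpy()
    return out


def combine_tags(table: pd.DataFrame, background_flags: set | None = None) -> pd.DataFrame:
    """Collapse uptag/downtag intensities to one value per (strain, replicate, day).

    Geometric mean of the two tags — the arithmetic mean on the log scale,
    matching the multiplicative error model.  A tag flagged as background
    (``(strain_id, tag, replicate)`` in ``background_flags``) is dropped and
    the other tag used alone; with both tags flagged the geometric mean is
    kept (the strain will sit at background and fall to the background
    filter).  Returns a tidy DataFrame with columns strain_id, replicate,
    day, intensity, n_tags.
    """
    table = _validate_tag_table(table)
    background_flags = background_flags or set()
    if background_flags:
        flag_key = list(map(tuple, table[["strain_id", "tag", "replicate"]].itertuples(index=False)))
        flagged = np.array([k in background_flags for k in flag_key])
        group_key = pd.MultiIndex.from_frame(table[["strain_id", "replicate", "day"]])
        both = pd.Series(flagged, index=group_key).groupby(level=[0, 1, 2]).transform("all")
        use = ~flagged | both.to_numpy()  # keep both tags when both are background
        table = table.loc[use]
    with np.errstate(divide="ignore"):
        logs = np.log(table["intensity"].to_numpy())
    combined = (
        table.assign(_log=logs)
        .groupby(["strain_id", "replicate", "day"], as_index=False)
        .agg(intensity=("_log", lambda v: float(np.exp(np.mean(v)))), n_tags=("_log", "size"))
    )
    return combined


@dataclass
class AgingProfileMatrix:
    """Per-strain log2 intensity ratios versus the reference day.

    ``replicates`` maps replicate index -> strain x day DataFrame of
    ``r[s, t] = log2(I[s, t] / I[s, ref])`` (reference column identically 0);
    ``averaged`` is the arithmetic mean across replicate layers where
    present.  NaN marks masked entries; ``mask_reasons`` records why a
    strain/replicate was masked.
    """

    replicates: dict[int, pd.DataFrame]
    averaged: pd.DataFrame
    reference_day: int
    mask_reasons: dict[tuple[str, int], str] = field(default_factory=dict)

    @property
    def days(self) -> list:
        return list(self.averaged.columns)

    @property
    def non_reference_days(self) -> list:
        return [d for d in self.days if d != self.reference_day]

    @property
    def strain_ids(self) -> pd.Index:
        return self.averaged.index

    def restrict(self, strains) -> "AgingProfileMatrix":
        strains = pd.Index(strains)
        return AgingProfileMatrix(
            replicates={r: m.loc[m.index.intersection(strains)] for r, m in self.replicates.items()},
            averaged=self.averaged.loc[self.averaged.index.intersection(strains)],
            reference_day=self.reference_day,
            mask_reasons=dict(self.mask_reasons),
        )


def _average_layers(layers: dict[int, pd.DataFrame]) -> pd.DataFrame:
    stacked = np.stack([m.to_numpy(dtype=float) for m in layers.values()])
    with warnings.catch_warnings():  # all-NaN (fully masked) entries stay NaN
        warnings.simplefilter("ignore", category=RuntimeWarning)
        avg = np.nanmean(stacked, axis=0)
    any_layer = next(iter(layers.values()))
    return pd.DataFrame(avg, index=any_layer.index, columns=any_layer.columns)


def compute_profiles(strain_intensities: pd.DataFrame, reference_day: int = 3) -> AgingProfileMatrix:
    """Aging profiles from combined strain-level intensities.

    ``r[s, t] = log2(I[s, t] / I[s, ref])`` per replicate; the reference
    column is exactly zero.  Strains with zero or missing reference-day
    intensity in a replicate are masked there with a reason code.
    """
    wide = strain_intensities.pivot_table(
        index="strain_id", columns="day", values="intensity", aggfunc="first"
    )
    days = sorted(wide.columns)
    if reference_day not in days:
        raise ChronoscreenError(f"reference day {reference_day} absent from data")
    reps = sorted(strain_intensities["replicate"].unique())
    all_strains = pd.Index(sorted(strain_intensities["strain_id"].unique()), name="strain_id")
    layers: dict[int, pd.DataFrame] = {}
    reasons: dict[tuple[str, int], str] = {}
    for rep in reps:
        sub = strain_intensities[strain_intensities["replicate"] == rep]
        mat = (
            sub.pivot(index="strain_id", columns="day", values="intensity")
            .reindex(index=all_strains, columns=days)
        )
        ref = mat[reference_day]
        bad = ~(ref > 0)
        for sid in mat.index[bad.fillna(True)]:
            reasons[(sid, rep)] = (
                "reference_day_missing" if pd.isna(ref.get(sid)) else "reference_day_zero"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            profile = np.log2(mat.to_numpy() / ref.to_numpy()[:, None])
        profile[bad.fillna(True).to_numpy(), :] = np.nan
        layer = pd.DataFrame(profile, index=mat.index, columns=days)
        ok = ~bad.fillna(True)
        layer.loc[ok, reference_day] = 0.0
        layers[int(rep)] = layer
    return AgingProfileMatrix(
        replicates=layers,
        averaged=_average_layers(layers),
        reference_day=reference_day,
        mask_reasons=reasons,
    )
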