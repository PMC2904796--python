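"""Synthetic pooled chronological-lifespan screens with known ground truth.

The generator emulates a competitive aging experiment on a pooled yeast
deletion collection: every strain carries a unique barcode pair (uptag /
downtag), two replicate pools age side by side in the same medium, and at
each sampled day the surviving cells are quantified through barcode
hybridization intensities plus a pool-level CFU/mL count.  Each strain dies
along a Boltzmann sigmoid with its own midpoint ``t50``; long- and
short-lived strains get their midpoint multiplied up or down.  Optional
nuisance processes mirror the screen's known artifacts: per-tag affinity
differences, lognormal measurement noise, tags that hybridize at background
level regardless of abundance, and adaptive regrowth (a late step gain in
viable count that inflates apparent longevity).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InputError, SimulationError

__all__ = [
    "ScreenConfig",
    "SyntheticTruth",
    "boltzmann",
    "survival_fraction",
    "simulate_truth",
    "simulate_pool_dynamics",
    "simulate_tag_intensities",
    "simulate_screen",
    "evaluate_recovery",
]


def boltzmann(t, top: float, bottom: float, t50: float, tau: float):
    """Four-parameter Boltzmann sigmoid, decreasing in ``t``.

    ``V(t) = bottom + (top - bottom) / (1 + exp((t - t50) / tau))``.
    This single definition is shared by the generator and the survival-fitting
    module so that parameter recovery is exact in the noiseless limit.
    """
    t = np.asarray(t, dtype=float)
    z = np.clip((t - t50) / tau, -700.0, 700.0)  # avoid exp overflow; saturates anyway
    return bottom + (top - bottom) / (1.0 + np.exp(z))


def survival_fraction(t, t50: float, tau: float, reference_day: float):
    """Fraction of reference-day viability: sigmoid normalized to 1 at the reference day."""
    return boltzmann(t, 1.0, 0.0, t50, tau) / boltzmann(reference_day, 1.0, 0.0, t50, tau)


@dataclass(frozen=True)
class ScreenConfig:
    """Design constants of a simulated pooled screen.

    Defaults follow the real experiment's design: ~4,800 viable deletion
    strains aged as two replicate pools, sampled at days 3, 9, 11, 15 and 20
    with day 3 defining 100% survival, ~12% short-lived and ~1% long-lived
    strains, ~10% of tags at hybridization background, and occasional
    adaptive regrowth producing a CFU bump from day 12 on.
    """

    n_strains: int = 4800
    timepoints: tuple[int, ...] = (3, 9, 11, 15, 20)
    reference_day: int = 3
    n_replicates: int = 2
    pool_t50_mean: float = 11.0
    pool_t50_sd: float = 0.75
    slope_tau: float = 2.0
    frac_long: float = 0.01
    long_t50_multiplier: float = 1.8
    frac_short: float = 0.12
    short_t50_multiplier: float = 0.5
    noise_sigma: float = 0.3
    tag_affinity_sigma: float = 0.5
    frac_background_tags: float = 0.10
    background_level: float = 20.0
    intensity_scale: float = 1e6
    p_regrow: float = 0.01
    regrow_day: int = 12
    regrow_gain: float = 5.0
    cfu_jitter_sigma: float = 0.02
    initial_cells_per_strain: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(self.timepoints)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ConfigurationError("timepoints must be strictly increasing")
        if self.reference_day not in days:
            raise ConfigurationError("reference_day must be one of the timepoints")
        for name in ("frac_long", "frac_short", "frac_background_tags", "p_regrow"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        if self.frac_long + self.frac_short > 1.0:
            raise ConfigurationError("frac_long + frac_short exceeds 1")
        for name in ("pool_t50_sd", "noise_sigma", "tag_affinity_sigma", "cfu_jitter_sigma"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.long_t50_multiplier <= 1.0:
            raise ConfigurationError("long_t50_multiplier must exceed 1")
        if not 0.0 < self.short_t50_multiplier < 1.0:
            raise ConfigurationError("short_t50_multiplier must lie in (0, 1)")
        if self.slope_tau <= 0 or self.background_level <= 0 or self.intensity_scale <= 0:
            raise ConfigurationError("slope_tau, background_level, intensity_scale must be > 0")
        if self.n_strains < 1 or self.n_replicates < 1:
            raise ConfigurationError("need at least one strain and one replicate")

    def with_(self, **kwargs) -> "ScreenConfig":
        return replace(self, **kwargs)


@dataclass
class SyntheticTruth:
    """Planted per-strain ground truth of a simulated screen.

    ``table`` has one row per strain: ``strain_id``, ``true_t50`` (days),
    ``true_class`` in {short, long, neutral}, ``regrows`` flag and
    ``regrow_day``, per-tag affinities, and per-tag background flags.
    """

    table: pd.DataFrame
    config: ScreenConfig = field(repr=False)

    @property
    def strain_ids(self) -> pd.Index:
        return pd.Index(self.table["strain_id"])

    def classes(self) -> pd.Series:
        return self.table.set_index("strain_id")["true_class"]


def simulate_truth(config: ScreenConfig) -> SyntheticTruth:
    """Draw per-strain lifespans, classes, tag properties and regrowth flags.

    Exactly ``round(frac_long * n)`` strains are long-lived and
    ``round(frac_short * n)`` short-lived; base midpoints come from a normal
    truncated below at the first sampled day and are then multiplied by the
    class multiplier.  Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_strains
    n_long = round(config.frac_long * n)
    n_short = round(config.frac_short * n)
    if n_long + n_short > n:
        raise ConfigurationError("rounded class counts exceed n_strains")

    floor = float(config.timepoints[0])
    if config.pool_t50_sd == 0:
        base_t50 = np.full(n, max(config.pool_t50_mean, floor))
    else:
        a = (floor - config.pool_t50_mean) / config.pool_t50_sd
        base_t50 = stats.truncnorm.rvs(
            a, np.inf, loc=config.pool_t50_mean, scale=config.pool_t50_sd,
            size=n, random_state=rng,
        )

    classes = np.array(["neutral"] * n, dtype=object)
    order = rng.permutation(n)
    classes[order[:n_long]] = "long"
    classes[order[n_long:n_long + n_short]] = "short"
    mult = np.where(
        classes == "long", config.long_t50_multiplier,
        np.where(classes == "short", config.short_t50_multiplier, 1.0),
    )
    t50 = base_t50 * mult

    regrows = rng.random(n) < config.p_regrow
    up_aff = np.exp(rng.normal(0.0, config.tag_affinity_sigma, size=n))
    down_aff = np.exp(rng.normal(0.0, config.tag_affinity_sigma, size=n))
    up_bg = rng.random(n) < config.frac_background_tags
    down_bg = rng.random(n) < config.frac_background_tags

    width = len(str(n))
    table = pd.DataFrame(
        {
            "strain_id": [f"strain{i:0{width}d}" for i in range(n)],
            "true_t50": t50,
            "true_class": classes,
            "regrows": regrows,
            "regrow_day": np.where(regrows, config.regrow_day, np.nan),
            "uptag_affinity": up_aff,
            "downtag_affinity": down_aff,
            "uptag_background": up_bg,
            "downtag_background": down_bg,
        }
    )
    return SyntheticTruth(table=table, config=config)


def simulate_pool_dynamics(
    truth: SyntheticTruth, config: ScreenConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Viable cells per strain per day, and the pool CFU table per replicate.

    Each strain follows its planted sigmoid normalized to the reference day;
    regrowing strains get a step gain of ``regrow_gain`` from ``regrow_day``
    on.  The pool count is the sum over strains; each replicate's CFU reading
    gets independent small lognormal jitter (the underlying viable counts are
    shared, as both replicate pools were seeded identically).

    Returns ``(viable, pool_cfu)`` where ``viable`` is a strain x day
    DataFrame and ``pool_cfu`` has columns replicate, day, cfu_per_ml,
    percent_survival (reference day = 100 exactly).
    """
    config = config or truth.config
    days = np.asarray(config.timepoints, dtype=float)
    t50 = truth.table["true_t50"].to_numpy()
    frac = survival_fraction(days[None, :], t50[:, None], config.slope_tau, config.reference_day)
    counts = config.initial_cells_per_strain * frac
    gain = np.where(
        truth.table["regrows"].to_numpy()[:, None] & (days[None, :] >= config.regrow_day),
        config.regrow_gain, 1.0,
    )
    counts = counts * gain
    viable = pd.DataFrame(counts, index=truth.strain_ids, columns=config.timepoints)
    viable.index.name = "strain_id"
    viable.columns.name = "day"

    totals = counts.sum(axis=0)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for rep in range(1, config.n_replicates + 1):
        jitter = np.exp(rng.normal(0.0, config.cfu_jitter_sigma, size=len(days)))
        cfu = totals * jitter
        ref_i = list(config.timepoints).index(config.reference_day)
        pct = 100.0 * cfu / cfu[ref_i]
        pct[ref_i] = 100.0
        for d, c, p in zip(config.timepoints, cfu, pct):
            rows.append({"replicate": rep, "day": d, "cfu_per_ml": c, "percent_survival": p})
    return viable, pd.DataFrame(rows)


def simulate_tag_intensities(
    viable: pd.DataFrame, truth: SyntheticTruth, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-tag hybridization intensities for every replicate and sampled day.

    A sample of the aging pool is regrown in fresh medium before tagging;
    equal growth rates make the outgrowth proportion-preserving, so the
    intensity of a normal tag is ``affinity * (strain's share of viable
    cells) * scale`` with independent lognormal noise per tag, replicate and
    day.  Background-flagged tags hybridize near ``background_level``
    regardless of abundance.  Deterministic for fixed config seed.
    """
    config = config or truth.config
    counts = viable.to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if np.any(totals <= 0):
        raise SimulationError("pool extinct: zero total viable cells at a sampled day")
    shares = counts / totals[None, :]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n, t = counts.shape
    frames = []
    for rep in range(1, config.n_replicates + 1):
        for tag, aff_col, bg_col in (
            ("up", "uptag_affinity", "uptag_background"),
            ("down", "downtag_affinity", "downtag_background"),
        ):
            aff = truth.table[aff_col].to_numpy()[:, None]
            bg = truth.table[bg_col].to_numpy()[:, None]
            noise = np.exp(rng.normal(0.0, config.noise_sigma, size=(n, t)))
            signal = config.intensity_scale * aff * shares * noise
            bg_noise = np.exp(rng.normal(0.0, config.noise_sigma, size=(n, t)))
            background = config.background_level * bg_noise
            intensity = np.where(bg, background, signal)
            frames.append(
                pd.DataFrame(
                    {
                        "strain_id": np.repeat(viable.index.to_numpy(), t),
                        "tag": tag,
                        "replicate": rep,
                        "day": np.tile(np.asarray(config.timepoints), n),
                        "intensity": intensity.ravel(),
                    }
                )
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["strain_id", "tag", "replicate", "day"], ignore_index=True)


def simulate_screen(config: ScreenConfig):
    """Convenience wrapper: truth, viable counts, pool CFUs, tag intensities."""
    truth = simulate_truth(config)
    viable, pool_cfu = simulate_pool_dynamics(truth, config)
    intensities = simulate_tag_intensities(viable, truth, config)
    return truth, viable, pool_cfu, intensities


_CLASSES = ("short", "long", "neutral")


def evaluate_recovery(truth: SyntheticTruth, calls: pd.Series | dict) -> pd.DataFrame:
    """Per-class precision/recall of predicted classes against planted truth.

    ``calls`` maps strain_id -> predicted class; strains absent from the
    mapping (e.g. removed by QC) count as non-calls.  Precision with zero
    calls for a class is NaN with ``no_calls=True``.
    """
    calls = pd.Series(calls, dtype=object)
    unknown = calls.index.difference(truth.strain_ids)
    if len(unknown):
        raise InputError(f"unknown strain ids in calls: {list(unknown[:5])}")
    true = truth.classes()
    pred = calls.reindex(true.index).fillna("none")
    rows = []
    for cls in _CLASSES:
        tp = int(((pred == cls) & (true == cls)).sum())
        fp = int(((pred == cls) & (true != cls)).sum())
        fn = int(((pred != cls) & (true == cls)).sum())
        n_called = tp + fp
        rows.append(
            {
                "class": cls,
                "tp": tp,
                "fp": fp,
                "fn": fn,
                "n_called": n_called,
                "n_true": tp + fn,
                "precision": tp / n_called if n_called else float("nan"),
                "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
                "no_calls": n_called == 0,
            }
        )
    return pd.DataFrame(rows).set_index("class")
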