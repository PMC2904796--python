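"""Self-contained validation experiments on synthetic screens.

Each function generates its own data with the synthetic generator, runs the
relevant pipeline stages from scratch and returns the measured quantities.
They back both the validation test suite and the reproduction script, so the
numbers reported anywhere are always recomputed, never stored.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cluster import classify_clusters, kmeans_profiles, strain_classes
from .qc import apply_qc, flag_background_tags
from .simulate import ScreenConfig, simulate_screen, survival_fraction
from .survival import reconstruct_survival
from .tagio import combine_tags, compute_profiles, mean_normalize
from .timecourse import significant_strains, timecourse_test

__all__ = [
    "prepare_profiles",
    "null_fdr_experiment",
    "planted_recovery_experiment",
    "zero_noise_consistency",
]


def prepare_profiles(cfg: ScreenConfig, qc: bool = True):
    """Simulate a screen and run it through normalization, QC and profiling."""
    truth, viable, pool_cfu, intensities = simulate_screen(cfg)
    normalized = mean_normalize(intensities)
    flags = flag_background_tags(normalized, cfg.background_level)
    combined = combine_tags(normalized, background_flags=flags)
    profiles = compute_profiles(combined, reference_day=cfg.reference_day)
    if not qc:
        return truth, pool_cfu, profiles, None
    averaged, report = apply_qc(combined, profiles, cfg.background_level)
    return truth, pool_cfu, profiles, (averaged, report)


def null_fdr_experiment(
    n_strains: int = 2000,
    noise_sigma: float = 0.3,
    B: int = 200,
    n_seeds: int = 10,
    q_cutoff: float = 0.1,
    seed: int = 0,
) -> dict:
    """Proportion of q <= cutoff calls on screens with no real lifespan effects.

    Flat truth: every strain shares the same midpoint, no regrowth, no
    background tags — only measurement noise.  With no true signal the
    q <= 0.1 call rate estimates the worst-case false-positive behaviour of
    the whole time-course analysis.
    """
    props = []
    for i in range(n_seeds):
        cfg = ScreenConfig(
            n_strains=n_strains, pool_t50_sd=0.0, frac_long=0.0, frac_short=0.0,
            noise_sigma=noise_sigma, frac_background_tags=0.0, p_regrow=0.0,
            seed=seed + i,
        )
        truth, _, profiles, _ = prepare_profiles(cfg, qc=False)
        res = timecourse_test(profiles, B=B, seed=seed + 1000 + i)
        props.append(len(significant_strains(res, q_cutoff)) / int(res["testable"].sum()))
    return {"per_seed": props, "mean": float(np.mean(props)), "n_strains": n_strains,
            "B": B, "n_seeds": n_seeds}


def planted_recovery_experiment(
    seed: int,
    n_strains: int = 1000,
    frac_long: float = 0.05,
    long_mult: float = 1.8,
    frac_short: float = 0.10,
    short_mult: float = 0.5,
    noise_sigma: float = 0.3,
    B: int = 500,
    q_cutoff: float = 0.1,
) -> dict:
    """Recovery of planted long-/short-lived strains by the full pipeline.

    QC -> K-means classification -> time-course test; a strain is called for
    a class when its cluster carries that label AND its q-value passes the
    cutoff.  QC-excluded strains count as non-calls.  Only the planted class
    effects are present (no regrowth), so the returned precision/recall
    measure class recovery, not confound handling.
    """
    cfg = ScreenConfig(
        n_strains=n_strains, frac_long=frac_long, long_t50_multiplier=long_mult,
        frac_short=frac_short, short_t50_multiplier=short_mult,
        noise_sigma=noise_sigma, p_regrow=0.0, seed=seed,
    )
    truth, _, profiles, (averaged, report) = prepare_profiles(cfg)
    model = kmeans_profiles(averaged, k=10, seed=seed + 11)
    classify_clusters(model)
    classes = strain_classes(model)
    res = timecourse_test(profiles.restrict(report.retained), B=B, seed=seed + 17)
    sig = set(significant_strains(res, q_cutoff))
    calls = pd.Series(
        {s: c for s, c in classes.items() if c in ("short", "long") and s in sig},
        dtype=object,
    )
    from .simulate import evaluate_recovery

    metrics = evaluate_recovery(truth, calls)
    return {
        "long_recall": float(metrics.loc["long", "recall"]),
        "long_precision": float(metrics.loc["long", "precision"]),
        "short_recall": float(metrics.loc["short", "recall"]),
        "n_strains": n_strains,
        "metrics": metrics,
    }


def zero_noise_consistency(n_strains: int = 50, seed: int = 3) -> dict:
    """Max deviation between reconstructed and planted percent survival.

    With all nuisance processes off, the reconstruction (fold ratio x pool
    CFU, day-3 = 100%) must return exactly the planted sigmoids.
    """
    cfg = ScreenConfig(
        n_strains=n_strains, noise_sigma=0.0, tag_affinity_sigma=0.0,
        frac_background_tags=0.0, p_regrow=0.0, cfu_jitter_sigma=0.0, seed=seed,
    )
    truth, pool_cfu, profiles, _ = prepare_profiles(cfg, qc=False)
    curves = reconstruct_survival(profiles, pool_cfu)
    days = np.asarray(cfg.timepoints, dtype=float)
    t50 = truth.table.set_index("strain_id")["true_t50"]
    planted = 100.0 * survival_fraction(
        days[None, :], t50.loc[curves.percent.index].to_numpy()[:, None],
        cfg.slope_tau, cfg.reference_day,
    )
    dev = np.abs(curves.percent.to_numpy() - planted)
    return {"max_abs_dev": float(dev.max()), "n_strains": n_strains}
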