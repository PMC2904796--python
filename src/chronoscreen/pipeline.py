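"""End-to-end orchestration: simulate -> profiles -> qc -> cluster -> test -> survival -> enrich.

One YAML config drives a reproducible run.  A single seed fans out to
per-stage child seeds by fixed offsets, so rerunning the same config gives
bit-identical artifacts; the JSON report reconciles strain counts across
stages (input = background-excluded + RSME-excluded + retained; class
tallies partition the retained set).
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cluster import classify_clusters, kmeans_profiles, strain_classes
from .enrichment import AnnotationMap, enrich
from .errors import ConfigurationError
from .qc import apply_qc
from .simulate import ScreenConfig, simulate_screen
from .survival import fit_all_strains, reconstruct_survival
from .tagio import (
    combine_tags,
    compute_profiles,
    mean_normalize,
    read_pool_cfu,
    read_tag_intensities,
    write_pool_cfu,
    write_tag_intensities,
)
from .qc import flag_background_tags

__all__ = ["PipelineConfig", "run_pipeline"]

# fixed per-stage seed offsets fanned out from the single config seed
_SEED_KMEANS = 11
_SEED_PERMUTATION = 17


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    outdir: str = "chronoscreen_run"
    seed: int = 0
    simulate: bool = True
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    intensities_path: str | None = None
    cfu_path: str | None = None
    annotation_path: str | None = None
    reference_day: int = 3
    background_level: float = 20.0
    k_factor: float = 2.0
    rsme_percentile: float = 90.0
    k_clusters: int = 10
    n_init: int = 20
    theta_short: float = 0.5
    theta_long: float = 0.5
    spline_df: int | None = None
    permutations: int = 1000
    pi0_lambda: float = 0.5
    q_cutoff: float = 0.1
    enrich_alpha: float = 0.01

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        screen = ScreenConfig(**raw.pop("screen", {}))
        cfg = cls(screen=screen, **raw)
        if not cfg.simulate:
            if not cfg.intensities_path or not cfg.cfu_path:
                raise ConfigurationError(
                    "simulate=false requires intensities_path and cfu_path"
                )
            for p in (cfg.intensities_path, cfg.cfu_path):
                if not Path(p).exists():
                    raise ConfigurationError(f"input file not found: {p}")
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["screen"] = asdict(self.screen)
        return d


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Run every stage, write artifacts under ``config.outdir``, return the report."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software_version": __version__,
        "config": config.to_dict(),
        "seeds": {
            "root": config.seed,
            "kmeans": config.seed + _SEED_KMEANS,
            "permutation": config.seed + _SEED_PERMUTATION,
        },
        "stages": {},
        "artifacts": {},
    }

    def stage(name):
        report["stages"][name] = {"wall_time_s": None}
        return time.perf_counter()

    def done(name, t0, **counts):
        report["stages"][name]["wall_time_s"] = round(time.perf_counter() - t0, 3)
        report["stages"][name].update(counts)

    # --- inputs -----------------------------------------------------------
    t0 = stage("input")
    if config.simulate:
        screen_cfg = config.screen.with_(seed=config.seed)
        truth, viable, pool_cfu, intensities = simulate_screen(screen_cfg)
        truth.table.to_csv(out / "truth.tsv", sep="\t", index=False)
        write_tag_intensities(intensities, out / "tag_intensities.tsv")
        write_pool_cfu(pool_cfu, out / "pool_cfu.tsv")
        report["artifacts"]["truth"] = str(out / "truth.tsv")
        reference_day = screen_cfg.reference_day
        background_level = screen_cfg.background_level
    else:
        intensities = read_tag_intensities(config.intensities_path)
        pool_cfu = read_pool_cfu(config.cfu_path)
        reference_day = config.reference_day
        background_level = config.background_level
    n_input = intensities["strain_id"].nunique()
    done("input", t0, n_strains=n_input)

    # --- profiles ---------------------------------------------------------
    t0 = stage("profiles")
    normalized = mean_normalize(intensities)
    tag_flags = flag_background_tags(normalized, background_level, config.k_factor)
    combined = combine_tags(normalized, background_flags=tag_flags)
    profiles = compute_profiles(combined, reference_day=reference_day)
    done("profiles", t0, n_background_tags=len(tag_flags))

    # --- qc ---------------------------------------------------------------
    t0 = stage("qc")
    averaged, qc_report = apply_qc(
        combined, profiles, background_level, config.k_factor, config.rsme_percentile
    )
    qc_report.to_json(out / "qc_report.json")
    qc_report.rsme_per_strain.to_csv(out / "rsme.tsv", sep="\t")
    done(
        "qc", t0,
        n_excluded_background=len(qc_report.excluded_background),
        n_excluded_rsme=len(qc_report.excluded_rsme),
        n_excluded_rsme_uncomputable=len(qc_report.extra["excluded_rsme_uncomputable"]),
        n_retained=len(qc_report.retained),
    )

    # --- cluster ----------------------------------------------------------
    t0 = stage("cluster")
    model = kmeans_profiles(
        averaged, k=config.k_clusters, seed=config.seed + _SEED_KMEANS, n_init=config.n_init
    )
    classify_clusters(model, config.theta_short, config.theta_long)
    classes = strain_classes(model)
    model.centroids.to_csv(out / "centroids.tsv", sep="\t")
    pd.DataFrame({"cluster": model.assignment, "lifespan_class": classes}).to_csv(
        out / "clusters.tsv", sep="\t"
    )
    tallies = classes.value_counts().to_dict()
    done(
        "cluster", t0, k=model.k, within_cluster_ss=model.within_cluster_ss,
        n_short=int(tallies.get("short", 0)), n_long=int(tallies.get("long", 0)),
        n_neutral=int(tallies.get("neutral", 0)),
    )

    # --- timecourse test --------------------------------------------------
    t0 = stage("test")
    from .timecourse import significant_strains, timecourse_test

    results = timecourse_test(
        profiles.restrict(qc_report.retained),
        df=config.spline_df,
        B=config.permutations,
        seed=config.seed + _SEED_PERMUTATION,
        lam=config.pi0_lambda,
    )
    results.to_csv(out / "timecourse.tsv", sep="\t")
    significant = significant_strains(results, config.q_cutoff)
    done(
        "test", t0, n_tested=int(results["testable"].sum()),
        n_significant=len(significant), pi0=results.attrs["pi0"],
    )

    # --- survival ---------------------------------------------------------
    t0 = stage("survival")
    curves = reconstruct_survival(averaged, pool_cfu)
    fits = fit_all_strains(curves)
    curves.percent.to_csv(out / "percent_survival.tsv", sep="\t")
    fits.to_csv(out / "survival_fits.tsv", sep="\t")
    done("survival", t0, n_curves=len(curves.percent), n_converged=int(fits["converged"].sum()))

    # --- enrichment -------------------------------------------------------
    t0 = stage("enrich")
    if config.annotation_path:
        annotation = AnnotationMap.from_tsv(config.annotation_path).restrict(qc_report.retained)
        short_sig = sorted(set(classes.index[classes == "short"]) & set(significant))
        enr = enrich(short_sig, annotation, config.enrich_alpha) if short_sig else None
        if enr is not None:
            enr.to_csv(out / "enrichment.tsv", sep="\t")
        done("enrich", t0, n_terms=0 if enr is None else len(enr))
    else:
        done("enrich", t0, skipped=True)

    for name in ("clusters", "timecourse", "percent_survival", "survival_fits",
                 "centroids", "qc_report"):
        suffix = "json" if name == "qc_report" else "tsv"
        p = out / f"{name}.{suffix}"
        if p.exists():
            report["artifacts"][name] = str(p)

    # partition identities
    s = report["stages"]
    report["counts_reconciled"] = (
        s["qc"]["n_retained"]
        == s["input"]["n_strains"]
        - s["qc"]["n_excluded_background"]
        - s["qc"]["n_excluded_rsme"]
        - s["qc"]["n_excluded_rsme_uncomputable"]
    ) and (
        s["cluster"]["n_short"] + s["cluster"]["n_long"] + s["cluster"]["n_neutral"]
        == s["qc"]["n_retained"]
    )
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
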