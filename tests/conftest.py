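"""Shared fixtures: small synthetic screens built at test time."""

import numpy as np
import pandas as pd
import pytest

from chronoscreen import ScreenConfig, simulate_screen
from chronoscreen.qc import flag_background_tags
from chronoscreen.tagio import combine_tags, compute_profiles, mean_normalize


def noiseless_config(**overrides) -> ScreenConfig:
    """All nuisance processes off: noise, tag affinity, background, regrowth, jitter."""
    base = dict(
        n_strains=60,
        noise_sigma=0.0,
        tag_affinity_sigma=0.0,
        frac_background_tags=0.0,
        p_regrow=0.0,
        cfu_jitter_sigma=0.0,
        seed=7,
    )
    base.update(overrides)
    return ScreenConfig(**base)


@pytest.fixture(scope="session")
def small_screen():
    """A modest screen with every nuisance process on, shared across tests."""
    cfg = ScreenConfig(n_strains=250, seed=11)
    truth, viable, pool_cfu, intensities = simulate_screen(cfg)
    return cfg, truth, viable, pool_cfu, intensities


@pytest.fixture(scope="session")
def small_profiles(small_screen):
    cfg, truth, viable, pool_cfu, intensities = small_screen
    normalized = mean_normalize(intensities)
    flags = flag_background_tags(normalized, cfg.background_level)
    combined = combine_tags(normalized, background_flags=flags)
    profiles = compute_profiles(combined, reference_day=cfg.reference_day)
    return cfg, combined, profiles


def tiny_tag_table(n_strains=2, days=(3, 9, 11, 15, 20), reps=(1, 2), value=100.0):
    """Dense constant-intensity tag table, handy for format/edge-case tests."""
    rows = [
        {"strain_id": f"s{i}", "tag": tag, "replicate": r, "day": d, "intensity": value}
        for i in range(n_strains)
        for tag in ("up", "down")
        for r in reps
        for d in days
    ]
    return pd.DataFrame(rows)


def profiles_from_layers(layers: dict[int, np.ndarray], days, reference_day=3, strains=None):
    """Build an AgingProfileMatrix directly from per-replicate arrays."""
    from chronoscreen.tagio import AgingProfileMatrix, _average_layers

    first = next(iter(layers.values()))
    n = np.asarray(first).shape[0]
    idx = pd.Index(strains if strains is not None else [f"s{i:04d}" for i in range(n)],
                   name="strain_id")
    reps = {
        r: pd.DataFrame(np.asarray(mat, dtype=float), index=idx, columns=list(days))
        for r, mat in layers.items()
    }
    return AgingProfileMatrix(
        replicates=reps, averaged=_average_layers(reps), reference_day=reference_day
    )
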