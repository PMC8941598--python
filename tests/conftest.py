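"""Shared fixtures: small simulated studies and hand-built feature tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from zftox.containers import FeatureTable
from zftox.synthetic import SimConfig, make_plate_layout, simulate_feature_table


def small_sim_config(seed: int = 11, **overrides) -> SimConfig:
    """Reduced feature population (full plate design) for fast tests."""
    defaults = dict(
        seed=seed,
        n_null=30,
        n_effect_per_shape=2,
        n_qc_absent=4,
        n_blank_contaminant=4,
        n_insource=2,
        n_biotp=12,
        n_lipid_null=10,
        n_lipid_effect=3,
        n_lipid_low_ratio=4,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """Noisy small study: (table, truth, config)."""
    cfg = small_sim_config(seed=11)
    layout = make_plate_layout(cfg.n_doses, cfg.n_per_group, cfg.n_neg, cfg.n_pos,
                               cfg.nominal_doses)
    table, truth = simulate_feature_table(layout, cfg)
    return table, truth, cfg


@pytest.fixture(scope="session")
def noiseless_study():
    """Noise-free, drift-free small study for exact-survivor checks."""
    cfg = small_sim_config(seed=12, noise_cv=0.0, loading_cv=0.0, drift="none")
    layout = make_plate_layout(cfg.n_doses, cfg.n_per_group, cfg.n_neg, cfg.n_pos,
                               cfg.nominal_doses)
    table, truth = simulate_feature_table(layout, cfg)
    return table, truth, cfg


def build_table(
    intensities: dict[str, list[float]],
    sample_roles: list[str],
    mz: dict[str, float] | None = None,
    rt: dict[str, float] | None = None,
    assay: str = "nontarget",
    injection_index: list[int] | None = None,
) -> FeatureTable:
    """Hand-built FeatureTable: intensities maps feature_id -> per-sample values."""
    n = len(sample_roles)
    sample_ids = [f"s{i}" for i in range(n)]
    samples = pd.DataFrame(
        {
            "well": [""] * n,
            "role": sample_roles,
            "group": sample_roles,
            "dose_group": [-1] * n,
            "nominal_dose": [np.nan] * n,
            "injection_index": injection_index or list(range(1, n + 1)),
            "dead_120hpf": [pd.NA] * n,
            "edema": [pd.NA] * n,
            "hatched_48hpf": [pd.NA] * n,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    fids = list(intensities)
    feats = pd.DataFrame(
        {
            "mz": [(mz or {}).get(f, 100.0 + i) for i, f in enumerate(fids)],
            "rt_seconds": [(rt or {}).get(f, 100.0 + 10 * i) for i, f in enumerate(fids)],
            "assay": [assay] * len(fids),
        },
        index=pd.Index(fids, name="feature_id"),
    )
    inten = pd.DataFrame(
        np.array([intensities[f] for f in fids], dtype=float),
        index=feats.index,
        columns=samples.index,
    )
    return FeatureTable(inten, feats, samples)
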