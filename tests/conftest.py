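"""Shared fixtures: small synthetic batteries and fast pipeline settings."""

from __future__ import annotations

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.scales import ItemDefinition, ScaleBattery


def make_ordinal_battery(p: int, levels=(1, 2, 3, 4)) -> ScaleBattery:
    """All-ordinal battery of p items (generic depression-like items)."""
    items = tuple(
        ItemDefinition(f"I{i + 1}", f"item {i + 1}", tuple(levels), "DEP")
        for i in range(p)
    )
    lo, hi = sum(l[0] for l in [levels] * p), sum(l[-1] for l in [levels] * p)
    return ScaleBattery(items=items, dep_cutoff=(lo + hi) // 2)


def uniform_design(p: int, n: int, levels=(1, 2, 3, 4)) -> sn.SyntheticDesign:
    probs = [np.full(len(levels), 1.0 / len(levels))] * p
    return sn.SyntheticDesign(
        battery=make_ordinal_battery(p, levels), category_probs=probs, n=n
    )


@pytest.fixture(scope="session")
def fast_config() -> sn.PipelineConfig:
    """Cheap pipeline settings for resampling-heavy tests."""
    return sn.PipelineConfig(correlation="pearson", path_count=20, path_ratio=0.05)


@pytest.fixture(scope="session")
def study_sample():
    """One firefighter-like sample at survey scale, reused across tests."""
    truth, design = sn.firefighter_like_design(n=10000, seed=42)
    rm = sn.sample_responses(truth, design, seed=1)
    return truth, design, rm


def net_from_weights(W, labels=None) -> sn.NetworkModel:
    return sn.NetworkModel.from_weights(np.asarray(W, dtype=float), node_labels=labels)
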