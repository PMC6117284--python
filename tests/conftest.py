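import numpy as np
import pandas as pd
import pytest

from riverunmix import SourceGroup, SourceSet, TracerTable, WatershedGraph
from riverunmix.io_report import TEST_PROFILE, McmcSettings
from riverunmix.mixing_model import PosteriorDraws


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def test_mcmc():
    """Short, deterministic MCMC profile for unit tests."""
    def _make(seed=0, **overrides):
        opts = {**TEST_PROFILE, **overrides}
        return McmcSettings(**opts, seed=seed)
    return _make


def make_tracer_table(node, values, factor=None, panel=None):
    values = np.atleast_2d(np.asarray(values, float))
    panel = panel or [f"tr{j + 1}" for j in range(values.shape[1])]
    idx = [f"s{i}" for i in range(values.shape[0])]
    data = pd.DataFrame(values, columns=panel, index=idx)
    fac = pd.Series(factor if factor is not None else ["all"] * len(idx), index=idx)
    return TracerTable(node, data=data, factor=fac)


def make_source_set(node, group_samples, class_map=None):
    """group_samples: {name: 2-D array samples x tracers}."""
    groups = {}
    for name, arr in group_samples.items():
        arr = np.atleast_2d(np.asarray(arr, float))
        panel = [f"tr{j + 1}" for j in range(arr.shape[1])]
        groups[name] = SourceGroup(name, raw=pd.DataFrame(arr, columns=panel))
    return SourceSet(node, groups=groups, class_map=dict(class_map or {}))


@pytest.fixture
def confluence_graph():
    """Two tributaries meeting at a confluence node with no local sources."""
    return WatershedGraph(
        nodes=["M1", "M2", "M3"],
        edges=[("M1", "M3"), ("M2", "M3")],
        local_sources={
            "M1": {"BLF": "BLF", "MF": "MF", "LL": "LL", "UP": "UP"},
            "M2": {"MF": "MF", "LL": "LL", "UP": "UP"},
            "M3": {},
        },
        classes=["BLF", "MF", "LL", "UP"],
        areas={"M1": 14.4, "M2": 1.00, "M3": 15.4},
    )


@pytest.fixture
def confluence_point_mass(confluence_graph):
    """Degenerate node posteriors at early-wet-season mean proportions."""
    posts = {
        "M1": PosteriorDraws.point_mass(
            "M1", {"EW": {"BLF": 0.70, "MF": 0.19, "LL": 0.03, "UP": 0.08}}
        ),
        "M2": PosteriorDraws.point_mass(
            "M2", {"EW": {"MF": 0.75, "LL": 0.12, "UP": 0.13}}
        ),
        "M3": PosteriorDraws.point_mass("M3", {"EW": {"M1": 0.74, "M2": 0.26}}),
    }
    return posts
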