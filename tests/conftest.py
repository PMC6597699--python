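"""Shared fixtures: phantom pipelines are expensive (~20 s each), so results
are computed once per session and shared across tests."""

from dataclasses import dataclass

import numpy as np
import pytest

import htchannel as hc
from htchannel.phantoms import ChannelSpec, PhantomSpec, make_ventricle_phantom, preset_spec


@dataclass
class CaseArtifacts:
    vol: object
    gt: object
    viable: object
    mesh: object
    graph: object
    candidates: list


def _run_case(spec, seed=0):
    vol, gt = make_ventricle_phantom(spec)
    viable = hc.extract_viable(vol)
    mesh = hc.clean_mesh(hc.mask_to_mesh(viable), 10_000, 0.5, 100)
    graph = hc.skeletonize(mesh, seed=seed)
    candidates = hc.detect_ht_channels(viable, graph)
    return CaseArtifacts(vol, gt, viable, mesh, graph, candidates)


@pytest.fixture(scope="session")
def phantom_case():
    """phantom_case(name_or_spec, seed=0) -> CaseArtifacts, cached."""
    cache = {}

    def get(name_or_spec, seed=0):
        spec = preset_spec(name_or_spec) if isinstance(name_or_spec, str) else name_or_spec
        key = (repr(spec), seed)
        if key not in cache:
            cache[key] = _run_case(spec, seed)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def length_spec():
    """PhantomSpec with a designed straight channel of the given length."""

    def make(length_mm):
        return PhantomSpec(channel=ChannelSpec(radius_mm=3.0, length_mm=length_mm))

    return make


@pytest.fixture(scope="session")
def skeleton_of():
    """skeleton_of(mask) -> SkeletonGraph via the standard cleanup, cached."""
    cache = {}

    def get(key, mask, target=4000):
        if key not in cache:
            mesh = hc.clean_mesh(hc.mask_to_mesh(mask), target, 0.5, 100)
            cache[key] = hc.skeletonize(mesh, seed=0)
        return cache[key]

    return get


@pytest.fixture
def two_blob_mask():
    m = hc.BinaryMask(np.zeros((60, 24, 24), dtype=bool), (1.0, 1.0, 1.0))
    m.grid[4:24, 6:18, 6:18] = True
    m.grid[34:54, 6:18, 6:18] = True
    return m
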