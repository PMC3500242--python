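import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

import srna_census as sc

#: Seed for the full-scale synthetic study used by the end-to-end tests.
STUDY_SEED = 11


def _run(profile, bundle):
    reads, manifest = sc.simulate_library(profile, bundle)
    result = sc.run_pipeline(
        reads,
        name=profile.profile_kind,
        preprocess_cfg=sc.PreprocessConfig(adapter3p=profile.adapter3p),
        decoys=bundle.decoys,
        mirna_refs=bundle.mirna,
        aphid_specific_refs=bundle.aphid_specific,
        plant_refs=bundle.plant,
        ests=bundle.ests,
        endosymbiont_ref=bundle.endosymbiont,
        contigs=bundle.contigs,
        repeat_refs=bundle.repeats,
    )
    return result, manifest


@pytest.fixture(scope="session")
def study_pair():
    """Full-scale (200k reads each) susceptible/resistant pair plus pipelines."""
    base = sc.SimulationProfile(seed=STUDY_SEED)
    bundle, _ = sc.make_reference_bundle(base)
    out = {"bundle": bundle}
    for kind in ("susceptible", "resistant"):
        prof = sc.SimulationProfile(seed=STUDY_SEED, profile_kind=kind)
        result, manifest = _run(prof, bundle)
        out[kind] = {"profile": prof, "result": result, "manifest": manifest}
    return out


@pytest.fixture(scope="session")
def small_pair():
    """Scaled-down pair (20k reads) for quick invariant checks."""
    base = sc.SimulationProfile(seed=5, library_size=20_000)
    bundle, _ = sc.make_reference_bundle(base)
    out = {"bundle": bundle}
    for kind in ("susceptible", "resistant"):
        prof = sc.SimulationProfile(seed=5, profile_kind=kind, library_size=20_000)
        result, manifest = _run(prof, bundle)
        out[kind] = {"profile": prof, "result": result, "manifest": manifest}
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
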