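"""Shared fixtures: synthetic universes, scans, and GC cluster models.

The heavier objects are session-scoped so the calibration, power and GC
matching checks can share one universe and one set of pre-scanned genomic
sites, mirroring how the pipeline caches genomic scans.
"""

import numpy as np
import pytest

import localmotif as lm
from localmotif import synthdata as sd
from localmotif import null_model as nm

UNIVERSE_SEED = 20101
POWER_SEED = 30201


@pytest.fixture(scope="session")
def universe():
    """2000-promoter universe with two GC classes (CpG-like and GC-poor)."""
    return sd.generate_universe(2000, sd.DEFAULT_CLASSES, seed=UNIVERSE_SEED)


@pytest.fixture(scope="session")
def universe_labels(universe):
    return np.array([m.tags["class"] == "gc_high" for m in universe])


@pytest.fixture(scope="session")
def gc2(universe):
    return nm.fit_gc_clusters(universe, 2, seed=7)


@pytest.fixture(scope="session")
def common_sites(universe):
    return lm.scan(universe, sd.common_motif())


@pytest.fixture(scope="session")
def sharp_sites(universe):
    return lm.scan(universe, sd.implant_motif())


@pytest.fixture(scope="session")
def power_universe():
    """5000-promoter universe used by the implant-recovery simulations."""
    return sd.generate_universe(5000, sd.DEFAULT_CLASSES, seed=POWER_SEED)


@pytest.fixture(scope="session")
def power_sharp_sites(power_universe):
    return lm.scan(power_universe, sd.implant_motif())


@pytest.fixture(scope="session")
def power_gc2(power_universe):
    return nm.fit_gc_clusters(power_universe, 2, seed=11)


@pytest.fixture
def small_set():
    """Deterministic 5-promoter set over the default span, no motif signal."""
    rng = np.random.default_rng(5150)
    members = [
        lm.PromoterSequence(
            f"s{i}", "".join(rng.choice(list("ACGT"), size=5000)), -3000, 2000
        )
        for i in range(5)
    ]
    return lm.PromoterSet(members, label="small")
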