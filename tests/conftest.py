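import numpy as np
import pytest

from founderage import FounderSimConfig, MarkerDef, MarkerKind, Side

# Published per-marker generation estimates (integers as printed) for the two
# datable founder mutations, keyed by estimator.  The distances (Mb from the
# mutation) are the published ones; markers excluded for an estimator are
# simply absent from its dict.
TABLE2_DISTANCES_C2278 = {
    "D14S1043": 3.34,
    "D14S72": 3.32,
    "D14S742": 2.52,
    "D14S275": 1.98,
    "D14S1042": 4.54,
    "D14S1060": 8.7,
}

TABLE2_C2278 = {
    "bergman": {"D14S1043": 40, "D14S72": 65, "D14S742": 29, "D14S275": 20, "D14S1042": 19},
    "risch": {"D14S72": 33, "D14S742": 29, "D14S275": 20, "D14S1042": 13, "D14S1060": 7},
    "labuda": {"D14S72": 52, "D14S742": 37, "D14S275": 31, "D14S1042": 21, "D14S1060": 11},
}

TABLE2_DELACACA = {
    "bergman": {"D14S72": 18, "D14S742": 24, "D14S275": 23, "D14S1042": 20, "D14S1060": 10},
    "risch": {"D14S72": 26, "D14S742": 24, "D14S275": 23, "D14S1042": 20},
    "labuda": {"D14S72": 45, "D14S742": 34, "D14S275": 35, "D14S1042": 29},
}


@pytest.fixture
def table2_c2278():
    return TABLE2_C2278


@pytest.fixture
def table2_delacaca():
    return TABLE2_DELACACA


@pytest.fixture
def table2_distances():
    return TABLE2_DISTANCES_C2278


def make_markers(positions):
    """Markers from signed Mb positions (negative = proximal side)."""
    out = []
    for i, pos in enumerate(positions):
        side = Side.PROXIMAL if pos < 0 else Side.DISTAL
        out.append(
            MarkerDef(
                name=f"m{i + 1}",
                kind=MarkerKind.MICROSATELLITE,
                distance_mb=abs(pos),
                side=side,
            )
        )
    return out


@pytest.fixture
def five_markers():
    # m1 m2 proximal, m3 m4 m5 distal; locus between m2 and m3
    return make_markers([-2.0, -1.0, 1.0, 2.0, 3.0])


@pytest.fixture
def rng():
    return np.random.default_rng(1)


@pytest.fixture
def small_sim_config():
    return FounderSimConfig(true_age=30, n_disease=20, n_control=100, seed=1)
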