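import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from otsp import BiasModel, PrimerPanel, make_st_design

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_panel() -> PrimerPanel:
    return PrimerPanel(("V1", "V2", "V3"), ("J1", "J2"))


@pytest.fixture(scope="session")
def small_design(small_panel):
    return make_st_design(small_panel, seed=11)


@pytest.fixture(scope="session")
def default_panel() -> PrimerPanel:
    return PrimerPanel.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def small_bias_model(small_panel) -> BiasModel:
    return BiasModel.separable(small_panel, seed=7, mean_level=400.0,
                               log_spread=2.0, dispersion=0.1)


def levenshtein(a: str, b: str) -> int:
    """Plain quadratic edit-distance DP (test oracle, kept independent)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def brute_force_find(read: str, barcode: str, max_dist: int):
    """Oracle: min edit distance over every window, leftmost tie-break."""
    best = (max_dist + 1, -1)
    for s in range(len(read)):
        d_s = min(levenshtein(barcode, read[s:e])
                  for e in range(s, len(read) + 1))
        if d_s < best[0]:
            best = (d_s, s)
    if best[1] < 0:
        return None
    return best[1], best[0]
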