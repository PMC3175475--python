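import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from clinezone import SimConfig, project_positions, simulate_zone
from clinezone.transect import cline_observations

NUCLEAR = ("CXCR4", "SLC8A3", "RAG1")
ALL_LOCI = ("ND4",) + NUCLEAR


def clean_config(seed: int = 0, n: int = 300, width: float = 0.75, **kw) -> SimConfig:
    """Zone with no mixing/asymmetry: pure HWE + LE tanh clines, shared (c=0, w)."""
    defaults = dict(
        n=n,
        seed=seed,
        mix_amplitude=0.0,
        mt_asymmetry=None,
        center_per_locus={name: 0.0 for name in ALL_LOCI},
        width_per_locus={name: width for name in ALL_LOCI},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def generator_frame_obs(ds, cfg, loci="all"):
    """Observations projected in the generator's own frame (position == axis coord)."""
    proj = project_positions(ds, cfg.heading_true, origin=(cfg.origin_lat, cfg.origin_lon))
    return cline_observations(proj, loci)


@pytest.fixture(scope="session")
def default_zone():
    """One realization of the full default study conditions."""
    cfg = SimConfig(seed=11)
    return cfg, simulate_zone(cfg)


@pytest.fixture(scope="session")
def clean_zone():
    """One clean (HWE/LE, symmetric) realization for recovery checks."""
    cfg = clean_config(seed=1)
    return cfg, simulate_zone(cfg)
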