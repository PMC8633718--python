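import numpy as np
import pytest

import pullpmf as pp


@pytest.fixture(scope="session")
def protocol():
    """The reference pulling protocol: k = 12 kcal/mol/Å², T = 310 K."""
    return pp.default_protocol(velocity=0.00625)


@pytest.fixture(scope="session")
def pulling_run():
    """The reference 75-replica Langevin pulling run (seed 0).

    Shared across tests; treat as read-only.
    """
    cfg = pp.default_pulling_config(seed=0)
    traces = pp.simulate_pulling(cfg)
    works = pp.align_works(traces, cfg.protocol, grid_spacing=0.1)
    return cfg, traces, works


def two_replica_workset(temperature=310.0):
    """WorkSet with final works {0, 1.2} kcal/mol on a 2-point grid."""
    proto = pp.PullingProtocol(
        spring_constant=12.0, velocity=0.00625, temperature=temperature
    )
    return pp.WorkSet(
        grid=np.array([0.0, 1.0]),
        works=np.array([[0.0, 0.0], [0.0, 1.2]]),
        protocol=proto,
        replica_ids=["a", "b"],
    )


def workset_from_samples(samples, temperature=310.0):
    """WorkSet whose second grid point carries the given final works."""
    samples = np.asarray(samples, dtype=float)
    proto = pp.PullingProtocol(
        spring_constant=12.0, velocity=0.00625, temperature=temperature
    )
    works = np.column_stack([np.zeros_like(samples), samples])
    return pp.WorkSet(
        grid=np.array([0.0, 1.0]),
        works=works,
        protocol=proto,
        replica_ids=[f"r{i}" for i in range(len(samples))],
    )
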