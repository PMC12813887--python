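import numpy as np
import pytest

from cardyn.model import AtomRecord, DomainMap, Frame, Trajectory
from cardyn.synthetic import build_receptor_model, domain_map_for, preset_config, simulate


def ca_atom(serial: int, residue_id: int, position, chain: str = "A",
            name: str = "CA", element: str = "C", residue_name: str = "ALA",
            is_hetero: bool = False) -> AtomRecord:
    return AtomRecord(serial=serial, name=name, element=element,
                      residue_name=residue_name, residue_id=residue_id,
                      chain_id=chain, position=np.asarray(position, dtype=float),
                      is_hetero=is_hetero)


def ca_chain_frame(n_res: int, spacing: float = 3.8) -> Frame:
    """A straight CA-only chain along x, one residue per atom."""
    topo = [ca_atom(i + 1, i + 1, (i * spacing, 0.0, 0.0)) for i in range(n_res)]
    return Frame(topo, np.array([[i * spacing, 0.0, 0.0] for i in range(n_res)]))


def trajectory_from_coords(topology, coords_per_frame) -> Trajectory:
    return Trajectory(topology, np.asarray(coords_per_frame, dtype=float))


@pytest.fixture(scope="session")
def receptor_domain_map() -> DomainMap:
    return DomainMap(domains={
        "AB": [("A", 1, 250)], "HI": [("A", 251, 295)], "TM": [("A", 296, 320)],
        "CS": [("A", 321, 362)], "SI": [("A", 363, 475)],
    })


@pytest.fixture(scope="session")
def apo_run():
    """One full-length apo preset simulation, shared across the suite."""
    cfg = preset_config("apo", seed=11)
    topo = build_receptor_model(cfg)
    traj = simulate(topo, cfg)
    return cfg, topo, traj, domain_map_for(topo, cfg)


@pytest.fixture(scope="session")
def holo_run():
    cfg = preset_config("holo", seed=11)
    topo = build_receptor_model(cfg)
    traj = simulate(topo, cfg)
    return cfg, topo, traj, domain_map_for(topo, cfg)


@pytest.fixture(scope="session")
def short_apo_run():
    """A fast, short apo simulation for pipeline/CLI tests."""
    cfg = preset_config("apo", seed=5, n_steps=6000, stride=100)
    topo = build_receptor_model(cfg)
    traj = simulate(topo, cfg)
    return cfg, topo, traj, domain_map_for(topo, cfg)
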