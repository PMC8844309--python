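import numpy as np
import pytest

import porepass as pp

Z_AXIS = pp.ChannelAxis(origin=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]))


@pytest.fixture(scope="session")
def z_axis():
    return Z_AXIS


@pytest.fixture(scope="session")
def cylinder_toy():
    """Straight cylinder, wall radius 6 Å, atom radius 1.7 Å → clearance 4.3 Å."""
    spec = pp.ToyChannelSpec(
        ring_stations=[-10.0, 10.0], ring_radii=[6.0, 6.0], atoms_per_ring=48
    )
    return pp.make_toy_channel(spec)


@pytest.fixture(scope="session")
def hourglass_toy():
    """Hourglass 8 → 4 → 8 Å wall radius; waist clearance 4 − 1.7 = 2.3 Å."""
    spec = pp.ToyChannelSpec(
        ring_stations=[-10.0, 0.0, 10.0], ring_radii=[8.0, 4.0, 8.0], atoms_per_ring=48
    )
    return pp.make_toy_channel(spec)


@pytest.fixture(scope="session")
def cage_geometry():
    """Compartment geometry with one side-portal annulus."""
    return pp.ChannelGeometry(
        cylinder_radius=8.0,
        z_extracellular=20.0,
        z_pore_top=20.0,
        z_pore_bottom=0.0,
        z_cage_bottom=-30.0,
        portals=[pp.PortalAnnulus(r_range=(8.0, 14.0), z_range=(-25.0, -15.0))],
    )


def scripted_trajectory(path_labels, geom, axis=Z_AXIS, dt=0.1):
    """Build a single-ion trajectory whose frames sit at representative
    points of the requested compartments (independent of the labeller)."""
    rep = {
        "BULK_CYT": np.array([20.0, 0.0, -40.0]),
        "PORTAL": np.array([10.0, 0.0, -20.0]),
        "CAGE": np.array([0.0, 0.0, -10.0]),
        "PORE": np.array([0.0, 0.0, 10.0]),
        "BULK_EXT": np.array([0.0, 0.0, 25.0]),
    }
    pos = np.array([[rep[name]] for name in path_labels])
    times = np.arange(len(path_labels)) * dt
    return pp.IonTrajectory(times=times, ion_positions=pos, axis=axis, ion_charge=-1.0)
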