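"""Shared fixtures.

The expensive searches (exhaustive enumeration of the 27-well chain and the
free-guest search) are session-scoped so the example-level tests and the
acceptance tests reuse one computation.
"""

import numpy as np
import pytest

import miningminima as mm


@pytest.fixture(scope="session")
def chain1():
    """4-atom chain with one 3-fold torsion: exactly 3 wells."""
    return mm.build_chain(1)


@pytest.fixture(scope="session")
def chain3():
    """6-atom chain with three 3-fold torsions: exactly 27 wells."""
    return mm.build_chain(3)


@pytest.fixture(scope="session")
def chain3_search(chain3):
    """Full search on the 3-torsion chain: (pool, history)."""
    return mm.run_search(chain3)


@pytest.fixture(scope="session")
def chain3_grid_oracle(chain3):
    """Grid-seeded enumeration oracle (12 points per torsion)."""
    return mm.enumerate_minima_grid(chain3, grid_points=12)


@pytest.fixture(scope="session")
def chain1_search(chain1):
    return mm.run_search(chain1)


@pytest.fixture(scope="session")
def host_guest():
    return mm.build_host_guest()


@pytest.fixture(scope="session")
def guest_search(host_guest):
    _, guest, _ = host_guest
    return mm.run_search(guest)


@pytest.fixture(scope="session")
def thermo_config():
    return mm.ThermoConfig()


@pytest.fixture(scope="session")
def three_state_trajectory():
    """10^4-frame synthetic dihedral series with 3 states (0.5/0.3/0.2)."""
    spec = mm.SyntheticTrajectorySpec(
        dihedrals={"chi": [(-60.0, 25.0, 0.5), (60.0, 25.0, 0.3), (-180.0, 25.0, 0.2)]},
        n_frames=10_000, seed=2024)
    return spec, mm.generate_dihedral_trajectory(spec)


def torsional_quadrature_g(system, pool, config, n_grid=None):
    """Dense-quadrature oracle for G on systems with 1 or 2 free torsions.

    Bond/angle factors are taken from the harmonic block of the best
    conformer (identical treatment on both sides); the torsional domain is
    integrated on a dense grid with bonds and angles fixed at their
    minimized values.
    """
    import itertools

    best = pool[0]
    st = mm.cartesian_to_bat(system, best.coords,
                             zmatrix=mm.reference_zmatrix(system))
    q0 = st.q
    ti = st.torsion_indices
    ba = best.hessian.bond_angle_indices
    blk = best.hessian.full[np.ix_(ba, ba)]
    rt = config.rt
    log_ba = 0.5 * np.sum(np.log(2 * np.pi * rt / np.linalg.eigvalsh(blk)))
    if n_grid is None:
        n_grid = 2001 if len(ti) == 1 else 241
    axes = [np.linspace(-np.pi, np.pi, n_grid) for _ in ti]
    if len(ti) == 1:
        es = np.empty(n_grid)
        for a, p in enumerate(axes[0]):
            q = q0.copy()
            q[ti[0]] = p
            es[a] = mm.potential_energy(system, mm.bat_to_cartesian(st.with_q(q)))
        z_t = np.trapezoid(np.exp(-es / rt), axes[0])
    elif len(ti) == 2:
        es = np.empty((n_grid, n_grid))
        for a, p in enumerate(axes[0]):
            for b, r in enumerate(axes[1]):
                q = q0.copy()
                q[ti[0]] = p
                q[ti[1]] = r
                es[a, b] = mm.potential_energy(system, mm.bat_to_cartesian(st.with_q(q)))
        z_t = np.trapezoid(np.trapezoid(np.exp(-es / rt), axes[1], axis=1), axes[0])
    else:
        raise ValueError("oracle supports 1 or 2 torsions")
    return float(-rt * (config.external_log_factor + log_ba + np.log(z_t)))
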