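import numpy as np
import pytest

from cbench.protocol import two_shell_protocol, volume_order
from cbench.substrate import Substrate, build_substrate
from cbench.walk import (
    WalkConfig,
    _memberships,
    _prep_tables,
    _pulse_weights,
    simulate_walk,
)


@pytest.fixture(scope="module")
def walk_protocol():
    return two_shell_protocol(n_directions=12, n_b0=2)


class TestFreeDiffusion:
    def test_empty_box_matches_exponential(self, walk_protocol):
        """Unrestricted spins attenuate as exp(-bD), within 3 Monte-Carlo
        standard errors on every volume."""
        res = simulate_walk(
            Substrate(), WalkConfig(n_spins=8000, rng_seed=1), walk_protocol
        )
        order = volume_order(walk_protocol)
        for k, shell in enumerate(walk_protocol.shells):
            sl = order[f"shell{k}"]
            expect = np.exp(-shell.b_value * 1.0)
            resid = np.abs(res.signal.values[sl] - expect)
            assert np.all(resid <= 3 * res.std_error[sl] + 1e-12)

    def test_b0_volumes_exactly_one(self, walk_protocol):
        res = simulate_walk(
            Substrate(), WalkConfig(n_spins=500, rng_seed=2), walk_protocol
        )
        assert np.all(res.signal.values[:2] == 1.0)

    def test_msd_calibration(self):
        """Mean squared displacement per axis = 2 D t within 1% at
        t = 10 ms (free diffusion)."""
        prot = two_shell_protocol(n_directions=12, n_b0=1,
                                  delta_small=5.0, delta_big=5.0)
        cfg = WalkConfig(n_spins=100_000, rng_seed=3)
        res = simulate_walk(Substrate(), cfg, prot)
        t = len(_pulse_weights(prot, cfg.dt)) * cfg.dt
        msd = (res.displacements**2).mean(axis=0)
        assert np.allclose(msd, 2.0 * cfg.diffusivity * t, rtol=0.01)


class TestMembranes:
    def test_no_membrane_crossings(self, walk_protocol):
        """Spin compartments are conserved: nobody ends up on the wrong
        side of a cylinder or sphere surface (simulate_walk asserts this
        internally and would raise)."""
        sub = build_substrate(24, 12, rng_seed=5)
        res = simulate_walk(sub, WalkConfig(n_spins=3000, rng_seed=6),
                            walk_protocol)
        assert np.all(np.isfinite(res.displacements))
        tables = _prep_tables(sub)
        c0, s0 = _memberships(sub, res.start_positions, tables)
        c1, s1 = _memberships(sub, res.start_positions + res.displacements,
                              tables)
        assert np.array_equal(c0, c1)
        assert np.array_equal(s0, s1)

    def test_restricted_spins_displace_less(self, walk_protocol):
        sub = build_substrate(88, 0, rng_seed=7)
        res = simulate_walk(sub, WalkConfig(n_spins=4000, rng_seed=8),
                            walk_protocol)
        tables = _prep_tables(sub)
        cyl, _ = _memberships(sub, res.start_positions, tables)
        inside = cyl >= 0
        assert inside.sum() > 50  # ~4% of spins start intra-cylinder
        trans = res.displacements[:, :2]
        r2 = np.einsum("ij,ij->i", trans, trans)
        # cylinder walls cap transverse motion well below free diffusion
        assert r2[inside].mean() < 0.5 * r2[~inside].mean()

    def test_seed_in_spheres_flag(self, walk_protocol):
        sub = Substrate(
            box=(30.0, 30.0, 30.0),
            sph_center=np.array([[15.0, 15.0, 15.0]]),
            sph_radius=np.array([10.0]),
        )
        res = simulate_walk(
            sub, WalkConfig(n_spins=2000, rng_seed=9, seed_in_spheres=False),
            walk_protocol,
        )
        tables = _prep_tables(sub)
        _, sph = _memberships(sub, res.start_positions, tables)
        assert np.all(sph == -1)  # ~15% of the box is sphere, all excluded
        res2 = simulate_walk(
            sub, WalkConfig(n_spins=2000, rng_seed=9, seed_in_spheres=True),
            walk_protocol,
        )
        _, sph2 = _memberships(sub, res2.start_positions, tables)
        assert (sph2 >= 0).sum() > 100

    def test_step_length_warning(self, walk_protocol):
        sub = Substrate(
            box=(30.0, 30.0, 30.0),
            sph_center=np.array([[15.0, 15.0, 15.0]]),
            sph_radius=np.array([0.5]),
        )
        with pytest.warns(UserWarning, match="step length"):
            simulate_walk(sub, WalkConfig(n_spins=10, rng_seed=0), walk_protocol)


class TestSoma:
    def test_adding_spheres_changes_mean_more_than_anisotropy(self, walk_protocol):
        """Growing the restricted isotropic pool moves the b=7 mean summary
        measure more than the directional (l2) one."""
        from cbench.summary import summary_vectors

        base = build_substrate(48, 0, rng_seed=11)
        plus = build_substrate(48, 57, rng_seed=11)
        cfg = WalkConfig(n_spins=8000, rng_seed=12)
        sv0 = summary_vectors(
            simulate_walk(base, cfg, walk_protocol).signal.values, walk_protocol
        )
        sv1 = summary_vectors(
            simulate_walk(plus, cfg, walk_protocol).signal.values, walk_protocol
        )
        d = np.abs(sv1 - sv0)
        assert d[0] > d[1]  # b7: mean moves more than l2
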