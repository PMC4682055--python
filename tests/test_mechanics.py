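"""Energies, chiral tension, forces, noise and the overdamped update."""

import numpy as np
import pytest

from chiralsheet.mesh import (
    APFrame,
    TissueMesh,
    build_hexagonal_sheet,
    cell_area,
    cell_perimeter,
    junction_angles,
)
from chiralsheet.mechanics import (
    ChiralityParams,
    ConfinementSpec,
    MechanicalParams,
    NoiseParams,
    NumericalInstabilityError,
    chiral_line_tension,
    compute_forces,
    confinement_force,
    sample_tension_noise,
    step,
    total_energy,
)
from chiralsheet.mesh import A7_BORDER


def finite_difference_forces(mesh, mech, chir, frame, offsets=None, h=1e-6):
    fd = np.zeros_like(mesh.positions)
    for i in range(mesh.n_vertices):
        for k in range(2):
            orig = mesh.positions[i, k]
            mesh.positions[i, k] = orig + h
            ep = total_energy(mesh, mech, chir, frame, offsets)
            mesh.positions[i, k] = orig - h
            em = total_energy(mesh, mech, chir, frame, offsets)
            mesh.positions[i, k] = orig
            fd[i, k] = -(ep - em) / (2 * h)
    return fd


class TestChiralLineTension:
    def test_maximal_at_preferred_angle(self):
        assert chiral_line_tension(45.0, ChiralityParams(), 1.0) == pytest.approx(1.0)

    def test_vanishes_at_mirror_angle(self):
        assert chiral_line_tension(-45.0, ChiralityParams(), 1.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_half_at_zero(self):
        assert chiral_line_tension(0.0, ChiralityParams(), 1.0) == pytest.approx(0.5)

    def test_disabled_returns_symmetric_control(self):
        params = ChiralityParams(enabled=False)
        theta = np.linspace(-89, 90, 13)
        assert np.allclose(chiral_line_tension(theta, params, 0.12), 0.12)

    def test_per_junction_preferred_angles(self):
        params = ChiralityParams()
        out = chiral_line_tension(
            np.array([30.0, 60.0]), params, 1.0, theta_pref_deg=np.array([30.0, 60.0])
        )
        assert np.allclose(out, 1.0)


class TestTotalEnergy:
    def test_unit_square_closed_form(self, unit_square_mesh, down_frame):
        # A = A0 = 1 kills the area term; Gamma = 0 kills the perimeter
        # term; uniform tension 0.1 on perimeter 4 leaves E = 0.4.
        mech = MechanicalParams(K=1.0, A0=1.0, Gamma=0.0, gamma0=0.1)
        chir = ChiralityParams(enabled=False)
        E = total_energy(unit_square_mesh, mech, chir, down_frame)
        assert E == pytest.approx(0.4)

    def test_zero_energy_at_rest(self, unit_square_mesh, down_frame):
        mech = MechanicalParams(K=2.0, A0=1.0, Gamma=0.0, gamma0=0.0)
        E = total_energy(unit_square_mesh, mech, ChiralityParams(), down_frame)
        assert E == pytest.approx(0.0, abs=1e-12)

    def test_matches_term_by_term_recomputation(self, jittered_sheet, down_frame):
        mech = MechanicalParams()
        chir = ChiralityParams()
        theta = junction_angles(jittered_sheet, down_frame)
        expected = 0.0
        for f in range(jittered_sheet.n_faces):
            A = cell_area(jittered_sheet, f)
            P = cell_perimeter(jittered_sheet, f)
            expected += 0.5 * mech.K * (A - mech.A0) ** 2 + 0.5 * mech.Gamma * P**2
        lengths = jittered_sheet.junction_lengths()
        for j in range(jittered_sheet.n_junctions):
            gamma = mech.gamma0 * 0.5 * (1 + np.cos(2 * np.radians(theta[j] - 45.0)))
            expected += gamma * lengths[j]
        E = total_energy(jittered_sheet, mech, chir, down_frame)
        assert E == pytest.approx(expected, rel=1e-12)


class TestForces:
    @pytest.mark.parametrize("chir", [
        ChiralityParams(enabled=False),
        ChiralityParams(enabled=True, include_angle_gradient=True),
    ], ids=["uniform-tension", "chiral-full-gradient"])
    def test_matches_energy_gradient(self, down_frame, chir):
        rng = np.random.default_rng(11)
        mech = MechanicalParams()
        for _ in range(5):
            mesh = build_hexagonal_sheet(3, 3, 0.62)
            mesh.positions += rng.normal(0, 0.05, mesh.positions.shape)
            offsets = rng.normal(0, 0.02, mesh.n_junctions)
            F = compute_forces(mesh, mech, chir, down_frame, noise_offsets=offsets)
            fd = finite_difference_forces(mesh, mech, chir, down_frame, offsets)
            scale = np.abs(fd).max()
            assert np.abs(F - fd).max() / scale < 1e-4

    def test_radial_frame_gradient(self, radial_frame):
        rng = np.random.default_rng(5)
        mesh = build_hexagonal_sheet(3, 3, 0.62)
        mesh.positions += rng.normal(0, 0.04, mesh.positions.shape) + np.array([4.0, 4.0])
        chir = ChiralityParams(include_angle_gradient=True)
        mech = MechanicalParams()
        F = compute_forces(mesh, mech, chir, radial_frame)
        fd = finite_difference_forces(mesh, mech, chir, radial_frame)
        assert np.abs(F - fd).max() / np.abs(fd).max() < 1e-4

    def test_global_force_balance(self, jittered_sheet, down_frame):
        F = compute_forces(jittered_sheet, MechanicalParams(), ChiralityParams(),
                           down_frame)
        assert np.allclose(F.sum(axis=0), 0.0, atol=1e-10)

    def test_mirror_equivariance(self, down_frame):
        rng = np.random.default_rng(2)
        mesh = build_hexagonal_sheet(3, 3, 0.62)
        mesh.positions += rng.normal(0, 0.05, mesh.positions.shape)
        mech = MechanicalParams()
        F = compute_forces(mesh, mech, ChiralityParams(theta_pref=45.0), down_frame)

        mirrored = mesh.copy()
        mirrored.positions[:, 0] *= -1
        mirrored.faces = [list(reversed(loop)) for loop in mirrored.faces]
        mirrored.invalidate()
        Fm = compute_forces(mirrored, mech, ChiralityParams(theta_pref=-45.0),
                            down_frame)
        assert np.allclose(Fm[:, 0], -F[:, 0], atol=1e-12)
        assert np.allclose(Fm[:, 1], F[:, 1], atol=1e-12)

    def test_uniform_hexagonal_sheet_interior_fixed_point(self, down_frame):
        # By threefold symmetry each interior vertex of a uniform hexagonal
        # tiling is force-free when the tension is symmetric and quiet.
        mesh = build_hexagonal_sheet(4, 4, 0.62)
        F = compute_forces(mesh, MechanicalParams(),
                           ChiralityParams(enabled=False), down_frame)
        topo = mesh.topology()
        interior = [v for v in range(mesh.n_vertices)
                    if len(topo["vertex_faces"][v]) == 3]
        assert len(interior) > 0
        # vertex coordinates are rounded to 1e-9 during construction, which
        # leaves a comparable residual in the symmetric cancellation
        assert np.abs(F[interior]).max() < 1e-8


class TestConfinement:
    def spec(self):
        return ConfinementSpec(r_inner=6.0, r_outer=10.0, k_wall=10.0,
                               radius_by_role={A7_BORDER: 10.0})

    def test_zero_on_the_circle(self):
        f = confinement_force((10.0, 0.0), A7_BORDER, self.spec())
        assert np.allclose(f, 0.0)

    def test_restoring_magnitude(self):
        f = confinement_force((10.1, 0.0), A7_BORDER, self.spec())
        assert np.linalg.norm(f) == pytest.approx(1.0, rel=1e-12)
        assert f[0] < 0  # pointing inward

    def test_matches_wall_energy_gradient(self):
        spec = self.spec()
        k, r0 = spec.k_wall, 10.0
        h = 1e-7
        for radius in (9.7, 10.0, 10.4):
            f = confinement_force((radius, 0.0), A7_BORDER, spec)
            e = lambda r: 0.5 * k * (r - r0) ** 2
            fd = -(e(radius + h) - e(radius - h)) / (2 * h)
            assert f[0] == pytest.approx(fd, abs=1e-5)


class TestTensionNoise:
    def test_zero_sigma_stays_zero(self):
        rng = np.random.default_rng(0)
        offsets = np.zeros(50)
        params = NoiseParams(sigma=0.0, tau=1.0)
        for _ in range(10):
            offsets = sample_tension_noise(offsets, params, 0.01, rng)
        assert np.all(offsets == 0.0)

    def test_deterministic_under_seed(self):
        params = NoiseParams(sigma=0.1, tau=1.0)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            offsets = np.zeros(20)
            history = []
            for _ in range(100):
                offsets = sample_tension_noise(offsets, params, 0.01, rng)
                history.append(offsets.copy())
            out.append(np.array(history))
        assert np.array_equal(out[0], out[1])

    def test_stationary_standard_deviation(self):
        # Long-run sample s.d. of the OU offsets matches sigma within 5%.
        sigma = 0.07
        params = NoiseParams(sigma=sigma, tau=1.0)
        rng = np.random.default_rng(8)
        offsets = np.zeros(300)
        samples = []
        for i in range(6000):
            offsets = sample_tension_noise(offsets, params, 0.05, rng)
            if i > 200:
                samples.append(offsets.copy())
        sd = np.std(np.concatenate(samples))
        assert abs(sd - sigma) / sigma < 0.05


class TestStep:
    def test_zero_forces_leave_positions(self, jittered_sheet):
        before = jittered_sheet.positions.copy()
        step(jittered_sheet, np.zeros_like(before), 0.01)
        assert np.array_equal(jittered_sheet.positions, before)

    def test_overdamped_displacement(self):
        mesh = TissueMesh(np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]]),
                          np.array([[0, 1], [1, 2], [2, 0]]), [[0, 1, 2]],
                          friction=np.array([2.0, 1.0, 1.0]))
        forces = np.zeros((3, 2))
        forces[0] = (2.0, 0.0)
        step(mesh, forces, 0.01)
        assert np.allclose(mesh.positions[0], (0.01, 0.0))

    def test_infinite_friction_pins_vertex(self):
        mesh = TissueMesh(np.array([[0.0, 0.0], [2.0, 0.0], [1.0, 1.0]]),
                          np.array([[0, 1], [1, 2], [2, 0]]), [[0, 1, 2]],
                          friction=np.array([np.inf, 1.0, 1.0]))
        step(mesh, np.ones((3, 2)), 0.5)
        assert np.allclose(mesh.positions[0], (0.0, 0.0))

    def test_non_finite_positions_raise(self, jittered_sheet):
        forces = np.zeros_like(jittered_sheet.positions)
        forces[0, 0] = np.nan
        with pytest.raises(NumericalInstabilityError):
            step(jittered_sheet, forces, 0.01)

    def test_noiseless_relaxation_descends_energy(self, down_frame):
        rng = np.random.default_rng(4)
        mesh = build_hexagonal_sheet(2, 2, 0.62)
        mesh.positions += rng.normal(0, 0.03, mesh.positions.shape)
        mech = MechanicalParams()
        chir = ChiralityParams(enabled=False)
        energy = total_energy(mesh, mech, chir, down_frame)
        for _ in range(300):
            F = compute_forces(mesh, mech, chir, down_frame)
            step(mesh, F, 0.002)
            e_next = total_energy(mesh, mech, chir, down_frame)
            assert e_next <= energy + 1e-12
            energy = e_next
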