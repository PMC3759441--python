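import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conforma.errors import SelectionError, ValidationError
from conforma.structure_io import Ensemble, Frame
from conforma.synthetic import (
    ModalTrajectorySpec,
    generate_modal_trajectory,
    random_orthonormal_modes,
    reference_frame,
    stream_rng,
    _default_reference,
)
from conforma.trajectory import (
    compute_pca,
    extract_window,
    kabsch_superpose,
    porcupine_arrows,
    rmsd_series,
    select_indices,
)

from conftest import make_atom, make_frame


def rotation_grid_rmsd(mobile, reference):
    """Oracle: coarse SO(3) grid search plus local polish, no Kabsch SVD."""
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    m0, r0 = mobile - cm, reference - cr

    def f(rotvec):
        r = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((m0 @ r.T - r0) ** 2, axis=1))))

    best_val, best_rv = np.inf, None
    for a in np.arange(0.0, 360.0, 24.0):
        for b in np.arange(0.0, 180.1, 24.0):
            for c in np.arange(0.0, 360.0, 24.0):
                rv = Rotation.from_euler("zyz", [a, b, c], degrees=True).as_rotvec()
                v = f(rv)
                if v < best_val:
                    best_val, best_rv = v, rv
    res = minimize(
        f, best_rv, method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-15, "maxiter": 10000},
    )
    return min(best_val, float(res.fun))


def _cloud(rng, n=5):
    return rng.uniform(-3.0, 3.0, size=(n, 3))


class TestKabsch:
    def test_identity(self):
        rng = np.random.default_rng(0)
        pts = _cloud(rng)
        result = kabsch_superpose(pts, pts)
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_recovered(self):
        rng = np.random.default_rng(1)
        ref = _cloud(rng)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        mobile = ref @ rot.T + np.array([1.0, 2.0, 3.0])
        result = kabsch_superpose(mobile, ref)
        assert result.rmsd <= 1e-9
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_rotation_is_proper_even_for_reflection_bait(self):
        rng = np.random.default_rng(2)
        ref = _cloud(rng, n=6)
        mobile = ref.copy()
        mobile[:, 0] *= -1  # mirrored cloud
        result = kabsch_superpose(mobile, ref)
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_pair_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ref = _cloud(rng)
        rot = Rotation.random(random_state=rng).as_matrix()
        mobile = ref @ rot.T + rng.uniform(-5, 5, 3) + rng.normal(0, 0.05, ref.shape)
        got = kabsch_superpose(mobile, ref).rmsd
        want = rotation_grid_rmsd(mobile, ref)
        assert got == pytest.approx(want, abs=1e-3)
        assert got <= want + 1e-9  # Kabsch is the true minimum

    def test_collinear_selection_raises(self):
        line = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(SelectionError):
            kabsch_superpose(line, line + 1.0)

    def test_too_few_atoms_raises(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(SelectionError):
            kabsch_superpose(pts, pts)

    def test_fit_never_increases_rmsd(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            a, b = _cloud(rng, 8), _cloud(rng, 8)
            raw = float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
            assert kabsch_superpose(a, b).rmsd <= raw + 1e-12


def _protein_frames(n_frames, n_res=4, displace=None):
    """Frames with N/CA/C/O per residue; optional (frame, atom, delta) displacement."""
    frames = []
    rng = np.random.default_rng(42)
    base = rng.uniform(0, 10, size=(n_res * 4, 3))
    for t in range(n_frames):
        coords = base.copy()
        if displace and displace[0] == t:
            coords[displace[1]] = coords[displace[1]] + displace[2]
        atoms = []
        serial = 1
        for r in range(n_res):
            for name, element in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
                atoms.append(
                    make_atom(serial, coords[serial - 1], name=name, element=element,
                              residue_name="GLY", residue_number=r + 1)
                )
                serial += 1
        frames.append(make_frame(atoms, index=t, time_ps=10.0 * (t + 1)))
    return frames


class TestRmsdSeries:
    def test_identical_frames_all_zero(self):
        frames = _protein_frames(4)
        ens = Ensemble(frames=frames)
        series = rmsd_series(ens, frames[0], "mainchain_CON")
        assert [r for _, r in series] == pytest.approx([0.0] * 4, abs=1e-12)

    def test_rigidly_transformed_frames_near_zero(self):
        frames = _protein_frames(3)
        rng = np.random.default_rng(5)
        moved = []
        for f in frames:
            rot = Rotation.random(random_state=rng).as_matrix()
            moved.append(f.with_coords(f.coords() @ rot.T + rng.uniform(-9, 9, 3)))
        ens = Ensemble(frames=[Frame(index=i, time_ps=f.time_ps, atoms=m.atoms)
                               for i, (f, m) in enumerate(zip(frames, moved))])
        series = rmsd_series(ens, frames[0], "mainchain_CON")
        assert max(r for _, r in series) <= 1e-9

    def test_single_displacement_closed_form(self):
        # atom 0 ("N", in the mainchain selection) moves 1 A in frame 1
        frames = _protein_frames(3, displace=(1, 0, np.array([1.0, 0.0, 0.0])))
        ens = Ensemble(frames=frames)
        series = rmsd_series(ens, frames[0], "mainchain_CON", fit=False)
        n_sel = len(select_indices(frames[0], "mainchain_CON"))
        assert n_sel == 12  # C, O, N of 4 residues; CA excluded
        assert series[1][1] == pytest.approx(np.sqrt(1.0 / n_sel), abs=1e-12)
        assert series[0][1] == 0.0
        assert series[2][1] == 0.0

    def test_mainchain_selection_excludes_calpha(self):
        frames = _protein_frames(1)
        idx = select_indices(frames[0], "mainchain_CON")
        names = {frames[0].atoms[i].name for i in idx}
        assert names == {"C", "O", "N"}

    def test_empty_selection_raises(self):
        frame = make_frame([make_atom(1, [0, 0, 0], name="P", element="P",
                                      residue_name="LIG")])
        with pytest.raises(SelectionError):
            select_indices(frame, "mainchain_CON")


def _timed_ensemble(times):
    frames = []
    for i, t in enumerate(times):
        atoms = [make_atom(1, [0.0, 0.0, 0.0]), make_atom(2, [1.0, 0.0, 0.0]),
                 make_atom(3, [0.0, 1.0, 0.0])]
        frames.append(make_frame(atoms, index=i, time_ps=t))
    return Ensemble(frames=frames)


class TestExtractWindow:
    def test_last_4ns_at_10ps_yields_400_frames(self):
        ens = _timed_ensemble(np.arange(0.0, 25000.1, 10.0))
        out = extract_window(ens, window_ns=4.0, interval_ps=10.0)
        assert len(out) == 400
        assert out.frames[0].time_ps == pytest.approx(21010.0)
        assert out.frames[-1].time_ps == pytest.approx(25000.0)

    def test_full_span_identity(self):
        ens = _timed_ensemble(np.arange(10.0, 1000.1, 10.0))
        out = extract_window(ens, window_ns=1.0, interval_ps=10.0)
        assert len(out) == len(ens)
        assert [f.time_ps for f in out] == [f.time_ps for f in ens]

    def test_interval_not_multiple_of_spacing(self):
        ens = _timed_ensemble(np.arange(0.0, 100.1, 10.0))
        with pytest.raises(ValueError):
            extract_window(ens, window_ns=0.05, interval_ps=15.0)

    def test_window_longer_than_trajectory(self):
        ens = _timed_ensemble(np.arange(0.0, 100.1, 10.0))
        with pytest.raises(ValueError):
            extract_window(ens, window_ns=1.0, interval_ps=10.0)

    def test_subsampling_interval(self):
        ens = _timed_ensemble(np.arange(0.0, 200.1, 10.0))
        out = extract_window(ens, window_ns=0.1, interval_ps=20.0)
        assert [f.time_ps for f in out] == [120.0, 140.0, 160.0, 180.0, 200.0]


class TestPca:
    def test_constant_trajectory_all_zero_eigenvalues(self):
        spec = ModalTrajectorySpec(n_atoms=8, n_frames=5, modes=np.zeros((0, 24)),
                                   amplitudes=[], noise_sd=0.0, seed=1)
        ens = generate_modal_trajectory(spec)
        modes = compute_pca(ens, reference_frame(spec))
        assert all(m.eigenvalue == 0.0 for m in modes)

    def test_planted_single_mode_recovery(self):
        ref = _default_reference(10, stream_rng(11, "reference"))
        u = random_orthonormal_modes(ref, 1, stream_rng(11, "modes"))
        spec = ModalTrajectorySpec(n_atoms=10, n_frames=200, modes=u,
                                   amplitudes=[2.0], noise_sd=0.0, seed=11, reference=ref)
        ens = generate_modal_trajectory(spec)
        modes = compute_pca(ens, reference_frame(spec))
        assert abs(float(np.dot(modes[0].vector, u[0]))) >= 0.999
        # eigenvalue equals the sample variance of the planted amplitudes
        amps = stream_rng(11, "amplitudes").normal(size=(200, 1)) * 2.0
        assert modes[0].eigenvalue == pytest.approx(float(np.var(amps, ddof=1)), rel=1e-6)

    def test_trace_identity(self):
        spec = ModalTrajectorySpec(n_atoms=12, n_frames=40, modes=np.zeros((0, 36)),
                                   amplitudes=[], noise_sd=0.3, seed=2)
        ens = generate_modal_trajectory(spec)
        ref = reference_frame(spec)
        modes = compute_pca(ens, ref)
        idx = select_indices(ref, "calpha")
        rows = []
        for frame in ens:
            fit = kabsch_superpose(frame.coords(idx), ref.coords(idx))
            rows.append(fit.apply(frame.coords(idx)).ravel())
        x = np.array(rows)
        x -= x.mean(axis=0)
        trace = float(np.trace(x.T @ x)) / (len(ens) - 1)
        assert sum(m.eigenvalue for m in modes) == pytest.approx(trace, rel=1e-8)

    def test_modes_orthonormal_and_sorted(self):
        ref = _default_reference(10, stream_rng(3, "reference"))
        u = random_orthonormal_modes(ref, 3, stream_rng(3, "modes"))
        spec = ModalTrajectorySpec(n_atoms=10, n_frames=80, modes=u,
                                   amplitudes=[3.0, 2.0, 1.0], noise_sd=0.1,
                                   seed=3, reference=ref)
        modes = compute_pca(generate_modal_trajectory(spec), reference_frame(spec))
        evals = [m.eigenvalue for m in modes]
        assert all(e0 >= e1 for e0, e1 in zip(evals, evals[1:]))
        assert all(e >= -1e-10 for e in evals)
        vecs = np.array([m.vector for m in modes[:10]])
        assert np.allclose(vecs @ vecs.T, np.eye(10), atol=1e-8)
        fractions = [m.variance_fraction for m in modes]
        assert sum(fractions) == pytest.approx(1.0, abs=1e-9)

    def test_dense_eigendecomposition_oracle(self):
        spec = ModalTrajectorySpec(n_atoms=6, n_frames=30, modes=np.zeros((0, 18)),
                                   amplitudes=[], noise_sd=0.2, seed=4)
        ens = generate_modal_trajectory(spec)
        ref = reference_frame(spec)
        modes = compute_pca(ens, ref)
        idx = select_indices(ref, "calpha")
        rows = []
        for frame in ens:
            fit = kabsch_superpose(frame.coords(idx), ref.coords(idx))
            rows.append(fit.apply(frame.coords(idx)).ravel())
        x = np.array(rows)
        x -= x.mean(axis=0)
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        evals = s**2 / (len(ens) - 1)
        for k in range(min(5, len(evals))):
            assert modes[k].eigenvalue == pytest.approx(float(evals[k]), rel=1e-8)
            cos = abs(float(np.dot(modes[k].vector, vt[k])))
            assert cos == pytest.approx(1.0, abs=1e-8)

    def test_fewer_than_two_frames_raises(self):
        spec = ModalTrajectorySpec(n_atoms=5, n_frames=1, modes=np.zeros((0, 15)),
                                   amplitudes=[], seed=5)
        ens = generate_modal_trajectory(spec)
        with pytest.raises(ValidationError):
            compute_pca(ens, reference_frame(spec))


class TestPorcupine:
    def _mode_and_ref(self):
        spec = ModalTrajectorySpec(n_atoms=7, n_frames=30, modes=np.zeros((0, 21)),
                                   amplitudes=[], noise_sd=0.2, seed=6)
        ens = generate_modal_trajectory(spec)
        ref = reference_frame(spec)
        return ref, compute_pca(ens, ref)[0]

    def test_zero_scale_degenerate(self):
        ref, mode = self._mode_and_ref()
        arrows = porcupine_arrows(ref, mode, scale=0.0)
        assert all(np.allclose(a.start, a.end) for a in arrows)

    def test_scale_linearity(self):
        ref, mode = self._mode_and_ref()
        a1 = porcupine_arrows(ref, mode, scale=5.0)
        a2 = porcupine_arrows(ref, mode, scale=10.0)
        for x, y in zip(a1, a2):
            assert np.allclose(2.0 * (x.end - x.start), y.end - y.start, atol=1e-12)

    def test_planted_mode_longest_arrow(self):
        ref = _default_reference(10, stream_rng(7, "reference"))
        u = np.zeros((1, 30))
        u[0, 12] = 1.0  # atom 4 carries all the motion
        spec = ModalTrajectorySpec(n_atoms=10, n_frames=100, modes=u,
                                   amplitudes=[2.0], noise_sd=0.0, seed=7, reference=ref)
        modes = compute_pca(generate_modal_trajectory(spec), reference_frame(spec))
        arrows = porcupine_arrows(reference_frame(spec), modes[0], scale=4.0)
        lengths = [float(np.linalg.norm(a.end - a.start)) for a in arrows]
        assert int(np.argmax(lengths)) == 4

    def test_length_mismatch_raises(self):
        ref, mode = self._mode_and_ref()
        bad = type(mode)(index=1, eigenvalue=1.0, vector=np.ones(9), variance_fraction=0.5)
        with pytest.raises(ValidationError):
            porcupine_arrows(ref, bad, scale=1.0)
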