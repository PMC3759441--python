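"""Seeded synthetic inputs: contact databases, labeled pose ensembles, and
trajectories with planted collective modes.

Every generator is deterministic given (spec, seed).  One global seed expands
into independent per-stream seeds via ``SeedSequence([seed, crc32(label)])``,
so adding a new generator never perturbs existing streams.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConstructionError, ValidationError
from .potential import ContactObservation
from .structure_io import AtomRecord, Ensemble, Frame, Role

__all__ = [
    "DistanceLaw",
    "ContactDBSpec",
    "PoseEnsembleSpec",
    "ModalTrajectorySpec",
    "generate_contact_db",
    "generate_pose_ensemble",
    "generate_modal_trajectory",
    "random_orthonormal_modes",
    "write_labels",
    "read_labels",
]


def stream_rng(seed: int, *labels) -> np.random.Generator:
    """Independent generator for a named stream of the global seed."""
    keys = [zlib.crc32(str(label).encode()) for label in labels]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


@dataclass(frozen=True)
class DistanceLaw:
    """Normal distance law truncated to (0, upper]."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValidationError("distance law sd must be > 0")

    def sample(self, n: int, rng: np.random.Generator, upper: float) -> np.ndarray:
        if self.mean <= 0 or upper <= 0:
            raise ValidationError("distance law requires positive mean and upper bound")
        a = (1e-9 - self.mean) / self.sd
        b = (upper - self.mean) / self.sd
        if b <= a:
            raise ValidationError("truncation bound below the distribution support")
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd, size=n, random_state=rng)


# ---------------------------------------------------------------------------
# Contact databases
# ---------------------------------------------------------------------------


@dataclass
class ContactDBSpec:
    """Per-type-pair truncated-normal distance laws with counts."""

    laws: dict[tuple[str, str], DistanceLaw]
    counts: dict[tuple[str, str], int]
    d_max_gen: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.laws) != set(self.counts):
            raise ValidationError("laws and counts must cover the same type pairs")
        if any(c < 1 for c in self.counts.values()):
            raise ValidationError("counts must be >= 1")

    def to_dict(self) -> dict:
        return {
            "laws": {
                "|".join(k): {"mean": v.mean, "sd": v.sd} for k, v in sorted(self.laws.items())
            },
            "counts": {"|".join(k): v for k, v in sorted(self.counts.items())},
            "d_max_gen": self.d_max_gen,
            "seed": self.seed,
        }


def generate_contact_db(spec: ContactDBSpec) -> list[ContactObservation]:
    """Seeded reproducible draws from each pair's truncated normal."""
    out: list[ContactObservation] = []
    for pair in sorted(spec.laws):
        law = spec.laws[pair]
        rng = stream_rng(spec.seed, "contacts", *pair)
        distances = law.sample(spec.counts[pair], rng, spec.d_max_gen)
        out.extend(ContactObservation(pair[0], pair[1], float(d)) for d in distances)
    return out


# ---------------------------------------------------------------------------
# Pose ensembles
# ---------------------------------------------------------------------------


@dataclass
class PoseEnsembleSpec:
    """Pose ensemble with a known near-native subset.

    ``n_contacts`` pocket atoms are planted on a wide grid, each with one
    ligand atom whose distance is drawn from the favorable law (near-native
    frames) or the decoy law (decoy frames).  A probe (cofactor) / target
    (ligand) reactive pair sits at ``reactive_baseline`` plus per-frame
    jitter; near-native frames draw jitter shifted by
    ``near_native_reactive_shift`` (negative = closer to the probe).
    """

    n_frames: int
    near_native_fraction: float
    n_contacts: int
    favorable: DistanceLaw
    decoy: DistanceLaw
    ligand_type_element: str = "C"
    pocket_type_element: str = "O"
    reactive_baseline: float = 3.0
    reactive_jitter_sd: float = 0.05
    near_native_reactive_shift: float = 0.0
    d_max_gen: float = 8.0
    pocket_spacing: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.near_native_fraction <= 1.0:
            raise ValidationError("near_native_fraction must lie in [0, 1]")
        if self.n_frames < 1 or self.n_contacts < 1:
            raise ValidationError("n_frames and n_contacts must be >= 1")
        if self.reactive_baseline + self.near_native_reactive_shift <= 0:
            raise ConstructionError("requested reactive geometry is infeasible (<= 0 Å)")
        if self.pocket_spacing < 2 * self.d_max_gen:
            raise ConstructionError(
                "pocket spacing must exceed twice the generation range to keep contacts independent"
            )


NEAR_NATIVE = "near_native"
DECOY = "decoy"


def _pose_atoms(spec: PoseEnsembleSpec) -> list[AtomRecord]:
    """Topology template; coordinates are overwritten per frame."""
    atoms: list[AtomRecord] = []
    serial = 1
    s = spec.pocket_spacing
    for i in range(spec.n_contacts):
        atoms.append(
            AtomRecord(
                serial=serial,
                name=spec.pocket_type_element,
                element=spec.pocket_type_element,
                residue_name="GLY",
                residue_number=101 + i,
                chain_id="A",
                coords=np.array([i * s, 0.0, 0.0]),
                role=Role.RECEPTOR,
            )
        )
        serial += 1
    for i in range(spec.n_contacts):
        atoms.append(
            AtomRecord(
                serial=serial,
                name=f"{spec.ligand_type_element}{i + 1}",
                element=spec.ligand_type_element,
                residue_name="LIG",
                residue_number=1,
                chain_id="L",
                coords=np.array([i * s, 3.0, 0.0]),
                role=Role.LIGAND,
                is_hetatm=True,
            )
        )
        serial += 1
    # cofactor iron + ferryl oxygen probe, far from the contact grid
    atoms.append(
        AtomRecord(
            serial=serial,
            name="FE",
            element="FE",
            residue_name="HEM",
            residue_number=900,
            chain_id="A",
            coords=np.array([-2 * s, 0.0, 0.0]),
            role=Role.COFACTOR,
            is_hetatm=True,
        )
    )
    serial += 1
    atoms.append(
        AtomRecord(
            serial=serial,
            name="O1",
            element="O",
            residue_name="HEM",
            residue_number=900,
            chain_id="A",
            coords=np.array([-2 * s + 1.6, 0.0, 0.0]),
            role=Role.COFACTOR,
            is_hetatm=True,
        )
    )
    serial += 1
    # reactive target: ligand carbon adjacent to the probe
    atoms.append(
        AtomRecord(
            serial=serial,
            name=f"{spec.ligand_type_element}7",
            element=spec.ligand_type_element,
            residue_name="LIG",
            residue_number=1,
            chain_id="L",
            coords=np.array([-2 * s + 1.6 + spec.reactive_baseline, 0.0, 0.0]),
            role=Role.LIGAND,
            is_hetatm=True,
        )
    )
    return atoms


def probe_target_serials(spec: PoseEnsembleSpec) -> tuple[int, int]:
    """Serials of the reactive probe (ferryl O) and target (ligand C7)."""
    n = spec.n_contacts
    return 2 * n + 2, 2 * n + 3


def generate_pose_ensemble(spec: PoseEnsembleSpec) -> tuple[Ensemble, list[str]]:
    """Build the ensemble and its per-frame labels (labels are a sidecar,
    never written into the PDB, so the scoring pipeline cannot cheat)."""
    n_near = int(round(spec.near_native_fraction * spec.n_frames))
    label_rng = stream_rng(spec.seed, "labels")
    order = label_rng.permutation(spec.n_frames)
    labels = [DECOY] * spec.n_frames
    for idx in order[:n_near]:
        labels[int(idx)] = NEAR_NATIVE

    template = _pose_atoms(spec)
    probe_serial, target_serial = probe_target_serials(spec)
    s = spec.pocket_spacing
    frames: list[Frame] = []
    for t in range(spec.n_frames):
        rng = stream_rng(spec.seed, "frame", t)
        law = spec.favorable if labels[t] == NEAR_NATIVE else spec.decoy
        dists = law.sample(spec.n_contacts, rng, spec.d_max_gen)
        dirs = rng.normal(size=(spec.n_contacts, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        coords = np.array([a.coords for a in template])
        for i in range(spec.n_contacts):
            pocket_xyz = coords[i]
            coords[spec.n_contacts + i] = pocket_xyz + dists[i] * dirs[i]
        jitter = rng.normal(0.0, spec.reactive_jitter_sd)
        shift = spec.near_native_reactive_shift if labels[t] == NEAR_NATIVE else 0.0
        reactive_d = spec.reactive_baseline + shift + jitter
        if reactive_d <= 0:
            raise ConstructionError(f"frame {t}: jittered reactive distance <= 0")
        probe_xyz = coords[probe_serial - 1]
        coords[target_serial - 1] = probe_xyz + np.array([reactive_d, 0.0, 0.0])
        frame = Frame(index=t, time_ps=10.0 * (t + 1), atoms=list(template))
        frame = frame.with_coords(coords)
        frames.append(frame)
    return Ensemble(frames=frames), labels


def write_labels(labels: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("frame\tlabel\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")


def read_labels(path) -> list[str]:
    labels = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "frame\tlabel":
            raise ValidationError("unrecognized labels file header")
        for line in fh:
            labels.append(line.rstrip("\n").split("\t")[1])
    return labels


# ---------------------------------------------------------------------------
# Modal trajectories
# ---------------------------------------------------------------------------


@dataclass
class ModalTrajectorySpec:
    """Trajectory with <= 3 planted orthonormal collective modes plus noise."""

    n_atoms: int
    n_frames: int
    modes: np.ndarray  # (k, 3N) orthonormal rows
    amplitudes: Sequence[float]  # strictly decreasing sigma_k
    noise_sd: float = 0.0
    rigid_motion: bool = False
    seed: int = 0
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes, dtype=float))
        k = self.modes.shape[0]
        if k > 3 or self.modes.shape[1] != 3 * self.n_atoms:
            raise ValidationError("modes must be a (k<=3, 3N) array")
        if len(self.amplitudes) != k:
            raise ValidationError("one amplitude per mode required")
        amps = list(self.amplitudes)
        if any(a < 0 for a in amps) or any(a0 <= a1 for a0, a1 in zip(amps, amps[1:]) if a1 > 0):
            raise ValidationError("amplitudes must be non-negative and strictly ordered")
        gram = self.modes @ self.modes.T
        if not np.allclose(gram, np.eye(k), atol=1e-8):
            raise ValidationError("planted modes must be orthonormal")


def _default_reference(n_atoms: int, rng: np.random.Generator) -> np.ndarray:
    """Open-helix C-alpha trace: non-degenerate, reproducible geometry."""
    t = np.arange(n_atoms)
    coords = np.stack(
        [3.8 * t, 4.0 * np.cos(0.6 * t), 4.0 * np.sin(0.6 * t)], axis=1
    )
    return coords + 0.1 * rng.normal(size=coords.shape)


def rigid_body_basis(reference: np.ndarray) -> np.ndarray:
    """Orthonormal basis (6, 3N) of infinitesimal rigid motions at *reference*."""
    n = len(reference)
    centered = reference - reference.mean(axis=0)
    basis = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = 1.0
        basis.append(v.ravel())
    for axis in np.eye(3):
        basis.append(np.cross(np.tile(axis, (n, 1)), centered).ravel())
    q, _ = np.linalg.qr(np.array(basis).T)
    return q.T


def random_orthonormal_modes(
    reference: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """k orthonormal 3N vectors orthogonal to the rigid-body subspace.

    Orthogonality to rigid motions keeps planted modes recoverable after
    superposition removes global translation/rotation.
    """
    n3 = reference.size
    rigid = rigid_body_basis(reference)
    raw = rng.normal(size=(k, n3))
    raw -= (raw @ rigid.T) @ rigid
    q, _ = np.linalg.qr(raw.T)
    return q.T[:k]


def reference_frame(spec: ModalTrajectorySpec) -> Frame:
    """The noise-free reference geometry as a Frame (PCA fit target)."""
    rng_ref = stream_rng(spec.seed, "reference")
    reference = (
        np.asarray(spec.reference, dtype=float)
        if spec.reference is not None
        else _default_reference(spec.n_atoms, rng_ref)
    )
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            residue_name="ALA",
            residue_number=i + 1,
            chain_id="A",
            coords=reference[i],
            role=Role.RECEPTOR,
        )
        for i in range(spec.n_atoms)
    ]
    return Frame(index=0, time_ps=0.0, atoms=atoms)


def generate_modal_trajectory(spec: ModalTrajectorySpec) -> Ensemble:
    """frame_t = reference + sum_k a_k(t) mode_k + noise, a_k ~ N(0, sigma_k^2);
    an optional random rigid motion is applied last so superposition must
    remove it."""
    rng_ref = stream_rng(spec.seed, "reference")
    reference = (
        np.asarray(spec.reference, dtype=float)
        if spec.reference is not None
        else _default_reference(spec.n_atoms, rng_ref)
    )
    if reference.shape != (spec.n_atoms, 3):
        raise ValidationError("reference must be an (N, 3) array")
    amp_rng = stream_rng(spec.seed, "amplitudes")
    noise_rng = stream_rng(spec.seed, "noise")
    rigid_rng = stream_rng(spec.seed, "rigid")
    k = spec.modes.shape[0]
    frames = []
    template = [
        AtomRecord(
            serial=i + 1,
            name="CA",
            element="C",
            residue_name="ALA",
            residue_number=i + 1,
            chain_id="A",
            coords=reference[i],
            role=Role.RECEPTOR,
        )
        for i in range(spec.n_atoms)
    ]
    base_frame = Frame(index=0, time_ps=0.0, atoms=template)
    for t in range(spec.n_frames):
        disp = np.zeros(3 * spec.n_atoms)
        if k:
            a = amp_rng.normal(size=k) * np.asarray(spec.amplitudes, dtype=float)
            disp = a @ spec.modes
        coords = reference + disp.reshape(-1, 3)
        if spec.noise_sd > 0:
            coords = coords + noise_rng.normal(0.0, spec.noise_sd, size=coords.shape)
        if spec.rigid_motion:
            coords = _random_rigid(coords, rigid_rng)
        atoms = base_frame.with_coords(coords).atoms
        frames.append(Frame(index=t, time_ps=10.0 * (t + 1), atoms=atoms))
    return Ensemble(frames=frames)


def _random_rigid(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20.0, 20.0, size=3)
    center = coords.mean(axis=0)
    return (coords - center) @ rot.T + center + trans
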