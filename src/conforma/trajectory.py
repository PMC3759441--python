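"""Equilibration diagnostics and essential dynamics.

Superposition (Kabsch, reflections excluded), RMSD time series over standard
atom selections, stable-window frame extraction, covariance PCA of C-alpha
coordinates, and porcupine-arrow construction for mode visualization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import SelectionError, ValidationError
from .structure_io import AMINO_ACIDS, Ensemble, Frame

__all__ = [
    "SuperpositionResult",
    "EigenMode",
    "PorcupineArrow",
    "kabsch_superpose",
    "select_indices",
    "rmsd_series",
    "extract_window",
    "compute_pca",
    "porcupine_arrows",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform x -> rotation @ x + translation, plus post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: Sequence[int] | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition of *mobile* onto *reference*.

    The rotation is proper (det = +1); reflections are excluded by flipping
    the sign of the smallest singular vector when needed.  The returned RMSD
    is computed over the selection after applying the transform.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValidationError("mobile and reference must be matching (N, 3) arrays")
    if selection is None:
        sel_m, sel_r = mobile, reference
    else:
        idx = np.asarray(list(selection), dtype=int)
        sel_m, sel_r = mobile[idx], reference[idx]
    if len(sel_m) < 3:
        raise SelectionError("superposition needs at least 3 selected atoms")

    cm = sel_m.mean(axis=0)
    cr = sel_r.mean(axis=0)
    m0 = sel_m - cm
    r0 = sel_r - cr
    if np.linalg.matrix_rank(m0, tol=1e-8) < 2 or np.linalg.matrix_rank(r0, tol=1e-8) < 2:
        raise SelectionError("degenerate (collinear) selection: rotation is not determined")

    h = m0.T @ r0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = cr - rotation @ cm
    fitted = sel_m @ rotation.T + translation
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - sel_r) ** 2, axis=1))))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def select_indices(frame: Frame, spec) -> list[int]:
    """Resolve a selection spec to atom indices.

    "mainchain_CON" picks atoms literally named C, O or N in amino-acid
    residues (C-alpha deliberately excluded); "calpha" picks CA atoms of
    amino-acid residues; any other iterable is taken as explicit indices.
    """
    if spec == "mainchain_CON":
        idx = [
            i
            for i, a in enumerate(frame.atoms)
            if a.name in ("C", "O", "N") and a.residue_name.upper() in AMINO_ACIDS
        ]
    elif spec == "calpha":
        idx = [
            i
            for i, a in enumerate(frame.atoms)
            if a.name == "CA" and a.residue_name.upper() in AMINO_ACIDS
        ]
    elif spec == "all":
        idx = list(range(len(frame.atoms)))
    else:
        idx = [int(i) for i in spec]
        if any(i < 0 or i >= len(frame.atoms) for i in idx):
            raise SelectionError("selection index out of range")
    if not idx:
        raise SelectionError(f"selection {spec!r} matched no atoms")
    return idx


def rmsd_series(
    ensemble: Ensemble,
    reference: Frame,
    selection_spec="mainchain_CON",
    fit: bool = True,
) -> list[tuple[float, float]]:
    """(time_ps, RMSD Å) per frame, superposed on *reference* over the selection.

    With ``fit=False`` frames are compared in place (useful for pre-aligned
    fixtures and for checking that fitting never increases the RMSD).
    """
    idx = select_indices(reference, selection_spec)
    ref = reference.coords(idx)
    out = []
    for frame in ensemble:
        mob = frame.coords(idx)
        if fit:
            rmsd = kabsch_superpose(mob, ref).rmsd
        else:
            rmsd = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
        out.append((frame.time_ps, rmsd))
    return out


def extract_window(ensemble: Ensemble, window_ns: float, interval_ps: float) -> Ensemble:
    """Frames with time in the half-open window (T_end - window, T_end].

    Frames are resampled at *interval_ps* anchored at the final frame, so the
    last frame is always included; e.g. a 25 000 ps trajectory at 10 ps
    spacing with a 4 ns window at 10 ps intervals yields exactly 400 frames.
    """
    times = ensemble.times
    if len(times) < 2:
        raise ValidationError("window extraction needs >= 2 frames")
    spacing = np.diff(times)
    if not np.allclose(spacing, spacing[0], rtol=0, atol=1e-6):
        raise ValidationError("frame times are not uniformly spaced")
    dt = float(spacing[0])
    window_ps = 1000.0 * window_ns
    span = float(times[-1] - times[0])
    # one spacing of slack: a trajectory whose first frame sits one interval
    # after the origin can still be covered in full by the half-open window
    if window_ps > span + dt + 1e-9:
        raise ValueError(f"window {window_ps} ps exceeds trajectory span {span} ps")
    ratio = interval_ps / dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"interval {interval_ps} ps is not a positive multiple of the frame spacing {dt} ps"
        )
    t_end = float(times[-1])
    lo = t_end - window_ps
    picked = []
    for frame, t in zip(ensemble.frames, times):
        if t <= lo + 1e-9:
            continue
        steps = (t_end - t) / interval_ps
        if abs(steps - round(steps)) <= 1e-9:
            picked.append(frame)
    frames = [
        Frame(index=i, time_ps=f.time_ps, atoms=f.atoms) for i, f in enumerate(picked)
    ]
    return Ensemble(frames=frames)


@dataclass
class EigenMode:
    """One principal mode of the fitted coordinate covariance."""

    index: int  # 1-based; 1 = largest eigenvalue
    eigenvalue: float  # Å^2
    vector: np.ndarray  # 3N, unit length
    variance_fraction: float


def compute_pca(
    ensemble: Ensemble,
    reference: Frame | None = None,
    selection_spec="calpha",
) -> list[EigenMode]:
    """Covariance PCA of selected-atom coordinates after superposition.

    Each frame is fit to the reference over the selection; the (F, 3N)
    coordinate matrix is mean-centered, the covariance (F-1 denominator)
    diagonalized, and modes returned sorted by non-increasing eigenvalue.
    Eigenvector signs are fixed so the largest-magnitude component is
    positive.
    """
    if len(ensemble) < 2:
        raise ValidationError("PCA needs at least 2 frames")
    if reference is None:
        reference = ensemble.frames[0]
    idx = select_indices(reference, selection_spec)
    ref = reference.coords(idx)
    rows = []
    for frame in ensemble:
        mob = frame.coords(idx)
        fit = kabsch_superpose(mob, ref)
        rows.append(fit.apply(mob).ravel())
    x = np.array(rows)
    x -= x.mean(axis=0)
    cov = (x.T @ x) / (len(ensemble) - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    evals = np.where(np.abs(evals) < 1e-12, 0.0, evals)
    total = float(evals.sum())
    modes = []
    for i in range(len(evals)):
        v = evecs[:, i].copy()
        if v[int(np.argmax(np.abs(v)))] < 0:
            v = -v
        modes.append(
            EigenMode(
                index=i + 1,
                eigenvalue=float(max(evals[i], 0.0)),
                vector=v,
                variance_fraction=float(evals[i] / total) if total > 0 else 0.0,
            )
        )
    return modes


@dataclass
class PorcupineArrow:
    atom_index: int
    start: np.ndarray
    end: np.ndarray


def porcupine_arrows(
    reference: Frame,
    mode: EigenMode,
    scale: float,
    selection_spec="calpha",
) -> list[PorcupineArrow]:
    """One arrow per selected atom: reference coords plus the scaled mode component.

    A single scale factor applies to every atom, so relative arrow lengths
    are independent of the scale chosen.
    """
    idx = select_indices(reference, selection_spec)
    if len(mode.vector) != 3 * len(idx):
        raise ValidationError(
            f"mode length {len(mode.vector)} does not match 3 x {len(idx)} selected atoms"
        )
    comps = np.asarray(mode.vector, dtype=float).reshape(-1, 3)
    arrows = []
    for arrow_i, atom_i in enumerate(idx):
        start = reference.atoms[atom_i].coords.copy()
        arrows.append(
            PorcupineArrow(atom_index=atom_i, start=start, end=start + scale * comps[arrow_i])
        )
    return arrows
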