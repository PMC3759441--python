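"""Per-variant ensemble analysis: pocket selection, frame scoring,
representative selection, reactive-distance feasibility, SRS-classified
per-residue tables, hydrogen-bond networks, and cross-variant comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, SelectionError, ValidationError
from .potential import ScoreReport, StatisticalPotential, score_complex
from .structure_io import Ensemble, Frame, Role

__all__ = [
    "PocketDefinition",
    "SRSMap",
    "HydrogenBond",
    "VariantRow",
    "VariantComparison",
    "select_pocket",
    "reactive_distance",
    "score_ensemble",
    "select_representative",
    "per_residue_table",
    "mean_pocket_score",
    "find_hydrogen_bonds",
    "compare_variants",
    "example_srs_map",
]

#: Annotation threshold: a reactive pair closer than this is flagged as
#: catalytically infeasible.  Used as an annotation only, never as a filter.
MIN_ALLOWED_REACTIVE_DISTANCE = 2.9


@dataclass
class PocketDefinition:
    """Residues scored against the ligand, fixed once per ensemble."""

    residues: set[tuple[str, int, str]]
    cutoff: float
    include_cofactor: bool = True


def select_pocket(frame: Frame, cutoff: float = 5.0, include_cofactor: bool = True) -> PocketDefinition:
    """Receptor residues with any atom within *cutoff* Å of any ligand atom.

    Cofactor residues are appended when *include_cofactor* is set, regardless
    of distance (the cofactor is part of the scored site by construction).
    """
    ligand = [a for a in frame.atoms if a.role == Role.LIGAND]
    if not ligand:
        raise SelectionError("frame has no ligand-role atoms; assign roles first")
    lig_xyz = np.array([a.coords for a in ligand])
    residues: set[tuple[str, int, str]] = set()
    receptor = [a for a in frame.atoms if a.role == Role.RECEPTOR]
    if receptor:
        rec_xyz = np.array([a.coords for a in receptor])
        dmin = cdist(rec_xyz, lig_xyz).min(axis=1)
        for a, d in zip(receptor, dmin):
            if d <= cutoff:
                residues.add(a.residue_key)
    if include_cofactor:
        residues.update(a.residue_key for a in frame.atoms if a.role == Role.COFACTOR)
    return PocketDefinition(residues=residues, cutoff=cutoff, include_cofactor=include_cofactor)


def reactive_distance(
    frame: Frame,
    probe_serial: int,
    target_serial: int,
    min_allowed: float = MIN_ALLOWED_REACTIVE_DISTANCE,
) -> tuple[float, bool]:
    """Euclidean probe-target distance and a feasibility flag (distance >= min_allowed)."""
    probe = frame.atom_by_serial(probe_serial)
    target = frame.atom_by_serial(target_serial)
    d = float(np.linalg.norm(probe.coords - target.coords))
    return d, d >= min_allowed


def score_ensemble(
    ensemble: Ensemble,
    potential: StatisticalPotential,
    pocket: PocketDefinition,
    reactive_pair_spec: tuple[int, int] | None = None,
) -> list[ScoreReport]:
    """One ScoreReport per frame, in frame order."""
    reports = []
    for frame in ensemble:
        try:
            reports.append(score_complex(potential, frame, pocket, reactive_pair_spec))
        except Exception as exc:
            raise type(exc)(f"frame {frame.index}: {exc}") from exc
    return reports


def select_representative(reports: Sequence[ScoreReport]) -> int:
    """Frame index with the lowest total score; ties go to the earliest frame."""
    if not reports:
        raise ValidationError("no score reports given")
    best = min(reports, key=lambda r: (r.total, r.frame_index))
    return best.frame_index


@dataclass
class SRSMap:
    """Named residue ranges (inclusive) classifying pocket residues.

    Residues outside every range classify as "non-SRS".  Ranges must not
    overlap within a chain.
    """

    ranges: list[tuple[str, str, int, int]]  # (label, chain, start, end)

    def __post_init__(self) -> None:
        per_chain: dict[str, list[tuple[int, int, str]]] = {}
        for label, chain, start, end in self.ranges:
            if end < start:
                raise ConfigError(f"{label}: end residue {end} precedes start {start}")
            per_chain.setdefault(chain, []).append((start, end, label))
        for chain, spans in per_chain.items():
            spans.sort()
            for (s0, e0, l0), (s1, e1, l1) in zip(spans, spans[1:]):
                if s1 <= e0:
                    raise ConfigError(
                        f"overlapping ranges {l0} and {l1} on chain {chain!r}"
                    )

    def classify(self, chain: str, residue_number: int) -> str:
        for label, rchain, start, end in self.ranges:
            if rchain == chain and start <= residue_number <= end:
                return label
        return "non-SRS"


def example_srs_map(chain: str = "A") -> SRSMap:
    """Placeholder six-range map for a P450-like numbering.

    The ranges are illustrative configuration, not a computed result;
    real analyses should supply literature-derived ranges for their system.
    """
    return SRSMap(
        ranges=[
            ("SRS-1", chain, 96, 117),
            ("SRS-2", chain, 198, 205),
            ("SRS-3", chain, 233, 240),
            ("SRS-4", chain, 288, 302),
            ("SRS-5", chain, 359, 368),
            ("SRS-6", chain, 470, 477),
        ]
    )


def per_residue_table(report: ScoreReport, srs_map: SRSMap) -> pd.DataFrame:
    """Per-residue scores labeled by SRS range; the cofactor gets its own row.

    Rows are sorted by (chain, residue number).  Column sums reproduce
    ``report.total``: protein rows plus the cofactor row(s).
    """
    rows = []
    for (chain, resnum, resname), score in report.per_residue.items():
        key = (chain, resnum, resname)
        if key in report.cofactor_residues:
            label = "cofactor"
        else:
            label = srs_map.classify(chain, resnum)
        rows.append(
            {
                "chain": chain,
                "residue_number": resnum,
                "residue_name": resname,
                "srs": label,
                "score": score,
            }
        )
    df = pd.DataFrame(
        rows, columns=["chain", "residue_number", "residue_name", "srs", "score"]
    )
    return df.sort_values(["chain", "residue_number"], kind="stable").reset_index(drop=True)


def mean_pocket_score(
    reports: Sequence[ScoreReport],
    residues: Iterable[tuple[str, int, str]],
) -> float:
    """Mean over frames of the per-frame sum of the given residues' scores."""
    if not reports:
        raise ValidationError("no score reports given")
    subset = list(residues)
    known = set(reports[0].per_residue)
    unknown = [r for r in subset if r not in known]
    if unknown:
        raise KeyError(f"residues not in the score reports: {unknown}")
    sums = [sum(rep.per_residue[r] for r in subset) for rep in reports]
    return float(np.mean(sums))


@dataclass
class HydrogenBond:
    donor: tuple[tuple[str, int, str], str]  # (residue key, atom name)
    acceptor: tuple[tuple[str, int, str], str]
    distance: float
    angle: float | None = None


def _is_hydrogen(atom) -> bool:
    return atom.element.upper() == "H" or (not atom.element and atom.name.startswith("H"))


def find_hydrogen_bonds(
    frame: Frame,
    donor_residues: set[tuple[str, int]],
    acceptor_residues: set[tuple[str, int]],
    max_da: float = 3.5,
    min_angle: float | None = None,
) -> list[HydrogenBond]:
    """Geometric donor-acceptor detection.

    Donors are N/O heavy atoms in *donor_residues*; acceptors are O heavy
    atoms in *acceptor_residues*.  A pair qualifies when the heavy-atom
    distance is <= *max_da* and, only when the donor carries hydrogens and
    *min_angle* is set, the best D-H...A angle is >= *min_angle* degrees.
    Residues are addressed by (chain, residue number); intra-residue pairs
    are skipped.
    """
    if not donor_residues or not acceptor_residues:
        raise SelectionError("donor and acceptor residue sets must be non-empty")
    donors = [
        a
        for a in frame.atoms
        if a.element.upper() in ("N", "O")
        and (a.chain_id, a.residue_number) in donor_residues
    ]
    acceptors = [
        a
        for a in frame.atoms
        if a.element.upper() == "O"
        and (a.chain_id, a.residue_number) in acceptor_residues
    ]
    hydrogens = [a for a in frame.atoms if _is_hydrogen(a)]
    bonds = []
    for d in donors:
        d_h = [
            h
            for h in hydrogens
            if (h.chain_id, h.residue_number) == (d.chain_id, d.residue_number)
            and float(np.linalg.norm(h.coords - d.coords)) <= 1.2
        ]
        for acc in acceptors:
            if (d.chain_id, d.residue_number) == (acc.chain_id, acc.residue_number):
                continue
            dist = float(np.linalg.norm(d.coords - acc.coords))
            if dist > max_da or dist == 0.0:
                continue
            angle = None
            if d_h:
                angle = max(_dha_angle(d.coords, h.coords, acc.coords) for h in d_h)
                if min_angle is not None and angle < min_angle:
                    continue
            bonds.append(
                HydrogenBond(
                    donor=(d.residue_key, d.name),
                    acceptor=(acc.residue_key, acc.name),
                    distance=dist,
                    angle=angle,
                )
            )
    bonds.sort(key=lambda b: (b.donor, b.acceptor))
    return bonds


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray, acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


@dataclass
class VariantRow:
    name: str
    representative_index: int
    total: float
    reactive_score: float | None
    reactive_distance: float | None
    feasible: bool | None


@dataclass
class VariantComparison:
    rows: dict[str, VariantRow]
    ranking: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        data = [
            {
                "variant": r.name,
                "representative_frame": r.representative_index,
                "total_score": r.total,
                "reactive_score": r.reactive_score,
                "reactive_distance_A": r.reactive_distance,
                "feasible": r.feasible,
                "rank": self.ranking.index(r.name) + 1,
            }
            for r in self.rows.values()
        ]
        df = pd.DataFrame(data).sort_values("rank", kind="stable").reset_index(drop=True)
        return df


def compare_variants(
    reports_by_variant: Mapping[str, Sequence[ScoreReport]],
    min_allowed: float = MIN_ALLOWED_REACTIVE_DISTANCE,
) -> VariantComparison:
    """Representative frame per variant plus a ranking by reactive-pair score.

    Every variant's reports must carry reactive-pair data consistently
    (all present or all absent); ranking is by ascending reactive score,
    most favorable first, with variant name breaking ties.
    """
    if len(reports_by_variant) < 2:
        raise ConfigError("variant comparison needs at least 2 variants")
    has_reactive = {
        name: all(r.reactive_pair is not None for r in reports)
        for name, reports in reports_by_variant.items()
    }
    if len(set(has_reactive.values())) > 1:
        raise ConfigError(
            "mismatched reactive specs: some variants carry reactive-pair data, others do not"
        )
    rows: dict[str, VariantRow] = {}
    for name, reports in reports_by_variant.items():
        if not reports:
            raise ValidationError(f"variant {name!r} has no reports")
        rep_idx = select_representative(reports)
        rep = next(r for r in reports if r.frame_index == rep_idx)
        if rep.reactive_pair is not None:
            rd = rep.reactive_distance
            rows[name] = VariantRow(
                name=name,
                representative_index=rep_idx,
                total=rep.total,
                reactive_score=rep.reactive_pair.score,
                reactive_distance=rd,
                feasible=None if rd is None else rd >= min_allowed,
            )
        else:
            rows[name] = VariantRow(
                name=name,
                representative_index=rep_idx,
                total=rep.total,
                reactive_score=None,
                reactive_distance=None,
                feasible=None,
            )
    if all(r.reactive_score is not None for r in rows.values()):
        ranking = sorted(rows, key=lambda n: (rows[n].reactive_score, n))
    else:
        ranking = sorted(rows, key=lambda n: (rows[n].total, n))
    return VariantComparison(rows=rows, ranking=ranking)
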