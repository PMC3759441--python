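"""Distance-binned knowledge-based pair potential with a mean reference state.

The potential is trained on a table of intermolecular atom-type-pair contact
distances.  For each (unordered) type pair a binned probability table is
estimated with Laplace-style pseudocounts; the *reference* table is the same
estimator applied to all contacts pooled over type pairs.  A pair at distance
``d`` in bin ``k`` scores

    s = -ln( P_pair(k) / P_ref(k) )

so negative values mark contacts more probable than the type-pooled average
(favorable), positive values less probable (unfavorable), and any distance
outside the binning range scores exactly 0 (no interaction).  Complex scores
are additive over ligand-pocket atom pairs, which makes per-pair and
per-residue decompositions exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import (
    EmptyPotentialError,
    PotentialFormatError,
    ValidationError,
)
from .structure_io import Frame, Role

__all__ = [
    "ContactObservation",
    "DistanceBinning",
    "StatisticalPotential",
    "PairScore",
    "ScoreReport",
    "bin_index",
    "build_potential",
    "pair_score",
    "score_complex",
    "save_potential",
    "load_potential",
    "read_contacts",
    "write_contacts",
    "report_to_tsv",
]

_FORMAT_NAME = "conforma-potential"
_FORMAT_VERSION = 1


class ContactObservation(NamedTuple):
    """One observed intermolecular contact distance between two atom types."""

    type_a: str
    type_b: str
    distance: float


def pair_key(type_a: str, type_b: str) -> tuple[str, str]:
    """Canonical unordered key: (a, b) and (b, a) map to the same table."""
    return (type_a, type_b) if type_a <= type_b else (type_b, type_a)


@dataclass(frozen=True)
class DistanceBinning:
    """Half-open uniform bins [d_min + k*width, d_min + (k+1)*width)."""

    d_min: float = 0.0
    d_max: float = 6.0
    width: float = 0.2

    def __post_init__(self) -> None:
        if self.d_min < 0 or self.d_max <= self.d_min or self.width <= 0:
            raise ValidationError("require 0 <= d_min < d_max and width > 0")
        n = (self.d_max - self.d_min) / self.width
        if abs(n - round(n)) > 1e-9 or round(n) < 1:
            raise ValidationError("(d_max - d_min) / width must be a positive integer")

    @property
    def n_bins(self) -> int:
        return int(round((self.d_max - self.d_min) / self.width))

    def edges(self) -> np.ndarray:
        return self.d_min + self.width * np.arange(self.n_bins + 1)


def bin_index(distance: float, binning: DistanceBinning) -> int | None:
    """Bin of *distance*, or None when outside [d_min, d_max).

    Raises ValueError for non-positive distances (a zero or negative
    interatomic distance is a caller bug, not an out-of-range contact).
    """
    if distance <= 0:
        raise ValueError(f"distance must be positive, got {distance}")
    if distance < binning.d_min or distance >= binning.d_max:
        return None
    k = int(math.floor((distance - binning.d_min) / binning.width))
    # guard the float edge case where (d - d_min)/width rounds up to n_bins
    return min(k, binning.n_bins - 1)


@dataclass
class StatisticalPotential:
    """Binned per-type-pair probability tables plus the pooled reference table."""

    binning: DistanceBinning
    pair_tables: dict[tuple[str, str], np.ndarray]
    reference_table: np.ndarray
    pseudocount: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        nb = self.binning.n_bins
        tables = list(self.pair_tables.values()) + [self.reference_table]
        for t in tables:
            if t.shape != (nb,):
                raise ValidationError("probability table length does not match binning")
            if not np.all(t > 0):
                raise ValidationError("probability tables must be strictly positive")
            if abs(float(t.sum()) - 1.0) > 1e-9:
                raise ValidationError("probability tables must sum to 1")


def _normalized_counts(counts: np.ndarray, pseudocount: float) -> np.ndarray:
    smoothed = counts.astype(float) + pseudocount
    return smoothed / smoothed.sum()


def build_potential(
    contacts: Iterable[ContactObservation],
    binning: DistanceBinning | None = None,
    pseudocount: float = 1.0,
    provenance: Mapping | None = None,
) -> StatisticalPotential:
    """Estimate the potential from a contact database.

    Per type pair, table(k) = (c_k + a) / sum_j (c_j + a) with a the
    pseudocount; the reference table applies the identical rule to all
    contacts pooled over type pairs (the mean reference state).  Contacts
    outside the binning range are ignored but tallied in provenance.
    """
    if binning is None:
        binning = DistanceBinning()
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be > 0")
    nb = binning.n_bins
    counts: dict[tuple[str, str], np.ndarray] = {}
    pooled = np.zeros(nb, dtype=np.int64)
    n_total = 0
    n_out = 0
    for obs in contacts:
        n_total += 1
        k = bin_index(obs.distance, binning)
        key = pair_key(obs.type_a, obs.type_b)
        if key not in counts:
            counts[key] = np.zeros(nb, dtype=np.int64)
        if k is None:
            n_out += 1
            continue
        counts[key][k] += 1
        pooled[k] += 1
    if int(pooled.sum()) == 0:
        raise EmptyPotentialError(
            f"none of the {n_total} contacts fall inside "
            f"[{binning.d_min}, {binning.d_max}) Å"
        )
    meta = dict(provenance or {})
    meta.update(n_contacts=n_total, n_out_of_range=n_out, n_type_pairs=len(counts))
    return StatisticalPotential(
        binning=binning,
        pair_tables={k: _normalized_counts(c, pseudocount) for k, c in counts.items()},
        reference_table=_normalized_counts(pooled, pseudocount),
        pseudocount=pseudocount,
        provenance=meta,
    )


def pair_score(
    potential: StatisticalPotential,
    type_a: str,
    type_b: str,
    distance: float,
) -> float:
    """Score one atom pair; 0.0 exactly outside the binning range.

    Type pairs absent from the training contacts fall back on the reference
    table and therefore score 0 at any in-range distance.
    """
    k = bin_index(distance, potential.binning)
    if k is None:
        return 0.0
    table = potential.pair_tables.get(pair_key(type_a, type_b))
    if table is None:
        table = potential.reference_table
    ratio = float(table[k]) / float(potential.reference_table[k])
    return -math.log(ratio)


# ---------------------------------------------------------------------------
# Complex scoring
# ---------------------------------------------------------------------------


@dataclass
class PairScore:
    atom_a: int  # serial
    atom_b: int  # serial
    distance: float
    bin: int | None
    score: float


@dataclass
class ScoreReport:
    """Score decomposition for one frame: total = Σ per_pair = Σ per_residue."""

    frame_index: int
    total: float
    per_pair: list[PairScore]
    per_residue: dict[tuple[str, int, str], float]
    cofactor_residues: set[tuple[str, int, str]] = field(default_factory=set)
    reactive_pair: PairScore | None = None
    reactive_distance: float | None = None


def score_complex(
    potential: StatisticalPotential,
    frame: Frame,
    pocket,
    reactive_pair_spec: tuple[int, int] | None = None,
) -> ScoreReport:
    """Score all ligand × pocket-atom pairs of one frame.

    *pocket* is a PocketDefinition; partner atoms are every non-ligand atom
    whose residue belongs to the pocket (cofactor residues included when the
    pocket was built with ``include_cofactor``).  Pairs are listed in
    (ligand serial, partner serial) order for reproducible reports.
    """
    ligand_atoms = [a for a in frame.atoms if a.role == Role.LIGAND]
    pocket_residues = set(pocket.residues)
    partner_atoms = [
        a
        for a in frame.atoms
        if a.role != Role.LIGAND and a.residue_key in pocket_residues
    ]
    for a in ligand_atoms + partner_atoms:
        if a.atom_type is None:
            raise ValidationError(
                f"atom serial {a.serial} has no atom_type; run assign_atom_types first"
            )
    ligand_atoms.sort(key=lambda a: a.serial)
    partner_atoms.sort(key=lambda a: a.serial)

    per_pair: list[PairScore] = []
    per_residue: dict[tuple[str, int, str], float] = {a.residue_key: 0.0 for a in partner_atoms}
    total = 0.0
    for la in ligand_atoms:
        for pa in partner_atoms:
            d = float(np.linalg.norm(la.coords - pa.coords))
            if d <= 0:
                raise ValidationError(
                    f"coincident atoms: serials {la.serial} and {pa.serial}"
                )
            k = bin_index(d, potential.binning)
            s = pair_score(potential, la.atom_type, pa.atom_type, d)
            per_pair.append(PairScore(atom_a=la.serial, atom_b=pa.serial, distance=d, bin=k, score=s))
            per_residue[pa.residue_key] += s
            total += s

    reactive = None
    reactive_distance = None
    if reactive_pair_spec is not None:
        probe = frame.atom_by_serial(reactive_pair_spec[0])
        target = frame.atom_by_serial(reactive_pair_spec[1])
        d = float(np.linalg.norm(probe.coords - target.coords))
        k = bin_index(d, potential.binning) if d > 0 else None
        s = pair_score(potential, probe.atom_type or probe.element, target.atom_type or target.element, d) if d > 0 else 0.0
        reactive = PairScore(atom_a=probe.serial, atom_b=target.serial, distance=d, bin=k, score=s)
        reactive_distance = d

    cof = {a.residue_key for a in partner_atoms if a.role == Role.COFACTOR}
    return ScoreReport(
        frame_index=frame.index,
        total=total,
        per_pair=per_pair,
        per_residue=per_residue,
        cofactor_residues=cof,
        reactive_pair=reactive,
        reactive_distance=reactive_distance,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_potential(potential: StatisticalPotential, path) -> None:
    """Serialize to JSON; float repr round-trips losslessly."""
    payload = {
        "format": _FORMAT_NAME,
        "version": _FORMAT_VERSION,
        "binning": {
            "d_min": potential.binning.d_min,
            "d_max": potential.binning.d_max,
            "width": potential.binning.width,
        },
        "pseudocount": potential.pseudocount,
        "pair_tables": {
            "|".join(key): table.tolist() for key, table in sorted(potential.pair_tables.items())
        },
        "reference_table": potential.reference_table.tolist(),
        "provenance": potential.provenance,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_potential(path) -> StatisticalPotential:
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise PotentialFormatError(f"corrupt potential file: {exc}") from None
    if not isinstance(payload, dict) or payload.get("format") != _FORMAT_NAME:
        raise PotentialFormatError("not a conforma potential file")
    if payload.get("version") != _FORMAT_VERSION:
        raise PotentialFormatError(
            f"unsupported potential version {payload.get('version')!r}"
        )
    try:
        binning = DistanceBinning(**payload["binning"])
        pair_tables = {
            tuple(key.split("|")): np.asarray(table, dtype=float)
            for key, table in payload["pair_tables"].items()
        }
        return StatisticalPotential(
            binning=binning,
            pair_tables=pair_tables,  # type: ignore[arg-type]
            reference_table=np.asarray(payload["reference_table"], dtype=float),
            pseudocount=float(payload["pseudocount"]),
            provenance=payload.get("provenance", {}),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise PotentialFormatError(f"malformed potential payload: {exc}") from None


def read_contacts(path) -> list[ContactObservation]:
    """Read a contact database TSV/CSV with columns type_a, type_b, distance."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else None
    df = pd.read_csv(path, sep=sep, engine="python")
    missing = {"type_a", "type_b", "distance"} - set(df.columns)
    if missing:
        raise ValidationError(f"contact table missing columns: {sorted(missing)}")
    return [
        ContactObservation(str(a), str(b), float(d))
        for a, b, d in zip(df["type_a"], df["type_b"], df["distance"])
    ]


def write_contacts(contacts: Sequence[ContactObservation], path) -> None:
    df = pd.DataFrame(contacts, columns=["type_a", "type_b", "distance"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def report_to_tsv(report: ScoreReport, path) -> None:
    """Export one ScoreReport: pair rows then per-residue summary rows."""
    rows = []
    for p in report.per_pair:
        rows.append(
            {
                "record": "pair",
                "frame": report.frame_index,
                "atom_a": p.atom_a,
                "atom_b": p.atom_b,
                "distance_A": round(p.distance, 6),
                "bin": "" if p.bin is None else p.bin,
                "score": repr(p.score),
            }
        )
    for key in sorted(report.per_residue):
        chain, resnum, resname = key
        rows.append(
            {
                "record": "residue",
                "frame": report.frame_index,
                "atom_a": "",
                "atom_b": "",
                "distance_A": "",
                "bin": f"{chain}:{resnum}:{resname}",
                "score": repr(report.per_residue[key]),
            }
        )
    rows.append(
        {
            "record": "total",
            "frame": report.frame_index,
            "atom_a": "",
            "atom_b": "",
            "distance_A": "",
            "bin": "",
            "score": repr(report.total),
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
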