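import numpy as np
import pytest

from conforma.potential import ContactObservation, DistanceBinning, build_potential
from conforma.structure_io import AtomRecord, Ensemble, Frame, Role


def make_atom(
    serial,
    coords,
    name="CA",
    element="C",
    residue_name="ALA",
    residue_number=1,
    chain_id="A",
    role=Role.RECEPTOR,
    atom_type=None,
    is_hetatm=False,
):
    return AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        coords=np.asarray(coords, dtype=float),
        role=role,
        atom_type=atom_type,
        is_hetatm=is_hetatm,
    )


def make_frame(atoms, index=0, time_ps=None):
    return Frame(index=index, time_ps=float(index * 10.0 if time_ps is None else time_ps), atoms=atoms)


@pytest.fixture
def two_model_atoms():
    """Atom factory for a 5-atom topology used by several round-trip tests."""

    def build(offset):
        return [
            make_atom(1, [0.0 + offset, 0.0, 0.0], name="N", element="N"),
            make_atom(2, [1.4 + offset, 0.1, 0.0], name="CA", element="C"),
            make_atom(3, [2.2 + offset, 1.1, 0.5], name="C", element="C"),
            make_atom(4, [3.4 + offset, 1.0, 0.6], name="O", element="O"),
            make_atom(
                5,
                [5.0 + offset, 3.0, 1.0],
                name="FE",
                element="FE",
                residue_name="HEM",
                residue_number=99,
                is_hetatm=True,
            ),
        ]

    return build


@pytest.fixture
def two_model_ensemble(two_model_atoms):
    return Ensemble(
        frames=[
            make_frame(two_model_atoms(0.0), index=0, time_ps=0.0),
            make_frame(two_model_atoms(0.5), index=1, time_ps=10.0),
        ]
    )


@pytest.fixture
def toy_binning():
    return DistanceBinning(d_min=0.0, d_max=6.0, width=0.2)


@pytest.fixture
def toy_potential(toy_binning):
    rng = np.random.default_rng(7)
    contacts = [
        ContactObservation("C", "O", float(d))
        for d in rng.uniform(2.0, 4.0, size=300)
    ] + [
        ContactObservation("C", "N", float(d))
        for d in rng.uniform(3.5, 5.5, size=300)
    ]
    return build_potential(contacts, toy_binning, pseudocount=1.0)


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def oracle_potential_tables(contacts, d_min, d_max, width, alpha):
    """From-scratch histogram/pseudocount recount, independent of build_potential."""
    n_bins = int(round((d_max - d_min) / width))
    pair_counts = {}
    pooled = [0] * n_bins
    for a, b, d in contacts:
        key = tuple(sorted((a, b)))
        pair_counts.setdefault(key, [0] * n_bins)
        if d < d_min or d >= d_max or d <= 0:
            continue
        k = int((d - d_min) // width)
        if k == n_bins:
            k -= 1
        pair_counts[key][k] += 1
        pooled[k] += 1
    def norm(counts):
        tot = sum(counts) + alpha * n_bins
        return [(c + alpha) / tot for c in counts]
    tables = {k: norm(v) for k, v in pair_counts.items()}
    return tables, norm(pooled)


def oracle_pair_score(tables, reference, d_min, d_max, width, type_a, type_b, d):
    import math

    if d < d_min or d >= d_max:
        return 0.0
    k = int((d - d_min) // width)
    key = tuple(sorted((type_a, type_b)))
    p = tables.get(key, reference)[k]
    return -math.log(p / reference[k])
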