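"""Interface labeling by the heavy-atom distance rule and dataset curation."""

import numpy as np
import pytest

from rbsite.structures import (
    INTERFACE,
    NON_INTERFACE,
    UNRESOLVED,
    ChainStructure,
    CurationFilters,
    InterfaceLabeling,
    Residue,
    RNAComponent,
    UnresolvedConvention,
    apply_curation_filters,
    label_interface,
    parse_complex,
    read_labeled_table,
    write_labeled_table,
)

from conftest import brute_force_labels, random_complex


def single_residue_chain(distance):
    chain = ChainStructure("A", [Residue(1, "A", np.array([[distance, 0.0, 0.0]]))])
    rna = RNAComponent(np.array([[0.0, 0.0, 0.0]]), 1)
    return chain, rna


@pytest.mark.parametrize(
    "distance,expected",
    [(4.9, INTERFACE), (5.0, INTERFACE), (5.1, NON_INTERFACE)],
)
def test_cutoff_boundary_inclusive(distance, expected):
    chain, rna = single_residue_chain(distance)
    assert label_interface(chain, rna).labels[0] == expected


def test_line_geometry_matches_bruteforce_oracle():
    # residues on a line, RNA atom at residue 1: only nearby residues contact
    residues = [Residue(i + 1, "A", np.array([[3.0 * i, 0.0, 0.0]])) for i in range(10)]
    chain = ChainStructure("A", residues)
    rna = RNAComponent(np.array([[0.0, 0.0, 0.0]]), 1)
    got = label_interface(chain, rna).labels
    assert np.array_equal(got, brute_force_labels(chain, rna, 5.0))
    assert got[0] == INTERFACE and got[1] == INTERFACE and got[2] == NON_INTERFACE


@pytest.mark.parametrize("seed", range(8))
def test_random_clouds_match_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    chain, rna = random_complex(rng, n_residues=40, n_rna_atoms=60, unresolved_prob=0.1)
    got = label_interface(chain, rna).labels
    assert np.array_equal(got, brute_force_labels(chain, rna, 5.0))


def test_monotone_in_cutoff(rng):
    chain, rna = random_complex(rng, n_residues=30, n_rna_atoms=30)
    prev = set()
    for cutoff in (2.0, 5.0, 8.0, 12.0):
        iface = set(np.flatnonzero(label_interface(chain, rna, cutoff).labels == INTERFACE))
        assert prev <= iface
        prev = iface


def test_rigid_motion_invariance(rng):
    chain, rna = random_complex(rng, n_residues=25, n_rna_atoms=30)
    before = label_interface(chain, rna).labels
    # random rotation (QR of a Gaussian matrix) + translation, applied jointly
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    t = rng.uniform(-50, 50, size=3)
    moved = ChainStructure(
        "A",
        [
            Residue(r.sequence_index, r.amino_acid,
                    r.heavy_atom_coordinates @ Q.T + t if r.resolved else np.empty((0, 3)),
                    resolved=r.resolved)
            for r in chain.residues
        ],
    )
    moved_rna = RNAComponent(rna.atom_coordinates @ Q.T + t, rna.nucleotide_count)
    assert np.allclose(label_interface(moved, moved_rna).labels, before)


def test_empty_structure_is_error():
    chain = ChainStructure("A", [Residue(1, "A", np.empty((0, 3)), resolved=False)])
    rna = RNAComponent(np.array([[0.0, 0.0, 0.0]]), 1)
    with pytest.raises(ValueError, match="empty structure"):
        label_interface(chain, rna)


def test_zero_atom_rna_gives_all_non_interface():
    chain = ChainStructure("A", [Residue(1, "A", np.zeros((1, 3))),
                                 Residue(2, "A", np.ones((1, 3)))])
    labels = label_interface(chain, RNAComponent(np.empty((0, 3)), 0)).labels
    assert np.array_equal(labels, [NON_INTERFACE, NON_INTERFACE])


def test_unresolved_conventions():
    labeling = InterfaceLabeling("A", [1, -1, 0], UnresolvedConvention.NEGATIVE)
    assert np.array_equal(labeling.binary(), [1, 0, 0])
    labeling = InterfaceLabeling("A", [1, -1, 0], UnresolvedConvention.EXCLUDE)
    assert np.array_equal(labeling.binary(), [1, -1, 0])


def test_invalid_cutoff_rejected():
    chain, rna = single_residue_chain(1.0)
    with pytest.raises(ValueError):
        label_interface(chain, rna, cutoff_angstrom=0.0)


# -- curation ---------------------------------------------------------------

def _chain_of(n, atoms_per_residue=2):
    return ChainStructure(
        "A",
        [Residue(i + 1, "A", np.tile([[float(i), 0, 0]], (atoms_per_residue, 1))
                 + np.arange(atoms_per_residue)[:, None] * [0, 1.0, 0])
         for i in range(n)],
    )


def _labeling(n, n_interface):
    labels = np.zeros(n, dtype=int)
    labels[:n_interface] = 1
    return InterfaceLabeling("A", labels)


@pytest.mark.parametrize(
    "length,n_iface,accepted,reason",
    [
        (60, 4, False, "min_interface"),
        (39, 10, False, "min_length"),
        (40, 5, True, None),
    ],
)
def test_curation_boundaries(length, n_iface, accepted, reason):
    verdict = apply_curation_filters(_chain_of(length), _labeling(length, n_iface))
    assert verdict.accepted is accepted
    assert verdict.reason == reason


def test_curation_ca_only_and_resolution():
    chain = _chain_of(50, atoms_per_residue=1)
    assert apply_curation_filters(chain, _labeling(50, 10)).reason == "ca_only"
    chain = _chain_of(50)
    chain.metadata["resolution"] = 3.9
    assert apply_curation_filters(chain, _labeling(50, 10)).reason == "max_resolution"
    chain.metadata["resolution"] = 2.0
    chain.metadata["method"] = "solution nmr"
    assert apply_curation_filters(chain, _labeling(50, 10)).reason == "non_xray"
    chain.metadata["method"] = "x-ray diffraction"
    assert apply_curation_filters(chain, _labeling(50, 10)).accepted


def test_curation_mismatched_labeling_is_error():
    with pytest.raises(ValueError):
        apply_curation_filters(_chain_of(10), _labeling(9, 2))


# -- I/O --------------------------------------------------------------------

def test_labeled_table_round_trip(tmp_path):
    chain = _chain_of(6)
    labeling = InterfaceLabeling("A", [1, 0, -1, 0, 1, 0])
    path = tmp_path / "labels.tsv"
    write_labeled_table([(chain, labeling)], path)
    back = read_labeled_table(path)
    seq, labels = back["A"]
    assert seq == chain.sequence
    assert np.array_equal(labels, labeling.labels)


def test_toy_pdb_round_trip(tmp_path):
    from rbsite.synthetic import SyntheticComplexSpec, make_complex, write_toy_pdb

    chain, rna, truth = make_complex(SyntheticComplexSpec(25, 0.2, seed=3))
    path = tmp_path / "toy.pdb"
    write_toy_pdb(chain, rna, path)
    chains, rna_parsed = parse_complex(path)
    assert len(chains) == 1
    parsed = chains[0]
    assert parsed.sequence == chain.sequence
    assert rna_parsed.nucleotide_count == rna.nucleotide_count
    relabeled = label_interface(parsed, rna_parsed)
    assert np.array_equal(relabeled.labels, truth.labels)


def test_residue_invariants():
    with pytest.raises(ValueError):
        Residue(1, "A", np.empty((0, 3)), resolved=True)
    with pytest.raises(ValueError):
        Residue(1, "B", np.zeros((1, 3)))  # B is not an amino acid code
    with pytest.raises(ValueError):
        ChainStructure("A", [Residue(2, "A", np.zeros((1, 3))),
                             Residue(1, "A", np.zeros((1, 3)))])
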