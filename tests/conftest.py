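import numpy as np
import pytest

from rbsite.alignment import AlignmentStatistics, PairwiseAlignment
from rbsite.structures import ChainStructure, Residue, RNAComponent


def random_complex(rng, n_residues=30, n_rna_atoms=40, box=20.0, unresolved_prob=0.0):
    """Random coordinate clouds for oracle comparisons (not geometric toys)."""
    residues = []
    for i in range(n_residues):
        if rng.random() < unresolved_prob:
            residues.append(Residue(i + 1, "A", np.empty((0, 3)), resolved=False))
        else:
            coords = rng.uniform(0, box, size=(rng.integers(1, 4), 3))
            residues.append(Residue(i + 1, "A", coords))
    if not any(r.resolved for r in residues):
        residues[0] = Residue(1, "A", rng.uniform(0, box, size=(1, 3)))
    rna = RNAComponent(rng.uniform(0, box, size=(n_rna_atoms, 3)), n_rna_atoms)
    return ChainStructure("A", residues), rna


def brute_force_labels(chain, rna, cutoff):
    """All-pairs distance scan oracle for the interface rule."""
    labels = []
    for res in chain.residues:
        if not res.resolved:
            labels.append(-1)
            continue
        if len(rna.atom_coordinates) == 0:
            labels.append(0)
            continue
        dmin = min(
            float(np.linalg.norm(a - b))
            for a in res.heavy_atom_coordinates
            for b in rna.atom_coordinates
        )
        labels.append(1 if dmin <= cutoff else 0)
    return np.array(labels)


def identity_alignment(query_id, homolog_id, n, e_value=1e-50, positives=None, identities=None):
    return PairwiseAlignment(
        query_id=query_id,
        homolog_id=homolog_id,
        position_map=[(i + 1, i + 1) for i in range(n)],
        e_value=e_value,
        length=n,
        identities=n if identities is None else identities,
        positives=n if positives is None else positives,
        query_length=n,
        homolog_length=n,
    )


def make_stats(ps=0.8, is_=0.6, neg_log_e=30.0, log_l=2.0, frac_q=1.0, frac_h=1.0):
    return AlignmentStatistics(ps, is_, neg_log_e, log_l, frac_q, frac_h)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
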