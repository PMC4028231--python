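"""The synthetic-data generators: determinism and statistical targeting."""

import numpy as np
import pytest

from rbsite.homology import predict_query
from rbsite.ic_model import Zone
from rbsite.structures import INTERFACE, UNRESOLVED, label_interface
from rbsite.synthetic import (
    DB_E_CAP,
    SyntheticComplexSpec,
    SyntheticHomologSpec,
    flip_probability_for_correlation,
    invert_alignment_statistics,
    make_complex,
    make_homolog_db,
    make_pssm,
    write_toy_pdb,
)

from conftest import brute_force_labels


def test_complex_interface_count_by_construction():
    chain, rna, labeling = make_complex(SyntheticComplexSpec(20, 0.25, seed=0))
    assert labeling.n_interface == 5
    relabeled = label_interface(chain, rna)
    assert np.array_equal(relabeled.labels, labeling.labels)


def test_complex_matches_bruteforce_oracle():
    chain, rna, labeling = make_complex(SyntheticComplexSpec(40, 0.3, seed=2))
    assert np.array_equal(brute_force_labels(chain, rna, 5.0), labeling.labels)


def test_complex_deterministic_byte_identical(tmp_path):
    for run in ("a", "b"):
        chain, rna, _ = make_complex(SyntheticComplexSpec(30, 0.2, seed=9))
        write_toy_pdb(chain, rna, tmp_path / f"{run}.pdb")
    assert (tmp_path / "a.pdb").read_bytes() == (tmp_path / "b.pdb").read_bytes()


def test_complex_unresolved_fraction():
    _, _, labeling = make_complex(SyntheticComplexSpec(40, 0.25, unresolved_fraction=0.25, seed=1))
    assert int(np.sum(labeling.labels == UNRESOLVED)) == 10


def test_infeasible_interface_request_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        make_complex(SyntheticComplexSpec(20, 0.01, seed=0))


# -- conservation targeting -------------------------------------------------

def test_flip_probability_limits():
    labels = np.array([1, 1, 0, 0, 1, 0, 0, 0])
    assert flip_probability_for_correlation(labels, 1.0) == 0.0
    assert flip_probability_for_correlation(labels, -1.0) == 1.0
    assert flip_probability_for_correlation(labels, 0.0) == pytest.approx(0.5, abs=1e-9)


def test_flip_probability_monotone_in_target():
    labels = np.tile([1, 0, 0, 1, 0], 20)
    fs = [flip_probability_for_correlation(labels, t) for t in (-0.8, -0.3, 0.0, 0.4, 0.9)]
    assert all(b < a for a, b in zip(fs, fs[1:]))


def test_realized_correlation_near_target_for_long_chains():
    labels = (np.random.default_rng(30).random(500) < 0.3).astype(int)
    for k, target in enumerate((0.0, 0.5, 0.9)):
        rng = np.random.default_rng(100 + k)
        f = flip_probability_for_correlation(labels, target)
        flips = rng.random(500) < f
        hom = np.where(flips, 1 - labels, labels)
        realized = np.corrcoef(labels, hom)[0, 1] if len(set(hom)) > 1 else 0.0
        assert realized == pytest.approx(target, abs=0.1)


def test_invert_statistics_hits_target():
    from rbsite.alignment import compute_statistics
    from rbsite.ic_model import predict_ic
    from rbsite.alignment import PairwiseAlignment

    for target in (-0.1, 0.17, 0.45, 0.7, 0.85):
        e_value, positives = invert_alignment_statistics(target, 200)
        aln = PairwiseAlignment("q", "h", [(i + 1, i + 1) for i in range(200)],
                                e_value, 200, int(positives * 0.9), positives, 200, 200)
        stats = compute_statistics(aln, e_cap=DB_E_CAP)
        assert predict_ic(stats) == pytest.approx(target, abs=0.01)


def test_invert_statistics_unreachable_target_rejected():
    with pytest.raises(ValueError, match="unreachable"):
        invert_alignment_statistics(1.5, 200)


def test_homolog_db_zone_targeting():
    rng = np.random.default_rng(31)
    qlab = (rng.random(100) < 0.3).astype(int)
    db = make_homolog_db("q", qlab, [
        SyntheticHomologSpec("safe", 0.95, 0.8, seed=1),
        SyntheticHomologSpec("twi", 0.5, 0.5, seed=2),
        SyntheticHomologSpec("dark", 0.17, 0.17, seed=3),
        SyntheticHomologSpec("none", 0.05, 0.05, seed=4),
    ])
    zones = {h.alignment.homolog_id: h.zone for h in db.hits_for("q")}
    assert zones == {"safe": Zone.SAFE, "twi": Zone.TWILIGHT,
                     "dark": Zone.DARK, "none": Zone.NONE}


def test_perfect_homolog_recovers_query_labels():
    rng = np.random.default_rng(32)
    qlab = (rng.random(60) < 0.3).astype(int)
    db = make_homolog_db("q", qlab, [SyntheticHomologSpec("h", 1.0, 0.8, seed=5)])
    res = predict_query("q", 60, db.hits_for("q"))
    assert res.zone_used is Zone.SAFE
    assert np.array_equal(res.calls, qlab.astype(float))


def test_indels_leave_unaligned_positions_missing():
    rng = np.random.default_rng(33)
    qlab = (rng.random(80) < 0.3).astype(int)
    db = make_homolog_db("q", qlab, [SyntheticHomologSpec("h", 1.0, 0.8,
                                                          indel_rate=0.3, seed=6)])
    res = predict_query("q", 80, db.hits_for("q"))
    covered = ~np.isnan(res.scores)
    assert 0 < covered.sum() < 80
    assert np.array_equal(res.calls[covered], qlab[covered].astype(float))


def test_db_directory_round_trip(tmp_path):
    from rbsite.database import HomologDatabase

    rng = np.random.default_rng(34)
    qlab = (rng.random(50) < 0.3).astype(int)
    db = make_homolog_db("q", qlab, [SyntheticHomologSpec("h1", 0.8, 0.75, seed=7),
                                     SyntheticHomologSpec("h2", 0.3, 0.3, seed=8)])
    db.save(tmp_path / "db")
    back = HomologDatabase.load(tmp_path / "db")
    assert set(back.chains) == set(db.chains)
    assert back.e_cap == db.e_cap
    for cid in db.chains:
        assert back.sequence(cid) == db.sequence(cid)
        assert np.array_equal(back.labels(cid), db.labels(cid))
    a = {h.alignment.homolog_id: h.predicted_ic for h in db.hits_for("q")}
    b = {h.alignment.homolog_id: h.predicted_ic for h in back.hits_for("q")}
    assert a.keys() == b.keys()
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-9)


# -- PSSMs ------------------------------------------------------------------

def test_pssm_null_effect_distributions_match(rng):
    lab = rng.integers(0, 2, 400)
    pssm = make_pssm(lab, effect_size=0.0, seed=40)
    pos = pssm.matrix[lab == 1].mean(axis=0)
    neg = pssm.matrix[lab == 0].mean(axis=0)
    assert np.all(np.abs(pos - neg) < 0.8)  # no systematic class shift


def test_pssm_effect_shifts_signal_columns():
    rng = np.random.default_rng(41)
    lab = rng.integers(0, 2, 400)
    pssm = make_pssm(lab, signal_columns=(0, 1, 2), effect_size=4.0, seed=42)
    shift = pssm.matrix[lab == 1].mean(axis=0) - pssm.matrix[lab == 0].mean(axis=0)
    assert np.all(shift[:3] > 2.0)
    assert np.all(np.abs(shift[3:]) < 1.0)


def test_pssm_deterministic_and_bounded():
    lab = np.array([0, 1] * 20)
    a = make_pssm(lab, seed=43)
    b = make_pssm(lab, seed=43)
    assert np.array_equal(a.matrix, b.matrix) and a.sequence == b.sequence
    assert a.matrix.min() >= -10 and a.matrix.max() <= 12
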