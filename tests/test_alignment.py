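"""Alignment statistics and the interface-conservation score."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rbsite.alignment import (
    PairwiseAlignment,
    compute_statistics,
    ic_score,
    read_alignment_table,
    read_blast_xml,
    write_alignment_table,
)

from conftest import identity_alignment


def test_perfect_self_alignment_statistics():
    aln = identity_alignment("q", "h", 100, e_value=1e-50)
    s = compute_statistics(aln)
    assert s.positive_score == 1.0
    assert s.identity_score == 1.0
    assert s.log_l == pytest.approx(2.0)
    assert s.frac_query == s.frac_homolog == 1.0
    assert s.neg_log_e == pytest.approx(50.0)


def test_direct_ratios():
    aln = identity_alignment("q", "h", 100, positives=80, identities=60)
    s = compute_statistics(aln)
    assert s.positive_score == pytest.approx(0.8)
    assert s.identity_score == pytest.approx(0.6)


def test_zero_evalue_capped():
    aln = identity_alignment("q", "h", 50, e_value=0.0)
    assert compute_statistics(aln).neg_log_e == 200.0
    assert compute_statistics(aln, e_cap=99.0).neg_log_e == 99.0


def test_length_fraction_is_relative_to_shorter_chain():
    aln = PairwiseAlignment("q", "h", [(i + 1, i + 1) for i in range(50)],
                            1e-10, 50, 40, 45, 200, 50)
    s = compute_statistics(aln)
    assert s.frac_query == pytest.approx(0.25)
    assert s.frac_homolog == pytest.approx(1.0)
    assert s.length_fraction == pytest.approx(1.0)


def test_alignment_invariants_enforced():
    with pytest.raises(ValueError):  # identities > positives
        identity_alignment("q", "h", 10, positives=5, identities=7)
    with pytest.raises(ValueError):  # non-monotone map
        PairwiseAlignment("q", "h", [(2, 1), (1, 2)], 1e-5, 2, 2, 2, 5, 5)
    with pytest.raises(ValueError):  # mapped position beyond chain length
        PairwiseAlignment("q", "h", [(1, 1), (6, 2)], 1e-5, 2, 2, 2, 5, 5)


# -- IC score ---------------------------------------------------------------

def test_ic_boundary_cases_exact():
    q = np.array([1, 1, 0, 0, 1])
    assert ic_score(q, q).value == pytest.approx(1.0)
    assert ic_score(q, 1 - q).value == pytest.approx(-1.0)


def test_ic_equals_pearson_oracle():
    q = np.array([1, 1, 0, 0, 1])
    h = np.array([1, 0, 0, 0, 1])
    expected = np.corrcoef(q, h)[0, 1]
    assert ic_score(q, h).value == pytest.approx(expected, abs=1e-12)


def test_ic_equals_matthews_of_aligned_table(rng):
    from sklearn.metrics import matthews_corrcoef

    for _ in range(50):
        n = rng.integers(5, 60)
        q = rng.integers(0, 2, n)
        h = rng.integers(0, 2, n)
        res = ic_score(q, h)
        if res.degenerate:
            assert len(set(q)) == 1 or len(set(h)) == 1
            continue
        assert res.value == pytest.approx(matthews_corrcoef(q, h), abs=1e-10)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=40))
def test_ic_symmetric(pairs):
    q = np.array([a for a, _ in pairs])
    h = np.array([b for _, b in pairs])
    assert ic_score(q, h).value == pytest.approx(ic_score(h, q).value, abs=1e-12)


def test_ic_masks_unresolved_columns():
    q = np.array([1, -1, 0, 1, 0])
    h = np.array([1, 1, -1, 0, 0])
    # only columns 0, 3 and 4 are comparable
    res = ic_score(q, h)
    assert res.n_columns == 3
    assert not res.degenerate
    assert res.value == pytest.approx(np.corrcoef([1, 1, 0], [1, 0, 0])[0, 1], abs=1e-12)


def test_ic_empty_after_masking_is_error():
    with pytest.raises(ValueError, match="no comparable columns"):
        ic_score([-1, -1], [0, 1])


def test_ic_constant_vector_degenerate_flag():
    res = ic_score([1, 1, 1], [0, 1, 0])
    assert res.value == 0.0 and res.degenerate


# -- I/O --------------------------------------------------------------------

def test_alignment_table_round_trip(tmp_path, rng):
    alns = []
    for k in range(5):
        n = int(rng.integers(5, 30))
        qpos = np.sort(rng.choice(np.arange(1, 61), size=n, replace=False))
        hpos = np.sort(rng.choice(np.arange(1, 51), size=n, replace=False))
        alns.append(
            PairwiseAlignment(f"q{k}", f"h{k}", list(zip(qpos.tolist(), hpos.tolist())),
                              float(10.0 ** -rng.integers(1, 100)), n,
                              int(rng.integers(0, n // 2 + 1)), int(rng.integers(n // 2, n + 1)),
                              60, 50)
        )
    path = tmp_path / "alns.tsv"
    write_alignment_table(alns, path)
    back = read_alignment_table(path)
    assert len(back) == len(alns)
    for a, b in zip(alns, back):
        assert a.position_map == b.position_map
        sa, sb = compute_statistics(a), compute_statistics(b)
        assert sa == sb


BLAST_XML = """<?xml version="1.0"?>
<!DOCTYPE BlastOutput PUBLIC "-//NCBI//NCBI BlastOutput/EN" "NCBI_BlastOutput.dtd">
<BlastOutput>
  <BlastOutput_program>blastp</BlastOutput_program>
  <BlastOutput_version>BLASTP 2.2.27+</BlastOutput_version>
  <BlastOutput_reference>ref</BlastOutput_reference>
  <BlastOutput_db>db</BlastOutput_db>
  <BlastOutput_query-ID>Query_1</BlastOutput_query-ID>
  <BlastOutput_query-def>q1</BlastOutput_query-def>
  <BlastOutput_query-len>12</BlastOutput_query-len>
  <BlastOutput_param>
    <Parameters>
      <Parameters_matrix>BLOSUM62</Parameters_matrix>
      <Parameters_expect>10</Parameters_expect>
      <Parameters_gap-open>11</Parameters_gap-open>
      <Parameters_gap-extend>1</Parameters_gap-extend>
      <Parameters_filter>F</Parameters_filter>
    </Parameters>
  </BlastOutput_param>
  <BlastOutput_iterations>
    <Iteration>
      <Iteration_iter-num>1</Iteration_iter-num>
      <Iteration_query-ID>Query_1</Iteration_query-ID>
      <Iteration_query-def>q1</Iteration_query-def>
      <Iteration_query-len>12</Iteration_query-len>
      <Iteration_hits>
        <Hit>
          <Hit_num>1</Hit_num>
          <Hit_id>gnl|db|h1</Hit_id>
          <Hit_def>h1</Hit_def>
          <Hit_accession>h1</Hit_accession>
          <Hit_len>10</Hit_len>
          <Hit_hsps>
            <Hsp>
              <Hsp_num>1</Hsp_num>
              <Hsp_bit-score>40.0</Hsp_bit-score>
              <Hsp_score>90</Hsp_score>
              <Hsp_evalue>1e-08</Hsp_evalue>
              <Hsp_query-from>2</Hsp_query-from>
              <Hsp_query-to>11</Hsp_query-to>
              <Hsp_hit-from>1</Hsp_hit-from>
              <Hsp_hit-to>9</Hsp_hit-to>
              <Hsp_identity>7</Hsp_identity>
              <Hsp_positive>8</Hsp_positive>
              <Hsp_gaps>1</Hsp_gaps>
              <Hsp_align-len>10</Hsp_align-len>
              <Hsp_qseq>ACDEFGHIKL</Hsp_qseq>
              <Hsp_hseq>ACDEF-HIKL</Hsp_hseq>
              <Hsp_midline>ACDEF HIKL</Hsp_midline>
            </Hsp>
          </Hit_hsps>
        </Hit>
      </Iteration_hits>
      <Iteration_stat>
        <Statistics>
          <Statistics_db-num>1</Statistics_db-num>
          <Statistics_db-len>10</Statistics_db-len>
          <Statistics_hsp-len>0</Statistics_hsp-len>
          <Statistics_eff-space>120</Statistics_eff-space>
          <Statistics_kappa>0.041</Statistics_kappa>
          <Statistics_lambda>0.267</Statistics_lambda>
          <Statistics_entropy>0.14</Statistics_entropy>
        </Statistics>
      </Iteration_stat>
    </Iteration>
  </BlastOutput_iterations>
</BlastOutput>
"""


def test_blast_xml_parse(tmp_path):
    path = tmp_path / "blast.xml"
    path.write_text(BLAST_XML)
    alns = read_blast_xml(path)
    assert len(alns) == 1
    aln = alns[0]
    assert (aln.query_id, aln.homolog_id) == ("q1", "h1")
    assert aln.length == 10 and aln.identities == 7 and aln.positives == 8
    assert aln.query_length == 12 and aln.homolog_length == 10
    # gap column (query F aligned to -) is absent from the position map
    assert len(aln.position_map) == 9
    assert aln.position_map[0] == (2, 1)
    assert aln.position_map[-1] == (11, 9)
    s = compute_statistics(aln)
    assert s.neg_log_e == pytest.approx(8.0)
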