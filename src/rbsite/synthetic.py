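"""Deterministic synthetic data for every pipeline stage.

Every generator is a pure function of its seed(s), so tests and the
reproducibility study need no downloads and no external tools.  The
generators emulate the *statistical structure* the pipeline consumes —
interface geometry under the 5 Å rule, homolog databases with controlled
label conservation and alignment statistics landing in requested homology
zones, PSSMs with a planted class signal — not realistic protein geometry or
evolution.

Zone targeting note: under the shipped IC-model coefficients the positive
score contributes at most 0.6 to the predicted IC while the intercept is
−0.532, so predicted scores above the Safe cutoff (0.70) hinge on the
−log(E) term.  The synthetic database therefore emits extreme E-values
(down to underflow, E = 0) and carries an E-value cap of 744.4 in its config
(−ln of the smallest positive double, i.e. the natural-log reading of an
underflowed E-value); with that convention every zone is reachable and the
inversion below lands the predicted IC on the requested value up to the
integer quantization of the positives count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .alignment import PairwiseAlignment
from .database import HomologDatabase
from .ic_model import ICModel
from .structures import (
    AA_ALPHABET,
    INTERFACE,
    NON_INTERFACE,
    UNRESOLVED,
    ChainStructure,
    InterfaceLabeling,
    Residue,
    RNAComponent,
)
from .svm_window import PSSM

#: E-value underflow cap written into synthetic database configs (see module
#: docstring): −ln of the smallest positive double, i.e. the natural-log
#: reading of an underflowed E-value; chosen so all three homology zones are
#: reachable.
DB_E_CAP = 744.4

#: Residue spacing (Å) along the synthetic backbone; far above the 5 Å cutoff
#: so only deliberately placed RNA atoms create interface contacts.
_SPACING = 20.0
_CONTACT = 3.0


@dataclass
class SyntheticComplexSpec:
    """Recipe for a toy protein–RNA complex with a known interface."""

    chain_length: int = 50
    interface_fraction: float = 0.25
    unresolved_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.interface_fraction < 1.0:
            raise ValueError("interface_fraction must lie in (0, 1)")
        if not 0.0 <= self.unresolved_fraction < 1.0:
            raise ValueError("unresolved_fraction must lie in [0, 1)")
        if self.chain_length < 2:
            raise ValueError("chain_length must be >= 2")


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=length))


def make_complex(spec: SyntheticComplexSpec) -> tuple[ChainStructure, RNAComponent, InterfaceLabeling]:
    """Build a toy complex whose 5 Å labeling equals the planted interface.

    Residues sit on a line 20 Å apart (two heavy atoms each, so the chain is
    never CA-only); one RNA atom is placed 3 Å from each planted interface
    residue.  Raises on an infeasible request (no interface residue after
    rounding).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chain_length
    n_iface = round(spec.interface_fraction * L)
    if n_iface < 1:
        raise ValueError("infeasible geometry: interface would be empty")
    n_unres = round(spec.unresolved_fraction * L)
    order = rng.permutation(L)
    iface_idx = set(order[:n_iface].tolist())
    unres_idx = set(order[n_iface : n_iface + n_unres].tolist())

    seq = random_sequence(L, rng)
    residues = []
    rna_atoms = []
    labels = np.full(L, NON_INTERFACE, dtype=int)
    for i in range(L):
        if i in unres_idx:
            residues.append(Residue(i + 1, seq[i], np.empty((0, 3)), resolved=False))
            labels[i] = UNRESOLVED
            continue
        x = i * _SPACING
        coords = np.array([[x, 0.0, 0.0], [x, 1.5, 0.0]])
        residues.append(Residue(i + 1, seq[i], coords))
        if i in iface_idx:
            rna_atoms.append([x, -_CONTACT, 0.0])
            labels[i] = INTERFACE
    chain = ChainStructure("A", residues, {"resolution": 2.0, "method": "x-ray diffraction"})
    rna = RNAComponent(np.array(rna_atoms), nucleotide_count=len(rna_atoms))
    return chain, rna, InterfaceLabeling("A", labels)


def write_toy_pdb(chain: ChainStructure, rna: RNAComponent, path) -> None:
    """Write the toy complex in PDB format (protein chain A, RNA chain B)."""
    aa3 = {v: k for k, v in {
        "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
        "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
        "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
        "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    }.items()}
    def atom_line(serial, name, resname, chain_id, resnum, x, y, z, element):
        # PDB fixed columns: name 13-16, altloc 17, resname 18-20, chain 22,
        # resseq 23-26, coords 31-54, element 77-78
        return (
            f"ATOM  {serial:5d} {name:<4s} {resname:>3s} {chain_id}{resnum:4d}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
        )

    serial = 1
    lines = [
        "HEADER    SYNTHETIC COMPLEX",
        "EXPDTA    X-RAY DIFFRACTION",
        "REMARK   2 RESOLUTION.    2.00 ANGSTROMS.",
    ]
    for res in chain.residues:
        if not res.resolved:
            continue
        resname = aa3.get(res.amino_acid, "GLY")
        for j, (x, y, z) in enumerate(res.heavy_atom_coordinates):
            name = "CA" if j == 0 else "CB"
            lines.append(
                atom_line(serial, name, resname, "A", res.sequence_index, x, y, z, "C")
            )
            serial += 1
    for k, (x, y, z) in enumerate(rna.atom_coordinates, start=1):
        lines.append(atom_line(serial, "P", "A", "B", k, x, y, z, "P"))
        serial += 1
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Homolog databases with controlled conservation
# ---------------------------------------------------------------------------

def flip_probability_for_correlation(labels: np.ndarray, target: float) -> float:
    """Per-position flip probability whose expected label correlation equals
    ``target`` for the given binary label vector.

    Flipping each label independently with probability f gives
    corr(f) = (1 − 2f)·sqrt(Var_q / Var_h(f)); the unique root in [0, 1] is
    solved numerically (closed form up to the root solve).
    """
    q = np.asarray(labels, dtype=int)
    p = float(np.mean(q == 1))
    if not 0.0 < p < 1.0:
        raise ValueError("label vector must contain both classes")
    if not -1.0 <= target <= 1.0:
        raise ValueError("target correlation must lie in [-1, 1]")
    var_q = p * (1 - p)

    def corr(f: float) -> float:
        mu = p * (1 - f) + (1 - p) * f
        var_h = mu * (1 - mu)
        return (1 - 2 * f) * math.sqrt(var_q / var_h)

    if target >= 1.0:
        return 0.0
    if target <= -1.0:
        return 1.0
    return float(brentq(lambda f: corr(f) - target, 1e-12, 1 - 1e-12))


@dataclass
class SyntheticHomologSpec:
    """Recipe for one database homolog of a given query.

    ``target_ic`` sets the expected conservation of the homolog's labels;
    ``target_predicted_ic`` (defaults to ``target_ic``) sets where the
    emitted alignment statistics land under the default IC model, hence the
    hit's homology zone.  ``indel_rate`` removes query positions from the
    alignment (coverage gaps).
    """

    name: str
    target_ic: float = 0.9
    target_predicted_ic: float | None = None
    indel_rate: float = 0.0
    positive_score: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.target_ic <= 1.0:
            raise ValueError("target_ic must lie in [-1, 1]")
        if not 0.0 <= self.indel_rate < 1.0:
            raise ValueError("indel_rate must lie in [0, 1)")


def invert_alignment_statistics(
    target_predicted_ic: float,
    alignment_length: int,
    model: ICModel | None = None,
    e_cap: float = DB_E_CAP,
    ps_range: tuple[float, float] = (0.05, 0.93),
) -> tuple[float, int]:
    """Choose (E-value, positives) so the predicted IC hits the target.

    With length fractions pinned at 1 the model leaves two free statistics;
    the positive score is kept inside ``ps_range`` (its ceiling below the
    0.95 similarity-exclusion cutoff) and the remainder is assigned to the
    −log10(E) term, using a representable E-value when that suffices and an
    underflowed E = 0 (read back as ``e_cap``) otherwise.  Raises when the
    target is unreachable under these conventions.
    """
    model = model or ICModel()
    m = alignment_length
    base = model.intercept + model.coef_log_l * math.log10(m) + model.coef_length_fraction * 1.0
    needed = target_predicted_ic - base
    b1, b3 = model.coef_neg_log_e, model.coef_positive_score
    ps_min, ps_max = ps_range

    x = (needed - b3 * ps_max) / b1
    if x < 1.0:
        x = 1.0
    if x <= 300.0:
        # ceil keeps the recomputed positive score at or below its ceiling
        x = float(math.ceil(x - 1e-9))
        ps = (needed - b1 * x) / b3
    else:
        x = float(e_cap)
        ps = (needed - b1 * e_cap) / b3
    if not ps_min - 1e-9 <= ps <= ps_max + 1e-9:
        raise ValueError(
            f"target predicted IC {target_predicted_ic} unreachable "
            f"(requires positive score {ps:.3f} outside {ps_range})"
        )
    e_value = 0.0 if x == float(e_cap) and x > 300.0 else 10.0 ** (-x)
    positives = int(round(min(max(ps, ps_min), ps_max) * m))
    return e_value, max(1, positives)


def make_homolog_db(
    query_id: str,
    query_labels,
    specs: list[SyntheticHomologSpec],
    model: ICModel | None = None,
    e_cap: float = DB_E_CAP,
) -> HomologDatabase:
    """Build a synthetic homolog database for one query.

    Each spec yields one homolog chain (labels flipped from the query's to
    hit ``target_ic`` in expectation, indels applied after label assignment
    so the position map stays correct) and one alignment record whose
    statistics land the predicted IC on ``target_predicted_ic`` under the
    default model and this database's E-cap convention.
    """
    qlab = np.asarray(query_labels, dtype=int)
    LQ = len(qlab)
    chains: dict[str, tuple[str, np.ndarray]] = {}
    alignments: list[PairwiseAlignment] = []
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        keep = rng.random(LQ) >= spec.indel_rate
        resolved = qlab != UNRESOLVED
        keep &= resolved
        if keep.sum() < 2:
            raise ValueError(f"homolog {spec.name}: alignment too short")
        qpos = np.flatnonzero(keep) + 1
        m = len(qpos)
        aligned_q = qlab[keep]
        f = flip_probability_for_correlation(aligned_q, spec.target_ic)
        flips = rng.random(m) < f
        hlab = np.where(flips, 1 - aligned_q, aligned_q)
        target_pred = (
            spec.target_ic if spec.target_predicted_ic is None else spec.target_predicted_ic
        )
        e_value, positives = invert_alignment_statistics(
            target_pred, m, model, e_cap,
            ps_range=(0.05, 0.93) if spec.positive_score is None
            else (spec.positive_score, spec.positive_score),
        )
        identities = max(0, int(0.9 * positives))
        aln = PairwiseAlignment(
            query_id=query_id,
            homolog_id=spec.name,
            position_map=[(int(q), j + 1) for j, q in enumerate(qpos)],
            e_value=e_value,
            length=m,
            identities=identities,
            positives=positives,
            query_length=LQ,
            homolog_length=m,
        )
        chains[spec.name] = (random_sequence(m, rng), hlab.astype(int))
        alignments.append(aln)
    return HomologDatabase(chains, alignments, e_cap=e_cap)


# ---------------------------------------------------------------------------
# Synthetic PSSMs
# ---------------------------------------------------------------------------

def make_pssm(
    labels,
    signal_columns=(0, 1, 2),
    effect_size: float = 4.0,
    seed: int = 0,
    protein_id: str = "synthetic",
    sequence: str | None = None,
) -> PSSM:
    """Synthetic PSSM: integer background scores uniform on [−3, 2] (the
    range typical log-odds concentrate in), with
    interface rows shifted by ``effect_size`` on the signal columns; values
    clipped to the ASCII dialect's [−10, 12] range."""
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    lab = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    mat = rng.integers(-3, 3, size=(len(lab), 20)).astype(float)
    for col in signal_columns:
        mat[lab == 1, col] += effect_size
    mat = np.clip(np.round(mat), -10, 12)
    if sequence is None:
        sequence = random_sequence(len(lab), rng)
    return PSSM(protein_id, mat, sequence=sequence)


def make_chain_dataset(
    n_chains: int,
    chain_length: int = 60,
    interface_fraction: float = 0.3,
    signal_columns=(0, 1, 2),
    effect_size: float = 4.0,
    seed: int = 0,
    signal_offsets: tuple[int, ...] = (0,),
):
    """Labeled PSSM chains for SVM experiments.

    ``signal_offsets`` plants the class signal at the given window offsets
    relative to the labeled residue (e.g. ``(-2, 2)`` puts signal only on
    neighbours, so narrow windows cannot see it).
    """
    from .svm_window import ChainSample

    rng = np.random.default_rng(seed)
    chains = []
    for c in range(n_chains):
        lab = (rng.random(chain_length) < interface_fraction).astype(int)
        if lab.sum() == 0:
            lab[rng.integers(chain_length)] = 1
        if lab.sum() == chain_length:
            lab[rng.integers(chain_length)] = 0
        mat = rng.integers(-3, 3, size=(chain_length, 20)).astype(float)
        for i in np.flatnonzero(lab == 1):
            for off in signal_offsets:
                j = i + off
                if 0 <= j < chain_length:
                    for col in signal_columns:
                        mat[j, col] += effect_size
        mat = np.clip(np.round(mat), -10, 12)
        pssm = PSSM(f"chain{c:03d}", mat, sequence=random_sequence(chain_length, rng))
        chains.append(ChainSample(f"chain{c:03d}", pssm, lab))
    return chains
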