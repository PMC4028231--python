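"""Protein–RNA complex structures and per-residue interface labels.

An *interface residue* is an amino acid with at least one heavy (non-hydrogen)
atom within a distance cutoff (default 5 Å) of any atom of the bound RNA in a
solved complex.  This module parses PDB-format complexes, extracts per-chain
interface labelings under that rule, and applies the dataset-curation filters
used to build non-redundant training/benchmark sets (minimum chain length,
minimum interface size, resolution / experiment-type / CA-only exclusions).

Residues absent from the coordinate section ("unresolved") cannot be labeled
from geometry; two conventions are supported: exclude them from downstream
counting, or count them as non-interface (the training convention).
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

#: Per-residue label values.
INTERFACE = 1
NON_INTERFACE = 0
UNRESOLVED = -1

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

_RNA_RESNAMES = {"A", "C", "G", "U", "I", "RA", "RC", "RG", "RU"}


class UnresolvedConvention(str, enum.Enum):
    """How residues without coordinates are labeled."""

    EXCLUDE = "exclude-unresolved"
    NEGATIVE = "unresolved-as-negative"


@dataclass
class Residue:
    """One amino acid of a chain.

    ``heavy_atom_coordinates`` is an (n_atoms, 3) float array in Å; empty for
    unresolved residues.  ``author_number`` preserves the file's numbering as
    metadata only — positions are always the sequential 1-based index.
    """

    sequence_index: int
    amino_acid: str
    heavy_atom_coordinates: np.ndarray
    resolved: bool = True
    author_number: int | None = None

    def __post_init__(self) -> None:
        self.heavy_atom_coordinates = np.asarray(
            self.heavy_atom_coordinates, dtype=float
        ).reshape(-1, 3)
        if self.resolved != (len(self.heavy_atom_coordinates) > 0):
            raise ValueError(
                "resolved flag inconsistent with coordinate count for residue "
                f"{self.sequence_index}"
            )
        if self.amino_acid not in AA_ALPHABET and self.amino_acid != "X":
            raise ValueError(f"unknown amino acid code {self.amino_acid!r}")


@dataclass
class ChainStructure:
    """An ordered protein chain with heavy-atom coordinates."""

    chain_id: str
    residues: list[Residue]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = [r.sequence_index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("sequence_index must be strictly increasing")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.amino_acid for r in self.residues)

    @property
    def n_resolved(self) -> int:
        return sum(r.resolved for r in self.residues)

    def is_ca_only(self) -> bool:
        """True when every resolved residue has exactly one heavy atom."""
        resolved = [r for r in self.residues if r.resolved]
        return bool(resolved) and all(
            len(r.heavy_atom_coordinates) == 1 for r in resolved
        )


@dataclass
class RNAComponent:
    """All atoms of the RNA partner(s) in a complex."""

    atom_coordinates: np.ndarray
    nucleotide_count: int = 0

    def __post_init__(self) -> None:
        self.atom_coordinates = np.asarray(
            self.atom_coordinates, dtype=float
        ).reshape(-1, 3)
        if self.nucleotide_count < 0:
            raise ValueError("nucleotide_count must be >= 0")
        if not np.all(np.isfinite(self.atom_coordinates)):
            raise ValueError("RNA coordinates must be finite")


@dataclass
class InterfaceLabeling:
    """Per-residue interface labels for one chain.

    ``labels[i]`` is INTERFACE, NON_INTERFACE or UNRESOLVED for the residue at
    sequential position i+1.
    """

    chain_id: str
    labels: np.ndarray
    convention: UnresolvedConvention = UnresolvedConvention.NEGATIVE

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        bad = set(np.unique(self.labels)) - {INTERFACE, NON_INTERFACE, UNRESOLVED}
        if bad:
            raise ValueError(f"invalid label values: {sorted(bad)}")

    @property
    def n_interface(self) -> int:
        return int(np.sum(self.labels == INTERFACE))

    def binary(self) -> np.ndarray:
        """Labels with UNRESOLVED mapped per the convention.

        Under EXCLUDE the unresolved entries stay -1 and must be masked by the
        caller; under NEGATIVE they become 0.
        """
        out = self.labels.copy()
        if self.convention is UnresolvedConvention.NEGATIVE:
            out[out == UNRESOLVED] = NON_INTERFACE
        return out


def label_interface(
    chain: ChainStructure,
    rna: RNAComponent,
    cutoff_angstrom: float = 5.0,
    convention: UnresolvedConvention | str = UnresolvedConvention.NEGATIVE,
) -> InterfaceLabeling:
    """Label each residue interface/non-interface by the heavy-atom rule.

    A residue is an interface residue iff the minimum distance between any of
    its heavy atoms and any RNA atom is <= ``cutoff_angstrom`` (inclusive at
    the boundary).  Unresolved residues are labeled UNRESOLVED; how they are
    treated downstream follows ``convention``.

    Raises
    ------
    ValueError
        If ``cutoff_angstrom`` <= 0 or the chain has no resolved residues
        ("empty structure").  An RNA with zero atoms is *not* an error: every
        resolved residue is then non-interface.
    """
    convention = UnresolvedConvention(convention)
    if cutoff_angstrom <= 0:
        raise ValueError("cutoff_angstrom must be positive")
    if chain.n_resolved == 0:
        raise ValueError(f"empty structure: chain {chain.chain_id!r} has no resolved residues")

    labels = np.full(len(chain), UNRESOLVED, dtype=int)
    if len(rna.atom_coordinates) == 0:
        for i, res in enumerate(chain.residues):
            if res.resolved:
                labels[i] = NON_INTERFACE
        return InterfaceLabeling(chain.chain_id, labels, convention)

    tree = cKDTree(rna.atom_coordinates)
    for i, res in enumerate(chain.residues):
        if not res.resolved:
            continue
        dmin, _ = tree.query(res.heavy_atom_coordinates, k=1)
        labels[i] = INTERFACE if float(np.min(dmin)) <= cutoff_angstrom else NON_INTERFACE
    return InterfaceLabeling(chain.chain_id, labels, convention)


@dataclass
class CurationFilters:
    """Dataset-curation thresholds.

    Chains are rejected when the interface has fewer than ``min_interface``
    residues or the chain is shorter than ``min_length`` amino acids; optional
    metadata-based rules reject low-resolution, non-X-ray and CA-only entries.
    """

    min_interface: int = 5
    min_length: int = 40
    max_resolution: float = 3.5
    require_xray: bool = True
    exclude_ca_only: bool = True


@dataclass
class CurationResult:
    accepted: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.accepted


def apply_curation_filters(
    chain: ChainStructure,
    labeling: InterfaceLabeling,
    params: CurationFilters | None = None,
) -> CurationResult:
    """Accept or reject a labeled chain for database construction.

    Metadata-dependent rules (resolution, experiment type) are skipped with a
    logged warning when the metadata is absent; the geometric CA-only check
    runs whenever coordinates exist.
    """
    params = params or CurationFilters()
    if len(labeling.labels) != len(chain):
        raise ValueError("labeling does not correspond to chain")

    if len(chain) < params.min_length:
        return CurationResult(False, "min_length")
    if labeling.n_interface < params.min_interface:
        return CurationResult(False, "min_interface")

    resolution = chain.metadata.get("resolution")
    if resolution is None:
        logger.warning("chain %s: no resolution metadata, rule skipped", chain.chain_id)
    elif resolution > params.max_resolution:
        return CurationResult(False, "max_resolution")

    method = chain.metadata.get("method")
    if params.require_xray:
        if method is None:
            logger.warning("chain %s: no method metadata, rule skipped", chain.chain_id)
        elif "x-ray" not in str(method).lower():
            return CurationResult(False, "non_xray")

    if params.exclude_ca_only and chain.n_resolved > 0 and chain.is_ca_only():
        return CurationResult(False, "ca_only")

    return CurationResult(True)


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def _residue_heavy_atoms(res) -> np.ndarray:
    coords = []
    for atom in res.get_atoms():
        # DisorderedAtom resolves to the highest-occupancy altloc by default.
        if atom.element in ("H", "D"):
            continue
        coords.append(atom.coord)
    return np.asarray(coords, dtype=float).reshape(-1, 3)


def parse_complex(
    path: str | Path,
    protein_chains: Sequence[str] | None = None,
    fill_gaps: bool = True,
) -> tuple[list[ChainStructure], RNAComponent]:
    """Parse a PDB-format protein–RNA complex.

    Returns the protein chains (optionally restricted to ``protein_chains``)
    and a single :class:`RNAComponent` pooling all nucleic-acid atoms in the
    file.  With ``fill_gaps`` true, jumps in the author residue numbering
    within a chain are filled with unresolved ``X`` residues so that
    sequential positions approximate the full chain.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("cplx", str(path))
    model = next(structure.get_models())

    header = structure.header or {}
    meta = {
        "resolution": header.get("resolution") or None,
        "method": header.get("structure_method") or None,
    }

    chains: list[ChainStructure] = []
    rna_coords: list[np.ndarray] = []
    rna_nt = 0
    for pdb_chain in model:
        residues: list[Residue] = []
        prev_author = None
        seq_idx = 0
        for res in pdb_chain:
            hetflag, author_num, _ = res.id
            resname = res.get_resname().strip()
            if resname in _RNA_RESNAMES:
                coords = _residue_heavy_atoms(res)
                if len(coords):
                    rna_coords.append(coords)
                    rna_nt += 1
                continue
            if hetflag != " " or resname not in _THREE_TO_ONE:
                continue
            if fill_gaps and prev_author is not None and author_num > prev_author + 1:
                for _ in range(author_num - prev_author - 1):
                    seq_idx += 1
                    residues.append(
                        Residue(seq_idx, "X", np.empty((0, 3)), resolved=False)
                    )
            coords = _residue_heavy_atoms(res)
            seq_idx += 1
            residues.append(
                Residue(
                    seq_idx,
                    _THREE_TO_ONE.get(resname, "X"),
                    coords,
                    resolved=len(coords) > 0,
                    author_number=author_num,
                )
            )
            prev_author = author_num
        if residues and (protein_chains is None or pdb_chain.id in protein_chains):
            chains.append(ChainStructure(pdb_chain.id, residues, dict(meta)))

    rna = RNAComponent(
        np.vstack(rna_coords) if rna_coords else np.empty((0, 3)),
        nucleotide_count=rna_nt,
    )
    return chains, rna


# ---------------------------------------------------------------------------
# Labeled-sequence table and FASTA output
# ---------------------------------------------------------------------------

_LABEL_NAMES = {INTERFACE: "interface", NON_INTERFACE: "non-interface", UNRESOLVED: "unresolved"}
_NAME_LABELS = {v: k for k, v in _LABEL_NAMES.items()}


def write_labeled_table(
    pairs: Iterable[tuple[ChainStructure, InterfaceLabeling]],
    path: str | Path,
) -> None:
    """Write per-residue labels as TSV: chain_id, position, amino_acid, label."""
    with open(path, "w") as fh:
        fh.write("chain_id\tposition\tamino_acid\tlabel\n")
        for chain, labeling in pairs:
            for res, lab in zip(chain.residues, labeling.labels):
                fh.write(
                    f"{chain.chain_id}\t{res.sequence_index}\t{res.amino_acid}\t"
                    f"{_LABEL_NAMES[int(lab)]}\n"
                )


def read_labeled_table(path: str | Path) -> dict[str, tuple[str, np.ndarray]]:
    """Read a labeled-sequence TSV back as {chain_id: (sequence, labels)}."""
    seqs: dict[str, list[str]] = {}
    labs: dict[str, list[int]] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chain_id", "position", "amino_acid", "label"]:
            raise ValueError(f"unexpected labeled-table header: {header}")
        for line in fh:
            cid, pos, aa, label = line.rstrip("\n").split("\t")
            seqs.setdefault(cid, []).append(aa)
            labs.setdefault(cid, []).append(_NAME_LABELS[label])
            if int(pos) != len(seqs[cid]):
                raise ValueError(f"non-sequential position for chain {cid}")
    return {cid: ("".join(seqs[cid]), np.array(labs[cid], dtype=int)) for cid in seqs}


def write_fasta(chains: Iterable[ChainStructure], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(c.sequence), id=c.chain_id, description="") for c in chains
    ]
    seqio_write(records, str(path), "fasta")
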