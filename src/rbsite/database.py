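"""Homolog database: labeled RNA-binding chains plus precomputed alignments.

A database directory mirrors what a BLAST-searchable collection of protein
chains with experimentally known interface residues needs to support
homology transfer without external tools:

    db/
      index.tsv        chain_id, length, n_interface
      sequences.fasta  chain sequences
      labels.tsv       per-residue labels (structures module table format)
      alignments.tsv   optional precomputed query-vs-db alignment table
      config.txt       statistics conventions (E-value underflow cap, log base)

Searching with external BLAST against the FASTA is supported by the CLI; the
test path and the synthetic study consume ``alignments.tsv`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alignment import (
    DEFAULT_E_CAP,
    PairwiseAlignment,
    compute_statistics,
    read_alignment_table,
    write_alignment_table,
)
from .homology import HomologHit
from .ic_model import ICModel, ZoneThresholds, assign_zone, predict_ic
from .structures import read_labeled_table


@dataclass
class HomologDatabase:
    """In-memory homolog database: {chain_id: (sequence, labels)}."""

    chains: dict[str, tuple[str, np.ndarray]]
    alignments: list[PairwiseAlignment] = field(default_factory=list)
    e_cap: float = DEFAULT_E_CAP
    log_base: float = 10.0

    def __len__(self) -> int:
        return len(self.chains)

    def labels(self, chain_id: str) -> np.ndarray:
        return self.chains[chain_id][1]

    def sequence(self, chain_id: str) -> str:
        return self.chains[chain_id][0]

    def hits_for(
        self,
        query_id: str,
        model: ICModel | None = None,
        thresholds: ZoneThresholds | None = None,
        alignments: list[PairwiseAlignment] | None = None,
    ) -> list[HomologHit]:
        """Annotate this database's alignments for one query as homolog hits
        (statistics computed under the database's E-cap / log-base
        conventions)."""
        pool = self.alignments if alignments is None else alignments
        hits = []
        for aln in pool:
            if aln.query_id != query_id or aln.homolog_id not in self.chains:
                continue
            stats = compute_statistics(aln, e_cap=self.e_cap, log_base=self.log_base)
            w = predict_ic(stats, model)
            hits.append(
                HomologHit(aln, stats, w, assign_zone(w, thresholds), self.labels(aln.homolog_id))
            )
        return hits

    # -- directory round trip -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "sequences.fasta", "w") as fh:
            for cid, (seq, _) in sorted(self.chains.items()):
                fh.write(f">{cid}\n{seq}\n")
        with open(directory / "labels.tsv", "w") as fh:
            fh.write("chain_id\tposition\tamino_acid\tlabel\n")
            names = {1: "interface", 0: "non-interface", -1: "unresolved"}
            for cid, (seq, labels) in sorted(self.chains.items()):
                for i, (aa, lab) in enumerate(zip(seq, labels), start=1):
                    fh.write(f"{cid}\t{i}\t{aa}\t{names[int(lab)]}\n")
        with open(directory / "index.tsv", "w") as fh:
            fh.write("chain_id\tlength\tn_interface\n")
            for cid, (seq, labels) in sorted(self.chains.items()):
                fh.write(f"{cid}\t{len(seq)}\t{int(np.sum(labels == 1))}\n")
        with open(directory / "config.txt", "w") as fh:
            fh.write(f"e_cap = {self.e_cap!r}\nlog_base = {self.log_base!r}\n")
        write_alignment_table(self.alignments, directory / "alignments.tsv")

    @classmethod
    def load(cls, directory: str | Path) -> "HomologDatabase":
        directory = Path(directory)
        chains = read_labeled_table(directory / "labels.tsv")
        config = {"e_cap": DEFAULT_E_CAP, "log_base": 10.0}
        cfg_path = directory / "config.txt"
        if cfg_path.exists():
            for line in cfg_path.read_text().splitlines():
                key, _, value = line.partition("=")
                if key.strip() in config:
                    config[key.strip()] = float(value)
        aln_path = directory / "alignments.tsv"
        alignments = read_alignment_table(aln_path) if aln_path.exists() else []
        return cls(chains, alignments, **config)
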