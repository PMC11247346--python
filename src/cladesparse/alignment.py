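"""Per-gene alignment reading and one-hot encoding.

A phylogenomic dataset is a collection of per-gene multiple sequence
alignments (one FASTA file per gene); taxa may be absent from individual
genes.  For supervised sparse learning the alignments are turned into a
binary design matrix: one row per taxon, and for every polymorphic site
one indicator column per residue character observed at that site.  Genes
map to contiguous column blocks, which is what the group penalty of the
solver acts on.

Gap and ambiguity characters are treated as "no state": they never get a
column of their own and contribute 0 everywhere.  A (taxon, gene) pair
with no sequence at all is an all-zero block and is flagged in
``missing_mask`` so downstream reports can distinguish "absent data"
from "zero concordance".
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneAlignment",
    "EncodedDataset",
    "read_gene_fastas",
    "one_hot_encode",
]

GAP_CHARS = {"-", ".", "?", "*"}
AA_AMBIGUOUS = {"X", "B", "Z", "J"}
# IUPAC nucleotide ambiguity codes (everything that is not a concrete base).
NT_AMBIGUOUS = {"N", "R", "Y", "S", "W", "K", "M", "B", "D", "H", "V"}
NT_BASES = {"A", "C", "G", "T", "U"}


class AlignmentError(ValueError):
    """Malformed alignment input (ragged lengths, duplicates, empty file)."""


@dataclasses.dataclass
class GeneAlignment:
    """One gene's aligned sequences keyed by taxon id."""

    gene_id: str
    sequences: dict[str, str]
    length: int
    alphabet: str  # "amino_acid" | "nucleotide"

    def __post_init__(self) -> None:
        for taxon, seq in self.sequences.items():
            if len(seq) != self.length:
                raise AlignmentError(
                    f"gene {self.gene_id!r}: sequence for {taxon!r} has length "
                    f"{len(seq)}, expected {self.length}"
                )
        if self.alphabet not in ("amino_acid", "nucleotide"):
            raise AlignmentError(f"unknown alphabet {self.alphabet!r}")

    @property
    def taxa(self) -> set[str]:
        return set(self.sequences)

    def no_state_chars(self) -> set[str]:
        amb = NT_AMBIGUOUS if self.alphabet == "nucleotide" else AA_AMBIGUOUS
        return GAP_CHARS | amb


@dataclasses.dataclass
class EncodedDataset:
    """One-hot design matrix with gene-level grouping.

    ``group_map`` maps gene id -> (start, stop) half-open column range;
    the ranges partition the columns of ``X`` in order.  ``missing_mask``
    is taxa x genes, True where the taxon has no sequence for the gene.
    ``column_meta`` has one row per column: (gene_id, site, residue),
    site being the 0-based column index within the gene's alignment.
    """

    X: np.ndarray
    group_map: dict[str, tuple[int, int]]
    taxon_order: list[str]
    y: np.ndarray
    missing_mask: np.ndarray
    column_meta: pd.DataFrame

    @property
    def n_taxa(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.group_map)

    def gene_index(self, gene_id: str) -> int:
        return self.gene_ids.index(gene_id)

    def taxon_index(self, taxon: str) -> int:
        return self.taxon_order.index(taxon)

    def group_starts(self) -> np.ndarray:
        return np.array([a for a, _ in self.group_map.values()], dtype=np.intp)

    def group_sizes(self) -> np.ndarray:
        return np.array([b - a for a, b in self.group_map.values()], dtype=np.intp)

    def member_taxa(self) -> list[str]:
        return [t for t, yv in zip(self.taxon_order, self.y) if yv > 0]

    def column_meta_tsv(self, path: str | Path) -> None:
        """Audit dump of the column map (1-based site coordinates)."""
        meta = self.column_meta.copy()
        meta["site"] = meta["site"] + 1
        meta.insert(0, "column", np.arange(len(meta)))
        meta.to_csv(path, sep="\t", index=False)


def _detect_alphabet(residues: set[str]) -> str:
    informative = {r for r in residues if r not in GAP_CHARS}
    if informative and informative <= (NT_BASES | NT_AMBIGUOUS):
        return "nucleotide"
    return "amino_acid"


def read_gene_fastas(paths: Iterable[str | Path]) -> list[GeneAlignment]:
    """Read one FASTA alignment per path; gene id is the file-name stem.

    Sequences are uppercased on read.  Raises :class:`AlignmentError` for
    an empty file, ragged sequence lengths, or a duplicated taxon header.
    """
    genes = []
    for path in paths:
        path = Path(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise AlignmentError(f"{path}: no sequences found")
        sequences: dict[str, str] = {}
        length = len(records[0].seq)
        for rec in records:
            if rec.id in sequences:
                raise AlignmentError(f"{path}: duplicate taxon header {rec.id!r}")
            seq = str(rec.seq).upper()
            if len(seq) != length:
                raise AlignmentError(
                    f"{path}: sequence {rec.id!r} has length {len(seq)}, "
                    f"but {records[0].id!r} has length {length} "
                    "(alignment is ragged)"
                )
            sequences[rec.id] = seq
        residues = set().union(*(set(s) for s in sequences.values()))
        genes.append(
            GeneAlignment(
                gene_id=path.stem,
                sequences=sequences,
                length=length,
                alphabet=_detect_alphabet(residues),
            )
        )
    return genes


def read_manifest(manifest: str | Path) -> list[GeneAlignment]:
    """Read gene alignments listed one path per line in a manifest file."""
    manifest = Path(manifest)
    paths = []
    for line in manifest.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            p = Path(line)
            paths.append(p if p.is_absolute() else manifest.parent / p)
    return read_gene_fastas(paths)


def one_hot_encode(
    genes: Sequence[GeneAlignment],
    taxa: Sequence[str],
    y: Sequence[int] | np.ndarray,
    drop_monomorphic: bool = True,
) -> EncodedDataset:
    """Build the grouped one-hot design matrix for the given taxon set.

    For each (gene, site) one indicator column is created per residue
    character observed among the non-missing taxa, in ASCII order.  Sites
    monomorphic across the non-missing taxa carry no signal and are
    dropped by default.  Gaps/ambiguity codes produce no column and no 1.
    """
    taxa = list(taxa)
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (len(taxa),):
        raise ValueError("y must align with taxa")
    if not np.all(np.isin(y, (-1.0, 1.0))):
        raise ValueError("y entries must be +1 or -1")
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon in taxa")

    covered = set().union(*(g.taxa for g in genes)) if genes else set()
    orphans = [t for t in taxa if t not in covered]
    if orphans:
        raise ValueError(f"taxa absent from every gene: {orphans}")

    n = len(taxa)
    blocks: list[np.ndarray] = []
    group_map: dict[str, tuple[int, int]] = {}
    meta_rows: list[tuple[str, int, str]] = []
    missing_mask = np.zeros((n, len(genes)), dtype=bool)
    col = 0

    for gi, gene in enumerate(genes):
        no_state = gene.no_state_chars()
        present = [ti for ti, t in enumerate(taxa) if t in gene.sequences]
        missing_mask[:, gi] = True
        missing_mask[present, gi] = False
        # residue matrix for present taxa: (n_present, length)
        seqs = [gene.sequences[taxa[ti]] for ti in present]
        start = col
        for site in range(gene.length):
            states = [s[site] for s in seqs]
            residues = sorted({c for c in states if c not in no_state})
            if drop_monomorphic and len(residues) < 2:
                continue
            if not residues:
                continue
            for residue in residues:
                colvec = np.zeros(n, dtype=np.float64)
                for ti, c in zip(present, states):
                    if c == residue:
                        colvec[ti] = 1.0
                blocks.append(colvec)
                meta_rows.append((gene.gene_id, site, residue))
                col += 1
        group_map[gene.gene_id] = (start, col)

    if col == 0:
        raise ValueError("no informative columns after filtering")

    X = np.column_stack(blocks)
    column_meta = pd.DataFrame(meta_rows, columns=["gene", "site", "residue"])
    return EncodedDataset(
        X=X,
        group_map=group_map,
        taxon_order=taxa,
        y=y,
        missing_mask=missing_mask,
        column_meta=column_meta,
    )
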