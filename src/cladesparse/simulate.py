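"""Synthetic phylogenomic fixtures with known clade structure.

The generator emulates the situation the diagnostics target: a dataset
of many gene alignments in which a designated clade is monophyletic,
most genes carry clade-diagnostic site patterns, a minority carry
discordant patterns (a pseudo-clade mixing taxa from both sides), and
introgression-like contamination can be planted by swapping one gene's
sequences between an in-clade and an out-clade taxon.

Sequence generation is pattern-based rather than a substitution-process
simulation along branches: every gene has a set of diagnostic sites at
which clade members share a residue absent from the outside group (whose
own modal residue differs), while the remaining sites follow a shared
background residue with independent per-taxon noise.  Sparse learning
consumes site patterns, so this keeps the planted signal analytically
controllable — which genes support the clade, and how strongly, is known
exactly.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import warnings
from pathlib import Path

import dendropy
import numpy as np

from .alignment import GeneAlignment
from .phylogeny import CladeHypothesis

__all__ = ["SimConfig", "SwapRecord", "simulate_dataset", "plant_swaps", "write_dataset"]

NT_RESIDUES = "ACGT"
AA_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

CLADE_LABEL = "FOCAL"


@dataclasses.dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a desk-scale dataset: a 20-member clade against 20
    outside taxa, 30 genes of 200 aligned sites, 10% of sites
    diagnostic in supporting genes, 3 discordant genes, and 5% per-taxon
    background noise.  ``missing_rate`` (27%) matches the per-gene taxon
    coverage typical of published phylogenomic supermatrices, where a
    gene is often sequenced for only two-thirds of the taxa;
    ``partial_rate`` is the chance a present sequence is truncated by a
    contiguous gap span (30-70% of sites), as ragged alignments are in
    practice.  Partial coverage is what makes single genes insufficient
    classifiers, so fitted clade models combine several genes, as they
    do on real data.
    """

    n_in: int = 20
    n_out: int = 20
    n_genes: int = 30
    sites_per_gene: int = 200
    p_support: float = 0.1
    n_discordant_genes: int = 3
    missing_rate: float = 0.27
    partial_rate: float = 0.3
    alphabet: str = "nucleotide"
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_in", "n_out", "n_genes", "sites_per_gene"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("p_support", "missing_rate", "partial_rate", "noise"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_discordant_genes < 0 or self.n_discordant_genes >= self.n_genes:
            raise ValueError("n_discordant_genes must be in [0, n_genes)")
        if self.alphabet not in ("nucleotide", "amino_acid"):
            raise ValueError("alphabet must be nucleotide or amino_acid")

    @property
    def residues(self) -> str:
        return NT_RESIDUES if self.alphabet == "nucleotide" else AA_RESIDUES


@dataclasses.dataclass(frozen=True)
class SwapRecord:
    """One planted contamination event."""

    gene_id: str
    taxon_in: str
    taxon_out: str
    mode: str  # "reciprocal" | "nonreciprocal"


@dataclasses.dataclass
class SimResult:
    genes: list[GeneAlignment]
    tree: dendropy.Tree
    hypothesis: CladeHypothesis
    truth: dict  # diagnostic sites, discordant genes, per-gene signal


def _random_subtree(labels: list[str], rng: np.random.Generator) -> str:
    """Random bifurcating Newick subtree over the labels, with branch lengths."""
    if len(labels) == 1:
        return f"{labels[0]}:{rng.uniform(0.05, 0.5):.4f}"
    labels = list(labels)
    rng.shuffle(labels)
    k = int(rng.integers(1, len(labels)))
    left = _random_subtree(labels[:k], rng)
    right = _random_subtree(labels[k:], rng)
    return f"({left},{right}):{rng.uniform(0.05, 0.5):.4f}"


def _build_tree(cfg: SimConfig, rng: np.random.Generator) -> tuple[str, list[str], list[str]]:
    ins = [f"in{i:02d}" for i in range(1, cfg.n_in + 1)]
    outs = [f"out{i:02d}" for i in range(1, cfg.n_out + 1)]
    clade = _random_subtree(ins, rng)
    # strip the root-edge length of the clade subtree so we can label it
    core = clade.rsplit(":", 1)[0]
    blen = clade.rsplit(":", 1)[1]
    clade = f"{core}{CLADE_LABEL}:{blen}" if core.startswith("(") else clade
    outside = _random_subtree(outs, rng)
    return f"({clade},{outside});", ins, outs


def simulate_dataset(cfg: SimConfig) -> SimResult:
    """Generate gene alignments, the species tree, and the hypothesis.

    Fully reproducible from ``cfg.seed``.  Supporting genes carry a
    Binomial(sites, p_support) number of diagnostic sites (resampled if
    zero, with a warning after 100 attempts) at which the clade is
    perfectly separated from the outside group; discordant genes give the
    diagnostic residue to a random mixed subset of taxa instead.
    """
    rng = np.random.default_rng(cfg.seed)
    newick, ins, outs = _build_tree(cfg, rng)
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    hypothesis = CladeHypothesis(
        source="newick_tree",
        clade_taxa=set(ins),
        all_taxa=ins + outs,
        tree=tree,
        clade_id=CLADE_LABEL,
    )

    residues = cfg.residues
    taxa = ins + outs
    n_taxa = len(taxa)
    in_idx = np.arange(len(ins))

    discordant = sorted(
        int(i) for i in rng.choice(cfg.n_genes, cfg.n_discordant_genes, replace=False)
    )
    genes: list[GeneAlignment] = []
    truth: dict = {
        "clade": ins,
        "discordant_genes": [],
        "diagnostic_sites": {},
        "n_diagnostic": {},
    }

    for g in range(cfg.n_genes):
        gene_id = f"gene{g + 1:03d}"
        n_diag = int(rng.binomial(cfg.sites_per_gene, cfg.p_support))
        attempts = 0
        while n_diag == 0:
            attempts += 1
            if attempts == 100:
                warnings.warn(
                    f"{gene_id}: 100 resamples needed to obtain a diagnostic site"
                )
            n_diag = int(rng.binomial(cfg.sites_per_gene, cfg.p_support))
        diag_sites = np.sort(
            rng.choice(cfg.sites_per_gene, n_diag, replace=False)
        )

        if g in discordant:
            # pseudo-clade: a mixed subset of in- and out-clade taxa
            k_in = int(rng.integers(1, len(ins)))
            k_out = int(rng.integers(1, len(outs)))
            members = np.concatenate(
                [
                    rng.choice(len(ins), k_in, replace=False),
                    len(ins) + rng.choice(len(outs), k_out, replace=False),
                ]
            )
        else:
            members = in_idx

        member_mask = np.zeros(n_taxa, dtype=bool)
        member_mask[members] = True

        seq = np.empty((n_taxa, cfg.sites_per_gene), dtype="<U1")
        for site in range(cfg.sites_per_gene):
            modal = residues[int(rng.integers(len(residues)))]
            chars = np.full(n_taxa, modal, dtype="<U1")
            noisy = rng.random(n_taxa) < cfg.noise
            others = [r for r in residues if r != modal]
            chars[noisy] = rng.choice(others, int(noisy.sum()))
            seq[:, site] = chars
        for site in diag_sites:
            # clade members share r_in; outside taxa carry a distinct
            # modal residue r_out with homoplasious noise that may hit
            # any other residue, r_in included (as real data do)
            r_in = residues[int(rng.integers(len(residues)))]
            others = [r for r in residues if r != r_in]
            r_out = others[int(rng.integers(len(others)))]
            chars = np.full(n_taxa, r_out, dtype="<U1")
            noisy = (~member_mask) & (rng.random(n_taxa) < cfg.noise)
            alt = [r for r in residues if r != r_out]
            chars[noisy] = rng.choice(alt, int(noisy.sum()))
            chars[member_mask] = r_in
            seq[:, site] = chars

        # partial coverage: a contiguous gap span truncates some sequences
        if cfg.partial_rate > 0:
            for ti in range(n_taxa):
                if rng.random() < cfg.partial_rate:
                    span = int(cfg.sites_per_gene * rng.uniform(0.3, 0.7))
                    start = int(rng.integers(0, cfg.sites_per_gene - span + 1))
                    seq[ti, start:start + span] = "-"

        sequences = {t: "".join(seq[i]) for i, t in enumerate(taxa)}
        genes.append(
            GeneAlignment(
                gene_id=gene_id,
                sequences=sequences,
                length=cfg.sites_per_gene,
                alphabet=cfg.alphabet,
            )
        )
        truth["diagnostic_sites"][gene_id] = [int(s) for s in diag_sites]
        truth["n_diagnostic"][gene_id] = int(n_diag)
        if g in discordant:
            truth["discordant_genes"].append(gene_id)

    # missingness: drop (taxon, gene) pairs, keeping every taxon in >= 1
    # gene and >= 2 taxa of each class in every gene; per-gene rates are
    # heterogeneous (uniform on [0, 2*missing_rate]) so some genes are
    # near-complete and others sparse, as real supermatrices are
    if cfg.missing_rate > 0:
        lo = min(0.1, cfg.missing_rate)
        gene_rates = rng.uniform(lo, 2 * cfg.missing_rate - lo, cfg.n_genes)
        drop = rng.random((n_taxa, cfg.n_genes)) < gene_rates[None, :]
        for ti in range(n_taxa):
            if drop[ti].all():
                drop[ti, int(rng.integers(cfg.n_genes))] = False
        for g in range(cfg.n_genes):
            for side in (np.arange(len(ins)), np.arange(len(ins), n_taxa)):
                while (~drop[side, g]).sum() < 2:
                    dropped = side[drop[side, g]]
                    drop[int(rng.choice(dropped)), g] = False
        for g, gene in enumerate(genes):
            for ti, t in enumerate(taxa):
                if drop[ti, g]:
                    gene.sequences.pop(t, None)

    return SimResult(genes=genes, tree=tree, hypothesis=hypothesis, truth=truth)


def plant_swaps(
    genes: list[GeneAlignment],
    hypothesis: CladeHypothesis,
    target_gene: str,
    mode: str,
    n_replicates: int = 100,
    seed: int = 0,
) -> list[tuple[list[GeneAlignment], SwapRecord]]:
    """Plant introgression-like contamination in one gene.

    Per replicate, one in-clade and one out-clade taxon (both carrying
    the target gene) are chosen uniformly at random.  ``reciprocal``
    exchanges their sequences for that gene; ``nonreciprocal`` copies the
    outside sequence over the member's (the outside taxon is untouched).
    Only the target gene is modified.
    """
    if mode not in ("reciprocal", "nonreciprocal"):
        raise ValueError("mode must be reciprocal or nonreciprocal")
    rng = np.random.default_rng(seed)
    gene = next((g for g in genes if g.gene_id == target_gene), None)
    if gene is None:
        raise KeyError(f"gene {target_gene!r} not found")
    ins = sorted(t for t in gene.sequences if t in hypothesis.clade_taxa)
    outs = sorted(t for t in gene.sequences if t not in hypothesis.clade_taxa)
    if not ins or not outs:
        raise ValueError(
            f"gene {target_gene!r} is missing from all taxa on one side"
        )

    out_sets = []
    for _ in range(n_replicates):
        t_in = ins[int(rng.integers(len(ins)))]
        t_out = outs[int(rng.integers(len(outs)))]
        mutated = []
        for g in genes:
            if g.gene_id != target_gene:
                mutated.append(g)
                continue
            g2 = copy.deepcopy(g)
            if mode == "reciprocal":
                g2.sequences[t_in], g2.sequences[t_out] = (
                    g2.sequences[t_out],
                    g2.sequences[t_in],
                )
            else:
                g2.sequences[t_in] = g2.sequences[t_out]
            mutated.append(g2)
        out_sets.append(
            (mutated, SwapRecord(target_gene, t_in, t_out, mode))
        )
    return out_sets


def write_dataset(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA per gene, the labelled Newick tree, a response file, a
    manifest of gene paths, and a JSON ground-truth record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    manifest_lines = []
    for gene in result.genes:
        p = outdir / f"{gene.gene_id}.fasta"
        with open(p, "w") as fh:
            for taxon in sorted(gene.sequences):
                fh.write(f">{taxon}\n{gene.sequences[taxon]}\n")
        manifest_lines.append(p.name)
    paths["manifest"] = outdir / "genes.txt"
    paths["manifest"].write_text("\n".join(manifest_lines) + "\n")
    paths["tree"] = outdir / "species.nwk"
    paths["tree"].write_text(
        result.tree.as_string(schema="newick", suppress_rooting=True)
    )
    paths["response"] = outdir / "response.txt"
    paths["response"].write_text(
        "\n".join(
            f"{t}\t{'+1' if t in result.hypothesis.clade_taxa else '-1'}"
            for t in result.hypothesis.all_taxa
        )
        + "\n"
    )
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(result.truth, indent=1))
    return paths
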