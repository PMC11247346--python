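"""Clade hypothesis parsing and phylogeny-aware class balancing.

The clade of interest defines a binary response over taxa: +1 for every
species inside the (hypothesised monophyletic) clade, -1 for everyone
else.  The hypothesis comes either from a rooted Newick tree whose
internal node carrying the clade label is identified by name, or from a
plain two-column response file.

Logistic models are sensitive to class imbalance, and in phylogenomics
the outside group is usually much larger than the clade.  Balancing is
phylogeny-aware: the outside taxa kept are the closest sister lineages
of the clade (walking rootward from the clade node), and any residual
excess is trimmed by repeatedly removing one random member of the
closest remaining pair of outside leaves.  When the clade itself is the
larger class, no taxon is dropped; the minority class is up-weighted
instead.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import dendropy
import numpy as np

__all__ = ["CladeHypothesis", "BalanceResult", "parse_hypothesis", "balance_classes"]


class HypothesisError(ValueError):
    """Invalid clade hypothesis input."""


@dataclasses.dataclass
class CladeHypothesis:
    source: str  # "newick_tree" | "response_file"
    clade_taxa: set[str]
    all_taxa: list[str]
    tree: dendropy.Tree | None = None
    clade_id: str | None = None

    def __post_init__(self) -> None:
        if not self.clade_taxa:
            raise HypothesisError("clade of interest is empty")
        if not self.clade_taxa < set(self.all_taxa):
            raise HypothesisError(
                "clade of interest must be a proper subset of all taxa"
            )

    def response(self) -> np.ndarray:
        return np.array(
            [1.0 if t in self.clade_taxa else -1.0 for t in self.all_taxa]
        )


@dataclasses.dataclass
class BalanceResult:
    selected_taxa: list[str]
    y: np.ndarray
    class_weights: dict[int, float]
    removed_taxa: list[tuple[str, str]]  # (taxon, reason)
    scenario: str  # "1" | "2" | "balanced"


def _leaf_labels(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def parse_hypothesis(
    tree_file: str | Path | None = None,
    response_file: str | Path | None = None,
    clade_id: str | None = None,
) -> CladeHypothesis:
    """Build the clade hypothesis from a Newick tree or a response file.

    Exactly one of ``tree_file`` (with ``clade_id`` naming a labelled
    internal node) and ``response_file`` (two columns: taxon, +1/-1) is
    given.
    """
    if (tree_file is None) == (response_file is None):
        raise HypothesisError("provide exactly one of tree_file / response_file")

    if tree_file is not None:
        if clade_id is None:
            raise HypothesisError("clade_id is required with a tree")
        tree = dendropy.Tree.get(
            path=str(tree_file), schema="newick", preserve_underscores=True
        )
        target = None
        labels = []
        for node in tree.preorder_node_iter():
            if node.is_leaf():
                continue
            if node.label:
                labels.append(node.label)
                if node.label == clade_id:
                    target = node
        if target is None:
            raise HypothesisError(
                f"clade id {clade_id!r} not found; labelled internal nodes: "
                f"{labels or '(none)'}"
            )
        all_taxa = _leaf_labels(tree.seed_node)
        clade_taxa = set(_leaf_labels(target))
        if clade_taxa == set(all_taxa):
            raise HypothesisError("clade of interest contains all taxa")
        return CladeHypothesis(
            source="newick_tree",
            clade_taxa=clade_taxa,
            all_taxa=all_taxa,
            tree=tree,
            clade_id=clade_id,
        )

    all_taxa: list[str] = []
    clade_taxa: set[str] = set()
    for ln, line in enumerate(Path(response_file).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise HypothesisError(f"response file line {ln}: expected 2 columns")
        taxon, value = parts
        if value not in ("1", "+1", "-1"):
            raise HypothesisError(
                f"response file line {ln}: value {value!r} is not +1/-1"
            )
        all_taxa.append(taxon)
        if value in ("1", "+1"):
            clade_taxa.add(taxon)
    return CladeHypothesis(
        source="response_file", clade_taxa=clade_taxa, all_taxa=all_taxa
    )


def _pairwise_distances(
    tree: dendropy.Tree, taxa: list[str], metric: str = "patristic"
) -> dict[tuple[str, str], float]:
    """Patristic distances among the named leaves; edge-count fallback
    (with a warning) when any edge lacks a branch length."""
    has_lengths = metric == "patristic" and all(
        e.length is not None
        for e in tree.preorder_edge_iter()
        if e.head_node is not tree.seed_node
    )
    if metric == "patristic" and not has_lengths:
        warnings.warn(
            "tree has edges without branch lengths; using edge-count distances",
            stacklevel=3,
        )
    pdm = tree.phylogenetic_distance_matrix()
    namespace = {t.label: t for t in tree.taxon_namespace}
    out = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            key = tuple(sorted((a, b)))
            if has_lengths:
                out[key] = pdm.patristic_distance(namespace[a], namespace[b])
            else:
                out[key] = pdm.path_edge_count(namespace[a], namespace[b])
    return out


def _find_clade_node(tree: dendropy.Tree, clade_taxa: set[str]) -> dendropy.Node:
    for node in tree.preorder_internal_node_iter():
        if set(_leaf_labels(node)) == clade_taxa:
            return node
    raise HypothesisError("clade of interest is not monophyletic in the tree")


def balance_classes(
    h: CladeHypothesis,
    seed: int = 0,
    distance: str = "patristic",
) -> BalanceResult:
    """Equalise (or re-weight) the clade / non-clade classes.

    Scenario 1 (clade smaller): keep the closest successive sister
    lineages of the clade until at least as many outside taxa are
    retained as clade members, then trim the surplus by removing one
    random member of the closest remaining outside pair until the counts
    match.  Scenario 2 (clade larger): keep every taxon and weight the
    outside class by S_+1/S_-1.  Already balanced: identity.
    """
    rng = np.random.default_rng(seed)
    plus = [t for t in h.all_taxa if t in h.clade_taxa]
    minus = [t for t in h.all_taxa if t not in h.clade_taxa]
    s_plus, s_minus = len(plus), len(minus)

    def result(selected, removed, weights, scenario):
        if sum(1 for t in selected if t in h.clade_taxa) < 2:
            raise HypothesisError("fewer than 2 clade members after balancing")
        if sum(1 for t in selected if t not in h.clade_taxa) < 2:
            raise HypothesisError("fewer than 2 outside taxa after balancing")
        y = np.array([1.0 if t in h.clade_taxa else -1.0 for t in selected])
        return BalanceResult(
            selected_taxa=list(selected),
            y=y,
            class_weights=weights,
            removed_taxa=removed,
            scenario=scenario,
        )

    if s_plus == s_minus:
        return result(list(h.all_taxa), [], {1: 1.0, -1: 1.0}, "balanced")

    if s_plus > s_minus:
        w = s_plus / s_minus
        return result(list(h.all_taxa), [], {1: 1.0, -1: w}, "2")

    # Scenario 1: clade is the minority.
    removed: list[tuple[str, str]] = []
    if h.tree is None:
        warnings.warn(
            "scenario-1 balancing without a tree: down-sampling the outside "
            "class at random",
            stacklevel=2,
        )
        keep = sorted(rng.choice(minus, size=s_plus, replace=False).tolist())
        removed = [(t, "random_downsample") for t in minus if t not in keep]
        retained = set(keep)
        selected = [t for t in h.all_taxa if t in h.clade_taxa or t in retained]
        return result(selected, removed, {1: 1.0, -1: 1.0}, "1")

    clade_node = _find_clade_node(h.tree, h.clade_taxa)

    # Rootward sister walk: accumulate sibling subtrees until the outside
    # pool is at least the clade size.
    pool: list[str] = []
    node = clade_node
    while len(pool) < s_plus and node.parent_node is not None:
        parent = node.parent_node
        for sib in parent.child_nodes():
            if sib is not node:
                pool.extend(
                    lf for lf in _leaf_labels(sib) if lf not in h.clade_taxa
                )
        node = parent
    if len(pool) < s_plus:
        pool = list(minus)  # degenerate topology; use everyone outside
    removed.extend(
        (t, "outside_sister_walk") for t in minus if t not in set(pool)
    )

    # Trim the surplus: repeatedly drop one random member of the closest
    # remaining pair (lexicographic pair order breaks distance ties).
    if len(pool) > s_plus:
        metric = "topological" if distance == "topological" else "patristic"
        dists = _pairwise_distances(h.tree, sorted(pool), metric=metric)
        remaining = set(pool)
        while len(remaining) > s_plus:
            best = min(
                (
                    (d, pair)
                    for pair, d in dists.items()
                    if pair[0] in remaining and pair[1] in remaining
                ),
                key=lambda item: (item[0], item[1]),
            )
            victim = best[1][int(rng.integers(2))]
            remaining.discard(victim)
            removed.append((victim, "closest_pair_trim"))
        pool = [t for t in pool if t in remaining]

    retained = set(pool)
    selected = [t for t in h.all_taxa if t in h.clade_taxa or t in retained]
    res = result(selected, removed, {1: 1.0, -1: 1.0}, "1")
    n_plus = int(np.sum(res.y > 0))
    n_minus = int(np.sum(res.y < 0))
    assert n_plus == n_minus, "scenario-1 postcondition: classes must be equal"
    return res
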