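"""Taxonomic distances and taxonomy-tree UniFrac.

Without marker-gene phylogenies, between-genus relatedness is read off the
ranked taxonomy: two genera are close when their lineages agree over many
consecutive ranks from the top down. That ultrametric has an exact tree
realization — the rank hierarchy itself with unit branch lengths — which is
what the UniFrac family needs. Generalized UniFrac interpolates between
presence/absence (alpha -> 0 down-weights abundant branches) and the
weighted-normalized form (alpha = 1) via

    d_alpha(A, B) = sum_i b_i (pA_i + pB_i)^alpha |pA_i - pB_i| / (pA_i + pB_i)
                    -----------------------------------------------------------
                    sum_i b_i (pA_i + pB_i)^alpha

summing over branches i with subtree proportion totals pA_i, pB_i and
lengths b_i; branches unoccupied in both samples are skipped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode

from .tables import ProportionTable, TaxonomyTable, UNCLASSIFIED


def _lineage_keys(tax: TaxonomyTable, genus: str) -> list[tuple]:
    """Prefix keys for each rank level; unclassified ranks are made private
    to the genus so they never merge with anything (including each other)."""
    lineage = tax.lineage(genus)
    keys: list[tuple] = []
    prefix: list[str] = []
    private = False
    for depth, label in enumerate(lineage):
        if label == UNCLASSIFIED or private:
            # once a rank is unclassified the remaining path is private
            private = True
            prefix.append(f"{UNCLASSIFIED}:{genus}:{depth}")
        else:
            prefix.append(label)
        keys.append(tuple(prefix))
    return keys


def taxonomic_distance(tax: TaxonomyTable) -> DistanceMatrix:
    """Genus x genus distance 1 - k/L, with k the number of consecutive
    top-down ranks at which the lineages agree (an ``unclassified`` label
    matches nothing, not even another ``unclassified``)."""
    genera = tax.genus_ids
    L = tax.n_ranks
    keys = {g: _lineage_keys(tax, g) for g in genera}
    n = len(genera)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        ki, kj = keys[genera[i]], keys[genera[j]]
        k = 0
        while k < L and ki[k] == kj[k]:
            k += 1
        d[i, j] = d[j, i] = 1.0 - k / L
    return DistanceMatrix(d, ids=genera)


def taxonomy_to_tree(tax: TaxonomyTable) -> TreeNode:
    """Materialize the rank hierarchy as a rooted tree with unit branch
    lengths; every leaf (genus) sits at depth L, so leaf-to-leaf path length
    divided by 2L reproduces :func:`taxonomic_distance`."""
    root = TreeNode(name="root")
    nodes: dict[tuple, TreeNode] = {(): root}
    for genus in tax.genus_ids:
        parent_key: tuple = ()
        for depth, key in enumerate(_lineage_keys(tax, genus)):
            if key not in nodes:
                is_leaf = depth == tax.n_ranks - 1
                node = TreeNode(name=genus if is_leaf else key[-1], length=1.0)
                nodes[parent_key].append(node)
                nodes[key] = node
            parent_key = key
    return root


def _branch_profile(tree: TreeNode, props: ProportionTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-branch (non-root node) subtree proportion totals for each sample.

    Returns (lengths, node x sample matrix, sample ids), excluding samples
    flagged empty (they are dropped from the output matrix, never imputed).
    """
    samples = [s for s in props.sample_ids if s not in props.empty_samples]
    leaf_names = {leaf.name for leaf in tree.tips()}
    extra = [g for g in props.genus_ids if g not in leaf_names]
    if extra:
        raise ValueError(f"proportion rows not in tree: {extra[:5]}")
    pmat = props.df[samples]
    totals: dict[int, np.ndarray] = {}
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            vec = (
                pmat.loc[node.name].to_numpy(dtype=float)
                if node.name in pmat.index
                else np.zeros(len(samples))
            )
        else:
            vec = np.sum([totals[id(c)] for c in node.children], axis=0)
            if np.isscalar(vec):  # childless internal node (degenerate)
                vec = np.zeros(len(samples))
        totals[id(node)] = vec
        if node is not tree:
            lengths.append(float(node.length if node.length is not None else 1.0))
            rows.append(vec)
    return np.asarray(lengths), np.asarray(rows), samples


def generalized_unifrac(
    tree: TreeNode, props: ProportionTable, alpha: float
) -> DistanceMatrix:
    """Generalized UniFrac distance between all sample pairs for one alpha
    in [0, 1]; alpha = 1 is the weighted-normalized form."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    b, P, samples = _branch_profile(tree, props)
    n = len(samples)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa, pb = P[:, i], P[:, j]
        tot = pa + pb
        occ = tot > 0
        w = b[occ] * tot[occ] ** alpha
        denom = w.sum()
        if denom == 0:
            val = 0.0
        else:
            val = float((w * np.abs(pa[occ] - pb[occ]) / tot[occ]).sum() / denom)
        d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=samples)


def weighted_unifrac(tree: TreeNode, props: ProportionTable) -> DistanceMatrix:
    """Weighted-normalized UniFrac (generalized form at alpha = 1)."""
    return generalized_unifrac(tree, props, alpha=1.0)


def unweighted_unifrac(tree: TreeNode, props: ProportionTable) -> DistanceMatrix:
    """Presence/absence UniFrac: unshared occupied branch length over total
    occupied branch length."""
    b, P, samples = _branch_profile(tree, props)
    pres = P > 0
    n = len(samples)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        a_occ, b_occ = pres[:, i], pres[:, j]
        union = a_occ | b_occ
        denom = b[union].sum()
        val = 0.0 if denom == 0 else float(b[a_occ ^ b_occ].sum() / denom)
        d[i, j] = d[j, i] = val
    return DistanceMatrix(d, ids=samples)


def unifrac_family(
    tree: TreeNode, props: ProportionTable, alphas: tuple[float, ...] = (0.0, 0.5, 1.0)
) -> dict[str, DistanceMatrix]:
    """The distance family fed to the omnibus screen: generalized UniFrac at
    each alpha plus the unweighted matrix."""
    out = {f"gunifrac_a{a:g}": generalized_unifrac(tree, props, a) for a in alphas}
    out["unweighted"] = unweighted_unifrac(tree, props)
    return out


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])
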