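"""Selection of ortholog groups whose focal species form a single-copy pair.

Given per-OG gene trees with leaf labels encoding ``<species><delim><gene>``,
an OG passes when each of the two focal species contributes exactly one leaf
and those two leaves are sisters in the unrooted tree — i.e. the bipartition
{focal A leaf, focal B leaf} versus everything else exists. The test is
therefore invariant to rooting (trees from ML software are unrooted).
"""

from __future__ import annotations

from typing import Iterable

import dendropy
import pandas as pd

__all__ = ["parse_newick", "focal_pair_status", "select_ogs", "PASS",
           "FAIL_COPY_NUMBER", "FAIL_TOPOLOGY"]

PASS = "pass"
FAIL_COPY_NUMBER = "fail_copy_number"
FAIL_TOPOLOGY = "fail_topology"


def parse_newick(text: str) -> dendropy.Tree:
    """Parse one Newick tree; branch lengths and support values tolerated."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"malformed Newick: {exc}") from exc
    if len(tree.leaf_nodes()) < 2:
        raise ValueError("tree has fewer than 2 leaves")
    # the status test handles unrootedness itself; treat the parsed shape as
    # a rooted view to keep dendropy's MRCA machinery quiet
    tree.is_rooted = True
    return tree


def _species_of(label: str, delimiter: str) -> str:
    return label.split(delimiter)[0]


def focal_pair_status(
    tree: dendropy.Tree | str,
    species_a: str,
    species_b: str,
    delimiter: str = "_",
) -> str:
    """Classify one gene tree with respect to the focal species pair.

    Returns ``pass`` when each focal species has exactly one leaf and the two
    focal leaves form one side of a bipartition of the unrooted tree (sister
    pair regardless of rooting); ``fail_copy_number`` when either species has
    0 or >= 2 leaves; ``fail_topology`` otherwise.
    """
    if not species_a or not species_b or species_a == species_b:
        raise ValueError("two distinct, non-empty focal species tags are required")
    if isinstance(tree, str):
        tree = parse_newick(tree)
    leaves = tree.leaf_nodes()
    labels = [lf.taxon.label for lf in leaves]
    a_leaves = [lf for lf, lab in zip(leaves, labels)
                if _species_of(lab, delimiter) == species_a]
    b_leaves = [lf for lf, lab in zip(leaves, labels)
                if _species_of(lab, delimiter) == species_b]
    if len(a_leaves) != 1 or len(b_leaves) != 1:
        return FAIL_COPY_NUMBER
    focal = {a_leaves[0].taxon, b_leaves[0].taxon}
    others = {lf.taxon for lf in leaves} - focal
    if not others:  # two-leaf tree: trivially sisters
        return PASS
    mrca = tree.mrca(taxa=focal)
    if {lf.taxon for lf in mrca.leaf_iter()} == focal:
        return PASS
    # unrooted view: the pair is also a cherry if all other leaves form a clade
    mrca_others = tree.mrca(taxa=others)
    if {lf.taxon for lf in mrca_others.leaf_iter()} == others:
        return PASS
    return FAIL_TOPOLOGY


def _leaf_count(tree: dendropy.Tree, species: str, delimiter: str) -> int:
    return sum(
        1 for lf in tree.leaf_nodes()
        if _species_of(lf.taxon.label, delimiter) == species
    )


def select_ogs(
    trees: Iterable[tuple[str, str]],
    species_a: str,
    species_b: str,
    delimiter: str = "_",
) -> tuple[list[str], pd.DataFrame]:
    """Select passing OGs from (og_id, newick) records.

    Returns the passing OG ids and a per-OG status table with focal leaf
    counts. Duplicate OG ids raise ValueError.
    """
    rows = []
    seen: set[str] = set()
    for og_id, newick in trees:
        if og_id in seen:
            raise ValueError(f"duplicate OG id: {og_id}")
        seen.add(og_id)
        tree = parse_newick(newick)
        status = focal_pair_status(tree, species_a, species_b, delimiter)
        rows.append({
            "og_id": og_id,
            "status": status,
            "n_leaves_A": _leaf_count(tree, species_a, delimiter),
            "n_leaves_B": _leaf_count(tree, species_b, delimiter),
        })
    table = pd.DataFrame(rows, columns=["og_id", "status", "n_leaves_A", "n_leaves_B"])
    passing = table.loc[table["status"] == PASS, "og_id"].tolist()
    return passing, table
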