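"""Taxonomic trees and the complementary-sample construction.

Occurrence records carry a full classification path (e.g. kingdom /
phylum / ... / genus / species).  Merging the paths of all records in a
study region yields a rooted taxonomic tree.  Given a set of taxa of
interest N_y, the nodes under their lowest common ancestor (LCA) that
do not belong to any taxon of interest form the *complementary taxa*:
taxonomically close groups whose occurrences measure sampling activity
rather than the focal taxa's ecology.  Their per-cell presences define
the complementary response y^c used to fit the sampling-effort process;
cells holding only focal-taxon records become pseudo-absences, and
cells with no record at all are either absences or missing depending on
the study's missing-data policy.

Nodes are identified by their full path tuple from the root, so a name
is unique within its parent but may recur elsewhere in the tree.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import networkx as nx

from .lattice import Lattice, CellResponse, MISSING

#: default Darwin-Core-like rank columns, most inclusive first
DEFAULT_RANKS = ("kingdom", "phylum", "class", "order", "family",
                 "genus", "species")

ROOT: tuple = ()


@dataclass
class TaxonomicTree:
    """A rooted taxonomic tree built from record classification paths.

    Attributes
    ----------
    graph : networkx.DiGraph
        Edges point parent -> child; node keys are path tuples and the
        synthetic root is the empty tuple.  Each node stores ``name``
        and ``rank`` attributes.
    leaf_records : dict
        Full path tuple -> list of record indices mapped to that leaf.
    ranks : tuple of str
        Rank names, most inclusive first.
    """

    graph: nx.DiGraph
    leaf_records: dict
    ranks: tuple

    @property
    def root(self) -> tuple:
        return ROOT

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def resolve(self, taxon) -> tuple:
        """Resolve a taxon reference (path tuple or unique name)."""
        if isinstance(taxon, tuple):
            if taxon not in self.graph:
                raise KeyError(f"taxon {taxon!r} not in tree")
            return taxon
        hits = [n for n in self.graph if n != ROOT and n[-1] == taxon]
        if not hits:
            raise KeyError(f"taxon {taxon!r} not in tree")
        if len(hits) > 1:
            raise KeyError(f"taxon name {taxon!r} is ambiguous: {hits}")
        return hits[0]

    def descendants(self, node) -> set:
        """All strict descendants of ``node`` (path-prefix test)."""
        node = self.resolve(node)
        k = len(node)
        return {n for n in self.graph if len(n) > k and n[:k] == node}

    def records_under(self, node) -> list:
        """Indices of records whose path passes through ``node``."""
        node = self.resolve(node)
        k = len(node)
        out = []
        for leaf, recs in self.leaf_records.items():
            if leaf[:k] == node:
                out.extend(recs)
        return out

    def to_newick(self, path=None) -> str:
        """Newick export of the topology (names only, for inspection)."""
        import skbio

        def build(node):
            children = [build(c) for c in sorted(self.graph.successors(node))]
            name = "root" if node == ROOT else node[-1]
            t = skbio.TreeNode(name=name.replace(" ", "_"))
            t.extend(children)
            return t

        nwk = str(build(ROOT))
        if path is not None:
            with open(path, "w") as fh:
                fh.write(nwk)
        return nwk


@dataclass
class ComplementSpec:
    """Taxa of interest, their LCA and the complementary taxa.

    ``complement_taxa`` are the roots of the maximal subtrees under the
    LCA that contain no taxon of interest; together their node sets are
    exactly the LCA-rooted subtree minus the induced subtree of the
    taxa of interest.
    """

    taxa_of_interest: list
    lca: tuple
    complement_taxa: list

    def to_json(self, path=None):
        obj = {
            "taxa_of_interest": [list(t) for t in self.taxa_of_interest],
            "lca": list(self.lca),
            "complement_taxa": [list(t) for t in self.complement_taxa],
        }
        if path is None:
            return json.dumps(obj, indent=2)
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)
        return None

    @classmethod
    def from_json(cls, path_or_str) -> "ComplementSpec":
        try:
            obj = json.loads(path_or_str)
        except (ValueError, TypeError):
            with open(path_or_str) as fh:
                obj = json.load(fh)
        return cls(
            taxa_of_interest=[tuple(t) for t in obj["taxa_of_interest"]],
            lca=tuple(obj["lca"]),
            complement_taxa=[tuple(t) for t in obj["complement_taxa"]],
        )


def build_tree(records: pd.DataFrame, ranks=DEFAULT_RANKS,
               on_incomplete: str = "raise") -> TaxonomicTree:
    """Build a taxonomic tree from an occurrence table.

    Parameters
    ----------
    records : DataFrame
        One row per occurrence with one column per rank in ``ranks``.
        Row positions (0-based) are the record indices used throughout.
    ranks : sequence of str
        Ordered rank columns, most inclusive first.
    on_incomplete : "raise" or "drop"
        Records with any missing/empty rank value are rejected with a
        per-record report ("raise") or dropped; dropped indices are
        listed on the returned tree's ``dropped_records`` attribute.
    """
    ranks = tuple(ranks)
    missing = [c for c in ranks if c not in records.columns]
    if missing:
        raise ValueError(f"records lack rank columns: {missing}")
    sub = records.loc[:, list(ranks)]
    bad_mask = sub.isna().any(axis=1) | (
        sub.astype(object).apply(lambda c: c.astype(str).str.strip().eq(""))
        .any(axis=1))
    bad = list(np.nonzero(bad_mask.to_numpy())[0])
    if bad and on_incomplete == "raise":
        raise ValueError(
            "records with incomplete taxonomic information: "
            f"rows {bad[:20]}{'...' if len(bad) > 20 else ''}")
    graph = nx.DiGraph()
    graph.add_node(ROOT, name="root", rank="root")
    leaf_records: dict = {}
    good = np.nonzero(~bad_mask.to_numpy())[0]
    paths = sub.to_numpy(dtype=object)
    for idx in good:
        path = tuple(str(v) for v in paths[idx])
        node = ROOT
        for depth, name in enumerate(path):
            child = path[: depth + 1]
            if child not in graph:
                graph.add_node(child, name=name, rank=ranks[depth])
                graph.add_edge(node, child)
            node = child
        leaf_records.setdefault(path, []).append(int(idx))
    tree = TaxonomicTree(graph=graph, leaf_records=leaf_records, ranks=ranks)
    tree.dropped_records = bad
    return tree


def lowest_common_ancestor(tree: TaxonomicTree, taxa) -> tuple:
    """Deepest node ancestral to (or equal to) every taxon in ``taxa``.

    With path-tuple node keys this is the longest common prefix.
    """
    paths = [tree.resolve(t) for t in taxa]
    if not paths:
        raise ValueError("taxa set is empty")
    lca = paths[0]
    for p in paths[1:]:
        k = 0
        while k < min(len(lca), len(p)) and lca[k] == p[k]:
            k += 1
        lca = lca[:k]
    return lca


def complementary_taxa(tree: TaxonomicTree, taxa_of_interest) -> ComplementSpec:
    """Complementary taxa of a set of taxa of interest.

    The complement is the set of maximal subtrees under LCA(N_y) that
    contain no taxon of interest: the node set of the LCA-rooted
    subtree minus the induced subtree of N_y (ancestor chains from the
    LCA plus all descendants of each taxon of interest).
    """
    toi = [tree.resolve(t) for t in taxa_of_interest]
    if not toi:
        raise ValueError("taxa_of_interest is empty")
    lca = lowest_common_ancestor(tree, toi)
    # a single taxon (or one containing all others) is its own LCA and
    # would leave nothing complementary; step up to its parent so the
    # complement becomes "the rest of" the next-higher taxon
    if lca in toi and lca != ROOT:
        lca = lca[:-1]
    # induced subtree of N_y below the LCA: spine nodes + descendants
    induced = set()
    for t in toi:
        for depth in range(len(lca) + 1, len(t) + 1):
            induced.add(t[:depth])
        induced |= tree.descendants(t)
    under_lca = tree.descendants(lca)
    complement_nodes = under_lca - induced
    roots = sorted(
        n for n in complement_nodes
        if len(n) == len(lca) + 1 or n[:-1] not in complement_nodes
    )
    if not roots:
        warnings.warn("taxa of interest exhaust the LCA subtree; "
                      "complementary sample is empty")
    return ComplementSpec(taxa_of_interest=toi, lca=lca,
                          complement_taxa=roots)


def records_to_cells(records: pd.DataFrame, lattice: Lattice,
                     lon_col: str = "decimalLongitude",
                     lat_col: str = "decimalLatitude") -> np.ndarray:
    """Map each record to its lattice cell position (-1 if outside)."""
    return lattice.locate(records[lon_col].to_numpy(dtype=float),
                          records[lat_col].to_numpy(dtype=float))


def _cells_with_records(tree: TaxonomicTree, taxa, record_cells) -> set:
    cells = set()
    for t in taxa:
        for rec in tree.records_under(t):
            pos = int(record_cells[rec])
            if pos >= 0:
                cells.add(pos)
    return cells


def complementary_response(tree: TaxonomicTree, complement: ComplementSpec,
                           record_cells, lattice: Lattice,
                           missing_policy: str = "none") -> CellResponse:
    """Per-cell complementary response y^c.

    For each cell x: y^c(x) = 1 if at least one record of any
    complementary taxon falls in x; else 0 (pseudo-absence) if at least
    one record of any taxon of interest falls in x; otherwise missing
    under policy ``"no-information-missing"`` or 0 under ``"none"``.
    A cell holding both kinds of records is 1 — sampling by the
    complementary taxa did occur there.
    """
    if missing_policy not in ("none", "no-information-missing"):
        raise ValueError("missing_policy must be 'none' or "
                         "'no-information-missing'")
    record_cells = np.asarray(record_cells)
    comp_cells = _cells_with_records(tree, complement.complement_taxa,
                                     record_cells)
    toi_cells = _cells_with_records(tree, complement.taxa_of_interest,
                                    record_cells)
    fill = MISSING if missing_policy == "no-information-missing" else 0
    vals = np.full(lattice.n_cells, fill, dtype=np.int8)
    vals[sorted(toi_cells)] = 0
    vals[sorted(comp_cells)] = 1
    return CellResponse(values=vals)


def presence_response(tree: TaxonomicTree, taxon, record_cells,
                      lattice: Lattice,
                      missing_cells=None) -> CellResponse:
    """Per-cell presence response y_i for one taxon of interest.

    A cell is 1 iff a record whose path passes through ``taxon`` falls
    in it, 0 otherwise.  ``missing_cells`` (boolean mask or index
    array) optionally marks no-information cells as missing, mirroring
    the policy applied to the complementary response.
    """
    record_cells = np.asarray(record_cells)
    vals = np.zeros(lattice.n_cells, dtype=np.int8)
    if missing_cells is not None:
        vals[np.asarray(missing_cells)] = MISSING
    for pos in sorted(_cells_with_records(tree, [taxon], record_cells)):
        vals[pos] = 1
    return CellResponse(values=vals)
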