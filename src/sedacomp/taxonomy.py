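"""Taxonomy tree storage, lineage queries and lowest-common-ancestor computation.

Both sequencing arms of the pipeline reduce sequence evidence to taxa through
the same primitive: given a set of candidate taxa for a sequence, assign the
deepest node of the taxonomy that is ancestral to (or equal to) all of them
(the lowest common ancestor, LCA).  This module holds the tree, answers
lineage and rank queries, and decides clade membership (e.g. "is this taxon a
terrestrial plant?") for the damage-calibration step.

Trees are read either from a single 4-column TSV (``taxid  parent  rank
name``) or from the NCBI taxonomy dump dialect (``nodes.dmp`` +
optional ``names.dmp``).  Internal ids are plain integers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "RANKS",
    "Taxon",
    "TaxonomyTree",
    "TaxonomyError",
    "load_taxonomy",
]

#: Canonical rank order, coarse to fine.  Trees may additionally contain
#: unranked nodes ("no rank", "clade"), which rank queries skip over.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

_UNRANKED = frozenset({"no rank", "clade", "root", ""})


class TaxonomyError(ValueError):
    """Raised for malformed taxonomy input (cycles, orphans, duplicates)."""


@dataclass(frozen=True)
class Taxon:
    taxid: int
    parent: int
    rank: str
    name: str


class TaxonomyTree:
    """Rooted taxonomy with integer node ids.

    The root is the unique node whose parent is itself (NCBI convention).
    Construction validates that every non-root parent exists, that there is
    exactly one root, and that no cycles exist.
    """

    def __init__(self, taxa: Iterable[Taxon]):
        nodes: dict[int, Taxon] = {}
        for t in taxa:
            if t.taxid in nodes:
                raise TaxonomyError(f"duplicate taxon id {t.taxid}")
            nodes[t.taxid] = t
        if not nodes:
            raise TaxonomyError("empty taxonomy")
        roots = [t.taxid for t in nodes.values() if t.parent == t.taxid]
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {len(roots)}")
        self._nodes = nodes
        self.root: int = roots[0]
        for t in nodes.values():
            if t.parent not in nodes:
                raise TaxonomyError(
                    f"orphan node {t.taxid}: parent {t.parent} not in tree"
                )
        self._check_acyclic()
        self._lineage_cache: dict[int, tuple[int, ...]] = {}

    def _check_acyclic(self) -> None:
        state: dict[int, int] = {}  # 0 in-progress, 1 done
        for start in self._nodes:
            path = []
            node = start
            while state.get(node) is None and node != self.root:
                state[node] = 0
                path.append(node)
                node = self._nodes[node].parent
                if state.get(node) == 0:
                    raise TaxonomyError(f"cycle detected involving taxon {node}")
            for n in path:
                state[n] = 1

    # -- basic queries ---------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    def __iter__(self):
        return iter(self._nodes)

    def node(self, taxid: int) -> Taxon:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise KeyError(f"unknown taxon id {taxid}") from None

    def parent(self, taxid: int) -> int:
        return self.node(taxid).parent

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def find(self, name: str) -> int:
        """Id of the unique node with this exact name (helper for configs)."""
        hits = [t.taxid for t in self._nodes.values() if t.name == name]
        if len(hits) != 1:
            raise KeyError(f"name {name!r} matches {len(hits)} nodes")
        return hits[0]

    def lineage(self, taxid: int) -> tuple[int, ...]:
        """Ordered ids from the root down to ``taxid`` (inclusive)."""
        cached = self._lineage_cache.get(taxid)
        if cached is not None:
            return cached
        self.node(taxid)
        path = []
        node = taxid
        while node != self.root:
            path.append(node)
            node = self._nodes[node].parent
        path.append(self.root)
        out = tuple(reversed(path))
        self._lineage_cache[taxid] = out
        return out

    # -- LCA and rank queries --------------------------------------------

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty id set.

        The singleton LCA is the node itself; ids spanning the whole tree
        resolve to the root (never an error).
        """
        ids = list(taxids)
        if not ids:
            raise ValueError("lca of an empty id set")
        lin = self.lineage(ids[0])
        depth = len(lin)
        for taxid in ids[1:]:
            other = self.lineage(taxid)
            limit = min(depth, len(other))
            d = 0
            while d < limit and lin[d] == other[d]:
                d += 1
            depth = d
        return lin[depth - 1]

    def rank_ancestor(self, taxid: int, rank: str) -> int | None:
        """The unique ancestor-or-self of ``taxid`` at ``rank``, else None.

        Unranked intermediate nodes are skipped; a lineage lacking the rank
        yields None.
        """
        for node in reversed(self.lineage(taxid)):
            if self._nodes[node].rank == rank:
                return node
        return None

    def descends_from(self, taxid: int, ancestor: int) -> bool:
        """True iff ``ancestor`` appears in the lineage of ``taxid``."""
        self.node(ancestor)
        return ancestor in self.lineage(taxid)

    def is_reference_plant(
        self,
        taxid: int,
        plant_root: int,
        exclusions: Iterable[int] = (),
    ) -> bool:
        """Membership test for the damage-calibration clade.

        True iff ``taxid`` descends from the designated plant clade
        (typically Viridiplantae) and from none of the excluded clades
        (e.g. the marine eelgrass genus *Zostera*, which the calibration
        must not include because it is not transported terrestrially).
        """
        if not self.descends_from(taxid, plant_root):
            return False
        lin = set(self.lineage(taxid))
        return not any(e in lin for e in exclusions)


# -- parsing -------------------------------------------------------------


def _parse_tsv(path: Path) -> list[Taxon]:
    taxa = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["taxid", "parent"]:
            raise TaxonomyError(
                f"{path}:1: expected header 'taxid\\tparent\\trank\\tname'"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise TaxonomyError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise TaxonomyError(f"{path}:{lineno}: non-integer taxon id") from None
            taxa.append(Taxon(taxid, parent, fields[2], fields[3]))
    return taxa


def _parse_ncbi_dump(nodes_path: Path, names_path: Path | None) -> list[Taxon]:
    names: dict[int, str] = {}
    if names_path is not None and names_path.exists():
        with open(names_path) as fh:
            for line in fh:
                fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
                if len(fields) >= 4 and fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]
    taxa = []
    with open(nodes_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = [f.strip() for f in line.rstrip("\t|\n").split("\t|\t")]
            if len(fields) < 3:
                raise TaxonomyError(f"{nodes_path}:{lineno}: expected >= 3 dmp fields")
            try:
                taxid, parent = int(fields[0]), int(fields[1])
            except ValueError:
                raise TaxonomyError(f"{nodes_path}:{lineno}: non-integer taxon id") from None
            taxa.append(Taxon(taxid, parent, fields[2], names.get(taxid, str(taxid))))
    return taxa


def load_taxonomy(source: str | os.PathLike) -> TaxonomyTree:
    """Load a taxonomy from a 4-column TSV, a ``nodes.dmp`` file, or a
    directory containing ``nodes.dmp`` (+ optional ``names.dmp``).

    The dialect is chosen by file name and content: files named ``*.dmp`` or
    directories use the NCBI dump convention, anything else the TSV header
    convention.
    """
    path = Path(source)
    if path.is_dir():
        return TaxonomyTree(_parse_ncbi_dump(path / "nodes.dmp", path / "names.dmp"))
    if path.suffix == ".dmp":
        names = path.with_name("names.dmp")
        return TaxonomyTree(_parse_ncbi_dump(path, names if names.exists() else None))
    return TaxonomyTree(_parse_tsv(path))
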