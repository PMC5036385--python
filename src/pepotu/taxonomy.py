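"""Rank-annotated rooted taxonomies: loading, lineage queries and LCA.

A :class:`TaxonomyTree` is a closed world: every taxid it is asked about must
be present, every non-root node's parent must be present, and the parent chain
from any node must reach the single root. Ranks are the seven canonical NCBI
levels plus ``no_rank``; ``no_rank`` nodes are transparent for rank projection
(they are skipped by :meth:`TaxonomyTree.ancestor_at_rank` and never returned).

Two on-disk dialects are supported:

* NCBI taxdump (``nodes.dmp``/``names.dmp``): fields separated by ``\\t|\\t``,
  records terminated by ``\\t|``; only scientific names are read.
* A simplified 4-column TSV (``taxid``, ``parent_taxid``, ``rank``, ``name``)
  with a header row — compact and writable, used by the synthetic generator.

Merged/deleted taxid remapping is not handled: unknown taxids are hard errors.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

from .errors import TaxonomyStructureError, UnknownRankError, UnknownTaxonError

#: Canonical ranks, ordered root-ward to leaf-ward.
RANKS: tuple[str, ...] = (
    "superkingdom",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

NO_RANK = "no_rank"

_RANK_SET = frozenset(RANKS) | {NO_RANK}


def normalize_rank(rank: str) -> str:
    """Map a raw rank label to the enumerated set; unknown ranks → ``no_rank``."""
    r = rank.strip().lower().replace(" ", "_")
    return r if r in _RANK_SET else NO_RANK


@dataclass(frozen=True)
class TaxonNode:
    """One taxon: identifier, parent link, rank annotation and name."""

    taxid: int
    parent_taxid: int
    rank: str
    name: str = ""


class TaxonomyTree:
    """Rooted tree of :class:`TaxonNode` with lineage/LCA queries.

    Construction validates every structural invariant: unique taxids (implied
    by the mapping), exactly one root (``parent_taxid == taxid``), all parents
    present, acyclicity, and no repeated non-``no_rank`` rank along any
    root-to-node path.
    """

    def __init__(self, nodes: Mapping[int, TaxonNode]):
        self._nodes: dict[int, TaxonNode] = dict(nodes)
        if not self._nodes:
            raise TaxonomyStructureError("taxonomy has no nodes")
        roots = [n.taxid for n in self._nodes.values() if n.parent_taxid == n.taxid]
        if len(roots) != 1:
            raise TaxonomyStructureError(
                f"taxonomy must have exactly one root, found {len(roots)}: {sorted(roots)}"
            )
        self.root_taxid: int = roots[0]
        for node in self._nodes.values():
            if node.taxid <= 0:
                raise TaxonomyStructureError(f"taxid must be positive, got {node.taxid}")
            if node.parent_taxid not in self._nodes:
                raise TaxonomyStructureError(
                    f"node {node.taxid} references missing parent {node.parent_taxid}"
                )
        self._depth: dict[int, int] = {}
        self._compute_depths()
        self._check_rank_paths()

    # -- construction helpers -------------------------------------------------

    def _compute_depths(self) -> None:
        for taxid in self._nodes:
            chain = []
            cur = taxid
            while cur not in self._depth:
                if cur == self.root_taxid:
                    self._depth[cur] = 0
                    break
                chain.append(cur)
                cur = self._nodes[cur].parent_taxid
                if len(chain) > len(self._nodes):
                    raise TaxonomyStructureError(
                        f"cycle detected on parent chain of taxid {taxid}"
                    )
            base = self._depth[cur]
            for i, t in enumerate(reversed(chain), start=1):
                self._depth[t] = base + i
        # chains that never reach root are impossible here: every parent exists
        # and cycles are caught above, so all chains terminate at the root.

    def _check_rank_paths(self) -> None:
        for taxid in self._nodes:
            seen: set[str] = set()
            for _, t in self.lineage(taxid):
                r = self._nodes[t].rank
                if r == NO_RANK:
                    continue
                if r in seen:
                    raise TaxonomyStructureError(
                        f"rank '{r}' repeats on the path to taxid {taxid}"
                    )
                seen.add(r)

    # -- basic access ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self._nodes)

    def __contains__(self, taxid: int) -> bool:
        return taxid in self._nodes

    @property
    def nodes(self) -> Mapping[int, TaxonNode]:
        return self._nodes

    def node(self, taxid: int) -> TaxonNode:
        try:
            return self._nodes[taxid]
        except KeyError:
            raise UnknownTaxonError(f"taxid {taxid} not in taxonomy") from None

    def name(self, taxid: int) -> str:
        return self.node(taxid).name

    def rank(self, taxid: int) -> str:
        return self.node(taxid).rank

    def depth(self, taxid: int) -> int:
        self.node(taxid)
        return self._depth[taxid]

    def taxids_at_rank(self, rank: str) -> list[int]:
        """All taxids annotated with ``rank``, sorted."""
        _check_rank(rank)
        return sorted(t for t, n in self._nodes.items() if n.rank == rank)

    # -- queries --------------------------------------------------------------

    def lineage(self, taxid: int) -> list[tuple[str, int]]:
        """Ordered ``(rank, taxid)`` pairs from the root down to ``taxid``."""
        node = self.node(taxid)
        out: list[tuple[str, int]] = []
        cur = node.taxid
        while True:
            out.append((self._nodes[cur].rank, cur))
            if cur == self.root_taxid:
                break
            cur = self._nodes[cur].parent_taxid
        out.reverse()
        return out

    def ancestor_at_rank(self, taxid: int, rank: str) -> int | None:
        """The unique ancestor-or-self of ``taxid`` annotated ``rank``, else None.

        ``no_rank`` nodes are transparent: they are skipped and never returned
        (requesting rank ``no_rank`` is an error).
        """
        _check_rank(rank)
        cur = self.node(taxid).taxid
        while True:
            if self._nodes[cur].rank == rank:
                return cur
            if cur == self.root_taxid:
                return None
            cur = self._nodes[cur].parent_taxid

    def lca(self, taxids: Iterable[int]) -> int:
        """Lowest common ancestor of a non-empty collection of taxids.

        The LCA of a singleton is the member itself; duplicates and ordering
        are irrelevant.
        """
        ids = sorted(set(taxids))
        if not ids:
            raise ValueError("lca of an empty taxid set is undefined")
        for t in ids:
            self.node(t)
        cur = ids[0]
        for t in ids[1:]:
            cur = self._lca_pair(cur, t)
            if cur == self.root_taxid:
                break
        return cur

    def _lca_pair(self, a: int, b: int) -> int:
        da, db = self._depth[a], self._depth[b]
        while da > db:
            a = self._nodes[a].parent_taxid
            da -= 1
        while db > da:
            b = self._nodes[b].parent_taxid
            db -= 1
        while a != b:
            a = self._nodes[a].parent_taxid
            b = self._nodes[b].parent_taxid
        return a


def _check_rank(rank: str) -> None:
    if rank not in RANKS:
        raise UnknownRankError(f"unknown rank '{rank}'; expected one of {RANKS}")


# -- readers / writers --------------------------------------------------------


def _as_text(source: str | Path | TextIO) -> TextIO:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8")
    return source


def _split_dmp(line: str) -> list[str]:
    line = line.rstrip("\n")
    if line.endswith("\t|"):
        line = line[: -len("\t|")]
    return [f.strip() for f in line.split("\t|\t")]


def read_taxonomy(
    nodes_source: str | Path | TextIO, names_source: str | Path | TextIO | None = None
) -> TaxonomyTree:
    """Read a taxonomy in NCBI taxdump dialect (``nodes.dmp`` + ``names.dmp``).

    Field 1 of ``nodes.dmp`` is the taxid, field 2 the parent taxid, field 3
    the rank. Only names of class ``scientific name`` are attached. Unknown
    rank labels are mapped to ``no_rank``. Structural defects (duplicate
    taxids, missing parents, zero/multiple roots) raise
    :class:`TaxonomyStructureError`.
    """
    names: dict[int, str] = {}
    if names_source is not None:
        with _as_text(names_source) as fh:
            for line in fh:
                if not line.strip():
                    continue
                fields = _split_dmp(line)
                if len(fields) < 4:
                    continue
                if fields[3] == "scientific name":
                    names[int(fields[0])] = fields[1]
    nodes: dict[int, TaxonNode] = {}
    with _as_text(nodes_source) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = _split_dmp(line)
            if len(fields) < 3:
                raise TaxonomyStructureError(f"malformed nodes record: {line!r}")
            taxid = int(fields[0])
            if taxid in nodes:
                raise TaxonomyStructureError(f"duplicate taxid {taxid}")
            nodes[taxid] = TaxonNode(
                taxid=taxid,
                parent_taxid=int(fields[1]),
                rank=normalize_rank(fields[2]),
                name=names.get(taxid, ""),
            )
    return TaxonomyTree(nodes)


TSV_HEADER = ("taxid", "parent_taxid", "rank", "name")


def read_taxonomy_tsv(source: str | Path | TextIO) -> TaxonomyTree:
    """Read the simplified 4-column TSV dialect (header row required)."""
    nodes: dict[int, TaxonNode] = {}
    with _as_text(source) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header[:4]) != TSV_HEADER:
            raise TaxonomyStructureError(
                f"taxonomy TSV header must be {TSV_HEADER}, got {tuple(header)}"
            )
        for line in fh:
            if not line.strip():
                continue
            taxid_s, parent_s, rank, name = line.rstrip("\n").split("\t")[:4]
            taxid = int(taxid_s)
            if taxid in nodes:
                raise TaxonomyStructureError(f"duplicate taxid {taxid}")
            nodes[taxid] = TaxonNode(taxid, int(parent_s), normalize_rank(rank), name)
    return TaxonomyTree(nodes)


def write_taxonomy_tsv(tree: TaxonomyTree, dest: str | Path | TextIO) -> None:
    """Write a tree in the simplified TSV dialect (round-trips exactly)."""
    own = isinstance(dest, (str, Path))
    fh: TextIO = open(dest, "w", encoding="utf-8") if own else dest  # type: ignore[arg-type]
    try:
        fh.write("\t".join(TSV_HEADER) + "\n")
        for taxid in sorted(tree.nodes):
            n = tree.nodes[taxid]
            fh.write(f"{n.taxid}\t{n.parent_taxid}\t{n.rank}\t{n.name}\n")
    finally:
        if own:
            fh.close()


def tree_from_rows(rows: Sequence[tuple[int, int, str, str]]) -> TaxonomyTree:
    """Build a tree from ``(taxid, parent_taxid, rank, name)`` tuples."""
    nodes: dict[int, TaxonNode] = {}
    for taxid, parent, rank, name in rows:
        if taxid in nodes:
            raise TaxonomyStructureError(f"duplicate taxid {taxid}")
        nodes[taxid] = TaxonNode(taxid, parent, normalize_rank(rank), name)
    return TaxonomyTree(nodes)
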