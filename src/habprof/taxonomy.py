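"""A minimal ranked taxonomy tree (domain .. genus) for LCA assignment.

The tree plays the role a SILVA-style SSU reference lineage table plays in
a full pipeline: every reference sequence carries a root-to-genus lineage,
and read classification walks that lineage under per-rank identity gates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: Ranks in root-to-leaf order. The (implicit) root sits above ``domain``.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")

ROOT = "root"


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    name: str
    rank: str  # one of RANKS
    parent: str  # parent taxon id (ROOT for domains)


class TaxonomyTree:
    """Single-rooted ranked tree; ranks strictly deepen along every path."""

    def __init__(self, nodes: Iterable[TaxNode]):
        self.nodes: dict[str, TaxNode] = {}
        for node in nodes:
            if node.taxon_id in self.nodes:
                raise ValueError(f"duplicate taxon id {node.taxon_id!r}")
            if node.rank not in RANKS:
                raise ValueError(f"unknown rank {node.rank!r}")
            self.nodes[node.taxon_id] = node
        self._children: dict[str, list[str]] = {}
        for node in self.nodes.values():
            self._children.setdefault(node.parent, []).append(node.taxon_id)
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.parent == ROOT:
                if node.rank != "domain":
                    raise ValueError(
                        f"{node.taxon_id!r}: children of the root must be domains"
                    )
                continue
            parent = self.nodes.get(node.parent)
            if parent is None:
                raise KeyError(f"{node.taxon_id!r}: unknown parent {node.parent!r}")
            if RANKS.index(node.rank) <= RANKS.index(parent.rank):
                raise ValueError(
                    f"{node.taxon_id!r}: rank {node.rank!r} does not deepen "
                    f"below parent rank {parent.rank!r}"
                )

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def rank_of(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].rank

    def children(self, taxon_id: str) -> list[str]:
        return self._children.get(taxon_id, [])

    def lineage(self, taxon_id: str) -> list[TaxNode]:
        """Root-to-taxon path (root excluded)."""
        if taxon_id not in self.nodes:
            raise KeyError(f"taxon {taxon_id!r} not in taxonomy")
        path = []
        cur: Optional[str] = taxon_id
        while cur is not None and cur != ROOT:
            node = self.nodes[cur]
            path.append(node)
            cur = node.parent
        return path[::-1]

    def at_rank(self, taxon_id: str, rank: str) -> Optional[str]:
        """Ancestor (or self) of ``taxon_id`` at ``rank``, or None."""
        for node in self.lineage(taxon_id):
            if node.rank == rank:
                return node.taxon_id
        return None

    def descendants(self, taxon_id: str) -> list[str]:
        out, stack = [], [taxon_id]
        while stack:
            cur = stack.pop()
            for child in self.children(cur):
                out.append(child)
                stack.append(child)
        return out

    def genera(self, under: Optional[str] = None) -> list[str]:
        """All genus-level taxa, optionally restricted to a subtree."""
        if under is None:
            pool: Iterable[str] = self.nodes
        else:
            if under not in self.nodes:
                raise KeyError(f"taxon {under!r} not in taxonomy")
            pool = [under, *self.descendants(under)]
        return sorted(t for t in pool if self.nodes[t].rank == "genus")

    # --- serialization -------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            (n.taxon_id, n.parent, n.rank, n.name)
            for n in sorted(self.nodes.values(), key=lambda n: n.taxon_id)
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "parent_id", "rank", "name"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyTree":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(
            TaxNode(r.taxon_id, r.name, r.rank, r.parent_id)
            for r in df.itertuples(index=False)
        )


def toy_taxonomy(
    domains: Sequence[str] = ("Bacteria", "Fungi"),
    branching: Mapping[str, int] | None = None,
) -> TaxonomyTree:
    """A small complete taxonomy for tests and synthetic hit tables.

    Each domain branches with the given factor at every rank below it
    (default 2), yielding ``b^5`` genera per domain. Taxon ids encode the
    path, e.g. ``Bacteria;p1;c2;o1;f2;g1``.
    """
    branching = dict(branching or {})
    nodes: list[TaxNode] = []
    prefixes = {"phylum": "p", "class": "c", "order": "o", "family": "f", "genus": "g"}

    def grow(parent_id: str, rank_idx: int) -> None:
        if rank_idx >= len(RANKS):
            return
        rank = RANKS[rank_idx]
        for i in range(1, branching.get(rank, 2) + 1):
            tid = f"{parent_id};{prefixes[rank]}{i}"
            nodes.append(TaxNode(tid, f"{prefixes[rank]}{i}", rank, parent_id))
            grow(tid, rank_idx + 1)

    for dom in domains:
        nodes.append(TaxNode(dom, dom, "domain", ROOT))
        grow(dom, 1)
    return TaxonomyTree(nodes)
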