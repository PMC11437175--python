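"""Lineage parsing and the dataset-specific taxonomic tree.

The tree that defines the model's output space is built from the observed
classifier annotations only, so it is a subgraph of the full taxonomy and
the space of possible predictions is restricted to taxa that actually
appear in the annotation set. Nodes are identified by their full path, not
their bare name, so homonymous taxa in different clades remain distinct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
N_RANKS = len(RANKS)
LINEAGE_SEP = ";"


@dataclass(frozen=True)
class Lineage:
    """A (possibly partial) rank-ordered annotation path for one contig.

    ``labels`` is a contiguous prefix of the seven-rank ladder starting at
    domain; an empty tuple means the contig is unannotated.
    """

    contig_id: str
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.labels) > N_RANKS:
            raise ValueError(
                f"lineage for {self.contig_id!r} has {len(self.labels)} ranks, "
                f"maximum is {N_RANKS}"
            )
        if any(not lab for lab in self.labels):
            raise ValueError(
                f"lineage for {self.contig_id!r} has an empty intermediate rank; "
                "non-contiguous lineages are not supported"
            )

    @property
    def depth(self) -> int:
        return len(self.labels)

    def truncate(self, rank: str | int) -> "Lineage":
        idx = rank if isinstance(rank, int) else RANKS.index(rank) + 1
        return Lineage(self.contig_id, self.labels[:idx])


@dataclass
class AnnotationSet:
    """Per-contig lineages from one classifier."""

    lineages: dict[str, Lineage]
    source_name: str = "classifier"

    def __len__(self) -> int:
        return len(self.lineages)

    def get(self, contig_id: str) -> Lineage:
        return self.lineages.get(contig_id, Lineage(contig_id))

    def annotated_ids(self) -> list[str]:
        return [cid for cid, lin in self.lineages.items() if lin.labels]

    def to_tsv(self, path: str | Path, sep: str = LINEAGE_SEP) -> None:
        with open(path, "w") as fh:
            fh.write("contigname\tlineage\n")
            for cid, lin in self.lineages.items():
                fh.write(f"{cid}\t{sep.join(lin.labels)}\n")


def parse_annotations(
    path: str | Path, sep: str = LINEAGE_SEP, source_name: str | None = None
) -> AnnotationSet:
    """Parse a two-column lineage TSV (contig id, sep-delimited lineage).

    A header row whose first field is ``contigname`` is skipped. An empty
    second column yields an unannotated contig. Duplicate contig ids and
    lineages deeper than seven ranks are errors.
    """
    path = Path(path)
    lineages: dict[str, Lineage] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            cid = parts[0].strip()
            if lineno == 1 and cid.lower() in ("contigname", "contig_id", "contig"):
                continue
            lineage_str = parts[1].strip() if len(parts) > 1 else ""
            labels = tuple(
                lab.strip() for lab in lineage_str.split(sep) if lab.strip()
            ) if lineage_str else ()
            if cid in lineages:
                raise ValueError(f"{path}:{lineno}: duplicate contig id {cid!r}")
            if len(labels) > N_RANKS:
                raise ValueError(
                    f"{path}:{lineno}: lineage has {len(labels)} fields, maximum is {N_RANKS}"
                )
            lineages[cid] = Lineage(cid, labels)
    return AnnotationSet(lineages, source_name=source_name or path.stem)


@dataclass
class _Node:
    node_id: int
    name: str
    rank: int  # 0-based index into RANKS; -1 for the synthetic root
    parent: int  # -1 for the root
    path: tuple[str, ...]
    children: list[int] = field(default_factory=list)


class TaxTree:
    """Rank tree over the observed annotation paths.

    Leaves are the childless nodes; ``leaf_index`` assigns them contiguous
    output indices 0..N_l-1, ordered lexicographically by full path so the
    assignment is deterministic across runs. ``leaf_mask`` holds, per node,
    the 0/1 incidence vector over descendant leaves used both to aggregate
    leaf likelihoods bottom-up and to route gradients through the flat
    softmax.
    """

    def __init__(self, paths: Iterable[tuple[str, ...]]):
        self._nodes: list[_Node] = [_Node(0, "", -1, -1, ())]
        self._by_path: dict[tuple[str, ...], int] = {(): 0}
        n_inserted = 0
        for path in paths:
            if not path:
                continue
            n_inserted += 1
            for depth in range(1, len(path) + 1):
                prefix = tuple(path[:depth])
                if prefix in self._by_path:
                    continue
                parent = self._by_path[prefix[:-1]]
                node = _Node(len(self._nodes), prefix[-1], depth - 1, parent, prefix)
                self._nodes.append(node)
                self._by_path[prefix] = node.node_id
                self._nodes[parent].children.append(node.node_id)
        if n_inserted == 0:
            raise ValueError("cannot build a taxonomic tree: all lineages are empty")

        leaves = sorted(
            (n.node_id for n in self._nodes[1:] if not n.children),
            key=lambda nid: self._nodes[nid].path,
        )
        self.leaf_index: dict[int, int] = {nid: i for i, nid in enumerate(leaves)}
        self.leaves: tuple[int, ...] = tuple(leaves)
        self.n_leaves: int = len(leaves)

        # 0/1 leaf incidence per node, filled bottom-up (children precede
        # parents in reverse insertion order is not guaranteed, so recurse
        # over the explicit child lists instead).
        self.leaf_mask = np.zeros((len(self._nodes), self.n_leaves), dtype=np.float64)
        order = self._postorder()
        for nid in order:
            node = self._nodes[nid]
            if not node.children:
                if nid != 0:
                    self.leaf_mask[nid, self.leaf_index[nid]] = 1.0
            else:
                for child in node.children:
                    self.leaf_mask[nid] += self.leaf_mask[child]
        np.clip(self.leaf_mask, 0.0, 1.0, out=self.leaf_mask)

    def _postorder(self) -> list[int]:
        out: list[int] = []
        stack: list[tuple[int, bool]] = [(0, False)]
        while stack:
            nid, expanded = stack.pop()
            if expanded:
                out.append(nid)
            else:
                stack.append((nid, True))
                for child in self._nodes[nid].children:
                    stack.append((child, False))
        return out

    # -- queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    def node(self, node_id: int) -> _Node:
        return self._nodes[node_id]

    def find(self, path: tuple[str, ...]) -> int | None:
        """Node id for a full path, or None if the path is not in the tree."""
        return self._by_path.get(tuple(path))

    def resolve(self, path: tuple[str, ...]) -> int:
        nid = self.find(path)
        if nid is None:
            raise KeyError(f"path {LINEAGE_SEP.join(path)!r} is not in the tree")
        return nid

    def children(self, node_id: int) -> tuple[int, ...]:
        return tuple(self._nodes[node_id].children)

    def node_path(self, node_id: int) -> list[int]:
        """Ancestors from the domain level down to the node, root excluded."""
        if not 0 <= node_id < len(self._nodes):
            raise KeyError(f"unknown node id {node_id}")
        out: list[int] = []
        nid = node_id
        while nid != 0:
            out.append(nid)
            nid = self._nodes[nid].parent
        out.reverse()
        return out

    def descendant_leaf_set(self, node_id: int) -> set[int]:
        return {i for i in np.flatnonzero(self.leaf_mask[node_id])}

    def leaf_paths(self) -> list[tuple[str, ...]]:
        return [self._nodes[nid].path for nid in self.leaves]

    # -- (de)serialisation ----------------------------------------------

    def serialize(self, path: str | Path) -> None:
        """Write one `full_path<TAB>rank` line per node (root excluded)."""
        with open(path, "w") as fh:
            for node in self._nodes[1:]:
                fh.write(f"{LINEAGE_SEP.join(node.path)}\t{RANKS[node.rank]}\n")

    @classmethod
    def deserialize(cls, path: str | Path) -> "TaxTree":
        paths = []
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    paths.append(tuple(line.split("\t")[0].split(LINEAGE_SEP)))
        return cls(paths)

    def content_hash(self) -> str:
        import hashlib

        digest = hashlib.sha256()
        for node in self._nodes[1:]:
            digest.update(LINEAGE_SEP.join(node.path).encode())
            digest.update(b"\n")
        return digest.hexdigest()[:16]


def build_tree(annotations: AnnotationSet | Mapping[str, Lineage] | Iterable[Lineage]) -> TaxTree:
    """Build the output-space tree from an annotation set."""
    if isinstance(annotations, AnnotationSet):
        lineages: Iterable[Lineage] = annotations.lineages.values()
    elif isinstance(annotations, Mapping):
        lineages = annotations.values()
    else:
        lineages = annotations
    return TaxTree(lin.labels for lin in lineages)
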