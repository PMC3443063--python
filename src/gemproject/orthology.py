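"""Ortholog-map ingestion and consensus voting.

Several orthology methods (protein families, Inparanoid-style pairs,
OrthoMCL-style clusters, ...) each propose scaffold-gene → target-gene
candidates, possibly grouped into paralog families.  No single method
handles duplication, family expansion and fusion equally well, so the
candidates are pooled and put to a vote: per scaffold gene, candidate
target groups are formed (by shared paralog-group label where given,
otherwise by connected components of shared target genes across methods)
and each group scores one vote per supporting method.  The retained
groups constitute the consensus homolog map used for GPR rewriting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

__all__ = ["OrthologMap", "ConsensusHomologMap", "load_map", "build_consensus"]


@dataclass
class OrthologMap:
    """One method's scaffold→target predictions.

    ``pairs`` maps a scaffold gene id to a set of (target gene id,
    paralog-group label or None) tuples.  A scaffold gene may map to
    zero, one, or many targets.
    """

    method_name: str
    pairs: dict[str, set[tuple[str, Optional[str]]]] = field(default_factory=dict)

    def add(self, scaffold: str, target: str, group: Optional[str] = None) -> None:
        if not scaffold or not target:
            raise ValueError("gene ids must be non-empty")
        self.pairs.setdefault(scaffold, set()).add((target, group))

    def targets_of(self, scaffold: str) -> frozenset[str]:
        return frozenset(t for t, _ in self.pairs.get(scaffold, ()))

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            for scaffold in sorted(self.pairs):
                for target, group in sorted(
                    self.pairs[scaffold], key=lambda p: (p[0], p[1] or "")
                ):
                    row = [scaffold, target] + ([group] if group else [])
                    fh.write("\t".join(row) + "\n")
        return path


class OrthologMapFormatError(ValueError):
    pass


def load_map(path: str | Path, method_name: str, sep: str = "\t") -> OrthologMap:
    """Read a two-or-three-column delimited file (scaffold id, target id,
    optional paralog-group label).  Duplicate rows are deduplicated; an
    empty file is a valid empty map."""
    path = Path(path)
    omap = OrthologMap(method_name=method_name)
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split(sep)
            if len(cols) < 2 or not cols[0].strip() or not cols[1].strip():
                raise OrthologMapFormatError(
                    f"{path}:{lineno}: expected 2-3 columns "
                    f"(scaffold, target[, group]), got {line!r}"
                )
            group = cols[2].strip() if len(cols) >= 3 and cols[2].strip() else None
            omap.add(cols[0].strip(), cols[1].strip(), group)
    return omap


@dataclass
class ConsensusHomologMap:
    """Voted scaffold gene → candidate target paralog groups.

    ``groups`` maps each scaffold gene to a list of (target gene group,
    votes) entries, ordered by decreasing votes then lexicographically.
    ``targets_of`` unions the retained groups, which is how tied
    top-voted groups are merged at rewrite time.
    """

    groups: dict[str, list[tuple[frozenset[str], int]]] = field(default_factory=dict)
    ties: dict[str, int] = field(default_factory=dict)  # scaffold gene -> tied vote

    def targets_of(self, scaffold: str) -> frozenset[str]:
        out: set[str] = set()
        for grp, _votes in self.groups.get(scaffold, ()):
            out |= grp
        return frozenset(out)

    def scaffold_genes(self) -> frozenset[str]:
        return frozenset(self.groups)

    @classmethod
    def identity(cls, genes: Iterable[str]) -> "ConsensusHomologMap":
        """Map every gene to itself with one vote (useful for self-projection)."""
        return cls(groups={g: [(frozenset((g,)), 1)] for g in genes})

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("scaffold_gene\ttarget_group\tvotes\n")
            for scaffold in sorted(self.groups):
                for grp, votes in self.groups[scaffold]:
                    fh.write(f"{scaffold}\t{';'.join(sorted(grp))}\t{votes}\n")
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConsensusHomologMap":
        cmap = cls()
        with Path(path).open() as fh:
            header = fh.readline()
            if header and not header.startswith("scaffold_gene"):
                raise OrthologMapFormatError(f"{path}: missing consensus header")
            for raw in fh:
                if not raw.strip():
                    continue
                scaffold, group, votes = raw.rstrip("\n").split("\t")
                cmap.groups.setdefault(scaffold, []).append(
                    (frozenset(group.split(";")), int(votes))
                )
        return cmap


def build_consensus(
    maps: Sequence[OrthologMap],
    min_votes: int = 1,
    consensus: str = "top",
) -> ConsensusHomologMap:
    """Tally votes across ortholog maps into a consensus homolog map.

    Per scaffold gene, target genes proposed together (same method and
    same group label; unlabelled rows stay singleton proposals) are
    linked; connected components over those links across all methods
    form the candidate paralog groups.  A group's votes count the
    methods proposing at least one of its members.  With
    ``consensus="top"`` (divergent-prediction mode) only the top-voted
    group(s) survive — ties are all kept, and logged, to be unioned at
    rewrite time; with ``consensus="all"`` every group with at least
    ``min_votes`` votes survives.
    """
    if not maps:
        raise ValueError("at least one ortholog map is required")
    if consensus not in ("top", "all"):
        raise ValueError(f"unknown consensus mode {consensus!r}")

    scaffold_genes = sorted(set().union(*(set(m.pairs) for m in maps)))
    result = ConsensusHomologMap()
    for sgene in scaffold_genes:
        graph: nx.Graph = nx.Graph()
        support: dict[str, set[str]] = {}  # method -> targets proposed
        for m in maps:
            entries = m.pairs.get(sgene)
            if not entries:
                continue
            support[m.method_name] = {t for t, _ in entries}
            graph.add_nodes_from(t for t, _ in entries)
            by_label: dict[Optional[str], list[str]] = {}
            for target, label in entries:
                by_label.setdefault(label, []).append(target)
            for label, members in by_label.items():
                if label is None:
                    continue  # unlabelled rows stay singletons within a method
                members = sorted(set(members))
                for a, b in zip(members, members[1:]):
                    graph.add_edge(a, b)
        if not graph:
            continue
        voted: list[tuple[frozenset[str], int]] = []
        for comp in nx.connected_components(graph):
            votes = sum(1 for targets in support.values() if targets & comp)
            if votes >= min_votes:
                voted.append((frozenset(comp), votes))
        if not voted:
            continue
        voted.sort(key=lambda gv: (-gv[1], tuple(sorted(gv[0]))))
        if consensus == "top":
            best = voted[0][1]
            kept = [gv for gv in voted if gv[1] == best]
            if len(kept) > 1:
                result.ties[sgene] = best
            voted = kept
        result.groups[sgene] = voted
    return result
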