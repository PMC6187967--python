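"""Merge overlapping per-gene ortholog predictions into exclusive groups.

Ortholog sets predicted independently per query gene generally overlap.
To avoid analysing the same gene twice, overlapping sets are merged
transitively (connected components of the set-overlap graph) into
mutually exclusive merged ortholog groups.  The representative groups
used by all cross-species analyses are then chosen: *whole* groups that
coincide exactly with a single gene's prediction and contain all three
focal species, and *subset* groups carved out of fused groups by the
same criterion restricted to the focal triple.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .data_io import DataError, Member, OrthologPrediction

__all__ = [
    "MergedOrthoGroup",
    "RepresentativeSet",
    "union_isoform_predictions",
    "merge_ortholog_sets",
    "select_representatives",
    "write_groups",
    "read_groups",
]


@dataclass(frozen=True)
class MergedOrthoGroup:
    group_id: str
    members: frozenset[Member]
    provenance: str = "whole"  # whole | subset
    parent_group_id: str | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"{self.group_id}: empty group")
        if self.provenance not in ("whole", "subset"):
            raise DataError(f"{self.group_id}: bad provenance {self.provenance!r}")

    def species(self) -> set[str]:
        return {sp for sp, _ in self.members}


@dataclass
class RepresentativeSet:
    whole_groups: list[MergedOrthoGroup]
    subset_groups: list[MergedOrthoGroup]
    focal_species: tuple[str, str, str]

    @property
    def groups(self) -> list[MergedOrthoGroup]:
        return self.whole_groups + self.subset_groups


def union_isoform_predictions(
    per_isoform: Mapping[Member, frozenset[Member] | set[Member]],
    isoform_to_gene: Mapping[Member, Member],
) -> list[OrthologPrediction]:
    """Collapse per-isoform ortholog predictions to one prediction per gene.

    The gene-level ortholog set is the union over that gene's isoforms.
    Ortholog members are assumed to already be gene-level identifiers.
    """
    by_gene: dict[Member, set[Member]] = {}
    for isoform, members in per_isoform.items():
        if isoform not in isoform_to_gene:
            raise DataError(f"isoform {isoform} has no parent gene mapping")
        gene = isoform_to_gene[isoform]
        by_gene.setdefault(gene, set()).update(members)
    preds = []
    for gene, members in sorted(by_gene.items()):
        members.add(gene)
        preds.append(OrthologPrediction(gene, frozenset(members)))
    return preds


def _group_id(ordinal: int) -> str:
    return f"MergedOrthoGroup{ordinal:06d}"


def merge_ortholog_sets(
    predictions: Sequence[OrthologPrediction],
) -> list[MergedOrthoGroup]:
    """Transitively merge overlapping ortholog sets into exclusive groups.

    Two predictions sharing at least one gene end up in the same group
    (connected components of the overlap graph).  Group ids are assigned
    by sorting groups on their smallest member, so the partition and its
    labels are invariant to input order.
    """
    if not predictions:
        raise DataError("merge_ortholog_sets: empty prediction list")
    g: nx.Graph = nx.Graph()
    for pred in predictions:
        members = sorted(pred.orthologs)
        anchor = members[0]
        g.add_node(anchor)
        for m in members[1:]:
            g.add_edge(anchor, m)
    components = [frozenset(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: min(c))
    return [
        MergedOrthoGroup(_group_id(i + 1), comp, "whole", None)
        for i, comp in enumerate(components)
    ]


def _has_all_focal(members: Iterable[Member], focal: Sequence[str]) -> bool:
    present = {sp for sp, _ in members}
    return all(sp in present for sp in focal)


def select_representatives(
    groups: Sequence[MergedOrthoGroup],
    predictions: Sequence[OrthologPrediction],
    focal_species: Sequence[str],
) -> RepresentativeSet:
    """Choose the whole and subset groups used by cross-species analyses.

    A *whole* representative is a merged group that (1) contains at
    least one member from each focal species and (2) equals some single
    gene's predicted ortholog set.  Within the remaining groups, the
    member genes' predictions restricted to the focal triple are taken
    as candidates; candidates meeting the presence criterion are unioned
    whenever they overlap (keeping subsets mutually exclusive) and
    numbered Sub001, Sub002, ... within their parent group.
    """
    focal = tuple(focal_species)
    if len(focal) != 3:
        raise DataError("focal_species must be a triple")
    pred_sets = {p.orthologs for p in predictions}
    member_to_preds: dict[Member, list[OrthologPrediction]] = {}
    for p in predictions:
        member_to_preds.setdefault(p.query_gene, []).append(p)

    whole: list[MergedOrthoGroup] = []
    subsets: list[MergedOrthoGroup] = []
    for grp in groups:
        if _has_all_focal(grp.members, focal) and grp.members in pred_sets:
            whole.append(grp)
            continue
        # candidate subsets: single-gene predictions restricted to the
        # focal triple, for query genes inside this merged group
        candidates: list[frozenset[Member]] = []
        for member in grp.members:
            for pred in member_to_preds.get(member, []):
                restricted = frozenset(
                    m for m in pred.orthologs if m[0] in focal
                )
                if restricted and _has_all_focal(restricted, focal):
                    candidates.append(restricted)
        if not candidates:
            continue
        # union overlapping candidates (connected components again)
        cg: nx.Graph = nx.Graph()
        for cand in candidates:
            members = sorted(cand)
            anchor = members[0]
            cg.add_node(anchor)
            for m in members[1:]:
                cg.add_edge(anchor, m)
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(cg)), key=min
        )
        for k, comp in enumerate(comps, start=1):
            subsets.append(
                MergedOrthoGroup(
                    f"{grp.group_id}Sub{k:03d}", comp, "subset", grp.group_id
                )
            )
    return RepresentativeSet(whole, subsets, focal)


def write_groups(groups: Iterable[MergedOrthoGroup], path: str | Path) -> None:
    rows = []
    for g in groups:
        for sp, gene in sorted(g.members):
            rows.append((g.group_id, sp, gene, g.provenance, g.parent_group_id or ""))
    pd.DataFrame(
        rows, columns=["group_id", "species_id", "gene_id", "provenance", "parent_group_id"]
    ).to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> list[MergedOrthoGroup]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for gid, sub in df.groupby("group_id", sort=True):
        members = frozenset(zip(sub["species_id"], sub["gene_id"]))
        prov = sub["provenance"].iloc[0]
        parent = sub["parent_group_id"].iloc[0] or None
        out.append(MergedOrthoGroup(str(gid), members, prov, parent))
    return out
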