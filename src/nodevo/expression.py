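"""Nodule/root enhancement classification across species.

A gene is nodule-enhanced when its nodule-over-root log2 fold change
exceeds +1 with an adjusted p-value below the species cutoff, and
root-enhanced symmetrically below -1 (all inequalities strict).  Group
calls aggregate paralogs: one significant paralog is enough, opposing
paralogs make the group "both".  Core groups are those enhanced in the
same tissue in every focal species.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_io import DataError, ExpressionRecord
from .ortho_merge import MergedOrthoGroup, RepresentativeSet

__all__ = [
    "SpeciesThresholds",
    "EnhancementCall",
    "CoreGroupSet",
    "classify_gene",
    "classify_group_species",
    "classify_groups",
    "find_core_groups",
    "load_pathway_table",
    "pathway_presence_summary",
]


@dataclass(frozen=True)
class SpeciesThresholds:
    species_id: str
    p_cutoff: float
    fc_cutoff: float = 1.0

    def __post_init__(self) -> None:
        if self.p_cutoff <= 0 or self.fc_cutoff <= 0:
            raise DataError(f"{self.species_id}: cutoffs must be > 0")


@dataclass(frozen=True)
class EnhancementCall:
    group_id: str
    species_id: str
    call: str  # nodule | root | both | none
    supporting_genes: tuple[str, ...] = ()

    def counts_as(self, tissue: str) -> bool:
        return self.call == tissue or self.call == "both"


@dataclass
class CoreGroupSet:
    nodule_core: set[str]
    root_core: set[str]


def classify_gene(record: ExpressionRecord, thresholds: SpeciesThresholds) -> str:
    """Classify one gene as ``nodule``, ``root`` or ``ns`` (strict cutoffs)."""
    if record.species_id != thresholds.species_id:
        raise DataError(
            f"species mismatch: record {record.species_id!r} vs "
            f"thresholds {thresholds.species_id!r}"
        )
    if record.adj_p < thresholds.p_cutoff:
        if record.log2fc > thresholds.fc_cutoff:
            return "nodule"
        if record.log2fc < -thresholds.fc_cutoff:
            return "root"
    return "ns"


def classify_group_species(
    group_id: str,
    species_id: str,
    gene_calls: Mapping[str, str],
) -> EnhancementCall:
    """Aggregate per-paralog calls into one call for (group, species).

    ``gene_calls`` maps gene id to the per-gene call.  One enhanced
    paralog suffices; paralogs enhanced in opposite tissues yield
    "both"; no enhanced paralog yields "none".
    """
    if not gene_calls:
        raise DataError(f"{group_id}/{species_id}: no gene calls supplied")
    nod = sorted(g for g, c in gene_calls.items() if c == "nodule")
    root = sorted(g for g, c in gene_calls.items() if c == "root")
    if nod and root:
        return EnhancementCall(group_id, species_id, "both", tuple(nod + root))
    if nod:
        return EnhancementCall(group_id, species_id, "nodule", tuple(nod))
    if root:
        return EnhancementCall(group_id, species_id, "root", tuple(root))
    return EnhancementCall(group_id, species_id, "none")


def classify_groups(
    groups: Sequence[MergedOrthoGroup],
    records: Mapping[str, Mapping[str, ExpressionRecord]],
    thresholds: Mapping[str, SpeciesThresholds],
) -> dict[tuple[str, str], EnhancementCall]:
    """Call every (group, species) with at least one expression record.

    ``records`` maps species_id -> gene_id -> record.  Group members
    without a record (e.g. presence-only orthologs from species lacking
    expression data) contribute nothing.
    """
    calls: dict[tuple[str, str], EnhancementCall] = {}
    for grp in groups:
        by_species: dict[str, dict[str, str]] = {}
        for sp, gene in grp.members:
            if sp not in records or sp not in thresholds:
                continue
            rec = records[sp].get(gene)
            if rec is None:
                continue
            by_species.setdefault(sp, {})[gene] = classify_gene(rec, thresholds[sp])
        for sp, gene_calls in by_species.items():
            calls[(grp.group_id, sp)] = classify_group_species(
                grp.group_id, sp, gene_calls
            )
    return calls


def find_core_groups(
    representatives: RepresentativeSet,
    calls: Mapping[tuple[str, str], EnhancementCall],
    *,
    both_counts: bool = True,
) -> CoreGroupSet:
    """Groups enhanced in the same tissue in all three focal species.

    With ``both_counts`` (default) a "both" call counts toward each
    tissue, so a group that is "both" everywhere lands in both cores.
    """
    nodule: set[str] = set()
    root: set[str] = set()
    for grp in representatives.groups:
        per_species = []
        for sp in representatives.focal_species:
            call = calls.get((grp.group_id, sp))
            if call is None:
                raise DataError(f"missing call for {grp.group_id}/{sp}")
            per_species.append(call)
        def hits(tissue: str) -> bool:
            if both_counts:
                return all(c.counts_as(tissue) for c in per_species)
            return all(c.call == tissue for c in per_species)
        if hits("nodule"):
            nodule.add(grp.group_id)
        if hits("root"):
            root.add(grp.group_id)
    return CoreGroupSet(nodule, root)


# --------------------------------------------------------------------------
# RNS pathway gene table
# --------------------------------------------------------------------------

#: default per-species thresholds for the packaged pathway table
PATHWAY_THRESHOLDS = {
    "Ct": SpeciesThresholds("Ct", 0.005),
    "Dg": SpeciesThresholds("Dg", 0.001),
    "Mt": SpeciesThresholds("Mt", 0.001),
}

#: species whose members carry expression values (legume calls use Mt
#: only; Lj entries contribute presence, never calls)
_FOCAL = ("Ct", "Dg", "Mt")
_LEGUME_SPECIES = {"Mt", "Lj"}


def load_pathway_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged symbiosis-pathway gene table (or one like it).

    Columns: gene_name, group_id (empty when the gene's orthologs were
    not assigned a merged group), species, gene_id, log2fc, adj_p
    (empty for presence-only entries), is_ortholog (0 marks rows that
    are sequence-similar homologs only, not predicted orthologs).
    """
    if path is None:
        ref = importlib.resources.files("nodevo").joinpath(
            "data/rns_pathway_table.tsv"
        )
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", dtype={"gene_name": str, "group_id": str})
    else:
        df = pd.read_csv(path, sep="\t", dtype={"gene_name": str, "group_id": str})
    df["group_id"] = df["group_id"].fillna("")
    df["is_ortholog"] = df["is_ortholog"].astype(int)
    return df


def _pathway_species_call(
    sub: pd.DataFrame, species: str, thresholds: Mapping[str, SpeciesThresholds]
) -> str | None:
    """Call one species for one pathway gene; None when no usable record."""
    rows = sub[(sub["species"] == species) & (sub["is_ortholog"] == 1)]
    rows = rows.dropna(subset=["log2fc", "adj_p"])
    if rows.empty:
        return None
    gene_calls = {
        r.gene_id: classify_gene(
            ExpressionRecord(r.gene_id, species, float(r.log2fc), float(r.adj_p)),
            thresholds[species],
        )
        for r in rows.itertuples(index=False)
    }
    return classify_group_species("pathway", species, gene_calls).call


def pathway_presence_summary(
    table: pd.DataFrame,
    thresholds: Mapping[str, SpeciesThresholds] = PATHWAY_THRESHOLDS,
) -> pd.DataFrame:
    """Score each pathway gene for ortholog presence and universal calls.

    Returns one row per gene with ``ortholog_in_all`` (an ortholog in
    Ct, Dg and a legume), ``universal_call`` (nodule/root when the call
    agrees across Ct, Dg and Mt, else none), and ``has_group`` (the
    gene's orthologs fall in a named merged group).
    """
    rows = []
    for gene_name, sub in table.groupby("gene_name", sort=False):
        present = {
            sp
            for sp, flag in zip(sub["species"], sub["is_ortholog"])
            if int(flag) == 1
        }
        in_all = (
            "Ct" in present
            and "Dg" in present
            and bool(present & _LEGUME_SPECIES)
        )
        calls = {sp: _pathway_species_call(sub, sp, thresholds) for sp in _FOCAL}
        universal = "none"
        for tissue in ("nodule", "root"):
            if all(c is not None and (c == tissue or c == "both") for c in calls.values()):
                universal = tissue
                break
        has_group = bool(str(sub["group_id"].iloc[0]).strip())
        rows.append(
            {
                "gene_name": gene_name,
                "ortholog_in_all": in_all,
                "universal_call": universal,
                "has_group": has_group,
                "call_Ct": calls["Ct"],
                "call_Dg": calls["Dg"],
                "call_Mt": calls["Mt"],
            }
        )
    return pd.DataFrame(rows)
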