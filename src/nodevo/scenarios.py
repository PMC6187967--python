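"""Four-scenario branch-model hypothesis test for the origin of RNS.

Each ortholog group's tree carries up to four special branch classes:
the stem of the nitrogen-fixing clade (class ``a``), the terminal
branches to the two actinorhizal hosts (``b`` for *C. thyrsiflorus*,
``c`` for *D. glomerata*), and the stem of the legumes (``d``).  The
competing evolutionary scenarios free different subsets of these
classes to take their own dN/dS:

    NULL     no extra class (one omega everywhere)
    SINGLE   class a            — single gain at the base of the NFC
    MULTI    classes b, c, d    — independent gains per host lineage
    TWOSTEP  classes a, b, c, d — predisposition then gains of function

Scenarios significantly worse than the best (Shimodaira–Hasegawa test
over RELL-resampled site log-likelihoods, p < alpha) are rejected; the
rejection pattern classifies each group in a two-row table: for branch
a among {SINGLE, TWOSTEP}, for branches b–d among {MULTI, TWOSTEP}.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_model import (
    BACKGROUND,
    FitResult,
    TreeIndex,
    fit_model,
)
from .data_io import CodonAlignment, DataError, Phylogeny, RunConfig, read_newick

__all__ = [
    "SCENARIOS",
    "CladeDefinitions",
    "TreeChoice",
    "ScenarioTestResult",
    "default_species_tree",
    "default_clades",
    "read_clades",
    "label_branches",
    "kh_test",
    "sh_test",
    "run_group",
    "tabulate",
]

#: scenario name -> branch classes given their own omega
SCENARIOS: dict[str, tuple[str, ...]] = {
    "NULL": (),
    "SINGLE": ("a",),
    "MULTI": ("b", "c", "d"),
    "TWOSTEP": ("a", "b", "c", "d"),
}


@dataclass(frozen=True)
class CladeDefinitions:
    """Taxon memberships defining the labeled branches."""

    nfc_taxa: frozenset[str]
    legume_taxa: frozenset[str]
    ct_taxon: str
    dg_taxon: str

    def __post_init__(self) -> None:
        if not self.legume_taxa <= self.nfc_taxa:
            raise DataError("legume taxa must be a subset of the NFC taxa")
        for t in (self.ct_taxon, self.dg_taxon):
            if t not in self.nfc_taxa:
                raise DataError(f"{t!r} must be an NFC member")


def default_species_tree() -> Phylogeny:
    """The packaged 15-taxon family-level constrained topology (synthetic
    branch lengths)."""
    ref = importlib.resources.files("nodevo").joinpath("data/species_tree.nwk")
    with importlib.resources.as_file(ref) as p:
        return read_newick(p)


def default_clades() -> CladeDefinitions:
    return CladeDefinitions(
        nfc_taxa=frozenset(
            {"Mtr", "Lja", "Gma", "Pvu", "Ppe", "Fve", "Cth", "Csa", "Dgl", "Jre", "Bpe"}
        ),
        legume_taxa=frozenset({"Mtr", "Lja", "Gma", "Pvu"}),
        ct_taxon="Cth",
        dg_taxon="Dgl",
    )


def read_clades(path: str | Path) -> CladeDefinitions:
    """Read clade definitions from a TSV with columns ``role``, ``taxon``.

    Roles: nfc, legume (legume taxa are added to the NFC automatically),
    ct, dg.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    nfc, legume, ct, dg = set(), set(), None, None
    for row in df.itertuples(index=False):
        role = row.role.strip().lower()
        if role == "nfc":
            nfc.add(row.taxon)
        elif role == "legume":
            legume.add(row.taxon)
        elif role == "ct":
            ct = row.taxon
        elif role == "dg":
            dg = row.taxon
        else:
            raise DataError(f"unknown clade role {row.role!r}")
    if ct is None or dg is None:
        raise DataError("clade file must name the ct and dg taxa")
    nfc |= legume | {ct, dg}
    return CladeDefinitions(frozenset(nfc), frozenset(legume), ct, dg)


# ---------------------------------------------------------------------------
# branch labeling
# ---------------------------------------------------------------------------

def _clade_stem_edge(tree, members: set[str]):
    """Stem edge of the clade of ``members``, or None if non-monophyletic
    (or the clade spans the whole tree, leaving no stem)."""
    if not members:
        return None
    if len(members) == 1:
        (taxon,) = members
        for leaf in tree.leaf_node_iter():
            if leaf.taxon.label == taxon:
                return leaf.edge
        return None
    mrca = tree.mrca(taxon_labels=sorted(members))
    if mrca is None or mrca is tree.seed_node:
        return None
    under = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    if under != members:
        return None
    return mrca.edge


def label_branches(phy: Phylogeny, clades: CladeDefinitions) -> dict[str, bool]:
    """Assign branch classes on ``phy`` in place; report class availability.

    ``a`` labels the stem of the NFC clade, ``b``/``c`` the terminal
    branches of the Ct and Dg taxa, ``d`` the stem of the legumes;
    everything else is background.  A class whose clade is absent or
    non-monophyletic on this tree is left unassigned and reported
    unavailable.  Missing Ct or Dg tips are fatal.
    """
    tree = phy.tree
    tree.is_rooted = True  # MRCA queries are relative to the seed node
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    for t in (clades.ct_taxon, clades.dg_taxon):
        if t not in tips:
            raise DataError(f"required tip {t!r} absent from the tree")
    for edge in tree.preorder_edge_iter():
        edge.branch_class = BACKGROUND
    availability = {}
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == clades.ct_taxon:
            leaf.edge.branch_class = "b"
        elif leaf.taxon.label == clades.dg_taxon:
            leaf.edge.branch_class = "c"
    availability["b"] = True
    availability["c"] = True
    nfc_present = clades.nfc_taxa & tips
    stem_a = _clade_stem_edge(tree, nfc_present) if len(nfc_present) >= 2 else None
    if stem_a is not None:
        stem_a.branch_class = "a"
    availability["a"] = stem_a is not None
    legume_present = clades.legume_taxa & tips
    stem_d = _clade_stem_edge(tree, legume_present) if legume_present else None
    if stem_d is not None:
        stem_d.branch_class = "d"
    availability["d"] = stem_d is not None
    return availability


def available_scenarios(availability: Mapping[str, bool]) -> list[str]:
    return [
        name
        for name, classes in SCENARIOS.items()
        if all(availability.get(c, False) for c in classes)
    ]


# ---------------------------------------------------------------------------
# RELL-based tests
# ---------------------------------------------------------------------------

def kh_test(fit1: FitResult, fit2: FitResult, n_rell: int = 1000, seed: int = 0) -> float:
    """Kishino–Hasegawa test of two fits via RELL site resampling.

    The observed total log-likelihood difference is compared to a null
    generated by bootstrap-resampling sites and centering the replicate
    differences at zero; the two-sided p-value is the fraction of
    centered replicates at least as extreme as the observation.
    """
    l1, l2 = fit1.site_lnl, fit2.site_lnl
    if l1.shape != l2.shape:
        raise DataError("site log-likelihood vectors differ in length")
    d = l1 - l2
    obs = float(d.sum())
    rng = np.random.default_rng(seed)
    n = d.size
    idx = rng.integers(0, n, size=(n_rell, n))
    reps = d[idx].sum(axis=1)
    centered = reps - reps.mean()
    return float(np.mean(np.abs(centered) >= abs(obs)))


def sh_test(
    fits: Mapping[str, FitResult],
    n_rell: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, float], set[str]]:
    """Shimodaira–Hasegawa test over a candidate scenario set.

    All candidates are compared to the best via RELL replicates with
    per-candidate centering and the max statistic; candidates with
    p < alpha are rejected.  The best candidate is never rejected; a
    single candidate yields an empty rejection set.
    """
    names = sorted(fits)
    if len(names) < 2:
        return ({n: 1.0 for n in names}, set())
    lmat = np.stack([fits[n].site_lnl for n in names])
    n_sites = lmat.shape[1]
    if any(fits[n].site_lnl.size != n_sites for n in names):
        raise DataError("candidates have unequal site counts")
    totals = lmat.sum(axis=1)
    t_obs = totals.max() - totals
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_sites, size=(n_rell, n_sites))
    reps = lmat[:, idx].sum(axis=2)  # (n_candidates, n_rell)
    centered = reps - reps.mean(axis=1, keepdims=True)
    best_rep = centered.max(axis=0)
    t_rep = best_rep[None, :] - centered
    p = {names[i]: float(np.mean(t_rep[i] >= t_obs[i])) for i in range(len(names))}
    best_name = names[int(np.argmax(totals))]
    rejected = {n for n in names if p[n] < alpha and n != best_name}
    return p, rejected


# ---------------------------------------------------------------------------
# per-group pipeline
# ---------------------------------------------------------------------------

@dataclass
class TreeChoice:
    constrained_fit: FitResult
    unconstrained_fit: FitResult | None
    kh_p: float
    chosen: str  # constrained | unconstrained


@dataclass
class ScenarioTestResult:
    group_id: str
    fitted: dict[str, FitResult]
    skipped: dict[str, str]
    sh_p: dict[str, float]
    rejected: set[str]
    null_rejected: bool
    branch_a_category: str  # reject_TWOSTEP | reject_neither | reject_SINGLE | n.a.
    branch_bcd_category: str  # reject_TWOSTEP | reject_neither | reject_MULTI | n.a.
    tree_choice: TreeChoice | None = None

    def summary(self) -> dict:
        return {
            "group_id": self.group_id,
            "fitted": {
                name: {
                    "lnl": fit.lnl_total,
                    "kappa": fit.params.kappa,
                    "omega": fit.params.omega_by_class,
                    "converged": fit.converged,
                }
                for name, fit in self.fitted.items()
            },
            "skipped": self.skipped,
            "sh_p": self.sh_p,
            "rejected": sorted(self.rejected),
            "null_rejected": self.null_rejected,
            "branch_a_category": self.branch_a_category,
            "branch_bcd_category": self.branch_bcd_category,
            "tree": None if self.tree_choice is None else self.tree_choice.chosen,
        }


def _pair_category(
    null_rejected: bool,
    fitted: Mapping[str, FitResult],
    rejected: set[str],
    first: str,
    second: str,
) -> str:
    """Classify a group on one table row from the rejection pattern of a
    scenario pair; n.a. when out of scope (NULL retained, a scenario not
    fitted, or both rejected)."""
    if not null_rejected or first not in fitted or second not in fitted:
        return "n.a."
    r1, r2 = first in rejected, second in rejected
    if r1 and r2:
        return "n.a."
    if r2:
        return f"reject_{second}"
    if r1:
        return f"reject_{first}"
    return "reject_neither"


def run_group(
    alignment: CodonAlignment,
    constrained_tree: Phylogeny,
    unconstrained_tree: Phylogeny | None,
    clades: CladeDefinitions,
    config: RunConfig | None = None,
    group_id: str = "group",
) -> ScenarioTestResult:
    """Full scenario test for one ortholog group.

    The constrained tree is used unless the unconstrained one is
    significantly better under the one-ratio model (KH test, p < alpha).
    The NULL fit estimates branch lengths (per ``branch_length_mode``);
    alternative scenarios reuse them.  The SH test runs jointly over
    NULL and every fitted alternative.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    kh_seed, sh_seed = (int(s) for s in rng.integers(0, 2**31 - 1, size=2))

    avail_c = label_branches(constrained_tree, clades)
    null_c = fit_model(
        alignment, constrained_tree, (), config, scenario="NULL"
    )
    choice: TreeChoice
    if unconstrained_tree is not None:
        avail_u = label_branches(unconstrained_tree, clades)
        null_u = fit_model(
            alignment, unconstrained_tree, (), config, scenario="NULL"
        )
        kh_p = kh_test(null_c, null_u, config.n_rell, kh_seed)
        if kh_p < config.kh_alpha and null_u.lnl_total > null_c.lnl_total:
            choice = TreeChoice(null_c, null_u, kh_p, "unconstrained")
            tree, availability, null_fit = unconstrained_tree, avail_u, null_u
        else:
            choice = TreeChoice(null_c, null_u, kh_p, "constrained")
            tree, availability, null_fit = constrained_tree, avail_c, null_c
    else:
        choice = TreeChoice(null_c, None, 1.0, "constrained")
        tree, availability, null_fit = constrained_tree, avail_c, null_c

    fitted: dict[str, FitResult] = {"NULL": null_fit}
    skipped: dict[str, str] = {}
    for name, classes in SCENARIOS.items():
        if name == "NULL":
            continue
        missing = [c for c in classes if not availability.get(c, False)]
        if missing:
            skipped[name] = f"missing branch class(es): {','.join(missing)}"
            continue
        # warm-start each scenario from every fitted sub-scenario it
        # extends, so the nesting inequality holds by construction
        warm = [
            fitted[sub].params
            for sub, sub_classes in SCENARIOS.items()
            if sub in fitted and set(sub_classes) <= set(classes)
        ]
        fitted[name] = fit_model(
            alignment,
            tree,
            classes,
            config,
            fixed_lengths=null_fit.branch_lengths,
            branch_length_mode="fixed",
            scenario=name,
            start_params=warm,
        )
    sh_p, rejected = sh_test(fitted, config.n_rell, config.sh_alpha, sh_seed)
    null_rejected = "NULL" in rejected
    return ScenarioTestResult(
        group_id=group_id,
        fitted=fitted,
        skipped=skipped,
        sh_p=sh_p,
        rejected=rejected,
        null_rejected=null_rejected,
        branch_a_category=_pair_category(
            null_rejected, fitted, rejected, "SINGLE", "TWOSTEP"
        ),
        branch_bcd_category=_pair_category(
            null_rejected, fitted, rejected, "MULTI", "TWOSTEP"
        ),
        tree_choice=choice,
    )


def tabulate(results: Sequence[ScenarioTestResult]) -> pd.DataFrame:
    """Two-row count/percentage table of rejection categories.

    Row ``a`` counts groups over {reject TWOSTEP, reject neither,
    reject SINGLE}; row ``b,c,d`` over {reject TWOSTEP, reject neither,
    reject MULTI}.  Groups whose category is n.a. for a row are
    excluded from that row.
    """
    rows = []
    for branch, attr, alternative in (
        ("a", "branch_a_category", "SINGLE"),
        ("b,c,d", "branch_bcd_category", "MULTI"),
    ):
        cols = ["reject_TWOSTEP", "reject_neither", f"reject_{alternative}"]
        counts = {c: 0 for c in cols}
        for res in results:
            cat = getattr(res, attr)
            if cat in counts:
                counts[cat] += 1
        total = sum(counts.values())
        row: dict[str, object] = {
            "branches": branch,
            "alternative": alternative,
            "total": total,
        }
        for c, generic in zip(cols, ("reject_TWOSTEP", "reject_neither", "reject_alternative")):
            row[generic] = counts[c]
            row[f"{generic}_pct"] = 100.0 * counts[c] / total if total else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
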