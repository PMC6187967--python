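"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover the pipeline's inputs: overlapping ortholog
predictions over many species with paralogs and overlap noise; paired
nodule/root log2 fold-change tables with controllable cross-species
correlation and a stated fraction of enhanced groups; and codon
alignments evolved along a branch-class-labeled tree under the same
GY94 process the inference uses.  Every generator is a pure function of
its config and seed, and returns the ground truth alongside the data so
oracle tests can score recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .codon_model import (
    BACKGROUND,
    CODONS,
    N_CODONS,
    CodonModelParams,
    build_rate_matrix,
    transition_matrix,
)
from .data_io import CodonAlignment, DataError, ExpressionRecord, OrthologPrediction, Phylogeny
from .ortho_merge import MergedOrthoGroup
from .similarity import DissonancePair

__all__ = [
    "ExpressionSimConfig",
    "SeqSimConfig",
    "SimulatedExpression",
    "gen_ortholog_predictions",
    "gen_expression",
    "gen_codon_alignment",
]


# ---------------------------------------------------------------------------
# ortholog predictions
# ---------------------------------------------------------------------------

def gen_ortholog_predictions(
    n_families: int,
    species_list: Sequence[str],
    dup_rate: float = 0.0,
    noise: float = 0.0,
    seed: int = 0,
) -> tuple[list[OrthologPrediction], list[frozenset]]:
    """Ground-truth ortholog families and noisy per-gene predictions.

    Each family holds one gene per species plus extra paralogs appearing
    with probability ``dup_rate`` (geometric, capped at 3 extras).  Each
    gene predicts its own family; with probability ``noise`` a
    prediction additionally drags in one random gene from another
    family, so merging fuses the two families.  Returns (predictions,
    truth families).
    """
    rng = np.random.default_rng(seed)
    families: list[set] = []
    for f in range(n_families):
        fam = set()
        for sp in species_list:
            fam.add((sp, f"{sp}_g{f:05d}"))
            extra = 0
            while extra < 3 and rng.random() < dup_rate:
                extra += 1
                fam.add((sp, f"{sp}_g{f:05d}p{extra}"))
        families.append(fam)
    predictions: list[OrthologPrediction] = []
    for f, fam in enumerate(families):
        for gene in sorted(fam):
            members = set(fam)
            if noise > 0 and len(families) > 1 and rng.random() < noise:
                other = int(rng.integers(0, len(families) - 1))
                if other >= f:
                    other += 1
                stranger = sorted(families[other])[
                    int(rng.integers(0, len(families[other])))
                ]
                members.add(stranger)
            predictions.append(OrthologPrediction(gene, frozenset(members)))
    return predictions, [frozenset(f) for f in families]


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSimConfig:
    """Controls for the paired fold-change generator.

    Null (non-enhanced) fold changes are multivariate normal across
    species with marginal sd ``null_sd`` and pairwise correlation
    ``rho``; enhanced groups add a shared tissue shift drawn from
    N(effect_mean, effect_sd) (positive for nodule, negative for root).
    Paralogs scatter around their species' group value with sd
    ``within_sd``.  Enhanced genes receive adjusted p-values below any
    practical cutoff, null genes clearly above, so threshold logic is
    exercisable without a differential-expression model.
    """

    n_groups: int = 1000
    species: tuple[str, ...] = ("Ct", "Dg", "Mt")
    paralog_rate: float = 0.0
    frac_nodule: float = 0.1
    frac_root: float = 0.1
    effect_mean: float = 3.0
    effect_sd: float = 1.0
    null_sd: float = 1.5
    within_sd: float = 0.5
    rho: float = 0.4
    p_enhanced_max: float = 0.0005
    p_null_min: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.frac_nodule <= 1 and 0 <= self.frac_root <= 1):
            raise DataError("enhanced fractions must lie in [0, 1]")
        if self.frac_nodule + self.frac_root > 1:
            raise DataError("enhanced fractions must sum to <= 1")
        if not (-1 <= self.rho <= 1):
            raise DataError("rho must lie in [-1, 1]")
        if len(self.species) > 2 and self.rho < 0:
            raise DataError("negative rho only supported for two species")


@dataclass
class SimulatedExpression:
    records: dict[str, list[ExpressionRecord]]
    groups: list[MergedOrthoGroup]
    truth: pd.DataFrame  # group_id, tissue (nodule|root|none), per-species fc
    config: ExpressionSimConfig

    def dissonance_pair(self, species_a: str, species_b: str) -> DissonancePair:
        """Member fold-change vectors per group for one species pair."""
        by_gene = {
            sp: {r.gene_id: r.log2fc for r in recs}
            for sp, recs in self.records.items()
        }
        ga: dict[str, np.ndarray] = {}
        gb: dict[str, np.ndarray] = {}
        for grp in self.groups:
            a = [by_gene[species_a][g] for sp, g in sorted(grp.members) if sp == species_a]
            b = [by_gene[species_b][g] for sp, g in sorted(grp.members) if sp == species_b]
            ga[grp.group_id] = np.array(a)
            gb[grp.group_id] = np.array(b)
        return DissonancePair(species_a, species_b, ga, gb)


def gen_expression(cfg: ExpressionSimConfig) -> SimulatedExpression:
    rng = np.random.default_rng(cfg.seed)
    n, k = cfg.n_groups, len(cfg.species)
    # correlated null component: factor model for rho >= 0, explicit
    # Cholesky for a (possibly negative) two-species rho
    if k == 2:
        cov = cfg.null_sd**2 * np.array([[1.0, cfg.rho], [cfg.rho, 1.0]])
        base = rng.multivariate_normal(np.zeros(2), cov, size=n)
    else:
        z = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, k))
        base = cfg.null_sd * (np.sqrt(cfg.rho) * z + np.sqrt(1 - cfg.rho) * e)

    tissue = np.array(["none"] * n, dtype=object)
    n_nod = int(round(cfg.frac_nodule * n))
    n_root = int(round(cfg.frac_root * n))
    order = rng.permutation(n)
    tissue[order[:n_nod]] = "nodule"
    tissue[order[n_nod : n_nod + n_root]] = "root"
    shift = np.zeros(n)
    enhanced = tissue != "none"
    shift[enhanced] = np.abs(
        rng.normal(cfg.effect_mean, cfg.effect_sd, size=int(enhanced.sum()))
    )
    shift[tissue == "root"] *= -1.0
    species_fc = base + shift[:, None]

    records: dict[str, list[ExpressionRecord]] = {sp: [] for sp in cfg.species}
    groups: list[MergedOrthoGroup] = []
    truth_rows = []
    for g in range(n):
        gid = f"SimGroup{g + 1:06d}"
        members = set()
        for j, sp in enumerate(cfg.species):
            n_par = 1
            while n_par < 4 and rng.random() < cfg.paralog_rate:
                n_par += 1
            for p in range(n_par):
                gene = f"{sp}_s{g:05d}" + (f"p{p}" if p else "")
                fc = species_fc[g, j] + (
                    rng.normal(0.0, cfg.within_sd) if n_par > 1 else 0.0
                )
                if tissue[g] == "none":
                    adj_p = rng.uniform(cfg.p_null_min, 1.0)
                else:
                    adj_p = rng.uniform(0.0, cfg.p_enhanced_max)
                records[sp].append(ExpressionRecord(gene, sp, float(fc), float(adj_p)))
                members.add((sp, gene))
        groups.append(MergedOrthoGroup(gid, frozenset(members)))
        row = {"group_id": gid, "tissue": tissue[g]}
        for j, sp in enumerate(cfg.species):
            row[f"fc_{sp}"] = species_fc[g, j]
        truth_rows.append(row)
    return SimulatedExpression(records, groups, pd.DataFrame(truth_rows), cfg)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------

@dataclass
class SeqSimConfig:
    tree: Phylogeny  # branch classes already assigned on the edges
    omega_by_class: dict[str, float] = field(
        default_factory=lambda: {BACKGROUND: 0.2}
    )
    kappa: float = 2.0
    pi: np.ndarray | None = None  # uniform over sense codons when None
    n_codons: int = 300
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_codons < 1:
            raise DataError("n_codons must be >= 1")
        if any(w <= 0 for w in self.omega_by_class.values()):
            raise DataError("omega values must be > 0")
        if BACKGROUND not in self.omega_by_class:
            self.omega_by_class[BACKGROUND] = 0.2
        if self.pi is None:
            self.pi = np.full(N_CODONS, 1.0 / N_CODONS)
        self.pi = np.asarray(self.pi, dtype=float)


def gen_codon_alignment(cfg: SeqSimConfig) -> tuple[CodonAlignment, CodonModelParams]:
    """Evolve codon states from the root down the labeled tree.

    The root sequence is drawn from pi; each branch applies the
    transition matrix expm(Q_class * t) of its class.  Returns the tip
    alignment and the generating parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    params = CodonModelParams(cfg.kappa, dict(cfg.omega_by_class), cfg.pi)
    qs = {
        cls: build_rate_matrix(cfg.kappa, w, params.pi)
        for cls, w in cfg.omega_by_class.items()
    }
    tree = cfg.tree.tree
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.choice(N_CODONS, size=cfg.n_codons, p=params.pi)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        edge = node.edge
        cls = getattr(edge, "branch_class", None)
        if cls is None:
            raise DataError("simulation tree has an unlabeled branch")
        if cls not in qs:
            qs[cls] = build_rate_matrix(
                cfg.kappa, params.omega(cls), params.pi
            )
        t = float(edge.length if edge.length is not None else 0.0)
        parent_states = states[id(node.parent_node)]
        if t == 0.0:
            states[id(node)] = parent_states.copy()
            continue
        p = transition_matrix(qs[cls], t, params.pi)
        child = np.empty_like(parent_states)
        for s in np.unique(parent_states):
            mask = parent_states == s
            child[mask] = rng.choice(N_CODONS, size=int(mask.sum()), p=p[s])
        states[id(node)] = child
    sequences = {}
    for leaf in tree.leaf_node_iter():
        seq = states[id(leaf)]
        sequences[leaf.taxon.label] = "".join(CODONS[s] for s in seq)
    return CodonAlignment(sequences), params
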