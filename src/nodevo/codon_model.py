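"""Codon substitution likelihood engine with per-branch-class dN/dS.

The substitution process is the Goldman–Yang codon model: instantaneous
rates between sense codons differing at a single nucleotide are
proportional to the target codon frequency pi_j, multiplied by the
transition/transversion ratio kappa for transitions and by omega
(dN/dS) for amino-acid-changing substitutions.  Stop codons are
excluded (61 sense codons, universal code).  Each branch of the tree
carries a *branch class* label; every class has its own omega while
kappa and the codon frequencies are shared, which is the branch model
used to detect shifts in selective pressure on pre-specified branches.

Per-site log-likelihoods are computed by Felsenstein pruning with the
transition matrix expm(Q_class * t) on each branch, obtained from the
symmetric eigendecomposition that time-reversibility affords.  Gap or
ambiguous codons are treated as fully missing (sum over all 61 states).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy import optimize

from .data_io import CodonAlignment, DataError, Phylogeny, RunConfig, _is_resolved

__all__ = [
    "CODONS",
    "CODON_INDEX",
    "N_CODONS",
    "BRANCH_CLASSES",
    "BACKGROUND",
    "CodonModelParams",
    "FitResult",
    "build_rate_matrix",
    "transition_matrix",
    "f3x4_frequencies",
    "empirical_codon_frequencies",
    "assign_uniform_classes",
    "TreeIndex",
    "prune_loglik",
    "fit_model",
]

# ---------------------------------------------------------------------------
# genetic code (universal); 61 sense codons in lexicographic ACGT order
# ---------------------------------------------------------------------------

from Bio.Data import CodonTable as _CodonTable

_TABLE = _CodonTable.unambiguous_dna_by_id[1]
CODONS: tuple[str, ...] = tuple(
    sorted(c for c in _TABLE.forward_table if len(c) == 3 and set(c) <= set("ACGT"))
)
N_CODONS = len(CODONS)  # 61
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
_AA = np.array([_TABLE.forward_table[c] for c in CODONS])

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

BACKGROUND = "background"
BRANCH_CLASSES = (BACKGROUND, "a", "b", "c", "d")


def _pair_structure() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Index arrays over codon pairs differing at exactly one nucleotide."""
    ii, jj, ts, nonsyn = [], [], [], []
    for i, j in itertools.permutations(range(N_CODONS), 2):
        ci, cj = CODONS[i], CODONS[j]
        diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
        if len(diffs) != 1:
            continue
        ii.append(i)
        jj.append(j)
        ts.append(diffs[0] in _TRANSITIONS)
        nonsyn.append(_AA[i] != _AA[j])
    return (
        np.array(ii),
        np.array(jj),
        np.array(ts, dtype=bool),
        np.array(nonsyn, dtype=bool),
    )


_I, _J, _TS, _NONSYN = _pair_structure()

_PI_FLOOR = 1e-10  # keep observed codons likelihood-visible under sparse F3x4


@dataclass
class CodonModelParams:
    kappa: float
    omega_by_class: dict[str, float]
    pi: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        if self.pi.shape != (N_CODONS,):
            raise DataError(f"pi must have {N_CODONS} entries")
        if np.any(self.pi < 0) or not np.isclose(self.pi.sum(), 1.0, atol=1e-8):
            raise DataError("pi must be non-negative and sum to 1")
        if self.kappa <= 0 or any(w <= 0 for w in self.omega_by_class.values()):
            raise DataError("kappa and omega must be > 0")

    def omega(self, branch_class: str) -> float:
        if branch_class in self.omega_by_class:
            return self.omega_by_class[branch_class]
        return self.omega_by_class[BACKGROUND]


@dataclass
class FitResult:
    lnl_total: float
    site_lnl: np.ndarray
    params: CodonModelParams
    branch_lengths: np.ndarray
    scale: float = 1.0
    converged: bool = True
    n_iter: int = 0
    scenario: str | None = None

    def __post_init__(self) -> None:
        if not np.isclose(self.lnl_total, float(np.sum(self.site_lnl)), atol=1e-8):
            raise DataError("lnl_total does not match the per-site sum")


# ---------------------------------------------------------------------------
# rate matrix
# ---------------------------------------------------------------------------

def build_rate_matrix(kappa: float, omega: float, pi: np.ndarray) -> np.ndarray:
    """GY94 generator, scaled to one expected substitution per codon.

    Off-diagonal entries are zero for multi-nucleotide changes and
    pi_j * {1, kappa} * {1, omega} otherwise; rows sum to zero.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (N_CODONS,) or np.any(pi < 0) or not np.isclose(pi.sum(), 1.0):
        raise DataError("invalid codon frequency vector")
    q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_J] * np.where(_TS, kappa, 1.0) * np.where(_NONSYN, omega, 1.0)
    q[_I, _J] = rates
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -float(pi @ np.diag(q))
    if mu <= 0:
        raise DataError("degenerate rate matrix (zero total rate)")
    return q / mu


def _eigen(q: np.ndarray, pi: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Symmetric eigendecomposition of a reversible generator.

    Returns (A, lam, B) with expm(Q t) = A @ diag(exp(lam t)) @ B.
    """
    sqrt_pi = np.sqrt(np.maximum(pi, _PI_FLOOR))
    s = (sqrt_pi[:, None] * q) / sqrt_pi[None, :]
    lam, v = np.linalg.eigh((s + s.T) / 2.0)
    a = v / sqrt_pi[:, None]
    b = v.T * sqrt_pi[None, :]
    return a, lam, b


def transition_matrix(q: np.ndarray, t: float, pi: np.ndarray) -> np.ndarray:
    """expm(Q t) via the reversible eigendecomposition; rows sum to 1."""
    a, lam, b = _eigen(q, pi)
    p = (a * np.exp(lam * t)[None, :]) @ b
    np.clip(p, 0.0, None, out=p)
    p /= p.sum(axis=1, keepdims=True)
    return p


# ---------------------------------------------------------------------------
# codon frequencies
# ---------------------------------------------------------------------------

def f3x4_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """F3x4: codon frequencies from position-specific nucleotide counts."""
    counts = np.zeros((3, 4))
    nuc_index = {n: k for k, n in enumerate("ACGT")}
    for taxon in alignment.taxa:
        for codon in alignment.codons(taxon):
            if _is_resolved(codon):
                for pos, nuc in enumerate(codon):
                    counts[pos, nuc_index[nuc]] += 1
    if counts.sum() == 0:
        raise DataError("no resolved codons in alignment")
    freqs = counts / counts.sum(axis=1, keepdims=True)
    pi = np.array(
        [
            freqs[0, nuc_index[c[0]]]
            * freqs[1, nuc_index[c[1]]]
            * freqs[2, nuc_index[c[2]]]
            for c in CODONS
        ]
    )
    pi = np.maximum(pi, _PI_FLOOR)
    return pi / pi.sum()


def empirical_codon_frequencies(alignment: CodonAlignment) -> np.ndarray:
    """Observed sense-codon frequencies, floored and renormalized."""
    counts = np.zeros(N_CODONS)
    for taxon in alignment.taxa:
        for codon in alignment.codons(taxon):
            if _is_resolved(codon):
                counts[CODON_INDEX[codon]] += 1
    if counts.sum() == 0:
        raise DataError("no resolved codons in alignment")
    pi = np.maximum(counts / counts.sum(), _PI_FLOOR)
    return pi / pi.sum()


# ---------------------------------------------------------------------------
# tree indexing and pruning
# ---------------------------------------------------------------------------

def assign_uniform_classes(phy: Phylogeny, label: str = BACKGROUND) -> Phylogeny:
    """Label every branch of ``phy`` with the same class (in place)."""
    for edge in phy.tree.preorder_edge_iter():
        edge.branch_class = label
    return phy


class TreeIndex:
    """Postorder arrays for fast repeated pruning on one tree.

    Node 0..n-1 in postorder, root last.  Each non-root node stores the
    length and class of the branch above it.
    """

    def __init__(self, phy: Phylogeny, alignment: CodonAlignment):
        tree = phy.tree
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self._node_pos = {id(n): i for i, n in enumerate(nodes)}
        self.children: list[list[int]] = [[] for _ in nodes]
        self.lengths = np.zeros(self.n_nodes)
        self.classes: list[str] = [BACKGROUND] * self.n_nodes
        self.tip_states: dict[int, np.ndarray] = {}
        self.root = self.n_nodes - 1
        taxa = set(alignment.taxa)
        for i, node in enumerate(nodes):
            if node is not tree.seed_node:
                edge = node.edge
                self.lengths[i] = float(edge.length if edge.length is not None else 0.0)
                cls = getattr(edge, "branch_class", None)
                if cls is None:
                    raise DataError(
                        "unlabeled branch: run label_branches or "
                        "assign_uniform_classes first"
                    )
                self.classes[i] = cls
            if node.is_leaf():
                label = node.taxon.label
                if label not in taxa:
                    raise DataError(f"tip {label!r} missing from alignment")
                states = np.array(
                    [
                        CODON_INDEX[c] if _is_resolved(c) else -1
                        for c in alignment.codons(label)
                    ],
                    dtype=np.int64,
                )
                self.tip_states[i] = states
            else:
                for child in node.child_nodes():
                    self.children[i].append(self._node_pos[id(child)])
        self.n_sites = alignment.n_codons
        self.class_set = sorted(
            {self.classes[i] for i in range(self.n_nodes) if i != self.root}
        )


def _site_loglik(
    index: TreeIndex,
    params: CodonModelParams,
    lengths: np.ndarray | None = None,
) -> np.ndarray:
    """Per-site log-likelihood by pruning; lengths override the tree's."""
    if lengths is None:
        lengths = index.lengths
    pi = np.maximum(params.pi, _PI_FLOOR)
    pi = pi / pi.sum()
    eigs = {}
    for cls in index.class_set:
        q = build_rate_matrix(params.kappa, params.omega(cls), pi)
        eigs[cls] = _eigen(q, pi)
    # transition matrix above each non-root node
    pmats: dict[int, np.ndarray] = {}
    for i in range(index.n_nodes):
        if i == index.root:
            continue
        a, lam, b = eigs[index.classes[i]]
        p = (a * np.exp(lam * lengths[i])[None, :]) @ b
        np.clip(p, 0.0, None, out=p)
        pmats[i] = p

    n_sites = index.n_sites
    partial: dict[int, np.ndarray] = {}
    log_scale = np.zeros(n_sites)
    for i in range(index.n_nodes):
        if i in index.tip_states:
            continue  # tip partials are consumed directly below
        prod = np.ones((n_sites, N_CODONS))
        for c in index.children[i]:
            p = pmats[c]
            if c in index.tip_states:
                states = index.tip_states[c]
                contrib = np.ones((n_sites, N_CODONS))
                resolved = states >= 0
                contrib[resolved] = p[:, states[resolved]].T
            else:
                contrib = partial.pop(c) @ p.T
            prod *= contrib
        top = prod.max(axis=1)
        top[top == 0.0] = 1.0
        prod /= top[:, None]
        log_scale += np.log(top)
        partial[i] = prod
    if index.root in index.tip_states:  # single-tip degenerate tree
        states = index.tip_states[index.root]
        lik = np.where(states >= 0, pi[np.maximum(states, 0)], 1.0)
        return np.log(lik)
    root_partial = partial[index.root]
    site_lik = root_partial @ pi
    return np.log(np.maximum(site_lik, 1e-300)) + log_scale


def prune_loglik(
    alignment: CodonAlignment,
    phy: Phylogeny,
    params: CodonModelParams,
) -> FitResult:
    """Likelihood of fixed parameters on a branch-class-labeled tree."""
    index = TreeIndex(phy, alignment)
    site_lnl = _site_loglik(index, params)
    return FitResult(
        float(site_lnl.sum()), site_lnl, params, index.lengths.copy(), 1.0, True, 0
    )


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------

_STARTS = ((2.0, 0.5), (4.0, 1.5))  # (kappa, omega) multi-start values


def fit_model(
    alignment: CodonAlignment,
    phy: Phylogeny,
    free_classes: Sequence[str],
    config: RunConfig | None = None,
    *,
    pi: np.ndarray | None = None,
    fixed_lengths: np.ndarray | None = None,
    branch_length_mode: str | None = None,
    scenario: str | None = None,
    start_params: CodonModelParams | Sequence[CodonModelParams] | None = None,
) -> FitResult:
    """Maximize the branch-model likelihood over kappa and per-class omega.

    ``free_classes`` lists the branch classes given their own omega; all
    other branches share the background omega.  Branch-length handling
    follows ``branch_length_mode`` (default from config): "fixed" keeps
    the input lengths, "scale" additionally fits a single rescaling
    factor, "full" fits every branch length.  Bounded quasi-Newton on
    log-transformed parameters with multi-start; non-convergence is
    flagged on the result, not fatal.
    """
    config = config or RunConfig()
    mode = branch_length_mode or config.branch_length_mode
    index = TreeIndex(phy, alignment)
    for cls in free_classes:
        if cls not in index.class_set:
            raise DataError(f"free class {cls!r} not present on the tree")
    free = sorted(set(free_classes))
    base_lengths = (
        np.asarray(fixed_lengths, dtype=float)
        if fixed_lengths is not None
        else index.lengths.copy()
    )
    if base_lengths.shape != index.lengths.shape:
        raise DataError("fixed_lengths does not match the tree")
    if pi is None:
        pi = f3x4_frequencies(alignment)

    lo_w, hi_w = config.omega_bounds
    lo_k, hi_k = config.kappa_bounds
    n_rate = 2 + len(free)  # kappa, background omega, free-class omegas
    nonroot = np.array([i for i in range(index.n_nodes) if i != index.root])
    min_len = 1e-6

    def unpack(x: np.ndarray) -> tuple[CodonModelParams, np.ndarray, float]:
        kappa = float(np.exp(x[0]))
        omegas = {BACKGROUND: float(np.exp(x[1]))}
        for k, cls in enumerate(free):
            omegas[cls] = float(np.exp(x[2 + k]))
        params = CodonModelParams(kappa, omegas, pi)
        if mode == "fixed":
            lengths, scale = base_lengths, 1.0
        elif mode == "scale":
            scale = float(np.exp(x[n_rate]))
            lengths = base_lengths * scale
        else:  # full
            lengths = base_lengths.copy()
            lengths[nonroot] = np.exp(x[n_rate:])
            scale = 1.0
        return params, lengths, scale

    def neg_lnl(x: np.ndarray) -> float:
        params, lengths, _ = unpack(x)
        return -float(_site_loglik(index, params, lengths).sum())

    bounds = [(np.log(lo_k), np.log(hi_k)), (np.log(lo_w), np.log(hi_w))]
    bounds += [(np.log(lo_w), np.log(hi_w))] * len(free)
    if mode == "scale":
        bounds += [(np.log(1e-3), np.log(1e3))]
    elif mode == "full":
        bounds += [(np.log(min_len), np.log(50.0))] * len(nonroot)

    best: optimize.OptimizeResult | None = None
    n_starts = max(1, config.n_starts)
    # warm starts (e.g. from the NULL fit, or from SINGLE/MULTI when
    # fitting TWOSTEP) guarantee a nested model never scores below the
    # model(s) it extends: the optimizer begins at their optimum
    if start_params is None:
        warm: list[CodonModelParams] = []
    elif isinstance(start_params, CodonModelParams):
        warm = [start_params]
    else:
        warm = list(start_params)
    starts: list[tuple[float, list[float]]] = [
        (p.kappa, [p.omega(BACKGROUND)] + [p.omega(c) for c in free]) for p in warm
    ]
    for kappa0, omega0 in _STARTS[: max(0, n_starts - len(starts))]:
        starts.append((kappa0, [omega0] * (1 + len(free))))
    for kappa0, omegas0 in starts:
        x0 = [np.log(kappa0)] + [np.log(w) for w in omegas0]
        if mode == "scale":
            x0 += [0.0]
        elif mode == "full":
            x0 += list(np.log(np.maximum(base_lengths[nonroot], min_len)))
        res = optimize.minimize(
            neg_lnl,
            np.array(x0),
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": config.lnl_tol, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    params, lengths, scale = unpack(best.x)
    site_lnl = _site_loglik(index, params, lengths)
    return FitResult(
        float(site_lnl.sum()),
        site_lnl,
        params,
        lengths,
        scale,
        bool(best.success),
        int(best.nit),
        scenario,
    )
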