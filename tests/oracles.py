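"""Independent brute-force oracles used by unit and acceptance tests."""

import numpy as np

from nodevo.codon_model import (
    CODON_INDEX,
    N_CODONS,
    build_rate_matrix,
    transition_matrix,
)


def exhaustive_quartet_loglik(phy, aln, params):
    """Site log-likelihoods on a rooted 4-taxon tree by summing over all
    internal-node codon assignments (61^3 terms per site).

    Independent of the pruning implementation: transition matrices are
    taken per edge and combined by explicit enumeration.
    """
    tree = phy.tree
    pi = params.pi
    pmats = {}
    for node in tree.postorder_node_iter():
        if node is not tree.seed_node:
            q = build_rate_matrix(
                params.kappa, params.omega(node.edge.branch_class), pi
            )
            pmats[id(node)] = transition_matrix(q, node.edge.length, pi)
    root = tree.seed_node
    left, right = root.child_nodes()
    lc = left.child_nodes()
    rc = right.child_nodes()
    states = {
        leaf.taxon.label: [CODON_INDEX[c] for c in aln.codons(leaf.taxon.label)]
        for leaf in tree.leaf_node_iter()
    }
    out = []
    for site in range(aln.n_codons):
        x = {label: s[site] for label, s in states.items()}
        total = 0.0
        for r in range(N_CODONS):
            for u in range(N_CODONS):
                for v in range(N_CODONS):
                    term = pi[r] * pmats[id(left)][r, u] * pmats[id(right)][r, v]
                    term *= pmats[id(lc[0])][u, x[lc[0].taxon.label]]
                    term *= pmats[id(lc[1])][u, x[lc[1].taxon.label]]
                    term *= pmats[id(rc[0])][v, x[rc[0].taxon.label]]
                    term *= pmats[id(rc[1])][v, x[rc[1].taxon.label]]
                    total += term
        out.append(np.log(total))
    return np.array(out)
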