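"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: truth tables are
enumerated exhaustively, LP optima come from basic-feasible-solution
enumeration, and dead ends from a direct scan of the stoichiometry
table.
"""

from __future__ import annotations

import itertools

import numpy as np

from gemproject import gpr as gprmod


def truth_table(evaluator, genes):
    """Evaluate a boolean function over every subset of the genes."""
    genes = sorted(genes)
    table = {}
    for r in range(len(genes) + 1):
        for combo in itertools.combinations(genes, r):
            table[frozenset(combo)] = bool(evaluator(set(combo)))
    return table


def eval_tree_directly(tree, present):
    """Plain recursive evaluation, independent of gemproject.gpr.evaluate."""
    if isinstance(tree, gprmod.Gene):
        return tree.gene in present
    if isinstance(tree, gprmod.And):
        return all(eval_tree_directly(c, present) for c in tree.children)
    return any(eval_tree_directly(c, present) for c in tree.children)


def eval_gene_sets(sets, present):
    """Membership semantics of a minimal-gene-set list."""
    return any(s <= present for s in sets)


def substitute_and_evaluate(tree, mapping, present_targets):
    """Semantic oracle for rewriting: replace each scaffold leaf by the OR
    of its target candidates (false when empty) and evaluate."""
    if isinstance(tree, gprmod.Gene):
        return any(t in present_targets for t in mapping.get(tree.gene, ()))
    if isinstance(tree, gprmod.And):
        return all(substitute_and_evaluate(c, mapping, present_targets) for c in tree.children)
    return any(substitute_and_evaluate(c, mapping, present_targets) for c in tree.children)


def lp_max_by_vertex_enumeration(S, bounds, c, tol=1e-9):
    """Maximize c.v subject to S v = 0, l <= v <= u by enumerating basic
    feasible solutions; intended for toy problems (<= ~8 reactions).

    For each choice of basic columns B (|B| = rank considerations handled
    via lstsq + residual check) and each assignment of the nonbasic
    variables to one of their finite bounds, solve for the basic part and
    keep feasible points.
    """
    S = np.asarray(S, dtype=float)
    m, n = S.shape
    lows = np.array([b[0] for b in bounds], dtype=float)
    ups = np.array([b[1] for b in bounds], dtype=float)
    c = np.asarray(c, dtype=float)
    best = None
    max_basis = min(m, n)
    for k in range(0, max_basis + 1):
        for basic in itertools.combinations(range(n), k):
            nonbasic = [j for j in range(n) if j not in basic]
            choices = []
            for j in nonbasic:
                opts = [v for v in (lows[j], ups[j]) if np.isfinite(v)]
                if not opts:
                    opts = [0.0]
                choices.append(sorted(set(opts)))
            B = S[:, list(basic)]
            for assignment in itertools.product(*choices):
                rhs = -S[:, nonbasic] @ np.array(assignment) if nonbasic else np.zeros(m)
                if k:
                    xb, *_ = np.linalg.lstsq(B, rhs, rcond=None)
                    if np.linalg.norm(B @ xb - rhs) > 1e-7:
                        continue
                else:
                    xb = np.zeros(0)
                    if np.linalg.norm(rhs) > 1e-7:
                        continue
                x = np.zeros(n)
                x[list(basic)] = xb
                x[nonbasic] = assignment
                if np.any(x < lows - tol) or np.any(x > ups + tol):
                    continue
                val = float(c @ x)
                if best is None or val > best:
                    best = val
    return best


def structural_dead_end_scan(model):
    """Direct stoichiometry-table scan for dead-end metabolites."""
    roles = {}
    for mid, met in model.metabolites.items():
        if met.boundary:
            continue
        produced = consumed = False
        for rxn in model.reactions.values():
            coef = rxn.stoichiometry.get(mid)
            if coef is None:
                continue
            forward_ok = rxn.upper_bound > 0
            backward_ok = rxn.lower_bound < 0
            if coef > 0:
                produced |= forward_ok
                consumed |= backward_ok
            elif coef < 0:
                consumed |= forward_ok
                produced |= backward_ok
        if produced and not consumed:
            roles[mid] = "never-consumed"
        elif consumed and not produced:
            roles[mid] = "never-produced"
    return roles
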