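"""Independent reference implementations used only to cross-check the
package: straight-line re-statements of the rules, exact arithmetic, and
brute-force enumeration.  Nothing here imports the code paths it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


# -- literal somatic filter rules -------------------------------------------


def literal_discovery(biopsies, blood):
    """Plain transcription of the discovery rules: some biopsy with
    BAF >= 5% and >= 3 alt reads; blood with >= 10x depth and 0 alt reads."""
    blood_alt, blood_depth = blood
    any_biopsy = False
    for alt, depth in biopsies.values():
        if depth == 0:
            continue
        baf = Fraction(alt, depth)
        if baf >= Fraction(5, 100) and alt >= 3:
            any_biopsy = True
    return any_biopsy and blood_depth >= 10 and blood_alt == 0


def literal_validation(biopsies, blood):
    """Plain transcription of the validation rules: some biopsy with
    BAF >= 3% and >= 10 alt reads; blood with >= 50x depth and BAF <= 1%."""
    blood_alt, blood_depth = blood
    any_biopsy = False
    for alt, depth in biopsies.values():
        if depth == 0:
            continue
        if Fraction(alt, depth) >= Fraction(3, 100) and alt >= 10:
            any_biopsy = True
    if blood_depth < 50:
        return False
    return any_biopsy and Fraction(blood_alt, blood_depth) <= Fraction(1, 100)


# -- exact binomial tail -----------------------------------------------------


def exact_binom_tail(k: int, n: int, p: Fraction = Fraction(2, 3)) -> float:
    """P(X >= k | n, p) by exact integer summation, converted to float at
    the very end."""
    num = p.numerator
    den = p.denominator
    total = sum(
        comb(n, i) * num**i * (den - num) ** (n - i) for i in range(k, n + 1)
    )
    return float(Fraction(total, den**n))


def exact_binom_tail_all(n: int, p: Fraction = Fraction(2, 3)) -> np.ndarray:
    """P(X >= k) for k = 0..n via exact suffix sums."""
    num, den = p.numerator, p.denominator
    terms = [comb(n, i) * num**i * (den - num) ** (n - i) for i in range(n + 1)]
    denom = den**n
    out = np.empty(n + 1)
    suffix = 0
    for k in range(n, -1, -1):
        suffix += terms[k]
        out[k] = float(Fraction(suffix, denom))
    return out


# -- brute-force clone-tree enumeration -------------------------------------


def _is_acyclic(parent: dict[str, str]) -> bool:
    for node in parent:
        seen = {node}
        cur = parent[node]
        while cur != "root":
            if cur in seen:
                return False
            seen.add(cur)
            cur = parent[cur]
    return True


def _consistent(parent: dict[str, str], phi, eps: float) -> bool:
    clones = list(phi.index)
    cols = list(phi.columns)
    for c in clones:
        p = parent[c]
        if p != "root" and any(phi.loc[c, b] > phi.loc[p, b] + eps for b in cols):
            return False
    for node in ["root"] + clones:
        kids = [c for c in clones if parent[c] == node]
        if len(kids) < 2:
            continue
        for b in cols:
            cap = 1.0 if node == "root" else phi.loc[node, b]
            if sum(phi.loc[k, b] for k in kids) > cap + eps:
                return False
    return True


def enumerate_consistent_trees(phi, eps: float) -> list[dict[str, str]]:
    """All rooted trees over the clusters (each cluster choosing any other
    cluster or the root as parent) that satisfy the child-below-parent and
    sibling-sum constraints under ``eps``.  Exhaustive for small cluster
    counts; parent choices are pre-pruned by the pairwise child-below-parent
    test, which any consistent tree must pass."""
    clones = list(phi.index)
    cols = list(phi.columns)
    allowed = {}
    for c in clones:
        opts = ["root"]
        for p in clones:
            if p != c and all(phi.loc[c, b] <= phi.loc[p, b] + eps for b in cols):
                opts.append(p)
        allowed[c] = opts
    out = []
    for combo in itertools.product(*(allowed[c] for c in clones)):
        parent = dict(zip(clones, combo))
        if _is_acyclic(parent) and _consistent(parent, phi, eps):
            out.append(parent)
    return out


# -- tree comparison ---------------------------------------------------------


def same_tree_under_mapping(
    parent_a: dict[str, str], parent_b: dict[str, str], a_to_b: dict[str, str]
) -> bool:
    """Do two parent maps describe the same rooted tree once A's node names
    are translated through ``a_to_b``?"""
    if set(a_to_b) != set(parent_a) or set(a_to_b.values()) != set(parent_b):
        return False
    for child, par in parent_a.items():
        want = "root" if par == "root" else a_to_b[par]
        if parent_b[a_to_b[child]] != want:
            return False
    return True
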