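"""Clone-tree reconstruction from per-biopsy clone fractions.

The inheritance assumption: every clone carries all somatic mutations of its
ancestors, so a clone's carrying fraction phi (fraction of cancer cells
bearing its private mutations, i.e. the clone plus all descendants) can
never exceed an ancestor's in any biopsy, and sibling subclones cannot sum
past their parent (the pigeonhole constraint).

``build_tree`` turns a clones x biopsies phi matrix into a rooted tree:

* A is an ancestor of B iff phi(A, b) >= phi(B, b) - eps in every biopsy b
  and B is present (phi > eps) only where A is present;
* each cluster's parent is its minimal (lowest) ancestor; clusters with no
  ancestor hang off a virtual root whose phi is 1 everywhere;
* among multiple minimal ancestors the most prevalent one (largest phi sum
  over biopsies) is chosen, ties broken by cluster id, and the ambiguity is
  recorded;
* the constructed tree is then validated (single root, acyclic, child and
  sibling-sum constraints within eps); an inconsistency raises
  ``TreeInconsistencyError`` carrying the offending (biopsy, clusters,
  fractions) certificate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CloneTree",
    "TreeInconsistencyError",
    "build_tree",
    "biopsy_composition",
    "classify_metastatic_pattern",
    "ROOT",
]

ROOT = "root"


class TreeInconsistencyError(ValueError):
    """No tree consistent with the fraction matrix under the tolerance."""

    def __init__(self, message: str, certificate: list[tuple] | None = None):
        super().__init__(message)
        self.certificate = certificate or []


@dataclass
class CloneTree:
    """Rooted clone tree plus the per-biopsy cumulative fraction matrix."""

    parent: dict[str, str]  # clone id -> parent clone id or ROOT
    phi: pd.DataFrame  # clones x biopsies cumulative fractions
    epsilon: float = 0.1
    mutation_counts: dict[str, int] = field(default_factory=dict)
    ambiguous_parents: dict[str, list[str]] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)  # clusters too small to place

    @property
    def clones(self) -> list[str]:
        return list(self.parent)

    def children(self, node: str) -> list[str]:
        return sorted(c for c, p in self.parent.items() if p == node)

    def ancestors(self, node: str) -> list[str]:
        out = []
        cur = self.parent.get(node)
        while cur is not None and cur != ROOT:
            out.append(cur)
            cur = self.parent.get(cur)
        return out

    def descendants(self, node: str) -> set[str]:
        out: set[str] = set()
        stack = [node]
        while stack:
            for c in self.children(stack.pop()):
                out.add(c)
                stack.append(c)
        return out

    def is_ancestor(self, a: str, b: str) -> bool:
        return a in self.ancestors(b)

    def validate(self) -> None:
        phi, eps = self.phi, self.epsilon
        cert: list[tuple] = []
        for child, par in self.parent.items():
            if par == ROOT:
                continue
            bad = phi.loc[child] > phi.loc[par] + eps
            for b in phi.columns[bad]:
                cert.append((b, (par, child), (phi.loc[par, b], phi.loc[child, b])))
        nodes = [ROOT] + list(self.parent)
        for node in nodes:
            kids = self.children(node)
            if len(kids) < 2:
                continue
            parent_phi = pd.Series(1.0, index=phi.columns) if node == ROOT else phi.loc[node]
            sums = phi.loc[kids].sum(axis=0)
            bad = sums > parent_phi + eps
            for b in phi.columns[bad]:
                cert.append((b, tuple(kids), (float(parent_phi[b]), float(sums[b]))))
        if cert:
            raise TreeInconsistencyError(
                f"{len(cert)} pigeonhole violation(s); first: biopsy {cert[0][0]}, "
                f"clusters {cert[0][1]}, fractions {cert[0][2]}",
                certificate=cert,
            )


def _ancestor_matrix(phi: pd.DataFrame, eps: float) -> pd.DataFrame:
    clones = list(phi.index)
    present = phi > eps
    anc = pd.DataFrame(False, index=clones, columns=clones)
    for a in clones:
        for b in clones:
            if a == b:
                continue
            ge = (phi.loc[a] >= phi.loc[b] - eps).all()
            contained = (~present.loc[b] | present.loc[a]).all()
            anc.loc[a, b] = bool(ge and contained)
    # mutual candidates (near-identical profiles): keep only the direction
    # from the more prevalent (larger phi sum) clone, tie-broken by id, so
    # the relation stays antisymmetric
    for a in clones:
        for b in clones:
            if a < b and anc.loc[a, b] and anc.loc[b, a]:
                sa, sb = phi.loc[a].sum(), phi.loc[b].sum()
                if (sa, b) >= (sb, a):  # a wins: a stays ancestor of b
                    anc.loc[b, a] = False
                else:
                    anc.loc[a, b] = False
    return anc


def build_tree(
    phi: pd.DataFrame,
    epsilon: float = 0.1,
    mutation_counts: dict[str, int] | None = None,
    min_mutations: int = 0,
) -> CloneTree:
    """Construct the rooted clone tree consistent with a cumulative fraction
    matrix (clones as rows, biopsies as columns).

    Clusters with fewer than ``min_mutations`` member mutations are excluded
    from construction and listed in ``tree.excluded`` (too few mutations to
    place with confidence).  Raises :class:`TreeInconsistencyError` when no
    consistent tree exists under ``epsilon``.
    """
    phi = phi.astype(float)
    counts = dict(mutation_counts or {})
    excluded = [c for c in phi.index if counts and counts.get(c, 0) < min_mutations]
    kept = [c for c in phi.index if c not in excluded]
    sub = phi.loc[kept]
    anc = _ancestor_matrix(sub, epsilon)
    parent: dict[str, str] = {}
    ambiguous: dict[str, list[str]] = {}
    for b in kept:
        cands = [a for a in kept if anc.loc[a, b]]
        # minimal ancestors: not an ancestor of any other candidate
        minimal = [a for a in cands if not any(anc.loc[a, c] for c in cands if c != a)]
        if not minimal:
            parent[b] = ROOT
            continue
        minimal.sort(key=lambda a: (-float(sub.loc[a].sum()), a))
        parent[b] = minimal[0]
        if len(minimal) > 1:
            ambiguous[b] = minimal
    tree = CloneTree(
        parent=parent,
        phi=sub,
        epsilon=epsilon,
        mutation_counts=counts,
        ambiguous_parents=ambiguous,
        excluded=excluded,
    )
    # acyclicity is structural (parent is always an ancestor under an
    # antisymmetric relation) but verify defensively
    for node in parent:
        seen = {node}
        cur = parent[node]
        while cur != ROOT:
            if cur in seen:
                raise TreeInconsistencyError(f"cycle through {cur}")
            seen.add(cur)
            cur = parent[cur]
    tree.validate()
    return tree


def biopsy_composition(tree: CloneTree) -> pd.DataFrame:
    """Exclusive per-biopsy clone fractions (the pie-chart view).

    The exclusive fraction of clone c is phi(c) minus the summed phi of its
    children, floored at 0; the residual up to 1 is reported as the
    ``normal_or_unexplained`` row.
    """
    phi = tree.phi
    rows = {}
    for clone in phi.index:
        kids = tree.children(clone)
        child_sum = phi.loc[kids].sum(axis=0) if kids else 0.0
        rows[clone] = np.maximum(phi.loc[clone] - child_sum, 0.0)
    comp = pd.DataFrame(rows).T.reindex(phi.index)
    top = tree.children(ROOT)
    explained = phi.loc[top].sum(axis=0).clip(upper=1.0) if top else 0.0
    comp.loc["normal_or_unexplained"] = np.maximum(1.0 - explained, 0.0)
    return comp


def classify_metastatic_pattern(tree: CloneTree, roles: dict[str, str]) -> list[str]:
    """Classify the seeding/evolution pattern relating node and primary.

    Returns the sorted list of applicable labels among
    ``monoclonal_seeding`` (the node-and-primary-shared clones form a single
    ancestral chain), ``polyclonal_seeding`` (>= 2 ancestrally unrelated
    primary lineages present in the node) and ``parallel`` (a node-private
    and a primary-private sibling clone coexist: independent subclone birth
    on both sides).  ``["none"]`` when the cohort has no node biopsy.
    """
    node_biopsies = [s for s, r in roles.items() if r == "lymph_node" and s in tree.phi.columns]
    primary_biopsies = [
        s for s, r in roles.items() if r != "lymph_node" and s in tree.phi.columns
    ]
    if not node_biopsies:
        return ["none"]
    eps = tree.epsilon
    present_node = {c for c in tree.clones if (tree.phi.loc[c, node_biopsies] > eps).any()}
    present_primary = {
        c for c in tree.clones if (tree.phi.loc[c, primary_biopsies] > eps).any()
    }
    shared = sorted(present_node & present_primary)
    labels: set[str] = set()
    if shared:
        chain = all(
            a == b or tree.is_ancestor(a, b) or tree.is_ancestor(b, a)
            for a in shared
            for b in shared
        )
        labels.add("monoclonal_seeding" if chain else "polyclonal_seeding")
    node_private = present_node - present_primary
    primary_private = present_primary - present_node
    for c in node_private:
        for d in primary_private:
            if c != d and tree.parent.get(c) == tree.parent.get(d):
                labels.add("parallel")
    return sorted(labels) if labels else ["none"]
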