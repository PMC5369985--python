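"""Synthetic multi-region cohort generator with known ground truth.

The generator emulates a multi-biopsy tumor study design: per patient, one
blood/normal sample plus several tumor biopsies (typically three primary
regions and one lymph node), each a mixture of normal cells (1 - purity)
and cancer cells distributed over the clones of a rooted clone tree.
Defaults mirror the study scale the pipeline targets: exome-like mean depth
95x, ultra-deep validation depth 1693x, biopsy purity in 20-80%, tens to a
hundred-odd somatic mutations per patient, 1-3 prominent clones per biopsy,
and clone-private regional copy events (LOH, copy-neutral LOH, gains).

For mutation i carried by a fraction ``f`` of the cancer cells of biopsy b
(purity rho, mutant copies m in carriers, locus total copies n in
carriers), the true B-allele frequency is

    baf = rho*f*m / ( rho*nbar + 2*(1-rho) )

with nbar the mean tumor copy number at the locus.  Observed counts are
depth ~ Poisson(mean depth) and alt ~ Binomial(depth, baf); the blood
sample draws alt ~ Binomial(depth, error_rate) at somatic sites
(error_rate defaults to 0.1%, below the 1% blood-BAF validation ceiling so
filter tests can exercise that boundary).  Germline heterozygous SNPs
(true BAF 0.5 in every sample, blood included) are emitted alongside for
germline-exclusion and copy-number checks.  The exome and deep runs share
the same true BAFs; the deep run resamples counts at higher depth, the way
a validation assay re-measures the same positions.

Copy-number input is emitted pre-binned: per biopsy, windows of
``window_size`` normal reads whose tumor read count is scaled by
(rho*nbar + 2*(1-rho))/2 for the local copy number, with Poisson noise.

The clone-fraction matrix is stored in CUMULATIVE form: phi(c, b) is the
fraction of cancer cells in biopsy b carrying clone c's private mutations,
i.e. clone c plus all its descendants.  Invariants: the root has phi = 1
everywhere (tumor biopsies), children never exceed parents, and sibling
phis sum to at most the parent's (pigeonhole).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clonal import STATES
from .io import AlleleCount, CohortTable, VariantAnnotation

__all__ = [
    "CopyEvent",
    "TaggedMutation",
    "SimScenario",
    "GroundTruth",
    "SimulatedCohort",
    "simulate_cohort",
    "scenario_like_patient1",
    "random_scenario",
    "true_baf_mixture",
]

#: copy states a regional event can install in its clone's cells
EVENT_STATES = {
    "B": (1, 1),  # LOH: mutant retained, wild-type lost
    "BB": (2, 2),  # copy-neutral LOH
    "ABB": (2, 3),  # mutant gain, wild-type retained
    "loss": (0, 1),  # pure one-copy loss (no mutation involved)
    "gain": (0, 3),  # pure one-copy gain
}

_EFFECT_CHOICES = np.array(
    ["synonymous", "missense", "stopgain", "frameshift", "splice", "other"]
)
_EFFECT_PROBS = np.array([0.20, 0.60, 0.08, 0.05, 0.03, 0.04])

_BASES = np.array(list("ACGT"))

WINDOW_SPAN_BP = 100_000  # genomic span of one simulated depth window


@dataclass(frozen=True)
class CopyEvent:
    """A clone-private regional copy event covering a whole simulated
    chromosome segment."""

    clone: str
    chrom: str
    state: str  # key of EVENT_STATES

    def __post_init__(self):
        if self.state not in EVENT_STATES:
            raise ValueError(f"unknown copy state {self.state!r}")


@dataclass(frozen=True)
class TaggedMutation:
    """A deliberately placed mutation (fixed chromosome, gene, effect) —
    used to co-locate mutations with copy events, e.g. a truncal mutation
    that later loses its wild-type allele in a subclone."""

    clone: str
    chrom: str
    gene: str
    effect: str


@dataclass
class SimScenario:
    """Generative description of one synthetic patient."""

    patient_id: str
    normal_sample: str
    biopsies: list[tuple[str, str]]  # (sample_id, role)
    purity: dict[str, float]  # biopsy sample_id -> rho in (0, 1]
    parent: dict[str, str | None]  # clone -> parent clone (root -> None)
    mutations_per_clone: dict[str, int]
    phi: pd.DataFrame  # clones x biopsies, cumulative carrying fractions
    copy_events: list[CopyEvent] = field(default_factory=list)
    tagged_mutations: list[TaggedMutation] = field(default_factory=list)
    depth_wes: float = 95.0
    depth_deep: float = 1693.0
    depth_blood: float | None = None  # blood depth for the exome run (default = depth_wes)
    error_rate: float = 0.001
    n_germline_hets: int = 60
    n_neutral_chroms: int = 8
    windows_per_chrom: int = 25
    window_size: int = 10_000
    seed: int = 0

    @property
    def biopsy_ids(self) -> list[str]:
        return [s for s, _ in self.biopsies]

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.biopsies)

    @property
    def root(self) -> str:
        roots = [c for c, p in self.parent.items() if p is None]
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root clone, got {roots}")
        return roots[0]

    @property
    def clones(self) -> list[str]:
        return list(self.parent)

    def descendants(self, clone: str) -> set[str]:
        out: set[str] = set()
        stack = [clone]
        while stack:
            cur = stack.pop()
            for c, p in self.parent.items():
                if p == cur:
                    out.add(c)
                    stack.append(c)
        return out

    def lineage(self, clone: str) -> set[str]:
        """clone plus all descendants (the cells carrying its mutations)."""
        return {clone} | self.descendants(clone)

    def is_in_lineage(self, descendant: str, ancestor: str) -> bool:
        return descendant in self.lineage(ancestor)

    def cohort_table(self) -> CohortTable:
        return CohortTable(
            patient_id=self.patient_id,
            normal_sample=self.normal_sample,
            biopsy_samples=list(self.biopsies),
        )

    def validate(self, atol: float = 1e-9) -> None:
        root = self.root
        phi = self.phi
        if set(phi.index) != set(self.parent):
            raise ValueError("phi rows must match the clone set")
        if list(phi.columns) != self.biopsy_ids:
            raise ValueError("phi columns must match the biopsy ids, in order")
        if not np.allclose(phi.loc[root], 1.0, atol=atol):
            raise ValueError("root clone must have phi = 1 in every biopsy")
        for c, p in self.parent.items():
            if p is None:
                continue
            if (phi.loc[c] > phi.loc[p] + atol).any():
                raise ValueError(f"clone {c} exceeds its parent {p} in some biopsy")
        for p in self.parent:
            kids = [c for c, q in self.parent.items() if q == p]
            if len(kids) >= 2:
                if (phi.loc[kids].sum(axis=0) > phi.loc[p] + atol).any():
                    raise ValueError(f"children of {p} violate the pigeonhole constraint")
        for b in self.biopsy_ids:
            if not 0 < self.purity[b] <= 1:
                raise ValueError(f"purity of {b} out of (0, 1]")
        # events in overlapping lineages on the same chromosome must nest
        for ch, evs in itertools.groupby(
            sorted(self.copy_events, key=lambda e: e.chrom), key=lambda e: e.chrom
        ):
            evs = list(evs)
            for a, bv in itertools.combinations(evs, 2):
                la, lb = self.lineage(a.clone), self.lineage(bv.clone)
                if la & lb and not (la <= lb or lb <= la):
                    raise ValueError(
                        f"overlapping copy events on {ch} in non-nested lineages "
                        f"({a.clone}, {bv.clone})"
                    )
        for t in self.tagged_mutations:
            if t.clone not in self.parent:
                raise ValueError(f"tagged mutation references unknown clone {t.clone}")


@dataclass
class GroundTruth:
    """Per-mutation and per-clone truth the simulator guarantees."""

    mutations: pd.DataFrame  # index mut_id: chrom, pos, ref, alt, clone, gene, effect
    true_baf: pd.DataFrame  # mutations x biopsies
    state: pd.DataFrame  # mutations x biopsies copy-state labels
    phi: pd.DataFrame  # clones x biopsies (cumulative)
    purity: dict[str, float]
    scenario: SimScenario


@dataclass
class SimulatedCohort:
    counts_wes: list[AlleleCount]
    counts_deep: list[AlleleCount]
    windows: dict[str, pd.DataFrame]  # biopsy -> pre-binned window table
    annotations: list[VariantAnnotation]
    truth: GroundTruth


def true_baf_mixture(
    rho: float,
    f_mut: float,
    carrier_events: list[tuple[float, int, int]],
    locus_events: list[tuple[float, int]],
) -> float:
    """Expected BAF at a locus where the mutation's carriers are split over
    copy states.

    ``carrier_events`` lists (fraction, m, n) for sub-lineages of the
    carriers holding an aberrant state; the remaining carriers are (1, 2).
    ``locus_events`` lists (fraction, n) for every tumor sub-lineage
    (carrier or not) whose locus copy number deviates from 2.
    """
    if rho == 0:
        return 0.0
    f_aber = sum(f for f, _, _ in carrier_events)
    if f_aber > f_mut + 1e-9:
        raise ValueError("aberrant carrier fractions exceed the carrying fraction")
    mutant = sum(f * m for f, m, _ in carrier_events) + (f_mut - f_aber) * 1
    nbar = 2.0 + sum(f * (n - 2) for f, n in locus_events)
    denom = rho * nbar + 2.0 * (1.0 - rho)
    return (rho * mutant) / denom


def _chrom_list(scenario: SimScenario) -> list[str]:
    neutral = [f"chr{i}" for i in range(1, scenario.n_neutral_chroms + 1)]
    special = sorted(
        {e.chrom for e in scenario.copy_events}
        | {t.chrom for t in scenario.tagged_mutations}
    )
    return neutral + [c for c in special if c not in neutral]


def _place_mutations(scenario: SimScenario, rng: np.random.Generator) -> pd.DataFrame:
    """Assign every mutation a chromosome, position, alleles, gene, effect."""
    neutral = [f"chr{i}" for i in range(1, scenario.n_neutral_chroms + 1)]
    event_chroms = {e.chrom for e in scenario.copy_events}
    free_neutral = [c for c in neutral if c not in event_chroms]
    if not free_neutral:
        raise ValueError("no event-free chromosome left for background mutations")
    rows = []
    mid = 0
    for t in scenario.tagged_mutations:
        rows.append((f"m{mid:04d}", t.chrom, t.clone, t.gene, t.effect))
        mid += 1
    for clone in scenario.clones:
        for _ in range(scenario.mutations_per_clone.get(clone, 0)):
            chrom = free_neutral[mid % len(free_neutral)]
            effect = str(rng.choice(_EFFECT_CHOICES, p=_EFFECT_PROBS))
            rows.append((f"m{mid:04d}", chrom, clone, f"GENE{mid:04d}", effect))
            mid += 1
    df = pd.DataFrame(rows, columns=["mut_id", "chrom", "clone", "gene", "effect"])
    span = scenario.windows_per_chrom * WINDOW_SPAN_BP
    pos = np.zeros(len(df), dtype=np.int64)
    for chrom, idx in df.groupby("chrom").groups.items():
        k = len(idx)
        pos[np.asarray(idx)] = np.sort(rng.choice(np.arange(1, span + 1), size=k, replace=False))
    df["pos"] = pos
    refs = rng.choice(_BASES, size=len(df))
    alts = np.array([str(rng.choice([b for b in "ACGT" if b != r])) for r in refs])
    df["ref"] = refs
    df["alt"] = alts
    return df.set_index("mut_id")


def _mutation_truth(
    scenario: SimScenario, muts: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """True BAF and copy-state label per mutation per biopsy."""
    biopsies = scenario.biopsy_ids
    baf = pd.DataFrame(0.0, index=muts.index, columns=biopsies)
    state = pd.DataFrame("AB", index=muts.index, columns=biopsies)
    events_by_chrom: dict[str, list[CopyEvent]] = {}
    for e in scenario.copy_events:
        events_by_chrom.setdefault(e.chrom, []).append(e)
    for mut_id, row in muts.iterrows():
        mclone = row["clone"]
        lineage_m = scenario.lineage(mclone)
        evs = events_by_chrom.get(row["chrom"], [])
        for b in biopsies:
            rho = scenario.purity[b]
            f_mut = float(scenario.phi.loc[mclone, b])
            carrier_events, locus_events = [], []
            dominant, dom_frac = "AB", 0.0
            for e in evs:
                f_e = float(scenario.phi.loc[e.clone, b])
                if f_e <= 0:
                    continue
                m_e, n_e = EVENT_STATES[e.state]
                locus_events.append((f_e, n_e))
                if e.clone in lineage_m:  # event inside the carrier lineage
                    carrier_events.append((f_e, m_e, n_e))
                    if f_e > dom_frac:
                        dominant, dom_frac = e.state, f_e
                elif mclone in scenario.lineage(e.clone):
                    # event in an ancestor: every carrier is affected
                    carrier_events.append((f_mut, m_e, n_e))
                    if f_mut > dom_frac:
                        dominant, dom_frac = e.state, f_mut
            baf.loc[mut_id, b] = true_baf_mixture(rho, f_mut, carrier_events, locus_events)
            state.loc[mut_id, b] = dominant if f_mut > 0 else "absent"
    return baf, state


def _sample_counts(
    scenario: SimScenario,
    muts: pd.DataFrame,
    baf: pd.DataFrame,
    germline: pd.DataFrame,
    mean_depth: float,
    blood_depth: float,
    rng: np.random.Generator,
) -> list[AlleleCount]:
    counts: list[AlleleCount] = []

    def emit(sample, frame, probs):
        depth = rng.poisson(lam=frame_depth, size=len(frame))
        alt = rng.binomial(depth, probs)
        for (mut_id, row), d, a in zip(frame.iterrows(), depth, alt):
            counts.append(
                AlleleCount(
                    sample_id=sample, chrom=str(row["chrom"]), pos=int(row["pos"]),
                    ref=str(row["ref"]), alt=str(row["alt"]),
                    ref_reads=int(d - a), alt_reads=int(a),
                )
            )

    for b in scenario.biopsy_ids:
        frame_depth = mean_depth
        emit(b, muts, baf[b].to_numpy())
        emit(b, germline, np.full(len(germline), 0.5))
    frame_depth = blood_depth
    emit(scenario.normal_sample, muts, np.full(len(muts), scenario.error_rate))
    emit(scenario.normal_sample, germline, np.full(len(germline), 0.5))
    return counts


def _simulate_windows(
    scenario: SimScenario, rng: np.random.Generator
) -> dict[str, pd.DataFrame]:
    chroms = _chrom_list(scenario)
    events_by_chrom: dict[str, list[CopyEvent]] = {}
    for e in scenario.copy_events:
        events_by_chrom.setdefault(e.chrom, []).append(e)
    out: dict[str, pd.DataFrame] = {}
    for b in scenario.biopsy_ids:
        rho = scenario.purity[b]
        rows = []
        for ch in chroms:
            nbar = 2.0
            for e in events_by_chrom.get(ch, ()):
                f_e = float(scenario.phi.loc[e.clone, b])
                _, n_e = EVENT_STATES[e.state]
                nbar += f_e * (n_e - 2)
            scale = (rho * nbar + 2.0 * (1.0 - rho)) / 2.0
            for w in range(scenario.windows_per_chrom):
                start = w * WINDOW_SPAN_BP + 1
                end = (w + 1) * WINDOW_SPAN_BP
                tumor = int(rng.poisson(scenario.window_size * scale))
                rows.append((ch, start, end, scenario.window_size, tumor))
        out[b] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "normal_reads", "tumor_reads"]
        )
    return out


def simulate_cohort(scenario: SimScenario, seed: int | None = None) -> SimulatedCohort:
    """Draw one synthetic cohort (exome + deep count tables, window tables,
    annotations, ground truth) from a scenario.

    A fixed seed gives byte-identical output.  The scenario is validated
    before any sampling.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    muts = _place_mutations(scenario, rng)
    baf, state = _mutation_truth(scenario, muts)
    # germline het SNPs on event-free chromosomes
    neutral = [
        c
        for c in (f"chr{i}" for i in range(1, scenario.n_neutral_chroms + 1))
        if c not in {e.chrom for e in scenario.copy_events}
    ]
    span = scenario.windows_per_chrom * WINDOW_SPAN_BP
    grows = []
    for g in range(scenario.n_germline_hets):
        ch = neutral[g % len(neutral)]
        pos = int(rng.integers(1, span + 1))
        ref = str(rng.choice(_BASES))
        alt = str(rng.choice([x for x in "ACGT" if x != ref]))
        grows.append((f"g{g:04d}", ch, pos, ref, alt))
    germline = pd.DataFrame(
        grows, columns=["site_id", "chrom", "pos", "ref", "alt"]
    ).set_index("site_id")

    blood_wes = scenario.depth_blood if scenario.depth_blood is not None else scenario.depth_wes
    counts_wes = _sample_counts(scenario, muts, baf, germline, scenario.depth_wes, blood_wes, rng)
    counts_deep = _sample_counts(
        scenario, muts, baf, germline, scenario.depth_deep, scenario.depth_deep, rng
    )
    windows = _simulate_windows(scenario, rng)
    annotations = [
        VariantAnnotation(
            chrom=str(r["chrom"]), pos=int(r["pos"]), ref=str(r["ref"]),
            alt=str(r["alt"]), gene=str(r["gene"]), effect=str(r["effect"]),
        )
        for _, r in muts.iterrows()
    ]
    truth = GroundTruth(
        mutations=muts, true_baf=baf, state=state, phi=scenario.phi.copy(),
        purity=dict(scenario.purity), scenario=scenario,
    )
    return SimulatedCohort(counts_wes, counts_deep, windows, annotations, truth)


# ---------------------------------------------------------------------------
# canned and random scenarios
# ---------------------------------------------------------------------------


def scenario_like_patient1(seed: int = 0) -> SimScenario:
    """A seven-clone scenario shaped like the most structured patient of a
    multi-region study: three primary regions plus one node.

    Tree: truncal clone c1a with daughters c2a and c2b; c2b with three
    daughters c3a (front/center), c3b (node-private) and c3c (back); c4a a
    node-private daughter of c3b.  The front biopsy is fully taken over by
    the c3a lineage; the node carries only the c3b lineage on the truncal
    background (monoclonal seeding with parallel subclone birth in primary
    and node).  A truncal mutation on chr10 loses its wild-type allele
    independently in the c3b and c3c lineages (two regional LOH events in
    disjoint sub-lineages); a truncal stopgain on chr11 suffers LOH in c3b
    only; a truncal stopgain on chr18 shows clonal LOH in all cancer cells.
    """
    biopsies = [
        ("front", "tumor_front"),
        ("center", "tumor_center"),
        ("back", "tumor_back"),
        ("node", "lymph_node"),
    ]
    parent = {
        "c1a": None,
        "c2a": "c1a",
        "c2b": "c1a",
        "c3a": "c2b",
        "c3b": "c2b",
        "c3c": "c2b",
        "c4a": "c3b",
    }
    phi = pd.DataFrame(
        {
            "front": [1.0, 0.0, 1.0, 1.0, 0.0, 0.0, 0.0],
            "center": [1.0, 0.35, 0.65, 0.40, 0.0, 0.0, 0.0],
            "back": [1.0, 0.62, 0.38, 0.0, 0.0, 0.38, 0.0],
            "node": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0, 0.45],
        },
        index=["c1a", "c2a", "c2b", "c3a", "c3b", "c3c", "c4a"],
    )
    return SimScenario(
        patient_id="P1",
        normal_sample="blood",
        biopsies=biopsies,
        purity={"front": 0.70, "center": 0.60, "back": 0.65, "node": 0.50},
        parent=parent,
        mutations_per_clone={
            "c1a": 30, "c2a": 20, "c2b": 25, "c3a": 20, "c3b": 20, "c3c": 20, "c4a": 20,
        },
        phi=phi,
        copy_events=[
            CopyEvent("c3b", "chr10", "B"),
            CopyEvent("c3c", "chr10", "B"),
            CopyEvent("c3b", "chr11", "B"),
            CopyEvent("c1a", "chr18", "B"),
        ],
        tagged_mutations=[
            TaggedMutation("c1a", "chr10", "CALML5", "missense"),
            TaggedMutation("c1a", "chr11", "DCLRE1C", "stopgain"),
            TaggedMutation("c1a", "chr18", "DSEL", "stopgain"),
        ],
        seed=seed,
    )


def _random_tree(n_clones: int, rng: np.random.Generator) -> dict[str, str | None]:
    clones = [f"c{i}" for i in range(1, n_clones + 1)]
    parent: dict[str, str | None] = {clones[0]: None}
    for i in range(1, n_clones):
        parent[clones[i]] = clones[int(rng.integers(0, i))]
    return parent


def _random_phi(
    parent: dict[str, str | None],
    n_biopsies: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per biopsy: 1-3 prominent clones occupy the cancer cells; cumulative
    phi is the lineage sum of their exclusive masses."""
    clones = list(parent)
    root = next(c for c, p in parent.items() if p is None)
    biopsy_ids = [f"b{j}" for j in range(1, n_biopsies + 1)]
    phi = pd.DataFrame(0.0, index=clones, columns=biopsy_ids)
    remaining = set(clones)
    lineage_up: dict[str, list[str]] = {}
    for c in clones:
        chain = [c]
        cur = parent[c]
        while cur is not None:
            chain.append(cur)
            cur = parent[cur]
        lineage_up[c] = chain
    for b in biopsy_ids:
        k = int(rng.integers(1, 4))
        pool = sorted(remaining) if len(remaining) >= k else clones
        chosen = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        remaining -= set(chosen)
        weights = rng.dirichlet(np.full(len(chosen), 2.0))
        weights = np.round(weights * 20) / 20  # coarse occupancies
        weights = np.maximum(weights, 0.05)
        weights = weights / weights.sum()
        for c, w in zip(chosen, weights):
            for anc in lineage_up[c]:
                phi.loc[anc, b] += w
    phi.loc[root] = 1.0
    return phi.clip(upper=1.0)


def _identifiable(
    parent: dict[str, str | None],
    phi: pd.DataFrame,
    purity: dict[str, float],
    depth: float,
    eps: float,
    sep_sd: float,
) -> bool:
    clones = list(parent)
    lineages = {}
    for c in clones:
        lin = {c}
        frontier = [c]
        while frontier:
            cur = frontier.pop()
            for d, p in parent.items():
                if p == cur:
                    lin.add(d)
                    frontier.append(d)
        lineages[c] = lin
    margin = eps + 0.05
    rho = np.array([purity[b] for b in phi.columns])
    theta = phi.to_numpy() * rho[None, :] / 2.0
    for i, a in enumerate(clones):
        if (phi.loc[a] <= eps + 0.05).all():
            return False  # clone effectively absent everywhere
        for j, b in enumerate(clones):
            if i >= j:
                continue
            related = b in lineages[a] or a in lineages[b]
            if related:
                anc, dec = (a, b) if b in lineages[a] else (b, a)
                # the ancestor must dominate somewhere, else profiles collide
                if not (phi.loc[anc] >= phi.loc[dec] + margin).any():
                    return False
            else:
                if not (phi.loc[a] >= phi.loc[b] + margin).any():
                    return False
                if not (phi.loc[b] >= phi.loc[a] + margin).any():
                    return False
            # cluster separation in read-count space
            diff = np.abs(theta[i] - theta[j])
            tmax = np.maximum(theta[i], theta[j])
            sd = np.sqrt(np.maximum(tmax * (1 - tmax), 1e-12) / depth)
            if not (diff >= sep_sd * sd).any():
                return False
    return True


def random_scenario(
    n_clones: int,
    seed: int,
    n_biopsies: int = 4,
    muts_per_clone: int = 20,
    depth: float = 1693.0,
    sep_sd: float = 5.0,
    eps: float = 0.1,
    max_tries: int = 1000,
) -> SimScenario:
    """Draw a random identifiable scenario: a random rooted clone tree, 1-3
    prominent clones per biopsy, purity uniform in [0.2, 0.8], rejected
    until every clone is detectable, every pair of clusters is separated by
    at least ``sep_sd`` binomial standard deviations in some biopsy, and
    the phi matrix pins down a unique tree under tolerance ``eps``."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        parent = _random_tree(n_clones, rng)
        phi = _random_phi(parent, n_biopsies, rng)
        biopsy_ids = list(phi.columns)
        purity = {b: float(np.round(rng.uniform(0.2, 0.8), 2)) for b in biopsy_ids}
        if not _identifiable(parent, phi, purity, depth, eps, sep_sd):
            continue
        roles = ["tumor_front", "tumor_center", "tumor_back", "lymph_node"]
        biopsies = [
            (b, roles[i] if i < len(roles) else "other") for i, b in enumerate(biopsy_ids)
        ]
        scen = SimScenario(
            patient_id=f"SIM{seed}",
            normal_sample="blood",
            biopsies=biopsies,
            purity=purity,
            parent=parent,
            mutations_per_clone={c: muts_per_clone for c in parent},
            phi=phi,
            depth_deep=depth,
            seed=seed,
        )
        scen.validate()
        return scen
    raise RuntimeError(
        f"no identifiable scenario with {n_clones} clones found in {max_tries} tries"
    )
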