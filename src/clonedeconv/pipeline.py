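"""End-to-end orchestration: filter -> copy number -> clonal -> tree ->
reports, for one patient or a cohort, with deterministic seeding.

Stage order for one patient:

1. discovery filter on the exome-depth counts (when provided), then the
   validation filter on the ultra-deep counts restricted to the discovered
   sites (validation assays the discovery candidates); the confirmation
   rate is their ratio;
2. window LogR per biopsy and LogR lookup for every validated mutation;
3. an AB screen (mutations whose LogR stays near 0 in every biopsy carry
   the clean clone signal), binomial-mixture clustering of the screened
   mutations, BAF-ratio clone fractions, copy-state assignment of every
   mutation, and nearest-cluster attachment of the non-AB mutations;
4. clone-tree construction from the fraction matrix and the metastatic
   pattern classification;
5. Venn counts, the nonsynonymous:synonymous selection test and the
   per-gene driver-evidence input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import cnv, io, phylo, reports
from .clonal import (
    ClusterFit,
    assign_state,
    clone_fractions,
    cluster_mutations,
    estimate_purity,
    identify_clonal_cluster,
)
from .filtering import FilterConfig, SomaticVariant, call_sites, confirmation_rate
from .io import CohortTable

__all__ = [
    "PipelineParams",
    "PatientResult",
    "RunConfig",
    "StageFailure",
    "analyze_patient",
    "run_pipeline",
    "run_simulation",
]


class StageFailure(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineParams:
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    window_size: int = cnv.DEFAULT_WINDOW_SIZE
    k_max: int = 8
    epsilon: float = 0.1
    min_cluster_mutations: int = 5
    venn_min_alt: int = 5
    #: max |LogR| in any biopsy for a mutation to enter AB clustering
    ab_logr_tol: float = 0.15
    tau_baf: float = 0.08
    tau_logr: float = 0.4
    seed: int = 0
    #: biopsy -> purity; biopsies not listed are estimated from the data
    purity: dict[str, float] = field(default_factory=dict)


@dataclass
class PatientResult:
    patient_id: str
    discovery: list[SomaticVariant]
    validated: list[SomaticVariant]
    confirmation_rate: float
    alt: pd.DataFrame  # validated mutations x biopsies
    depth: pd.DataFrame
    baf: pd.DataFrame
    logr: pd.DataFrame
    purity: dict[str, float]
    fit: ClusterFit | None
    cluster_of: pd.Series  # mutation key -> cluster id (AB members + attached)
    phi: pd.DataFrame | None  # clusters x biopsies
    states: pd.DataFrame | None  # mutations x biopsies copy-state labels
    tree: phylo.CloneTree | None
    composition: pd.DataFrame | None
    patterns: list[str]
    venn: reports.VennSummary
    ns_ratio: float
    ns_pvalue: float
    driver_input: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def _variant_matrices(variants: list[SomaticVariant], biopsies: list[str]):
    keys = [f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}" for v in variants]
    alt = pd.DataFrame(
        [[v.observations.get(b, (0, 0))[0] for b in biopsies] for v in variants],
        index=keys, columns=biopsies, dtype=int,
    )
    depth = pd.DataFrame(
        [[v.observations.get(b, (0, 0))[1] for b in biopsies] for v in variants],
        index=keys, columns=biopsies, dtype=int,
    )
    return alt, depth


def analyze_patient(
    cohort: CohortTable,
    counts_deep: pd.DataFrame,
    windows: dict[str, pd.DataFrame] | None = None,
    counts_wes: pd.DataFrame | None = None,
    annotations=None,
    params: PipelineParams | None = None,
) -> PatientResult:
    """Run the full per-patient analysis; see the module docstring for the
    stage order.  ``windows`` maps biopsy id to a pre-binned window table
    (chrom, start, end, normal_reads, tumor_reads)."""
    params = params or PipelineParams()
    biopsies = cohort.biopsy_ids
    ann_map = {}
    for a in annotations or []:
        ann_map[(a.chrom, a.pos, a.ref, a.alt)] = a
    warns: list[str] = []

    # -- stage 1: filtering ------------------------------------------------
    discovery: list[SomaticVariant] = []
    conf_rate = float("nan")
    if counts_wes is not None:
        discovery = call_sites(
            counts_wes, cohort, "discovery", params.filter_config, annotations=ann_map
        )
        disc_keys = {v.key for v in discovery}
        mask = [
            (str(r.chrom), int(r.pos), str(r.ref), str(r.alt)) in disc_keys
            for r in counts_deep.itertuples()
        ]
        deep_subset = counts_deep[np.asarray(mask, dtype=bool)]
    else:
        deep_subset = counts_deep
    validated = call_sites(
        deep_subset, cohort, "validation", params.filter_config, annotations=ann_map
    )
    if counts_wes is not None:
        conf_rate = confirmation_rate(discovery, validated)
    if not validated:
        raise StageFailure("filtering", f"no validated variants for {cohort.patient_id}")

    alt, depth = _variant_matrices(validated, biopsies)
    with np.errstate(invalid="ignore", divide="ignore"):
        baf = (alt / depth.replace(0, np.nan)).fillna(0.0)

    # -- stage 2: copy number ---------------------------------------------
    var_pos = pd.DataFrame(
        {"chrom": [v.chrom for v in validated], "pos": [v.pos for v in validated]},
        index=alt.index,
    )
    logr = pd.DataFrame(0.0, index=alt.index, columns=biopsies)
    if windows:
        for b in biopsies:
            table = windows.get(b)
            if table is None:
                warns.append(f"no window table for biopsy {b}; LogR set to 0")
                continue
            ws = cnv.windows_from_table(table)
            cnv.compute_logr(ws)
            assigned = cnv.assign_logr(var_pos, ws)
            logr[b] = assigned["logr"].fillna(0.0)
    else:
        warns.append("no copy-number input; LogR assumed 0 everywhere")

    # -- stage 3: clonal deconvolution ------------------------------------
    ab_mask = (logr.abs() <= params.ab_logr_tol).all(axis=1)
    ab_keys = alt.index[ab_mask]
    if len(ab_keys) < 2:
        raise StageFailure("clonal", "fewer than 2 AB-state mutations to cluster")
    fit = cluster_mutations(
        alt.loc[ab_keys].to_numpy(),
        depth.loc[ab_keys].to_numpy(),
        k_max=params.k_max,
        seed=params.seed,
    )
    clonal_idx, unambiguous = identify_clonal_cluster(fit.mean_baf)
    if not unambiguous:
        warns.append("clonal cluster ambiguous; using largest-BAF-sum cluster")
    # stable cluster naming: clonal first, then by descending BAF sum
    order = sorted(
        range(fit.k),
        key=lambda j: (j != clonal_idx, -float(fit.mean_baf[j].sum()), j),
    )
    names = {j: f"clone{i + 1:02d}" for i, j in enumerate(order)}
    phi_mat = clone_fractions(fit.mean_baf, clonal_idx)
    phi = pd.DataFrame(
        phi_mat[order], index=[names[j] for j in order], columns=biopsies
    )
    cluster_of = pd.Series(
        [names[j] for j in fit.labels], index=ab_keys, dtype=object
    )
    # purity per biopsy: provided, else 2 x mode of the clonal cluster's BAFs
    purity: dict[str, float] = {}
    clonal_members = ab_keys[fit.labels == clonal_idx]
    for b in biopsies:
        if b in params.purity:
            purity[b] = float(params.purity[b])
            continue
        try:
            purity[b] = estimate_purity(baf.loc[clonal_members, b], sample_id=b).rho
        except ValueError as exc:
            warns.append(f"purity estimation failed for {b} ({exc}); assuming 1.0")
            purity[b] = 1.0

    # copy-state assignment for every validated mutation, per biopsy where
    # it is present
    states = pd.DataFrame("absent", index=alt.index, columns=biopsies)
    for b in biopsies:
        fracs = [f for f in phi[b].tolist() if f > 0] + [1.0]
        present = alt[b] >= params.filter_config.secondary_min_alt
        for key in alt.index[present]:
            label, _, sub = assign_state(
                float(baf.loc[key, b]),
                float(logr.loc[key, b]),
                purity[b],
                candidate_fractions=fracs,
                tau_baf=params.tau_baf,
                tau_logr=params.tau_logr,
            )
            states.loc[key, b] = label + ("*" if sub and label != "unassigned" else "")
    # attach non-AB mutations to the nearest cluster in presence-pattern
    # space (binary presence, ties by BAF distance)
    non_ab = alt.index[~ab_mask]
    if len(non_ab):
        cluster_presence = phi.to_numpy() > params.epsilon
        for key in non_ab:
            pres = (alt.loc[key] >= params.filter_config.secondary_min_alt).to_numpy()
            ham = (cluster_presence != pres[None, :]).sum(axis=1)
            dist = np.linalg.norm(
                phi.to_numpy() * (baf.loc[key].to_numpy().max() or 1.0)
                - baf.loc[key].to_numpy()[None, :],
                axis=1,
            )
            best = int(np.lexsort((dist, ham))[0])
            cluster_of.loc[key] = phi.index[best]

    # -- stage 4: phylogeny ------------------------------------------------
    sizes = cluster_of.value_counts().to_dict()
    tree = None
    composition = None
    patterns = ["none"]
    try:
        tree = phylo.build_tree(
            phi,
            epsilon=params.epsilon,
            mutation_counts={c: int(sizes.get(c, 0)) for c in phi.index},
            min_mutations=params.min_cluster_mutations,
        )
        composition = phylo.biopsy_composition(tree)
        patterns = phylo.classify_metastatic_pattern(tree, cohort.roles)
    except phylo.TreeInconsistencyError as exc:
        warns.append(f"tree construction failed: {exc}")

    # -- stage 5: reports --------------------------------------------------
    no_data = [b for b in biopsies if (depth[b] == 0).all()]
    venn = reports.venn_counts(
        alt, min_alt=params.venn_min_alt, patient_id=cohort.patient_id,
        exclude_biopsies=no_data,
    )
    effects = [v.annotation.effect for v in validated if v.annotation is not None]
    n_nonsyn = sum(e in reports.NONSYN_EFFECTS for e in effects)
    n_syn = sum(e in reports.SYN_EFFECTS for e in effects)
    if n_nonsyn + n_syn:
        ns_ratio, ns_p = reports.ns_ratio_test(n_nonsyn, n_syn)
    else:
        ns_ratio, ns_p = float("nan"), float("nan")
    state_map = {
        v.key: {b: states.loc[k, b].rstrip("*") for b in biopsies}
        for v, k in zip(validated, alt.index)
    }
    driver_input = reports.variants_to_driver_input(
        validated, states=state_map, patient_id=cohort.patient_id
    )

    return PatientResult(
        patient_id=cohort.patient_id,
        discovery=discovery,
        validated=validated,
        confirmation_rate=conf_rate,
        alt=alt, depth=depth, baf=baf, logr=logr,
        purity=purity,
        fit=fit,
        cluster_of=cluster_of,
        phi=phi,
        states=states,
        tree=tree,
        composition=composition,
        patterns=patterns,
        venn=venn,
        ns_ratio=ns_ratio,
        ns_pvalue=ns_p,
        driver_input=driver_input,
        warnings=warns,
    )


# ---------------------------------------------------------------------------
# file-level runs
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    cohort: str
    counts_deep: str
    out_dir: str
    counts_wes: str | None = None
    windows_dir: str | None = None  # contains <biopsy>.windows.tsv per biopsy
    annotations: str | None = None
    external_evidence: str | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        data = yaml.safe_load(open(path))
        pdata = data.pop("params", {}) or {}
        params = PipelineParams(**pdata)
        return cls(params=params, **data)

    def validate(self) -> None:
        for attr in ("cohort", "counts_deep", "counts_wes", "annotations", "external_evidence"):
            path = getattr(self, attr)
            if path is not None and not os.path.exists(path):
                raise FileNotFoundError(f"{attr}: {path}")


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage for every patient in the cohort and write the report
    tables, trees and run summary under ``config.out_dir``.  Returns the
    summary dict.  Identical config + inputs give identical outputs."""
    config.validate()
    cohorts = io.read_cohort(config.cohort)
    counts_deep = io.counts_to_frame(io.read_counts(config.counts_deep))
    counts_wes = (
        io.counts_to_frame(io.read_counts(config.counts_wes))
        if config.counts_wes
        else None
    )
    annotations = io.read_annotations(config.annotations) if config.annotations else []
    external = (
        pd.read_csv(config.external_evidence, sep="\t") if config.external_evidence else None
    )
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {
        "seed": config.params.seed,
        "params": {
            "k_max": config.params.k_max,
            "epsilon": config.params.epsilon,
            "window_size": config.params.window_size,
            "min_cluster_mutations": config.params.min_cluster_mutations,
            "venn_min_alt": config.params.venn_min_alt,
        },
        "stages": ["filtering", "cnv", "clonal", "phylo", "reports"],
        "patients": {},
    }
    all_driver_inputs = []
    for cohort in cohorts:
        windows = {}
        if config.windows_dir:
            for b in cohort.biopsy_ids:
                wpath = os.path.join(config.windows_dir, f"{b}.windows.tsv")
                if os.path.exists(wpath):
                    windows[b] = pd.read_csv(wpath, sep="\t", comment="#")
        try:
            result = analyze_patient(
                cohort,
                counts_deep[counts_deep["sample"].isin(
                    set(cohort.biopsy_ids) | {cohort.normal_sample}
                )],
                windows=windows or None,
                counts_wes=(
                    counts_wes[counts_wes["sample"].isin(
                        set(cohort.biopsy_ids) | {cohort.normal_sample}
                    )]
                    if counts_wes is not None
                    else None
                ),
                annotations=annotations,
                params=config.params,
            )
        except StageFailure as exc:
            raise StageFailure(exc.stage, f"patient {cohort.patient_id}: {exc}") from exc
        pdir = os.path.join(config.out_dir, cohort.patient_id)
        tables = {
            "validated_variants": _variants_frame(result),
            "cluster_assignments": result.cluster_of.rename("cluster").rename_axis("mutation").reset_index(),
            "clone_fractions": result.phi.rename_axis("clone").reset_index(),
            "venn_counts": result.venn.to_frame(),
            "biopsy_composition": (
                result.composition.rename_axis("clone").reset_index()
                if result.composition is not None
                else pd.DataFrame(columns=["clone"])
            ),
        }
        io.write_report_tables(tables, pdir)
        if result.tree is not None:
            io.write_tree_newick(result.tree, os.path.join(pdir, "clone_tree.nwk"))
        all_driver_inputs.append(result.driver_input)
        summary["patients"][cohort.patient_id] = {
            "n_discovery": len(result.discovery),
            "n_validated": len(result.validated),
            "confirmation_rate": _nan_to_none(result.confirmation_rate),
            "n_clusters": result.fit.k if result.fit else 0,
            "purity": result.purity,
            "patterns": result.patterns,
            "ns_ratio": _nan_to_none(result.ns_ratio),
            "ns_pvalue": _nan_to_none(result.ns_pvalue),
            "warnings": result.warnings,
        }
    drivers = reports.driver_table(pd.concat(all_driver_inputs, ignore_index=True), external)
    io.write_report_tables({"driver_table": drivers}, config.out_dir)
    io.write_run_summary(summary, os.path.join(config.out_dir, "run_summary.json"))
    return summary


def _nan_to_none(x: float):
    return None if x != x else float(x)


def _variants_frame(result: PatientResult) -> pd.DataFrame:
    rows = []
    for v, key in zip(result.validated, result.alt.index):
        row = {
            "mutation": key, "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "gene": v.annotation.gene if v.annotation else "",
            "effect": v.annotation.effect if v.annotation else "",
        }
        for b in result.alt.columns:
            row[f"alt_{b}"] = int(result.alt.loc[key, b])
            row[f"depth_{b}"] = int(result.depth.loc[key, b])
            row[f"baf_{b}"] = round(float(result.baf.loc[key, b]), 6)
            row[f"state_{b}"] = result.states.loc[key, b]
        rows.append(row)
    return pd.DataFrame(rows)


def run_simulation(scenario, out_dir: str, seed: int | None = None) -> dict:
    """Simulate a cohort from a scenario and write every input table plus
    the ground truth under ``out_dir``.  ``seed`` overrides the scenario's
    seed; omitting both is an error (determinism is mandatory)."""
    from .simulate import SimScenario, simulate_cohort

    if not isinstance(scenario, SimScenario):
        raise TypeError("scenario must be a SimScenario")
    if seed is None and scenario.seed is None:
        raise ValueError("a seed is required for simulation")
    cohort = simulate_cohort(scenario, seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    io.write_counts(cohort.counts_wes, os.path.join(out_dir, "counts_wes.tsv"))
    io.write_counts(cohort.counts_deep, os.path.join(out_dir, "counts_deep.tsv"))
    io.write_annotations(cohort.annotations, os.path.join(out_dir, "annotations.tsv"))
    io.write_cohort([scenario.cohort_table()], os.path.join(out_dir, "cohort.yaml"))
    wdir = os.path.join(out_dir, "windows")
    os.makedirs(wdir, exist_ok=True)
    for b, table in cohort.windows.items():
        with open(os.path.join(wdir, f"{b}.windows.tsv"), "w") as fh:
            fh.write("#coords=1-based\n")
            table.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    tdir = os.path.join(out_dir, "truth")
    io.write_report_tables(
        {
            "mutations": cohort.truth.mutations.rename_axis("mut_id").reset_index(),
            "true_baf": cohort.truth.true_baf.rename_axis("mut_id").reset_index(),
            "states": cohort.truth.state.rename_axis("mut_id").reset_index(),
            "phi": cohort.truth.phi.rename_axis("clone").reset_index(),
        },
        tdir,
    )
    io.write_run_summary(
        {
            "patient_id": scenario.patient_id,
            "seed": seed if seed is not None else scenario.seed,
            "purity": scenario.purity,
            "n_mutations": int(len(cohort.truth.mutations)),
            "n_clones": len(scenario.parent),
        },
        os.path.join(out_dir, "simulation_summary.json"),
    )
    return {"n_mutations": int(len(cohort.truth.mutations)), "out_dir": out_dir}
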