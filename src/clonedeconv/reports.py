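"""Cohort-level heterogeneity and driver-evidence summaries.

Three analyses:

* Venn counts of shared/private mutations across a patient's biopsies —
  a mutation counts as present in a biopsy only with at least ``min_alt``
  (default 5) alternative reads there, so each validated mutation falls in
  exactly one biopsy-subset cell;
* a selection test on the nonsynonymous:synonymous ratio — under neutral
  (passenger) mutagenesis roughly two of three point mutations are
  nonsynonymous, so the observed nonsynonymous count is tested one-sided
  against Binomial(n, 2/3); an excess signals positive selection;
* a rule-based candidate-driver table combining recurrence across patients,
  loss-of-function effect, LOH over the mutant locus and bi-allelic hits,
  with external evidence columns (e.g. database frequencies, survival
  hazard ratios) passed through verbatim when supplied — never computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import LOF_EFFECTS

__all__ = [
    "VennSummary",
    "venn_counts",
    "ns_ratio_test",
    "driver_table",
    "NONSYN_EFFECTS",
    "SYN_EFFECTS",
]

#: point-mutation classes entering the selection test
NONSYN_EFFECTS = frozenset({"missense", "stopgain", "stoploss"})
SYN_EFFECTS = frozenset({"synonymous"})


@dataclass
class VennSummary:
    patient_id: str
    counts: dict[frozenset, int]  # biopsy subset -> number of mutations

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("+".join(sorted(subset)) if subset else "(none)", n)
            for subset, n in sorted(
                self.counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["biopsies", "n_mutations"])


def venn_counts(
    alt: pd.DataFrame,
    min_alt: int = 5,
    patient_id: str = "",
    exclude_biopsies: Iterable[str] = (),
) -> VennSummary:
    """Classify each validated mutation into the subset of biopsies where it
    has at least ``min_alt`` alternative reads.

    ``alt`` is a mutations x biopsies frame of alt read counts.  Biopsies
    named in ``exclude_biopsies`` (e.g. one with no tumor content or no
    data) are dropped from the diagram.  Mutations below threshold
    everywhere land in the empty-subset cell, so the cells always partition
    the full validated set.
    """
    keep = [b for b in alt.columns if b not in set(exclude_biopsies)]
    present = alt[keep] >= min_alt
    counts: dict[frozenset, int] = {}
    for _, row in present.iterrows():
        subset = frozenset(b for b in keep if row[b])
        counts[subset] = counts.get(subset, 0) + 1
    return VennSummary(patient_id=patient_id, counts=counts)


def ns_ratio_test(
    n_nonsyn: int, n_syn: int, null_prop: float = 2.0 / 3.0, method: str = "binomial"
) -> tuple[float, float]:
    """Test whether the nonsynonymous:synonymous ratio exceeds the neutral
    expectation (2:1 by default).

    Returns ``(ratio, p_value)`` with ratio = n_nonsyn / n_syn (inf when no
    synonymous mutations) and the one-sided p-value
    P(X >= n_nonsyn | n, null_prop) from the exact binomial tail; pass
    ``method="chisq"`` for the chi-square goodness-of-fit alternative
    (two-sided, halved when the observed ratio exceeds the null).
    """
    if n_nonsyn < 0 or n_syn < 0:
        raise ValueError("counts must be non-negative")
    n = n_nonsyn + n_syn
    if n == 0:
        return (math.nan, math.nan)
    ratio = math.inf if n_syn == 0 else n_nonsyn / n_syn
    if method == "binomial":
        p = float(stats.binom.sf(n_nonsyn - 1, n, null_prop))
    elif method == "chisq":
        expected = np.array([n * null_prop, n * (1 - null_prop)])
        chi2, p2 = stats.chisquare([n_nonsyn, n_syn], expected)
        p = float(p2 / 2 if n_nonsyn / n > null_prop else 1 - p2 / 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return (ratio, min(p, 1.0))


def driver_table(
    variants: pd.DataFrame,
    external: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Build the per-gene candidate-driver evidence table.

    ``variants`` needs one row per (patient, mutation) with columns
    ``patient_id``, ``gene``, ``effect`` and ``loh`` (True when the mutation
    sits in a B or BB copy state in any biopsy of that patient).  Rows with
    a missing/empty gene are excluded (their count is returned in the
    ``n_unannotated`` attribute of the frame).

    Flags per gene:

    * ``recurrence`` — mutated in >= 2 patients;
    * ``lof`` — any loss-of-function mutation (stopgain/frameshift/splice);
    * ``loh`` — any member mutation under LOH in any biopsy;
    * ``biallelic`` — >= 2 independent hits in one patient: either two
      distinct mutations, or a mutation whose locus also lost the
      wild-type allele.

    Rank is the number of true flags; rows are ordered rank-descending then
    alphabetically.  ``external`` (per-gene columns such as a driver-score
    flag, database frequency or hazard-ratio text) is merged verbatim.
    """
    needed = {"patient_id", "gene", "effect", "loh"}
    if not needed.issubset(variants.columns):
        raise ValueError(f"variants frame must have columns {sorted(needed)}")
    annotated = variants[variants["gene"].notna() & (variants["gene"] != "")]
    n_unannotated = len(variants) - len(annotated)
    rows = []
    for gene, grp in annotated.groupby("gene", sort=True):
        recurrence = grp["patient_id"].nunique() >= 2
        lof = grp["effect"].isin(LOF_EFFECTS).any()
        loh = bool(grp["loh"].any())
        biallelic = False
        for _, pgrp in grp.groupby("patient_id"):
            n_hits = len(pgrp) + int(pgrp["loh"].any())
            if n_hits >= 2:
                biallelic = True
                break
        flags = {"recurrence": recurrence, "lof": lof, "loh": loh, "biallelic": biallelic}
        rows.append({"gene": gene, **flags, "rank": sum(flags.values())})
    table = pd.DataFrame(rows, columns=["gene", "recurrence", "lof", "loh", "biallelic", "rank"])
    if external is not None:
        table = table.merge(external, on="gene", how="left")
    table = table.sort_values(["rank", "gene"], ascending=[False, True]).reset_index(drop=True)
    table.attrs["n_unannotated"] = n_unannotated
    return table


def variants_to_driver_input(
    variants: Iterable, states: Mapping[tuple, Mapping[str, str]] | None = None,
    patient_id: str = "",
) -> pd.DataFrame:
    """Adapt called :class:`~clonedeconv.filtering.SomaticVariant` records
    (plus per-biopsy copy-state labels) into the frame `driver_table`
    consumes."""
    rows = []
    for v in variants:
        if v.annotation is None:
            gene, effect = "", "other"
        else:
            gene, effect = v.annotation.gene, v.annotation.effect
        st = (states or {}).get(v.key, {})
        loh = any(lbl in ("B", "BB") for lbl in st.values())
        rows.append(
            {
                "patient_id": patient_id, "chrom": v.chrom, "pos": v.pos,
                "gene": gene, "effect": effect, "loh": loh,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "chrom", "pos", "gene", "effect", "loh"])
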