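"""Two-stage somatic variant selection from matched tumor/blood read counts.

Discovery stage (exome-depth data): a site is called somatic when some
biopsy shows B-allele frequency (BAF) >= 5% with >= 3 alternative reads,
while the blood sample has >= 10x coverage and exactly 0 alternative reads.

Validation stage (ultra-deep data): a site is called when some biopsy shows
BAF >= 3% with >= 10 alternative reads, while blood has >= 50x coverage and
BAF <= 1%.  Once a site is called, its presence in the *other* biopsies is
granted down to arbitrarily low BAF provided the alternative read count is
high enough (default >= 5 reads) — the cross-sample rescue rule.

All thresholds are inclusive.  BAF threshold comparisons use exact rational
arithmetic (cross multiplication with the threshold held as a
``fractions.Fraction``), so a biopsy with 3 alt / 60 depth sits exactly on
the 5% boundary and is called; no float rounding can flip a boundary case.

Zero-depth biopsy records are treated as "no data" — they can neither call a
variant nor count against one called elsewhere.  A missing or zero-depth
blood record is an error: somatic status cannot be certified without it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import AlleleCount, CohortTable, VariantAnnotation

__all__ = [
    "FilterConfig",
    "StageConfig",
    "SomaticVariant",
    "CallResult",
    "MissingBloodError",
    "compute_baf",
    "call_discovery",
    "call_validation",
    "call_sites",
    "confirmation_rate",
]


class MissingBloodError(ValueError):
    """The blood/normal sample has no usable record at a site."""


def _as_fraction(x) -> Fraction:
    # Fraction(str(0.05)) == 1/20 exactly; Fraction(0.05) would inherit the
    # binary rounding error and mis-rank exact boundary counts.
    if isinstance(x, Fraction):
        return x
    return Fraction(str(x))


@dataclass(frozen=True)
class StageConfig:
    """Thresholds for one filter stage (all inclusive)."""

    min_baf: Fraction
    min_alt: int
    blood_min_depth: int
    blood_max_alt: int | None = None  # discovery: exact cap on blood alt reads
    blood_max_baf: Fraction | None = None  # validation: cap on blood BAF

    def __post_init__(self):
        object.__setattr__(self, "min_baf", _as_fraction(self.min_baf))
        if self.blood_max_baf is not None:
            object.__setattr__(self, "blood_max_baf", _as_fraction(self.blood_max_baf))
        if not 0 <= self.min_baf <= 1:
            raise ValueError("min_baf must be in [0, 1]")
        if self.min_alt < 0 or self.blood_min_depth < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class FilterConfig:
    discovery: StageConfig = field(
        default_factory=lambda: StageConfig(
            min_baf=Fraction(5, 100), min_alt=3, blood_min_depth=10, blood_max_alt=0
        )
    )
    validation: StageConfig = field(
        default_factory=lambda: StageConfig(
            min_baf=Fraction(3, 100), min_alt=10, blood_min_depth=50,
            blood_max_baf=Fraction(1, 100),
        )
    )
    #: minimum alt reads for cross-sample presence of an already-called variant
    secondary_min_alt: int = 5

    def __post_init__(self):
        if self.secondary_min_alt < 0:
            raise ValueError("secondary_min_alt must be non-negative")


@dataclass
class CallResult:
    called: bool
    qualifying: set[str] = field(default_factory=set)  # samples meeting the primary rule
    present_in: set[str] = field(default_factory=set)  # qualifying + rescued samples


@dataclass
class SomaticVariant:
    """A called variant with per-sample observations."""

    chrom: str
    pos: int
    ref: str
    alt: str
    #: sample_id -> (alt_reads, depth)
    observations: dict[str, tuple[int, int]]
    called_in: set[str]
    stage: str  # "discovery" | "validated"
    annotation: VariantAnnotation | None = None

    def baf(self, sample_id: str) -> float:
        alt, depth = self.observations[sample_id]
        return compute_baf(alt, depth - alt)

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def compute_baf(alt_reads: int, ref_reads: int) -> float:
    """B-allele frequency: alt / (ref + alt); NaN at zero depth (undefined,
    deliberately not 0)."""
    if alt_reads < 0 or ref_reads < 0:
        raise ValueError("read counts must be non-negative")
    depth = alt_reads + ref_reads
    if depth == 0:
        return math.nan
    return alt_reads / depth


def _baf_at_least(alt: int, depth: int, threshold: Fraction) -> bool:
    # alt/depth >= p/q  <=>  alt*q >= p*depth  (depth > 0)
    return alt * threshold.denominator >= threshold.numerator * depth


def _baf_at_most(alt: int, depth: int, threshold: Fraction) -> bool:
    return alt * threshold.denominator <= threshold.numerator * depth


def _blood_ok(blood_alt: int, blood_depth: int, cfg: StageConfig) -> bool:
    if blood_depth < cfg.blood_min_depth:
        return False
    if cfg.blood_max_alt is not None and blood_alt > cfg.blood_max_alt:
        return False
    if cfg.blood_max_baf is not None and not _baf_at_most(blood_alt, blood_depth, cfg.blood_max_baf):
        return False
    return True


def _site_call(
    biopsies: Mapping[str, tuple[int, int]],
    blood: tuple[int, int] | None,
    cfg: StageConfig,
    secondary_min_alt: int | None,
) -> CallResult:
    if blood is None:
        raise MissingBloodError("no blood record at site; somatic status cannot be certified")
    blood_alt, blood_depth = blood
    qualifying = {
        sid
        for sid, (alt, depth) in biopsies.items()
        if depth > 0 and alt >= cfg.min_alt and _baf_at_least(alt, depth, cfg.min_baf)
    }
    called = bool(qualifying) and _blood_ok(blood_alt, blood_depth, cfg)
    if not called:
        return CallResult(False, set(), set())
    present = set(qualifying)
    if secondary_min_alt is not None:
        present |= {
            sid
            for sid, (alt, depth) in biopsies.items()
            if depth > 0 and alt >= secondary_min_alt
        }
    return CallResult(True, qualifying, present)


def call_discovery(
    biopsies: Mapping[str, tuple[int, int]],
    blood: tuple[int, int] | None,
    config: FilterConfig | None = None,
) -> CallResult:
    """Apply the discovery (exome) criteria at one site.

    ``biopsies`` maps sample id to (alt_reads, depth); ``blood`` is the
    (alt_reads, depth) pair of the matched normal.
    """
    cfg = (config or FilterConfig()).discovery
    return _site_call(biopsies, blood, cfg, secondary_min_alt=None)


def call_validation(
    biopsies: Mapping[str, tuple[int, int]],
    blood: tuple[int, int] | None,
    config: FilterConfig | None = None,
) -> CallResult:
    """Apply the validation (ultra-deep) criteria at one site, including the
    cross-sample rescue of low-BAF presence at >= ``secondary_min_alt`` alt
    reads."""
    config = config or FilterConfig()
    return _site_call(biopsies, blood, config.validation, config.secondary_min_alt)


# ---------------------------------------------------------------------------
# cohort-level driver
# ---------------------------------------------------------------------------


def call_sites(
    counts: Iterable[AlleleCount] | pd.DataFrame,
    cohort: CohortTable,
    stage: str = "discovery",
    config: FilterConfig | None = None,
    annotations: Mapping[tuple[str, int, str, str], VariantAnnotation] | None = None,
    blocklist: set[tuple[str, int, str, str]] | None = None,
) -> list[SomaticVariant]:
    """Run one filter stage over every site of a patient's count table.

    Sites on the optional ``blocklist`` (e.g. known germline polymorphisms)
    are skipped before evaluation.  Samples absent at a site are synthesized
    as depth-0 records ("no data"), never silently dropped; a missing blood
    record raises :class:`MissingBloodError` naming the site.
    """
    config = config or FilterConfig()
    if stage not in ("discovery", "validation"):
        raise ValueError(f"unknown stage {stage!r}")
    if isinstance(counts, pd.DataFrame):
        df = counts
    else:
        from .io import counts_to_frame

        df = counts_to_frame(counts)
    sample_ids = set(cohort.biopsy_ids) | {cohort.normal_sample}
    df = df[df["sample"].isin(sample_ids)]
    out: list[SomaticVariant] = []
    caller = call_discovery if stage == "discovery" else call_validation
    for key, grp in df.groupby(["chrom", "pos", "ref", "alt"], sort=True):
        key = (str(key[0]), int(key[1]), str(key[2]), str(key[3]))
        if blocklist and key in blocklist:
            continue
        obs = {
            str(r.sample): (int(r.alt_reads), int(r.ref_reads) + int(r.alt_reads))
            for r in grp.itertuples()
        }
        blood = obs.get(cohort.normal_sample)
        if blood is None or blood[1] == 0:
            raise MissingBloodError(
                f"blood sample {cohort.normal_sample} missing or zero-depth at "
                f"{key[0]}:{key[1]}"
            )
        biopsies = {sid: obs.get(sid, (0, 0)) for sid in cohort.biopsy_ids}
        res = caller(biopsies, blood, config)
        if res.called:
            out.append(
                SomaticVariant(
                    chrom=key[0],
                    pos=key[1],
                    ref=key[2],
                    alt=key[3],
                    observations={sid: biopsies[sid] for sid in cohort.biopsy_ids},
                    called_in=res.present_in if stage == "validation" else res.qualifying,
                    stage="validated" if stage == "validation" else "discovery",
                    annotation=(annotations or {}).get(key),
                )
            )
    return out


def call_sites_vectorized(
    alt: np.ndarray,
    depth: np.ndarray,
    blood_alt: np.ndarray,
    blood_depth: np.ndarray,
    stage: str = "discovery",
    config: FilterConfig | None = None,
) -> np.ndarray:
    """Vectorized call decision for many sites at once.

    ``alt``/``depth`` are (n_sites, n_biopsies) integer arrays, the blood
    vectors (n_sites,).  Returns a boolean vector.  Integer cross
    multiplication keeps the thresholds exact, matching the scalar rules
    bit for bit.
    """
    config = config or FilterConfig()
    cfg = config.discovery if stage == "discovery" else config.validation
    alt = np.asarray(alt, dtype=np.int64)
    depth = np.asarray(depth, dtype=np.int64)
    blood_alt = np.asarray(blood_alt, dtype=np.int64)
    blood_depth = np.asarray(blood_depth, dtype=np.int64)
    p, q = cfg.min_baf.numerator, cfg.min_baf.denominator
    qual = (depth > 0) & (alt >= cfg.min_alt) & (alt * q >= p * depth)
    any_qual = qual.any(axis=1)
    blood_ok = blood_depth >= cfg.blood_min_depth
    if cfg.blood_max_alt is not None:
        blood_ok &= blood_alt <= cfg.blood_max_alt
    if cfg.blood_max_baf is not None:
        bp, bq = cfg.blood_max_baf.numerator, cfg.blood_max_baf.denominator
        blood_ok &= blood_alt * bq <= bp * blood_depth
    return any_qual & blood_ok


def confirmation_rate(
    discovery: Iterable[tuple] | Iterable[SomaticVariant],
    validated: Iterable[tuple] | Iterable[SomaticVariant],
) -> float:
    """Fraction of discovery-stage sites confirmed by validation.

    NaN when the discovery set is empty (undefined, not 0).
    """

    def keys(items):
        return {v.key if isinstance(v, SomaticVariant) else tuple(v) for v in items}

    disc, val = keys(discovery), keys(validated)
    if not disc:
        return math.nan
    extra = val - disc
    if extra:
        raise ValueError(f"{len(extra)} validated sites absent from the discovery set")
    return len(val) / len(disc)
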