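"""Readers and writers for the formats the pipeline touches.

All genomic coordinates are 1-based inclusive (VCF convention) everywhere in
the package, including the BED-like window tables, which are written with an
explicit ``#coords=1-based`` header flag.

Formats handled here:

* allele count tables (TSV with columns sample, chrom, pos, ref, alt,
  ref_reads, alt_reads) and a minimal VCF dialect whose per-sample ``AD``
  field carries ref,alt depths;
* variant annotation TSV (chrom, pos, ref, alt, gene, effect);
* cohort descriptions (YAML or TSV) mapping a patient to one blood/normal
  sample and an ordered list of tumor biopsies with roles;
* Newick clone trees (clone ids as labels, mutation counts as branch
  lengths);
* the TSV report tables and the JSON run summary.

Computation never lives here; modules downstream consume the plain
dataclasses / DataFrames these functions return.
"""

from __future__ import annotations

import io as _stdio
import json
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "AlleleCount",
    "VariantAnnotation",
    "CohortTable",
    "EFFECTS",
    "LOF_EFFECTS",
    "BIOPSY_ROLES",
    "read_counts",
    "write_counts",
    "counts_to_frame",
    "frame_to_counts",
    "read_annotations",
    "write_annotations",
    "read_cohort",
    "write_cohort",
    "write_tree_newick",
    "read_tree_newick",
    "write_report_tables",
    "write_run_summary",
]

EFFECTS = frozenset(
    {
        "synonymous",
        "missense",
        "stopgain",
        "stoploss",
        "frameshift",
        "inframe_indel",
        "splice",
        "other",
    }
)
#: effect classes counted as loss-of-function in driver evidence
LOF_EFFECTS = frozenset({"stopgain", "frameshift", "splice"})

BIOPSY_ROLES = frozenset(
    {"tumor_front", "tumor_center", "tumor_back", "lymph_node", "other"}
)


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass(frozen=True)
class AlleleCount:
    """Ref/alt read counts for one sample at one genomic position.

    The alternative allele is the "B allele"; ``alt_reads / depth`` is the
    B-allele frequency used throughout the pipeline.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    ref_reads: int
    alt_reads: int
    #: set when the record was synthesized for a sample missing at the site
    missing: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref_reads < 0 or self.alt_reads < 0:
            raise ValueError(
                f"negative read count at {self.chrom}:{self.pos} "
                f"({self.ref_reads}, {self.alt_reads})"
            )

    @property
    def depth(self) -> int:
        return self.ref_reads + self.alt_reads


@dataclass(frozen=True)
class VariantAnnotation:
    """Gene and functional-class annotation of a variant."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str

    def __post_init__(self) -> None:
        if self.effect not in EFFECTS:
            raise ValueError(f"unknown effect {self.effect!r}; expected one of {sorted(EFFECTS)}")

    @property
    def is_lof(self) -> bool:
        return self.effect in LOF_EFFECTS


@dataclass
class CohortTable:
    """One patient's sample layout: a blood/normal sample plus >= 1 biopsies."""

    patient_id: str
    normal_sample: str
    biopsy_samples: list[tuple[str, str]] = field(default_factory=list)  # (sample_id, role)

    def __post_init__(self) -> None:
        if not self.biopsy_samples:
            raise ValueError(f"patient {self.patient_id}: at least one biopsy required")
        for sid, role in self.biopsy_samples:
            if role not in BIOPSY_ROLES:
                raise ValueError(f"unknown biopsy role {role!r} for sample {sid}")
            if sid == self.normal_sample:
                raise ValueError(f"sample {sid} cannot be both normal and biopsy")

    @property
    def biopsy_ids(self) -> list[str]:
        return [sid for sid, _ in self.biopsy_samples]

    @property
    def roles(self) -> dict[str, str]:
        return dict(self.biopsy_samples)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

_COUNT_COLUMNS = ["sample", "chrom", "pos", "ref", "alt", "ref_reads", "alt_reads"]


def read_counts(path: str | os.PathLike, format: str = "tsv") -> list[AlleleCount]:
    """Read per-sample allele counts from a TSV table or a minimal VCF.

    The TSV dialect has columns sample, chrom, pos, ref, alt, ref_reads,
    alt_reads (a header row is accepted and detected).  The VCF dialect needs
    a per-sample ``AD`` FORMAT field holding ref,alt depths; multi-allelic
    rows are decomposed into one record per alternative allele.
    """
    if format == "tsv":
        return _read_counts_tsv(path)
    if format == "vcf":
        return _read_counts_vcf(path)
    raise ValueError(f"unknown counts format {format!r}")


def _read_counts_tsv(path: str | os.PathLike) -> list[AlleleCount]:
    records: list[AlleleCount] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if lineno == 1 and fields[:2] == ["sample", "chrom"]:
                continue  # header row
            if len(fields) != len(_COUNT_COLUMNS):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(_COUNT_COLUMNS)} columns, got {len(fields)}"
                )
            sample, chrom, pos, ref, alt, ref_reads, alt_reads = fields
            try:
                rec = AlleleCount(
                    sample_id=sample,
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref,
                    alt=alt,
                    ref_reads=int(ref_reads),
                    alt_reads=int(alt_reads),
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def _read_counts_vcf(path: str | os.PathLike) -> list[AlleleCount]:
    import pysam

    records: list[AlleleCount] = []
    with pysam.VariantFile(os.fspath(path)) as vf:
        samples = list(vf.header.samples)
        for row in vf:
            alts = row.alts or ()
            for ai, alt in enumerate(alts):
                for sample in samples:
                    call = row.samples[sample]
                    ad = call.get("AD")
                    if ad is None or ad[0] is None:
                        raise FormatError(
                            f"{path}: sample {sample} at {row.chrom}:{row.pos} "
                            "lacks the AD depth field"
                        )
                    records.append(
                        AlleleCount(
                            sample_id=sample,
                            chrom=row.chrom,
                            pos=row.pos,
                            ref=row.ref,
                            alt=alt,
                            ref_reads=int(ad[0]),
                            alt_reads=int(ad[ai + 1]),
                        )
                    )
    return records


def write_counts(counts: Iterable[AlleleCount], path: str | os.PathLike) -> None:
    """Write allele counts in the canonical TSV dialect (with header)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_COUNT_COLUMNS) + "\n")
        for c in counts:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.pos}\t{c.ref}\t{c.alt}\t"
                f"{c.ref_reads}\t{c.alt_reads}\n"
            )


def counts_to_frame(counts: Iterable[AlleleCount]) -> pd.DataFrame:
    """Long-format DataFrame view of allele counts (one row per sample-site)."""
    rows = [
        (c.sample_id, c.chrom, c.pos, c.ref, c.alt, c.ref_reads, c.alt_reads)
        for c in counts
    ]
    return pd.DataFrame(rows, columns=_COUNT_COLUMNS)


def frame_to_counts(frame: pd.DataFrame) -> list[AlleleCount]:
    return [
        AlleleCount(
            sample_id=str(r["sample"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            ref=str(r["ref"]),
            alt=str(r["alt"]),
            ref_reads=int(r["ref_reads"]),
            alt_reads=int(r["alt_reads"]),
        )
        for _, r in frame.iterrows()
    ]


# ---------------------------------------------------------------------------
# annotations and cohort
# ---------------------------------------------------------------------------


def read_annotations(path: str | os.PathLike) -> list[VariantAnnotation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    needed = {"chrom", "pos", "ref", "alt", "gene", "effect"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: annotation table must have columns {sorted(needed)}")
    return [
        VariantAnnotation(
            chrom=str(r.chrom), pos=int(r.pos), ref=str(r.ref), alt=str(r.alt),
            gene=str(r.gene), effect=str(r.effect),
        )
        for r in df.itertuples()
    ]


def write_annotations(annotations: Iterable[VariantAnnotation], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tgene\teffect\n")
        for a in annotations:
            fh.write(f"{a.chrom}\t{a.pos}\t{a.ref}\t{a.alt}\t{a.gene}\t{a.effect}\n")


def read_cohort(path: str | os.PathLike) -> list[CohortTable]:
    """Read cohort layout from YAML (list of patients) or TSV."""
    text = open(path).read()
    path_str = os.fspath(path)
    if path_str.endswith((".yaml", ".yml")) or text.lstrip().startswith(("-", "patients:")):
        data = yaml.safe_load(text)
        if isinstance(data, dict):
            data = data.get("patients", [])
        tables = []
        for entry in data:
            tables.append(
                CohortTable(
                    patient_id=str(entry["patient_id"]),
                    normal_sample=str(entry["normal_sample"]),
                    biopsy_samples=[(str(s["sample_id"]), str(s["role"])) for s in entry["biopsies"]],
                )
            )
        return tables
    # TSV: patient_id, sample_id, role ("normal" marks the blood sample)
    df = pd.read_csv(_stdio.StringIO(text), sep="\t")
    tables = []
    for pid, grp in df.groupby("patient_id", sort=True):
        normals = grp[grp.role == "normal"].sample_id.tolist()
        if len(normals) != 1:
            raise FormatError(f"patient {pid}: exactly one normal sample required, got {len(normals)}")
        biopsies = [(str(r.sample_id), str(r.role)) for r in grp.itertuples() if r.role != "normal"]
        tables.append(CohortTable(patient_id=str(pid), normal_sample=normals[0], biopsy_samples=biopsies))
    return tables


def write_cohort(tables: Sequence[CohortTable], path: str | os.PathLike) -> None:
    data = [
        {
            "patient_id": t.patient_id,
            "normal_sample": t.normal_sample,
            "biopsies": [{"sample_id": sid, "role": role} for sid, role in t.biopsy_samples],
        }
        for t in tables
    ]
    with open(path, "w") as fh:
        yaml.safe_dump({"patients": data}, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Newick clone trees
# ---------------------------------------------------------------------------


def write_tree_newick(tree, path: str | os.PathLike) -> None:
    """Serialize a clone tree as Newick: clone ids as labels, mutation counts
    as branch lengths.

    ``tree`` is any object with a ``parent`` mapping (clone id -> parent id,
    with the top clone(s) mapping to ``None`` or to the virtual ``"root"``)
    and an optional ``mutation_counts`` mapping (clone id -> int).  Raises
    ``ValueError`` on cyclic parent links.
    """
    parent = dict(tree.parent)
    counts = dict(getattr(tree, "mutation_counts", None) or {})
    children: dict[str | None, list[str]] = {}
    for child, par in parent.items():
        if par == child:
            raise ValueError(f"clone {child!r} is its own parent")
        key = None if par in (None, "root") else par
        children.setdefault(key, []).append(child)
    # cycle check: walk up from every node
    for node in parent:
        seen = {node}
        cur = parent[node]
        while cur not in (None, "root"):
            if cur in seen:
                raise ValueError(f"cyclic parent links involving clone {cur!r}")
            seen.add(cur)
            cur = parent.get(cur)

    def render(node: str) -> str:
        kids = sorted(children.get(node, []))
        label = node
        length = counts.get(node, 0)
        if kids:
            return "(" + ",".join(render(k) for k in kids) + f"){label}:{length}"
        return f"{label}:{length}"

    top = sorted(children.get(None, []))
    if not top:
        raise ValueError("tree has no clones attached to the root")
    newick = "(" + ",".join(render(t) for t in top) + ")root;"
    with open(path, "w") as fh:
        fh.write(newick + "\n")


def read_tree_newick(path: str | os.PathLike) -> tuple[dict[str, str | None], dict[str, float]]:
    """Parse a Newick clone tree back into (parent map, branch-length map).

    The virtual root label ``root`` is normalized away: its children map to
    ``None``.
    """
    import dendropy

    tree = dendropy.Tree.get(path=os.fspath(path), schema="newick")
    parent: dict[str, str | None] = {}
    lengths: dict[str, float] = {}

    def label_of(node) -> str | None:
        if node.taxon is not None and node.taxon.label:
            return str(node.taxon.label)
        return str(node.label) if node.label else None

    for node in tree.preorder_node_iter():
        lab = label_of(node)
        if lab is None or lab == "root":
            continue
        par = node.parent_node
        plab = label_of(par) if par is not None else None
        if plab == "root":
            plab = None
        parent[lab] = plab
        lengths[lab] = float(node.edge.length) if node.edge.length is not None else 0.0
    return parent, lengths


# ---------------------------------------------------------------------------
# report tables and run summary
# ---------------------------------------------------------------------------


def write_report_tables(results: dict[str, pd.DataFrame], out_dir: str | os.PathLike) -> list[str]:
    """Write each result DataFrame as ``<name>.tsv`` under ``out_dir``.

    Column order is taken from the frame; rows are written as-is (callers
    sort), floats with repr-round-tripping precision, so reruns on identical
    input are byte-identical.  Returns the written paths.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in sorted(results):
        path = os.path.join(os.fspath(out_dir), f"{name}.tsv")
        results[name].to_csv(path, sep="\t", index=False, lineterminator="\n")
        written.append(path)
    return written


def write_run_summary(summary: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
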