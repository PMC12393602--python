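"""Global CNV burden: per-sample metrics over CNV classes and gene sets.

Burden is counted per sample under a declarative metric spec (CNV type,
size range, genic status, pLI constraint bin, gene-set membership,
singleton status) and tested two ways: a logistic regression of case
status on the burden count with stratum, LRR SD and raw-call-count
covariates, and a complementary carrier CMH test across the same strata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cnv_data import CNVCall, GeneModel, SampleRecord, genes_by_chrom, overlap_bp
from .qc_filters import reciprocal_overlap
from .stats_core import (
    NonIdentifiableModelError,
    StratifiedCountTable,
    StratumCounts,
    TestResult,
    cmh_test,
    fisher_or,
    fit_burden_logistic,
)
from .stratification import Stratum

logger = logging.getLogger(__name__)

__all__ = [
    "BurdenMetricSpec",
    "DEFAULT_SIZE_BINS",
    "mark_singletons",
    "compute_burden",
    "carrier_table_for_spec",
    "run_burden_suite",
    "BurdenSuiteRow",
    "geneset_carrier_fisher",
    "compare_call_sizes",
    "leave_one_out",
    "CatalogEntry",
    "read_cnv_catalog",
    "match_known_cnvs",
    "read_gene_set",
]

# size-stratified burden bins (half-open on the left, closed on the right)
DEFAULT_SIZE_BINS = (
    (100_000, 200_000),
    (200_000, 500_000),
    (500_000, 1_000_000),
    (1_000_000, None),
)


@dataclass(frozen=True)
class BurdenMetricSpec:
    """Predicates defining one burden metric (all must hold for a call)."""

    name: str
    cnv_types: tuple[str, ...] = ("DEL", "DUP")
    size_range: tuple[int, int | None] | None = None  # (lo, hi]; hi None = unbounded
    genic_filter: str = "any"  # any | genic | nongenic
    pli_bin: str = "none"  # none | >0.9 | >0.995 | <0.9
    gene_set: str | None = None
    singleton_only: bool = False

    def __post_init__(self) -> None:
        if self.genic_filter not in ("any", "genic", "nongenic"):
            raise ValueError(f"bad genic_filter {self.genic_filter!r}")
        if self.pli_bin not in ("none", ">0.9", ">0.995", "<0.9"):
            raise ValueError(f"bad pli_bin {self.pli_bin!r}")
        if self.size_range is not None:
            lo, hi = self.size_range
            if hi is not None and lo >= hi:
                raise ValueError("size_range lo must be < hi")


def mark_singletons(
    calls: Sequence[CNVCall],
    overlap_rule: Callable[[CNVCall, CNVCall], bool] | None = None,
) -> list[bool]:
    """Per-call singleton flags: no *other sample* carries a matching call.

    Default identity rule: same CNV type, >= 50% reciprocal overlap,
    dataset-wide.
    """
    rule = overlap_rule or (
        lambda a, b: a.cnv_type == b.cnv_type and reciprocal_overlap(a, b) >= 0.5
    )
    by_chrom_type: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        by_chrom_type.setdefault((c.chrom, c.cnv_type), []).append(c)
    flags = []
    for c in calls:
        peers = by_chrom_type[(c.chrom, c.cnv_type)]
        flags.append(
            not any(p.sample_id != c.sample_id and rule(c, p) for p in peers)
        )
    return flags


def _pli_genes(genes: Sequence[GeneModel], pli_bin: str) -> list[GeneModel]:
    if pli_bin == ">0.9":
        return [g for g in genes if g.pli is not None and g.pli > 0.9]
    if pli_bin == ">0.995":
        return [g for g in genes if g.pli is not None and g.pli > 0.995]
    if pli_bin == "<0.9":
        return [g for g in genes if g.pli is not None and g.pli < 0.9]
    return list(genes)


def _hits_coding(call: CNVCall, gene_index: dict[str, list[GeneModel]]) -> bool:
    for g in gene_index.get(call.chrom, []):
        if overlap_bp(call, g.coding_intervals) >= 1:
            return True
    return False


def compute_burden(
    calls: Sequence[CNVCall],
    genes: Sequence[GeneModel],
    gene_sets: dict[str, set[str]],
    spec: BurdenMetricSpec,
    sample_ids: Sequence[str],
    singleton_flags: Sequence[bool] | None = None,
) -> np.ndarray:
    """Count, per sample, the analysis-grade calls satisfying the spec.

    A call counts toward a pLI bin (or a gene set) iff it overlaps at least
    one protein-coding base of at least one gene in that bin (set) —
    intron-only overlap never counts.
    """
    if spec.gene_set is not None and spec.gene_set not in gene_sets:
        raise KeyError(f"unknown gene set {spec.gene_set!r}")
    all_index = genes_by_chrom(genes)
    bin_index = (
        all_index if spec.pli_bin == "none"
        else genes_by_chrom(_pli_genes(genes, spec.pli_bin))
    )
    set_index = None
    if spec.gene_set is not None:
        members = gene_sets[spec.gene_set]
        set_index = genes_by_chrom([g for g in genes if g.gene_id in members])
    if spec.singleton_only and singleton_flags is None:
        singleton_flags = mark_singletons(calls)

    counts = {sid: 0 for sid in sample_ids}
    for k, c in enumerate(calls):
        if c.sample_id not in counts:
            continue
        if c.cnv_type not in spec.cnv_types:
            continue
        if spec.size_range is not None:
            lo, hi = spec.size_range
            if not (c.length() > lo and (hi is None or c.length() <= hi)):
                continue
        if spec.genic_filter != "any":
            genic = _hits_coding(c, all_index)
            if spec.genic_filter == "genic" and not genic:
                continue
            if spec.genic_filter == "nongenic" and genic:
                continue
        if spec.pli_bin != "none" and not _hits_coding(c, bin_index):
            continue
        if set_index is not None and not _hits_coding(c, set_index):
            continue
        if spec.singleton_only and not singleton_flags[k]:
            continue
        counts[c.sample_id] += 1
    return np.array([counts[sid] for sid in sample_ids], dtype=int)


def carrier_table_for_spec(
    burden: np.ndarray, sample_ids: Sequence[str], strata: Sequence[Stratum],
    locus_id: str, cnv_type: str = "ANY",
) -> StratifiedCountTable:
    """Per-stratum 2x2 table of carriers (burden >= 1) vs non-carriers."""
    carrier = {sid: b >= 1 for sid, b in zip(sample_ids, burden)}
    rows = []
    for st in strata:
        rows.append(
            StratumCounts(
                stratum_id=st.stratum_id,
                case_carriers=sum(carrier.get(s, False) for s in st.case_ids),
                case_total=st.n_case,
                control_carriers=sum(carrier.get(s, False) for s in st.control_ids),
                control_total=st.n_control,
            )
        )
    return StratifiedCountTable(locus_id=locus_id, cnv_type=cnv_type, strata=tuple(rows))


@dataclass
class BurdenSuiteRow:
    spec: BurdenMetricSpec
    logistic: TestResult | None
    cmh: TestResult | None
    error: str | None = None


def run_burden_suite(
    samples: Sequence[SampleRecord],
    calls: Sequence[CNVCall],
    genes: Sequence[GeneModel],
    gene_sets: dict[str, set[str]],
    specs: Sequence[BurdenMetricSpec],
    strata: Sequence[Stratum],
) -> list[BurdenSuiteRow]:
    """Both burden tests for every metric spec; per-spec failures don't halt.

    Only samples assigned to a stratum enter; GROUP in the regression is
    the stratum id.
    """
    stratum_of: dict[str, str] = {}
    for st in strata:
        for sid in st.case_ids | st.control_ids:
            stratum_of[sid] = st.stratum_id
    kept = [s for s in samples if s.sample_id in stratum_of]
    sample_ids = [s.sample_id for s in kept]
    status = np.array([1 if s.is_case else 0 for s in kept])
    group = [stratum_of[s.sample_id] for s in kept]
    lrr = np.array([s.lrr_sd for s in kept])
    nraw = np.array([s.n_cnv_raw for s in kept])
    singleton_flags = mark_singletons(calls)

    rows: list[BurdenSuiteRow] = []
    for spec in specs:
        try:
            burden = compute_burden(calls, genes, gene_sets, spec, sample_ids,
                                    singleton_flags=singleton_flags)
        except KeyError as exc:
            rows.append(BurdenSuiteRow(spec=spec, logistic=None, cmh=None, error=str(exc)))
            continue
        table = carrier_table_for_spec(burden, sample_ids, strata, locus_id=spec.name)
        try:
            cmh = cmh_test(table)
        except ValueError as exc:
            cmh = None
            logger.warning("spec %s: CMH failed: %s", spec.name, exc)
        err = None
        try:
            logistic = fit_burden_logistic(status, burden, group, lrr, nraw)
        except (NonIdentifiableModelError, ValueError) as exc:
            logistic = None
            err = str(exc)
        rows.append(BurdenSuiteRow(spec=spec, logistic=logistic, cmh=cmh, error=err))
    return rows


def geneset_carrier_fisher(
    samples: Sequence[SampleRecord],
    calls: Sequence[CNVCall],
    genes: Sequence[GeneModel],
    gene_set: set[str],
    cnv_type: str = "DEL",
) -> tuple[float, float]:
    """Unstratified Fisher test of gene-set carrier status, case vs control.

    A carrier has >= 1 call of ``cnv_type`` overlapping coding bases of any
    member gene. Returns (sample OR, two-sided exact p).
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    set_index = genes_by_chrom([g for g in genes if g.gene_id in gene_set])
    carriers: set[str] = set()
    for c in calls:
        if c.cnv_type == cnv_type and _hits_coding(c, set_index):
            carriers.add(c.sample_id)
    a = sum(1 for s in samples if s.is_case and s.sample_id in carriers)
    b = sum(1 for s in samples if s.is_case) - a
    c_ = sum(1 for s in samples if not s.is_case and s.sample_id in carriers)
    d = sum(1 for s in samples if not s.is_case) - c_
    try:
        return fisher_or(a, b, c_, d)
    except ValueError as exc:
        raise ValueError(f"gene-set carrier test failed: {exc}") from exc


def compare_call_sizes(
    calls: Sequence[CNVCall], samples: Sequence[SampleRecord]
) -> tuple[float, float]:
    """Two-sided rank-sum test of call lengths, case carriers vs control.

    Apply any size subset (e.g. only > 1 Mb calls) upstream.
    """
    is_case = {s.sample_id: s.is_case for s in samples}
    case_lengths = [c.length() for c in calls if is_case.get(c.sample_id)]
    control_lengths = [c.length() for c in calls if is_case.get(c.sample_id) is False]
    if not case_lengths or not control_lengths:
        raise ValueError("both case and control call-length groups must be non-empty")
    stat, p = sps.mannwhitneyu(case_lengths, control_lengths, alternative="two-sided")
    return float(stat), float(p)


def leave_one_out(
    samples: Sequence[SampleRecord],
    calls: Sequence[CNVCall],
    suite_runner: Callable[[Sequence[SampleRecord], Sequence[CNVCall]], object],
) -> dict[str, object]:
    """Re-run a burden suite excluding each dataset in turn.

    ``suite_runner`` receives the remaining samples and calls (strata must
    be rebuilt inside it). A dataset whose exclusion makes the suite fail
    is flagged with the error message; remaining datasets still run.
    """
    datasets = sorted({s.dataset_id for s in samples})
    if len(datasets) < 2:
        raise ValueError("leave-one-out requires >= 2 datasets")
    out: dict[str, object] = {}
    for ds in datasets:
        sub_samples = [s for s in samples if s.dataset_id != ds]
        keep_ids = {s.sample_id for s in sub_samples}
        sub_calls = [c for c in calls if c.sample_id in keep_ids]
        try:
            out[ds] = suite_runner(sub_samples, sub_calls)
        except (ValueError, NonIdentifiableModelError) as exc:
            out[ds] = f"FAILED: {exc}"
    return out


@dataclass(frozen=True)
class CatalogEntry:
    """One curated known-CNV locus (e.g. a recognized NDD syndrome region)."""

    locus_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str


def read_cnv_catalog(path: str | Path) -> list[CatalogEntry]:
    """BED + type column: chrom, start, end, locus_id, cnv_type."""
    from .cnv_data import ParseError, normalize_chrom

    entries = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track")):
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            raise ParseError(f"{path}: line {lineno}: expected 5 columns")
        entries.append(
            CatalogEntry(
                locus_id=parts[3], chrom=normalize_chrom(parts[0]),
                start=int(parts[1]), end=int(parts[2]), cnv_type=parts[4].upper(),
            )
        )
    return entries


def match_known_cnvs(
    calls: Sequence[CNVCall],
    catalog: Sequence[CatalogEntry],
    min_catalog_coverage: float = 0.5,
) -> list[list[str]]:
    """Per-call list of catalog locus ids hit (same type, coverage rule).

    A hit requires matching CNV type and that the call covers at least
    ``min_catalog_coverage`` of the catalog locus.
    """
    hits: list[list[str]] = []
    for c in calls:
        mine = []
        for entry in catalog:
            if entry.cnv_type != c.cnv_type or entry.chrom != c.chrom:
                continue
            ov = min(c.end, entry.end) - max(c.start, entry.start)
            if ov > 0 and ov / (entry.end - entry.start) >= min_catalog_coverage:
                mine.append(entry.locus_id)
        hits.append(mine)
    return hits


def read_gene_set(path: str | Path) -> set[str]:
    """One-column TSV of gene ids (comment lines allowed)."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#") and line != "gene_id":
            out.add(line.split("\t")[0])
    return out
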