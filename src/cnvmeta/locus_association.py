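"""Gene- and sliding-window carrier association across strata.

Loci come in two families: protein-coding genes (a CNV counts only if it
overlaps coding sequence) and fixed-size sliding windows tiling each
autosome (200 kb windows advancing in 10 kb steps by default), which make
the scan robust to the differing probe layouts of the source arrays.
Deletions and duplications are tested separately, each family with its own
permutation-calibrated genome-wide threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cnv_data import CNVCall, GeneModel, GenomeLayout, normalize_chrom
from .stats_core import (
    MinPResult,
    StratifiedCountTable,
    StratumCounts,
    TestResult,
    adjust_two_rounds,
    cmh_test,
    external_score_terms,
    genomic_lambda,
    minp_permutation,
)
from .stratification import Stratum

__all__ = [
    "Window",
    "Locus",
    "AssociationRun",
    "make_windows",
    "gene_loci",
    "window_loci",
    "carrier_matrix",
    "carrier_counts",
    "read_external_counts",
    "write_external_counts",
    "merge_external_counts",
    "run_association",
    "results_to_frame",
]

WINDOW_SIZE = 200_000
WINDOW_STEP = 10_000


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int
    end: int

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Locus:
    """A test locus: an id plus the half-open intervals a CNV must touch."""

    locus_id: str
    chrom: str
    intervals: tuple[tuple[int, int], ...]


@dataclass
class AssociationRun:
    """One test family's full scan: per-locus results plus its null."""

    test_family: str  # e.g. "window:DEL", "gene:DUP"
    loci: list[Locus]
    results: list[TestResult]
    minp: MinPResult | None
    threshold: float | None
    lambda_: float
    tables: list[StratifiedCountTable] | None = None


def make_windows(
    genome: GenomeLayout, size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> list[Window]:
    """Tile each chromosome with fixed windows advancing in fixed steps.

    Windows start at 0 and must fit entirely on the chromosome; a
    chromosome shorter than ``size`` yields a single clipped
    whole-chromosome window so small test genomes remain scannable.
    """
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    windows: list[Window] = []
    for chrom, length in genome.chroms:
        if length < size:
            windows.append(Window(chrom=chrom, start=0, end=length))
            continue
        n = (length - size) // step + 1
        for i in range(n):
            windows.append(Window(chrom=chrom, start=i * step, end=i * step + size))
    return windows


def window_loci(windows: Iterable[Window]) -> list[Locus]:
    return [
        Locus(locus_id=w.locus_id, chrom=w.chrom, intervals=((w.start, w.end),))
        for w in windows
    ]


def gene_loci(genes: Iterable[GeneModel]) -> list[Locus]:
    return [
        Locus(locus_id=g.gene_id, chrom=g.chrom, intervals=g.coding_intervals)
        for g in genes
    ]


def carrier_matrix(
    calls: Sequence[CNVCall],
    loci: Sequence[Locus],
    sample_ids: Sequence[str],
    cnv_type: str,
) -> np.ndarray:
    """(n_samples, n_loci) carrier indicators: >= 1 bp overlap, deduplicated.

    A sample is a carrier at a locus if at least one of its calls of
    ``cnv_type`` overlaps any of the locus's intervals by >= 1 bp; call
    multiplicity does not matter.
    """
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    mat = np.zeros((len(sample_ids), len(loci)), dtype=bool)
    # index loci by chromosome with sorted starts for a scan
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for j, locus in enumerate(loci):
        for s, e in locus.intervals:
            by_chrom.setdefault(locus.chrom, []).append((s, e, j))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    for call in calls:
        if call.cnv_type != cnv_type:
            continue
        i = row_of.get(call.sample_id)
        if i is None:
            continue
        for s, e, j in by_chrom.get(call.chrom, []):
            if s >= call.end:
                break
            if e > call.start:
                mat[i, j] = True
    return mat


def carrier_counts(
    calls: Sequence[CNVCall],
    loci: Sequence[Locus],
    strata: Sequence[Stratum],
    cnv_type: str,
) -> list[StratifiedCountTable]:
    """Per-locus, per-stratum 2x2 carrier counts (each sample counted once)."""
    from .cnv_data import is_autosomal

    for locus in loci:
        if not is_autosomal(locus.chrom):
            raise KeyError(
                f"locus {locus.locus_id}: chromosome {locus.chrom!r} is not an "
                "admitted autosome"
            )
    sample_ids: list[str] = []
    for st in strata:
        sample_ids.extend(sorted(st.case_ids))
        sample_ids.extend(sorted(st.control_ids))
    mat = carrier_matrix(calls, loci, sample_ids, cnv_type)
    row_of = {sid: i for i, sid in enumerate(sample_ids)}
    # per-stratum carrier sums across all loci at once
    per_stratum: list[tuple[np.ndarray, np.ndarray]] = []
    for st in strata:
        case_rows = np.array([row_of[s] for s in sorted(st.case_ids)], dtype=int)
        control_rows = np.array([row_of[s] for s in sorted(st.control_ids)], dtype=int)
        per_stratum.append((mat[case_rows].sum(axis=0), mat[control_rows].sum(axis=0)))
    tables: list[StratifiedCountTable] = []
    for j, locus in enumerate(loci):
        rows = []
        for st, (case_sum, control_sum) in zip(strata, per_stratum):
            rows.append(
                StratumCounts(
                    stratum_id=st.stratum_id,
                    case_carriers=int(case_sum[j]),
                    case_total=st.n_case,
                    control_carriers=int(control_sum[j]),
                    control_total=st.n_control,
                )
            )
        tables.append(
            StratifiedCountTable(locus_id=locus.locus_id, cnv_type=cnv_type,
                                 strata=tuple(rows))
        )
    return tables


_EXT_COLUMNS = ["locus_id", "stratum_id", "cnv_type", "case_carriers",
                "case_total", "control_carriers", "control_total"]


def read_external_counts(path: str | Path) -> list[StratifiedCountTable]:
    """Read summary-count tables exchanged with collaborating datasets."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _EXT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"external count table missing columns: {missing}")
    # a given external stratum must report consistent totals across loci
    for (sid, _ct), grp in df.groupby(["stratum_id", "cnv_type"]):
        if grp["case_total"].nunique() > 1 or grp["control_total"].nunique() > 1:
            raise ValueError(
                f"external stratum {sid!r}: conflicting totals across loci"
            )
    tables = []
    for (locus, ct), grp in df.groupby(["locus_id", "cnv_type"], sort=False):
        rows = tuple(
            StratumCounts(
                stratum_id=str(r.stratum_id),
                case_carriers=int(r.case_carriers),
                case_total=int(r.case_total),
                control_carriers=int(r.control_carriers),
                control_total=int(r.control_total),
            )
            for r in grp.itertuples()
        )
        tables.append(StratifiedCountTable(locus_id=str(locus), cnv_type=str(ct),
                                           strata=rows))
    return tables


def write_external_counts(tables: Iterable[StratifiedCountTable], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("\t".join(_EXT_COLUMNS) + "\n")
        for t in tables:
            for s in t.strata:
                fh.write(
                    f"{t.locus_id}\t{s.stratum_id}\t{t.cnv_type}\t{s.case_carriers}\t"
                    f"{s.case_total}\t{s.control_carriers}\t{s.control_total}\n"
                )


def merge_external_counts(
    internal: Sequence[StratifiedCountTable],
    external: Sequence[StratifiedCountTable],
) -> list[StratifiedCountTable]:
    """Concatenate external summary strata onto internal per-locus tables.

    External stratum ids must not collide with internal ones; loci are
    matched by (locus_id, cnv_type), and external tables for unknown loci
    are ignored.
    """
    ext_by_locus: dict[tuple[str, str], StratifiedCountTable] = {
        (t.locus_id, t.cnv_type): t for t in external
    }
    merged = []
    for t in internal:
        ext = ext_by_locus.get((t.locus_id, t.cnv_type))
        if ext is None:
            merged.append(t)
            continue
        internal_ids = {s.stratum_id for s in t.strata}
        clash = internal_ids & {s.stratum_id for s in ext.strata}
        if clash:
            raise ValueError(
                f"locus {t.locus_id}: external stratum ids collide with internal: {clash}"
            )
        merged.append(
            StratifiedCountTable(
                locus_id=t.locus_id, cnv_type=t.cnv_type,
                strata=t.strata + ext.strata,
            )
        )
    return merged


def run_association(
    calls: Sequence[CNVCall],
    loci: Sequence[Locus],
    strata: Sequence[Stratum],
    cnv_type: str,
    test_family: str,
    external: Sequence[StratifiedCountTable] = (),
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> AssociationRun:
    """Full scan for one test family: CMH per locus, min(P) null, adjusted p.

    Internal samples are permuted within strata; external summary strata
    (no individual labels) are held fixed across permutations, a
    conservative treatment. The two-round doubling is applied to the
    FWER-adjusted p-values. Lambda is computed on the raw p-values.
    With ``n_perm = 0`` only raw results are produced.
    """
    if not loci:
        raise ValueError("no loci to test")
    tables = carrier_counts(calls, loci, strata, cnv_type)
    tables = merge_external_counts(tables, external) if external else tables
    results = [cmh_test(t) for t in tables]
    lam = genomic_lambda([r.p for r in results])

    minp_res = None
    threshold = None
    if n_perm > 0:
        sample_ids: list[str] = []
        is_case: list[bool] = []
        stratum_indices: list[np.ndarray] = []
        pos = 0
        for st in strata:
            members = sorted(st.case_ids) + sorted(st.control_ids)
            sample_ids.extend(members)
            is_case.extend([True] * st.n_case + [False] * st.n_control)
            stratum_indices.append(np.arange(pos, pos + len(members)))
            pos += len(members)
        mat = carrier_matrix(calls, loci, sample_ids, cnv_type)
        locus_order = [locus.locus_id for locus in loci]
        ext_num, ext_var = external_score_terms(external, locus_order)
        minp_res = minp_permutation(
            mat, stratum_indices, np.array(is_case), n_perm=n_perm,
            alpha=alpha, seed=seed, external_num=ext_num, external_var=ext_var,
        )
        threshold = minp_res.null.threshold
        for r, p_adj in zip(results, minp_res.p_adjusted):
            r.p_adjusted = float(adjust_two_rounds(float(p_adj)))

    return AssociationRun(
        test_family=test_family, loci=list(loci), results=results,
        minp=minp_res, threshold=threshold, lambda_=lam, tables=tables,
    )


def results_to_frame(run: AssociationRun) -> pd.DataFrame:
    """Flatten an AssociationRun to the fixed-column result table."""
    rows = []
    tables = run.tables or [None] * len(run.loci)
    for locus, r, table in zip(run.loci, run.results, tables):
        n_case = n_control = None
        if table is not None:
            n_case = sum(s.case_carriers for s in table.strata)
            n_control = sum(s.control_carriers for s in table.strata)
        rows.append({
            "locus_id": locus.locus_id,
            "type": run.test_family.split(":")[-1],
            "test_family": run.test_family,
            "n_case_carriers": n_case,
            "n_control_carriers": n_control,
            "statistic": r.statistic,
            "or": r.or_mh,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p": r.p,
            "p_adjusted": r.p_adjusted,
            "degenerate": r.degenerate,
        })
    return pd.DataFrame(rows)
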