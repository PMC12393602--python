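"""Sample- and call-level QC cascades for array-based CNV callsets.

Two filter tiers are distinguished downstream:

* *qualifying* calls — >= 10 probes, 30 kb - 20 Mb, autosomes only — the
  callset underlying carrier definitions;
* *analysis-grade* calls — additionally > 100 kb with >= 15 probes — the
  callset used for burden and association tests, where array noise makes
  small calls unreliable.

A biobank-style profile (intensity bounds on LRR SD / BAF drift / absWF,
call-count caps, adjacent-call merging, blacklist exclusion and a population
frequency cut) is provided for external callsets produced by PennCNV-like
pipelines.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

from .cnv_data import CNVCall, ParseError, SampleRecord, is_autosomal, normalize_chrom

logger = logging.getLogger(__name__)

__all__ = [
    "QCProfile",
    "DEFAULT_PROFILES",
    "flag_intensity_outliers",
    "apply_raw_call_limits",
    "filter_qualifying",
    "filter_analysis_grade",
    "merge_adjacent_calls",
    "filter_by_frequency",
    "exclude_regions",
    "biobank_sample_qc",
    "flag_count_outliers",
    "reciprocal_overlap",
    "FilterReport",
]


@dataclass(frozen=True)
class QCProfile:
    """Thresholds for one array group's QC cascade."""

    profile_name: str
    max_raw_calls: int = 30
    max_total_bp: int = 20_000_000
    min_probes_qualifying: int = 10
    min_len_qualifying: int = 30_000
    max_len_qualifying: int = 20_000_000
    min_len_analysis: int = 100_000
    min_probes_analysis: int = 15
    outlier_sd_multiplier: float = 3.0
    max_frequency: float | None = None

    def __post_init__(self) -> None:
        if self.min_len_qualifying >= self.max_len_qualifying:
            raise ValueError("min_len_qualifying must be < max_len_qualifying")
        for name in ("max_raw_calls", "max_total_bp", "min_probes_qualifying",
                     "min_len_qualifying", "min_probes_analysis", "min_len_analysis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.outlier_sd_multiplier <= 0:
            raise ValueError("outlier_sd_multiplier must be positive")


# Dense arrays (610K, GSA) tolerate up to 30 raw calls; the sparser
# OmniExpress group is capped at 15. Both cap total raw footprint at 20 Mb.
DEFAULT_PROFILES: dict[str, QCProfile] = {
    "OmniExpress": QCProfile(profile_name="OmniExpress", max_raw_calls=15),
    "610K": QCProfile(profile_name="610K", max_raw_calls=30),
    "GSA": QCProfile(profile_name="GSA", max_raw_calls=30),
}


@dataclass
class FilterReport:
    """Per-stage retention bookkeeping for a QC cascade."""

    stages: list[tuple[str, int, int]]  # (stage, removed_n, retained_n)

    def add(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append((stage, n_in - n_out, n_out))

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with Path(path).open("w") as fh:
            if header_comment:
                fh.write(header_comment if header_comment.endswith("\n")
                         else header_comment + "\n")
            fh.write("stage\tremoved_n\tretained_n\n")
            for stage, removed, retained in self.stages:
                fh.write(f"{stage}\t{removed}\t{retained}\n")


def flag_intensity_outliers(
    samples: Sequence[SampleRecord],
    sd_multiplier: float = 3.0,
) -> set[str]:
    """Flag samples whose intensity metrics are outliers within their dataset.

    A sample is flagged when any of LRR SD, BAF drift or GCWF lies more than
    ``sd_multiplier`` standard deviations from the dataset median of that
    metric. The SD is computed across the dataset; the center is the median.
    Datasets with fewer than 3 samples yield no flags (a warning is logged).
    """
    flagged: set[str] = set()
    by_dataset: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_dataset.setdefault(s.dataset_id, []).append(s)
    for dataset_id, members in by_dataset.items():
        if len(members) < 3:
            warnings.warn(
                f"dataset {dataset_id!r} has < 3 samples; skipping outlier detection",
                stacklevel=2,
            )
            continue
        for metric in ("lrr_sd", "baf_drift", "gcwf"):
            vals = np.array([getattr(s, metric) for s in members], dtype=float)
            sd = vals.std(ddof=1)
            if sd == 0:
                continue
            med = np.median(vals)
            for s, v in zip(members, vals):
                if abs(v - med) > sd_multiplier * sd:
                    flagged.add(s.sample_id)
    return flagged


def apply_raw_call_limits(
    samples: Sequence[SampleRecord],
    calls: Sequence[CNVCall] | None,
    profiles: dict[str, QCProfile] | None = None,
) -> set[str]:
    """Retain samples within their array group's raw call-count and bp caps.

    Raw counts and total bp come from the sample records (``n_cnv_raw``,
    ``total_cnv_bp``); if ``calls`` is given and a sample's ``total_cnv_bp``
    is 0, the footprint is recomputed from its calls.
    """
    profiles = profiles if profiles is not None else DEFAULT_PROFILES
    bp_by_sample: dict[str, int] = {}
    n_by_sample: dict[str, int] = {}
    if calls is not None:
        for c in calls:
            bp_by_sample[c.sample_id] = bp_by_sample.get(c.sample_id, 0) + c.length()
            n_by_sample[c.sample_id] = n_by_sample.get(c.sample_id, 0) + 1
    retained: set[str] = set()
    for s in samples:
        if s.array_group not in profiles:
            if n_by_sample.get(s.sample_id, s.n_cnv_raw):
                raise KeyError(
                    f"sample {s.sample_id}: no QC profile for array group "
                    f"{s.array_group!r}"
                )
            retained.add(s.sample_id)
            continue
        prof = profiles[s.array_group]
        n_raw = s.n_cnv_raw if s.n_cnv_raw else n_by_sample.get(s.sample_id, 0)
        total_bp = s.total_cnv_bp if s.total_cnv_bp else bp_by_sample.get(s.sample_id, 0)
        if n_raw <= prof.max_raw_calls and total_bp <= prof.max_total_bp:
            retained.add(s.sample_id)
    return retained


def filter_qualifying(
    calls: Iterable[CNVCall], profile: QCProfile | None = None
) -> list[CNVCall]:
    """Keep calls with >= 10 probes, length in [30 kb, 20 Mb], on chr1-22."""
    p = profile or QCProfile(profile_name="default")
    return [
        c
        for c in calls
        if c.n_probes >= p.min_probes_qualifying
        and p.min_len_qualifying <= c.length() <= p.max_len_qualifying
        and is_autosomal(c.chrom)
    ]


def filter_analysis_grade(
    calls: Iterable[CNVCall], profile: QCProfile | None = None
) -> list[CNVCall]:
    """Keep calls strictly > 100 kb with >= 15 probes (input: qualifying)."""
    p = profile or QCProfile(profile_name="default")
    return [
        c
        for c in calls
        if c.length() > p.min_len_analysis and c.n_probes >= p.min_probes_analysis
    ]


def merge_adjacent_calls(calls: Iterable[CNVCall], gap_fraction: float = 0.20) -> list[CNVCall]:
    """Merge nearby same-type calls within each sample and chromosome.

    Two consecutive calls merge when the intervening gap is less than
    ``gap_fraction`` of the span the merge would create. The scan proceeds
    left to right and iterates to a fixed point, so a merge can enable
    further merges. Probe counts are summed; merging never crosses samples,
    chromosomes or CNV types.
    """
    groups: dict[tuple[str, str, str], list[CNVCall]] = {}
    for c in calls:
        groups.setdefault((c.sample_id, c.chrom, c.cnv_type), []).append(c)
    out: list[CNVCall] = []
    for key, members in groups.items():
        members = sorted(members, key=lambda c: (c.start, c.end))
        changed = True
        while changed:
            changed = False
            merged: list[CNVCall] = [members[0]]
            for nxt in members[1:]:
                cur = merged[-1]
                span = max(cur.end, nxt.end) - cur.start
                gap = max(0, nxt.start - cur.end)
                if gap < gap_fraction * span:
                    merged[-1] = CNVCall(
                        sample_id=cur.sample_id,
                        chrom=cur.chrom,
                        start=cur.start,
                        end=max(cur.end, nxt.end),
                        cnv_type=cur.cnv_type,
                        n_probes=cur.n_probes + nxt.n_probes,
                        dataset_id=cur.dataset_id,
                    )
                    changed = True
                else:
                    merged.append(nxt)
            members = merged
        out.extend(members)
    out.sort(key=lambda c: (c.sample_id, c.chrom, c.start, c.end, c.cnv_type))
    return out


def reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    """Smaller of the two mutual overlap fractions (0 when disjoint)."""
    if a.chrom != b.chrom:
        return 0.0
    ov = min(a.end, b.end) - max(a.start, b.start)
    if ov <= 0:
        return 0.0
    return min(ov / a.length(), ov / b.length())


def _same_cnv_default(a: CNVCall, b: CNVCall) -> bool:
    return a.cnv_type == b.cnv_type and reciprocal_overlap(a, b) >= 0.5


def filter_by_frequency(
    calls: Sequence[CNVCall],
    n_samples: int,
    max_freq: float,
    overlap_rule: Callable[[CNVCall, CNVCall], bool] | None = None,
) -> list[CNVCall]:
    """Drop calls whose locus is carried by >= ``max_freq`` of all samples.

    Two calls are "the same CNV" under the ``overlap_rule`` (default: same
    type, >= 50% reciprocal overlap). A call is removed when the number of
    distinct samples carrying a matching call (including its own carrier)
    reaches ``max_freq * n_samples``.
    """
    if not (0.0 < max_freq <= 1.0):
        raise ValueError(f"max_freq must lie in (0, 1], got {max_freq}")
    rule = overlap_rule or _same_cnv_default
    by_chrom_type: dict[tuple[str, str], list[CNVCall]] = {}
    for c in calls:
        by_chrom_type.setdefault((c.chrom, c.cnv_type), []).append(c)
    threshold = max_freq * n_samples
    kept: list[CNVCall] = []
    for c in calls:
        peers = by_chrom_type[(c.chrom, c.cnv_type)]
        carriers = {p.sample_id for p in peers if rule(c, p)}
        carriers.add(c.sample_id)
        if len(carriers) < threshold:
            kept.append(c)
    return kept


def exclude_regions(
    calls: Iterable[CNVCall],
    blacklist: Sequence[tuple[str, int, int]] | str | Path,
    min_overlap_bp: int = 1,
) -> list[CNVCall]:
    """Drop calls overlapping blacklist intervals (centromeres, telomeres...).

    ``blacklist`` is either a BED path or a list of (chrom, start, end)
    half-open intervals. Default rule: any overlap of >= 1 bp removes the
    call; adjacency (0 bp) keeps it.
    """
    if isinstance(blacklist, (str, Path)):
        intervals = []
        for lineno, line in enumerate(Path(blacklist).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{blacklist}: line {lineno}: expected 3 BED columns")
            intervals.append((normalize_chrom(parts[0]), int(parts[1]), int(parts[2])))
    else:
        intervals = [(normalize_chrom(c), s, e) for c, s, e in blacklist]
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in intervals:
        by_chrom.setdefault(chrom, []).append((s, e))
    kept = []
    for c in calls:
        hit = any(
            min(c.end, e) - max(c.start, s) >= min_overlap_bp
            for s, e in by_chrom.get(c.chrom, [])
        )
        if not hit:
            kept.append(c)
    return kept


def biobank_sample_qc(
    samples: Sequence[SampleRecord],
    calls: Sequence[CNVCall],
    max_lrr_sd: float = 0.3,
    max_baf_drift: float = 0.01,
    max_abs_wf: float = 0.05,
    max_calls: int = 50,
    max_call_len: int = 20_000_000,
) -> set[str]:
    """Biobank-style sample retention: strict intensity bounds plus call caps.

    Retains a sample iff LRR SD < 0.3, BAF drift < 0.01 and |WF| < 0.05, its
    call count is <= 50, and it carries no call longer than 20 Mb. The
    waviness factor must be present under this profile.
    """
    n_calls: dict[str, int] = {}
    max_len: dict[str, int] = {}
    for c in calls:
        n_calls[c.sample_id] = n_calls.get(c.sample_id, 0) + 1
        max_len[c.sample_id] = max(max_len.get(c.sample_id, 0), c.length())
    retained: set[str] = set()
    for s in samples:
        if s.abs_wf is None:
            raise ValueError(
                f"sample {s.sample_id}: abs_wf required for the biobank QC profile"
            )
        if s.lrr_sd >= max_lrr_sd or s.baf_drift >= max_baf_drift or s.abs_wf >= max_abs_wf:
            continue
        if n_calls.get(s.sample_id, 0) > max_calls:
            continue
        if max_len.get(s.sample_id, 0) > max_call_len:
            continue
        retained.add(s.sample_id)
    return retained


def flag_count_outliers(samples: Sequence[SampleRecord], z_max: float = 1.96) -> set[str]:
    """Optional count-outlier flag: |z| of quantile-normalized CNV counts.

    Per-sample raw call counts are mapped to standard-normal quantiles by
    rank (quantile normalization against a Gaussian target), and samples
    with |z| > ``z_max`` are flagged.
    """
    from scipy import stats

    counts = np.array([s.n_cnv_raw for s in samples], dtype=float)
    n = len(counts)
    if n < 3:
        return set()
    ranks = stats.rankdata(counts, method="average")
    z = stats.norm.ppf(ranks / (n + 1))
    return {s.sample_id for s, zi in zip(samples, z) if abs(zi) > z_max}
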