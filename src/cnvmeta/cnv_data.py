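"""Domain types, readers/writers and interval arithmetic for CNV call data.

Internal coordinates are 0-based half-open (BED convention) throughout; the
1-based inclusive dialect used by some CNV callers is converted on ingest.
Chromosome tokens are normalized by stripping a leading ``chr``; downstream
analyses admit only autosomes ``1``..``22`` (sex-chromosome rows survive
ingest but are flagged by :func:`is_autosomal`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CNVCall",
    "SampleRecord",
    "GeneModel",
    "GenomeLayout",
    "ParseError",
    "CNV_TYPES",
    "normalize_chrom",
    "is_autosomal",
    "read_cnv_calls",
    "write_cnv_calls",
    "read_sample_table",
    "write_sample_table",
    "read_gene_annotation",
    "read_genome_layout",
    "merge_intervals",
    "overlap_bp",
    "interval_overlap_bp",
    "is_genic",
    "genes_by_chrom",
]

CNV_TYPES = ("DEL", "DUP")

AUTOSOMES = tuple(str(c) for c in range(1, 23))


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the line and field."""


def normalize_chrom(token: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome token."""
    t = str(token).strip()
    if t.lower().startswith("chr"):
        t = t[3:]
    return t


def is_autosomal(chrom: str) -> bool:
    return normalize_chrom(chrom) in AUTOSOMES


@dataclass(frozen=True)
class CNVCall:
    """One called deletion or duplication segment in one sample."""

    sample_id: str
    chrom: str
    start: int
    end: int
    cnv_type: str
    n_probes: int
    copy_number: int | None = None
    dataset_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"CNVCall {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                "start must be < end"
            )
        if self.n_probes < 1:
            raise ValueError(
                f"CNVCall {self.sample_id} {self.chrom}:{self.start}-{self.end}: "
                f"n_probes must be >= 1, got {self.n_probes}"
            )
        if self.cnv_type not in CNV_TYPES:
            raise ValueError(
                f"CNVCall cnv_type must be one of {CNV_TYPES}, got {self.cnv_type!r}"
            )

    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SampleRecord:
    """Per-sample metadata: array intensity QC metrics and phenotype label.

    ``lrr_sd``, ``baf_drift`` and ``gcwf`` are the PennCNV-style intensity
    quality metrics; ``abs_wf`` is the absolute waviness factor used by
    biobank-style QC profiles. ``n_cnv_raw`` and ``total_cnv_bp`` summarize
    the raw (pre-filter) callset for the sample.
    """

    sample_id: str
    dataset_id: str
    array_group: str
    sex: str
    status: str
    lrr_sd: float
    baf_drift: float
    gcwf: float
    abs_wf: float | None = None
    n_cnv_raw: int = 0
    total_cnv_bp: int = 0
    ancestry_cluster: int | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(
                f"sample {self.sample_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        if self.status not in ("case", "control"):
            raise ValueError(
                f"sample {self.sample_id}: status must be 'case' or 'control', "
                f"got {self.status!r}"
            )
        if self.lrr_sd < 0:
            raise ValueError(f"sample {self.sample_id}: lrr_sd must be >= 0")
        if self.n_cnv_raw < 0:
            raise ValueError(f"sample {self.sample_id}: n_cnv_raw must be >= 0")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass(frozen=True)
class GeneModel:
    """A gene with merged coding intervals and an optional pLI score."""

    gene_id: str
    chrom: str
    coding_intervals: tuple[tuple[int, int], ...]
    pli: float | None = None

    def __post_init__(self) -> None:
        prev_end = -1
        for s, e in self.coding_intervals:
            if s >= e:
                raise ValueError(f"gene {self.gene_id}: interval {s}-{e} empty")
            if s < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: intervals must be sorted, non-overlapping"
                )
            prev_end = e
        if self.pli is not None and not (0.0 <= self.pli <= 1.0):
            raise ValueError(
                f"gene {self.gene_id}: pLI must lie in [0, 1], got {self.pli}"
            )

    def coding_span(self) -> tuple[int, int]:
        return self.coding_intervals[0][0], self.coding_intervals[-1][1]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered autosome lengths defining the analyzable genome."""

    chroms: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for chrom, length in self.chroms:
            if length <= 0:
                raise ValueError(f"chromosome {chrom}: length must be > 0")
            if chrom in seen:
                raise ValueError(f"duplicate chromosome token {chrom!r}")
            seen.add(chrom)

    def length_of(self, chrom: str) -> int:
        c = normalize_chrom(chrom)
        for tok, length in self.chroms:
            if tok == c:
                return length
        raise KeyError(f"chromosome {chrom!r} not in genome layout")

    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chroms)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_CNV_COLUMNS = ["sample_id", "chrom", "start", "end", "cnv_type", "n_probes", "dataset_id"]


def _parse_call_row(lineno: int, fields: dict, one_based: bool) -> CNVCall:
    try:
        start = int(fields["start"])
        end = int(fields["end"])
        n_probes = int(fields["n_probes"])
    except (TypeError, ValueError) as exc:
        raise ParseError(f"line {lineno}: non-integer coordinate/probe field ({exc})") from None
    if one_based:
        # 1-based inclusive -> 0-based half-open
        start -= 1
    cnv_type = str(fields["cnv_type"]).upper()
    if cnv_type in ("DELETION", "LOSS"):
        cnv_type = "DEL"
    elif cnv_type in ("DUPLICATION", "GAIN"):
        cnv_type = "DUP"
    if cnv_type not in CNV_TYPES:
        raise ParseError(f"line {lineno}: unknown cnv_type token {fields['cnv_type']!r}")
    try:
        return CNVCall(
            sample_id=str(fields["sample_id"]),
            chrom=normalize_chrom(fields["chrom"]),
            start=start,
            end=end,
            cnv_type=cnv_type,
            n_probes=n_probes,
            dataset_id=str(fields.get("dataset_id", "") or ""),
        )
    except ValueError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None


def read_cnv_calls(path: str | Path, dialect: str = "tsv") -> list[CNVCall]:
    """Read CNV calls from a TSV, BED-like, or PennCNV-like file.

    Dialects:

    ``tsv``
        Native 7-column headered TSV (0-based half-open).
    ``bed-like``
        Headerless ``chrom start end sample_id cnv_type n_probes [dataset_id]``
        (0-based half-open).
    ``penncnv-like``
        Free-text PennCNV output lines, 1-based inclusive, e.g.
        ``chr2:50835001-51160000  numsnp=45  ...  state2,cn=1  SAMPLE.txt  ...``.
    """
    path = Path(path)
    if dialect not in ("tsv", "bed-like", "penncnv-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    calls: list[CNVCall] = []
    if dialect == "penncnv-like":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            calls.append(_parse_penncnv_line(lineno, line))
        return calls

    with path.open() as fh:
        lines = fh.read().splitlines()
    if dialect == "tsv":
        if not lines:
            raise ParseError("empty file, expected header")
        header = lines[0].rstrip("\n").split("\t")
        missing = [c for c in _CNV_COLUMNS[:6] if c not in header]
        if missing:
            raise ParseError(f"header missing required columns: {missing}")
        idx = {c: header.index(c) for c in header}
        body = lines[1:]
        offset = 2
    else:  # bed-like
        body = lines
        offset = 1
    for lineno, line in enumerate(body, start=offset):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if dialect == "tsv":
            if len(parts) < 6:
                raise ParseError(f"line {lineno}: expected >= 6 fields, got {len(parts)}")
            fields = {c: parts[i] for c, i in idx.items() if i < len(parts)}
        else:
            if len(parts) < 6:
                raise ParseError(f"line {lineno}: expected >= 6 fields, got {len(parts)}")
            fields = {
                "chrom": parts[0],
                "start": parts[1],
                "end": parts[2],
                "sample_id": parts[3],
                "cnv_type": parts[4],
                "n_probes": parts[5],
                "dataset_id": parts[6] if len(parts) > 6 else "",
            }
        calls.append(_parse_call_row(lineno, fields, one_based=False))
    return calls


def _parse_penncnv_line(lineno: int, line: str) -> CNVCall:
    parts = line.split()
    if len(parts) < 5:
        raise ParseError(f"line {lineno}: too few whitespace-separated fields")
    region = parts[0]
    try:
        chrom, span = region.split(":")
        s, e = span.split("-")
    except ValueError:
        raise ParseError(f"line {lineno}: malformed region token {region!r}") from None
    numsnp = None
    cn = None
    for tok in parts[1:]:
        if tok.startswith("numsnp="):
            numsnp = tok.split("=", 1)[1]
        elif "cn=" in tok:
            cn = tok.rsplit("cn=", 1)[1]
    if numsnp is None or cn is None:
        raise ParseError(f"line {lineno}: missing numsnp= or cn= field")
    try:
        cn_i = int(cn)
    except ValueError:
        raise ParseError(f"line {lineno}: non-integer copy number {cn!r}") from None
    cnv_type = "DEL" if cn_i < 2 else "DUP"
    sample = parts[4] if len(parts) > 4 else ""
    sample = Path(sample).stem
    call = _parse_call_row(
        lineno,
        {
            "sample_id": sample,
            "chrom": chrom,
            "start": s,
            "end": e,
            "cnv_type": cnv_type,
            "n_probes": numsnp,
        },
        one_based=True,
    )
    return replace(call, copy_number=cn_i)


def write_cnv_calls(calls: Iterable[CNVCall], path: str | Path) -> None:
    """Write calls as the native 7-column TSV (round-trips bit-exactly)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(_CNV_COLUMNS) + "\n")
        for c in calls:
            fh.write(
                f"{c.sample_id}\t{c.chrom}\t{c.start}\t{c.end}\t"
                f"{c.cnv_type}\t{c.n_probes}\t{c.dataset_id}\n"
            )


_SAMPLE_REQUIRED = [
    "sample_id", "dataset_id", "array_group", "sex", "status",
    "lrr_sd", "baf_drift", "gcwf", "n_cnv_raw",
]
_SAMPLE_OPTIONAL = ["abs_wf", "total_cnv_bp", "ancestry_cluster"]


def read_sample_table(path: str | Path) -> list[SampleRecord]:
    """Read the per-sample metadata TSV; rejects duplicate sample ids."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in _SAMPLE_REQUIRED if c not in df.columns]
    if missing:
        raise ParseError(f"sample table missing required columns: {missing}")
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"duplicate sample_id(s): {sorted(set(dupes))}")
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        status = str(row["status"]).strip().lower()
        if status not in ("case", "control"):
            raise ParseError(
                f"row {i + 2}: status {row['status']!r} not in {{'case', 'control'}}"
            )
        sex = str(row["sex"]).strip().upper()
        if sex not in ("M", "F"):
            raise ParseError(f"row {i + 2}: sex {row['sex']!r} not in {{'M', 'F'}}")
        abs_wf = None
        if "abs_wf" in df.columns and pd.notna(row.get("abs_wf")) and str(row["abs_wf"]) != "":
            abs_wf = float(row["abs_wf"])
        cluster = None
        if (
            "ancestry_cluster" in df.columns
            and pd.notna(row.get("ancestry_cluster"))
            and str(row["ancestry_cluster"]) != ""
        ):
            cluster = int(row["ancestry_cluster"])
        try:
            records.append(
                SampleRecord(
                    sample_id=str(row["sample_id"]),
                    dataset_id=str(row["dataset_id"]),
                    array_group=str(row["array_group"]),
                    sex=sex,
                    status=status,
                    lrr_sd=float(row["lrr_sd"]),
                    baf_drift=float(row["baf_drift"]),
                    gcwf=float(row["gcwf"]),
                    abs_wf=abs_wf,
                    n_cnv_raw=int(row["n_cnv_raw"]),
                    total_cnv_bp=int(row["total_cnv_bp"]) if "total_cnv_bp" in df.columns else 0,
                    ancestry_cluster=cluster,
                )
            )
        except ValueError as exc:
            raise ParseError(f"row {i + 2}: {exc}") from None
    return records


def write_sample_table(samples: Iterable[SampleRecord], path: str | Path) -> None:
    cols = _SAMPLE_REQUIRED + _SAMPLE_OPTIONAL
    with Path(path).open("w") as fh:
        fh.write("\t".join(cols) + "\n")
        for s in samples:
            row = [
                s.sample_id, s.dataset_id, s.array_group, s.sex, s.status,
                repr(s.lrr_sd), repr(s.baf_drift), repr(s.gcwf), str(s.n_cnv_raw),
                "" if s.abs_wf is None else repr(s.abs_wf),
                str(s.total_cnv_bp),
                "" if s.ancestry_cluster is None else str(s.ancestry_cluster),
            ]
            fh.write("\t".join(row) + "\n")


def read_gene_annotation(coding_bed: str | Path, pli_tsv: str | Path | None = None) -> list[GeneModel]:
    """Build gene models from a coding-interval BED and an optional pLI table.

    BED columns: chrom, start, end, gene_id. Per-gene intervals are merged to
    a sorted non-overlapping set; genes absent from the pLI table carry
    ``pli=None``.
    """
    by_gene: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for lineno, line in enumerate(Path(coding_bed).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ParseError(f"{coding_bed}: line {lineno}: expected 4 BED columns")
        chrom = normalize_chrom(parts[0])
        try:
            s, e = int(parts[1]), int(parts[2])
        except ValueError:
            raise ParseError(f"{coding_bed}: line {lineno}: non-integer coordinates") from None
        if s >= e:
            raise ParseError(f"{coding_bed}: line {lineno}: start >= end")
        gene = parts[3]
        if gene in by_gene:
            if by_gene[gene][0] != chrom:
                raise ParseError(
                    f"{coding_bed}: line {lineno}: gene {gene} spans multiple chromosomes"
                )
            by_gene[gene][1].append((s, e))
        else:
            by_gene[gene] = (chrom, [(s, e)])

    pli_map: dict[str, float] = {}
    if pli_tsv is not None:
        pdf = pd.read_csv(pli_tsv, sep="\t", comment="#")
        if pdf.shape[1] < 2:
            raise ParseError(f"{pli_tsv}: expected 2 columns (gene_id, pli)")
        gene_col, pli_col = pdf.columns[0], pdf.columns[1]
        for _, row in pdf.iterrows():
            val = float(row[pli_col])
            if not (0.0 <= val <= 1.0):
                raise ParseError(f"{pli_tsv}: pLI {val} for {row[gene_col]} outside [0, 1]")
            pli_map[str(row[gene_col])] = val

    genes = []
    for gene_id, (chrom, ivals) in by_gene.items():
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                coding_intervals=merge_intervals(ivals),
                pli=pli_map.get(gene_id),
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.coding_intervals[0][0], g.gene_id))
    return genes


def read_genome_layout(path: str | Path) -> GenomeLayout:
    """Read a 2-column (chrom, length) TSV into a GenomeLayout."""
    chroms: list[tuple[str, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        if parts[0].lower() in ("chrom", "chromosome"):
            continue
        chroms.append((normalize_chrom(parts[0]), int(parts[1])))
    return GenomeLayout(chroms=tuple(chroms))


def write_genome_layout(genome: GenomeLayout, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("chrom\tlength\n")
        for chrom, length in genome.chroms:
            fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Interval arithmetic
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Union of half-open intervals as a sorted non-overlapping tuple.

    Adjacent intervals ([10,20) and [20,30)) are coalesced.
    """
    ivals = sorted(intervals)
    if not ivals:
        return ()
    merged = [list(ivals[0])]
    for s, e in ivals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple((s, e) for s, e in merged)


def interval_overlap_bp(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def overlap_bp(call: CNVCall, intervals: Sequence[tuple[int, int]], chrom: str | None = None) -> int:
    """Shared bases between a call and a set of half-open intervals.

    If ``chrom`` is given and differs from the call's chromosome the result
    is 0. Intervals need not be disjoint; overlapping ones are merged first
    so each base counts once.
    """
    if chrom is not None and normalize_chrom(chrom) != call.chrom:
        return 0
    total = 0
    for s, e in merge_intervals(intervals):
        total += max(0, min(call.end, e) - max(call.start, s))
    return total


def genes_by_chrom(genes: Iterable[GeneModel]) -> dict[str, list[GeneModel]]:
    index: dict[str, list[GeneModel]] = {}
    for g in genes:
        index.setdefault(g.chrom, []).append(g)
    for lst in index.values():
        lst.sort(key=lambda g: g.coding_intervals[0][0])
    return index


def is_genic(call: CNVCall, genes: Iterable[GeneModel] | dict[str, list[GeneModel]]) -> bool:
    """True iff the call overlaps at least one protein-coding base."""
    if isinstance(genes, dict):
        candidates: Iterable[GeneModel] = genes.get(call.chrom, [])
    else:
        candidates = (g for g in genes if g.chrom == call.chrom)
    for g in candidates:
        if overlap_bp(call, g.coding_intervals) >= 1:
            return True
    return False
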