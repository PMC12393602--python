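"""Config-driven end-to-end runs: QC -> strata -> burden -> association.

The run config is a flat key/value mapping (YAML on disk). Every output
file carries a header comment recording the tool version, the seed and a
hash of the config, so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

from . import __version__
from . import burden_analysis, locus_association, qc_filters, stratification
from .cnv_data import (
    read_cnv_calls,
    read_gene_annotation,
    read_genome_layout,
    read_sample_table,
    write_cnv_calls,
)
from .stats_core import genomic_lambda

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    calls: str
    samples: str
    genome: str
    genes_bed: str
    pli_tsv: str
    pc_matrix: str | None = None
    external_counts: str | None = None
    outdir: str = "cnvmeta_out"
    window_size: int = 200_000
    window_step: int = 10_000
    n_perm: int = 10_000
    alpha: float = 0.05
    seed: int = 0
    n_pcs: int = 6
    knn_k: int = 15

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of issues; empty iff the config is runnable."""
    issues: list[str] = []
    for name in ("calls", "samples", "genome", "genes_bed", "pli_tsv"):
        path = getattr(config, name)
        if not Path(path).exists():
            issues.append(f"{name}: file not found: {path}")
    for name in ("pc_matrix", "external_counts"):
        path = getattr(config, name)
        if path is not None and not Path(path).exists():
            issues.append(f"{name}: file not found: {path}")
    if not (0 < config.alpha < 1):
        issues.append(f"alpha: must lie in (0, 1), got {config.alpha}")
    if config.window_step > config.window_size:
        issues.append("window_step: must be <= window_size")
    if config.window_step <= 0:
        issues.append("window_step: must be positive")
    if config.n_perm < 0:
        issues.append("n_perm: must be >= 0")
    return issues


def _header(config: RunConfig) -> str:
    return (
        f"# cnvmeta {__version__} seed={config.seed} "
        f"config_hash={config.config_hash()}\n"
    )


def _write_with_header(df, path: Path, config: RunConfig) -> None:
    with path.open("w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the artifact directory.

    Any stage failure halts the run with the stage name in the exception;
    outputs of completed stages are preserved.
    """
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid config: " + "; ".join(issues))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return deco

    # --- load -------------------------------------------------------------
    @stage("load")
    def loaded():
        calls = read_cnv_calls(config.calls)
        samples = read_sample_table(config.samples)
        genome = read_genome_layout(config.genome)
        genes = read_gene_annotation(config.genes_bed, config.pli_tsv)
        return calls, samples, genome, genes

    calls, samples, genome, genes = loaded
    log_lines.append(f"load: {len(calls)} calls, {len(samples)} samples, "
                     f"{len(genes)} genes")

    # --- QC ---------------------------------------------------------------
    @stage("qc")
    def qc_out():
        report = qc_filters.FilterReport(stages=[])
        outliers = qc_filters.flag_intensity_outliers(samples)
        s1 = [s for s in samples if s.sample_id not in outliers]
        report.add("intensity_outliers", len(samples), len(s1))
        retained = qc_filters.apply_raw_call_limits(s1, calls)
        s2 = [s for s in s1 if s.sample_id in retained]
        report.add("raw_call_limits", len(s1), len(s2))
        keep_ids = {s.sample_id for s in s2}
        c0 = [c for c in calls if c.sample_id in keep_ids]
        c1 = qc_filters.filter_qualifying(c0)
        report.add("qualifying", len(c0), len(c1))
        c2 = qc_filters.filter_analysis_grade(c1)
        report.add("analysis_grade", len(c1), len(c2))
        report.to_tsv(outdir / "qc_report.tsv", header_comment=_header(config))
        write_cnv_calls(c2, outdir / "calls_analysis_grade.tsv")
        return s2, c1, c2

    samples_qc, calls_qualifying, calls_analysis = qc_out
    log_lines.append(
        f"qc: {len(samples_qc)} samples retained, "
        f"{len(calls_qualifying)} qualifying / {len(calls_analysis)} analysis-grade calls"
    )

    # --- strata -----------------------------------------------------------
    @stage("strata")
    def strata_out():
        if config.pc_matrix is not None:
            ids, pcs = stratification.read_pc_matrix(config.pc_matrix)
            order = {sid: i for i, sid in enumerate(ids)}
            rows = [order[s.sample_id] for s in samples_qc]
            labels = stratification.cluster_ancestry(
                pcs[rows], n_pcs=config.n_pcs, knn_k=config.knn_k, seed=config.seed
            )
            strata, dropped = stratification.build_strata(samples_qc, labels)
        else:
            strata, dropped = stratification.build_strata(samples_qc)
        stratification.write_strata(strata, dropped, outdir / "strata.tsv",
                                    header_comment=_header(config))
        return strata, dropped

    strata, dropped = strata_out
    log_lines.append(f"strata: {len(strata)} strata, {len(dropped)} samples dropped")
    if not strata:
        raise RuntimeError("stage 'strata' failed: no stratum passed the inclusion rules")

    # --- burden -----------------------------------------------------------
    @stage("burden")
    def burden_out():
        import pandas as pd

        specs = default_burden_specs()
        gene_sets = {"pli_gt_0.9": {g.gene_id for g in genes
                                    if g.pli is not None and g.pli > 0.9}}
        rows = burden_analysis.run_burden_suite(
            samples_qc, calls_analysis, genes, gene_sets, specs, strata
        )
        recs = []
        for r in rows:
            recs.append({
                "spec": r.spec.name,
                "logistic_or": None if r.logistic is None else r.logistic.or_mh,
                "logistic_p": None if r.logistic is None else r.logistic.p,
                "cmh_or": None if r.cmh is None else r.cmh.or_mh,
                "cmh_p": None if r.cmh is None else r.cmh.p,
                "error": r.error,
            })
        df = pd.DataFrame(recs)
        _write_with_header(df, outdir / "burden.tsv", config)
        return rows

    burden_rows = burden_out
    log_lines.append(f"burden: {len(burden_rows)} metric specs tested")

    # --- association ------------------------------------------------------
    @stage("assoc")
    def assoc_out():
        windows = locus_association.make_windows(
            genome, size=config.window_size, step=config.window_step
        )
        wloci = locus_association.window_loci(windows)
        gloci = locus_association.gene_loci(genes)
        external = []
        if config.external_counts is not None:
            external = locus_association.read_external_counts(config.external_counts)
        runs = {}
        # independent nulls per test family, seeded from the run seed
        for i, (family, loci) in enumerate(
            [("gene", gloci), ("window", wloci)]
        ):
            for j, cnv_type in enumerate(("DEL", "DUP")):
                fam = f"{family}:{cnv_type}"
                ext = [t for t in external if t.cnv_type == cnv_type]
                runs[fam] = locus_association.run_association(
                    calls_analysis, loci, strata, cnv_type, fam,
                    external=ext, n_perm=config.n_perm, alpha=config.alpha,
                    seed=(config.seed * 4 + i * 2 + j) % (2**31),
                )
        return runs

    runs = assoc_out

    # --- report -----------------------------------------------------------
    import pandas as pd

    frames = [locus_association.results_to_frame(r) for r in runs.values()]
    _write_with_header(pd.concat(frames, ignore_index=True),
                       outdir / "association.tsv", config)
    report = [_header(config).rstrip("\n"), ""]
    report.extend(log_lines)
    report.append("")
    for fam, run in runs.items():
        top = min(zip(run.loci, run.results), key=lambda lr: lr[1].p)
        report.append(
            f"{fam}: lambda={run.lambda_:.3f} threshold="
            f"{'NA' if run.threshold is None else format(run.threshold, '.3g')} "
            f"top_locus={top[0].locus_id} p={top[1].p:.3g} "
            f"p_adj={'NA' if top[1].p_adjusted is None else format(top[1].p_adjusted, '.3g')}"
        )
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    with (outdir / "run_log.txt").open("w") as fh:
        fh.write(_header(config))
        fh.write("\n".join(log_lines) + "\n")
    return outdir


def default_burden_specs() -> list[burden_analysis.BurdenMetricSpec]:
    S = burden_analysis.BurdenMetricSpec
    return [
        S(name="all"),
        S(name="del_all", cnv_types=("DEL",)),
        S(name="dup_all", cnv_types=("DUP",)),
        S(name="genic", genic_filter="genic"),
        S(name="nongenic", genic_filter="nongenic"),
        S(name="gt_1mb", size_range=(1_000_000, None)),
        S(name="del_pli_gt_0.9", cnv_types=("DEL",), pli_bin=">0.9"),
        S(name="del_pli_lt_0.9", cnv_types=("DEL",), pli_bin="<0.9"),
    ]
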