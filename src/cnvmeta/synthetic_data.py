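"""Synthetic stratified case/control CNV cohorts with planted risk loci.

The generator emulates the statistical structure the analysis conditions
on: heterogeneous array groups and ancestry clusters with their own
baseline call rates and intensity-noise profiles, sexes, per-sample raw
call counts, and planted risk loci whose carrier status follows a
specified control frequency and carrier odds ratio. Background calls are
placed uniformly and independently of genes, so genic burden signal arises
only through planted loci (or an explicit genic-enrichment multiplier).

Because toy genomes are orders of magnitude smaller than a real genome
while call lengths and window sizes are kept realistic, the default
baseline call rate is chosen per scenario so that the *per-window
background carrier probability* — not the per-genome call count — matches
the regime being emulated (ultra-rare loci vs dense null scans).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from . import qc_filters
from .cnv_data import (
    CNVCall,
    GeneModel,
    GenomeLayout,
    SampleRecord,
    write_cnv_calls,
    write_genome_layout,
    write_sample_table,
)

__all__ = [
    "StratumSpec",
    "PlantedLocus",
    "SimConfig",
    "toy_genome",
    "genome_with_n_windows",
    "generate_gene_fixture",
    "simulate_cohort",
    "write_fixture",
    "confounded_config",
]


@dataclass(frozen=True)
class StratumSpec:
    """One simulated (array group, cluster, sex) cell of the cohort."""

    array_group: str
    cluster: int
    sex: str
    n_case: int
    n_control: int
    baseline_call_rate: float = 2.0  # mean raw background calls per sample
    probe_density: float = 1.0 / 6000.0  # probes per bp (array-like spacing)


@dataclass(frozen=True)
class PlantedLocus:
    """A risk locus: carrier frequency f in controls, carrier OR in cases."""

    chrom: str
    start: int
    end: int
    cnv_type: str
    control_freq: float
    odds_ratio: float

    def case_freq(self) -> float:
        f, r = self.control_freq, self.odds_ratio
        fc = f * r / (1.0 - f + f * r)
        if fc >= 1.0:
            raise ValueError(
                f"planted locus {self.chrom}:{self.start}-{self.end}: implied "
                f"case carrier frequency {fc} >= 1"
            )
        return fc


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    genome: GenomeLayout = field(
        default_factory=lambda: toy_genome(n_chroms=3, chrom_length=3_000_000)
    )
    strata_spec: tuple[StratumSpec, ...] = (
        StratumSpec("GSA", 0, "M", 250, 250),
        StratumSpec("GSA", 0, "F", 250, 250),
    )
    # log-normal call lengths; defaults give a ~150 kb median so both the
    # qualifying (30 kb) and analysis-grade (>100 kb) filters bite
    length_mu: float = math.log(150_000.0)
    length_sigma: float = 0.5
    planted_loci: tuple[PlantedLocus, ...] = ()
    n_genes: int = 60
    coding_fraction: float = 0.3
    pli_high_fraction: float = 0.2
    lrr_sd_model: tuple[tuple[str, tuple[float, float]], ...] = (
        ("GSA", (0.12, 0.02)),
        ("610K", (0.14, 0.02)),
        ("OmniExpress", (0.16, 0.03)),
    )
    # boundary jitter added around planted loci so carrier calls fully span them
    planted_jitter: int = 20_000

    def __post_init__(self) -> None:
        for pl in self.planted_loci:
            length = self.genome.length_of(pl.chrom)
            if not (0 <= pl.start < pl.end <= length):
                raise ValueError(
                    f"planted locus {pl.chrom}:{pl.start}-{pl.end} outside genome"
                )
            if not (0.0 <= pl.control_freq <= 1.0):
                raise ValueError("control_freq must lie in [0, 1]")
            if pl.odds_ratio <= 0:
                raise ValueError("odds_ratio must be > 0")
            pl.case_freq()  # validates the implied case frequency


def toy_genome(n_chroms: int = 3, chrom_length: int = 3_000_000) -> GenomeLayout:
    # only autosome tokens 1..22 survive the qualifying filter downstream
    if not (1 <= n_chroms <= 22):
        raise ValueError("toy genomes must use 1..22 chromosomes (autosome tokens)")
    return GenomeLayout(tuple((str(i + 1), chrom_length) for i in range(n_chroms)))


def genome_with_n_windows(n_windows: int, size: int = 200_000, step: int = 10_000) -> GenomeLayout:
    """Single-chromosome genome yielding exactly ``n_windows`` sliding windows."""
    length = (n_windows - 1) * step + size
    return GenomeLayout((("1", length),))


# ---------------------------------------------------------------------------
# Gene fixture
# ---------------------------------------------------------------------------

def generate_gene_fixture(
    config: SimConfig,
) -> tuple[list[GeneModel], dict[str, set[str]]]:
    """Non-overlapping genes with coding intervals, a pLI mixture, gene sets.

    pLI is drawn from a two-component mixture: ``pli_high_fraction`` of
    genes ~ U(0.95, 1) (dosage-intolerant), the rest ~ U(0, 0.5). Gene sets
    returned: ``pli_gt_0.9`` (derived), ``ndd_risk`` (a random 15%) and
    ``denovo_hits`` (a random 5% of the high-pLI genes).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 101]))
    genome = config.genome
    total_len = sum(length for _, length in genome.chroms)
    # allocate genes to chromosomes proportionally to length, remainder first
    lengths = [length for _, length in genome.chroms]
    alloc = [config.n_genes * l // total_len for l in lengths]
    i = 0
    while sum(alloc) < config.n_genes:
        alloc[i % len(alloc)] += 1
        i += 1
    offsets: list[tuple[str, int, int]] = []  # (chrom, slot_start, slot)
    for (chrom, length), n_here in zip(genome.chroms, alloc):
        if n_here == 0:
            continue
        slot = length // n_here
        gene_len = max(int(slot * 0.5), 3_000)
        if slot <= gene_len:
            raise ValueError(
                f"{config.n_genes} genes cannot fit in a {total_len} bp genome"
            )
        for k in range(n_here):
            offsets.append((chrom, k * slot, slot))
    if len(offsets) < config.n_genes:
        raise ValueError("genes cannot fit in genome with the chosen layout")
    genes: list[GeneModel] = []
    is_high = rng.random(config.n_genes) < config.pli_high_fraction
    for i, (chrom, slot_start, slot) in enumerate(offsets[: config.n_genes]):
        gene_len = max(int(slot * 0.5), 3_000)
        gstart = slot_start + int(rng.integers(0, slot - gene_len))
        n_exons = int(rng.integers(2, 6))
        coding_total = int(gene_len * config.coding_fraction)
        exon_len = max(coding_total // n_exons, 50)
        gap = (gene_len - n_exons * exon_len) // max(n_exons - 1, 1)
        exons = []
        cur = gstart
        for _ in range(n_exons):
            exons.append((cur, cur + exon_len))
            cur += exon_len + max(gap, 1)
        pli = float(rng.uniform(0.95, 1.0)) if is_high[i] else float(rng.uniform(0.0, 0.5))
        genes.append(
            GeneModel(
                gene_id=f"G{i + 1:04d}", chrom=chrom,
                coding_intervals=tuple(exons), pli=pli,
            )
        )
    ids = [g.gene_id for g in genes]
    high = {g.gene_id for g in genes if g.pli is not None and g.pli > 0.9}
    ndd = set(rng.choice(ids, size=max(1, len(ids) * 15 // 100), replace=False))
    denovo_pool = sorted(high) or ids
    denovo = set(rng.choice(denovo_pool, size=max(1, len(denovo_pool) // 3), replace=False))
    gene_sets = {"pli_gt_0.9": high, "ndd_risk": ndd, "denovo_hits": denovo}
    return genes, gene_sets


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(
    config: SimConfig,
) -> tuple[list[SampleRecord], list[CNVCall], np.ndarray]:
    """Simulate samples, CNV calls, and a PC matrix for the configured strata.

    Background calls per sample ~ Poisson(baseline rate), split evenly
    between DEL and DUP, placed uniformly on the genome with log-normal
    lengths; probe counts follow the stratum's probe density. Planted-locus
    carrier status is Bernoulli with the control frequency (controls) or
    the odds-ratio-implied case frequency (cases); each carrier receives
    one call spanning the locus with jittered boundaries. The PC matrix
    places ancestry clusters at well-separated centroids (first two PCs)
    with unit Gaussian noise on six PCs.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 202]))
    genome = config.genome
    chrom_names = [c for c, _ in genome.chroms]
    chrom_lengths = np.array([l for _, l in genome.chroms], dtype=float)
    chrom_probs = chrom_lengths / chrom_lengths.sum()
    lrr_model = dict(config.lrr_sd_model)

    samples: list[SampleRecord] = []
    calls: list[CNVCall] = []
    cluster_labels: list[int] = []
    counter = 0
    for spec in config.strata_spec:
        mu_lrr, sd_lrr = lrr_model.get(spec.array_group, (0.12, 0.02))
        for arm, n_arm in (("case", spec.n_case), ("control", spec.n_control)):
            for _ in range(n_arm):
                counter += 1
                sid = f"S{counter:06d}"
                dataset = f"{spec.array_group}_c{spec.cluster}"
                my_calls: list[CNVCall] = []
                n_bg = int(rng.poisson(spec.baseline_call_rate))
                for _ in range(n_bg):
                    ci = int(rng.choice(len(chrom_names), p=chrom_probs))
                    chrom = chrom_names[ci]
                    clen = int(chrom_lengths[ci])
                    length = int(rng.lognormal(config.length_mu, config.length_sigma))
                    length = max(1, min(length, clen - 1))
                    start = int(rng.integers(0, clen - length))
                    cnv_type = "DEL" if rng.random() < 0.5 else "DUP"
                    n_probes = max(1, round(length * spec.probe_density))
                    my_calls.append(
                        CNVCall(sample_id=sid, chrom=chrom, start=start,
                                end=start + length, cnv_type=cnv_type,
                                n_probes=n_probes, dataset_id=dataset)
                    )
                for pl in config.planted_loci:
                    freq = pl.case_freq() if arm == "case" else pl.control_freq
                    if rng.random() < freq:
                        j1 = int(rng.integers(0, config.planted_jitter + 1))
                        j2 = int(rng.integers(0, config.planted_jitter + 1))
                        s = max(0, pl.start - j1)
                        e = min(genome.length_of(pl.chrom), pl.end + j2)
                        n_probes = max(15, round((e - s) * spec.probe_density))
                        my_calls.append(
                            CNVCall(sample_id=sid, chrom=pl.chrom, start=s, end=e,
                                    cnv_type=pl.cnv_type, n_probes=n_probes,
                                    dataset_id=dataset)
                        )
                lrr = max(0.01, float(rng.normal(mu_lrr, sd_lrr)))
                baf = abs(float(rng.normal(0.002, 0.001)))
                gcwf = float(rng.normal(0.0, 0.01))
                samples.append(
                    SampleRecord(
                        sample_id=sid, dataset_id=dataset,
                        array_group=spec.array_group, sex=spec.sex, status=arm,
                        lrr_sd=round(lrr, 6), baf_drift=round(baf, 6),
                        gcwf=round(gcwf, 6), abs_wf=round(abs(gcwf), 6),
                        n_cnv_raw=len(my_calls),
                        total_cnv_bp=sum(c.length() for c in my_calls),
                        ancestry_cluster=spec.cluster,
                    )
                )
                cluster_labels.append(spec.cluster)
                calls.extend(my_calls)

    # PC matrix: cluster centroids on a circle of radius 10 in PC1/PC2
    uniq = sorted(set(cluster_labels))
    centroids = {}
    for i, lab in enumerate(uniq):
        theta = 2 * math.pi * i / max(len(uniq), 1)
        centroids[lab] = np.array([10 * math.cos(theta), 10 * math.sin(theta),
                                   0, 0, 0, 0])
    pcs = np.vstack([
        centroids[lab] + rng.normal(0, 1, size=6) for lab in cluster_labels
    ])
    return samples, calls, pcs


def confounded_config(
    seed: int = 0,
    n_per_stratum: int = 2000,
    low_rate: float = 16.0,
    high_rate: float = 24.0,
) -> SimConfig:
    """A cohort where ancestry confounds case status and call rate.

    Cluster 1 has both a higher case fraction (0.8 vs 0.2) and a doubled
    baseline call rate relative to cluster 0, so pooled (unstratified)
    carrier tests are inflated at every locus while within-cluster
    comparisons remain null — the regime stratified CMH testing absorbs.

    Stratum sizes and rates are chosen so expected per-window carrier
    counts are large enough (tens per stratum) for the chi-square
    approximation the inflation-factor diagnostic presumes.
    """
    n = n_per_stratum
    return SimConfig(
        seed=seed,
        genome=toy_genome(n_chroms=22, chrom_length=1_500_000),
        strata_spec=(
            StratumSpec("GSA", 0, "M", n_case=int(0.2 * n), n_control=int(0.8 * n),
                        baseline_call_rate=low_rate),
            StratumSpec("GSA", 1, "M", n_case=int(0.8 * n), n_control=int(0.2 * n),
                        baseline_call_rate=high_rate),
        ),
    )


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------

def write_fixture(
    outdir: str | Path,
    config: SimConfig,
) -> dict[str, int]:
    """Simulate a cohort and write every pipeline input plus a manifest.

    Emits ``calls.tsv``, ``samples.tsv``, ``genome.tsv``, ``genes.bed``,
    ``pli.tsv``, ``pc_matrix.tsv``, per-gene-set TSVs, and ``manifest.tsv``
    recording ground truth: the planted loci and the filter-cascade
    survivor counts (computed by running the QC filters on the simulated
    calls at generation time). Deterministic: same config, same bytes.
    Returns the manifest as a dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes, gene_sets = generate_gene_fixture(config)
    samples, calls, pcs = simulate_cohort(config)

    write_cnv_calls(calls, outdir / "calls.tsv")
    write_sample_table(samples, outdir / "samples.tsv")
    write_genome_layout(config.genome, outdir / "genome.tsv")
    with (outdir / "genes.bed").open("w") as fh:
        for g in genes:
            for s, e in g.coding_intervals:
                fh.write(f"{g.chrom}\t{s}\t{e}\t{g.gene_id}\n")
    with (outdir / "pli.tsv").open("w") as fh:
        fh.write("gene_id\tpli\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.pli:.6f}\n")
    with (outdir / "pc_matrix.tsv").open("w") as fh:
        fh.write("sample_id\t" + "\t".join(f"PC{i + 1}" for i in range(6)) + "\n")
        for s, row in zip(samples, pcs):
            vals = "\t".join(f"{v:.6f}" for v in row)
            fh.write(f"{s.sample_id}\t{vals}\n")
    for name, members in gene_sets.items():
        with (outdir / f"geneset_{name}.tsv").open("w") as fh:
            fh.write("gene_id\n")
            for gid in sorted(members):
                fh.write(gid + "\n")

    qualifying = qc_filters.filter_qualifying(calls)
    analysis = qc_filters.filter_analysis_grade(qualifying)
    manifest = {
        "n_samples": len(samples),
        "n_cases": sum(1 for s in samples if s.is_case),
        "n_controls": sum(1 for s in samples if not s.is_case),
        "n_calls_raw": len(calls),
        "n_calls_qualifying": len(qualifying),
        "n_calls_analysis_grade": len(analysis),
        "n_planted_loci": len(config.planted_loci),
        "seed": int(config.seed),
    }
    with (outdir / "manifest.tsv").open("w") as fh:
        fh.write("key\tvalue\n")
        for k, v in manifest.items():
            fh.write(f"{k}\t{v}\n")
        for i, pl in enumerate(config.planted_loci):
            fh.write(
                f"planted_locus_{i}\t{pl.chrom}:{pl.start}-{pl.end}:{pl.cnv_type}:"
                f"{pl.control_freq}:{pl.odds_ratio}\n"
            )
    return manifest
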