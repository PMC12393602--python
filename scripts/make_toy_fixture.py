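"""Regenerate the packaged toy cohort fixture under tests/data/toy_cohort/.

The fixture is deterministic (seed recorded in its manifest); re-running
this script reproduces the committed files byte-for-byte.
"""

from pathlib import Path

from cnvmeta import synthetic_data as sd

OUTDIR = Path(__file__).resolve().parent.parent / "tests" / "data" / "toy_cohort"

CONFIG = sd.SimConfig(
    seed=20_240_901,
    genome=sd.toy_genome(n_chroms=3, chrom_length=1_200_000),
    strata_spec=(
        sd.StratumSpec("GSA", 0, "M", 40, 40, baseline_call_rate=1.0),
        sd.StratumSpec("GSA", 0, "F", 40, 40, baseline_call_rate=1.0),
    ),
    planted_loci=(
        sd.PlantedLocus(chrom="2", start=400_000, end=600_000, cnv_type="DUP",
                        control_freq=0.05, odds_ratio=8.0),
    ),
    n_genes=24,
    planted_jitter=10_000,
)


def main() -> None:
    manifest = sd.write_fixture(OUTDIR, CONFIG)
    for k, v in manifest.items():
        print(f"{k}\t{v}")


if __name__ == "__main__":
    main()
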