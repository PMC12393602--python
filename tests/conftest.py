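from pathlib import Path

import numpy as np
import pytest

from cnvmeta.cnv_data import CNVCall, GeneModel, SampleRecord

FIXTURE_DIR = Path(__file__).parent / "data" / "toy_cohort"


def make_call(sample="S1", chrom="1", start=100_000, end=300_000,
              cnv_type="DEL", n_probes=20, dataset="D1") -> CNVCall:
    return CNVCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   cnv_type=cnv_type, n_probes=n_probes, dataset_id=dataset)


def make_sample(sid="S1", dataset="D1", array_group="GSA", sex="M",
                status="control", lrr_sd=0.12, baf_drift=0.002, gcwf=0.0,
                abs_wf=0.0, n_cnv_raw=2, total_cnv_bp=200_000) -> SampleRecord:
    return SampleRecord(sample_id=sid, dataset_id=dataset, array_group=array_group,
                        sex=sex, status=status, lrr_sd=lrr_sd, baf_drift=baf_drift,
                        gcwf=gcwf, abs_wf=abs_wf, n_cnv_raw=n_cnv_raw,
                        total_cnv_bp=total_cnv_bp)


@pytest.fixture(scope="session")
def fixture_dir() -> Path:
    return FIXTURE_DIR


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def simple_genes() -> list[GeneModel]:
    return [
        GeneModel(gene_id="GA", chrom="1",
                  coding_intervals=((100_000, 105_000), (150_000, 155_000)),
                  pli=0.97),
        GeneModel(gene_id="GB", chrom="1",
                  coding_intervals=((500_000, 520_000),), pli=0.30),
        GeneModel(gene_id="GC", chrom="2",
                  coding_intervals=((200_000, 210_000),), pli=0.999),
    ]
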