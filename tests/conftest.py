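import numpy as np
import pytest

from cghcohort import cna_calling, synthetic_data
from cghcohort.io_formats import CloneMap, Config


@pytest.fixture()
def cfg():
    return Config()


@pytest.fixture(scope="session")
def f1_cohort():
    return synthetic_data.simulate_cohort(synthetic_data.fixture("F1"), seed=42)


@pytest.fixture(scope="session")
def f1_results(f1_cohort):
    return cna_calling.call_cohort(
        f1_cohort.ratios, f1_cohort.clone_map, Config(rng_seed=42)
    )


@pytest.fixture()
def toy_map():
    """10-clone single-chromosome grid at integer Mb 0..9."""
    return CloneMap.from_records(
        [(f"C{i:02d}", "CFA1", float(i)) for i in range(10)],
        chrom_lengths={"CFA1": 10.0},
    )


def make_result(case_id, segs):
    """Helper: CaseCallResult from (chrom, start, end, state) tuples."""
    return cna_calling.CaseCallResult(
        case_id=case_id,
        segments=[
            cna_calling.Segment(
                case_id=case_id,
                chrom=c,
                start_mb=s,
                end_mb=e,
                state=st,
                mean_log2=-0.5 if st == "loss" else 0.5,
                n_clones=max(2, int(round(e - s))),
            )
            for c, s, e, st in segs
        ],
    )


@pytest.fixture()
def result_factory():
    return make_result
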