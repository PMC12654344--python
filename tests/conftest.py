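import numpy as np
import pytest

from medax.instruments import InstrumentSet
from medax.summary_io import HarmonizedPair, SummaryRecord


def make_instrument_set(bx, by, se_y, se_x=None, name="exposure", outcome="outcome"):
    """InstrumentSet from plain effect arrays (test helper)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    se_y = np.asarray(se_y, dtype=float)
    se_x = np.full_like(bx, 0.01) if se_x is None else np.asarray(se_x, dtype=float)
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{j + 1}",
            beta_exposure=float(bx[j]),
            se_exposure=float(se_x[j]),
            beta_outcome=float(by[j]),
            se_outcome=float(se_y[j]),
            eaf_exposure=0.3,
        )
        for j in range(bx.size)
    ]
    return InstrumentSet(exposure_name=name, outcome_name=outcome, pairs=pairs)


def make_record(snp_id="rs1", ea="A", oa="G", eaf=0.3, beta=0.1, se=0.01,
                pvalue=1e-8, n=10_000, chrom="1", pos_bp=1_000_000):
    return SummaryRecord(
        snp_id=snp_id, effect_allele=ea, other_allele=oa, eaf=eaf, beta=beta,
        se=se, pvalue=pvalue, n=n, chrom=chrom, pos_bp=pos_bp,
    )


@pytest.fixture
def proportional_set():
    """Exactly proportional beta_y = 0.5 * beta_x with equal outcome se."""
    bx = np.array([0.1, 0.2, 0.4, 0.3, 0.25])
    return make_instrument_set(bx, 0.5 * bx, np.full(5, 0.1))


@pytest.fixture
def dii_studies():
    """The four published DII-cholelithiasis odds ratios with 95% CIs."""
    from medax.meta_analysis import MetaStudy

    return [
        MetaStudy("Luo", 1.14, 1.01, 1.29),
        MetaStudy("Jiang", 1.10, 1.01, 1.19),
        MetaStudy("Wu", 1.44, 1.08, 1.91),
        MetaStudy("Cheng", 1.52, 1.19, 1.93),
    ]
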