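import numpy as np
import pytest
from hypothesis import settings

from tscmr import RatioInput, SummaryAssociation

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def write_gwas(path, rows, header=("SNP", "effect_allele", "other_allele",
                                   "eaf", "beta", "se", "pval", "samplesize")):
    """Write a GWAS summary-statistic TSV from row tuples (None -> blank)."""
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def ratio_fixture(rng):
    """Five SNPs with heterogeneous effects and weights."""
    ratios = []
    for i in range(5):
        b_gx = rng.uniform(0.05, 0.3)
        theta = 0.8
        b_gy = theta * b_gx + rng.normal(0, 0.02)
        ratios.append(
            RatioInput(
                b_gx=b_gx,
                se_gx=rng.uniform(0.005, 0.02),
                b_gy=b_gy,
                se_gy=rng.uniform(0.01, 0.05),
                snp_id=f"rs{i+1}",
            )
        )
    return ratios


def assoc(snp_id="rs1", ea="A", oa="G", beta=0.1, se=0.02, eaf=0.3,
          pval=None, n=None):
    return SummaryAssociation(
        snp_id=snp_id, effect_allele=ea, other_allele=oa,
        beta=beta, se=se, eaf=eaf, pval=pval, n=n,
    )
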