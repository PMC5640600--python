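import numpy as np
import pytest

from decstat import AssociationRecord, PairedRegionScan, SimulationConfig, generate_dataset


def make_record(
    snp_id="snp1",
    position=100,
    allele1="A",
    allele2="G",
    beta=0.5,
    se=0.1,
    p=0.01,
):
    return AssociationRecord(
        snp_id=snp_id, position=position, allele1=allele1, allele2=allele2,
        beta=beta, se=se, p=p,
    )


def make_pair(log1p_disease, log1p_eqtl, betas_disease=None, betas_eqtl=None):
    """Build a harmonized paired scan from log10(1/p) values and effect signs."""
    k = len(log1p_disease)
    betas_disease = betas_disease if betas_disease is not None else [1.0] * k
    betas_eqtl = betas_eqtl if betas_eqtl is not None else [1.0] * k
    rd = tuple(
        make_record(snp_id=f"s{i}", position=10 * (i + 1), beta=betas_disease[i],
                    p=10.0 ** (-log1p_disease[i]))
        for i in range(k)
    )
    re_ = tuple(
        make_record(snp_id=f"s{i}", position=10 * (i + 1), beta=betas_eqtl[i],
                    p=10.0 ** (-log1p_eqtl[i]))
        for i in range(k)
    )
    return PairedRegionScan(records_disease=rd, records_eqtl=re_)


@pytest.fixture(scope="session")
def shared_causal_dataset():
    """One region where the same variant drives expression and disease risk."""
    cfg = SimulationConfig(
        n_individuals=1000, n_snps=60, causal_index_expr=30, h2_expr=0.25,
        causal_index_dis=30, log_or_dis=0.6, seed=11,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def null_dataset():
    """A region with no genetic signal in either phenotype."""
    cfg = SimulationConfig(n_individuals=500, n_snps=50, seed=5)
    return generate_dataset(cfg)
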