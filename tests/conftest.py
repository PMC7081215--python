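import numpy as np
import pytest

import adipoloc as al


@pytest.fixture(scope="session")
def shared_locus():
    """One medium locus with a shared causal variant, reused across tests."""
    cfg = al.SimConfig(
        n_individuals=2000,
        m_variants=60,
        seed=11,
        architecture=al.CausalArchitecture((30,), (30,), h2_gwas=0.05, h2_eqtl=0.05),
        enrichment_mode="causal-centered",
    )
    haps = al.simulate_haplotypes(cfg)
    ld = al.compute_ld(haps)
    y_gwas, y_eqtl = al.simulate_phenotypes(haps, cfg.architecture, cfg.seed)
    gwas = al.marginal_summary_stats(haps, y_gwas)
    eqtl = al.marginal_summary_stats(haps, y_eqtl)
    return {"config": cfg, "haps": haps, "ld": ld, "gwas": gwas, "eqtl": eqtl}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)


def make_stats(z, n=1000, se=None, positions=None):
    """SummaryStats from a z vector (unit-ish se unless given)."""
    z = np.asarray(z, dtype=float)
    m = len(z)
    se = np.full(m, 0.05) if se is None else np.asarray(se, dtype=float)
    if positions is None:
        positions = np.arange(10, 10 * (m + 1), 10)
    return al.SummaryStats(
        variant_ids=[f"v{i}" for i in range(m)],
        positions=np.asarray(positions),
        beta=z * se,
        se=se,
        z=z,
        n=n,
    )


def identity_ld(m, signed=True):
    eye = np.eye(m)
    return al.LDMatrix(
        values=eye.copy(),
        variant_ids=[f"v{i}" for i in range(m)],
        signed_r=eye.copy() if signed else None,
    )
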