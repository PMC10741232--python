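import numpy as np
import pytest

import candigene as cg


@pytest.fixture
def two_snp_panel():
    """Deterministic 6-sample panel at two SNPs, both groups present."""
    snps = [
        cg.SnpMeta("snp1", "1", 100, "G", "T"),
        cg.SnpMeta("snp2", "1", 200, "A", "C"),
    ]
    geno = np.array(
        [[0, 0], [1, 1], [2, 2], [0, 1], [1, 0], [cg.MISSING, 2]], dtype=np.int8
    )
    return cg.GenotypePanel(
        snps=snps,
        samples=[f"s{i}" for i in range(6)],
        genotypes=geno,
        phenotype=np.array([1, 1, 1, 0, 0, 0], dtype=np.int8),
    )


@pytest.fixture
def xor_panel():
    """400-sample cohort with a planted marginal-free XOR pair among noise SNPs."""
    blocks = [
        cg.HaplotypeBlock(("L1",), ("A", "T"), (0.5, 0.5)),
        cg.HaplotypeBlock(("L2",), ("A", "T"), (0.5, 0.5)),
        cg.HaplotypeBlock(("N1",), ("A", "T"), (0.8, 0.2)),
        cg.HaplotypeBlock(("N2",), ("A", "T"), (0.7, 0.3)),
    ]
    pen = cg.make_xor_penetrance(("L1", "L2"), baseline=0.05, effect=0.25)
    panel, _ = cg.simulate_cohort(
        cg.SimulationConfig(
            blocks=blocks, n_cases=200, n_controls=200,
            penetrance=pen, missing_rate=0.0, seed=42,
        )
    )
    return panel


def null_panel(seed, n_cases=120, n_controls=95, mafs=(0.2, 0.3, 0.4)):
    """Pure-noise cohort: genotypes independent of the case/control label."""
    blocks = [
        cg.HaplotypeBlock((f"S{i}",), ("A", "T"), (1 - m, m))
        for i, m in enumerate(mafs)
    ]
    panel, _ = cg.simulate_cohort(
        cg.SimulationConfig(
            blocks=blocks, n_cases=n_cases, n_controls=n_controls,
            missing_rate=0.0, seed=seed,
        )
    )
    return panel
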