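import numpy as np
import pandas as pd
import pytest

from tissuemark.simulate import ModuleSpec, SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expr():
    """2 genes x 3 samples handcrafted TPM matrix."""
    return pd.DataFrame(
        [[1.5, 0.0, 3.25], [10.0, 20.0, 0.5]],
        index=pd.Index(["G1", "G2"], name="gene_id"),
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture
def tiny_annot():
    return pd.DataFrame(
        {"tissue": ["skin", "skin", "liver"]},
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )


def planted_two_module_spec(seed: int) -> SyntheticSpec:
    """50 + 50 module genes (loading 0.9, noise 0.2) and 100 independents."""
    genes = (
        [f"A{i:03d}" for i in range(50)]
        + [f"B{i:03d}" for i in range(50)]
        + [f"N{i:03d}" for i in range(100)]
    )
    return SyntheticSpec(
        n_tissues=1,
        samples_per_tissue=200,
        n_genes=200,
        noise_sd_log10=0.2,
        modules=[
            ModuleSpec(genes=genes[:50], loading=0.9, factor_sd=1.0),
            ModuleSpec(genes=genes[50:100], loading=0.9, factor_sd=1.0),
        ],
        gene_ids=genes,
        seed=seed,
    )


def planted_three_module_logexpr(seed: int, genes_per_module: int = 20):
    """Log-scale expression of three planted modules, plus the module truth."""
    genes = [f"M{m}G{i:02d}" for m in range(3) for i in range(genes_per_module)]
    spec = SyntheticSpec(
        n_tissues=1,
        samples_per_tissue=200,
        n_genes=len(genes),
        noise_sd_log10=0.3,
        modules=[
            ModuleSpec(genes=genes[m * genes_per_module:(m + 1) * genes_per_module],
                       loading=0.9, factor_sd=1.0)
            for m in range(3)
        ],
        gene_ids=genes,
        seed=seed,
    )
    expr, _, truth = generate(spec)
    return np.log10(expr + 1e-4), truth
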