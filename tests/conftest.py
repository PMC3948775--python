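import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import netdiffcor as nd

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from netdiffcor.simulate import gene_names


@pytest.fixture(scope="session")
def null_dataset():
    """Small two-group dataset with no planted correlation differences."""
    spec = nd.SimulationSpec(n_genes=60, n_edges=120, seed=0)
    net = nd.generate_network(spec)
    cm, truth = nd.generate_counts(net, spec)
    em = nd.normalize_log_cpm(cm)
    trimmed = nd.trim_to_genes(net, set(cm.genes))
    return {"spec": spec, "net": net, "cm": cm, "truth": truth, "em": em, "trimmed": trimmed}


@pytest.fixture(scope="session")
def planted_dataset():
    """Dataset with strong group-specific correlations planted on 10 edges."""
    genes = gene_names(60)
    planted = [((genes[2 * i], genes[2 * i + 1]), -0.9, 0.9) for i in range(10)]
    spec = nd.SimulationSpec(
        n_genes=60, n_edges=120, n_per_group=(20, 20), seed=0, planted_edges=planted
    )
    net = nd.generate_network(spec)
    cm, truth = nd.generate_counts(net, spec)
    em = nd.normalize_log_cpm(cm)
    trimmed = nd.trim_to_genes(net, set(cm.genes))
    return {"spec": spec, "net": net, "cm": cm, "truth": truth, "em": em, "trimmed": trimmed}


def make_count_matrix(values: np.ndarray, groups: list[str], prefix: str = "s") -> nd.CountMatrix:
    """CountMatrix from a raw integer array and per-sample group labels."""
    n_genes, n_samples = values.shape
    samples = [f"{prefix}{i + 1}" for i in range(n_samples)]
    genes = gene_names(n_genes)
    return nd.CountMatrix(
        counts=pd.DataFrame(np.asarray(values, dtype=np.int64), index=genes, columns=samples),
        groups=pd.Series(groups, index=samples, name="group"),
    )
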