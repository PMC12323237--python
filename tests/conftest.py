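import numpy as np
import pytest

from varprox.records import VariantRecord
from varprox.simulate import SimulationParams, simulate_population_variants


def rec(chrom="chr1", pos=100, ref="A", alt="G", ac=None, an=None, af=None,
        filter_status="PASS", **kw) -> VariantRecord:
    if ac is None and af is None:
        ac, an = 5, 1000
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, ac=ac, an=an,
                         af=af, filter_status=filter_status, **kw)


@pytest.fixture(scope="session")
def sim_small():
    """A shared small simulation (30k sites, seed 1) for structural tests."""
    params = SimulationParams(n_sites=30_000, seed=1)
    variants, truth = simulate_population_variants(params)
    return params, variants, truth
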