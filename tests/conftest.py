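import numpy as np
import pytest

from phylotrace import (SimulationConfig, TrackedVariant, VariantCounts,
                        simulate_patient)


def make_variant(variant_id="v1", clone_id="clonal", is_clonal=True, tnc="ACA",
                 ref=None, alt="T", multiplicity=1.0, cn_tumour=2.0,
                 cn_normal=2.0, **kw):
    ref = ref if ref is not None else tnc[1]
    return TrackedVariant(
        variant_id=variant_id, chrom="chr1", pos=kw.pop("pos", 100),
        ref=ref, alt=alt, tnc=tnc, clone_id=clone_id, is_clonal=is_clonal,
        multiplicity=multiplicity, cn_tumour=cn_tumour, cn_normal=cn_normal,
        **kw,
    )


def make_counts(variant_id="v1", dao=0, ddp=1000, sample_id="s1"):
    return VariantCounts(sample_id=sample_id, variant_id=variant_id, dao=dao, ddp=ddp)


@pytest.fixture(scope="session")
def simulated_patient():
    """One deterministic synthetic patient at ~0.9% clonal ctDNA level."""
    cfg = SimulationConfig(seed=11, n_clones=5, n_clonal_mutations=60,
                           n_mutations_per_subclone=6)
    return simulate_patient(11, cfg, clonal_level=0.009)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
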