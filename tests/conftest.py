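import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import spongenet as sp
from spongenet.synthetic import SyntheticConfig, generate_dataset, write_bundle

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic fixture: generator defaults, fixed seed."""
    return generate_dataset(SyntheticConfig(rng_seed=11))


@pytest.fixture(scope="session")
def small_dataset():
    cfg = SyntheticConfig(
        n_samples=80,
        n_mrna=60,
        n_lncrna=20,
        n_mirna=10,
        n_pure_triplets=6,
        n_mixed_triplets=2,
        n_direct_pairs=5,
        n_pure_mediators=2,
        n_mixed_mediators=1,
        utr_len=520,
        lnc_len=700,
        rng_seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_bundle(small_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(small_dataset, outdir)


@pytest.fixture(scope="session")
def default_bundle(default_dataset, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle_default")
    return write_bundle(default_dataset, outdir)


def _pipeline_config(bundle, outdir, **overrides):
    from spongenet.pipeline import PipelineConfig

    kwargs = dict(
        expression=bundle["expression"],
        annotation=bundle["annotation"],
        mirna_fasta=bundle["mirna_fasta"],
        utr_fasta=bundle["utr_fasta"],
        lnc_fasta=bundle["lnc_fasta"],
        metadata=bundle["samples"],
        condition="normal",
        outdir=str(outdir),
    )
    kwargs.update(overrides)
    return PipelineConfig(**kwargs)


@pytest.fixture(scope="session")
def make_pipeline_config():
    return _pipeline_config


@pytest.fixture(scope="session")
def default_run(default_bundle, make_pipeline_config, tmp_path_factory):
    """One full pipeline run on the standard fixture, shared across tests."""
    from spongenet.pipeline import run_pipeline

    outdir = tmp_path_factory.mktemp("run_default")
    cfg = make_pipeline_config(default_bundle, outdir)
    manifest = run_pipeline(cfg)
    return {"outdir": outdir, "manifest": manifest, "config": cfg}


@pytest.fixture()
def tiny_expression():
    data = pd.DataFrame(
        np.arange(12, dtype=float).reshape(3, 4),
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return sp.ExpressionMatrix(data)
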