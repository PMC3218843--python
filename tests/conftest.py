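import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from multisnp.align import align_reads
from multisnp.simulate import TemplateSpec, build_template, inject_variation, sample_pe_reads


@pytest.fixture(scope="session")
def diverged_pipeline():
    """A two-copy, 5%-diverged 3 kb template with 30x PE reads, aligned at k=2.

    Shared across tests that only need a realistic aligned data set.
    """
    spec = TemplateSpec(unit_length=1500, copies=2, inter_copy_divergence=0.05, seed=1)
    genome = build_template(spec)
    sample = inject_variation(genome, 0.002, 0.002, seed=2)
    reads = sample_pe_reads(sample, coverage=30, read_len=36, seed=3)
    alns = align_reads(reads, genome, 2)
    return {"genome": genome, "sample": sample, "reads": reads, "alignments": alns}
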