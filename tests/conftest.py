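import pytest

from sitpipe.cohort_sim import SimConfig, simulate_cohort
from sitpipe.gene_models import run_prioritization
from sitpipe.reference_cohort import (
    reference_candidates,
    reference_individuals,
    reference_variants,
)


@pytest.fixture(scope="session")
def reference_run():
    """Prioritization run on the encoded published cohort table."""
    individuals = reference_individuals()
    variants = reference_variants()
    candidates = reference_candidates()
    calls, summary, evidence = run_prioritization(variants, individuals, candidates)
    return {
        "individuals": individuals,
        "variants": variants,
        "candidates": candidates,
        "calls": calls,
        "summary": summary,
        "evidence": evidence,
    }


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic study (seed 1)."""
    return simulate_cohort(SimConfig(seed=1))
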