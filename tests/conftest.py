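import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cracklekit as ck
from cracklekit.pipeline import analyze_recording, build_cohort

settings.register_profile(
    "suite", derandomize=True, max_examples=30,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def geometry():
    return ck.default_geometry()


@pytest.fixture(scope="session")
def ipf_recording(geometry):
    """One annotated IPF recording (20 s, 3 breaths)."""
    profile = ck.builtin_profile("IPF")
    signal, annotation = ck.synthesize_recording(profile, geometry, seed=1)
    return signal, annotation


@pytest.fixture(scope="session")
def ipf_analysis(geometry, ipf_recording):
    signal, annotation = ipf_recording
    return analyze_recording(signal, 8000, geometry,
                             breath_boundaries=annotation.breath_boundaries())


@pytest.fixture(scope="session")
def small_cohort(geometry):
    """Analyzed 18-patient cohort (6 per group), shared across tests."""
    groups = {name: (ck.builtin_profile(name), 6) for name in ("IPF", "CHF", "PN")}
    return build_cohort(groups, geometry, seed=20260901)
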