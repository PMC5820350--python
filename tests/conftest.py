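"""Shared fixtures: one synthetic reference/catalog and a moderate-depth
read set reused across the sequencing-pipeline tests."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from escapewatch import synth

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def reference():
    return synth.make_reference(seed=7)


@pytest.fixture(scope="session")
def catalog():
    return synth.make_catalog(seed=11)


@pytest.fixture(scope="session")
def spectrum(reference, catalog):
    return synth.default_spectrum(reference, catalog)


#: molecule frequencies used for the shared read set
PLANTED = {
    "IS10@1200": 0.10,
    "IS186@2500": 0.03,
    "IS5@900": 0.01,
}


@pytest.fixture(scope="session")
def planted_truth(spectrum):
    labels = [m.label for m in spectrum.modes]
    snp_label = next(l for l in labels if l.startswith("SNP"))
    truth = {snp_label: 0.01, **PLANTED}
    truth["intact"] = 1.0 - sum(truth.values())
    return truth


@pytest.fixture(scope="session")
def readset(reference, catalog, spectrum, planted_truth):
    reads, ledger = synth.simulate_reads(
        reference, planted_truth, catalog, spectrum, depth=1500, seed=5
    )
    return reads, ledger


@pytest.fixture(scope="session")
def scanned(readset, reference, catalog):
    """Full scan of the shared read set, computed once."""
    from escapewatch.isscan.scan import scan_insertions

    reads, _ = readset
    freqs, events, unassigned = scan_insertions(reads, reference, catalog, min_support=3)
    return freqs, events, unassigned
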