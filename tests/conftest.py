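"""Shared fixtures: all test inputs are generated programmatically."""

from __future__ import annotations

import pytest

from shiftforge.fixtures import (
    FixtureSpec,
    build_shifts,
    build_structure,
    default_corpus_specs,
    write_pdb,
)
from shiftforge.pipeline import PipelineInput, build_dataset


@pytest.fixture(scope="session")
def helix_spec() -> FixtureSpec:
    return FixtureSpec(pdb_id="HLX1", sequence="AAFAAGAAAAAG", seed=7)


@pytest.fixture(scope="session")
def helix_structure(helix_spec):
    return build_structure(helix_spec)


@pytest.fixture(scope="session")
def helix_pdb_text(helix_structure):
    return write_pdb(helix_structure)


@pytest.fixture(scope="session")
def helix_star_text(helix_structure, helix_spec):
    text, _ = build_shifts(helix_structure, helix_spec)
    return text


@pytest.fixture(scope="session")
def helix_truth(helix_structure, helix_spec):
    _, truth = build_shifts(helix_structure, helix_spec)
    return truth


@pytest.fixture(scope="session")
def small_corpus_inputs():
    """Six toy proteins, enough for fast non-acceptance pipeline tests."""
    specs = default_corpus_specs(6, 12, noise_sigma=0.0, seed=11)
    inputs = []
    for s in specs:
        st = build_structure(s)
        star, _ = build_shifts(st, s)
        inputs.append(PipelineInput(s.pdb_id, s.bmrb_id, write_pdb(st), star))
    return inputs


@pytest.fixture(scope="session")
def small_dataset(small_corpus_inputs):
    dataset, mapping_records, report = build_dataset(
        small_corpus_inputs, homology_cutoff=None)
    assert not report.rejected, report.rejected
    return dataset, mapping_records, report
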