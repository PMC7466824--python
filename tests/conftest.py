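"""Shared fixtures and instance factories for the test suite."""

from __future__ import annotations

import pytest

from sem1r import build_toy_fixture, planted_rule_dataset, random_ontology
from sem1r.synthetic import GenerationError


@pytest.fixture(scope="session")
def toy():
    """The seven-term, three-example toy world."""
    return build_toy_fixture()


def make_instances(
    n,
    n_terms=12,
    max_parents=2,
    n_rows=8,
    n_cols=5,
    rule_length=2,
    noise_rate=0.1,
    base_seed=0,
    **kwargs,
):
    """Yield ``n`` planted instances, advancing the seed past the rare
    parameter draws for which no usable conjunction exists."""
    made = 0
    seed = base_seed
    while made < n:
        ontology = random_ontology(n_terms, max_parents, seed=seed)
        try:
            instance = planted_rule_dataset(
                ontology,
                n_rows,
                n_cols,
                rule_length=rule_length,
                noise_rate=noise_rate,
                seed=seed + 10_000,
                **kwargs,
            )
        except GenerationError:
            seed += 1
            continue
        seed += 1
        made += 1
        yield instance
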