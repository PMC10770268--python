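"""Shared fixtures: intervention specs, model bundles, rule sets.

Everything is generated programmatically; bundles are session-scoped since
the model builders are deterministic and the engines never mutate models.
"""

import pytest

from surgflow.fixtures import (
    InterventionSpec,
    PhaseSpec,
    StepSpec,
    build_models,
    build_rules,
    ci_spec,
    ramie_spec,
)


@pytest.fixture(scope="session")
def ci():
    return ci_spec()


@pytest.fixture(scope="session")
def ramie():
    return ramie_spec()


@pytest.fixture(scope="session")
def ci_bundle(ci):
    return build_models(ci)


@pytest.fixture(scope="session")
def ramie_bundle(ramie):
    return build_models(ramie)


@pytest.fixture(scope="session")
def ci_rules(ci):
    return build_rules(ci, seed=1)


@pytest.fixture(scope="session")
def ramie_rules(ramie):
    return build_rules(ramie, seed=1)


def variable_block_spec(k: int, m: int, post: bool = False,
                        name: str = "frag") -> InterventionSpec:
    """One phase with k required + m optional steps in variable order,
    optionally followed by a required step."""
    steps = [StepSpec(f"req_{i}", variable_group="g") for i in range(k)]
    steps += [StepSpec(f"opt_{i}", optional=True, variable_group="g")
              for i in range(m)]
    if post:
        steps.append(StepSpec("post_step"))
    spec = InterventionSpec(
        name=name, phases=(PhaseSpec("phase", tuple(steps)),),
        label_based=True, instruments=("a", "b"))
    spec.validate()
    return spec


def exclusive_spec(branch_lens=(1, 1), post: bool = True,
                   name: str = "excl") -> InterventionSpec:
    """One phase with an exclusive choice of paths, then a required step."""
    steps = []
    for b, n in enumerate(branch_lens):
        for i in range(n):
            steps.append(StepSpec(f"path{b}_{i}", exclusive_group="x", branch=b))
    if post:
        steps.append(StepSpec("post_step"))
    spec = InterventionSpec(
        name=name, phases=(PhaseSpec("phase", tuple(steps)),),
        label_based=True, instruments=("a", "b"))
    spec.validate()
    return spec


def chain_spec(n: int, name: str = "chain") -> InterventionSpec:
    spec = InterventionSpec(
        name=name,
        phases=(PhaseSpec("phase", tuple(StepSpec(f"t{i}") for i in range(n))),),
        label_based=True, instruments=("a", "b"))
    spec.validate()
    return spec
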