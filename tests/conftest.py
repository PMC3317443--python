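import random

import pytest

from partforge import (
    AnnotatedSequence,
    Feature,
    FixtureSpec,
    add_rule,
    generate_design,
    prdr_like_design,
)


@pytest.fixture
def prdr_design():
    """The [1,2,2,1,2,1] tagged-GFP library, no rules attached."""
    return prdr_like_design(seed=11)


@pytest.fixture
def prdr_with_rule():
    return prdr_like_design(seed=11, with_rule=True)


@pytest.fixture
def circular_source():
    rng = random.Random(7)
    residues = "".join(rng.choice("ACGT") for _ in range(100))
    return AnnotatedSequence(
        "circle100",
        residues,
        circular=True,
        features=[
            Feature("early", "misc_feature", 5, 20, 1),
            Feature("late", "cds", 60, 85, -1),
            Feature("wrapper", "misc_feature", 95, 4, 1),
        ],
    )


def random_valid_design(rng: random.Random, max_bins: int = 4, max_parts: int = 3):
    """A random small design that validates, for property tests."""
    sizes = tuple(rng.randint(1, max_parts) for _ in range(rng.randint(1, max_bins)))
    return generate_design(
        FixtureSpec(
            bin_sizes=sizes,
            part_length_range=(12, 30),
            seed=rng.randrange(2**31),
            topology=rng.choice(("circular", "linear")),
        )
    )


def attach_random_rules(design, rng: random.Random, n_rules: int):
    names = sorted(design.part_names())
    made = 0
    for k in range(n_rules * 3):
        if made >= n_rules:
            break
        op = rng.choice(["WITH", "NOTWITH", "NOTMORETHAN"])
        o1 = rng.choice(names)
        o2 = rng.randint(1, 2) if op == "NOTMORETHAN" else rng.choice(names)
        try:
            add_rule(design, f"r{k}", op, o1, o2)
        except Exception:
            continue
        made += 1
    return design
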