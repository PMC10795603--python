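import numpy as np
import pandas as pd
import pytest

from vaconcord import Cause, CauseList, Cohort

TOY_CONFUSION = {
    # reference cause -> counts of coder assignments (A, B, C)
    "A": (8, 1, 1),
    "B": (2, 6, 2),
    "C": (0, 2, 8),
}


@pytest.fixture(scope="session")
def toy_cause_list() -> CauseList:
    return CauseList(
        "toy",
        (
            Cause("A", "Cause A"),
            Cause("B", "Cause B"),
            Cause("C", "Cause C"),
            Cause("undet", "Undetermined", is_undetermined=True),
        ),
    )


def make_cohort(pairs, cause_list, coder="algo", extra_cols=None) -> Cohort:
    """Cohort from explicit (ref, coder) cause pairs; demographics arbitrary."""
    n = len(pairs)
    frame = pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "age_value": [30.0] * n,
            "age_unit": ["years"] * n,
            "sex": ["female" if i % 2 else "male" for i in range(n)],
            "place": ["in_facility" if i % 3 else "out_of_facility" for i in range(n)],
            "ref_cause": [p[0] for p in pairs],
            f"{coder}_cause": [p[1] for p in pairs],
        }
    )
    if extra_cols:
        for k, v in extra_cols.items():
            frame[k] = v
    return Cohort(frame, cause_list, [coder])


@pytest.fixture(scope="session")
def toy_pairs() -> list[tuple[str, str]]:
    pairs = []
    for ref, row in TOY_CONFUSION.items():
        for coder_cause, count in zip("ABC", row):
            pairs.extend([(ref, coder_cause)] * count)
    return pairs


@pytest.fixture(scope="session")
def toy_cohort(toy_pairs, toy_cause_list) -> Cohort:
    """The 30-death worked example: rows A:[8,1,1], B:[2,6,2], C:[0,2,8]."""
    return make_cohort(toy_pairs, toy_cause_list)


def random_pairs(rng: np.random.Generator, causes, n=None):
    """Random (ref, coder) pairs with non-uniform marginals."""
    n = n or int(rng.integers(5, 40))
    k = len(causes)
    ref_p = rng.dirichlet(np.ones(k))
    refs = rng.choice(causes, size=n, p=ref_p)
    coders = np.where(
        rng.random(n) < 0.4, refs, rng.choice(causes, size=n)
    )
    return list(zip(refs.tolist(), coders.tolist()))
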