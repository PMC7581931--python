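from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from habscore import (
    CommunityProfile,
    LabeledReference,
    ReferenceDatabase,
    SearchParams,
)

BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in BASES if b != ch]))
        else:
            out.append(ch)
    return "".join(out)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_db(rng) -> ReferenceDatabase:
    """Six references in three categories, two projects each, 300 bp."""
    refs = []
    for c, cat in enumerate(["soil", "marine", "freshwater"]):
        for i in range(2):
            refs.append(
                LabeledReference(
                    sequence_id=f"{cat}_{i}",
                    sequence=random_seq(rng, 300),
                    category=cat,
                    project_id=f"proj_{cat}_{i % 2}",
                )
            )
    return ReferenceDatabase(refs)


@pytest.fixture
def permissive_params() -> SearchParams:
    """Thresholds low enough that any positive-score alignment is reported."""
    return SearchParams(min_aligned_length=8, min_percent_identity=1e-6,
                        kmer_size=8)


@pytest.fixture
def toy_profile() -> CommunityProfile:
    counts = pd.DataFrame(
        {"s1": [60, 40], "s2": [10, 0]}, index=["f1", "f2"]
    )
    seqs = {"f1": "ACGT" * 50, "f2": "TTGCA" * 40}
    return CommunityProfile(counts, seqs)
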