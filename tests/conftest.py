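import numpy as np
import pandas as pd
import pytest

from oralgut import (
    CohortSpec, FeatureTable, SampleMetadata, TaxonomyTable, generate_cohort,
)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(n_children=5, n_adults=9, n_gut_pool=70, n_oral_pool=50,
                      n_shared=12, oral_dominant_fraction=0.5,
                      age_exclusive_fractions=(0.25, 0.25, 0.5),
                      read_depth=20_000, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    """A small sequenced cohort: (counts table, metadata, taxonomy, truth)."""
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def exact_cohort(small_spec):
    """The same cohort with sequencing disabled (expected percent compositions)."""
    import dataclasses
    spec = dataclasses.replace(small_spec, read_depth=None)
    return generate_cohort(spec)


@pytest.fixture()
def toy_table() -> FeatureTable:
    values = np.array([
        [5, 0, 2, 0],
        [1, 2, 0, 0],
        [0, 7, 0, 3],
        [4, 4, 4, 4],
    ])
    return FeatureTable([f"asv{i}" for i in range(1, 5)],
                        ["p1.gut", "p1.oral", "p2.gut", "p2.oral"], values)


@pytest.fixture()
def toy_metadata() -> SampleMetadata:
    df = pd.DataFrame({
        "individual_id": ["p1", "p1", "p2", "p2"],
        "habitat": ["gut", "oral", "gut", "oral"],
        "age_years": [8.0, 8.0, 35.0, 35.0],
        "sex": ["female", "female", "male", "male"],
    }, index=pd.Index(["p1.gut", "p1.oral", "p2.gut", "p2.oral"], name="sample_id"))
    return SampleMetadata(df)


def brute_force_within_individual(presence: pd.DataFrame,
                                  metadata: SampleMetadata) -> dict[str, set[str]]:
    """Exhaustive double loop over individuals x features (test oracle)."""
    out: dict[str, set[str]] = {}
    frame = metadata.frame
    for ind in frame["individual_id"].unique():
        sub = frame[frame["individual_id"] == ind]
        habs = dict(zip(sub["habitat"], sub.index))
        if set(habs) != {"oral", "gut"}:
            continue
        for fid in presence.index:
            if presence.loc[fid, habs["oral"]] and presence.loc[fid, habs["gut"]]:
                out.setdefault(fid, set()).add(ind)
    return out
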