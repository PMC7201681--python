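import numpy as np
import pandas as pd
import pytest

from fsvax import (
    IntensityDataset,
    TranscriptModel,
    minimal_profile,
    run_study,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def simple_transcript():
    # ATG AAA AAA AGC GAT TAA : M K K S D *  with a 7-A homopolymer
    return TranscriptModel("t1", "ATGAAAAAAAGCGATTAA", "GCTGCTGCTGCT")


def random_cds(rng, n_codons):
    """Random CDS with no internal in-frame stop: ATG + sense codons + stop."""
    import itertools

    stops = {"TAA", "TAG", "TGA"}
    sense = [c for c in ("".join(t) for t in itertools.product("ACGT", repeat=3))
             if c not in stops]
    body = rng.choice(sense, size=n_codons - 2)
    return "ATG" + "".join(body) + "TAA"


@pytest.fixture(scope="session")
def small_study():
    """One deterministic end-to-end run of the small demo profile."""
    return run_study(minimal_profile(7))


def make_dataset(values, groups, slides, cohorts=None, subjects=None):
    """Build an IntensityDataset from a plain array + metadata lists."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    sample_ids = [f"s{i}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "group": groups,
            "slide_id": slides,
            "cohort_id": cohorts or ["c1"] * n,
            "subject_id": subjects or sample_ids,
            "timepoint": ["T0" if g == "naive" else "T7" for g in groups],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    mat = pd.DataFrame(values, index=meta.index, columns=[f"p{j}" for j in range(p)])
    return IntensityDataset(mat, meta)
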