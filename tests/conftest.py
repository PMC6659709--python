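import numpy as np
import pandas as pd
import pytest

from mtpopgen.core import (
    MISSING,
    GenotypeMatrix,
    SampleTable,
    VariantRecord,
)


def make_gm(calls, positions=None, refs=None, alts=None, samples=None,
            reference_length=None, chrom="mt"):
    """Small-matrix builder used throughout the suite."""
    calls = np.asarray(calls, dtype=np.int16)
    nv, ns = calls.shape
    if positions is None:
        positions = list(range(10, 10 + 10 * nv, 10))
    if refs is None:
        refs = ["A"] * nv
    if alts is None:
        alts = [("G",)] * nv
    if samples is None:
        samples = [f"s{j}" for j in range(ns)]
    if reference_length is None:
        reference_length = max(positions) + 100
    variants = [
        VariantRecord(chrom, p, r, tuple(a))
        for p, r, a in zip(positions, refs, alts)
    ]
    return GenotypeMatrix(variants, samples, calls, reference_length)


def make_table(assignments):
    """SampleTable from {accession: subgroup}."""
    df = pd.DataFrame(
        {"accession": list(assignments), "subgroup": list(assignments.values())}
    )
    return SampleTable(df)


@pytest.fixture
def toy_gm():
    # 4 variants x 6 samples: 2 indica, 2 temperate_japonica, 2 wild
    calls = np.array(
        [
            [1, 1, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0],
            [1, 1, 1, 1, 0, 1],
            [0, 1, 0, MISSING, 1, 0],
        ],
        dtype=np.int16,
    )
    return make_gm(calls, positions=[100, 200, 300, 400])


@pytest.fixture
def toy_table():
    return make_table(
        {
            "s0": "indica",
            "s1": "indica",
            "s2": "temperate_japonica",
            "s3": "temperate_japonica",
            "s4": "wild_rufipogon",
            "s5": "wild_nivara",
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
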