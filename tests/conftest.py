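import numpy as np
import pytest

from enteroguild.types import CountTable


@pytest.fixture(scope="session")
def toy_count_table():
    """12-feature x 8-sample table with hand-enumerated filter outcomes.

    Expected behaviour of the QC chain (thresholds: presence < 2 AND
    fraction < 1e-6; depth < 10,000; prevalence > 0.20):

    * f02 (1 read in 1 sample, ~8e-8 of ~12.1M total) and f12 (all zero)
      are removed by the feature filter; f03 (1 sample but 100,000 reads)
      and f05 (2 samples, 1 read each) survive it.
    * s8 (9,999 reads) is removed by the depth filter; s7 (exactly
      10,000) is kept.
    * On the 7 remaining samples, f03, f06 and f10 are present in only
      one sample (1/7 <= 0.2) and fall to the prevalence filter.
    * Final survivors: f01, f04, f05, f07, f08, f09, f11 x s1..s7.
    """
    features = [f"f{i:02d}" for i in range(1, 13)]
    samples = [f"s{j}" for j in range(1, 9)]
    counts = np.zeros((12, 8), dtype=np.int64)
    counts[0] = [2_000_000] * 6 + [9_998, 9_997]  # f01 everywhere
    counts[1, 0] = 1  # f02: 1 read, 1 sample
    counts[2, 1] = 100_000  # f03: 1 sample, abundant
    counts[3] = 1  # f04: 1 read in all 8 samples
    counts[4, 0] = 1  # f05: 2 samples, 1 read each
    counts[4, 1] = 1
    counts[5, 2] = 500  # f06: 1 sample
    counts[6, 2] = 300  # f07: 2 samples
    counts[6, 3] = 400
    counts[7, :6] = 10  # f08: 6 samples
    counts[8, 4] = 2000  # f09: 2 samples
    counts[8, 5] = 2000
    counts[9, 6] = 1  # f10: s7 + s8 only
    counts[9, 7] = 1
    counts[10, :3] = 50  # f11: 3 samples
    # f12: all zeros
    return CountTable(
        counts=counts,
        feature_ids=features,
        sample_ids=samples,
        taxonomy={f: f.replace("f", "Genus") for f in features},
    )


TOY_AFTER_FEATURE_FILTER = [
    "f01", "f03", "f04", "f05", "f06", "f07", "f08", "f09", "f10", "f11",
]
TOY_AFTER_SAMPLE_FILTER = ["s1", "s2", "s3", "s4", "s5", "s6", "s7"]
TOY_AFTER_PREVALENCE = ["f01", "f04", "f05", "f07", "f08", "f09", "f11"]


@pytest.fixture(scope="session")
def small_guild_truth():
    from enteroguild.synthetic import simulate_guilds

    return simulate_guilds(30, 4, driver_weight=0.5, sparsity=0.5, seed=11)


@pytest.fixture(scope="session")
def exact_rank3():
    """A 12x9 matrix that is exactly rank 3 with nonnegative factors."""
    rng = np.random.default_rng(5)
    W0 = rng.random((12, 3))
    H0 = rng.dirichlet(np.ones(3), size=9).T
    W0 /= W0.sum(axis=0)
    return W0, H0, W0 @ H0
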