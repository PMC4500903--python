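import numpy as np
import pytest

from dynconn import (
    BlockCohortSpec,
    demo_sinusoid_pair,
    generate_cohort,
    sliding_window_correlation,
    summarize_edges,
)


@pytest.fixture(scope="session")
def figure_pair():
    """The worked-example anti-phase sinusoid pair (S1 high/steady,
    S2 low/fluctuating), 240 samples, period 60."""
    return demo_sinusoid_pair(n_samples=240, period=60.0)


@pytest.fixture(scope="session")
def designed_cohort():
    """The designed-effect cohort: 20 subjects, 40 nodes in 4 blocks,
    T=240 at TR=2 s, constant within coupling 0.8, global coupling
    0.3 + 0.2 sin(2*pi*t/200), bandpassed latents, fixed seed."""
    return generate_cohort(BlockCohortSpec(seed=20150714))


@pytest.fixture(scope="session")
def designed_summaries(designed_cohort):
    """Per-subject edge summaries of the designed cohort at w=45,
    Spearman (the primary analysis conditions)."""
    return [
        summarize_edges(sliding_window_correlation(s, 45, "spearman"))
        for s in designed_cohort.subjects
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for unit tests: 4 subjects, 12 nodes, 3 blocks."""
    labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    return generate_cohort(
        BlockCohortSpec(n_subjects=4, n_nodes=12, block_labels=labels,
                        n_timepoints=120, seed=11)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
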