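"""Shared fixtures: the expensive closed-loop simulation matrices are run
once per session and reused by the experiment-level and acceptance tests."""

import pytest

from wormgait.experiments import perturbation_matrix
from wormgait.neural import CPGParams


@pytest.fixture(scope="session")
def proprio_matrix():
    """Wild type + all perturbations, both environments, proprioceptive."""
    return perturbation_matrix("proprioceptive", ("none", "1", "2", "1+2", "3"))


@pytest.fixture(scope="session")
def cpg_matrix():
    """Wild type + muscle perturbations under imposed-frequency CPG drive."""
    return perturbation_matrix(
        "cpg", ("none", "1", "2", "1+2"), cpg=CPGParams(T_f=1.0), duration=12.0
    )
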