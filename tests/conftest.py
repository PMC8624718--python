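import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from ssetopo.model import Direction, GroundTruth, Match, Topology


@pytest.fixture
def worked_topology() -> Topology:
    """The top-ranked topology of an α+β chain whose β-sheet was detected
    well: five helix matches and three strand matches, one helix trace
    aligned in reverse."""
    F, R = Direction.FORWARD, Direction.REVERSE
    return Topology(
        (
            Match("S0", "L5", F),
            Match("S1", "L0", R),
            Match("S3", "L1", F),
            Match("S4", "L6", F),
            Match("S5", "L2", F),
            Match("S6", "L3", F),
            Match("S7", "L7", F),
            Match("S8", "L4", F),
        )
    )


@pytest.fixture
def truth_primary() -> GroundTruth:
    """Correspondence derived from the primary atomic structure: S5/L2
    (a turn mis-read as a short helix by both predictors) and S7/L7 (a long
    loop traced as a strand) are not correct secondary structures."""
    F, R = Direction.FORWARD, Direction.REVERSE
    pairs = {
        "S0": ("L5", F),
        "S1": ("L0", R),
        "S3": ("L1", F),
        "S4": ("L6", F),
        "S6": ("L3", F),
        "S8": ("L4", F),
    }
    return GroundTruth(
        pairs,
        frozenset(pairs),
        frozenset(t for t, _ in pairs.values()),
    )


@pytest.fixture
def truth_alternate(truth_primary) -> GroundTruth:
    """An alternative structure of the same sequence annotates the L7
    region as a strand, adding S7↔L7 to the correct pairs."""
    pairs = dict(truth_primary.pairs)
    pairs["S7"] = ("L7", Direction.FORWARD)
    return GroundTruth(
        pairs,
        frozenset(pairs),
        frozenset(t for t, _ in pairs.values()),
    )
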