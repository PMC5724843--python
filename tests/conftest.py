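import pytest

from warskew import GroupConfig, ParticipationParams


@pytest.fixture
def equal_cfg() -> GroupConfig:
    """One of two identical mid-sized groups."""
    return GroupConfig(n_males=20, total_resource=100.0, total_strength=100.0,
                       beta=0.1, sigma=0.1)


@pytest.fixture
def duel_scenario() -> tuple[GroupConfig, GroupConfig]:
    """One male per group; the attacker is twice as strong.

    With n_kill = 1 the attacker's payoff doubles (dx = +1) and the defender
    is killed (dx = -1), so at k = 10 both join their own side with
    probability ~1 and the viability index is ~= 2 - 1 = 1.
    """
    cfg1 = GroupConfig(1, 10.0, 2.0, 0.3, 0.3)
    cfg2 = GroupConfig(1, 10.0, 1.0, 0.3, 0.3)
    return cfg1, cfg2


@pytest.fixture
def default_params() -> ParticipationParams:
    return ParticipationParams()
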