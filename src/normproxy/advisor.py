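"""Decision engine mapping study characteristics to a recommended
norm-proxy construction strategy.

The mapping codifies the decision flow common to the five case studies:
if the survey measured others' expectations directly, cluster those norm
expectations at the PSU level; otherwise a proxy must be developed —
cluster the behaviour when the practice is visible to others, or fall
back on the attitude-behaviour discordance when it is hidden.  The
health concern then selects the hypothesis test.  Profiles outside the
five documented study paths receive the nearest branch, with the
rationale marked as extrapolated.
"""

from __future__ import annotations

import dataclasses
from enum import Enum


class Concern(str, Enum):
    AVOIDS_POSITIVE_ACTION_FEARING_SANCTION = "avoids_positive_action_fearing_sanction"
    DOES_NEGATIVE_ACTION_FEARING_SANCTION = "does_negative_action_fearing_sanction"
    SANCTIONED_FOR_NONCONFORMITY = "sanctioned_for_nonconformity"
    DOES_HARMFUL_ACTION_FOR_APPROVAL = "does_harmful_action_for_approval"


class Proxy(str, Enum):
    CLUSTER_NORM_EXPECTATIONS = "cluster_norm_expectations"
    CLUSTER_ATTITUDES = "cluster_attitudes"
    CLUSTER_BEHAVIOURS = "cluster_behaviours"
    BEHAVIOUR_ATTITUDE_DISCORDANCE = "behaviour_attitude_discordance"


class NormTest(str, Enum):
    NORMATIVE_CLUSTER_VS_POSITIVE_PRACTICE = "normative_cluster_vs_positive_practice"
    NORMATIVE_CLUSTER_VS_NEGATIVE_PRACTICE = "normative_cluster_vs_negative_practice"
    NONCONFORMITY_VS_OUTCOME = "nonconformity_vs_outcome"
    NORMATIVE_CLUSTER_VS_OUTCOME = "normative_cluster_vs_outcome"


@dataclasses.dataclass(frozen=True)
class StudyProfile:
    norm_data_collected: bool   # survey asked what others expect
    practice_visible: bool      # behaviour detectable by others
    concern: Concern


@dataclasses.dataclass(frozen=True)
class Strategy:
    proxy: Proxy
    test: NormTest
    rationale: str


_TEST_BY_CONCERN = {
    Concern.AVOIDS_POSITIVE_ACTION_FEARING_SANCTION:
        NormTest.NORMATIVE_CLUSTER_VS_POSITIVE_PRACTICE,
    Concern.DOES_NEGATIVE_ACTION_FEARING_SANCTION:
        NormTest.NORMATIVE_CLUSTER_VS_NEGATIVE_PRACTICE,
    Concern.SANCTIONED_FOR_NONCONFORMITY:
        NormTest.NONCONFORMITY_VS_OUTCOME,
    Concern.DOES_HARMFUL_ACTION_FOR_APPROVAL:
        NormTest.NORMATIVE_CLUSTER_VS_OUTCOME,
}

# The five documented study paths (norm_data, visible, concern); visible is
# irrelevant when norm data exist, so those paths match either value.
_DOCUMENTED = {
    (False, True, Concern.AVOIDS_POSITIVE_ACTION_FEARING_SANCTION),
    (True, True, Concern.DOES_NEGATIVE_ACTION_FEARING_SANCTION),
    (True, False, Concern.DOES_NEGATIVE_ACTION_FEARING_SANCTION),
    (False, False, Concern.AVOIDS_POSITIVE_ACTION_FEARING_SANCTION),
    (False, True, Concern.SANCTIONED_FOR_NONCONFORMITY),
    (True, True, Concern.DOES_HARMFUL_ACTION_FOR_APPROVAL),
    (True, False, Concern.DOES_HARMFUL_ACTION_FOR_APPROVAL),
}


def suggest_strategy(profile: StudyProfile) -> Strategy:
    """Deterministic total mapping over the 2 x 2 x 4 profile space."""
    concern = Concern(profile.concern)
    test = _TEST_BY_CONCERN[concern]
    if profile.norm_data_collected:
        proxy = Proxy.CLUSTER_NORM_EXPECTATIONS
        why = ("Norm expectations were measured directly; cluster them at "
               "the PSU level as the norms proxy.")
    elif profile.practice_visible:
        proxy = Proxy.CLUSTER_BEHAVIOURS
        why = ("No direct norms data; the practice is visible to others, so "
               "cluster the behaviour itself at the PSU level. (Visible "
               "practices can alternatively support clustered attitudes; "
               "clustered behaviour is preferred because the behaviour's "
               "distribution is what sanctioning actors observe.)")
    else:
        proxy = Proxy.BEHAVIOUR_ATTITUDE_DISCORDANCE
        why = ("No direct norms data and the practice is largely "
               "undetectable; use the gap between clustered behaviours and "
               "stated attitudes (taboo-gap discordance) as the proxy.")
    key = (profile.norm_data_collected, profile.practice_visible, concern)
    if key not in _DOCUMENTED:
        why += " [extrapolated from the documented decision paths]"
    return Strategy(proxy, test, why)


def all_profiles() -> list[StudyProfile]:
    """The full 16-cell profile space (exhaustiveness helper)."""
    return [StudyProfile(nd, vis, c)
            for nd in (False, True)
            for vis in (False, True)
            for c in Concern]
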