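import numpy as np
import pandas as pd
import pytest

import semforage as sf


def make_spoken_log(meanings, irts, participant="p0", cue="c0",
                    words=None, first_onset=1.0):
    """Build a spoken-mode log whose scored IRTs equal ``irts[1:]``.

    ``irts[0]`` is ignored (the first response of a cue has no IRT in spoken
    mode); pass None entries to mean "unused".
    """
    rows = []
    t = first_onset
    for k, m in enumerate(meanings):
        if k > 0:
            t = rows[-1]["offset"] + irts[k]
        rows.append(dict(participant=participant, cue=cue, response_index=k + 1,
                         word=words[k] if words else f"w{k}",
                         onset=t, offset=t + 0.4, meaning=m))
    return pd.DataFrame(rows)


def make_typed_log(meanings, irts, participant="p0", cue="c0", words=None,
                   n_chars=3, typing_time=1.0):
    """Typed-mode log whose raw IRTs equal ``irts`` exactly.

    Short words (n_chars <= 4) make the thinking-time correction vanish, so
    the scored IRT equals the raw inter-response delay.
    """
    rows = []
    t = 0.0
    for k, m in enumerate(meanings):
        fk = t + irts[k]
        val = fk + typing_time
        rows.append(dict(participant=participant, cue=cue, response_index=k + 1,
                         word=words[k] if words else f"w{k}",
                         first_keypress=fk, validation=val, n_chars=n_chars,
                         meaning=m))
        t = val
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def tiny_space():
    return sf.generate_semantic_space(n_cues=2, n_meanings=4,
                                      words_per_meaning=8, dim=20,
                                      within_sd=0.2, seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest default-policy cohort shared across read-only tests."""
    cfg = sf.CohortConfig(n_participants=24, n_nodes=16, n_planted=4)
    return sf.generate_cohort(cfg, seed=7)


@pytest.fixture(scope="session")
def small_scored(small_cohort):
    return sf.score(small_cohort.logs, embeddings=small_cohort.space)
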