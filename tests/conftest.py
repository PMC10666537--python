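"""Shared fixtures: one synthetic study world trained once per session.

The heavy fixture trains the default classifier family on four synthetic
endpoints at study scale (2000 training chemicals, 10% actives, 10 planted
toxicophore bits) and holds out 300 further compounds from the same
chemical universe for end-to-end voting validation.
"""

import pytest

from toxfinger.study import StudyResult, run_study

STUDY_SEED = 101


@pytest.fixture(scope="session")
def study_world() -> StudyResult:
    return run_study(seed=STUDY_SEED)
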