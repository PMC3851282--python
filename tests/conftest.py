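import pytest

from taxodebug import SessionState, anatomy_fixture
from taxodebug.session import register_new_candidates


@pytest.fixture
def colon():
    return anatomy_fixture("colon")


@pytest.fixture
def white_matter():
    return anatomy_fixture("white_matter")


@pytest.fixture
def laryngeal():
    return anatomy_fixture("laryngeal")


@pytest.fixture
def bone():
    return anatomy_fixture("bone")


@pytest.fixture
def colon_session(colon):
    net, facts = colon
    session = SessionState(net)
    register_new_candidates(session)
    return session, facts


@pytest.fixture
def white_matter_wrong_session(white_matter):
    """White-matter session with all three candidates validated wrong."""
    from taxodebug import Verdict, record_verdicts

    net, facts = white_matter
    session = SessionState(net)
    new = register_new_candidates(session)
    record_verdicts(session, [Verdict(defect=d, decision="wrong")
                              for d in new])
    return session, facts
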