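import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from textscm.corpus_io import (ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_UNLABELLED,
                               TextRecord, TrainingPartition)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def rec(rid, tokens, role=ROLE_UNLABELLED, **kw):
    """Shorthand record constructor used across the suite."""
    tokens = frozenset(tokens.split() if isinstance(tokens, str) else tokens)
    return TextRecord(record_id=rid, raw_text=" ".join(sorted(tokens)),
                      tokens=tokens, role=role, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def tiny_partition():
    """3 positives sharing 'angiogram', 2 clean negatives, 2 unlabelled."""
    P = tuple(rec(f"p{i}", f"angiogram extra{i}", ROLE_POSITIVE)
              for i in range(3))
    N = (rec("n0", "asthma review", ROLE_NEGATIVE),
         rec("n1", "blood pressure", ROLE_NEGATIVE))
    U = (rec("u0", "angiogram letter", ROLE_UNLABELLED),
         rec("u1", "knee pain", ROLE_UNLABELLED))
    return TrainingPartition(P=P, U=U, N=N)
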