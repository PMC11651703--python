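import numpy as np
import pandas as pd
import pytest

from socialrisk import build_session, make_menu_set, session_to_frame


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def menus():
    return make_menu_set()


@pytest.fixture()
def session_frame(menus):
    session = build_session(menus, "subj0", np.random.default_rng(7))
    return session_to_frame(session)


@pytest.fixture()
def toy_frame():
    """Five handmade trials covering every trial type."""
    rows = [
        # subject_id, idx, menu, p, vhs, vls, vhr, vlr, type, delta
        ("toy", 0, 0, 0.6, 2.00, 1.60, 3.85, 0.10, "solo", 0),
        ("toy", 1, 0, 0.4, 2.00, 1.60, 3.85, 0.10, "info_safe", 1),
        ("toy", 2, 1, 0.9, 2.50, 2.00, 4.8125, 0.125, "info_risky", -1),
        ("toy", 3, 1, 0.5, 2.50, 2.00, 4.8125, 0.125, "info_mix", 0),
        ("toy", 4, 0, 0.7, 2.00, 1.60, 3.85, 0.10, "solo", 0),
    ]
    cols = ["subject_id", "trial_index", "menu_id", "p_high", "v_high_safe",
            "v_low_safe", "v_high_risky", "v_low_risky", "trial_type", "delta"]
    return pd.DataFrame(rows, columns=cols)
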