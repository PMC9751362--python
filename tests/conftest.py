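"""Shared fixtures: hand-built record fixtures, calibration configs, and the
independent direct-likelihood oracle for the Gamma/inverse GLM."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from touchdid import SimulationConfig, default_lexicon


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_records(rows):
    """Build a stream DataFrame from (minute_offset, content_key, has_url,
    attitude, target_word) tuples; timestamps on 2020-04-01/02."""
    base = pd.Timestamp("2020-04-01 08:00")
    recs = []
    for minute, key, url, attitude, word in rows:
        recs.append(
            {
                "timestamp": base + pd.Timedelta(minutes=minute),
                "content_key": key,
                "has_url": bool(url),
                "has_marker": True,
                "attitude": attitude,
                "target_word": word,
                "is_noisy_target": word == "mahjong_tile",
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture(scope="session")
def cascade_fixture():
    """20 hand-constructed records with known duplicates, URL flags,
    blocklisted and out-of-lexicon words.

    Hand-counted cascade: 20 collected; dedup removes 2 exact duplicates
    (18); URL drop removes 3 (15); 12 attitude records remain of which 10
    carry a target word; blocklist/lexicon rejects 2, leaving 8 classified.
    """
    rows = [
        (0, "k1", 0, "desire", "cat"),
        (1, "k1", 0, "desire", "cat"),          # duplicate of k1
        (2, "k2", 1, "desire", "dog"),          # URL
        (3, "k3", 0, "avoidance", "doorknob"),
        (4, "k4", 0, "none", None),
        (5, "k5", 0, "desire", "mahjong_tile"),  # blocklisted
        (6, "k6", 0, "desire", None),            # no target extracted
        (7, "k7", 0, "avoidance", "money"),
        (8, "k8", 1, "none", None),              # URL
        (9, "k8", 1, "none", None),              # duplicate of k8
        (10, "k9", 0, "desire", "hand"),
        (11, "k10", 0, "desire", "unicorn"),     # out of lexicon
        (12, "k11", 0, "avoidance", "heat"),
        (13, "k12", 0, "none", None),
        (14, "k13", 0, "desire", "cat"),
        (15, "k14", 1, "desire", "cat"),         # URL
        (16, "k15", 0, "avoidance", None),       # no target extracted
        (17, "k16", 0, "none", None),
        (18, "k17", 0, "desire", "warmth"),
        (19, "k18", 0, "avoidance", "ditch"),
    ]
    expected_report = {
        "collected": 20,
        "after_dedup": 18,
        "after_url_drop": 15,
        "with_target": 10,
        "after_blocklist": 8,
    }
    return make_records(rows), expected_report


from touchdid.studies import calibration_config  # noqa: E402


@pytest.fixture(scope="session")
def calib_config():
    return calibration_config


def gamma_inverse_oracle(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct numerical likelihood maximisation for the Gamma GLM with
    inverse link, independent of IRLS.

    For the canonical (inverse) link the coefficient MLE does not depend on
    the Gamma shape, so it maximises sum(log eta - y*eta) with eta = X b,
    a concave problem solved here by Newton-CG with analytic derivatives.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def nll(b):
        eta = X @ b
        if np.any(eta <= 0):
            return np.inf
        return float(np.sum(y * eta - np.log(eta)))

    def grad(b):
        eta = X @ b
        return X.T @ (y - 1.0 / eta)

    def hess(b):
        eta = X @ b
        return X.T @ (X / eta[:, None] ** 2)

    b0, *_ = np.linalg.lstsq(X, 1.0 / y, rcond=None)
    if np.any(X @ b0 <= 0):  # fall back to a flat start at the global mean
        b0 = np.zeros(X.shape[1])
        b0[0] = 1.0 / y.mean()
    res = optimize.minimize(nll, b0, jac=grad, hess=hess, method="Newton-CG",
                            options={"xtol": 1e-14, "maxiter": 500})
    return res.x


@pytest.fixture(scope="session")
def glm_oracle():
    return gamma_inverse_oracle
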