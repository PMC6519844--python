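"""Shared fixtures and independent right-hand-side oracles.

The oracles below are literal, loop-based transcriptions of each model's
population equations, written independently of the vectorised matrix
builders so that M @ v can be checked against them on random vectors.
"""

import math

import numpy as np
import pytest


def base_rhs(v, r, a):
    """dN/dt of the base model, transcribed term by term."""
    n = len(v)
    out = np.zeros(n)
    out[0] = -r * v[0] + sum(2.0 * a * v[i - 1] for i in range(2, n + 1))
    for i in range(2, n + 1):
        nxt = v[i] if i < n else 0.0
        out[i - 1] = (
            r * v[i - 2] * (i - 1)
            - i * r * v[i - 1]
            - (i - 1) * a * v[i - 1]
            + 2.0 * a * nxt
        )
    return out


def escape_rhs(v, r, a, d, dp, dpp, c, cp):
    """dN/dt with replication escape and loss, transcribed term by term."""
    n = len(v)
    out = np.zeros(n)
    out[0] = (
        r * (-1.0 + 2.0 * d) * v[0]
        + sum(2.0 * r * dp * v[i - 1] for i in range(2, n + 1))
        + sum(2.0 * a * v[i - 1] for i in range(2, n + 1))
        - c * v[0]
    )
    v3 = v[2] if n >= 3 else 0.0
    out[1] = (
        r * (1.0 - d) * v[0]
        - 2.0 * r * (1.0 - dp) * v[1]
        - a * v[1]
        + 2.0 * a * v3
        - cp * v[1]
    )
    for i in range(3, n + 1):
        nxt = v[i] if i < n else 0.0
        out[i - 1] = (
            r * (2.0 * dp - i) * v[i - 1]
            + r * v[i - 2] * (i - 1 - 2.0 * dp + 3.0 * dpp - i * dpp)
            - (i - 1) * a * v[i - 1]
            + 2.0 * a * nxt
            - cp * v[i - 1]
        )
    return out


def q_rhs(v, r, a, q):
    """dN/dt of the subchain-escape model, transcribed term by term."""
    n = len(v)
    out = np.zeros(n)
    out[0] = -r * v[0] + sum(2.0 * a * v[j - 1] for j in range(2, n + 1))
    for i in range(2, n + 1):
        nxt = v[i] if i < n else 0.0
        tail = sum(2.0 * a * q * v[j - 1] for j in range(i + 2, n + 1))
        out[i - 1] = (
            -r * i * v[i - 1]
            + r * (i - 1) * v[i - 2]
            - a * (i - 1) * v[i - 1]
            + 2.0 * a * nxt
            + tail
        )
    return out


def force_rhs(v, r, a, b):
    """dN/dt of the force-breaking model with the printed aggregate sums."""
    n = len(v)
    out = np.zeros(n)
    out[0] = -r * v[0] + sum(
        2.0 * a * v[i - 1] * math.exp(b * (i - 1) / 2.0) for i in range(2, n + 1)
    )
    for i in range(2, n + 1):
        nxt = v[i] if i < n else 0.0
        if i % 2 == 0:
            brk = (
                a
                * math.exp(b * i * i / 8.0)
                * (
                    1.0
                    + 2.0
                    * sum(
                        math.exp(-((j - 1) ** 2) * b / 2.0)
                        for j in range(2, i // 2 + 1)
                    )
                )
            )
        else:
            brk = (
                2.0
                * a
                * math.exp(b * i * i / 8.0)
                * sum(
                    math.exp(-((j - 0.5) ** 2) * b / 2.0)
                    for j in range(1, (i - 1) // 2 + 1)
                )
            )
        out[i - 1] = (
            -r * i * v[i - 1]
            - brk * v[i - 1]
            + r * (i - 1) * v[i - 2]
            + 2.0 * a * nxt * math.exp(b * i / 2.0)
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
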