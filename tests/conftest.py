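"""Shared fixtures and helpers for the test suite.

All sequence fixtures are generated here at run time; nothing is read
from disk.
"""

from __future__ import annotations

import random

import pytest

from cgmap.chain import Fragment, GapFunction


def random_seq(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def random_fragments(rng: random.Random, n: int, span: int = 200, size: int = 20,
                     allow_degenerate: bool = False) -> list[Fragment]:
    out = []
    for _ in range(n):
        xs = rng.randint(0, span)
        ys = rng.randint(0, span)
        dx = rng.randint(0, size)
        dy = rng.randint(0, size)
        if allow_degenerate and rng.random() < 0.05:
            dx = 0
        out.append(Fragment(xs, ys, xs + dx, ys + dy, rng.uniform(0.5, 5.0)))
    return out


def random_concave_gap(rng: random.Random) -> GapFunction:
    a = rng.uniform(0.05, 2.5)
    b = rng.uniform(0.0, 2.0)
    kind = rng.choice(["log", "sqrt", "linear"])
    if kind == "log":
        return GapFunction.log_cost(a, b)
    if kind == "sqrt":
        return GapFunction.sqrt_cost(a, b)
    return GapFunction.linear_cost(a * 0.05, b)


@pytest.fixture()
def rng() -> random.Random:
    return random.Random(0xC6A7)
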