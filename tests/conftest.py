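from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from sectornet.model import CITIES, SECTORS, MemberRoster, Sociomatrix
from sectornet.simulate import GeneratorConfig, generate_dataset


def make_roster(
    sectors: list[str],
    cities: list[str] | None = None,
    original: list[bool] | None = None,
    ids: list[str] | None = None,
) -> MemberRoster:
    n = len(sectors)
    cities = cities or [CITIES[0]] * n
    original = original if original is not None else [True] * n
    ids = ids or [f"m{k:02d}" for k in range(1, n + 1)]
    return MemberRoster(
        pd.DataFrame(
            {
                "member_id": ids,
                "label": [f"member {k}" for k in range(n)],
                "sector": sectors,
                "city": cities,
                "original_member": original,
            }
        )
    )


def make_matrix(
    arcs: list[tuple[int, int]] | np.ndarray,
    n: int | None = None,
    ids: tuple[str, ...] | None = None,
    wave: str = "wave",
) -> Sociomatrix:
    if isinstance(arcs, np.ndarray):
        a = arcs
        n = a.shape[0]
    else:
        assert n is not None
        a = np.zeros((n, n), dtype=np.int8)
        for i, j in arcs:
            a[i, j] = 1
    ids = ids or tuple(f"m{k:02d}" for k in range(1, n + 1))
    return Sociomatrix(wave=wave, adjacency=a, member_ids=ids)


def random_digraph(rng: np.random.Generator, n: int, p: float = 0.4) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(np.int8)
    np.fill_diagonal(a, 0)
    return a


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    return generate_dataset(default_cfg, seed=1)


@pytest.fixture(scope="session")
def sector_cycle():
    """Sector labels cycling through a subset, for random block fixtures."""

    def _make(n: int, k: int = 3) -> list[str]:
        return [SECTORS[i % k] for i in range(n)]

    return _make
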