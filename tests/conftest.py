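"""Shared fixtures: desk-scale Gibbs-ensemble runs cached per session.

Several tests interrogate the same thermodynamic state points, so each state
point is simulated once per session and shared.  Desk scale here means
N = 256 particles and a few thousand cycles, which resolves the coexistence
densities and bond statistics to a few percent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from patchygibbs import engine
from patchygibbs.model import ModelParams

# Desk-scale run lengths used across the suite.
N_TOTAL = 256
N_EQUIL = 8_000
N_COLLECT = 8_000
STRIDE = 20


class RunCache:
    """Lazy cache of engine runs keyed by (eps_PR, X, T)."""

    def __init__(self) -> None:
        self._cache: dict[tuple, tuple[pd.DataFrame, engine.GibbsState]] = {}

    def get(
        self,
        eps_pr: float,
        x_ratio: float,
        temperature: float,
        n_total: int = N_TOTAL,
        n_equil: int = N_EQUIL,
        n_collect: int = N_COLLECT,
        warm_start: bool = True,
    ) -> tuple[pd.DataFrame, engine.GibbsState]:
        key = (eps_pr, x_ratio, temperature, n_total, n_equil, n_collect,
               warm_start)
        if key not in self._cache:
            params = ModelParams(eps_PR=eps_pr)
            seed = abs(hash(key)) % 100_000
            samples, state = engine.run(
                params,
                n_total=n_total,
                x_ratio=x_ratio,
                rho0=0.3,
                temperature=temperature,
                n_equil_cycles=n_equil,
                n_collect_cycles=n_collect,
                sample_stride=STRIDE,
                seed=seed,
                warm_start=warm_start,
            )
            self._cache[key] = (samples, state)
        return self._cache[key]


@pytest.fixture(scope="session")
def mc_runs() -> RunCache:
    return RunCache()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
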