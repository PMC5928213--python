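"""Gibbs-ensemble Monte Carlo engine.

Two periodic boxes at fixed total particle numbers, total volume and
temperature exchange volume and particles until each box settles into one bulk
phase.  Moves are (i) combined single-particle translation+rotation, (ii)
particle transfer between boxes, (iii) symmetric volume exchange proposed in
ln(V_I/V_II).  A cycle is a randomly interleaved sequence of the scheduled
attempt counts; by default 500 displacement, 500 exchange and 5 volume
attempts per cycle.

Hot loops are JIT-compiled (:mod:`patchygibbs._kernels`); this module owns
state setup, the cycle driver and the sample stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels as K
from .model import (
    Configuration,
    ModelParams,
    Species,
    random_quaternion,
    reference_patch_directions,
    quat_to_matrix,
)

__all__ = [
    "MoveSchedule",
    "GibbsState",
    "SAMPLE_COLUMNS",
    "initial_state",
    "displacement_move",
    "exchange_move",
    "volume_move",
    "run",
]

#: Wide per-sample record layout; suffixes _a/_b are the raw box identities
#: (phase labels I/II are assigned afterwards, per sample, by density).
SAMPLE_COLUMNS = ["cycle"] + [
    f"{name}_{box}"
    for box in ("a", "b")
    for name in ("n_P", "n_R", "volume", "energy", "bonds_PP", "bonds_PR", "bonds_RR")
]


@dataclass
class MoveSchedule:
    """Attempt counts per cycle and maximum step sizes."""

    n_displacement: int = 500
    n_exchange: int = 500
    n_volume: int = 5
    max_translation: float = 0.3
    max_rotation: float = 0.4
    max_ln_volume_change: float = 0.04

    def __post_init__(self) -> None:
        for name in ("n_displacement", "n_exchange", "n_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_translation", "max_rotation", "max_ln_volume_change"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


class GibbsState:
    """Two simulation boxes plus conserved totals, with cached energies.

    The per-box particle data live in flat capacity-``N_total`` arrays so that
    transfers never reallocate.  Cached box energies are maintained
    incrementally by the move kernels and always equal a from-scratch
    recomputation (energies are exact multiples of the well depths).
    """

    def __init__(
        self,
        box_a: Configuration,
        box_b: Configuration,
        params: ModelParams,
        temperature: float,
    ) -> None:
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.params = params
        self.temperature = float(temperature)
        cap = len(box_a) + len(box_b)
        self.capacity = cap
        self.pos = np.zeros((2, cap, 3))
        self.quat = np.zeros((2, cap, 4))
        self.patch = np.zeros((2, cap, 4, 3))
        self.spec = np.zeros((2, cap), dtype=np.int64)
        self.n = np.zeros(2, dtype=np.int64)
        self.nsp = np.zeros((2, 2), dtype=np.int64)
        self.L = np.zeros(2)
        self.energy = np.zeros(2)
        self.head = np.full((2, K.MAXCELLS), -1, dtype=np.int64)
        self.nxt = np.full((2, cap), -1, dtype=np.int64)
        self.nc = np.zeros(2, dtype=np.int64)
        # scratch buffers for volume moves
        self._pos_buf = np.zeros((2, cap, 3))
        self._head_buf = np.full((2, K.MAXCELLS), -1, dtype=np.int64)
        self._nxt_buf = np.full((2, cap), -1, dtype=np.int64)
        self._nc_buf = np.zeros(2, dtype=np.int64)
        self._L_buf = np.zeros(2)
        self._n_buf = np.zeros(2, dtype=np.int64)
        self._qbuf = np.zeros(4)
        self._pbuf = np.zeros((4, 3))

        self.refP = reference_patch_directions(Species.P)
        self.refR = reference_patch_directions(Species.R)
        self.cth = np.array([params.cos_theta_P, params.cos_theta_R])
        self.mvec = np.array([params.m_P, params.m_R], dtype=np.int64)
        self.eps = params.eps_matrix
        self.sigma2 = params.sigma**2
        self.rcut = params.well_edge
        self.rc2 = self.rcut**2

        for b, cfg in enumerate((box_a, box_b)):
            nb = len(cfg)
            self.n[b] = nb
            self.L[b] = cfg.box_edge
            self.pos[b, :nb] = cfg.positions
            self.quat[b, :nb] = cfg.orientations
            self.spec[b, :nb] = cfg.species
            for s in (0, 1):
                self.nsp[b, s] = int(np.sum(cfg.species == s))
            for i in range(nb):
                ref = self.refP if cfg.species[i] == 0 else self.refR
                self.patch[b, i, : len(ref)] = ref @ quat_to_matrix(
                    cfg.orientations[i]
                ).T
        self.v_total = float(self.L[0] ** 3 + self.L[1] ** 3)
        self.n_P_total = int(self.nsp[:, 0].sum())
        self.n_R_total = int(self.nsp[:, 1].sum())
        self.rebuild_cells()
        for b in range(2):
            e, ov = K.box_energy(
                b, self.pos, self.patch, self.spec, self.n, self.L,
                self.head, self.nxt, self.nc,
                self.sigma2, self.rc2, self.cth, self.mvec, self.eps,
            )
            if ov:
                raise ValueError(f"initial configuration of box {b} has overlaps")
            self.energy[b] = e

    # -- plumbing -----------------------------------------------------------

    def rebuild_cells(self) -> None:
        for b in range(2):
            self.nc[b] = K.choose_nc(self.L[b], self.rcut)
            K.build_cells(b, self.pos, self.n, self.L, self.nc, self.head, self.nxt)

    def seed(self, seed: int) -> None:
        """Seed the kernel RNG that drives all move proposals."""
        K.seed_rng(int(seed) % 2**31)

    def box(self, b: int) -> Configuration:
        nb = int(self.n[b])
        return Configuration(
            self.pos[b, :nb].copy(),
            self.quat[b, :nb].copy(),
            self.spec[b, :nb].copy(),
            float(self.L[b]),
        )

    @property
    def box_a(self) -> Configuration:
        return self.box(0)

    @property
    def box_b(self) -> Configuration:
        return self.box(1)

    @property
    def totals(self) -> tuple[int, int, float]:
        return self.n_P_total, self.n_R_total, self.v_total

    def recompute_energies(self) -> np.ndarray:
        """From-scratch O(N^2) energies of both boxes (consistency oracle)."""
        out = np.zeros(2)
        for b in range(2):
            e, ov = K.box_energy(
                b, self.pos, self.patch, self.spec, self.n, self.L,
                self.head, self.nxt, self.nc,
                self.sigma2, self.rc2, self.cth, self.mvec, self.eps,
            )
            if ov:
                raise RuntimeError("state contains a hard-core overlap")
            out[b] = e
        return out

    def check_invariants(self) -> None:
        assert int(self.nsp[:, 0].sum()) == self.n_P_total
        assert int(self.nsp[:, 1].sum()) == self.n_R_total
        v = self.L[0] ** 3 + self.L[1] ** 3
        assert abs(v - self.v_total) < 1e-9 * self.v_total
        fresh = self.recompute_energies()
        assert np.max(np.abs(fresh - self.energy)) < 1e-9


# -- single-move wrappers (unit-testable entry points) ----------------------


def displacement_move(state: GibbsState, schedule: MoveSchedule) -> tuple[int, float]:
    """One translation+rotation attempt; returns (outcome code, proposed dU)."""
    return K.attempt_displacement(
        state.pos, state.quat, state.patch, state.spec, state.n, state.L,
        state.energy, state.head, state.nxt, state.nc,
        state.sigma2, state.rc2, state.cth, state.mvec, state.eps,
        state.refP, state.refR,
        state.temperature, schedule.max_translation, schedule.max_rotation,
        state._qbuf, state._pbuf,
    )


def exchange_move(state: GibbsState) -> tuple[int, float]:
    """One particle-transfer attempt; returns (outcome code, proposed dU)."""
    return K.attempt_exchange(
        state.pos, state.quat, state.patch, state.spec, state.n, state.nsp,
        state.L, state.energy, state.head, state.nxt, state.nc,
        state.sigma2, state.rc2, state.cth, state.mvec, state.eps,
        state.refP, state.refR, state.temperature, state._qbuf, state._pbuf,
    )


def volume_move(state: GibbsState, schedule: MoveSchedule) -> tuple[int, float]:
    """One volume-exchange attempt; returns (outcome code, proposed dU)."""
    return K.attempt_volume(
        state.pos, state.patch, state.spec, state.n, state.L, state.energy,
        state.head, state.nxt, state.nc,
        state.sigma2, state.rc2, state.cth, state.mvec, state.eps,
        state.temperature, schedule.max_ln_volume_change, state.rcut,
        state._pos_buf, state._head_buf, state._nxt_buf, state._nc_buf,
        state._L_buf, state._n_buf,
    )


# -- initialization ---------------------------------------------------------


def _insert_box(
    n_p: int, n_r: int, edge: float, sigma: float, rng: np.random.Generator
) -> Configuration:
    """Random sequential insertion with a retry budget of 1e4 per particle."""
    n = n_p + n_r
    pos = np.zeros((n, 3))
    spec = np.concatenate(
        [np.zeros(n_p, dtype=np.int64), np.ones(n_r, dtype=np.int64)]
    )
    for i in range(n):
        for attempt in range(10_000):
            cand = rng.uniform(0.0, edge, size=3)
            d = cand - pos[:i]
            d -= edge * np.round(d / edge)
            if i == 0 or np.min(np.einsum("ij,ij->i", d, d)) > sigma**2:
                pos[i] = cand
                break
        else:
            raise RuntimeError(
                "random sequential insertion failed; density too high for "
                "naive placement - grow the system from a dilute start instead"
            )
    quat = np.array([random_quaternion(rng) for _ in range(n)])
    return Configuration(pos, quat, spec, edge)


def initial_state(
    params: ModelParams,
    n_total: int,
    x_ratio: float,
    rho0: float,
    temperature: float,
    seed: int,
    warm_start: bool = True,
) -> GibbsState:
    """Starting state for a Gibbs run, built by random sequential insertion.

    ``x_ratio`` is the overall regulator-to-protein number ratio X = N_R/N_P
    and ``rho0 = (N_P + N_R) sigma^3 / V_total`` the overall number density.

    With ``warm_start`` (default) the boxes start asymmetric — 80% of each
    species in a box compressed toward a liquid-like density — which removes
    most of the slow net particle/volume transfer from equilibration; the
    stationary distribution is independent of the start.  ``warm_start=False``
    gives equal volumes with an even split.
    """
    if n_total < 2:
        raise ValueError("need at least 2 particles")
    if rho0 <= 0:
        raise ValueError("rho0 must be positive")
    if x_ratio < 0:
        raise ValueError("x_ratio must be >= 0")
    n_r = int(round(n_total * x_ratio / (1.0 + x_ratio)))
    n_p = n_total - n_r
    v_total = n_total * params.sigma**3 / rho0
    rng = np.random.default_rng(seed)
    rho_dense, rho_dilute = 0.55, 0.05
    # Seed near coexistence so the slow net transfer starts small.
    # Inserting P into an existing bonded droplet is the slowest process in
    # these systems, so the droplet box starts as a liquid-density P-rich
    # phase; the regulator's droplet share scales with its bonding ability
    # eps_PR/eps_PP (inert regulators start fully dispersed, strongly bound
    # ones get a uniform share).  The droplet volume solves
    # rho(dense) = 0.55 with threshold-level P (0.05) left in the dilute box.
    if params.eps_PP > 0:
        r_share = 0.5 * min(1.0, params.eps_PR / params.eps_PP)
    else:
        r_share = 0.5
    nr_b = int(round(r_share * n_r))
    v_b = (n_p + nr_b - rho_dilute * v_total) / (rho_dense - rho_dilute)
    if warm_start and 0.1 * v_total < v_b < 0.9 * v_total:
        f_v = v_b / v_total
        np_b = min(n_p, max(0, int(round(rho_dense * v_b)) - nr_b))
    else:
        f_v = 0.5
        np_b = n_p // 2
        nr_b = n_r // 2
    edge_b = (f_v * v_total) ** (1.0 / 3.0)
    edge_a = ((1.0 - f_v) * v_total) ** (1.0 / 3.0)
    box_a = _insert_box(n_p - np_b, n_r - nr_b, edge_a, params.sigma, rng)
    box_b = _insert_box(np_b, nr_b, edge_b, params.sigma, rng)
    return GibbsState(box_a, box_b, params, temperature)


# -- cycle driver -----------------------------------------------------------


def run_state(
    state: GibbsState,
    schedule: MoveSchedule,
    n_equil_cycles: int,
    n_collect_cycles: int,
    sample_stride: int,
    seed: int,
    check_every: int = 0,
) -> pd.DataFrame:
    """Equilibrate, then collect; returns the sample stream as a DataFrame.

    Step sizes adapt toward 30-50% acceptance during equilibration only and
    are frozen for collection.  ``check_every`` > 0 re-derives the cached
    energies every that many cycles and aborts on any mismatch (test mode).
    """
    if sample_stride <= 0:
        raise ValueError("sample_stride must be positive")
    state.seed(seed)
    step = np.array(
        [
            schedule.max_translation,
            schedule.max_rotation,
            schedule.max_ln_volume_change,
        ]
    )
    args = (
        state.pos, state.quat, state.patch, state.spec, state.n, state.nsp,
        state.L, state.energy, state.head, state.nxt, state.nc,
        state.sigma2, state.rc2, state.cth, state.mvec, state.eps,
        state.refP, state.refR, state.temperature, state.rcut,
        schedule.n_displacement, schedule.n_exchange, schedule.n_volume,
        step,
    )
    bufs = (
        state._pos_buf, state._head_buf, state._nxt_buf, state._nc_buf,
        state._L_buf, state._n_buf,
    )
    empty = np.zeros((1, len(SAMPLE_COLUMNS)))
    if n_equil_cycles > 0:
        K.run_cycles(
            *args, n_equil_cycles, 0, True, 0, empty, 0, check_every, *bufs
        )
    n_samples = n_collect_cycles // sample_stride
    samples = np.zeros((n_samples, len(SAMPLE_COLUMNS)))
    if n_collect_cycles > 0:
        got = K.run_cycles(
            *args, n_collect_cycles, n_equil_cycles, False, sample_stride,
            samples, 0, check_every, *bufs,
        )
        samples = samples[:got]
    df = pd.DataFrame(samples, columns=SAMPLE_COLUMNS)
    for box in ("a", "b"):
        df[f"rho_P_{box}"] = df[f"n_P_{box}"] / df[f"volume_{box}"]
        df[f"rho_R_{box}"] = df[f"n_R_{box}"] / df[f"volume_{box}"]
    return df


def run(
    params: ModelParams,
    n_total: int,
    x_ratio: float,
    rho0: float,
    temperature: float,
    schedule: MoveSchedule | None = None,
    n_equil_cycles: int = 50_000,
    n_collect_cycles: int = 100_000,
    sample_stride: int = 50,
    seed: int = 0,
    check_every: int = 0,
    state: GibbsState | None = None,
    warm_start: bool = True,
) -> tuple[pd.DataFrame, GibbsState]:
    """Full Gibbs-ensemble run from a fresh (or resumed) state.

    Returns (sample stream, final state).  Fully reproducible for a given
    seed: initialization uses ``seed`` and the move stream uses ``seed + 1``.
    """
    if schedule is None:
        schedule = MoveSchedule()
    if state is None:
        state = initial_state(
            params, n_total, x_ratio, rho0, temperature, seed,
            warm_start=warm_start,
        )
    samples = run_state(
        state,
        schedule,
        n_equil_cycles,
        n_collect_cycles,
        sample_stride,
        seed + 1,
        check_every=check_every,
    )
    return samples, state
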