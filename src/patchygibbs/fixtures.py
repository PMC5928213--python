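"""Hand-built test configurations and deliberately naive oracles.

The oracle here re-derives the patch geometry and the directional square-well
energy from first principles (its own cosines, its own quaternion rotation,
plain double loops) so that it shares no code with the production paths in
:mod:`patchygibbs.model` and the simulation kernels.  Equality between the two
routes is itself the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import Configuration, ModelParams, OVERLAP, Species

__all__ = [
    "Fixture",
    "brute_force_energy",
    "brute_force_bond_pairs",
    "make_fixture",
    "fixture_names",
    "random_configuration",
    "synthetic_binodal",
]

_FIXTURE_NAMES = (
    "dimer_PP",
    "trimer_PPR",
    "square_well_limit",
    "dense_lattice_16",
    "ideal_gas_box",
)


def fixture_names() -> tuple[str, ...]:
    return _FIXTURE_NAMES


def _oracle_rotate(q, v):
    # Quaternion rotation written out longhand: v' = v + 2 w (u x v) + 2 u x (u x v)
    w = q[0]
    u = np.array([q[1], q[2], q[3]])
    t = 2.0 * np.cross(u, v)
    return v + w * t + np.cross(u, t)


def _oracle_patches(species: int, chi: float, q) -> tuple[list, float]:
    # Re-derived, not imported: patch frames and cos(theta) from the coverage
    # fraction alone.
    if species == 0:  # P: tetrahedron
        m = 4
        s = 1.0 / math.sqrt(3.0)
        ref = [
            np.array([s, s, s]),
            np.array([s, -s, -s]),
            np.array([-s, s, -s]),
            np.array([-s, -s, s]),
        ]
    else:  # R: poles
        m = 2
        ref = [np.array([0.0, 0.0, 1.0]), np.array([0.0, 0.0, -1.0])]
    cos_theta = 1.0 - 2.0 * chi / m
    return [_oracle_rotate(q, v) for v in ref], cos_theta


def _oracle_pair(pos_i, q_i, s_i, pos_j, q_j, s_j, params: ModelParams, box: float):
    d = pos_j - pos_i
    for k in range(3):
        while d[k] > 0.5 * box:
            d[k] -= box
        while d[k] < -0.5 * box:
            d[k] += box
    r = math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2)
    if r <= params.sigma:
        return OVERLAP, False
    if r > params.sigma + params.lam:
        return 0.0, False
    rhat = d / r
    ni, cos_i = _oracle_patches(s_i, params.chi, q_i)
    nj, cos_j = _oracle_patches(s_j, params.chi, q_j)
    bonded = False
    for a in ni:
        for b in nj:
            if float(np.dot(rhat, a)) > cos_i and float(np.dot(-rhat, b)) > cos_j:
                bonded = True
    if not bonded:
        return 0.0, False
    if s_i == 0 and s_j == 0:
        eps = params.eps_PP
    elif s_i == 1 and s_j == 1:
        eps = params.eps_RR
    else:
        eps = params.eps_PR
    return -eps, True


def brute_force_energy(config: Configuration, params: ModelParams):
    """O(N^2) double-loop total energy; no cell lists, no caching.

    Returns the overlap sentinel if any pair overlaps.
    """
    n = len(config)
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            e, _ = _oracle_pair(
                config.positions[i].copy(),
                config.orientations[i],
                int(config.species[i]),
                config.positions[j].copy(),
                config.orientations[j],
                int(config.species[j]),
                params,
                config.box_edge,
            )
            if e is OVERLAP:
                return OVERLAP
            total += e
    return total


def brute_force_bond_pairs(
    config: Configuration, params: ModelParams, include_zero_eps: bool = False
) -> list[tuple[int, int]]:
    """All bonded pairs by exhaustive search.

    By default only pairs whose well depth is positive count as bonds (a
    geometric R-R or zero-``eps_PR`` contact stabilises nothing).
    """
    n = len(config)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = int(config.species[i]), int(config.species[j])
            e, bonded = _oracle_pair(
                config.positions[i].copy(),
                config.orientations[i],
                si,
                config.positions[j].copy(),
                config.orientations[j],
                sj,
                params,
                config.box_edge,
            )
            if not bonded:
                continue
            if not include_zero_eps and params.eps(si, sj) <= 0.0:
                continue
            pairs.append((i, j))
    return pairs


@dataclass
class Fixture:
    """A named configuration with oracle-computed expected observables."""

    name: str
    configuration: Configuration
    params: ModelParams
    expected: dict = field(default_factory=dict)


def _quat_z_to(v: np.ndarray) -> np.ndarray:
    """Unit quaternion rotating +z onto unit vector v."""
    z = np.array([0.0, 0.0, 1.0])
    v = v / np.linalg.norm(v)
    d = float(np.dot(z, v))
    if d > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if d < -1.0 + 1e-12:
        return np.array([0.0, 1.0, 0.0, 0.0])  # 180 deg about x
    axis = np.cross(z, v)
    axis /= np.linalg.norm(axis)
    half = 0.5 * math.acos(d)
    return np.array(
        [math.cos(half), *(math.sin(half) * axis)]
    )


def _quat_patch0_to(species: Species, v: np.ndarray) -> np.ndarray:
    """Quaternion aligning the species' first reference patch with v."""
    if species is Species.R:
        return _quat_z_to(v)
    # P: first tetrahedral patch is (1,1,1)/sqrt(3)
    p0 = np.array([1.0, 1.0, 1.0]) / math.sqrt(3.0)
    v = v / np.linalg.norm(v)
    d = float(np.clip(np.dot(p0, v), -1.0, 1.0))
    if d > 1.0 - 1e-12:
        return np.array([1.0, 0.0, 0.0, 0.0])
    if d < -1.0 + 1e-12:
        perp = np.cross(p0, np.array([1.0, 0.0, 0.0]))
        perp /= np.linalg.norm(perp)
        return np.array([0.0, *perp])
    axis = np.cross(p0, v)
    axis /= np.linalg.norm(axis)
    half = 0.5 * math.acos(d)
    return np.array([math.cos(half), *(math.sin(half) * axis)])


def make_fixture(name: str) -> Fixture:
    """Reproducible hand-built configurations with oracle expectations.

    Available: ``dimer_PP``, ``trimer_PPR``, ``square_well_limit``,
    ``dense_lattice_16``, ``ideal_gas_box``.
    """
    box = 20.0
    if name == "dimer_PP":
        params = ModelParams(eps_PR=0.5)
        pos = np.array([[5.0, 5.0, 5.0], [6.2, 5.0, 5.0]])
        x = np.array([1.0, 0.0, 0.0])
        quat = np.array(
            [_quat_patch0_to(Species.P, x), _quat_patch0_to(Species.P, -x)]
        )
        spec = np.array([0, 0])
        cfg = Configuration(pos, quat, spec, box)
        fx = Fixture(name, cfg, params)
    elif name == "trimer_PPR":
        # Central P at origin bonded to a P along +x and an R along +y.
        params = ModelParams(eps_PR=0.5)
        x = np.array([1.0, 0.0, 0.0])
        y = np.array([0.0, 1.0, 0.0])
        pos = np.array([[5.0, 5.0, 5.0], [6.2, 5.0, 5.0], [5.0, 6.2, 5.0]])
        # Central P: tetrahedral patches include directions within theta_P of
        # both +x and +y when patch 0 -> (1,1,0)/sqrt(2): patch 0 is then
        # 45 deg from each axis, inside theta_P = acos(0.65) ~ 49.5 deg.
        diag = np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)
        quat = np.array(
            [
                _quat_patch0_to(Species.P, diag),
                _quat_patch0_to(Species.P, -x),
                _quat_z_to(-y),
            ]
        )
        spec = np.array([0, 0, 1])
        cfg = Configuration(pos, quat, spec, box)
        fx = Fixture(name, cfg, params)
    elif name == "square_well_limit":
        # chi -> 1 on the two-patch species: each polar patch spans a full
        # hemisphere, so the attraction is orientation-independent and the
        # pair reduces to a plain square well.
        params = ModelParams(chi=0.999999, eps_RR=1.0, check_patch_overlap=False)
        rng = np.random.default_rng(7)
        pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 6.3]])
        q = rng.normal(size=(2, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        cfg = Configuration(pos, q, np.array([1, 1]), box)
        fx = Fixture(name, cfg, params)
    elif name == "dense_lattice_16":
        # 16 P on an FCC fragment, nearest neighbours at 1.25 sigma (in-well);
        # orientations all identical, so bonding follows from geometry alone.
        params = ModelParams()
        a = 1.25 * math.sqrt(2.0)  # cubic lattice constant
        base = np.array(
            [[0.0, 0.0, 0.0], [0.5, 0.5, 0.0], [0.5, 0.0, 0.5], [0.0, 0.5, 0.5]]
        )
        cells = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1)]
        pts = []
        for c in cells:
            for b in base:
                pts.append((np.array(c) + b) * a)
        pos = np.array(pts) + 2.0
        quat = np.tile(np.array([1.0, 0.0, 0.0, 0.0]), (16, 1))
        cfg = Configuration(pos, quat, np.zeros(16, dtype=int), box)
        fx = Fixture(name, cfg, params)
    elif name == "ideal_gas_box":
        params = ModelParams(eps_PP=0.0, eps_PR=0.0, eps_RR=0.0)
        rng = np.random.default_rng(11)
        cfg = random_configuration(12, box, rng, x_ratio=1.0, min_distance=1.0)
        fx = Fixture(name, cfg, params)
    else:
        raise ValueError(f"unknown fixture {name!r}; choose from {_FIXTURE_NAMES}")

    fx.expected["energy"] = brute_force_energy(fx.configuration, fx.params)
    fx.expected["n_bond_pairs"] = len(
        brute_force_bond_pairs(fx.configuration, fx.params)
    )
    return fx


def random_configuration(
    n: int,
    box_edge: float,
    rng: np.random.Generator,
    x_ratio: float = 0.5,
    min_distance: float = 0.0,
) -> Configuration:
    """Random configuration for oracle-equivalence tests.

    Positions uniform in the box (optionally rejection-sampled to keep all
    minimum-image pair distances above ``min_distance``); orientations uniform;
    species R with probability ``x_ratio / (1 + x_ratio)``.
    """
    pos = np.zeros((n, 3))
    placed = 0
    attempts = 0
    while placed < n:
        attempts += 1
        if attempts > 10000 * n:
            raise RuntimeError("could not place particles at this density")
        cand = rng.uniform(0, box_edge, size=3)
        ok = True
        if min_distance > 0:
            for j in range(placed):
                d = cand - pos[j]
                d -= box_edge * np.round(d / box_edge)
                if float(d @ d) <= min_distance**2:
                    ok = False
                    break
        if ok:
            pos[placed] = cand
            placed += 1
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    p_r = x_ratio / (1.0 + x_ratio)
    spec = (rng.random(n) < p_r).astype(np.int64)
    return Configuration(pos, q, spec, box_edge)


def synthetic_binodal(
    t_c: float,
    rho_c: float,
    a: float,
    b: float,
    temperatures,
    noise: float = 0.0,
    seed: int | None = None,
):
    """Coexistence densities generated from the rectilinear-diameter law.

    The mean density is linear in T, ``(rho_I + rho_II)/2 = rho_c + A (T -
    T_c)``, and the width follows the Ising-like scaling ``rho_II - rho_I =
    B (T_c - T)^0.32``.  Optional multiplicative Gaussian noise of relative
    size ``noise`` is applied independently to each branch.

    Returns a list of ``(T, rho_I, rho_II)`` tuples.
    """
    temperatures = np.asarray(temperatures, dtype=float)
    if np.any(temperatures >= t_c):
        raise ValueError("all temperatures must lie strictly below t_c")
    if noise < 0:
        raise ValueError("noise must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for t in temperatures:
        mean = rho_c + a * (t - t_c)
        width = b * (t_c - t) ** 0.32
        lo = mean - 0.5 * width
        hi = mean + 0.5 * width
        if noise > 0:
            lo *= 1.0 + noise * rng.normal()
            hi *= 1.0 + noise * rng.normal()
        out.append((float(t), float(lo), float(hi)))
    return out
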