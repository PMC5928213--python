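"""Bond-network statistics of the droplet phase.

A bond is the geometric patch-contact condition between two particles inside
the square well.  Only pairs whose well depth is positive count in the
reports: a geometric contact between two regulators (``eps_RR = 0``), or
between P and R when ``eps_PR = 0``, stabilises nothing, so a regulator can
only have protein partners.

The headline observable is the average number of bonds per particle in the
dense phase, ``n_b``, and its decomposition

    n_b   = (rho_P n_b;P + rho_R n_b;R) / (rho_P + rho_R)
    n_b;P = n_b;P-P + n_b;P-R

both of which hold exactly per sample by construction (they are definitions,
not estimates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .model import Configuration, ModelParams

__all__ = [
    "BondCounts",
    "BondReport",
    "count_bonds",
    "bond_pairs",
    "bond_report",
    "extract_clusters",
    "block_stats",
    "dilute_limit_bonds_per_R",
]


@dataclass
class BondCounts:
    """Per-particle bonded-partner counts split by partner species."""

    p_partners: np.ndarray
    r_partners: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.p_partners + self.r_partners


def bond_pairs(
    config: Configuration, params: ModelParams, include_zero_eps: bool = False
) -> list[tuple[int, int]]:
    """All bonded particle pairs (each unordered pair once).

    ``include_zero_eps`` additionally reports geometric contacts in pair
    classes whose well depth is zero.
    """
    n = len(config)
    L = config.box_edge
    pos = config.positions
    spec = config.species
    patches = config.patch_directions()
    mvec = (params.m_P, params.m_R)
    cth = (params.cos_theta_P, params.cos_theta_R)
    eps = params.eps_matrix
    rc2 = params.well_edge**2
    s2 = params.sigma**2
    pairs: list[tuple[int, int]] = []
    for i in range(n):
        si = int(spec[i])
        d = pos[i + 1 :] - pos[i]
        d -= L * np.round(d / L)
        r2 = np.einsum("ij,ij->i", d, d)
        for k in np.nonzero((r2 > s2) & (r2 <= rc2))[0]:
            j = i + 1 + k
            sj = int(spec[j])
            if not include_zero_eps and eps[si, sj] <= 0.0:
                continue
            rhat = d[k] / math.sqrt(r2[k])
            if np.any(
                patches[i, : mvec[si]] @ rhat > cth[si]
            ) and np.any(patches[j, : mvec[sj]] @ (-rhat) > cth[sj]):
                pairs.append((i, int(j)))
    return pairs


def count_bonds(
    config: Configuration, params: ModelParams, include_zero_eps: bool = False
) -> BondCounts:
    """Distinct bonded partners of every particle, split by partner species.

    A pair contributes exactly one bond however many patch pairs align.
    """
    n = len(config)
    cp = np.zeros(n, dtype=np.int64)
    cr = np.zeros(n, dtype=np.int64)
    for i, j in bond_pairs(config, params, include_zero_eps):
        if config.species[j] == 0:
            cp[i] += 1
        else:
            cr[i] += 1
        if config.species[i] == 0:
            cp[j] += 1
        else:
            cr[j] += 1
    return BondCounts(cp, cr)


def extract_clusters(
    config: Configuration, params: ModelParams
) -> list[dict]:
    """Connected components of the bond graph.

    Returns one dict per component with ``members`` (particle ids), ``n_P``
    and ``n_R``.  Isolated particles form singleton components.
    """
    n = len(config)
    pairs = bond_pairs(config, params)
    if pairs:
        arr = np.asarray(pairs)
        data = np.ones(len(arr))
        adj = coo_matrix(
            (data, (arr[:, 0], arr[:, 1])), shape=(n, n)
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)
    out = []
    for c in range(n_comp):
        members = np.nonzero(labels == c)[0]
        out.append(
            {
                "members": members.tolist(),
                "n_P": int(np.sum(config.species[members] == 0)),
                "n_R": int(np.sum(config.species[members] == 1)),
            }
        )
    return out


@dataclass
class BondReport:
    """Time-averaged dense-phase bond statistics with block standard errors.

    ``nan`` R-specific fields mark "undefined" (no regulators in the dense
    phase), never zero bonding.
    """

    n_b: float
    n_bP: float
    n_bR: float
    n_bPP: float
    n_bPR: float
    rho_P: float
    rho_R: float
    r_fraction: float
    se_n_b: float = float("nan")
    se_n_bP: float = float("nan")
    se_n_bR: float = float("nan")
    n_samples: int = 0


def block_stats(values: np.ndarray, n_blocks: int = 10) -> tuple[float, float]:
    """Mean and standard error by block averaging.

    Samples from a Markov chain are autocorrelated; the s.e. of the mean is
    estimated from ``n_blocks`` contiguous block means.
    """
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if len(values) == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    n_blocks = min(n_blocks, len(values))
    blocks = np.array_split(values, n_blocks)
    bm = np.array([np.mean(b) for b in blocks])
    se = float(np.std(bm, ddof=1) / math.sqrt(len(bm))) if len(bm) > 1 else float("nan")
    return mean, se


def _dense_mask(samples: pd.DataFrame) -> np.ndarray:
    """Per-sample identity of the dense box: True where box b is denser."""
    rho_a = (samples["n_P_a"] + samples["n_R_a"]) / samples["volume_a"]
    rho_b = (samples["n_P_b"] + samples["n_R_b"]) / samples["volume_b"]
    return (rho_b > rho_a).to_numpy()


def bond_report(
    samples: pd.DataFrame, params: ModelParams, n_blocks: int = 10
) -> BondReport:
    """Dense-phase bond report from an engine sample stream.

    The dense box is identified per sample by total number density.  Pair
    classes with zero well depth are excluded from all bond tallies.
    """
    if len(samples) < 30:
        raise ValueError("need at least 30 samples for a bond report")
    dense_b = _dense_mask(samples)

    def dense(col: str) -> np.ndarray:
        a = samples[f"{col}_a"].to_numpy()
        b = samples[f"{col}_b"].to_numpy()
        return np.where(dense_b, b, a)

    n_p = dense("n_P")
    n_r = dense("n_R")
    vol = dense("volume")
    wpp = 1.0 if params.eps_PP > 0 else 0.0
    wpr = 1.0 if params.eps_PR > 0 else 0.0
    wrr = 1.0 if params.eps_RR > 0 else 0.0
    bpp = dense("bonds_PP") * wpp
    bpr = dense("bonds_PR") * wpr
    brr = dense("bonds_RR") * wrr

    with np.errstate(divide="ignore", invalid="ignore"):
        n_b = 2.0 * (bpp + bpr + brr) / (n_p + n_r)
        n_bP = np.where(n_p > 0, (2.0 * bpp + bpr) / np.maximum(n_p, 1), np.nan)
        n_bR = np.where(n_r > 0, (bpr + 2.0 * brr) / np.maximum(n_r, 1), np.nan)
        n_bPP = np.where(n_p > 0, 2.0 * bpp / np.maximum(n_p, 1), np.nan)
        n_bPR = np.where(n_p > 0, bpr / np.maximum(n_p, 1), np.nan)

    m_nb, se_nb = block_stats(n_b, n_blocks)
    m_nbP, se_nbP = block_stats(n_bP, n_blocks)
    m_nbR, se_nbR = block_stats(n_bR, n_blocks)
    m_nbPP, _ = block_stats(n_bPP, n_blocks)
    m_nbPR, _ = block_stats(n_bPR, n_blocks)
    rho_p, _ = block_stats(n_p / vol, n_blocks)
    rho_r, _ = block_stats(n_r / vol, n_blocks)
    return BondReport(
        n_b=m_nb,
        n_bP=m_nbP,
        n_bR=m_nbR,
        n_bPP=m_nbPP,
        n_bPR=m_nbPR,
        rho_P=rho_p,
        rho_R=rho_r,
        r_fraction=rho_r / (rho_p + rho_r),
        se_n_b=se_nb,
        se_n_bP=se_nbP,
        se_n_bR=se_nbR,
        n_samples=len(samples),
    )


def dilute_limit_bonds_per_R(reports: dict[float, BondReport]) -> float:
    """Bonds per regulator in the dilute-R limit, extrapolated to X -> 0.

    A single R surrounded by pure P cannot be simulated directly in a
    mixture run, so ``n_b;R`` is measured at the smallest available
    regulator-to-protein ratios and extrapolated linearly in X to zero.
    """
    xs = sorted(x for x in reports if np.isfinite(reports[x].n_bR))
    if len(xs) < 2:
        raise ValueError("need n_b;R at >= 2 ratios to extrapolate to X = 0")
    x = np.array(xs[:3])
    y = np.array([reports[v].n_bR for v in xs[:3]])
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept)


def clusters_to_json(clusters: list[dict], config: Configuration,
                     params: ModelParams) -> str:
    """Bond-graph components as a JSON adjacency-list document.

    Intended for external rendering tools: per component the member ids and
    species composition, plus the global adjacency list of bonded pairs.
    """
    import json

    adjacency: dict[int, list[int]] = {i: [] for i in range(len(config))}
    for i, j in bond_pairs(config, params):
        adjacency[i].append(j)
        adjacency[j].append(i)
    doc = {
        "n_particles": len(config),
        "species": ["PR"[int(s)] for s in config.species],
        "adjacency": {str(k): sorted(v) for k, v in adjacency.items()},
        "components": [
            {"members": c["members"], "n_P": c["n_P"], "n_R": c["n_R"]}
            for c in clusters
        ],
    }
    return json.dumps(doc, indent=1)
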