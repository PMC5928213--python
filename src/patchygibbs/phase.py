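"""Coexistence densities, binodals, tie lines and critical-point fits.

Phase labels are assigned per sample: whichever box currently has the higher
total number density is the dense phase II, the other the dilute phase I.
Labeling per sample (rather than by box index) is robust against the two
Gibbs boxes swapping identities during a long run.

The critical point is located from a binodal with the law of rectilinear
diameters plus an Ising-like width scaling with fixed exponent 0.32:

    (rho_I + rho_II) / 2 = rho_c + A (T - T_c)
    rho_II - rho_I       = B (T_c - T)^0.32

fitted with an iterative pruning of the temperatures nearest T_c until the
fitted T_c is stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .bonds import block_stats

__all__ = [
    "BinodalPoint",
    "CriticalFit",
    "NoCoexistenceError",
    "label_phases",
    "fit_critical_point",
    "threshold_ratio",
    "tie_lines",
]

CRITICAL_EXPONENT = 0.32  # fixed, never fitted


class NoCoexistenceError(RuntimeError):
    """Raised when a sample stream shows no resolvable two-phase split."""


@dataclass
class BinodalPoint:
    """Coexistence densities at one temperature (labels: I dilute, II dense)."""

    temperature: float
    rho_P_I: float
    rho_P_II: float
    rho_R_I: float = 0.0
    rho_R_II: float = 0.0
    se_rho_P_I: float = float("nan")
    se_rho_P_II: float = float("nan")
    se_rho_R_I: float = float("nan")
    se_rho_R_II: float = float("nan")
    fraction_unseparated: float = 0.0


@dataclass
class CriticalFit:
    """Critical point from the rectilinear-diameter fit."""

    t_c: float
    rho_P_c: float
    a: float
    b: float
    included_temperatures: list[float] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)


def label_phases(
    samples: pd.DataFrame,
    temperature: float,
    n_blocks: int = 10,
    max_unseparated: float = 0.5,
) -> tuple[pd.DataFrame, BinodalPoint]:
    """Per-sample dilute/dense assignment and the averaged coexistence point.

    Each sample's denser box (by total number density) becomes phase II.
    Samples whose total-density gap is below twice the pooled spread of the
    two branches are flagged near-critical/unseparated; if more than
    ``max_unseparated`` of samples are flagged, :class:`NoCoexistenceError`
    is raised.
    """
    rho_a = ((samples["n_P_a"] + samples["n_R_a"]) / samples["volume_a"]).to_numpy()
    rho_b = ((samples["n_P_b"] + samples["n_R_b"]) / samples["volume_b"]).to_numpy()
    dense_is_b = rho_b > rho_a

    def pick(col: str, dense: bool) -> np.ndarray:
        a = samples[f"{col}_a"].to_numpy()
        b = samples[f"{col}_b"].to_numpy()
        return np.where(dense_is_b == dense, b, a)

    out = pd.DataFrame(
        {
            "cycle": samples["cycle"].to_numpy(),
            "rho_tot_I": np.where(dense_is_b, rho_a, rho_b),
            "rho_tot_II": np.where(dense_is_b, rho_b, rho_a),
        }
    )
    for sp in ("P", "R"):
        nn_I = pick(f"n_{sp}", dense=False)
        nn_II = pick(f"n_{sp}", dense=True)
        v_I = pick("volume", dense=False)
        v_II = pick("volume", dense=True)
        out[f"rho_{sp}_I"] = nn_I / v_I
        out[f"rho_{sp}_II"] = nn_II / v_II

    gap = out["rho_tot_II"] - out["rho_tot_I"]
    pooled = math.sqrt(
        np.var(out["rho_tot_I"], ddof=1) + np.var(out["rho_tot_II"], ddof=1)
    )
    out["unseparated"] = gap < 2.0 * pooled
    frac = float(out["unseparated"].mean())
    if frac > max_unseparated:
        raise NoCoexistenceError(
            f"{100 * frac:.0f}% of samples show no two-phase density gap "
            f"(T = {temperature} likely at or above the critical point)"
        )

    stats = {}
    for col in ("rho_P_I", "rho_P_II", "rho_R_I", "rho_R_II"):
        stats[col] = block_stats(out[col].to_numpy(), n_blocks)
    point = BinodalPoint(
        temperature=float(temperature),
        rho_P_I=stats["rho_P_I"][0],
        rho_P_II=stats["rho_P_II"][0],
        rho_R_I=stats["rho_R_I"][0],
        rho_R_II=stats["rho_R_II"][0],
        se_rho_P_I=stats["rho_P_I"][1],
        se_rho_P_II=stats["rho_P_II"][1],
        se_rho_R_I=stats["rho_R_I"][1],
        se_rho_R_II=stats["rho_R_II"][1],
        fraction_unseparated=frac,
    )
    return out, point


def _fit_once(t: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> tuple[float, float, float, float, float]:
    """One joint fit: width law first (T_c, B), then the linear diameter.

    The nonlinear width fit uses multistart over T_c in (max T, max T + 0.15]
    to avoid the boundary minimum at T_c -> max T.
    """
    width = hi - lo
    mean = 0.5 * (hi + lo)
    t_max = float(np.max(t))

    def resid(p):
        t_c, log_b = p
        dt = np.maximum(t_c - t, 1e-12)
        return math.exp(log_b) * dt**CRITICAL_EXPONENT - width

    best = None
    for dt0 in (0.01, 0.03, 0.06, 0.10, 0.15):
        w_ref = float(np.max(width))
        b0 = math.log(max(w_ref / dt0**CRITICAL_EXPONENT, 1e-8))
        try:
            sol = least_squares(
                resid,
                x0=np.array([t_max + dt0, b0]),
                bounds=([t_max + 1e-9, -30.0], [t_max + 0.15, 30.0]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:
            continue
        cost = float(np.sum(sol.fun**2))
        if best is None or cost < best[0]:
            best = (cost, sol)
    if best is None:
        raise RuntimeError("width-law fit failed to converge from any start")
    cost, sol = best
    t_c = float(sol.x[0])
    b = math.exp(float(sol.x[1]))
    # linear rectilinear-diameter fit given T_c
    coef = np.polyfit(t - t_c, mean, 1)
    a = float(coef[0])
    rho_c = float(coef[1])
    return t_c, rho_c, a, b, cost


def fit_critical_point(
    binodal: list[BinodalPoint],
    delta_t_c_tol: float = 0.002,
    min_points: int = 4,
) -> CriticalFit:
    """Critical point by rectilinear-diameter fitting with pruning.

    Fits all points, then repeatedly drops the highest temperature (the point
    nearest the critical region, where the rectilinear law is least reliable)
    and refits, stopping when successive T_c estimates agree to
    ``delta_t_c_tol`` or only ``min_points`` temperatures remain.
    """
    pts = sorted(binodal, key=lambda p: p.temperature)
    if len(pts) < min_points:
        raise ValueError(f"need at least {min_points} binodal points")
    t = np.array([p.temperature for p in pts])
    lo = np.array([p.rho_P_I for p in pts])
    hi = np.array([p.rho_P_II for p in pts])

    trace = []
    n = len(pts)
    prev_tc = None
    result = None
    while n >= min_points:
        t_c, rho_c, a, b, cost = _fit_once(t[:n], lo[:n], hi[:n])
        trace.append(
            {
                "n_points": n,
                "t_c": t_c,
                "rho_P_c": rho_c,
                "A": a,
                "B": b,
                "cost": cost,
            }
        )
        result = CriticalFit(
            t_c=t_c,
            rho_P_c=rho_c,
            a=a,
            b=b,
            included_temperatures=[float(x) for x in t[:n]],
            trace=trace,
        )
        if prev_tc is not None and abs(t_c - prev_tc) < delta_t_c_tol:
            break
        prev_tc = t_c
        n -= 1
    return result


def threshold_ratio(
    reference: BinodalPoint, mixture: BinodalPoint
) -> tuple[float, float]:
    """Ratio of threshold P concentrations, pure system over mixture.

    Both points must be at the same temperature.  A ratio > 1 means the
    regulator lowers the threshold for droplet formation (promotes LLPS);
    < 1 means suppression.  Returns (ratio, propagated standard error).
    """
    if abs(reference.temperature - mixture.temperature) > 1e-9:
        raise ValueError("threshold ratio requires matching temperatures")
    if mixture.rho_P_I <= 0 or reference.rho_P_I <= 0:
        raise ValueError("undefined threshold ratio: a branch has zero density")
    ratio = reference.rho_P_I / mixture.rho_P_I
    rel = 0.0
    if np.isfinite(reference.se_rho_P_I):
        rel += (reference.se_rho_P_I / reference.rho_P_I) ** 2
    if np.isfinite(mixture.se_rho_P_I):
        rel += (mixture.se_rho_P_I / mixture.rho_P_I) ** 2
    return float(ratio), float(ratio * math.sqrt(rel))


def tie_lines(points: dict[float, BinodalPoint]) -> pd.DataFrame:
    """Tie-line endpoints over an X grid at fixed temperature.

    ``points`` maps the regulator-to-protein ratio X to the labeled
    coexistence point.  The slope sign says where the regulator partitions:
    negative (rho_R^I > rho_R^II) means it prefers the dilute phase, positive
    the droplet phase.
    """
    rows = []
    for x in sorted(points):
        p = points[x]
        d_rho_p = p.rho_P_II - p.rho_P_I
        d_rho_r = p.rho_R_II - p.rho_R_I
        slope = d_rho_r / d_rho_p if d_rho_p != 0 else float("nan")
        rows.append(
            {
                "X": x,
                "temperature": p.temperature,
                "rho_P_I": p.rho_P_I,
                "rho_R_I": p.rho_R_I,
                "rho_P_II": p.rho_P_II,
                "rho_R_II": p.rho_R_II,
                "se_rho_P_I": p.se_rho_P_I,
                "se_rho_P_II": p.se_rho_P_II,
                "se_rho_R_I": p.se_rho_R_I,
                "se_rho_R_II": p.se_rho_R_II,
                "slope": slope,
                "slope_sign": int(np.sign(slope)) if np.isfinite(slope) else 0,
            }
        )
    return pd.DataFrame(rows)
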