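"""Ligand-binding thermodynamics: CSPs, two-state K_D fits and the
four-state UTP / metal / protein equilibrium.

Paramagnetic observables are only produced by the ternary UTP:metal:protein
(UMP) complex, while free metal above ~80 uM causes unspecific broadening.
Planning a paramagnetic sample therefore needs the coupled equilibria

    U + M  <->  UM    (K_D1)        U + P  <->  UP    (K_D2)
    UM + P <->  UMP   (K_D3)        UP + M <->  UMP   (K_D4)

which form a thermodynamic cycle, K_D1 * K_D3 = K_D2 * K_D4.  Given total
concentrations the three free species (P, U, M) follow from mass balance:

    P + UP + UMP = P_t
    U + UP + UM + UMP = U_t
    M + UM + UMP = M_t

with UP = P U / K_D2, UM = U M / K_D1, UMP = P U M / (K_D2 K_D4).  The
solver is a damped Newton iteration on the logarithms of the free
concentrations (guaranteeing positivity) with a nested-bisection fallback.

Dissociation constants for the system studied here (UTP + LmUGP + di- or
trivalent metals) ship as ``TABLE1``; missing constants are filled through
the cycle, and metals whose UTP affinity could not be measured (Tb, Tm) use
the mean of the measured lanthanide K_D1 values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .peaks import TitrationSeries

__all__ = [
    "FourStateConstants",
    "SpeciesConcentrations",
    "KdFitResult",
    "TABLE1",
    "lanthanide_mean_kd1",
    "euclidean_csp",
    "two_state_isotherm",
    "fit_kd_global",
    "kd4_from_cycle",
    "solve_four_state",
    "plan_sample",
    "lanthanide_pcs_constants",
    "mn_pre_constants",
]


@dataclass(frozen=True)
class FourStateConstants:
    """K_D1..K_D4 in uM with per-constant provenance.

    Any one of K_D3 / K_D4 may be omitted and is filled via the cycle
    K_D1 * K_D3 = K_D2 * K_D4.  When all four are given and the cycle does
    not close (e.g. a K_D3 borrowed from another metal), the given K_D4
    governs UMP formation and the deviation is reported by
    ``cycle_deviation``.
    """

    kd1: float
    kd2: float
    kd3: float | None = None
    kd4: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in (("kd1", self.kd1), ("kd2", self.kd2)):
            if v is None or v <= 0:
                raise ValueError(f"{name} must be a positive concentration")
        if self.kd3 is None and self.kd4 is None:
            raise ValueError("need at least one of kd3 / kd4")
        for name, v in (("kd3", self.kd3), ("kd4", self.kd4)):
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")

    @property
    def kd3_eff(self) -> float:
        return self.kd3 if self.kd3 is not None else self.kd2 * self.kd4 / self.kd1

    @property
    def kd4_eff(self) -> float:
        return self.kd4 if self.kd4 is not None else kd4_from_cycle(self.kd1, self.kd2, self.kd3)

    def cycle_deviation(self) -> float | None:
        """Relative deviation of K_D1*K_D3 from K_D2*K_D4 (None if underspecified)."""
        if self.kd3 is None or self.kd4 is None:
            return None
        lhs, rhs = self.kd1 * self.kd3, self.kd2 * self.kd4
        return abs(lhs - rhs) / rhs


@dataclass
class SpeciesConcentrations:
    """Equilibrium species (uM) plus the totals they must conserve."""

    p: float
    u: float
    m: float
    up: float
    um: float
    ump: float
    p_total: float
    u_total: float
    m_total: float

    @property
    def fraction_ump(self) -> float:
        return self.ump / self.p_total

    @property
    def free_metal(self) -> float:
        return self.m

    def residuals(self) -> np.ndarray:
        scale = np.array([max(self.p_total, 1e-12), max(self.u_total, 1e-12),
                          max(self.m_total, 1e-12)])
        res = np.array(
            [
                self.p + self.up + self.ump - self.p_total,
                self.u + self.up + self.um + self.ump - self.u_total,
                self.m + self.um + self.ump - self.m_total,
            ]
        )
        return res / scale


# --- Dissociation constants (uM) for UTP + LmUGP + metals.  K_D1: metal-UTP;
# K_D2: UTP-protein; K_D3: UTP-protein at metal saturation; K_D4: metal-(UTP:protein).
# Tb/Tm K_D1 unmeasurable (strong PREs): filled with the measured-lanthanide mean.
# Mn K_D2/K_D3 borrowed from Mg (high Mn broadens spectra beyond detection).
TABLE1: dict[str, dict] = {
    "Mg": {"kd1": 82.0, "kd2": 155.0, "kd3": 115.0, "kd4": None,
           "provenance": {"kd1": "measured (ITC: 70)", "kd2": "measured", "kd3": "measured"}},
    "La": {"kd1": 11.0, "kd2": 152.0, "kd3": None, "kd4": 15.0,
           "provenance": {"kd1": "measured", "kd2": "measured", "kd4": "approximated"}},
    "Lu": {"kd1": 38.0, "kd2": 138.0, "kd3": None, "kd4": 46.0,
           "provenance": {"kd1": "measured", "kd2": "measured", "kd4": "approximated"}},
    "Eu": {"kd1": 28.0, "kd2": 112.0, "kd3": 152.0, "kd4": 38.0,
           "provenance": {"kd1": "measured", "kd2": "measured", "kd3": "measured",
                          "kd4": "cycle-derived"}},
    "Ce": {"kd1": 13.0, "kd2": 147.0, "kd3": None, "kd4": 17.0,
           "provenance": {"kd1": "measured", "kd2": "measured", "kd4": "approximated"}},
    "Tb": {"kd1": None, "kd2": 149.0, "kd3": None, "kd4": 30.0,
           "provenance": {"kd1": "lanthanide mean", "kd2": "measured", "kd4": "approximated"}},
    "Tm": {"kd1": None, "kd2": 154.0, "kd3": None, "kd4": 30.0,
           "provenance": {"kd1": "lanthanide mean", "kd2": "measured", "kd4": "approximated"}},
    "Mn": {"kd1": 77.0, "kd2": 155.0, "kd3": 115.0, "kd4": 107.0,
           "provenance": {"kd1": "measured", "kd2": "borrowed from Mg",
                          "kd3": "borrowed from Mg", "kd4": "approximated"}},
}

LANTHANIDES = ("La", "Lu", "Ce", "Eu", "Tb", "Tm")


def lanthanide_mean_kd1() -> float:
    """Mean of the measured lanthanide metal-UTP K_D1 values (uM)."""
    vals = [TABLE1[m]["kd1"] for m in LANTHANIDES if TABLE1[m]["kd1"] is not None]
    return float(np.mean(vals))


def constants_for(metal: str) -> FourStateConstants:
    """Four-state constants for one metal, filling Tb/Tm K_D1 from the mean."""
    row = TABLE1[metal]
    kd1 = row["kd1"] if row["kd1"] is not None else lanthanide_mean_kd1()
    return FourStateConstants(
        kd1=kd1, kd2=row["kd2"], kd3=row["kd3"], kd4=row["kd4"],
        provenance=row["provenance"],
    )


def euclidean_csp(dnu_h: float | np.ndarray, dnu_c: float | np.ndarray) -> np.ndarray:
    """Euclidean chemical shift perturbation sqrt(dH^2 + dC^2), Hz."""
    return np.sqrt(np.asarray(dnu_h, float) ** 2 + np.asarray(dnu_c, float) ** 2)


def two_state_isotherm(
    p_t: float, l_t: float | np.ndarray, kd: float, dnu_max: float | np.ndarray = 1.0
) -> np.ndarray:
    """Fast-exchange CSP for P + L <-> PL (closed-form quadratic root).

    Returns dnu_obs = [ (P_t + L_t + K_D) - sqrt((P_t + L_t + K_D)^2
    - 4 P_t L_t) ] / (2 P_t) * dnu_max.
    """
    if p_t <= 0:
        raise ValueError("p_t must be positive")
    l_t = np.asarray(l_t, float)
    s = p_t + l_t + kd
    frac = (s - np.sqrt(s**2 - 4.0 * p_t * l_t)) / (2.0 * p_t)
    return frac * np.asarray(dnu_max, float)


@dataclass
class KdFitResult:
    kd: float  # uM
    kd_sd: float
    dnu_max: dict[str, float]  # Hz per selected peak
    p_t: float
    selected_peaks: list[str]
    csp_table: pd.DataFrame


def _series_csps(series: TitrationSeries) -> pd.DataFrame:
    """Per-trajectory euclidean CSP (Hz) relative to point 0 at every point."""
    if not series.trajectories:
        raise ValueError("series has no tracked trajectories")
    p0 = series.peak_lists[0].set_index("peak_id")
    rows = []
    for tid, chain in series.trajectories.items():
        for k, pid in enumerate(chain):
            if pid is None:
                continue
            pk = series.peak_lists[k].set_index("peak_id")
            dh = (pk.at[pid, "delta_H"] - p0.at[tid, "delta_H"]) * series.spectrometer_mhz
            dc = (pk.at[pid, "delta_C"] - p0.at[tid, "delta_C"]) * (
                series.spectrometer_mhz * 0.25143  # gamma_C / gamma_H
            )
            rows.append(
                {"trajectory": tid, "point": k, "ligand_total": series.ligand_total[k],
                 "protein_total": series.protein_total[k],
                 "csp_hz": float(euclidean_csp(dh, dc))}
            )
    return pd.DataFrame(rows)


def fit_kd_global(
    series: TitrationSeries,
    mc_iterations: int = 1000,
    noise_hz: float | None = None,
    seed: int = 0,
    selected_peaks: list[str] | None = None,
) -> KdFitResult:
    """Global two-state K_D fit over the strongest titration curves.

    Curves are selected at the highest ligand point: CSPs larger than
    mean + 2 SD of all CSPs (the selection used for the printed constants);
    pass ``selected_peaks`` to override.  One shared K_D and a per-peak
    dnu_max are fitted by nonlinear least squares; the SD is one standard
    deviation over Monte-Carlo refits with Gaussian shift noise (defaults to
    the residual RMS when ``noise_hz`` is None).
    """
    if series.n_points < 4:
        raise ValueError("need at least 4 titration points")
    table = _series_csps(series)
    last = table[table["point"] == table["point"].max()]
    if selected_peaks is None:
        thresh = last["csp_hz"].mean() + 2.0 * last["csp_hz"].std(ddof=0)
        selected_peaks = sorted(last.loc[last["csp_hz"] > thresh, "trajectory"])
        if not selected_peaks:
            raise ValueError(
                "no curve passes the mean + 2 SD selection; pass selected_peaks explicitly"
            )
    sel = table[table["trajectory"].isin(selected_peaks)]
    p_t = float(np.mean(series.protein_total))
    peaks = list(selected_peaks)
    idx = {p: i for i, p in enumerate(peaks)}
    lt = sel["ligand_total"].to_numpy(float)
    y = sel["csp_hz"].to_numpy(float)
    which = sel["trajectory"].map(idx).to_numpy(int)

    def model(params: np.ndarray, yy: np.ndarray) -> np.ndarray:
        kd = params[0]
        dmax = params[1:]
        frac = two_state_isotherm(p_t, lt, abs(kd))
        return frac * dmax[which] - yy

    dmax0 = np.array(
        [last.loc[last["trajectory"] == p, "csp_hz"].iloc[0] for p in peaks]
    )
    x0 = np.concatenate([[100.0], dmax0])
    res = least_squares(model, x0, args=(y,), method="lm", max_nfev=10000)
    kd_fit = abs(float(res.x[0]))
    resid = model(res.x, y)
    sigma = noise_hz if noise_hz is not None else float(np.sqrt(np.mean(resid**2)))
    rng = np.random.default_rng(seed)
    draws = []
    if mc_iterations > 1 and sigma > 0:
        for _ in range(mc_iterations):
            yk = y + rng.normal(0.0, sigma, size=y.shape)
            rk = least_squares(model, res.x, args=(yk,), method="lm", max_nfev=10000)
            draws.append(abs(float(rk.x[0])))
    kd_sd = float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0
    return KdFitResult(
        kd=kd_fit,
        kd_sd=kd_sd,
        dnu_max=dict(zip(peaks, res.x[1:])),
        p_t=p_t,
        selected_peaks=peaks,
        csp_table=table,
    )


def kd4_from_cycle(kd1: float, kd2: float, kd3: float) -> float:
    """Close the thermodynamic cycle: K_D4 = K_D1 * K_D3 / K_D2 (uM)."""
    if min(kd1, kd2, kd3) <= 0:
        raise ValueError("constants must be positive")
    return kd1 * kd3 / kd2


def _species(free: np.ndarray, c: FourStateConstants) -> tuple[float, float, float]:
    p, u, m = free
    up = p * u / c.kd2
    um = u * m / c.kd1
    ump = p * u * m / (c.kd2 * c.kd4_eff)
    return up, um, ump


def solve_four_state(
    constants: FourStateConstants,
    p_total: float,
    u_total: float,
    m_total: float,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> SpeciesConcentrations:
    """Solve the three mass balances for the free concentrations.

    Damped Newton on log(P, U, M) (keeps every species positive), starting
    from the nested-bisection profile; raises with the residuals if the
    iteration stalls above ``tol`` (relative).
    """
    if min(p_total, u_total) <= 0 or m_total < 0:
        raise ValueError("totals must be positive (metal may be zero)")
    if m_total == 0:
        sol = _solve_pm_fixed(constants, p_total, u_total, 0.0)
        return sol
    x = np.log(_bisection_start(constants, p_total, u_total, m_total))
    totals = np.array([p_total, u_total, m_total])

    def resid(logf: np.ndarray) -> np.ndarray:
        p, u, m = np.exp(logf)
        up, um, ump = _species(np.exp(logf), constants)
        return (
            np.array([p + up + ump, u + up + um + ump, m + um + ump]) - totals
        ) / totals

    for _ in range(max_iter):
        r = resid(x)
        if np.max(np.abs(r)) < tol:
            break
        # analytic Jacobian wrt log-free concentrations
        p, u, m = np.exp(x)
        up, um, ump = _species(np.exp(x), constants)
        j = np.array(
            [
                [p + up + ump, up + ump, ump],
                [up + ump, u + up + um + ump, um + ump],
                [ump, um + ump, m + um + ump],
            ]
        ) / totals[:, None]
        try:
            step = np.linalg.solve(j, -r)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        base = np.max(np.abs(r))
        while lam > 1e-6:
            if np.max(np.abs(resid(x + lam * step))) < base:
                x = x + lam * step
                break
            lam /= 2.0
        else:
            break
    p, u, m = np.exp(x)
    up, um, ump = _species(np.exp(x), constants)
    sol = SpeciesConcentrations(p, u, m, up, um, ump, p_total, u_total, m_total)
    if np.max(np.abs(sol.residuals())) > 1e-9:
        raise RuntimeError(
            f"four-state solver did not converge; residuals {sol.residuals()}"
        )
    return sol


def _solve_pm_fixed(
    constants: FourStateConstants, p_total: float, u_total: float, m: float
) -> SpeciesConcentrations:
    """Closed-form P/U equilibrium at a fixed free-metal concentration.

    With M fixed, UP + UMP is a single effective two-state complex with
    K_eff = K_D2 / (1 + M / K_D4) and the ligand partitions as
    U_free_total = U (1 + M / K_D1); the quadratic root gives the complex.
    """
    a = 1.0 + m / constants.kd1 if m > 0 else 1.0
    k_eff = constants.kd2 / (1.0 + m / constants.kd4_eff)
    s = p_total + u_total + a * k_eff
    c_tot = (s - np.sqrt(s**2 - 4.0 * p_total * u_total)) / 2.0
    p = p_total - c_tot
    u = (u_total - c_tot) / a
    up = p * u / constants.kd2
    um = u * m / constants.kd1
    ump = p * u * m / (constants.kd2 * constants.kd4_eff)
    m_total = m + um + ump
    return SpeciesConcentrations(p, u, m, up, um, ump, p_total, u_total, m_total)


def _bisection_start(
    constants: FourStateConstants, p_total: float, u_total: float, m_total: float
) -> np.ndarray:
    """Nested bisection on free M: outer root of the metal balance."""

    def metal_balance(m: float) -> float:
        sol = _solve_pm_fixed(constants, p_total, u_total, m)
        return sol.m_total - m_total

    lo, hi = 0.0, m_total
    if metal_balance(hi) < 0:  # numerically impossible, but stay safe
        return np.array([p_total, u_total, m_total])
    m = brentq(metal_balance, max(lo, 1e-15 * m_total), hi, xtol=1e-12, rtol=1e-14)
    sol = _solve_pm_fixed(constants, p_total, u_total, m)
    return np.array([max(sol.p, 1e-30), max(sol.u, 1e-30), max(sol.m, 1e-30)])


def plan_sample(
    constants: FourStateConstants,
    p_total: float,
    u_total: float,
    m_grid: np.ndarray,
    occupancy_target: float | None = None,
    free_metal_ceiling: float = 80.0,
) -> tuple[pd.DataFrame, dict]:
    """Occupancy and free-metal curves over a total-metal grid.

    Recommends the largest M_t whose free metal stays below the ceiling and
    reports the occupancy achieved there; when an ``occupancy_target`` is
    given and unreachable under the ceiling, the best achievable point is
    reported with ``target_reached=False``.
    """
    m_grid = np.asarray(m_grid, float)
    if m_grid.size == 0:
        raise ValueError("metal grid is empty")
    rows = []
    for m_t in np.sort(m_grid):
        sol = solve_four_state(constants, p_total, u_total, float(m_t))
        rows.append(
            {"m_total": float(m_t), "fraction_ump": sol.fraction_ump,
             "free_metal": sol.free_metal}
        )
    curve = pd.DataFrame(rows)
    ok = curve[curve["free_metal"] <= free_metal_ceiling]
    if ok.empty:
        rec = curve.iloc[0]
        reached = False
    else:
        rec = ok.iloc[-1]
        reached = (
            occupancy_target is None or rec["fraction_ump"] >= occupancy_target
        )
    recommendation = {
        "m_total": float(rec["m_total"]),
        "fraction_ump": float(rec["fraction_ump"]),
        "free_metal": float(rec["free_metal"]),
        "target_reached": bool(reached),
    }
    return curve, recommendation


def lanthanide_pcs_constants() -> dict[str, FourStateConstants]:
    """Constants for the six lanthanide PCS samples."""
    return {m: constants_for(m) for m in LANTHANIDES}


def mn_pre_constants() -> FourStateConstants:
    """Constants for the Mn2+ PRE sample (K_D2/K_D3 borrowed from Mg)."""
    return constants_for("Mn")
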