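"""Pseudocontact shifts and anisotropic susceptibility (dchi) tensors.

A paramagnetic lanthanide bound near the protein shifts every nucleus by an
amount that depends on the metal-nucleus vector and the anisotropy of the
magnetic susceptibility: in the metal frame

    delta_pcs = (1 / 4 pi r^5) * [x^2-z^2, y^2-z^2, 2xy, 2xz, 2yz] . dchi5

where dchi5 = (dchi_xx, dchi_yy, dchi_xy, dchi_xz, dchi_yz) are the five
independent components of the traceless susceptibility-anisotropy tensor
(dchi_zz = -dchi_xx - dchi_yy).  The expression is linear in the five
components, so tensor fitting at a fixed metal position is a linear solve;
releasing the metal position adds three nonlinear coordinates.

Working units: tensor components in 1e-32 m^3, coordinates in Angstrom,
shifts in ppm internally (Hz at I/O given a 1H spectrometer frequency).
Only 1H shifts enter fits; 13C shifts may be stored but are never fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .structures import EnsembleStructure

__all__ = [
    "DchiTensor",
    "UTRTensor",
    "PCSDataset",
    "FitReport",
    "pcs_from_shifts",
    "calc_pcs",
    "fit_tensor",
    "to_utr",
    "bootstrap_tensor",
    "q_factor",
    "opposite_orientation",
    "expand_assignment_pcs",
]

# 1e6 (ppm) * 1e-32 (tensor unit, m^3) * 1e-20 (Angstrom^2 -> m^2)
# / (4 pi * (1e-10)^5 (Angstrom^5 -> m^5))  ==  1e4 / (4 pi)
_PPM_PREFACTOR = 1e4 / (4.0 * np.pi)


@dataclass
class DchiTensor:
    """Five-component traceless dchi tensor plus the metal position.

    ``components`` = (xx, yy, xy, xz, yz) in 1e-32 m^3; ``metal_position``
    in Angstrom.
    """

    components: np.ndarray
    metal_position: np.ndarray

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, float)
        self.metal_position = np.asarray(self.metal_position, float)
        if self.components.shape != (5,):
            raise ValueError("components must be (xx, yy, xy, xz, yz)")
        if not np.all(np.isfinite(self.components)):
            raise ValueError("non-finite tensor components")

    def matrix(self) -> np.ndarray:
        """Full traceless symmetric 3x3 form."""
        xx, yy, xy, xz, yz = self.components
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, -xx - yy]])


@dataclass
class UTRTensor:
    """Unique tensor representation: principal values + eigenframe Euler angles."""

    dchi_ax: float  # 1e-32 m^3
    dchi_rh: float
    alpha: float  # degrees, ZYZ
    beta: float
    gamma: float
    eigenvalues: np.ndarray = field(default_factory=lambda: np.zeros(3))
    degenerate: bool = False


@dataclass
class PCSDataset:
    """Observed PCS values keyed by methyl (or unassigned-peak) id.

    ``observations`` columns: key, pcs_ppm, error_ppm.  ``spectrometer_mhz``
    converts between ppm and Hz; metadata labels record which samples the
    differences came from.
    """

    observations: pd.DataFrame
    spectrometer_mhz: float = 500.0
    paramagnetic_label: str = ""
    diamagnetic_label: str = ""

    @property
    def pcs_hz(self) -> pd.Series:
        return self.observations["pcs_ppm"] * self.spectrometer_mhz

    def subset(self, idx: np.ndarray) -> "PCSDataset":
        return PCSDataset(
            self.observations.iloc[idx].reset_index(drop=True),
            self.spectrometer_mhz,
            self.paramagnetic_label,
            self.diamagnetic_label,
        )


@dataclass
class FitReport:
    q: float
    residuals: pd.DataFrame
    bootstrap_sd: dict | None = None
    metal_position_sd: float | None = None


def pcs_from_shifts(
    dia_peaks: pd.DataFrame,
    para_peaks: pd.DataFrame,
    peak_map: dict[str, str],
    spectrometer_mhz: float = 500.0,
    paramagnetic_label: str = "",
    diamagnetic_label: str = "",
) -> tuple[PCSDataset, list[str]]:
    """PCS = delta(1H)_para - delta(1H)_dia for mapped peak pairs (ppm).

    Unmatched peaks are returned in the second element, never fabricated.
    """
    dia = dia_peaks.set_index("peak_id")
    para = para_peaks.set_index("peak_id")
    rows, unmatched = [], []
    for d_id, p_id in peak_map.items():
        if d_id not in dia.index or p_id not in para.index:
            unmatched.append(d_id)
            continue
        rows.append(
            {
                "key": d_id,
                "pcs_ppm": float(para.at[p_id, "delta_H"] - dia.at[d_id, "delta_H"]),
                "error_ppm": 0.0,
            }
        )
    unmatched += [p for p in dia.index if p not in peak_map]
    ds = PCSDataset(
        pd.DataFrame(rows, columns=["key", "pcs_ppm", "error_ppm"]),
        spectrometer_mhz,
        paramagnetic_label,
        diamagnetic_label,
    )
    return ds, unmatched


def calc_pcs(tensor: DchiTensor, positions: np.ndarray) -> np.ndarray:
    """Evaluate the PCS field (ppm) at nuclear positions (Angstrom).

    ``positions`` is (..., 3); raises on zero metal-nucleus distance.
    """
    pos = np.asarray(positions, float)
    rel = pos - tensor.metal_position
    r2 = (rel**2).sum(-1)
    if np.any(r2 == 0):
        raise ValueError("nucleus coincides with the metal position")
    x, y, z = rel[..., 0], rel[..., 1], rel[..., 2]
    design = np.stack([x**2 - z**2, y**2 - z**2, 2 * x * y, 2 * x * z, 2 * y * z], axis=-1)
    return _PPM_PREFACTOR * (design @ tensor.components) / r2**2.5


def _ensemble_coords(ensemble: EnsembleStructure, keys: list[str]) -> np.ndarray:
    missing = [k for k in keys if k not in ensemble.common_atoms]
    if missing:
        raise KeyError(f"observation keys not in ensemble: {missing[:5]}")
    return ensemble.coordinates(keys)  # (n_models, n_keys, 3)


def _mean_calc(tensor: DchiTensor, coords: np.ndarray) -> np.ndarray:
    """Model-averaged calculated PCS per key (ppm)."""
    return calc_pcs(tensor, coords).mean(axis=0)


def fit_tensor(
    dataset: PCSDataset,
    ensemble: EnsembleStructure,
    init_metal: np.ndarray,
    move_metal: bool = True,
) -> tuple[DchiTensor, FitReport]:
    """Least-squares dchi tensor fit, optionally releasing the metal position.

    The five components enter linearly, so at any metal position they are
    obtained by a linear solve; when ``move_metal`` the three coordinates are
    refined jointly by nonlinear least squares around that inner solve.
    Calculated values are model-averaged over the ensemble.
    """
    obs = dataset.observations
    n_par = 8 if move_metal else 5
    if len(obs) < n_par:
        raise ValueError(f"underdetermined fit: {len(obs)} observations < {n_par} parameters")
    keys = list(obs["key"])
    y = obs["pcs_ppm"].to_numpy(float)
    coords = _ensemble_coords(ensemble, keys)

    def design_at(metal: np.ndarray) -> np.ndarray:
        rel = coords - metal  # (M, N, 3)
        r2 = (rel**2).sum(-1)
        x, yy, z = rel[..., 0], rel[..., 1], rel[..., 2]
        d = np.stack([x**2 - z**2, yy**2 - z**2, 2 * x * yy, 2 * x * z, 2 * yy * z], axis=-1)
        return _PPM_PREFACTOR * (d / r2[..., None] ** 2.5).mean(axis=0)  # (N, 5)

    def linear_solve(metal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a = design_at(metal)
        comp, *_ = np.linalg.lstsq(a, y, rcond=None)
        return comp, a @ comp - y

    metal = np.asarray(init_metal, float)
    if move_metal:
        # the r^-5 landscape has local minima; restart deterministically
        # around the initial guess and keep the best solution
        offsets = [np.zeros(3)] + [s * e for s in (3.0, -3.0) for e in np.eye(3)]
        best_x, best_cost = None, np.inf
        for off in offsets:
            res = least_squares(lambda p: linear_solve(p)[1], metal + off, method="lm")
            if res.cost < best_cost:
                best_x, best_cost = res.x, res.cost
        if best_x is None:
            raise RuntimeError("tensor fit did not converge from any start")
        metal = best_x
    comp, resid = linear_solve(metal)
    tensor = DchiTensor(components=comp, metal_position=metal)
    calc = _mean_calc(tensor, coords)
    q = q_factor(y, calc_pcs(tensor, coords))
    report = FitReport(
        q=q,
        residuals=pd.DataFrame({"key": keys, "obs_ppm": y, "calc_ppm": calc, "residual_ppm": y - calc}),
    )
    return tensor, report


def to_utr(tensor: DchiTensor) -> UTRTensor:
    """Unique tensor representation of the traceless 3x3 form.

    Eigenvalues ordered |zz| >= |yy| >= |xx|; dchi_ax = zz - (xx + yy)/2,
    dchi_rh = xx - yy; ZYZ Euler angles of the eigenframe in degrees.
    Near-degenerate eigenvalues flag the angles as undefined.
    """
    mat = tensor.matrix()
    vals, vecs = np.linalg.eigh(mat)
    order = np.argsort(np.abs(vals))  # xx, yy, zz by increasing magnitude
    vals = vals[order]
    vecs = vecs[:, order]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] *= -1
    scale = max(np.abs(vals).max(), 1e-300)
    degenerate = bool(
        np.isclose(np.abs(vals[2]), np.abs(vals[1]), rtol=1e-8, atol=1e-12 * scale)
        or np.isclose(np.abs(vals[1]), np.abs(vals[0]), rtol=1e-8, atol=1e-12 * scale)
    )
    ax = vals[2] - 0.5 * (vals[0] + vals[1])
    rh = vals[0] - vals[1]
    if degenerate:
        alpha = beta = gamma = float("nan")
    else:
        alpha, beta, gamma = Rotation.from_matrix(vecs).as_euler("ZYZ", degrees=True)
    return UTRTensor(
        dchi_ax=float(ax),
        dchi_rh=float(rh),
        alpha=float(alpha),
        beta=float(beta),
        gamma=float(gamma),
        eigenvalues=vals,
        degenerate=degenerate,
    )


def bootstrap_tensor(
    dataset: PCSDataset,
    ensemble: EnsembleStructure,
    init_metal: np.ndarray,
    move_metal: bool = True,
    iterations: int = 1000,
    sample_fraction: float = 0.8,
    seed: int = 0,
) -> dict:
    """Bootstrap SDs of the tensor parameters from random data subsets.

    Each iteration refits on ``sample_fraction`` of the observations drawn
    without replacement; underdetermined draws are skipped and counted.
    """
    if iterations < 2:
        raise ValueError("bootstrap needs at least 2 iterations for an SD")
    rng = np.random.default_rng(seed)
    n = len(dataset.observations)
    k = int(round(sample_fraction * n))
    comps, metals = [], []
    skipped = 0
    for _ in range(iterations):
        idx = rng.choice(n, size=k, replace=False)
        try:
            t, _ = fit_tensor(dataset.subset(idx), ensemble, init_metal, move_metal)
        except (ValueError, RuntimeError):
            skipped += 1
            continue
        comps.append(t.components)
        metals.append(t.metal_position)
    comps_arr = np.array(comps)
    metals_arr = np.array(metals)
    return {
        "component_sd": comps_arr.std(axis=0, ddof=1),
        "metal_sd_axes": metals_arr.std(axis=0, ddof=1),
        "metal_sd": float(np.sqrt(metals_arr.var(axis=0, ddof=1).sum())),
        "n_used": len(comps),
        "n_skipped": skipped,
    }


def q_factor(observed: np.ndarray, calculated: np.ndarray) -> float:
    """Ensemble Q factor.

    ``calculated`` may be (n_models, n_atoms) or (n_atoms,).  Per atom the
    numerator term is (sum_m [obs - calc_m])^2 and the denominator term is
    (sum_m obs)^2, so for a single model this reduces to the standard
    sqrt(sum (obs-calc)^2 / sum obs^2).
    """
    obs = np.asarray(observed, float)
    calc = np.atleast_2d(np.asarray(calculated, float))
    if calc.shape[-1] != obs.shape[0]:
        raise ValueError("observed/calculated key mismatch")
    n_models = calc.shape[0]
    num = ((n_models * obs - calc.sum(axis=0)) ** 2).sum()
    den = ((n_models * obs) ** 2).sum()
    if den == 0:
        raise ValueError("all observed values are zero")
    return float(np.sqrt(num / den))


def opposite_orientation(
    tensor_a: DchiTensor, tensor_b: DchiTensor, positions: np.ndarray
) -> bool:
    """True when the two predicted PCS fields anticorrelate over the probes."""
    fa = calc_pcs(tensor_a, positions)
    fb = calc_pcs(tensor_b, positions)
    if np.std(fa) == 0 or np.std(fb) == 0:
        raise ValueError("degenerate (constant) PCS field; orientation undefined")
    return bool(np.corrcoef(fa, fb)[0, 1] < 0)


def expand_assignment_pcs(
    consensus: pd.DataFrame,
    tensors: dict[str, DchiTensor],
    datasets: dict[str, "pd.DataFrame | object"],
    problem_factory,
    config,
    cutoffs: list[float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand a NOE-based consensus with PCS-restrained MMC runs.

    For each paramagnetic metal an MMC consensus is re-run with the PCS term
    active (weight ``config.w_pcs``) and the prior consistent assignments
    fixed; ``problem_factory(metal)`` must return the ready
    :class:`~methylwalk.assign.AssignmentProblem` carrying that metal's PCS
    penalties.  A new assignment is accepted only when at least two tensors
    of pairwise opposite orientation agree on it.  Prior assignments
    contradicted by a PCS run are reported, never deleted.

    Returns (augmented consensus, report of contradictions/rejections).
    """
    from dataclasses import replace as _replace

    from .assign import _run_consensus  # local import to avoid a cycle

    cutoffs = cutoffs or [config.cutoff]
    prior = dict(
        zip(
            consensus.loc[consensus["status"] == "consistent", "peak_id"],
            consensus.loc[consensus["status"] == "consistent", "residue"],
        )
    )
    metals = list(tensors)
    if len(metals) < 2:
        raise ValueError("PCS expansion needs at least two tensors")
    per_metal: dict[str, dict[str, str]] = {}
    contradictions = []
    for metal in metals:
        problem = problem_factory(metal)
        best: dict[str, str] = {}
        best_count = -1
        for c in cutoffs:
            cons = _run_consensus(problem, _replace(config, cutoff=c), prior)
            cmap = dict(
                zip(
                    cons.loc[cons["status"] == "consistent", "peak_id"],
                    cons.loc[cons["status"] == "consistent", "residue"],
                )
            )
            if len(cmap) > best_count:
                best, best_count = cmap, len(cmap)
        per_metal[metal] = best
        for pid, key in prior.items():
            if pid in best and best[pid] != key:
                contradictions.append(
                    {"peak_id": pid, "prior": key, "metal": metal, "pcs_residue": best[pid],
                     "problem": "pcs_contradicts_prior"}
                )
    augmented = consensus.copy()
    new_rows = []
    assigned_keys = set(prior.values())
    candidate_peaks = set().union(*[set(m) for m in per_metal.values()]) - set(prior)
    for pid in sorted(candidate_peaks):
        votes: dict[str, list[str]] = {}
        for metal, cmap in per_metal.items():
            if pid in cmap:
                votes.setdefault(cmap[pid], []).append(metal)
        for key, supporters in votes.items():
            if key in assigned_keys:
                continue
            opposite_pair = False
            for i in range(len(supporters)):
                for j in range(i + 1, len(supporters)):
                    if _tensors_opposite(tensors[supporters[i]], tensors[supporters[j]], datasets):
                        opposite_pair = True
            if len(supporters) >= 2 and opposite_pair:
                new_rows.append({"peak_id": pid, "residue": key, "metals": ";".join(supporters)})
                assigned_keys.add(key)
                break
    for row in new_rows:
        sel = augmented["peak_id"] == row["peak_id"]
        augmented.loc[sel, ["residue", "status"]] = [row["residue"], "consistent"]
        augmented.loc[sel, "candidates"] = "pcs:" + row["metals"]
    report = pd.DataFrame(contradictions)
    return augmented, report


def _tensors_opposite(ta: DchiTensor, tb: DchiTensor, datasets) -> bool:
    """Opposite-orientation gate on a shared sampling of the two fields."""
    pts = datasets.get("_probe_positions") if isinstance(datasets, dict) else None
    if pts is None:
        # sample on a sphere around the mean metal position
        rng = np.random.default_rng(7)
        centre = 0.5 * (ta.metal_position + tb.metal_position)
        dirs = rng.normal(size=(64, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        pts = centre + 15.0 * dirs
    try:
        return opposite_orientation(ta, tb, np.asarray(pts, float))
    except ValueError:
        return False
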