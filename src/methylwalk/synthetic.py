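"""Ground-truthed synthetic data for every stage of the pipeline.

The generator builds a two-state "toy protein": a packed constellation of
methyl probes in which a subset (a hinge domain) is rigidly rotated between
state A and state B, mimicking a ligand-induced conformational change.
From the known geometry, shifts, tensor and metal position it derives every
observable the pipeline consumes -- NOE cross-peak lists with dropout and
false positives, PCS and PRE tables, and fast-exchange CSP titrations --
so that recovery can be checked against the truth record.

Every generator is a pure function of its parameters and seed.  Chemical
shifts are drawn from literature-like methyl regions per residue type
(values in the ``SHIFT_REGIONS`` table are this package's own choices, not
measurements), which makes overlap statistics realistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pcs import DchiTensor, PCSDataset, calc_pcs
from .peaks import TitrationSeries
from .pre import PREDataset, PREPhysics, sbm_gamma2
from .binding import two_state_isotherm
from .structures import (
    DEFAULT_SCHEME,
    MethylGroup,
    StructureModel,
    extract_methyls,
)

__all__ = [
    "SHIFT_REGIONS",
    "LMUGP_TYPE_COUNTS",
    "SyntheticTruth",
    "make_two_state_toy",
    "simulate_noe_peaks",
    "simulate_pcs",
    "simulate_pre",
    "simulate_titration",
    "write_pdb",
]

# (13C ppm range, 1H ppm range) per residue type, methyl region
SHIFT_REGIONS = {
    "ALA": ((16.0, 23.0), (1.10, 1.60)),
    "ILE": ((9.0, 15.0), (0.50, 1.00)),
    "LEU": ((22.0, 27.0), (0.55, 1.05)),
    "VAL": ((19.0, 24.0), (0.70, 1.15)),
    "MET": ((15.0, 19.0), (1.70, 2.20)),
    "THR": ((20.0, 23.5), (1.00, 1.40)),
}

# LmUGP-like residue-type proportions (Ala/Ile/Leu/Met/Thr/Val)
LMUGP_TYPE_COUNTS = {"ALA": 43, "ILE": 16, "LEU": 50, "MET": 19, "THR": 30, "VAL": 41}

_PROBE_ATOM = {t: DEFAULT_SCHEME.probe_atom(t)[0] for t in LMUGP_TYPE_COUNTS}


@dataclass
class SyntheticTruth:
    """Everything needed to re-derive every simulated observable."""

    seed: int
    model_a: StructureModel
    model_b: StructureModel
    methyls_a: list[MethylGroup]
    methyls_b: list[MethylGroup]
    shifts: pd.DataFrame  # key, residue_type, delta_C_a, delta_H_a, delta_C_b, delta_H_b
    assignment_a: dict[str, str] = field(default_factory=dict)  # peak_id -> methyl key
    assignment_b: dict[str, str] = field(default_factory=dict)
    peak_map_ab: dict[str, str] = field(default_factory=dict)
    hinge_keys: list[str] = field(default_factory=list)

    def peak_list(self, state: str) -> pd.DataFrame:
        suffix = state.lower()
        rows = []
        for _, r in self.shifts.iterrows():
            pid = f"{suffix}{int(r['index']):03d}"
            rows.append(
                {"peak_id": pid, "delta_H": r[f"delta_H_{suffix}"],
                 "delta_C": r[f"delta_C_{suffix}"], "intensity": 1.0,
                 "residue_type": r["residue_type"], "assignment": None}
            )
        return pd.DataFrame(rows)


def _pack_probes(n: int, rng: np.random.Generator) -> np.ndarray:
    """Grid-with-jitter packing: min distance > 4 A, neighbours 5-8 A."""
    side = int(np.ceil(n ** (1.0 / 3.0))) + 1
    spacing = 5.8
    pts = []
    for i in range(side):
        for j in range(side):
            for k in range(side):
                pts.append((i * spacing, j * spacing, k * spacing))
    pts = np.array(pts, float)
    centre = pts.mean(axis=0)
    order = np.argsort(((pts - centre) ** 2).sum(axis=1))
    pts = pts[order[:n]]
    for attempt in range(20):
        jitter = rng.uniform(-0.85, 0.85, size=pts.shape)
        cand = pts + jitter
        d = np.sqrt(((cand[:, None] - cand[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > 4.0:
            return cand
    raise RuntimeError("could not pack probes without clashes")


def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.deg2rad(angle_deg)
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _draw_types(n: int, rng: np.random.Generator, exact: bool = False) -> list[str]:
    types = list(LMUGP_TYPE_COUNTS)
    counts = np.array([LMUGP_TYPE_COUNTS[t] for t in types], float)
    if exact and n == int(counts.sum()):
        seq = sum([[t] * int(c) for t, c in zip(types, counts)], [])
        rng.shuffle(seq)
        return seq
    probs = counts / counts.sum()
    return [types[i] for i in rng.choice(len(types), size=n, p=probs)]


def make_two_state_toy(
    n_probes: int = 50,
    hinge_fraction: float = 0.3,
    hinge_angle: float = 17.0,
    seed: int = 0,
    exact_type_counts: bool = False,
) -> SyntheticTruth:
    """Two conformers of one methyl constellation plus the full truth record.

    State B equals state A with the ``hinge_fraction`` of probes on one side
    of the structure rigidly rotated by ``hinge_angle`` degrees about a
    random axis through the hinge centroid.  Residue types follow
    LmUGP-like proportions; shifts are drawn from the per-type regions with
    per-state perturbations (largest for hinged probes).
    """
    if n_probes < 6:
        raise ValueError("need at least 6 probes")
    rng = np.random.default_rng(seed)
    coords_a = _pack_probes(n_probes, rng)
    types = _draw_types(n_probes, rng, exact=exact_type_counts)

    # hinge: the probes on one side of a random plane through the centroid
    n_hinge = int(round(hinge_fraction * n_probes))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    proj = (coords_a - coords_a.mean(axis=0)) @ direction
    hinge_idx = np.argsort(proj)[-n_hinge:] if n_hinge else np.array([], int)
    coords_b = coords_a.copy()
    if n_hinge and hinge_angle != 0:
        axis = rng.normal(size=3)
        pivot = coords_a[hinge_idx].mean(axis=0)
        rot = _rotation(axis, hinge_angle)
        coords_b[hinge_idx] = (coords_a[hinge_idx] - pivot) @ rot.T + pivot

    def build_model(coords: np.ndarray, model_id: str) -> StructureModel:
        rows = [
            ("A", i + 1, types[i], _PROBE_ATOM[types[i]],
             coords[i, 0], coords[i, 1], coords[i, 2])
            for i in range(n_probes)
        ]
        return StructureModel(
            model_id=model_id,
            atoms=pd.DataFrame(
                rows,
                columns=["chain", "residue_number", "residue_type", "atom_name", "x", "y", "z"],
            ),
        )

    model_a = build_model(coords_a, "1")
    model_b = build_model(coords_b, "1")
    methyls_a, _ = extract_methyls(model_a)
    methyls_b, _ = extract_methyls(model_b)
    keys = [g.key for g in methyls_a]

    rows = []
    hinge_set = set(hinge_idx.tolist())
    for i, t in enumerate(types):
        (c_lo, c_hi), (h_lo, h_hi) = SHIFT_REGIONS[t]
        dc = rng.uniform(c_lo, c_hi)
        dh = rng.uniform(h_lo, h_hi)
        big = i in hinge_set
        dc_b = dc + rng.normal(0, 0.35 if big else 0.05)
        dh_b = dh + rng.normal(0, 0.035 if big else 0.005)
        rows.append(
            {"index": i, "key": keys[i], "residue_type": t,
             "delta_C_a": dc, "delta_H_a": dh, "delta_C_b": dc_b, "delta_H_b": dh_b}
        )
    shifts = pd.DataFrame(rows)
    assignment_a = {f"a{i:03d}": keys[i] for i in range(n_probes)}
    assignment_b = {f"b{i:03d}": keys[i] for i in range(n_probes)}
    peak_map = {f"a{i:03d}": f"b{i:03d}" for i in range(n_probes)}
    return SyntheticTruth(
        seed=seed,
        model_a=model_a,
        model_b=model_b,
        methyls_a=methyls_a,
        methyls_b=methyls_b,
        shifts=shifts,
        assignment_a=assignment_a,
        assignment_b=assignment_b,
        peak_map_ab=peak_map,
        hinge_keys=[keys[i] for i in sorted(hinge_set)],
    )


def simulate_noe_peaks(
    truth: SyntheticTruth,
    state: str = "a",
    cutoff: float = 7.0,
    dropout: float = 0.0,
    false_rate: float = 0.0,
    overlap_merge_tol: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Distance-thresholded 4D NOE cross-peaks with imperfections.

    Both directions of every probe pair within ``cutoff`` are emitted; each
    direction is dropped independently with probability ``dropout``; false
    cross-peaks between beyond-cutoff pairs are added at ``false_rate``
    (relative to the true count); cross-peaks closer than
    ``overlap_merge_tol`` (ppm, both carbon dims) are merged.
    """
    if not (0 <= dropout <= 1 and 0 <= false_rate < 1):
        raise ValueError("dropout in [0,1], false_rate in [0,1)")
    rng = np.random.default_rng(seed)
    state = state.lower()
    methyls = truth.methyls_a if state == "a" else truth.methyls_b
    coords = np.stack([g.carbon_position for g in methyls])
    n = len(methyls)
    shifts = truth.shifts
    dc = shifts[f"delta_C_{state}"].to_numpy(float)
    dh = shifts[f"delta_H_{state}"].to_numpy(float)
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    rows = []
    pairs = [(i, j) for i in range(n) for j in range(n) if i != j and d[i, j] <= cutoff]
    for i, j in pairs:  # direction: source i -> destination j
        if dropout and rng.random() < dropout:
            continue
        rows.append(
            {"f1_C": dc[j], "f2_H": dh[j], "f3_C": dc[i], "f4_H": dh[i],
             "intensity": float(np.exp(-d[i, j] / 3.0))}
        )
    n_false = int(round(false_rate * len(pairs)))
    far = [(i, j) for i in range(n) for j in range(n) if i != j and d[i, j] > cutoff]
    if n_false and far:
        for k in rng.choice(len(far), size=min(n_false, len(far)), replace=False):
            i, j = far[k]
            rows.append(
                {"f1_C": dc[j], "f2_H": dh[j], "f3_C": dc[i], "f4_H": dh[i],
                 "intensity": 0.05}
            )
    noes = pd.DataFrame(rows, columns=["f1_C", "f2_H", "f3_C", "f4_H", "intensity"])
    if overlap_merge_tol > 0 and len(noes):
        merged, used = [], np.zeros(len(noes), bool)
        vals = noes[["f1_C", "f2_H", "f3_C", "f4_H"]].to_numpy()
        for a in range(len(noes)):
            if used[a]:
                continue
            close = (
                (np.abs(vals[:, 0] - vals[a, 0]) < overlap_merge_tol)
                & (np.abs(vals[:, 2] - vals[a, 2]) < overlap_merge_tol)
                & (np.abs(vals[:, 1] - vals[a, 1]) < overlap_merge_tol / 5.0)
                & (np.abs(vals[:, 3] - vals[a, 3]) < overlap_merge_tol / 5.0)
                & ~used
            )
            grp = noes[close]
            used |= close
            merged.append(
                {"f1_C": grp["f1_C"].mean(), "f2_H": grp["f2_H"].mean(),
                 "f3_C": grp["f3_C"].mean(), "f4_H": grp["f4_H"].mean(),
                 "intensity": grp["intensity"].sum()}
            )
        noes = pd.DataFrame(merged)
    return noes


def simulate_pcs(
    tensor: DchiTensor,
    methyls: list[MethylGroup],
    noise_hz: float = 0.0,
    spectrometer_mhz: float = 500.0,
    bleach_radius: float = 0.0,
    seed: int = 0,
) -> PCSDataset:
    """PCS observations from a known tensor (ppm table, Gaussian Hz noise).

    Probes within ``bleach_radius`` of the metal are dropped, emulating the
    PRE bleaching that hides resonances near a paramagnetic centre.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in methyls:
        r = np.linalg.norm(g.carbon_position - tensor.metal_position)
        if bleach_radius and r < bleach_radius:
            continue
        val = float(calc_pcs(tensor, g.carbon_position))
        if noise_hz:
            val += rng.normal(0.0, noise_hz) / spectrometer_mhz
        rows.append(
            {"key": g.key, "pcs_ppm": val,
             "error_ppm": max(noise_hz, 0.1) / spectrometer_mhz}
        )
    return PCSDataset(
        pd.DataFrame(rows, columns=["key", "pcs_ppm", "error_ppm"]),
        spectrometer_mhz=spectrometer_mhz,
        paramagnetic_label="synthetic",
        diamagnetic_label="synthetic",
    )


def simulate_pre(
    metal_position: np.ndarray,
    methyls: list[MethylGroup],
    physics: PREPhysics,
    noise_fraction: float = 0.0,
    min_error: float = 0.5,
    bleach_gamma2: float | None = 300.0,
    seed: int = 0,
) -> PREDataset:
    """Gamma2 observations from a known metal position (SBM + noise).

    Probes whose true Gamma2 exceeds ``bleach_gamma2`` are dropped: in a real
    spectrum such signals broaden beyond detection, so PRE tables only ever
    contain the measurable band around the metal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for g in methyls:
        r = np.linalg.norm(g.carbon_position - np.asarray(metal_position, float))
        g2 = float(sbm_gamma2(r, physics))
        if bleach_gamma2 is not None and g2 > bleach_gamma2:
            continue
        err = max(noise_fraction * abs(g2), min_error)
        obs = g2 + (rng.normal(0.0, err) if noise_fraction else 0.0)
        rows.append({"key": g.key, "gamma2": obs, "error": err})
    return PREDataset(pd.DataFrame(rows, columns=["key", "gamma2", "error"]))


def simulate_titration(
    kd: float,
    dnu_max_hz: dict[str, float],
    p_total: float,
    ligand_schedule: np.ndarray,
    noise_hz: float = 0.0,
    spectrometer_mhz: float = 600.0,
    seed: int = 0,
) -> TitrationSeries:
    """Fast-exchange CSP titration obeying the two-state isotherm.

    Each peak moves along a straight line in (H, C) shift space whose total
    length at saturation is its ``dnu_max_hz``; the bound fraction at every
    point follows the closed-form isotherm.  Trajectory truth is recorded.
    """
    rng = np.random.default_rng(seed)
    peak_ids = list(dnu_max_hz)
    n = len(peak_ids)
    base_h = rng.uniform(0.4, 2.2, n)
    base_c = rng.uniform(10.0, 26.0, n)
    angle = rng.uniform(0, 2 * np.pi, n)  # direction of motion in (H, C) Hz space
    mhz_c = spectrometer_mhz * 0.25143
    lists, lt_list, pt_list = [], [], []
    traj = {f"{pid}": [] for pid in peak_ids}
    for k, l_t in enumerate(np.asarray(ligand_schedule, float)):
        frac = two_state_isotherm(p_total, l_t, kd)
        rows = []
        for i, pid in enumerate(peak_ids):
            dnu = float(frac) * dnu_max_hz[pid]
            dh_hz = dnu * np.cos(angle[i]) + (rng.normal(0, noise_hz) if noise_hz else 0.0)
            dc_hz = dnu * np.sin(angle[i]) + (rng.normal(0, noise_hz) if noise_hz else 0.0)
            pid_k = pid if k == 0 else f"{pid}.{k}"
            rows.append(
                {"peak_id": pid_k, "delta_H": base_h[i] + dh_hz / spectrometer_mhz,
                 "delta_C": base_c[i] + dc_hz / mhz_c, "intensity": 1.0,
                 "residue_type": None, "assignment": None}
            )
            traj[pid].append(pid_k)
        lists.append(pd.DataFrame(rows))
        lt_list.append(float(l_t))
        pt_list.append(p_total)
    return TitrationSeries(
        ligand_total=lt_list,
        protein_total=pt_list,
        peak_lists=lists,
        spectrometer_mhz=spectrometer_mhz,
        trajectories=traj,
    )


def write_pdb(model: StructureModel, path: str) -> None:
    """Write a minimal, deterministic PDB file for one model."""
    lines = []
    for serial, (_, row) in enumerate(model.atoms.iterrows(), start=1):
        name = row["atom_name"]
        name_f = f" {name:<3s}" if len(name) < 4 else name
        lines.append(
            f"ATOM  {serial:5d} {name_f}{'':1s}{row['residue_type']:>3s} "
            f"{row['chain']:1s}{int(row['residue_number']):4d}    "
            f"{row['x']:8.3f}{row['y']:8.3f}{row['z']:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {name[0]:>2s}"
        )
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
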