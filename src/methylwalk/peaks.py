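"""Peak lists, residue typing, NOE networks and titration tracking.

A 2D 1H,13C HMQC spectrum gives one peak per methyl group.  Selectively
labeled samples type the peaks; 4D HMQC-NOESY-HMQC cross-peaks link peaks
that are close in space; titrations move peaks between protein states in
fast exchange, which lets assignments transfer between states.

Peak matching throughout uses a scaled Euclidean metric in
(delta_H, delta_C / CARBON_SCALE) ppm space: 13C shifts spread about five
times wider than 1H shifts in the methyl region, so CARBON_SCALE = 5 makes
tolerances comparable between dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "CARBON_SCALE",
    "read_peak_list",
    "write_peak_list",
    "classify_residue_types",
    "build_noe_network",
    "track_titration",
    "TitrationSeries",
]

CARBON_SCALE = 5.0

# Peak list columns (TSV dialect, header required)
PEAK_COLUMNS = ["peak_id", "delta_H", "delta_C", "intensity", "residue_type", "assignment"]
NOE_COLUMNS = ["f1_C", "f2_H", "f3_C", "f4_H", "intensity"]


def _scaled(dH: np.ndarray, dC: np.ndarray) -> np.ndarray:
    return np.column_stack([np.asarray(dH, float), np.asarray(dC, float) / CARBON_SCALE])


def read_peak_list(path: str) -> pd.DataFrame:
    """Read a peak list: the package TSV dialect or a Sparky ``.list`` file.

    Sparky lists are detected from the ``Assignment  w1  w2`` header; w1 is
    taken as 13C and w2 as 1H (the usual order for 13C HMQC lists).
    """
    with open(path) as fh:
        head = fh.readline()
    if head.strip().lower().startswith("assignment"):
        df = pd.read_csv(path, sep=r"\s+", engine="python")
        ncol = df.shape[1]
        cols = {"Assignment": "peak_id", df.columns[1]: "delta_C", df.columns[2]: "delta_H"}
        df = df.rename(columns=cols)
        if ncol > 3:
            df = df.rename(columns={df.columns[3]: "intensity"})
        else:
            df["intensity"] = 1.0
        df["residue_type"] = None
        df["assignment"] = None
        return df[PEAK_COLUMNS]
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("peak_id", "delta_H", "delta_C") if c not in df.columns]
    if missing:
        raise ValueError(f"peak list {path} lacks required columns {missing}")
    for c in PEAK_COLUMNS:
        if c not in df.columns:
            df[c] = 1.0 if c == "intensity" else None
    return df[PEAK_COLUMNS]


def write_peak_list(peaks: pd.DataFrame, path: str) -> None:
    peaks.to_csv(path, sep="\t", index=False)


def _validate_peaks(peaks: pd.DataFrame, name: str = "peaks") -> None:
    if peaks["peak_id"].duplicated().any():
        dup = peaks.loc[peaks["peak_id"].duplicated(), "peak_id"].iloc[0]
        raise ValueError(f"{name}: duplicate peak_id {dup!r}")
    if not np.all(np.isfinite(peaks[["delta_H", "delta_C"]].to_numpy(float))):
        raise ValueError(f"{name}: non-finite chemical shifts")


def _match_one(
    dH: float, dC: float, peaks: pd.DataFrame, tol_H: float, tol_C: float
) -> list[int]:
    """Indices of peaks within the tolerance box, nearest (scaled) first."""
    sel = (np.abs(peaks["delta_H"].to_numpy(float) - dH) <= tol_H) & (
        np.abs(peaks["delta_C"].to_numpy(float) - dC) <= tol_C
    )
    idx = np.flatnonzero(sel)
    if len(idx) > 1:
        pos = _scaled(peaks["delta_H"].to_numpy(float)[idx], peaks["delta_C"].to_numpy(float)[idx])
        d = np.linalg.norm(pos - _scaled([dH], [dC]), axis=1)
        idx = idx[np.argsort(d)]
    return idx.tolist()


def classify_residue_types(
    spectra: dict[str, pd.DataFrame],
    tol_H: float = 0.02,
    tol_C: float = 0.2,
    reference: str = "reference",
) -> pd.DataFrame:
    """Type the reference peaks by matching against selectively labeled samples.

    ``spectra`` maps a sample label to its peak list.  Single-type labels
    ("A", "I", "M", "T", "V") type directly; the Leu/Val pair uses leucine
    selective unlabeling: a reference peak matching the combined "LV" sample
    is Val if it also matches "V", otherwise Leu.  A peak matching selective
    samples of two different types is flagged ``ambiguous`` and left untyped.
    """
    if tol_H <= 0 or tol_C <= 0:
        raise ValueError("tolerances must be positive")
    if reference not in spectra:
        raise ValueError(f"no reference peak list {reference!r} in spectra")
    ref = spectra[reference].copy().reset_index(drop=True)
    _validate_peaks(ref, reference)

    one_letter = {"A": "ALA", "I": "ILE", "M": "MET", "T": "THR", "V": "VAL", "L": "LEU"}
    types: list[str | None] = [None] * len(ref)
    status = ["untyped"] * len(ref)

    def hits(label: str, i: int) -> bool:
        if label not in spectra:
            return False
        return bool(
            _match_one(ref.at[i, "delta_H"], ref.at[i, "delta_C"], spectra[label], tol_H, tol_C)
        )

    for i in range(len(ref)):
        found: list[str] = []
        for label in spectra:
            if label in (reference, "LV"):
                continue
            lab = label.upper().replace("PROS", "").replace("PS", "")
            if lab in one_letter and hits(label, i):
                found.append(one_letter[lab])
        if "LV" in spectra and hits("LV", i):
            # combined Leu+Val sample: Val iff also present in the Val-only list
            found.append("VAL" if "VAL" in found else "LEU")
        found = list(dict.fromkeys(found))
        if len(found) == 1:
            types[i] = found[0]
            status[i] = "typed"
        elif len(found) > 1:
            status[i] = "ambiguous"
    out = ref.copy()
    out["residue_type"] = types
    out["type_status"] = status
    return out


def build_noe_network(
    hmqc: pd.DataFrame,
    noes: pd.DataFrame,
    tol_H: float = 0.02,
    tol_C: float = 0.2,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Match 4D cross-peaks onto HMQC peaks and build the NOE graph.

    Each cross-peak has a source methyl at (f3_C, f4_H) and a destination at
    (f1_C, f2_H).  An edge is created when both ends match exactly one HMQC
    peak; the edge is ``mutual`` when the reversed cross-peak was also
    observed.  Diagonal (auto) cross-peaks are discarded.  Unmatched or
    ambiguous cross-peaks go to the returned report, never into the graph.
    """
    if tol_H <= 0 or tol_C <= 0:
        raise ValueError("tolerances must be positive")
    hmqc = hmqc.reset_index(drop=True)
    _validate_peaks(hmqc)
    g = nx.Graph()
    g.add_nodes_from(hmqc["peak_id"])
    directed: dict[tuple[str, str], int] = {}
    report_rows = []
    for _, row in noes.iterrows():
        src = _match_one(row["f4_H"], row["f3_C"], hmqc, tol_H, tol_C)
        dst = _match_one(row["f2_H"], row["f1_C"], hmqc, tol_H, tol_C)
        problem = None
        if not src or not dst:
            problem = "unmatched"
        elif len(src) > 1 or len(dst) > 1:
            problem = "ambiguous"
        if problem:
            report_rows.append(
                {
                    **{c: row[c] for c in NOE_COLUMNS if c in row},
                    "problem": problem,
                    "src_candidates": ";".join(hmqc["peak_id"].iloc[src]),
                    "dst_candidates": ";".join(hmqc["peak_id"].iloc[dst]),
                }
            )
            continue
        a = hmqc["peak_id"].iloc[src[0]]
        b = hmqc["peak_id"].iloc[dst[0]]
        if a == b:
            continue  # auto peak
        directed[(a, b)] = directed.get((a, b), 0) + 1
    for (a, b), n in sorted(directed.items()):
        mutual = (b, a) in directed
        if g.has_edge(a, b):
            g[a][b]["count"] += n
        else:
            g.add_edge(a, b, mutual=mutual, count=n)
        g[a][b]["mutual"] = g[a][b]["mutual"] or mutual
    report = pd.DataFrame(
        report_rows,
        columns=NOE_COLUMNS + ["problem", "src_candidates", "dst_candidates"],
    )
    return g, report


@dataclass
class TitrationSeries:
    """Ordered titration points with per-point peak lists.

    ``points`` rows carry (ligand_total, protein_total, peaks); ligand_total
    must be non-decreasing.  ``spectrometer_mhz`` is the 1H frequency used for
    ppm -> Hz conversion of CSPs.
    """

    ligand_total: list[float]
    protein_total: list[float]
    peak_lists: list[pd.DataFrame]
    spectrometer_mhz: float = 600.0
    trajectories: dict[str, list[str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lt = np.asarray(self.ligand_total, float)
        if np.any(np.diff(lt) < 0):
            raise ValueError("ligand_total must be non-decreasing")
        if not (len(self.ligand_total) == len(self.protein_total) == len(self.peak_lists)):
            raise ValueError("points of unequal length")

    @property
    def n_points(self) -> int:
        return len(self.peak_lists)


def track_titration(
    series: TitrationSeries, max_step: float = 0.05
) -> tuple[dict[str, list[str | None]], dict[str, str], pd.DataFrame]:
    """Greedy nearest-neighbour peak tracking through the titration.

    Links point-to-point in scaled (H, C/5) ppm space; a link longer than
    ``max_step`` (scaled ppm) breaks the trajectory.  When two peaks claim
    the same successor the closer wins and the loser is flagged.  Returns
    (trajectories keyed by point-0 peak_id, endpoint map, flagged report).
    """
    if series.n_points < 2:
        raise ValueError("need at least two titration points")
    traj: dict[str, list[str | None]] = {
        pid: [pid] for pid in series.peak_lists[0]["peak_id"]
    }
    flags = []
    current = {pid: pid for pid in traj}  # trajectory id -> current peak id
    for k in range(1, series.n_points):
        prev = series.peak_lists[k - 1].reset_index(drop=True)
        nxt = series.peak_lists[k].reset_index(drop=True)
        prev_pos = {
            r["peak_id"]: np.array([r["delta_H"], r["delta_C"] / CARBON_SCALE])
            for _, r in prev.iterrows()
        }
        nxt_pos = _scaled(nxt["delta_H"], nxt["delta_C"])
        nxt_ids = list(nxt["peak_id"])
        # candidate links sorted globally by distance: closer claims win
        cands = []
        for tid, pid in current.items():
            if pid is None or pid not in prev_pos:
                continue
            d = np.linalg.norm(nxt_pos - prev_pos[pid], axis=1)
            j = int(np.argmin(d))
            cands.append((float(d[j]), tid, j))
        taken: set[int] = set()
        linked: dict[str, str | None] = {tid: None for tid in current}
        for d, tid, j in sorted(cands):
            if d > max_step:
                flags.append({"trajectory": tid, "point": k, "problem": "step_too_large", "dist": d})
                continue
            if j in taken:
                flags.append({"trajectory": tid, "point": k, "problem": "successor_claimed", "dist": d})
                continue
            taken.add(j)
            linked[tid] = nxt_ids[j]
        for tid in traj:
            nxt_id = linked.get(tid)
            traj[tid].append(nxt_id)
            current[tid] = nxt_id
    endpoint = {tid: t[-1] for tid, t in traj.items() if t[-1] is not None}
    report = pd.DataFrame(flags, columns=["trajectory", "point", "problem", "dist"])
    return traj, endpoint, report
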