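"""Metropolis Monte Carlo assignment of typed peaks to methyl probes.

Each HMQC peak must be mapped to a methyl probe of the same residue type.
The energy of a mapping counts NOE edges whose mapped probe pair is farther
apart than the cut-off distance in the structure (mutual edges weight 1,
one-sided edges weight 1/2; an edge touching an unmapped peak always counts
as violated, so letting surplus peaks float never lowers the energy for
free).  Optional pseudocontact-shift and chemical-shift terms add weighted
absolute deviations between observed and probe-predicted values.

Confidence comes from consensus: independent annealing trials from random
starting permutations, a peak being "consistent" only when every trial maps
it identically.  Cut-off scanning picks the cut-off maximizing the number of
consistent peaks, and the two-state protocol transfers single-state
assignments through a titration peak map as fixed constraints for the other
state, iterating until the consistent sets stop growing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MMCConfig",
    "AssignmentProblem",
    "score_assignment",
    "run_mmc",
    "consensus",
    "scan_cutoff",
    "combine_states",
]


@dataclass(frozen=True)
class MMCConfig:
    """Annealing and scoring parameters for one batch of MMC trials."""

    cutoff: float = 7.0  # Angstrom
    n_trials: int = 20
    steps_per_trial: int = 20000
    t_start: float = 3.0
    t_end: float = 0.02
    n_levels: int = 50  # geometric cooling schedule
    w_noe: float = 1.0
    w_pcs: float = 10.0
    w_cs: float = 1e-12
    seed: int = 0
    quorum: float = 1.0  # fraction of trials that must agree; 1.0 = unanimity

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if min(self.w_noe, self.w_pcs, self.w_cs) < 0:
            raise ValueError("weights must be non-negative")


class AssignmentProblem:
    """Typed peaks, typed probes, the NOE graph and the distance table.

    ``peaks`` needs columns peak_id and residue_type; peaks with a null
    residue type cannot be placed and are reported in ``untyped``.
    ``pcs`` is an optional dict of {peak_id: (obs, {probe_key: calc})} used
    by the PCS energy term; ``cs`` has the same shape for chemical shifts.
    """

    def __init__(
        self,
        peaks: pd.DataFrame,
        probe_keys: list[str],
        probe_types: list[str],
        network: nx.Graph,
        distances: pd.DataFrame,
        pcs: dict | None = None,
        cs: dict | None = None,
    ):
        typed = peaks[peaks["residue_type"].notna()].reset_index(drop=True)
        self.untyped = [p for p in peaks["peak_id"] if p not in set(typed["peak_id"])]
        self.peak_ids: list[str] = list(typed["peak_id"])
        self.peak_types: list[str] = list(typed["residue_type"])
        self.probe_keys = list(probe_keys)
        self.probe_types = list(probe_types)
        if len(self.probe_keys) != len(self.probe_types):
            raise ValueError("probe_keys and probe_types length mismatch")
        self.dist = distances.loc[self.probe_keys, self.probe_keys].to_numpy(float)
        self._peak_index = {p: i for i, p in enumerate(self.peak_ids)}
        self._probe_index = {k: i for i, k in enumerate(self.probe_keys)}
        # adjacency over typed peaks only
        self.adj: list[list[tuple[int, float]]] = [[] for _ in self.peak_ids]
        self.edges: list[tuple[int, int, float]] = []
        for a, b, data in network.edges(data=True):
            if a not in self._peak_index or b not in self._peak_index:
                continue
            w = 1.0 if data.get("mutual", False) else 0.5
            i, j = self._peak_index[a], self._peak_index[b]
            self.edges.append((i, j, w))
            self.adj[i].append((j, w))
            self.adj[j].append((i, w))
        # per-peak x per-probe penalty matrices (absolute deviations)
        n_pk, n_pr = len(self.peak_ids), len(self.probe_keys)
        self.pcs_pen = self._penalty_matrix(pcs, n_pk, n_pr)
        self.cs_pen = self._penalty_matrix(cs, n_pk, n_pr)
        # type bookkeeping
        self.types = sorted(set(self.peak_types) | set(self.probe_types))
        self.peaks_by_type = {
            t: [i for i, pt in enumerate(self.peak_types) if pt == t] for t in self.types
        }
        self.probes_by_type = {
            t: [i for i, pt in enumerate(self.probe_types) if pt == t] for t in self.types
        }

    def _penalty_matrix(self, terms: dict | None, n_pk: int, n_pr: int) -> np.ndarray | None:
        if not terms:
            return None
        pen = np.zeros((n_pk, n_pr))
        for pid, (obs, calc_by_probe) in terms.items():
            if pid not in self._peak_index:
                continue
            i = self._peak_index[pid]
            for key, calc in calc_by_probe.items():
                if key in self._probe_index:
                    pen[i, self._probe_index[key]] = abs(obs - calc)
        return pen

    # mapping as array: peak index -> probe index or -1
    def mapping_to_dict(self, m: np.ndarray) -> dict[str, str | None]:
        return {
            pid: (self.probe_keys[m[i]] if m[i] >= 0 else None)
            for i, pid in enumerate(self.peak_ids)
        }

    def mapping_from_dict(self, d: dict[str, str | None]) -> np.ndarray:
        m = np.full(len(self.peak_ids), -1, dtype=int)
        for pid, key in d.items():
            if key is None or pid not in self._peak_index:
                continue
            m[self._peak_index[pid]] = self._probe_index[key]
        return m

    def validate_fixed(self, fixed: dict[str, str]) -> None:
        seen: dict[str, str] = {}
        for pid, key in fixed.items():
            if pid not in self._peak_index:
                raise ValueError(f"fixed peak {pid!r} not in problem")
            if key not in self._probe_index:
                raise ValueError(f"fixed probe {key!r} not in problem")
            i = self._peak_index[pid]
            if self.peak_types[i] != self.probe_types[self._probe_index[key]]:
                raise ValueError(f"fixed assignment {pid}->{key} violates residue type")
            if key in seen:
                raise ValueError(f"probe {key} fixed for both {seen[key]} and {pid}")
            seen[key] = pid


def _energy(
    problem: AssignmentProblem, m: np.ndarray, cutoff: float, cfg: MMCConfig
) -> float:
    viol = problem.dist > cutoff
    e = 0.0
    for i, j, w in problem.edges:
        if m[i] < 0 or m[j] < 0 or viol[m[i], m[j]]:
            e += w
    e *= cfg.w_noe
    for pen, weight in ((problem.pcs_pen, cfg.w_pcs), (problem.cs_pen, cfg.w_cs)):
        if pen is not None and weight > 0:
            mapped = m >= 0
            e += weight * pen[np.flatnonzero(mapped), m[mapped]].sum()
    return e


def score_assignment(
    problem: AssignmentProblem,
    mapping: dict[str, str | None],
    cutoff: float,
    config: MMCConfig | None = None,
) -> float:
    """Energy of a mapping (lower is better); see the module docstring."""
    cfg = config or MMCConfig(cutoff=cutoff)
    return _energy(problem, problem.mapping_from_dict(mapping), cutoff, cfg)


def _peak_cost(
    problem: AssignmentProblem,
    m: np.ndarray,
    i: int,
    probe: int,
    viol: np.ndarray,
    cfg: MMCConfig,
    skip: int = -1,
) -> float:
    """Energy contribution of peak i if it were mapped to ``probe`` (-1 = unmapped).

    Edges to ``skip`` are excluded (used to avoid double counting the i-j edge
    during a swap).
    """
    e = 0.0
    for j, w in problem.adj[i]:
        if j == skip:
            continue
        mj = m[j]
        if probe < 0 or mj < 0 or viol[probe, mj]:
            e += w * cfg.w_noe
    if probe >= 0:
        if problem.pcs_pen is not None and cfg.w_pcs > 0:
            e += cfg.w_pcs * problem.pcs_pen[i, probe]
        if problem.cs_pen is not None and cfg.w_cs > 0:
            e += cfg.w_cs * problem.cs_pen[i, probe]
    return e


def run_mmc(
    problem: AssignmentProblem,
    config: MMCConfig,
    fixed: dict[str, str] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, str | None], float]:
    """One annealing trial; returns the best-energy mapping visited.

    Starts from a random type-respecting permutation honouring ``fixed``
    entries (which are never touched by moves), proposes within-type swaps
    and relocations to free probes, and accepts by the Metropolis rule under
    a geometric cooling schedule.
    """
    fixed = fixed or {}
    problem.validate_fixed(fixed)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_pk = len(problem.peak_ids)
    m = np.full(n_pk, -1, dtype=int)
    fixed_mask = np.zeros(n_pk, dtype=bool)
    for pid, key in fixed.items():
        i = problem._peak_index[pid]
        m[i] = problem._probe_index[key]
        fixed_mask[i] = True
    # random start: per type, shuffle free probes over free peaks
    movable_by_type: dict[str, list[int]] = {}
    free_probes_count: dict[str, int] = {}
    for t in problem.types:
        pks = [i for i in problem.peaks_by_type[t] if not fixed_mask[i]]
        used = {m[i] for i in problem.peaks_by_type[t] if m[i] >= 0}
        prs = [p for p in problem.probes_by_type[t] if p not in used]
        rng.shuffle(pks)
        rng.shuffle(prs)
        slots = prs[: len(pks)] + [-1] * max(0, len(pks) - len(prs))
        for i, s in zip(pks, slots):
            m[i] = s
        movable_by_type[t] = pks
        free_probes_count[t] = max(0, len(prs) - len(pks))
    move_types = [t for t in problem.types if len(movable_by_type[t]) >= 1]
    move_types = [
        t
        for t in move_types
        if len(movable_by_type[t]) >= 2 or free_probes_count[t] >= 1
    ]
    viol = problem.dist > config.cutoff
    energy = _energy(problem, m, config.cutoff, config)
    best_m, best_e = m.copy(), energy
    if not move_types:
        return problem.mapping_to_dict(best_m), best_e

    weights = np.array([len(movable_by_type[t]) for t in move_types], float)
    weights /= weights.sum()
    steps = config.steps_per_trial
    level_len = max(1, steps // config.n_levels)
    ratio = (config.t_end / config.t_start) ** (1.0 / max(1, config.n_levels - 1))
    temp = config.t_start
    free_pool = {
        t: [
            p
            for p in problem.probes_by_type[t]
            if p not in set(m[problem.peaks_by_type[t]])
        ]
        for t in problem.types
    }
    for step in range(steps):
        if step > 0 and step % level_len == 0:
            temp *= ratio
        t = move_types[rng.choice(len(move_types), p=weights)]
        pks = movable_by_type[t]
        pool = free_pool[t]
        do_reloc = pool and (len(pks) < 2 or rng.random() < 0.5)
        if do_reloc:
            i = pks[rng.integers(len(pks))]
            k = rng.integers(len(pool))
            new_p = pool[k]
            old = _peak_cost(problem, m, i, m[i], viol, config)
            new = _peak_cost(problem, m, i, new_p, viol, config)
            de = new - old
            if de <= 0 or rng.random() < math.exp(-de / temp):
                old_p = m[i]
                m[i] = new_p
                pool[k] = old_p  # old_p may be -1: a floating slot enters the pool
                if old_p == -1:
                    pool.pop(k)
                energy += de
        else:
            if len(pks) < 2:
                continue
            i, j = rng.choice(len(pks), size=2, replace=False)
            i, j = pks[i], pks[j]
            if m[i] == m[j]:
                continue
            # the i-j edge (if any) is invariant under a swap (viol is
            # symmetric), so it is excluded from both sides and cancels
            old = (
                _peak_cost(problem, m, i, m[i], viol, config, skip=j)
                + _peak_cost(problem, m, j, m[j], viol, config, skip=i)
            )
            new = (
                _peak_cost(problem, m, i, m[j], viol, config, skip=j)
                + _peak_cost(problem, m, j, m[i], viol, config, skip=i)
            )
            de = new - old
            if de <= 0 or rng.random() < math.exp(-de / temp):
                m[i], m[j] = m[j], m[i]
                energy += de
        if energy < best_e - 1e-12:
            best_e = energy
            best_m = m.copy()
    # guard against float drift in the incremental energy
    best_e = _energy(problem, best_m, config.cutoff, config)
    return problem.mapping_to_dict(best_m), best_e


def consensus(trials: list[dict[str, str | None]], n_trials: int | None = None,
              quorum: float = 1.0) -> pd.DataFrame:
    """Per-peak agreement across trials.

    Returns a DataFrame with peak_id, residue (modal probe key), count,
    n_trials, status and candidates.  Status is ``consistent`` when the
    agreeing fraction reaches ``quorum`` (default unanimity) and the modal
    value is a real probe, ``unassigned`` when the peak floats in every
    trial, else ``ambiguous``.
    """
    if not trials:
        raise ValueError("need at least one trial")
    keys = set(trials[0])
    for t in trials[1:]:
        if set(t) != keys:
            raise ValueError("trials cover different peak sets")
    n = n_trials or len(trials)
    rows = []
    for pid in sorted(keys):
        values = [t[pid] for t in trials]
        counts: dict[str | None, int] = {}
        for v in values:
            counts[v] = counts.get(v, 0) + 1
        winner = max(counts, key=lambda k: counts[k])
        count = counts[winner]
        if winner is None and count == len(values):
            status = "unassigned"
        elif winner is not None and count >= quorum * n:
            status = "consistent"
        else:
            status = "ambiguous"
        rows.append(
            {
                "peak_id": pid,
                "residue": winner,
                "count": count,
                "n_trials": n,
                "status": status,
                "candidates": ";".join(
                    f"{k or '-'}:{v}" for k, v in sorted(counts.items(), key=lambda kv: -kv[1])
                ),
                "fixed": False,
            }
        )
    return pd.DataFrame(rows)


def _run_consensus(
    problem: AssignmentProblem, config: MMCConfig, fixed: dict[str, str] | None
) -> pd.DataFrame:
    seq = np.random.SeedSequence(config.seed)
    children = seq.spawn(config.n_trials)
    trials = []
    for child in children:
        mapping, _ = run_mmc(problem, config, fixed, rng=np.random.default_rng(child))
        trials.append(mapping)
    cons = consensus(trials, n_trials=config.n_trials, quorum=config.quorum)
    if fixed:
        cons.loc[cons["peak_id"].isin(fixed), "fixed"] = True
    return cons


def scan_cutoff(
    problem: AssignmentProblem,
    cutoffs: list[float],
    config: MMCConfig,
    fixed: dict[str, str] | None = None,
) -> tuple[float, pd.DataFrame, dict[float, pd.DataFrame]]:
    """Full consensus per cut-off; pick the cut-off with the most consistent
    peaks (ties -> smallest cut-off)."""
    if not cutoffs:
        raise ValueError("cutoff range is empty")
    counts = []
    per_cutoff: dict[float, pd.DataFrame] = {}
    for c in cutoffs:
        cons = _run_consensus(problem, replace(config, cutoff=c), fixed)
        per_cutoff[c] = cons
        counts.append({"cutoff": c, "consistent": int((cons["status"] == "consistent").sum())})
    table = pd.DataFrame(counts)
    best = table.sort_values(["consistent", "cutoff"], ascending=[False, True]).iloc[0]
    return float(best["cutoff"]), table, per_cutoff


@dataclass
class StateResult:
    consensus: pd.DataFrame
    fixed: dict[str, str]
    conflicts: pd.DataFrame = field(default_factory=pd.DataFrame)


def _consistent_map(cons: pd.DataFrame) -> dict[str, str]:
    sel = cons[cons["status"] == "consistent"]
    return dict(zip(sel["peak_id"], sel["residue"]))


def combine_states(
    problem_a: AssignmentProblem,
    problem_b: AssignmentProblem,
    peak_map: dict[str, str],
    config_a: MMCConfig,
    config_b: MMCConfig,
    fixed_a: dict[str, str] | None = None,
    fixed_b: dict[str, str] | None = None,
    max_rounds: int = 10,
    conflict_threshold: float = 0.5,
) -> tuple[StateResult, StateResult, pd.DataFrame]:
    """Two-state combination protocol.

    ``peak_map`` links state-A peak ids to state-B peak ids (endpoint map of
    a titration).  After independent consensus per state, assignments
    consistent in exactly one state are transferred through the map and
    fixed in a re-run of the other; iterate until the consistent sets stop
    growing.  Cross-state disagreements and transfers whose incident NOE
    violation weight exceeds ``conflict_threshold`` are reported, never
    silently overwritten.  Returns per-state results and a gain log.
    """
    fwd = dict(peak_map)
    if len(set(fwd.values())) != len(fwd):
        dupes = pd.Series(list(fwd.values()))
        bad = dupes[dupes.duplicated()].iloc[0]
        raise ValueError(f"peak_map maps two state-A peaks onto {bad!r}")
    rev = {v: k for k, v in fwd.items()}

    fa = dict(fixed_a or {})
    fb = dict(fixed_b or {})
    cons_a = _run_consensus(problem_a, config_a, fa)
    cons_b = _run_consensus(problem_b, config_b, fb)
    conflicts: list[dict] = []
    gains = [
        {
            "round": 0,
            "consistent_a": int((cons_a["status"] == "consistent").sum()),
            "consistent_b": int((cons_b["status"] == "consistent").sum()),
        }
    ]
    for rnd in range(1, max_rounds + 1):
        map_a = _consistent_map(cons_a)
        map_b = _consistent_map(cons_b)
        new_b, new_a = {}, {}
        for pid_a, key in map_a.items():
            pid_b = fwd.get(pid_a)
            if pid_b is None or pid_b in fb:
                continue
            if pid_b in map_b:
                if map_b[pid_b] != key:
                    conflicts.append(
                        {"peak_a": pid_a, "peak_b": pid_b, "residue_a": key,
                         "residue_b": map_b[pid_b], "problem": "cross_state_disagreement"}
                    )
                continue
            if key in problem_b._probe_index and key not in set(fb.values()) | set(new_b.values()):
                new_b[pid_b] = key
        for pid_b, key in map_b.items():
            pid_a = rev.get(pid_b)
            if pid_a is None or pid_a in fa or pid_a in map_a:
                continue
            if key in problem_a._probe_index and key not in set(fa.values()) | set(new_a.values()):
                new_a[pid_a] = key
        if not new_a and not new_b:
            break
        if new_b:
            fb.update(new_b)
            cons_b = _run_consensus(problem_b, config_b, fb)
        if new_a:
            fa.update(new_a)
            cons_a = _run_consensus(problem_a, config_a, fa)
        gains.append(
            {
                "round": rnd,
                "consistent_a": int((cons_a["status"] == "consistent").sum()),
                "consistent_b": int((cons_b["status"] == "consistent").sum()),
            }
        )
    # flag transferred fixes that violate the receiving state's NOEs
    for problem, cons, fixed, label in (
        (problem_a, cons_a, fa, "A"),
        (problem_b, cons_b, fb, "B"),
    ):
        m = problem.mapping_from_dict(_consistent_map(cons) | fixed)
        viol = problem.dist > (config_a.cutoff if label == "A" else config_b.cutoff)
        for pid, key in fixed.items():
            i = problem._peak_index[pid]
            bad = 0.0
            for j, w in problem.adj[i]:
                if m[j] >= 0 and m[i] >= 0 and viol[m[i], m[j]]:
                    bad += w
            if bad > conflict_threshold:
                conflicts.append(
                    {"peak_a" if label == "A" else "peak_b": pid, "residue_a": key,
                     "problem": f"fixed_assignment_violates_noes_state_{label}",
                     "violation_weight": bad}
                )
    conflict_df = pd.DataFrame(conflicts)
    return (
        StateResult(cons_a, fa, conflict_df),
        StateResult(cons_b, fb, conflict_df),
        pd.DataFrame(gains),
    )
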