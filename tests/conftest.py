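"""Shared fixtures: synthetic toys and a hand-constructed two-state problem."""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methylwalk import assign, structures, synthetic


@pytest.fixture(scope="session")
def toy50():
    """50-probe two-state toy with the default hinge (30%, 17 deg)."""
    return synthetic.make_two_state_toy(50, hinge_fraction=0.3, hinge_angle=17.0, seed=42)


@pytest.fixture(scope="session")
def toy50_ensemble(toy50):
    return structures.build_ensemble([toy50.model_a])


def make_problem(truth, state: str, cutoff: float = 7.0, dropout: float = 0.0,
                 seed: int = 1, tol_h: float = 0.004, tol_c: float = 0.04,
                 pcs=None):
    """AssignmentProblem for one state of a synthetic truth."""
    from methylwalk import peaks as pk

    noes = synthetic.simulate_noe_peaks(truth, state, cutoff=cutoff, dropout=dropout,
                                        seed=seed)
    pl = truth.peak_list(state)
    g, _ = pk.build_noe_network(pl, noes, tol_h, tol_c)
    methyls = truth.methyls_a if state == "a" else truth.methyls_b
    dist = structures.methyl_distances(methyls)
    return assign.AssignmentProblem(
        pl, [m.key for m in methyls], [m.residue_type for m in methyls], g, dist,
        pcs=pcs,
    )


# --- hand-constructed two-state fixture -------------------------------------
#
# Eight probes.  Four single-probe types (Ala, Ile, Met, Thr) anchor the
# problem; the Leu pair is NOE-isolated in state A but contacts the anchors in
# state B, and the Val pair vice versa.  Each state alone therefore leaves one
# same-type pair ambiguous, and the two states are complementary.

TWO_STATE_KEYS = ["ALA1-b", "ILE2-d1", "MET3-e", "THR4-g2", "LEU5-d2", "LEU6-d2",
                  "VAL7-g2", "VAL8-g2"]
TWO_STATE_TYPES = ["ALA", "ILE", "MET", "THR", "LEU", "LEU", "VAL", "VAL"]

_COORDS_A = np.array(
    [
        [0.0, 0.0, 0.0],   # Ala1
        [20.0, 0.0, 0.0],  # Ile2
        [40.0, 0.0, 0.0],  # Met3
        [60.0, 0.0, 0.0],  # Thr4
        [0.0, 30.0, 0.0],  # Leu5  (isolated in A)
        [30.0, 30.0, 0.0], # Leu6  (isolated in A)
        [20.0, 5.0, 0.0],  # Val7  (near Ile2 in A)
        [40.0, 5.0, 0.0],  # Val8  (near Met3 in A)
    ]
)
_COORDS_B = np.array(
    [
        [0.0, 0.0, 0.0],
        [20.0, 0.0, 0.0],
        [40.0, 0.0, 0.0],
        [60.0, 0.0, 0.0],
        [0.0, 5.0, 0.0],   # Leu5  (near Ala1 in B)
        [60.0, 5.0, 0.0],  # Leu6  (near Thr4 in B)
        [20.0, 30.0, 0.0], # Val7  (isolated in B)
        [50.0, 30.0, 0.0], # Val8  (isolated in B)
    ]
)

# state A: only the Val pair is anchored by NOEs; the Leu pair is isolated
TWO_STATE_EDGES_A = [("a6", "a1"), ("a7", "a2")]
# state B: only the Leu pair is anchored; the Val pair is isolated
TWO_STATE_EDGES_B = [("b4", "b0"), ("b5", "b3")]

TWO_STATE_PEAK_MAP = {f"a{i}": f"b{i}" for i in range(8)}
TWO_STATE_TRUTH_A = {f"a{i}": TWO_STATE_KEYS[i] for i in range(8)}
TWO_STATE_TRUTH_B = {f"b{i}": TWO_STATE_KEYS[i] for i in range(8)}


def _distance_table(coords: np.ndarray) -> pd.DataFrame:
    d = np.sqrt(((coords[:, None] - coords[None]) ** 2).sum(-1))
    return pd.DataFrame(d, index=TWO_STATE_KEYS, columns=TWO_STATE_KEYS)


def _state_problem(prefix: str, coords: np.ndarray, edges) -> assign.AssignmentProblem:
    peaks_df = pd.DataFrame(
        {
            "peak_id": [f"{prefix}{i}" for i in range(8)],
            "residue_type": TWO_STATE_TYPES,
        }
    )
    g = nx.Graph()
    g.add_nodes_from(peaks_df["peak_id"])
    for a, b in edges:
        g.add_edge(a, b, mutual=True, count=2)
    return assign.AssignmentProblem(
        peaks_df, TWO_STATE_KEYS, TWO_STATE_TYPES, g, _distance_table(coords)
    )


@pytest.fixture()
def two_state_fixture():
    """(problem_a, problem_b, peak_map, truth_a, truth_b) with complementary
    ambiguity between the states."""
    return (
        _state_problem("a", _COORDS_A, TWO_STATE_EDGES_A),
        _state_problem("b", _COORDS_B, TWO_STATE_EDGES_B),
        TWO_STATE_PEAK_MAP,
        TWO_STATE_TRUTH_A,
        TWO_STATE_TRUTH_B,
    )
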