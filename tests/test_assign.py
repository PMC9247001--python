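"""MMC assignment: energy oracle, annealing recovery, consensus, cut-off scan."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from methylwalk import assign, structures, synthetic
from methylwalk.assign import AssignmentProblem, MMCConfig, consensus, run_mmc, scan_cutoff

from conftest import make_problem


def brute_force_energy(problem, mapping, cutoff, w_noe=1.0, w_pcs=10.0, w_cs=1e-12):
    """Independent recount: loop over raw edges and penalty tables."""
    e = 0.0
    for i, j, w in problem.edges:
        pa = mapping.get(problem.peak_ids[i])
        pb = mapping.get(problem.peak_ids[j])
        if pa is None or pb is None:
            e += w * w_noe
            continue
        da = problem.dist[problem.probe_keys.index(pa), problem.probe_keys.index(pb)]
        if da > cutoff:
            e += w * w_noe
    for pen, weight in ((problem.pcs_pen, w_pcs), (problem.cs_pen, w_cs)):
        if pen is None:
            continue
        for idx, pid in enumerate(problem.peak_ids):
            key = mapping.get(pid)
            if key is not None:
                e += weight * pen[idx, problem.probe_keys.index(key)]
    return e


def exhaustive_best(problem, cutoff, cfg):
    """Enumerate all type-respecting bijections; return the minimum energy."""
    per_type = []
    for t in problem.types:
        pks = [problem.peak_ids[i] for i in problem.peaks_by_type[t]]
        prs = [problem.probe_keys[i] for i in problem.probes_by_type[t]]
        assert len(pks) <= len(prs) <= 7
        per_type.append([dict(zip(pks, perm)) for perm in itertools.permutations(prs, len(pks))])
    best = np.inf
    best_maps = []
    for combo in itertools.product(*per_type):
        mapping = {}
        for d in combo:
            mapping.update(d)
        e = brute_force_energy(problem, mapping, cutoff, cfg.w_noe, cfg.w_pcs, cfg.w_cs)
        if e < best - 1e-12:
            best, best_maps = e, [mapping]
        elif abs(e - best) <= 1e-12:
            best_maps.append(mapping)
    return best, best_maps


@pytest.fixture(scope="module")
def small_truth():
    return synthetic.make_two_state_toy(16, hinge_fraction=0.0, seed=7)


@pytest.fixture(scope="module")
def small_problem(small_truth):
    return make_problem(small_truth, "a", cutoff=7.0, seed=2)


class TestEnergy:
    def test_truth_mapping_has_zero_noe_energy(self, small_truth, small_problem):
        e = assign.score_assignment(small_problem, small_truth.assignment_a, 7.0)
        assert e == 0.0

    def test_energy_matches_brute_force_on_random_mappings(self, small_problem):
        rng = np.random.default_rng(0)
        cfg = MMCConfig(cutoff=7.0)
        for _ in range(20):
            mapping = {}
            for t in small_problem.types:
                pks = [small_problem.peak_ids[i] for i in small_problem.peaks_by_type[t]]
                prs = [small_problem.probe_keys[i] for i in small_problem.probes_by_type[t]]
                perm = rng.permutation(len(prs))
                for k, p in enumerate(pks):
                    mapping[p] = prs[perm[k]]
            fast = assign.score_assignment(small_problem, mapping, 7.0, cfg)
            slow = brute_force_energy(small_problem, mapping, 7.0)
            assert fast == pytest.approx(slow, abs=1e-9)
            assert fast >= 0.0

    def test_swapping_distant_probes_raises_energy_by_violated_edges(self, small_truth,
                                                                     small_problem):
        # swap the two same-type peaks whose probes are farthest apart
        best_pair, best_d = None, -1.0
        for t in small_problem.types:
            pks = [i for i in small_problem.peaks_by_type[t]]
            for a, b in itertools.combinations(pks, 2):
                ka = small_truth.assignment_a[small_problem.peak_ids[a]]
                kb = small_truth.assignment_a[small_problem.peak_ids[b]]
                d = small_problem.dist[small_problem.probe_keys.index(ka),
                                       small_problem.probe_keys.index(kb)]
                if d > best_d:
                    best_d, best_pair = d, (a, b)
        a, b = best_pair
        pa, pb = small_problem.peak_ids[a], small_problem.peak_ids[b]
        swapped = dict(small_truth.assignment_a)
        swapped[pa], swapped[pb] = swapped[pb], swapped[pa]
        e = assign.score_assignment(small_problem, swapped, 7.0)
        assert e == pytest.approx(brute_force_energy(small_problem, swapped, 7.0))
        assert e > 0.0

    def test_chemical_shift_term_is_de_facto_excluded(self, small_truth, small_problem):
        # attach a shift term of order 1 per peak; the default 1e-12 weight
        # changes the energy by < 1e-11 per peak
        cs = {
            pid: (1.0, {k: 0.0 for k in small_problem.probe_keys})
            for pid in small_problem.peak_ids
        }
        prob = AssignmentProblem(
            pd.DataFrame({"peak_id": small_problem.peak_ids,
                          "residue_type": small_problem.peak_types}),
            small_problem.probe_keys,
            small_problem.probe_types,
            nx.Graph(),
            pd.DataFrame(small_problem.dist, index=small_problem.probe_keys,
                         columns=small_problem.probe_keys),
            cs=cs,
        )
        e = assign.score_assignment(prob, small_truth.assignment_a, 7.0)
        assert 0 < e < 1e-11 * len(small_problem.peak_ids)


class TestRunMMC:
    def test_recovers_truth_and_matches_exhaustive_search(self):
        truth = synthetic.make_two_state_toy(10, hinge_fraction=0.0, seed=12)
        problem = make_problem(truth, "a", cutoff=8.0, seed=3)
        cfg = MMCConfig(cutoff=8.0, n_trials=1, steps_per_trial=6000, seed=5)
        mapping, e = run_mmc(problem, cfg)
        best_e, best_maps = exhaustive_best(problem, 8.0, cfg)
        assert e == pytest.approx(best_e, abs=1e-9)
        assert truth.assignment_a in best_maps
        if len(best_maps) == 1:
            assert mapping == truth.assignment_a

    def test_empty_network_gives_zero_energy_valid_permutation(self, small_truth):
        pl = small_truth.peak_list("a")
        dist = structures.methyl_distances(small_truth.methyls_a)
        prob = AssignmentProblem(pl, [m.key for m in small_truth.methyls_a],
                                 [m.residue_type for m in small_truth.methyls_a],
                                 nx.Graph(), dist)
        mapping, e = run_mmc(prob, MMCConfig(cutoff=7.0, steps_per_trial=500, seed=1))
        assert e == 0.0
        # type-respecting bijection
        truth_types = dict(zip(pl["peak_id"], pl["residue_type"]))
        key_types = dict(zip([m.key for m in small_truth.methyls_a],
                             [m.residue_type for m in small_truth.methyls_a]))
        vals = [v for v in mapping.values() if v is not None]
        assert len(vals) == len(set(vals)) == len(mapping)
        for pid, key in mapping.items():
            assert truth_types[pid] == key_types[key]

    def test_fixed_assignments_are_honoured_and_rest_recovered(self, small_truth,
                                                               small_problem):
        items = sorted(small_truth.assignment_a.items())
        fixed = dict(items[: int(0.8 * len(items))])
        cfg = MMCConfig(cutoff=7.0, n_trials=1, steps_per_trial=5000, seed=9)
        mapping, e = run_mmc(small_problem, cfg, fixed=fixed)
        assert e == 0.0
        for pid, key in fixed.items():
            assert mapping[pid] == key
        assert mapping == small_truth.assignment_a

    def test_infeasible_fixed_set_rejected(self, small_problem):
        t = next(t for t in small_problem.types if len(small_problem.peaks_by_type[t]) >= 2)
        keys = [small_problem.probe_keys[i] for i in small_problem.probes_by_type[t]]
        pks = [small_problem.peak_ids[i] for i in small_problem.peaks_by_type[t]]
        with pytest.raises(ValueError, match="fixed"):
            run_mmc(small_problem, MMCConfig(cutoff=7.0, steps_per_trial=10, seed=0),
                    fixed={pks[0]: keys[0], pks[1]: keys[0]})

    def test_reproducible_given_seed(self, small_problem):
        cfg = MMCConfig(cutoff=7.0, n_trials=1, steps_per_trial=3000, seed=123)
        m1, e1 = run_mmc(small_problem, cfg)
        m2, e2 = run_mmc(small_problem, cfg)
        assert m1 == m2 and e1 == e2


class TestConsensus:
    def test_identical_trials_all_consistent(self):
        trial = {"p1": "k1", "p2": "k2"}
        cons = consensus([trial] * 3)
        assert (cons["status"] == "consistent").all()
        assert (cons["count"] == 3).all()

    def test_single_disagreement_marks_only_that_peak(self):
        t1 = {"p1": "k1", "p2": "k2"}
        t2 = {"p1": "k1", "p2": "k3"}
        cons = consensus([t1, t1, t2]).set_index("peak_id")
        assert cons.at["p1", "status"] == "consistent"
        assert cons.at["p2", "status"] == "ambiguous"
        assert cons.at["p2", "count"] == 2

    def test_consistent_requires_unanimity(self):
        t1 = {"p1": "k1"}
        t2 = {"p1": "k2"}
        cons = consensus([t1] * 19 + [t2], n_trials=20)
        assert cons["status"].iloc[0] == "ambiguous"

    def test_all_floating_is_unassigned(self):
        cons = consensus([{"p1": None}] * 3)
        assert cons["status"].iloc[0] == "unassigned"

    def test_mismatched_peak_sets_rejected(self):
        with pytest.raises(ValueError, match="different peak sets"):
            consensus([{"p1": "k"}, {"p2": "k"}])

    def test_twenty_seeded_trials_recover_truth_on_noiseless_toy(self, small_truth,
                                                                 small_problem):
        cfg = MMCConfig(cutoff=7.0, n_trials=20, steps_per_trial=5000, seed=77)
        cons = assign._run_consensus(small_problem, cfg, None)
        cc = cons[cons["status"] == "consistent"]
        for r in cc.itertuples():
            assert small_truth.assignment_a[r.peak_id] == r.residue
        # the toy is small and well-connected: everything should resolve
        assert len(cc) == len(cons)


class TestScanCutoff:
    def test_consistency_peaks_near_generation_cutoff(self):
        truth = synthetic.make_two_state_toy(24, hinge_fraction=0.0, seed=21)
        problem = make_problem(truth, "a", cutoff=7.0, dropout=0.1, seed=4)
        cfg = MMCConfig(n_trials=6, steps_per_trial=4000, seed=3)
        best, table, _ = scan_cutoff(problem, [5.0, 7.0, 9.0, 11.0], cfg)
        counts = dict(zip(table["cutoff"], table["consistent"]))
        assert counts[best] == max(counts.values())
        assert best in (5.0, 7.0, 9.0)  # dropout can shift the peak one notch down

    def test_single_element_range(self, small_problem):
        cfg = MMCConfig(n_trials=2, steps_per_trial=1000, seed=1)
        best, table, _ = scan_cutoff(small_problem, [6.5], cfg)
        assert best == 6.5 and len(table) == 1

    def test_tie_break_prefers_smallest_cutoff(self, small_truth):
        # empty network: every cutoff yields identical (all-ambiguous) counts
        pl = small_truth.peak_list("a")
        dist = structures.methyl_distances(small_truth.methyls_a)
        prob = AssignmentProblem(pl, [m.key for m in small_truth.methyls_a],
                                 [m.residue_type for m in small_truth.methyls_a],
                                 nx.Graph(), dist)
        cfg = MMCConfig(n_trials=3, steps_per_trial=200, seed=2)
        best, table, _ = scan_cutoff(prob, [9.0, 5.0, 7.0], cfg)
        assert best == 5.0
        assert table["consistent"].nunique() == 1
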