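"""Compartmental kinetics: matrices, chain coupling, solvers, residence times.

The chain-coupling convention (daughter ingrowth at lambda_daughter times
branching, in activity units) is validated against an independent
atom-count (Bateman) formulation built directly in this module.
"""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from doseuq import (
    DecayChain,
    Radionuclide,
    ValidationError,
    aggregate_to_source_regions,
    build_chain_system,
    build_system_matrix,
    builtin_cerium_model,
    integrated_activity,
    solve_activities,
)
from doseuq.biokinetics import T_D_DEFAULT

from conftest import make_model


def two_member_chain(lam_p, lam_d, branching):
    ln2 = math.log(2.0)
    d = Radionuclide(name="d", half_life=ln2 / lam_d)
    p = Radionuclide(
        name="p", half_life=ln2 / lam_p, progeny=(("d", branching),)
    )
    return DecayChain(members=(p, d))


# ---------------------------------------------------------------------------
# system matrices
# ---------------------------------------------------------------------------

class TestSystemMatrix:
    def test_two_compartment_transcription(self):
        model = make_model(2, {(0, 1): 0.1})
        a = build_system_matrix(model, 0.0)
        assert np.allclose(a, [[-0.1, 0.0], [0.1, 0.0]])

    def test_decay_on_diagonal(self):
        model = make_model(2, {(0, 1): 0.1})
        a = build_system_matrix(model, 0.02)
        assert np.allclose(np.diag(a), [-0.12, -0.02])

    def test_cerium_model_columns_conserve(self, cerium_model):
        lam = 2.132761e-2
        a = build_system_matrix(cerium_model, lam)
        scale = max(1.0, max(cerium_model.transfers.values()))
        assert np.abs(a.sum(axis=0) + lam).max() <= 1e-12 * scale

    def test_negative_k_rejected(self):
        with pytest.raises(ValidationError):
            make_model(2, {(0, 1): -0.1})


class TestChainSystem:
    def test_single_compartment_coupling_block(self):
        chain = two_member_chain(0.1, 0.2, 1.0)
        system = build_chain_system(make_model(1, {}), chain)
        assert np.allclose(system.rate_matrix, [[-0.1, 0.0], [0.2, -0.2]])

    def test_zero_branching_decouples(self):
        chain = two_member_chain(0.1, 0.2, 0.0)
        system = build_chain_system(make_model(1, {}), chain)
        assert np.allclose(system.rate_matrix, [[-0.1, 0.0], [0.0, -0.2]])

    def test_unresolved_progeny_rejected(self):
        p = Radionuclide(name="p", half_life=1.0, progeny=(("ghost", 1.0),))
        chain = DecayChain(members=(p,))
        with pytest.raises(ValidationError):
            build_chain_system(make_model(1, {}), chain)

    def test_chain_matches_atom_count_oracle(self):
        """Activity-unit coupling agrees with the atom-based Bateman system."""
        rng = np.random.default_rng(7)
        ln2 = math.log(2.0)
        # 3-member toy chain with branching, over a 3-compartment model
        lams = [0.5, 1.1, 0.23]
        c = Radionuclide(name="c", half_life=ln2 / lams[2])
        b = Radionuclide(name="b", half_life=ln2 / lams[1], progeny=(("c", 0.8),))
        a_ = Radionuclide(
            name="a",
            half_life=ln2 / lams[0],
            progeny=(("b", 0.6), ("c", 0.3)),
        )
        chain = DecayChain(members=(a_, b, c))
        transfers = {
            (0, 1): rng.uniform(0.05, 1.0),
            (1, 2): rng.uniform(0.05, 1.0),
            (2, 0): rng.uniform(0.05, 1.0),
        }
        model = make_model(3, transfers)
        system = build_chain_system(model, chain)

        # independent oracle: atom counts N with production branching*lam_p*N_p
        k = np.zeros((3, 3))
        for (i, j), rate in transfers.items():
            k[j, i] += rate
            k[i, i] -= rate
        n_members = 3
        atom = np.zeros((9, 9))
        branch = {("a", "b"): 0.6, ("a", "c"): 0.3, ("b", "c"): 0.8}
        names = ["a", "b", "c"]
        for mi in range(n_members):
            atom[mi * 3 : mi * 3 + 3, mi * 3 : mi * 3 + 3] = k - lams[mi] * np.eye(3)
            for di in range(n_members):
                frac = branch.get((names[mi], names[di]), 0.0)
                if frac:
                    atom[di * 3 : di * 3 + 3, mi * 3 : mi * 3 + 3] += (
                        frac * lams[mi] * np.eye(3)
                    )
        n0 = np.zeros(9)
        n0[0] = 1.0 / lams[0]  # unit parent activity as atoms
        times = np.array([0.5, 1.0, 3.0, 10.0])
        sol = solve_activities(system, times)
        for ti, t in enumerate(times):
            n_t = expm(atom * t) @ n0
            q_oracle = np.concatenate(
                [lams[mi] * n_t[mi * 3 : mi * 3 + 3] for mi in range(3)]
            )
            q_impl = sol.q[:, :, ti].ravel()
            assert np.abs(q_impl - q_oracle).max() <= 1e-8 * max(
                1.0, np.abs(q_oracle).max()
            )


# ---------------------------------------------------------------------------
# solving
# ---------------------------------------------------------------------------

class TestSolveActivities:
    @pytest.mark.parametrize("method", ["expm", "stiff"])
    def test_single_compartment_exponential(self, method):
        nuc = Radionuclide(name="n", half_life=math.log(2.0) / 0.1)
        system = build_chain_system(make_model(1, {}), DecayChain.single(nuc))
        sol = solve_activities(system, np.array([0.0, 10.0]), method=method)
        assert sol.q[0, 0, 0] == pytest.approx(1.0)
        assert sol.q[0, 0, 1] == pytest.approx(math.exp(-1.0), rel=1e-7)

    def test_catenary_accumulation(self):
        nuc = Radionuclide(name="stable-ish", half_life=1e12)
        system = build_chain_system(
            make_model(2, {(0, 1): 0.1}), DecayChain.single(nuc)
        )
        times = np.array([0.0, 5.0, 30.0])
        sol = solve_activities(system, times)
        expected = 1.0 - np.exp(-0.1 * times)
        assert np.allclose(sol.q[0, 1], expected, rtol=1e-6, atol=1e-9)

    def test_bateman_parent_daughter(self):
        chain = two_member_chain(math.log(2.0), 2 * math.log(2.0), 1.0)
        system = build_chain_system(make_model(1, {}), chain)
        sol = solve_activities(system, np.array([1.0]))
        assert sol.activity("d", 0)[0] == pytest.approx(0.5, rel=1e-10)

    def test_activity_balance_without_decay(self):
        """With lambda ~ 0 and explicit sinks, total activity is conserved."""
        rng = np.random.default_rng(11)
        transfers = {
            (i, j): rng.uniform(0.01, 1.0)
            for i in range(5)
            for j in range(5)
            if i != j and rng.random() < 0.4
        }
        transfers[(0, 4)] = 0.3  # guarantee some flow
        nuc = Radionuclide(name="n", half_life=1e15)
        system = build_chain_system(make_model(5, transfers), DecayChain.single(nuc))
        sol = solve_activities(system, np.array([0.0, 1.0, 10.0, 100.0]))
        totals = sol.q.sum(axis=(0, 1))
        assert np.abs(totals - 1.0).max() <= 1e-8

    def test_unsorted_times_rejected(self):
        nuc = Radionuclide(name="n", half_life=1.0)
        system = build_chain_system(make_model(1, {}), DecayChain.single(nuc))
        with pytest.raises(ValidationError):
            solve_activities(system, np.array([1.0, 0.5]))


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------

class TestIntegratedActivity:
    def test_decay_only_infinite_horizon(self):
        nuc = Radionuclide(name="n", half_life=32.5)
        system = build_chain_system(make_model(1, {}), DecayChain.single(nuc))
        rt = integrated_activity(system, math.inf)
        assert rt.a_tilde[("n", 0)] == pytest.approx(32.5 / math.log(2.0), rel=1e-10)

    def test_closed_system_no_decay_gives_t_d(self):
        nuc = Radionuclide(name="n", half_life=1e300)  # effectively stable
        system = build_chain_system(make_model(1, {}), DecayChain.single(nuc))
        rt = integrated_activity(system, 1234.5)
        assert rt.a_tilde[("n", 0)] == pytest.approx(1234.5, rel=1e-9)

    def test_pure_removal_infinite_horizon(self):
        nuc = Radionuclide(name="n", half_life=1e300)
        system = build_chain_system(
            make_model(2, {(0, 1): 0.1}), DecayChain.single(nuc)
        )
        rt = integrated_activity(system, math.inf)
        assert rt.a_tilde[("n", 0)] == pytest.approx(10.0, rel=1e-9)

    def test_matches_trapezoid_quadrature(self, cerium_model, ce141_chain):
        system = build_chain_system(cerium_model, ce141_chain)
        rt = integrated_activity(system, 1000.0)
        # log-spaced grid: the alimentary transit spike decays within seconds
        times = np.concatenate([[0.0], np.geomspace(1e-7, 1000.0, 8000)])
        sol = solve_activities(system, times)
        approx = np.trapezoid(sol.q, times, axis=2)
        exact = np.array(
            [rt.a_tilde[("Ce-141", cid)] for cid in system.compartment_ids]
        )
        scale = max(exact.max(), 1e-12)
        assert np.abs(approx[0] - exact).max() <= 1e-5 * scale

    def test_increasing_removal_decreases_residence(self):
        """Raising any loss rate weakly decreases every residence time."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            sink = n - 1  # absorbing excreta-like compartment: no outflow
            transfers = {
                (int(i), int(j)): float(rng.uniform(0.01, 1.0))
                for i in range(n - 1)
                for j in range(n - 1)
                if i != j and rng.random() < 0.5
            }
            transfers[(0, sink)] = 0.1
            nuc = Radionuclide(name="n", half_life=float(rng.uniform(5, 500)))
            model = make_model(n, transfers)
            base = integrated_activity(
                build_chain_system(model, DecayChain.single(nuc)), 2000.0
            )
            donor = int(rng.integers(0, n - 1))
            bumped = dict(transfers)
            bumped[(donor, sink)] = bumped.get((donor, sink), 0.0) + 0.5
            pert = integrated_activity(
                build_chain_system(model.with_transfers(bumped), DecayChain.single(nuc)),
                2000.0,
            )
            for (member, cid), value in base.a_tilde.items():
                if cid == sink:
                    continue
                assert pert.a_tilde[(member, cid)] <= value + 1e-9

    def test_daughter_transformations_scale_with_branching(self):
        """Total daughter transformations = branching x parent's (atom count)."""
        for branching in (0.25, 1.0):
            chain = two_member_chain(0.2, 0.7, branching)
            system = build_chain_system(make_model(1, {}), chain)
            rt = integrated_activity(system, math.inf)
            parent_nt = rt.a_tilde[("p", 0)]  # = 1/lam_p
            daughter_nt = rt.a_tilde[("d", 0)]
            assert parent_nt == pytest.approx(1 / 0.2, rel=1e-10)
            assert daughter_nt == pytest.approx(branching * parent_nt, rel=1e-9)


class TestAggregation:
    def test_regions_sum_compartments(self, cerium_model, ce141_chain):
        system = build_chain_system(cerium_model, ce141_chain)
        rt = integrated_activity(system, 1000.0)
        agg = aggregate_to_source_regions(rt, cerium_model)
        region_map = cerium_model.source_region_map()
        liver_ids = [cid for cid, r in region_map.items() if r == "liver"]
        manual = sum(rt.a_tilde[("Ce-141", cid)] for cid in liver_ids)
        assert agg.a_tilde[("Ce-141", "liver")] == pytest.approx(manual, rel=1e-12)

    def test_excreta_excluded_but_total_conserved_before_drop(
        self, cerium_model, ce141_chain
    ):
        system = build_chain_system(cerium_model, ce141_chain)
        rt = integrated_activity(system, 1000.0)
        agg = aggregate_to_source_regions(rt, cerium_model)
        assert all(region not in ("excreta",) for _, region in agg.a_tilde)
        excreta_ids = [
            c.id for c in cerium_model.compartments if c.is_excreta
        ]
        dropped = sum(rt.a_tilde[("Ce-141", cid)] for cid in excreta_ids)
        assert agg.total() + dropped == pytest.approx(rt.total(), rel=1e-12)

    def test_identity_map_unchanged(self):
        model = make_model(2, {(0, 1): 0.1})
        nuc = Radionuclide(name="n", half_life=5.0)
        system = build_chain_system(model, DecayChain.single(nuc))
        rt = integrated_activity(system, 100.0)
        agg = aggregate_to_source_regions(rt, model)
        for cid in (0, 1):
            assert agg.a_tilde[("n", f"c{cid}")] == rt.a_tilde[("n", cid)]
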