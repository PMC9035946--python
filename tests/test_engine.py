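"""Engine mechanics: OU homeostasis, scheduling, selection, expansion."""

import math

import numpy as np
import pytest

from immunotox.engine import (
    InteractionRule,
    OUParams,
    ThymusThresholds,
    build_site_schedule,
    clonal_expansion,
    execute_site_interactions,
    haematopoiesis,
    mhc_peptide_complex,
    process_and_present,
    secrete,
    step_world,
    thymus_education,
    thymus_negative,
    thymus_positive,
)
from immunotox.entities import (
    Antigen,
    CellAgent,
    CellState,
    CellType,
    CompartmentId,
    Isotype,
)
from immunotox.shape_space import AffinityParams, BitString, sample_repertoire
from tests.conftest import make_empty_state


class TestOUStep:
    def test_fixed_point_without_noise(self, rng):
        from immunotox.engine import ou_step

        p = OUParams(mu=50.0, theta=0.3, sigma=0.0)
        assert ou_step(50.0, p, 1.0, rng) == 50.0

    def test_deterministic_relaxation(self, rng):
        from immunotox.engine import ou_step

        p = OUParams(mu=50.0, theta=0.3, sigma=0.0)
        x = ou_step(50.0 + 8.0, p, 1.0, rng, integer=False)
        assert x == pytest.approx(50.0 + 8.0 * math.exp(-0.3))

    def test_stationary_moments(self):
        """Long-run mean ~ mu and variance ~ sigma^2/(2 theta)."""
        from immunotox.engine import ou_step

        p = OUParams(mu=50.0, theta=0.5, sigma=3.0)
        rng = np.random.default_rng(99)
        n = 100_000
        xs = np.empty(n)
        x = p.mu
        for i in range(n):
            x = ou_step(x, p, 1.0, rng, integer=False)
            xs[i] = x
        var_true = p.sigma**2 / (2 * p.theta)
        # effective sample size under AR(1) autocorrelation exp(-theta)
        rho = math.exp(-p.theta)
        n_eff = n * (1 - rho) / (1 + rho)
        se_mean = math.sqrt(var_true / n_eff)
        assert abs(xs.mean() - p.mu) < 3 * se_mean
        se_var = var_true * math.sqrt(2.0 / n_eff)
        assert abs(xs.var() - var_true) < 3 * se_var


def _mk(ct, site=0, state=CellState.RESTING, **kw):
    return CellAgent(cell_type=ct, position=site, state=state, **kw)


def _dummy_rule(p, name="dummy", consumes=False, effects=None):
    return InteractionRule(
        name=name,
        kind="ASPECIFIC",
        partner_kind="cell",
        actors=lambda agents: [a for a in agents if a.cell_type is CellType.MAC],
        partners=lambda state, site: [
            a for a in state.site_agents(CompartmentId.SECONDARY_ORGAN, site)
            if a.cell_type is CellType.DC
        ],
        probability=lambda a, b, s, site: p,
        effects=effects or (lambda a, b, s, site, rng: None),
        consumes_partner=consumes,
    )


class TestSiteSchedule:
    def test_single_rule_single_agent(self, cfg):
        state, rng = make_empty_state(cfg)
        mac = _mk(CellType.MAC)
        plan = build_site_schedule([_dummy_rule(1.0)], [mac], rng)
        assert len(plan) == 1
        assert plan[0][1] is mac

    def test_same_seed_identical_plan(self, cfg):
        state, _ = make_empty_state(cfg)
        rules = [_dummy_rule(1.0, name=f"r{i}") for i in range(3)]
        agents = [_mk(CellType.MAC) for _ in range(4)]
        p1 = build_site_schedule(rules, agents, np.random.default_rng(5))
        p2 = build_site_schedule(rules, agents, np.random.default_rng(5))
        assert [(r.name, a.uid) for r, a in p1] == [(r.name, a.uid) for r, a in p2]

    def test_rule_order_uniform(self, cfg):
        """All 6 orderings of 3 rules occur with frequency ~1/6."""
        rules = [_dummy_rule(1.0, name=f"r{i}") for i in range(3)]
        agents = [_mk(CellType.MAC)]
        counts = {}
        n = 10_000
        rng = np.random.default_rng(17)
        for _ in range(n):
            plan = build_site_schedule(rules, agents, rng)
            key = tuple(r.name for r, _ in plan)
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 6
        se = math.sqrt((1 / 6) * (5 / 6) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 6) < 4 * se


class TestExecuteInteractions:
    def _state_with(self, cfg, n_mac, n_dc):
        state, rng = make_empty_state(cfg)
        for _ in range(n_mac):
            state.add_agent(CompartmentId.SECONDARY_ORGAN, _mk(CellType.MAC))
        for _ in range(n_dc):
            state.add_agent(CompartmentId.SECONDARY_ORGAN, _mk(CellType.DC))
        return state, rng

    def test_zero_probability_no_events(self, cfg):
        state, rng = self._state_with(cfg, 3, 3)
        events = execute_site_interactions(0, [_dummy_rule(0.0)], state, rng)
        assert events == []

    def test_certain_rule_one_success_per_actor(self, cfg):
        state, rng = self._state_with(cfg, 2, 3)
        events = execute_site_interactions(0, [_dummy_rule(1.0)], state, rng)
        assert len(events) == 2  # each actor stops at its first partner

    def test_consumed_partners_unavailable(self, cfg):
        state, rng = self._state_with(cfg, 3, 2)
        events = execute_site_interactions(
            0, [_dummy_rule(1.0, consumes=True)], state, rng
        )
        assert len(events) == 2  # third actor finds no partner left

    def test_at_least_one_event_probability(self, cfg):
        """1 actor, 2 partners, p=0.5: P(>=1 success) = 1 - 0.25 = 0.75."""
        state, _ = self._state_with(cfg, 1, 2)
        rule = _dummy_rule(0.5)
        n = 20_000
        rng = np.random.default_rng(23)
        hits = sum(
            bool(execute_site_interactions(0, [rule], state, rng))
            for _ in range(n)
        )
        se = math.sqrt(0.75 * 0.25 / n)
        assert abs(hits / n - 0.75) < 3 * se


class TestPresentation:
    def _apc(self, mhc_ii, mhc_i=()):
        return CellAgent(
            cell_type=CellType.DC, position=0, mhc_I=tuple(mhc_i),
            mhc_II=tuple(mhc_ii),
        )

    def test_no_feasible_pair_no_presentation(self, rng):
        aff = AffinityParams(l=6, d_min=5, alpha=1.0, p_max=1.0)
        mhc = BitString(6, 0b000000)
        antigen = Antigen("x", BitString(6, 0), (BitString(6, 0b000011),))  # d=2
        apc = self._apc([mhc])
        assert process_and_present(apc, antigen, "ENDOCYTIC", aff, rng) is None

    def test_perfect_complement_presents(self, rng):
        aff = AffinityParams(l=6, d_min=3, alpha=1.0, p_max=1.0)
        mhc = BitString(6, 0b101010)
        antigen = Antigen("x", BitString(6, 0), (mhc.complement(),))
        apc = self._apc([mhc])
        cx = process_and_present(apc, antigen, "ENDOCYTIC", aff, rng)
        assert cx == mhc_peptide_complex(mhc, mhc.complement())

    def test_wrong_pathway_class_pairing_rejected(self, rng):
        aff = AffinityParams(l=6, d_min=3, alpha=1.0, p_max=1.0)
        apc = self._apc([BitString(6, 1)], mhc_i=())
        antigen = Antigen("x", BitString(6, 0), (BitString(6, 7),))
        with pytest.raises(ValueError, match="no MHC strings"):
            process_and_present(apc, antigen, "CYTOSOLIC", aff, rng)

    def test_feasible_pairs_match_exhaustive_enumeration(self):
        """With deterministic binding (alpha=p_max=1) presentation succeeds
        iff brute-force enumeration finds a feasible MHC-peptide pair, and
        the returned complex always comes from that feasible set."""
        l = 6
        aff = AffinityParams(l=l, d_min=4, alpha=1.0, p_max=1.0)
        rng = np.random.default_rng(31)
        for _ in range(200):
            mhcs = sample_repertoire(2, l, rng)
            peps = tuple(sample_repertoire(3, l, rng))
            feasible = {
                (m.value, p.value)
                for m in mhcs
                for p in peps
                if bin(m.value ^ p.value).count("1") >= 4
            }
            apc = self._apc(mhcs)
            cx = process_and_present(
                apc, Antigen("x", BitString(l, 0), peps), "ENDOCYTIC", aff, rng
            )
            if not feasible:
                assert cx is None
            else:
                assert cx is not None
                assert any(m ^ p == cx.value for m, p in feasible)


class TestClonalExpansion:
    def _duplicating_b(self, dup=0, divisions=3):
        c = CellAgent(
            cell_type=CellType.B, position=0, state=CellState.DUPLICATING,
            receptor=BitString(12, 5), duplication_count=dup,
            divisions_remaining=divisions,
        )
        return c

    def test_hayflick_limit_blocks_division(self, rng):
        cell = self._duplicating_b(dup=10)
        assert clonal_expansion(cell, 10, rng) == []

    def test_daughters_inherit_incremented_count(self, rng):
        cell = self._duplicating_b(dup=3)
        d1, d2 = clonal_expansion(cell, 10, rng)
        assert d1.duplication_count == d2.duplication_count == 4
        assert d1.receptor == d2.receptor == cell.receptor

    def test_requires_duplicating_state(self, rng):
        cell = CellAgent(
            cell_type=CellType.B, position=0, receptor=BitString(12, 5)
        )
        with pytest.raises(ValueError):
            clonal_expansion(cell, 10, rng)

    def test_total_divisions_bounded_by_hayflick_tree(self, rng):
        """Unlimited stimulation: at most 2^h - 1 divisions per founder."""
        h = 5
        cells = [self._duplicating_b(dup=0, divisions=10**6)]
        divisions = 0
        while True:
            next_gen = []
            divided = False
            for c in cells:
                daughters = clonal_expansion(c, h, rng)
                if daughters:
                    divisions += 1
                    divided = True
                    next_gen.extend(daughters)
                else:
                    next_gen.append(c)
            cells = next_gen
            if not divided:
                break
        assert divisions == 2**h - 1  # full binary tree, saturated


def _brute_force_education(repertoire, mhc_set, self_complexes, thresholds):
    """Independent re-implementation on text bit-strings."""
    out = []
    for r in repertoire:
        rs = str(r)
        d_mhc = max(
            sum(a != b for a, b in zip(rs, str(m))) for m in mhc_set
        )
        if d_mhc < thresholds.theta_pos:
            continue
        if self_complexes:
            d_self = max(
                sum(a != b for a, b in zip(rs, str(c))) for c in self_complexes
            )
            if d_self >= thresholds.theta_neg:
                continue
        out.append(r)
    return out


class TestThymicEducation:
    def test_complement_in_mhc_set_is_kept(self):
        r = BitString(8, 0b10101010)
        thr = ThymusThresholds(theta_pos=8, theta_neg=9)
        assert thymus_positive(r, (r.complement(),), thr)

    def test_identical_to_sole_mhc_is_removed(self):
        r = BitString(8, 0b10101010)
        thr = ThymusThresholds(theta_pos=1, theta_neg=9)
        assert not thymus_positive(r, (r,), thr)

    def test_empty_mhc_set_rejected(self):
        with pytest.raises(ValueError):
            thymus_positive(BitString(8, 0), (), ThymusThresholds(1, 5))

    def test_negative_selection_empty_self_keeps_all(self):
        assert thymus_negative(BitString(8, 0), (), ThymusThresholds(1, 5))

    def test_complementary_self_complex_removed(self):
        r = BitString(8, 0b11110000)
        thr = ThymusThresholds(theta_pos=0, theta_neg=8)
        assert not thymus_negative(r, (r.complement(),), thr)

    def test_vacuous_thresholds_keep_everything(self):
        l = 8
        rep = [BitString(l, v) for v in range(2**l)]
        thr = ThymusThresholds(theta_pos=0, theta_neg=l + 1)
        mhc = (BitString(l, 0b1100), )
        selfc = (BitString(l, 0b0011), )
        assert thymus_education(rep, mhc, selfc, thr) == rep

    def test_exhaustive_oracle_equivalence_l8(self):
        """All 256 receptors against an independent text-based oracle."""
        l = 8
        rng = np.random.default_rng(41)
        rep = [BitString(l, v) for v in range(2**l)]
        mhc = tuple(sample_repertoire(2, l, rng))
        selfc = tuple(sample_repertoire(3, l, rng))
        thr = ThymusThresholds(theta_pos=3, theta_neg=7)
        got = thymus_education(rep, mhc, selfc, thr)
        expected = _brute_force_education(rep, mhc, selfc, thr)
        assert got == expected

    def test_random_repertoire_oracle_equivalence_l10(self):
        l = 10
        rng = np.random.default_rng(43)
        rep = sample_repertoire(10_000, l, rng)
        mhc = tuple(sample_repertoire(4, l, rng))
        selfc = tuple(sample_repertoire(8, l, rng))
        thr = ThymusThresholds(theta_pos=4, theta_neg=9)
        assert thymus_education(rep, mhc, selfc, thr) == (
            _brute_force_education(rep, mhc, selfc, thr)
        )


class TestHaematopoiesis:
    def test_at_target_no_change(self, cfg):
        cfg2 = cfg.with_overrides(
            {"lineages": {"B": {"mu": 10, "theta": 5.0, "sigma": 0.0}}}
        )
        state, rng = make_empty_state(cfg2, lineage_mus={"B": 10})
        n_before = len(state.agents(CompartmentId.SECONDARY_ORGAN))
        created = haematopoiesis(state, cfg2, rng)
        assert created == 0
        assert len(state.agents(CompartmentId.SECONDARY_ORGAN)) == n_before

    def test_relaxation_to_mean(self, cfg):
        """With sigma=0 and large theta the pool converges to mu quickly."""
        cfg2 = cfg.with_overrides(
            {"lineages": {"NK": {"mu": 50, "theta": 1.0, "sigma": 0.0}}}
        )
        state, rng = make_empty_state(cfg2, lineage_mus={"NK": 50})
        # empty the pool and restart the homeostat from zero
        state.compartments[CompartmentId.SECONDARY_ORGAN] = []
        state.invalidate_site_map()
        state.ou_targets[CellType.NK] = 0.0
        for _ in range(10):
            haematopoiesis(state, cfg2, rng)
        total = sum(
            1 for comp in CompartmentId
            for a in state.compartments[comp]
            if a.cell_type is CellType.NK
        )
        assert abs(total - 50) <= 1  # within 1% of mu=50

    def test_new_receptors_uniform(self, cfg):
        """Receptors of marrow-produced B cells pass a uniformity test."""
        cfg2 = cfg.with_overrides(
            {"shape_space": {"l": 8, "d_min": 6, "d_min_mhc": 5}}
        )
        state, rng = make_empty_state(cfg2)
        state.lineage_params[CellType.B] = OUParams(100_000, 50.0, 0.0)
        state.ou_targets[CellType.B] = 0.0
        haematopoiesis(state, cfg2, rng)
        marrow = state.compartments[CompartmentId.BONE_MARROW]
        values = [a.receptor.value for a in marrow if a.cell_type is CellType.B]
        assert len(values) > 90_000
        from scipy import stats

        counts = np.bincount(values, minlength=256)
        assert stats.chisquare(counts).pvalue > 0.01


class TestSecretion:
    def test_unsuppressed_delta_equals_base_rate(self, cfg):
        state, rng = make_empty_state(cfg)
        mac = _mk(CellType.MAC, state=CellState.ACTIVE)
        state.add_agent(CompartmentId.SECONDARY_ORGAN, mac)
        secrete(mac, state, state.secretion_table)
        rate = cfg["secretion"]["MAC.ACTIVE"]["IL6"]
        assert state.fields["IL6"].conc[0] == pytest.approx(rate)

    def test_full_suppression_zeroes_target_only(self, cfg):
        state, rng = make_empty_state(cfg)
        state.multipliers = {("CYTOKINE_SECRETION", "IL6"): 0.0}
        mac = _mk(CellType.MAC, state=CellState.ACTIVE)
        state.add_agent(CompartmentId.SECONDARY_ORGAN, mac)
        secrete(mac, state, state.secretion_table)
        assert state.fields["IL6"].conc[0] == 0.0
        assert state.fields["TNFA"].conc[0] > 0.0

    def test_plasma_cell_pool_linearity(self, cfg):
        """5 plasma cells, rate r, n rounds with no decay: pool = 5*r*n."""
        from immunotox.engine import _secrete_immunoglobulin

        state, rng = make_empty_state(cfg)
        for _ in range(5):
            plb = CellAgent(
                cell_type=CellType.PLB, position=2, state=CellState.ACTIVE,
                receptor=BitString(12, 99), isotype=Isotype.IgG,
            )
            state.add_agent(CompartmentId.SECONDARY_ORGAN, plb)
        n = 7
        for _ in range(n):
            _secrete_immunoglobulin(state, cfg)
        r = cfg["immunoglobulin"]["secretion_rate"]
        total = sum(c.sum() for c in state.ig_pools.values())
        assert total == pytest.approx(5 * r * n)


class TestStepWorld:
    def test_uninitialized_state_rejected(self, cfg):
        state, rng = make_empty_state(cfg)
        state.initialized = False
        with pytest.raises(RuntimeError):
            step_world(state, cfg, rng)

    def test_empty_world_only_clock_advances(self, cfg):
        state, rng = make_empty_state(cfg)
        step_world(state, cfg, rng)
        assert state.t == 1
        assert all(not v for v in state.compartments.values())
        assert all(f.total() == 0.0 for f in state.fields.values())

    def test_snapshot_determinism(self, cfg):
        """Same config and seed: identical serialized state at every step."""
        from immunotox.trial import antigen_from_id

        snaps = []
        for _ in range(2):
            state, rng = make_empty_state(
                cfg, seed=77, lineage_mus={"B": 20, "MAC": 10, "TH2": 10}
            )
            state.inject_antigen(antigen_from_id("probe", cfg.l), 200)
            run = []
            for _ in range(15):
                step_world(state, cfg, rng)
                run.append(state.snapshot())
            snaps.append(run)
        assert snaps[0] == snaps[1]

    def test_unmatched_pamp_free_antigen_decays_silently(self, cfg):
        """No complementary lymphocytes, no danger signal: the antigen
        decays below 1% of the dose and no immunoglobulin appears."""
        from immunotox.trial import antigen_from_id

        state, rng = make_empty_state(cfg)
        ag = antigen_from_id("inert", cfg.l, pamp=False)
        # B cells identical to the epitope: d=0 < d_min, cannot bind
        for _ in range(10):
            b = CellAgent(
                cell_type=CellType.B, position=0, receptor=ag.b_epitope
            )
            state.add_agent(CompartmentId.SECONDARY_ORGAN, b)
        state.inject_antigen(ag, 1000)
        for _ in range(80):
            step_world(state, cfg, rng)
        assert state.antigen_counts["inert"].sum() < 10  # < 1% of dose
        assert state.specific_ig_total("inert", Isotype.IgM) == 0.0
        assert state.specific_ig_total("inert", Isotype.IgG) == 0.0
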