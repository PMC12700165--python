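import itertools

import numpy as np
import pandas as pd
import pytest

from rumenaux import complementarity as cp
from rumenaux import kegg_modules as km
from rumenaux.types import Reaction

K1, K2, K3 = "K00001", "K00002", "K00003"


def defs_from(*pairs):
    return {mid: km.ModuleDefinition(mid, mid, km.parse_definition(d), d)
            for mid, d in pairs}


def scope_oracle(reactions, seeds):
    """Brute force: iterate single-reaction firings in every ordering
    until nothing changes; order independence is asserted by comparing
    random shuffles."""
    rng = np.random.default_rng(0)
    results = set()
    for _ in range(5):
        order = list(reactions)
        rng.shuffle(order)
        reach = set(seeds)
        progress = True
        while progress:
            progress = False
            for r in order:
                if r.substrates <= reach and not r.products <= reach:
                    reach |= r.products
                    progress = True
                if r.reversible and r.products <= reach \
                        and not r.substrates <= reach:
                    reach |= r.substrates
                    progress = True
        results.add(frozenset(reach))
    assert len(results) == 1, "oracle found order dependence"
    return set(next(iter(results)))


class TestCompletionGain:
    def test_aux_completes_missing_step(self):
        defs = defs_from(("M00001", f"{K1} {K2}"))
        gains = cp.completion_gain({K2}, {K1}, defs)
        assert gains["M00001"] == pytest.approx(0.5)

    def test_subset_aux_gains_nothing(self):
        defs = defs_from(("M00001", f"{K1} {K2}"), ("M00002", f"{K3}"))
        gains = cp.completion_gain({K1}, {K1, K2, K3}, defs)
        assert all(g == 0 for g in gains.values())

    def test_complete_target_gains_nothing(self):
        defs = defs_from(("M00001", f"{K1} {K2}"))
        gains = cp.completion_gain({K3}, {K1, K2}, defs)
        assert gains["M00001"] == 0.0

    def test_gain_never_negative_random_pairs(self):
        rng = np.random.default_rng(23)
        universe = [f"K{i:05d}" for i in range(1, 9)]
        defs = defs_from(
            ("M00001", "K00001 K00002,K00003"),
            ("M00002", "K00004+K00005 K00006"),
            ("M00003", "(K00001 K00007),K00008"))
        for _ in range(300):
            aux = {k for k in universe if rng.random() < 0.4}
            target = {k for k in universe if rng.random() < 0.4}
            gains = cp.completion_gain(aux, target, defs)
            assert all(g >= 0 for g in gains.values())
            if aux <= target:
                assert all(g == 0 for g in gains.values())


class TestScopeExpansion:
    def test_linear_chain(self):
        rx = [Reaction(frozenset("A"), frozenset("B")),
              Reaction(frozenset("B"), frozenset("C"))]
        assert cp.scope_expansion(rx, {"A"}) == {"A", "B", "C"}

    def test_no_reactions_returns_seeds(self):
        assert cp.scope_expansion([], {"A"}) == {"A"}

    def test_conjunctive_substrates_block(self):
        rx = [Reaction(frozenset({"A", "X"}), frozenset("B"))]
        assert cp.scope_expansion(rx, {"A"}) == {"A"}

    def test_reversible_fires_backwards(self):
        rx = [Reaction(frozenset("A"), frozenset("B"), reversible=True)]
        assert cp.scope_expansion(rx, {"B"}) == {"A", "B"}

    def test_empty_seeds_rejected(self):
        with pytest.raises(ValueError):
            cp.scope_expansion([], set())

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        mets = list("ABCDEFGH")
        for _ in range(100):
            rx = [Reaction(frozenset(rng.choice(mets, rng.integers(1, 3),
                                                replace=False)),
                           frozenset(rng.choice(mets, rng.integers(1, 3),
                                                replace=False)),
                           bool(rng.random() < 0.3))
                  for _ in range(int(rng.integers(1, 7)))]
            seeds = set(rng.choice(mets, 2, replace=False))
            once = cp.scope_expansion(rx, seeds)
            assert cp.scope_expansion(rx, once) == once

    def test_matches_brute_force_oracle(self):
        """Fixpoint equals the exhaustive random-ordering oracle on all
        small networks."""
        rng = np.random.default_rng(9)
        mets = list("ABCDEFGH")
        for _ in range(200):
            rx = [Reaction(frozenset(rng.choice(mets, rng.integers(1, 3),
                                                replace=False)),
                           frozenset(rng.choice(mets, rng.integers(1, 3),
                                                replace=False)),
                           bool(rng.random() < 0.3))
                  for _ in range(int(rng.integers(1, 7)))]
            seeds = set(rng.choice(mets, rng.integers(1, 3), replace=False))
            assert cp.scope_expansion(rx, seeds) == scope_oracle(rx, seeds)

    def test_monotone_in_seeds_and_reactions(self):
        rx = [Reaction(frozenset("A"), frozenset("B")),
              Reaction(frozenset("B"), frozenset("C")),
              Reaction(frozenset("D"), frozenset("E"))]
        small = cp.scope_expansion(rx[:1], {"A"})
        assert small <= cp.scope_expansion(rx, {"A"})
        assert cp.scope_expansion(rx, {"A"}) \
            <= cp.scope_expansion(rx, {"A", "D"})


class TestMetaboliteGain:
    TABLE = {K1: [Reaction(frozenset("A"), frozenset("B"))],
             K2: [Reaction(frozenset("B"), frozenset("C"))]}

    def test_chain_extension_counts_new_metabolite(self):
        assert cp.metabolite_gain({K2}, {K1}, self.TABLE, {"A"}) == 1

    def test_aux_without_reactions_gains_nothing(self):
        assert cp.metabolite_gain({K3}, {K1}, self.TABLE, {"A"}) == 0

    def test_default_seeds_are_never_produced(self):
        seeds = cp.default_seeds(self.TABLE)
        assert seeds == {"A"}


class TestAggregation:
    def _tp_presence(self, genomes, tps, absent=()):
        df = pd.DataFrame(True, index=pd.Index(genomes), columns=tps)
        for g, tp in absent:
            df.loc[g, tp] = False
        return df

    def _records(self, rows):
        return pd.DataFrame(rows, columns=["aux_genome", "target_genome",
                                           "module_id", "gain",
                                           "metabolite_gain"])

    def test_single_pair_single_tp(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1)])
        pres = self._tp_presence(["a1", "t1"], [1])
        raw, zs, n = cp.aggregate_contribution_by_tp(records, pres)
        assert raw.loc["M1", 1] == pytest.approx(0.5)
        assert n[1] == 1

    def test_divide_by_contributors(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1),
                                 ("a2", "t1", "M1", 0.5, 1)])
        pres = self._tp_presence(["a1", "a2", "t1"], [1])
        raw, _, n = cp.aggregate_contribution_by_tp(records, pres)
        assert raw.loc["M1", 1] == pytest.approx(0.5)
        assert n[1] == 2

    def test_constant_row_zscores_to_zero(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1)])
        pres = self._tp_presence(["a1", "t1"], [1, 2, 3])
        _, zs, _ = cp.aggregate_contribution_by_tp(records, pres)
        assert (zs.loc["M1"] == 0).all()

    def test_absent_pair_excluded_at_tp(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1)])
        pres = self._tp_presence(["a1", "t1"], [1, 2], absent=[("t1", 2)])
        raw, _, n = cp.aggregate_contribution_by_tp(records, pres)
        assert raw.loc["M1", 2] == 0.0
        assert n[2] == 0


class TestRankContributors:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["aux_genome", "target_genome",
                                           "module_id", "gain",
                                           "metabolite_gain"])

    def test_two_contributor_zscore(self):
        # totals 1.0 vs 3.0 -> population-SD z of (-0.707..., +0.707...)
        records = self._records([("a1", "t1", "M1", 1.0, 0),
                                 ("a2", "t1", "M1", 3.0, 0)])
        pres = pd.DataFrame(True, index=["a1", "a2", "t1"], columns=[1])
        raw, zs = cp.rank_contributors(records, pres)
        assert sorted(zs[1].tolist()) == pytest.approx(
            [-1 / np.sqrt(2), 1 / np.sqrt(2)])

    def test_sole_contributor_z_is_zero(self):
        records = self._records([("a1", "t1", "M1", 1.0, 0)])
        pres = pd.DataFrame(True, index=["a1", "t1"], columns=[1])
        _, zs = cp.rank_contributors(records, pres)
        assert zs.loc["a1", 1] == 0.0

    def test_absent_genome_contributes_zero_raw(self):
        records = self._records([("a1", "t1", "M1", 1.0, 0)])
        pres = pd.DataFrame([[True, False], [True, True]],
                            index=["a1", "t1"], columns=[1, 2])
        pres.loc["a1", 2] = False
        raw, _ = cp.rank_contributors(records, pres)
        assert raw.loc["a1", 2] == 0.0


class TestPersistentContributors:
    def _records(self, rows):
        return pd.DataFrame(rows, columns=["aux_genome", "target_genome",
                                           "module_id", "gain",
                                           "metabolite_gain"])

    def _presence(self, genomes, present_tps):
        tps = list(range(1, 15))
        df = pd.DataFrame(False, index=pd.Index(genomes), columns=tps)
        for g, tp_list in present_tps.items():
            df.loc[g, tp_list] = True
        return df

    def test_two_later_stages_included(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1)])
        pres = self._presence(["a1", "t1"], {"a1": [8, 12], "t1": [8, 12]})
        assert cp.persistent_contributors(records, pres) == {"a1"}

    def test_one_later_stage_excluded(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1)])
        pres = self._presence(["a1", "t1"], {"a1": [8], "t1": [8]})
        assert cp.persistent_contributors(records, pres) == set()

    def test_only_early_stages_excluded(self):
        records = self._records([("a1", "t1", "M1", 0.5, 1)])
        pres = self._presence(["a1", "t1"], {"a1": [5, 6], "t1": [5, 6]})
        assert cp.persistent_contributors(records, pres) == set()


def test_planted_records_recovered_exactly(bundle, cfg, tmp_path):
    """The gain>0 record set on the synthetic bundle equals the planted
    complementarity design, and every planted pair gains >= 1 metabolite."""
    from rumenaux import io as rio
    defs = km.parse_module_table(bundle.module_table)
    ko_sets = {g: set(d) for g, d in bundle.ko_counts.items()}
    groups = bundle.truth.groups
    aux = {g: ko_sets[g] for g in ko_sets if groups.get(g) == "auxiliary"}
    tgt = {g: ko_sets[g] for g in ko_sets
           if groups.get(g) == "non_auxiliary"}
    path = tmp_path / "rx.tsv"
    bundle.reaction_rows.to_csv(path, sep="\t", index=False)
    table = rio.read_reaction_table(path)
    records = cp.pairwise_records(aux, tgt, defs, reaction_table=table)
    got = set(map(tuple, records[["aux_genome", "target_genome",
                                  "module_id"]].to_numpy()))
    assert got == bundle.truth.complementarity
    assert (records["gain"] > 0).all()
    assert (records["metabolite_gain"] >= 1).all()
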