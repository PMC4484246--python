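import math

import networkx as nx
import numpy as np
import pytest

from degnet import abundance, metaweb
from degnet import synthetic_data as sd
from degnet.errors import ValidationError
from degnet.io_catalog import MetaboliteEvidence, Reaction
from degnet.metaweb import MetaNetwork


def profile_of(sample, family_counts, total=10_000):
    return abundance.CatabolicProfile(sample, family_counts, (float(total), 0.0), "dna")


class TestBuildNetwork:
    def test_single_reaction(self):
        prof = profile_of("S", {"XylE": 5.0})  # 0.05 %
        net = metaweb.build_network([prof], [Reaction("XylE", "CAT", "124")])
        assert net.nodes == {"CAT", "124"}
        assert list(net.edges) == [("CAT", "124", "XylE")]
        assert net.weight(("CAT", "124", "XylE"), "S") == pytest.approx(0.05)

    def test_all_zero_profiles_empty_network(self):
        net = metaweb.build_network(
            [profile_of("S", {})], [Reaction("XylE", "CAT", "124")]
        )
        assert net.edges == {}
        assert net.nodes == set()

    def test_random_instance_matches_set_oracle(self):
        rng = np.random.default_rng(8)
        fams = [f"F{i}" for i in range(15)]
        reactions = []
        for i in range(40):
            sub, prod = f"C{rng.integers(20):02d}", f"C{20 + rng.integers(20):02d}"
            rxn = Reaction(str(rng.choice(fams)), sub, prod)
            if rxn.key not in {r.key for r in reactions}:
                reactions.append(rxn)
        profiles = [
            profile_of(
                f"S{j}",
                {f: float(rng.integers(0, 3)) for f in fams if rng.random() < 0.5},
            )
            for j in range(6)
        ]
        net = metaweb.build_network(profiles, reactions)
        # independent set-comprehension oracle
        pct = {p.sample_id: p.family_percent for p in profiles}
        exp_edges = {
            (r.substrate_code, r.product_code, r.family_id)
            for r in reactions
            if any(pct[s].get(r.family_id, 0.0) > 0 for s in pct)
        }
        exp_nodes = {c for sub, prod, _ in exp_edges for c in (sub, prod)}
        assert set(net.edges) == exp_edges
        assert net.nodes == exp_nodes
        for (sub, prod, fam), weights in net.edges.items():
            for s in pct:
                assert weights[s] == pytest.approx(pct[s].get(fam, 0.0), abs=1e-12)

    def test_unknown_family_named(self):
        prof = profile_of("S", {"Mystery": 1.0})
        with pytest.raises(ValidationError, match="Mystery"):
            metaweb.build_network(
                [prof], [Reaction("XylE", "CAT", "124")], families=["XylE"]
            )

    def test_combined_superset_of_dna(self, default_study):
        """Edges present in the DNA-only network survive pooling with
        imputed evidence (combined weight > 0 wherever DNA weight > 0)."""
        study = default_study
        dna_profiles = {}
        combined_profiles = {}
        for sid, ann in study.annotations.items():
            dna = abundance.profile(abundance.screen_hits(ann))
            imputed = abundance.profile(
                abundance.impute_from_taxonomy(
                    study.otu_table, study.otu_map, study.genomes, sid
                ),
                source_mix="imputed",
            )
            dna_profiles[sid] = dna
            combined_profiles[sid] = abundance.merge_sources(dna, imputed)
        net_dna = metaweb.build_network(list(dna_profiles.values()), study.reactions)
        net_comb = metaweb.build_network(list(combined_profiles.values()), study.reactions)
        assert set(net_dna.edges) <= set(net_comb.edges)
        for key, weights in net_dna.edges.items():
            for s, w in weights.items():
                if w > 0:
                    assert net_comb.edges[key][s] > 0


# ---------------------------------------------------------------------------
# confidence model
# ---------------------------------------------------------------------------


def pava_oracle(values):
    """Independent unweighted pool-adjacent-violators (non-decreasing)."""
    blocks = [[v, 1] for v in values]  # [mean, size]
    out = []
    for mean, size in blocks:
        out.append([mean, size])
        while len(out) > 1 and out[-2][0] > out[-1][0]:
            m2, s2 = out.pop()
            m1, s1 = out.pop()
            out.append([(m1 * s1 + m2 * s2) / (s1 + s2), s1 + s2])
    result = []
    for mean, size in out:
        result.extend([mean] * size)
    return result


def evidence_rows(pairs, chemical="CAT"):
    """pairs: list of (gene_count, degraded?) -> (evidence, gene_counts)."""
    ev, counts = [], {}
    for i, (k, y) in enumerate(pairs):
        sid = f"s{i}"
        ev.append(
            MetaboliteEvidence(
                sid, chemical, "degraded" if y else "not_degraded", "substrate_depleted"
            )
        )
        counts[(sid, chemical)] = k
    return ev, counts


class TestFitConfidence:
    def test_all_degraded_smoothing_limit(self):
        # n rows, all degraded, all with the same gene count: every k has the
        # full n qualifying rows, so conf(k) = (n+1)/(n+2) everywhere
        n = 8
        ev, counts = evidence_rows([(5, 1)] * n)
        model = metaweb.fit_confidence(ev, counts)
        curve = model.curves["CAT"]
        for k in range(6):
            assert curve(k) == pytest.approx((n + 1) / (n + 2), abs=1e-12)
        assert curve(0) == pytest.approx(0.9, abs=1e-12)

    def test_monotonization_equals_pava_oracle(self):
        rng = np.random.default_rng(4)
        pairs = [(int(k), int(rng.random() < 0.5 + 0.1 * k)) for k in rng.integers(0, 6, 200)]
        ev, counts = evidence_rows(pairs)
        model = metaweb.fit_confidence(ev, counts)
        curve = model.curves["CAT"]
        # independent reconstruction: smoothed tail frequencies, then PAVA
        ks = np.array([k for k, _ in pairs])
        ys = np.array([y for _, y in pairs])
        raw = [
            (ys[ks >= k].sum() + 1) / ((ks >= k).sum() + 2) for k in range(ks.max() + 1)
        ]
        assert np.allclose(curve.raw, raw, atol=1e-12)
        assert np.allclose(curve.conf, pava_oracle(raw), atol=1e-10)

    def test_known_violator_sequence(self):
        # raw proportions 0.9, 0.7, 0.95 pool to 0.8, 0.8, 0.95
        assert pava_oracle([0.9, 0.7, 0.95]) == pytest.approx([0.8, 0.8, 0.95])
        from sklearn.isotonic import IsotonicRegression

        fit = IsotonicRegression(increasing=True).fit_transform(
            [0, 1, 2], [0.9, 0.7, 0.95]
        )
        assert np.allclose(fit, [0.8, 0.8, 0.95], atol=1e-12)

    def test_planted_curve_recovery(self):
        curve = sd.DEFAULT_CONFIDENCE_CURVE
        ev, counts, ks, _ = sd.generate_confidence_evidence(curve, 500, seed=3)
        model = metaweb.fit_confidence(ev, counts)
        planted = sd.tail_conditional(curve, ks)
        fitted = np.array([model.global_curve(k) for k in range(len(planted))])
        assert np.max(np.abs(fitted - planted)) <= 0.1

    def test_monotone_nondecreasing_always(self):
        for seed in range(5):
            ev, counts, *_ = sd.generate_confidence_evidence(
                sd.DEFAULT_CONFIDENCE_CURVE, 60, seed=seed
            )
            model = metaweb.fit_confidence(ev, counts)
            for curve in list(model.curves.values()) + [model.global_curve]:
                assert np.all(np.diff(curve.conf) >= -1e-12)
                assert np.all((curve.conf >= 0) & (curve.conf <= 1))

    def test_chemical_without_evidence_uses_global(self):
        ev, counts = evidence_rows([(2, 1), (3, 1), (0, 0)])
        model = metaweb.fit_confidence(ev, counts)
        assert model.confidence("UNSEEN", 2) == model.global_curve(2)

    def test_catalog_check(self):
        ev, counts = evidence_rows([(1, 1)])
        with pytest.raises(ValidationError, match="CAT"):
            metaweb.fit_confidence(ev, counts, catalog_codes=["ALK"])


class TestDegradable:
    @staticmethod
    def model_with(chemical="CAT"):
        # 8 identical all-degraded rows: conf(k) = 0.9 exactly for all k
        ev, counts = evidence_rows([(5, 1)] * 8, chemical=chemical)
        return metaweb.fit_confidence(ev, counts)

    def test_exact_threshold_included(self):
        # conf(k) == 0.9 exactly (smoothing limit with n = 8)
        model = self.model_with()
        net = MetaNetwork(samples=["S"], edges={("CAT", "124", "XylE"): {"S": 0.1}})
        dset = metaweb.degradable(net, model, {("S", "CAT"): 1}, threshold=0.90)
        assert dset.per_sample["S"] == {"CAT"}

    def test_low_confidence_excluded_despite_edge(self):
        ev, counts = evidence_rows([(0, 0), (0, 0), (5, 1), (5, 1)])
        model = metaweb.fit_confidence(ev, counts)
        assert model.confidence("CAT", 0) < 0.9
        net = MetaNetwork(samples=["S"], edges={("CAT", "124", "XylE"): {"S": 0.1}})
        dset = metaweb.degradable(net, model, {("S", "CAT"): 0})
        assert dset.per_sample["S"] == set()

    def test_random_instance_matches_brute_force(self, default_study):
        study = default_study
        profiles = [
            abundance.profile(abundance.screen_hits(a))
            for a in study.annotations.values()
        ]
        net = metaweb.build_network(profiles, study.reactions)
        counts = study.truth.gene_counts
        model = metaweb.fit_confidence(study.evidence, counts)
        dset = metaweb.degradable(net, model, counts)
        # exhaustive per-chemical re-evaluation
        for s in net.samples:
            expected = set()
            for chem in {sub for sub, _, _ in net.edges}:
                has_edge = any(
                    sub == chem and w.get(s, 0) > 0 for (sub, _, _), w in net.edges.items()
                )
                if has_edge and model.confidence(chem, counts.get((s, chem), 0)) >= 0.9:
                    expected.add(chem)
            assert dset.per_sample[s] == expected
        assert dset.union >= dset.per_sample[net.samples[0]]

    def test_threshold_monotonicity(self, default_study):
        study = default_study
        profiles = [
            abundance.profile(abundance.screen_hits(a))
            for a in study.annotations.values()
        ]
        net = metaweb.build_network(profiles, study.reactions)
        counts = study.truth.gene_counts
        model = metaweb.fit_confidence(study.evidence, counts)
        prev = None
        for thr in (0.95, 0.9, 0.8, 0.5, 0.1):
            dset = metaweb.degradable(net, model, counts, threshold=thr)
            if prev is not None:
                for s in net.samples:
                    assert prev.per_sample[s] <= dset.per_sample[s]
            prev = dset

    def test_bad_threshold(self):
        net = MetaNetwork(samples=["S"], edges={})
        model = self.model_with()
        with pytest.raises(ValidationError):
            metaweb.degradable(net, model, {}, threshold=0.0)


class TestReachableProducts:
    def chain(self):
        return MetaNetwork(
            samples=["S"],
            edges={
                ("a", "b", "F1"): {"S": 0.1},
                ("b", "c", "F2"): {"S": 0.2},
            },
        )

    def test_chain(self):
        assert metaweb.reachable_products(self.chain(), "S", ["a"]) == {"b", "c"}

    def test_zero_weight_breaks_chain(self):
        net = self.chain()
        net.edges[("b", "c", "F2")]["S"] = 0.0
        assert metaweb.reachable_products(net, "S", ["a"]) == {"b"}

    def test_unknown_source(self):
        with pytest.raises(ValidationError, match="zzz"):
            metaweb.reachable_products(self.chain(), "S", ["zzz"])

    def test_random_dag_matches_networkx(self):
        rng = np.random.default_rng(2)
        nodes = [f"n{i}" for i in range(30)]
        edges = {}
        for _ in range(60):
            i, j = sorted(rng.choice(30, size=2, replace=False))
            w = float(rng.random() > 0.3) * float(rng.random())
            edges[(nodes[i], nodes[j], f"F{i}_{j}")] = {"S": w}
        net = MetaNetwork(samples=["S"], edges=edges)
        sources = [nodes[0], nodes[3]]
        got = metaweb.reachable_products(net, "S", sources)
        # independent graph-library oracle
        g = nx.DiGraph()
        g.add_nodes_from(net.nodes)
        for (u, v, _), w in edges.items():
            if w["S"] > 0:
                g.add_edge(u, v)
        expected = set()
        for s in sources:
            expected |= nx.descendants(g, s)
        assert got == expected

    def test_idempotent_and_monotone(self):
        net = self.chain()
        first = metaweb.reachable_products(net, "S", ["a"])
        # monotone: adding an edge never removes reachability
        net.edges[("c", "d", "F3")] = {"S": 0.5}
        second = metaweb.reachable_products(net, "S", ["a"])
        assert first <= second


class TestCompareNetworks:
    def test_identical_networks(self):
        net = MetaNetwork(samples=["S"], edges={("a", "b", "F"): {"S": 0.2}})
        cmp = metaweb.compare_networks(net, net)
        assert cmp.only_in_a == set() and cmp.only_in_b == set()
        assert cmp.family_weight_ratio == {"F": pytest.approx(1.0)}

    def test_family_absent_in_b(self):
        a = MetaNetwork(
            samples=["S"],
            edges={("CAT", "124", "XylE"): {"S": 0.3}, ("CAT", "MUC", "CatA"): {"S": 0.1}},
        )
        b = MetaNetwork(samples=["S"], edges={("CAT", "MUC", "CatA"): {"S": 0.1}})
        cmp = metaweb.compare_networks(a, b)
        assert cmp.families_only_in_a == {"XylE"}
        assert cmp.only_in_a == {("CAT", "124", "XylE")}

    def test_random_pair_set_algebra(self):
        rng = np.random.default_rng(9)
        def rand_net():
            edges = {}
            for i in range(20):
                if rng.random() < 0.6:
                    edges[(f"c{i}", f"c{i + 20}", f"F{i}")] = {"S": float(rng.random())}
            return MetaNetwork(samples=["S"], edges=edges)

        a, b = rand_net(), rand_net()
        cmp = metaweb.compare_networks(a, b)
        ea, eb = set(a.edges), set(b.edges)
        assert cmp.shared_edges == ea & eb
        assert cmp.only_in_a == ea - eb
        assert cmp.only_in_b == eb - ea
        assert cmp.n_substrates_a == len({s for s, _, _ in ea})
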