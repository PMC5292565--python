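"""Rule engine: canonical labels, embeddings, network generation."""

import itertools
import random

import pytest

from vegfnet.rules import (
    Action, ModelStructureError, MoleculeType, Observable, Rule, Seed,
    canonical_label, find_embeddings, generate_network, match_embeddings,
    parse_pattern, parse_species,
)

R2ISH = MoleculeType("R", ("l", "c", "y"), {"y": ("U", "P")})
LIG = MoleculeType("V", ("r", "r"))
TYPES = {"R": R2ISH, "V": LIG}


def brute_force_isomorphic(g1, g2) -> bool:
    """Oracle: exhaustive search over molecule bijections and site matchings."""
    if g1.compartment != g2.compartment or len(g1.mols) != len(g2.mols):
        return False

    def site_match(m1, m2, perm):
        # try to biject sites of m1 onto sites of m2 preserving name, state
        # and bond image under the molecule permutation
        n = len(m1.sites)
        for sperm in itertools.permutations(range(n)):
            ok = True
            for a in range(n):
                b = sperm[a]
                if m1.sites[a] != m2.sites[b] or m1.states[a] != m2.states[b]:
                    ok = False
                    break
            if ok:
                yield sperm

    n = len(g1.mols)
    for perm in itertools.permutations(range(n)):
        if any(g1.mols[i].type.name != g2.mols[perm[i]].type.name
               for i in range(n)):
            continue
        for sperms in itertools.product(
                *(site_match(g1.mols[i], g2.mols[perm[i]], perm)
                  for i in range(n))):
            consistent = True
            for i in range(n):
                for a, partner in enumerate(g1.mols[i].bonds):
                    img = g2.mols[perm[i]].bonds[sperms[i][a]]
                    if partner is None:
                        if img is not None:
                            consistent = False
                            break
                    else:
                        j, sj = partner
                        if img != (perm[j], sperms[j][sj]):
                            consistent = False
                            break
                if not consistent:
                    break
            if consistent:
                return True
    return False


def random_complex(rng, max_mols=4):
    """Random small connected complex over TYPES."""
    n = rng.randint(1, max_mols)
    pats = []
    for i in range(n):
        pats.append(random.Random(rng.random()).choice(["R", "V"]))
    # build a random tree of bonds between compatible free sites
    mols = []
    g = parse_species("R(l,c,y~U)", TYPES)  # placeholder to copy types
    from vegfnet.rules import Molecule, SpeciesGraph
    for name in pats:
        m = Molecule(TYPES[name])
        if name == "R":
            m.states[2] = rng.choice(["U", "P"])
        mols.append(m)
    sg = SpeciesGraph(mols, "surf")
    for i in range(1, len(mols)):
        j = rng.randint(0, i - 1)
        free_i = [s for s, b in enumerate(mols[i].bonds) if b is None]
        free_j = [s for s, b in enumerate(mols[j].bonds) if b is None]
        if not free_i or not free_j:
            return None
        si, sj = rng.choice(free_i), rng.choice(free_j)
        mols[i].bonds[si] = (j, sj)
        mols[j].bonds[sj] = (i, si)
    return sg


def permuted_copy(g, rng):
    from vegfnet.rules import Molecule, SpeciesGraph
    n = len(g.mols)
    perm = list(range(n))
    rng.shuffle(perm)
    inv = {old: new for new, old in enumerate(perm)}
    mols = []
    for old in perm:
        m = g.mols[old]
        nm = Molecule(m.type)
        nm.states = list(m.states)
        nm.bonds = [(inv[p[0]], p[1]) if p else None for p in m.bonds]
        mols.append(nm)
    return SpeciesGraph(mols, g.compartment)


class TestCanonicalLabel:
    def test_symmetric_dimer_molecule_order(self):
        a = parse_species("R(l,c!1,y~U).R(l,c!1,y~P)", TYPES)
        b = parse_species("R(l,c!1,y~P).R(l,c!1,y~U)", TYPES)
        assert canonical_label(a) == canonical_label(b)

    def test_state_difference_distinguishes(self):
        a = parse_species("R(l,c,y~U)", TYPES)
        b = parse_species("R(l,c,y~P)", TYPES)
        assert canonical_label(a) != canonical_label(b)

    def test_compartment_distinguishes(self):
        a = parse_species("R(l,c,y~U)", TYPES, "surf")
        b = parse_species("R(l,c,y~U)", TYPES, "endo")
        assert canonical_label(a) != canonical_label(b)

    def test_label_invariant_under_permutation(self):
        rng = random.Random(7)
        checked = 0
        while checked < 100:
            g = random_complex(rng)
            if g is None:
                continue
            h = permuted_copy(g, rng)
            assert canonical_label(g) == canonical_label(h)
            assert brute_force_isomorphic(g, h)
            checked += 1

    def test_distinct_graphs_get_distinct_labels(self):
        # pairwise check on a pool of random complexes against the oracle
        rng = random.Random(11)
        pool = []
        while len(pool) < 25:
            g = random_complex(rng)
            if g is not None:
                pool.append(g)
        for g1, g2 in itertools.combinations(pool, 2):
            same_label = canonical_label(g1) == canonical_label(g2)
            assert same_label == brute_force_isomorphic(g1, g2)

    def test_dangling_bond_rejected(self):
        g = parse_species("R(l,c,y~U)", TYPES)
        g.mols[0].bonds[0] = (0, 1)  # half-bond: site 1 does not point back
        with pytest.raises(ModelStructureError):
            canonical_label(g)


class TestMatchEmbeddings:
    def test_unbound_receptor_vs_monomer(self):
        p = parse_pattern("R(l)", TYPES)
        g = parse_species("R(l,c,y~U)", TYPES)
        assert match_embeddings(p, g) == 1

    def test_two_free_arms_count_twice(self):
        p = parse_pattern("V(r)", TYPES)
        g = parse_species("V(r,r)", TYPES)
        assert match_embeddings(p, g) == 2

    def test_bound_site_pattern(self):
        p = parse_pattern("V(r!+)", TYPES)
        g = parse_species("V(r!1,r).R(l!1,c,y~U)", TYPES)
        assert match_embeddings(p, g) == 1

    def test_counts_equal_exhaustive_enumeration(self):
        rng = random.Random(23)
        pats = [parse_pattern(t, TYPES) for t in
                ["R(y~P)", "R(l)", "V(r!+)", "R(c!+)", "V(r)", "R(y~U,c)"]]
        checked = 0
        while checked < 20:
            g = random_complex(rng)
            if g is None:
                continue
            checked += 1
            for p in pats:
                got = match_embeddings(p, g)
                expect = _exhaustive_count(p, g)
                assert got == expect, (p, canonical_label(g))

    def test_disconnected_same_complex_pattern(self):
        p = parse_pattern("R(y~P).R(y~U)", TYPES)
        dimer = parse_species("R(l,c!1,y~P).R(l,c!1,y~U)", TYPES)
        assert match_embeddings(p, dimer) == 1
        mono = parse_species("R(l,c,y~P)", TYPES)
        assert match_embeddings(p, mono) == 0


def _exhaustive_count(p, g):
    """Independent embedding counter: brute force over all injective maps."""
    from vegfnet.rules import FREE, ANY, WILD
    n = 0
    mols = list(range(len(g.mols)))
    for mol_map in itertools.permutations(mols, len(p.mols)):
        if any(g.mols[mol_map[i]].type.name != p.mols[i].type
               for i in range(len(p.mols))):
            continue
        site_opts = []
        ok = True
        for i, pm in enumerate(p.mols):
            tm = g.mols[mol_map[i]]
            opts = []
            for assign in itertools.permutations(range(len(tm.sites)),
                                                 len(pm.psites)):
                good = True
                for k, ps in enumerate(pm.psites):
                    s = assign[k]
                    if tm.sites[s] != ps.name:
                        good = False
                        break
                    if ps.state is not None and tm.states[s] != ps.state:
                        good = False
                        break
                    b = tm.bonds[s]
                    if ps.bond is FREE and b is not None:
                        good = False
                        break
                    if ps.bond is ANY and b is None:
                        good = False
                        break
                    if isinstance(ps.bond, int) and b is None:
                        good = False
                        break
                if good:
                    opts.append(assign)
            if not opts:
                ok = False
                break
            site_opts.append(opts)
        if not ok:
            continue
        for combo in itertools.product(*site_opts):
            good = True
            ends = {}
            for i, pm in enumerate(p.mols):
                for k, ps in enumerate(pm.psites):
                    if isinstance(ps.bond, int):
                        ends.setdefault(ps.bond, []).append(
                            (mol_map[i], combo[i][k]))
            for bid, lst in ends.items():
                (ma, sa), (mb, sb) = lst
                if g.mols[ma].bonds[sa] != (mb, sb):
                    good = False
                    break
            if good:
                n += 1
    return n


class TestGenerateNetwork:
    def _toy_rules(self):
        types = {"L": MoleculeType("L", ("r",)), "R": MoleculeType("R", ("l",))}
        bind = Rule("bind", "react",
                    [parse_pattern("L(r)", types), parse_pattern("R(l)", types)],
                    "kon", actions=[Action("bond", (0, 0, 0), (1, 0, 0))])
        unbind = Rule("unbind", "react",
                      [parse_pattern("L(r!1).R(l!1)", types)], "koff",
                      actions=[Action("unbond", (0, 0, 0))])
        seeds = [Seed(parse_species("L(r)", types), "10"),
                 Seed(parse_species("R(l)", types), "20")]
        return types, seeds, [bind, unbind]

    def test_toy_reversible_binding(self):
        _, seeds, rules = self._toy_rules()
        net = generate_network(seeds, rules)
        assert net.n_species == 3
        assert net.n_reactions == 2       # one reversible pair, directed
        assert net.converged

    def test_single_monomer_no_rules(self):
        types = {"A": MoleculeType("A", ("a",))}
        net = generate_network([Seed(parse_species("A(a)", types), "1")], [])
        assert (net.n_species, net.n_reactions) == (1, 0)

    def test_order_independence(self):
        _, seeds, rules = self._toy_rules()
        n1 = generate_network(seeds, rules)
        n2 = generate_network(list(reversed(seeds)), list(reversed(rules)))
        assert n1.labels == n2.labels
        assert [(r.reactants, r.products, r.rate, r.factor)
                for r in n1.reactions] == \
               [(r.reactants, r.products, r.rate, r.factor)
                for r in n2.reactions]

    def test_homodimer_symmetry_factor(self):
        types = {"A": MoleculeType("A", ("a",))}
        dim = Rule("dim", "react",
                   [parse_pattern("A(a)", types), parse_pattern("A(a)", types)],
                   "kon", actions=[Action("bond", (0, 0, 0), (1, 0, 0))])
        undim = Rule("undim", "react",
                     [parse_pattern("A(a!1).A(a!1)", types)], "koff",
                     actions=[Action("unbond", (0, 0, 0))])
        net = generate_network([Seed(parse_species("A(a)", types), "5")],
                               [dim, undim])
        by_rule = {r.rule: r for r in net.reactions}
        assert by_rule["dim"].factor == pytest.approx(0.5)
        assert by_rule["undim"].factor == pytest.approx(1.0)

    def test_conservation_audit(self, network):
        """Non-degradation reactions balance per-molecule-type counts."""
        def counts(idx):
            out = {}
            for m in network.species[idx].mols:
                out[m.type.name] = out.get(m.type.name, 0) + 1
            return out

        for rx in network.reactions:
            if rx.degradation:
                assert rx.products == ()
                continue
            lhs, rhs = {}, {}
            for i in rx.reactants:
                for t, c in counts(i).items():
                    lhs[t] = lhs.get(t, 0) + c
            for i in rx.products:
                for t, c in counts(i).items():
                    rhs[t] = rhs.get(t, 0) + c
            assert lhs == rhs, rx

    def test_cap_flags_nonconvergence(self):
        _, seeds, rules = self._toy_rules()
        net = generate_network(seeds, rules, max_rounds=1)
        assert not net.converged

    def test_bad_caps_rejected(self):
        _, seeds, rules = self._toy_rules()
        with pytest.raises(ValueError):
            generate_network(seeds, rules, max_rounds=0)


class TestPackagedNetwork:
    def test_deterministic_regeneration(self, model, network):
        net2 = model.generate()
        assert net2.labels == network.labels
        assert len(net2.reactions) == len(network.reactions)

    def test_shuffled_rules_same_network(self, model, network):
        rules = list(model.rules)
        random.Random(3).shuffle(rules)
        net2 = generate_network(model.seeds, rules, model.observables)
        assert net2.labels == network.labels
        assert {(r.reactants, r.products, r.rate, r.factor)
                for r in net2.reactions} == \
               {(r.reactants, r.products, r.rate, r.factor)
                for r in network.reactions}

    def test_monotone_closure_converges(self, network):
        assert network.converged
        assert network.n_species > 100

    def test_anchor_types_merge_receptorless_endosomal_species(self, model):
        net = generate_network(model.seeds, model.rules, model.observables,
                               anchor_types={"VEGFR2"})
        assert net.n_species < model.generate().n_species
        for g in net.species:
            if g.compartment == "endo":
                assert any(m.type.name == "VEGFR2" for m in g.mols)
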