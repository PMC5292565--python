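"""Rule-based reaction-network generation over molecular site-graphs.

A molecular species is a connected *site-graph*: molecules carry named sites,
sites carry optional internal states (e.g. a phosphorylation flag) and may be
bonded pairwise.  Interaction rules are graph-rewriting operations (bond
make/break, state flips, whole-complex compartment moves and degradation)
applied to partially specified patterns.  Iterating the rules from a set of
seed species enumerates every reachable species and every mass-action
reaction between them, which is how combinatorially complex receptor models
(dimerisation x phosphorylation x trafficking x co-receptor decoration) are
specified compactly.

Species live in one of two compartments, ``surf`` (plasma membrane plus the
extracellular ligands it sees) and ``endo`` (endosomal).  The compartment is
a property of the whole complex; trafficking rules move or delete whole
complexes.

Statistical factors follow BioNetGen-style deterministic semantics:

* the rate of a generated reaction is ``k * factor * [S1](*[S2])`` where
  ``factor`` counts the distinct embeddings of the rule's patterns into the
  reactant species;
* a bimolecular rule whose two patterns are identical counts each unordered
  species pair once, and carries an extra factor 1/2 when both reactants are
  the *same* species (the usual homodimerisation convention);
* ``move``/``degrade`` rules fire once per matching complex (presence
  semantics), never proportionally to the number of internal matches.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

SURFACE = "surf"
ENDOSOME = "endo"
COMPARTMENTS = (SURFACE, ENDOSOME)

# bond specification markers for pattern sites
FREE = "free"       # site must be unbonded
ANY = "any"         # site must be bonded, partner unspecified (``!+``)
WILD = "wild"       # no constraint (``!?`` or site not mentioned)


class ModelStructureError(ValueError):
    """Malformed molecule/species/pattern definition."""


# ---------------------------------------------------------------------------
# molecule types and concrete species graphs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeType:
    """Declared molecule: ordered site list (duplicates allowed, e.g. the two
    receptor-binding arms of a VEGF dimer) and per-site allowed states."""

    name: str
    sites: tuple[str, ...] = ()
    states: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        for s in self.states:
            if s not in self.sites:
                raise ModelStructureError(
                    f"molecule {self.name}: state declared for unknown site {s!r}")

    def allowed_states(self, site: str) -> tuple[str, ...]:
        return self.states.get(site, ())


class Molecule:
    """One molecule instance inside a species graph."""

    __slots__ = ("type", "sites", "states", "bonds")

    def __init__(self, mtype: MoleculeType,
                 states: Sequence[str | None] | None = None):
        self.type = mtype
        self.sites = mtype.sites
        if states is None:
            states = [mtype.allowed_states(s)[0] if mtype.allowed_states(s)
                      else None for s in mtype.sites]
        self.states: list[str | None] = list(states)
        # per-site bond partner as (molecule_index, site_index) or None
        self.bonds: list[tuple[int, int] | None] = [None] * len(mtype.sites)


class SpeciesGraph:
    """A connected complex: molecules, bonds, site states, compartment."""

    __slots__ = ("mols", "compartment", "_label")

    def __init__(self, mols: list[Molecule], compartment: str = SURFACE):
        if compartment not in COMPARTMENTS:
            raise ModelStructureError(f"unknown compartment {compartment!r}")
        self.mols = mols
        self.compartment = compartment
        self._label: str | None = None

    # -- basic structure ----------------------------------------------------

    def copy(self) -> "SpeciesGraph":
        out = SpeciesGraph.__new__(SpeciesGraph)
        out.compartment = self.compartment
        out._label = None
        mols = []
        for m in self.mols:
            nm = Molecule.__new__(Molecule)
            nm.type = m.type
            nm.sites = m.sites
            nm.states = list(m.states)
            nm.bonds = list(m.bonds)
            mols.append(nm)
        out.mols = mols
        return out

    def validate(self) -> None:
        """Raise if bonds are not a symmetric perfect matching."""
        for i, m in enumerate(self.mols):
            for si, partner in enumerate(m.bonds):
                if partner is None:
                    continue
                j, sj = partner
                if not (0 <= j < len(self.mols)):
                    raise ModelStructureError("dangling bond: partner index out of range")
                back = self.mols[j].bonds[sj]
                if back != (i, si):
                    raise ModelStructureError(
                        f"dangling half-bond at molecule {i} site {si}")
            for si, st in enumerate(m.states):
                allowed = m.type.allowed_states(m.sites[si])
                if allowed and st not in allowed:
                    raise ModelStructureError(
                        f"{m.type.name}.{m.sites[si]}: state {st!r} not declared")
                if not allowed and st is not None:
                    raise ModelStructureError(
                        f"{m.type.name}.{m.sites[si]} carries a state but none declared")

    def is_connected(self) -> bool:
        if len(self.mols) <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for partner in self.mols[i].bonds:
                if partner is not None and partner[0] not in seen:
                    seen.add(partner[0])
                    stack.append(partner[0])
        return len(seen) == len(self.mols)

    def components(self) -> list["SpeciesGraph"]:
        """Split into connected components (used after bond deletion)."""
        n = len(self.mols)
        comp = [-1] * n
        ncomp = 0
        for start in range(n):
            if comp[start] >= 0:
                continue
            comp[start] = ncomp
            stack = [start]
            while stack:
                i = stack.pop()
                for partner in self.mols[i].bonds:
                    if partner is not None and comp[partner[0]] < 0:
                        comp[partner[0]] = ncomp
                        stack.append(partner[0])
            ncomp += 1
        if ncomp == 1:
            return [self]
        out = []
        for c in range(ncomp):
            idx = [i for i in range(n) if comp[i] == c]
            remap = {old: new for new, old in enumerate(idx)}
            mols = []
            for old in idx:
                m = self.mols[old]
                nm = Molecule.__new__(Molecule)
                nm.type = m.type
                nm.sites = m.sites
                nm.states = list(m.states)
                nm.bonds = [(remap[p[0]], p[1]) if p is not None else None
                            for p in m.bonds]
                mols.append(nm)
            out.append(SpeciesGraph(mols, self.compartment))
        return out

    # -- canonical labelling ------------------------------------------------

    def canonical_label(self) -> str:
        if self._label is None:
            self._label = _canonical_label(self)
        return self._label

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"<Species {self.canonical_label()}>"


def _initial_colors(g: SpeciesGraph) -> list[tuple]:
    cols = []
    for m in g.mols:
        sig = sorted(
            (m.sites[i], m.states[i] or "", m.bonds[i] is not None)
            for i in range(len(m.sites)))
        cols.append((m.type.name, tuple(sig)))
    return cols


def _refine_colors(g: SpeciesGraph, cols: list[tuple]) -> list[int]:
    """Weisfeiler-Lehman style refinement; returns integer color classes."""
    n = len(g.mols)
    ids = _compress(cols)
    for _ in range(n):
        nxt = []
        for i, m in enumerate(g.mols):
            nb = sorted(
                (m.sites[si], ids[p[0]], g.mols[p[0]].sites[p[1]],
                 g.mols[p[0]].states[p[1]] or "")
                for si, p in enumerate(m.bonds) if p is not None)
            nxt.append((ids[i], tuple(nb)))
        new_ids = _compress(nxt)
        if new_ids == ids:
            break
        ids = new_ids
    return ids


def _compress(keys: list) -> list[int]:
    order = sorted(set(keys), key=repr)
    lut = {k: i for i, k in enumerate(order)}
    return [lut[k] for k in keys]


def _string_for_order(g: SpeciesGraph, order: list[int]) -> str:
    """Serialise the graph for a fixed molecule order.

    Within a molecule, site entries are sorted by (name, state, partner's
    position in the order, partner site name), which makes duplicate site
    names (the two VEGF arms) deterministic.  Bond ids are assigned in
    first-encounter order.
    """
    pos = {old: new for new, old in enumerate(order)}
    bond_ids: dict[frozenset, int] = {}
    parts = []
    for old in order:
        m = g.mols[old]
        entries = []
        for si in range(len(m.sites)):
            p = m.bonds[si]
            if p is None:
                key = (m.sites[si], m.states[si] or "", -1, "")
            else:
                key = (m.sites[si], m.states[si] or "", pos[p[0]],
                       g.mols[p[0]].sites[p[1]])
            entries.append((key, si))
        entries.sort(key=lambda e: e[0])
        toks = []
        for key, si in entries:
            tok = m.sites[si]
            if m.states[si] is not None:
                tok += "~" + m.states[si]
            p = m.bonds[si]
            if p is not None:
                bk = frozenset({(old, si), p})
                if bk not in bond_ids:
                    bond_ids[bk] = len(bond_ids) + 1
                tok += f"!{bond_ids[bk]}"
            toks.append(tok)
        parts.append(f"{m.type.name}({','.join(toks)})")
    return "@" + g.compartment + ":" + ".".join(parts)


def _canonical_label(g: SpeciesGraph) -> str:
    g.validate()
    if not g.is_connected():
        raise ModelStructureError("species graph must be connected")
    n = len(g.mols)
    if n == 1:
        return _string_for_order(g, [0])
    ids = _refine_colors(g, _initial_colors(g))
    classes: dict[int, list[int]] = {}
    for i, c in enumerate(ids):
        classes.setdefault(c, []).append(i)
    ordered_classes = [classes[c] for c in sorted(classes)]
    best = None
    # enumerate orderings consistent with the refined partition; classes in
    # these models are tiny (receptor complexes of <= ~10 molecules)
    for perm_combo in itertools.product(
            *(itertools.permutations(cls) for cls in ordered_classes)):
        order = [i for cls in perm_combo for i in cls]
        s = _string_for_order(g, order)
        if best is None or s < best:
            best = s
    return best


def canonical_label(g: SpeciesGraph) -> str:
    """Canonical string label; equal labels iff graphs are isomorphic
    (respecting molecule types, site names, states, bonds, compartment)."""
    return g.canonical_label()


# ---------------------------------------------------------------------------
# patterns
# ---------------------------------------------------------------------------

@dataclass
class PatternSite:
    name: str
    state: str | None = None          # None: any state
    bond: object = WILD               # FREE | ANY | WILD | int bond id


@dataclass
class PatternMol:
    type: str
    psites: list[PatternSite] = field(default_factory=list)


@dataclass
class PatternGraph:
    """Partially specified species graph.

    ``mols`` may be *disconnected*: for unimolecular rules every pattern
    molecule must still embed into the same complex, which expresses
    "complex contains X and Y" conditions.  ``wildcard`` patterns (``*``)
    match any complex (used by trafficking rules).
    """

    mols: list[PatternMol] = field(default_factory=list)
    compartment: str | None = None
    wildcard: bool = False

    def key(self) -> str:
        """Order-insensitive comparison key (detects symmetric rules)."""
        if self.wildcard:
            return f"*@{self.compartment}"
        parts = []
        for m in self.mols:
            toks = sorted(
                (s.name, s.state or "", str(s.bond)) for s in m.psites)
            parts.append((m.type, tuple(toks)))
        return repr(sorted(parts, key=repr)) + f"@{self.compartment}"


def _pattern_matches_compartment(p: PatternGraph, g: SpeciesGraph) -> bool:
    return p.compartment is None or p.compartment == g.compartment


def find_embeddings(p: PatternGraph, g: SpeciesGraph) -> list[list[list[int]]]:
    """All embeddings of ``p`` into ``g``.

    Each embedding is a per-pattern-molecule list: ``emb[pm]`` is a list with
    the target molecule index first and then the target *site index* for each
    pattern site of that molecule.  Embeddings are injective on molecules and
    on sites within a molecule.
    """
    if not _pattern_matches_compartment(p, g):
        return []
    if p.wildcard:
        return [[]]
    out: list[list[list[int]]] = []
    npm = len(p.mols)
    mol_assign: list[int] = [-1] * npm
    site_assign: list[list[int]] = [[] for _ in range(npm)]
    used_mols: set[int] = set()

    def bond_ok(pm_i: int, ps_i: int, tgt: tuple[int, int] | None) -> bool:
        ps = p.mols[pm_i].psites[ps_i]
        b = ps.bond
        if b is WILD or b == WILD:
            return True
        if b is FREE or b == FREE:
            return tgt is None
        if b is ANY or b == ANY:
            return tgt is not None
        # intra-pattern bond id: target site must be bonded; partner checked
        # globally once the full assignment is known
        return tgt is not None

    def bonds_consistent() -> bool:
        # collect pattern bond endpoints
        ends: dict[int, list[tuple[int, int]]] = {}
        for pm_i, pm in enumerate(p.mols):
            for ps_i, ps in enumerate(pm.psites):
                if isinstance(ps.bond, int):
                    ends.setdefault(ps.bond, []).append((pm_i, ps_i))
        for bid, lst in ends.items():
            if len(lst) != 2:
                raise ModelStructureError(f"pattern bond !{bid} has {len(lst)} ends")
            (ma, sa), (mb, sb) = lst
            ta = (mol_assign[ma], site_assign[ma][sa])
            tb = (mol_assign[mb], site_assign[mb][sb])
            if g.mols[ta[0]].bonds[ta[1]] != tb:
                return False
        return True

    def match_sites(pm_i: int, ps_i: int) -> Iterable[bool]:
        pm = p.mols[pm_i]
        if ps_i == len(pm.psites):
            yield True
            return
        ps = pm.psites[ps_i]
        tm = g.mols[mol_assign[pm_i]]
        for si in range(len(tm.sites)):
            if si in site_assign[pm_i][:ps_i]:
                continue
            if tm.sites[si] != ps.name:
                continue
            if ps.state is not None and tm.states[si] != ps.state:
                continue
            if not bond_ok(pm_i, ps_i, tm.bonds[si]):
                continue
            site_assign[pm_i].append(si)
            yield from match_sites(pm_i, ps_i + 1)
            site_assign[pm_i].pop()

    def match_mol(pm_i: int):
        if pm_i == npm:
            if bonds_consistent():
                out.append([[mol_assign[i]] + list(site_assign[i])
                            for i in range(npm)])
            return
        pm = p.mols[pm_i]
        for mi, tm in enumerate(g.mols):
            if mi in used_mols or tm.type.name != pm.type:
                continue
            mol_assign[pm_i] = mi
            used_mols.add(mi)
            for _ in match_sites(pm_i, 0):
                match_mol(pm_i + 1)
            used_mols.discard(mi)
            mol_assign[pm_i] = -1

    match_mol(0)
    return out


def match_embeddings(p: PatternGraph, g: SpeciesGraph) -> int:
    """Number of distinct injective embeddings of the pattern into ``g``."""
    return len(find_embeddings(p, g))


# ---------------------------------------------------------------------------
# rules
# ---------------------------------------------------------------------------

@dataclass
class Action:
    """One primitive rewrite, addressed by (reactant#, pattern mol#, site#)."""

    kind: str                      # "bond" | "unbond" | "state"
    a: tuple[int, int, int]
    b: tuple[int, int, int] | None = None
    state: str | None = None


@dataclass
class Rule:
    name: str
    kind: str                      # "react" | "move" | "degrade"
    reactants: list[PatternGraph]
    rate: str                      # rate-constant expression (parameter names)
    actions: list[Action] = field(default_factory=list)
    target_compartment: str | None = None   # for "move"

    def __post_init__(self):
        if self.kind == "react" and not (1 <= len(self.reactants) <= 2):
            raise ModelStructureError(f"rule {self.name}: 1 or 2 reactant patterns required")
        if self.kind in ("move", "degrade") and len(self.reactants) != 1:
            raise ModelStructureError(f"rule {self.name}: trafficking rules take one pattern")
        if self.kind == "move" and self.target_compartment not in COMPARTMENTS:
            raise ModelStructureError(f"rule {self.name}: bad target compartment")

    @property
    def symmetric(self) -> bool:
        return (self.kind == "react" and len(self.reactants) == 2
                and self.reactants[0].key() == self.reactants[1].key())

    @property
    def automorphisms(self) -> int:
        """Action-invariant within-pattern automorphism count.

        Embedding counts are divided by this so that, e.g., breaking the
        symmetric bond of ``A(a!1).A(a!1)`` fires at ``k`` per dimer rather
        than ``2k`` (the two embeddings describe the same physical event).
        The swap symmetry *between* two identical reactant patterns is
        handled separately by the pair-enumeration convention.
        """
        if getattr(self, "_aut", None) is None:
            self._aut = _rule_automorphisms(self)
        return self._aut


def _pattern_bond_ends(p: PatternGraph) -> dict[tuple[int, int], tuple[int, int]]:
    """Map each bond-carrying psite (mol, psite) to its partner within ``p``."""
    ends: dict[int, list[tuple[int, int]]] = {}
    for mi, pm in enumerate(p.mols):
        for si, ps in enumerate(pm.psites):
            if isinstance(ps.bond, int):
                ends.setdefault(ps.bond, []).append((mi, si))
    out = {}
    for bid, lst in ends.items():
        if len(lst) != 2:
            raise ModelStructureError(f"pattern bond !{bid} has {len(lst)} ends")
        out[lst[0]] = lst[1]
        out[lst[1]] = lst[0]
    return out


def _canon_actions(rule: Rule, sigma) -> frozenset:
    """Canonical form of the action multiset under an address mapping.

    ``sigma(addr)`` maps an (reactant, mol, psite) address.  Unbond actions
    are represented by the unordered pair of endpoints of the pattern bond
    they break, so either end names the same event.
    """
    bond_ends = [_pattern_bond_ends(p) for p in rule.reactants]
    items = []
    for act in rule.actions:
        if act.kind == "state":
            items.append(("state", sigma(act.a), act.state))
        elif act.kind == "bond":
            items.append(("bond", frozenset({sigma(act.a), sigma(act.b)})))
        else:  # unbond
            ri, mi, si = act.a
            partner = bond_ends[ri].get((mi, si))
            if partner is None:
                items.append(("unbond", frozenset({sigma(act.a)})))
            else:
                items.append(("unbond", frozenset(
                    {sigma(act.a), sigma((ri, partner[0], partner[1]))})))
    return frozenset((i, items.count(i)) for i in items) if items else frozenset()


def _rule_automorphisms(rule: Rule) -> int:
    if rule.kind != "react":
        return 1
    patterns = rule.reactants
    base = _canon_actions(rule, lambda a: a)

    def psite_sig(ps: PatternSite):
        b = ps.bond if not isinstance(ps.bond, int) else "bond"
        return (ps.name, ps.state, b)

    def mol_sig(pm: PatternMol):
        return (pm.type, tuple(sorted(map(psite_sig, pm.psites), key=repr)))

    count = 0
    # joint enumeration over per-pattern molecule permutations
    per_pattern_perms = []
    for p in patterns:
        sigs = [mol_sig(pm) for pm in p.mols]
        perms = [perm for perm in itertools.permutations(range(len(p.mols)))
                 if all(sigs[i] == sigs[perm[i]] for i in range(len(perm)))]
        per_pattern_perms.append(perms)

    for combo in itertools.product(*per_pattern_perms):
        # per-molecule psite bijections: enumerate jointly
        bij_choices = []   # list of (ri, mi) -> list of tuple mappings
        addr_keys = []
        feasible = True
        for ri, (p, perm) in enumerate(zip(patterns, combo)):
            for mi, pm in enumerate(p.mols):
                tgt = p.mols[perm[mi]]
                n = len(pm.psites)
                opts = []
                for sp in itertools.permutations(range(n)):
                    if all(psite_sig(pm.psites[k]) == psite_sig(tgt.psites[sp[k]])
                           for k in range(n)):
                        opts.append(sp)
                if not opts:
                    feasible = False
                    break
                bij_choices.append(opts)
                addr_keys.append((ri, mi))
            if not feasible:
                break
        if not feasible:
            continue
        for site_combo in itertools.product(*bij_choices):
            smap = dict(zip(addr_keys, site_combo))

            def sigma(addr):
                ri, mi, si = addr
                return (ri, combo[ri][mi], smap[(ri, mi)][si])

            # pattern bonds must map onto pattern bonds
            ok = True
            for ri, p in enumerate(patterns):
                ends = _pattern_bond_ends(p)
                for (mi, si), (mj, sj) in ends.items():
                    a = sigma((ri, mi, si))
                    b = sigma((ri, mj, sj))
                    if ends.get((a[1], a[2])) != (b[1], b[2]):
                        ok = False
                        break
                if not ok:
                    break
            if ok and _canon_actions(rule, sigma) == base:
                count += 1
    return max(count, 1)


def _apply_actions(graph: SpeciesGraph, rule: Rule,
                   emb_per_reactant: list[list[list[int]]],
                   mol_offsets: list[int]) -> list[SpeciesGraph]:
    """Apply a react-rule's actions to a (merged) working copy."""

    def concrete(addr: tuple[int, int, int]) -> tuple[int, int]:
        ri, pmi, psi = addr
        rec = emb_per_reactant[ri][pmi]
        return rec[0] + mol_offsets[ri], rec[1 + psi]

    g = graph.copy()
    for act in rule.actions:
        mi, si = concrete(act.a)
        if act.kind == "state":
            g.mols[mi].states[si] = act.state
        elif act.kind == "bond":
            mj, sj = concrete(act.b)
            if g.mols[mi].bonds[si] is not None or g.mols[mj].bonds[sj] is not None:
                raise ModelStructureError(
                    f"rule {rule.name}: bond-add target site already bonded")
            g.mols[mi].bonds[si] = (mj, sj)
            g.mols[mj].bonds[sj] = (mi, si)
        elif act.kind == "unbond":
            p = g.mols[mi].bonds[si]
            if p is None:
                raise ModelStructureError(
                    f"rule {rule.name}: unbond on a free site")
            g.mols[p[0]].bonds[p[1]] = None
            g.mols[mi].bonds[si] = None
        else:  # pragma: no cover
            raise ModelStructureError(f"unknown action kind {act.kind}")
    return g.components()


def _merge(g1: SpeciesGraph, g2: SpeciesGraph) -> tuple[SpeciesGraph, int]:
    g = g1.copy()
    off = len(g.mols)
    g2c = g2.copy()
    for m in g2c.mols:
        m.bonds = [(p[0] + off, p[1]) if p is not None else None for p in m.bonds]
        g.mols.append(m)
    g._label = None
    return g, off


# ---------------------------------------------------------------------------
# reactions and the generated network
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    """Directed mass-action reaction between enumerated species."""

    reactants: tuple[int, ...]
    products: tuple[int, ...]
    rate: str                 # rate-constant expression
    factor: float             # statistical multiplicity
    rule: str = ""
    degradation: bool = False


@dataclass
class Seed:
    graph: SpeciesGraph
    amount: str = "0"         # initial-amount expression
    clamped: bool = False     # constant-concentration boundary species


@dataclass
class Observable:
    name: str
    pattern: PatternGraph
    mode: str = "molecules"   # "molecules": embedding-weighted; "species": 0/1
    skip_clamped: bool = True


class NetworkGenerationError(RuntimeError):
    pass


@dataclass
class ReactionNetwork:
    species: list[SpeciesGraph]
    labels: list[str]
    init: list[str]                      # per-species initial amount expression
    clamped: list[bool]
    reactions: list[Reaction]
    observables: list[Observable] = field(default_factory=list)
    converged: bool = True

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def observable_matrix(self):
        """Weight matrix W (n_obs x n_species): obs = W @ amounts."""
        import numpy as np
        W = np.zeros((len(self.observables), len(self.species)))
        for oi, obs in enumerate(self.observables):
            for si, g in enumerate(self.species):
                if obs.skip_clamped and self.clamped[si]:
                    continue
                n = match_embeddings(obs.pattern, g)
                W[oi, si] = (n if obs.mode == "molecules" else float(n > 0))
        return W

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def generate_network(seeds: list[Seed], rules: list[Rule],
                     observables: list[Observable] | None = None,
                     max_rounds: int = 60,
                     max_species: int = 20000,
                     anchor_types: set[str] | None = None) -> ReactionNetwork:
    """Enumerate the reaction network reachable from ``seeds`` under ``rules``.

    Iterates rule application until no rule produces a new species (fixed
    point) or a cap is hit, in which case the returned network is flagged
    ``converged=False``.  The result is finalised in canonical species order,
    so it is independent of seed and rule ordering.

    ``anchor_types`` implements receptor-anchored trafficking: the endosomal
    location belongs to complexes containing an anchor molecule (the
    trafficked receptor), so when dissociation inside the endosome sheds a
    fragment without an anchor, the fragment rejoins the surface pool rather
    than existing as a separate endosomal species.
    """
    if max_rounds <= 0 or max_species <= 0:
        raise ValueError("iteration/size caps must be positive")

    def normalize_comp(g: SpeciesGraph) -> SpeciesGraph:
        if (anchor_types and g.compartment == ENDOSOME
                and not any(m.type.name in anchor_types for m in g.mols)):
            g.compartment = SURFACE
            g._label = None
        return g

    label_to_idx: dict[str, int] = {}
    graphs: list[SpeciesGraph] = []
    seed_info: dict[int, Seed] = {}

    def register(g: SpeciesGraph) -> int:
        lab = g.canonical_label()
        idx = label_to_idx.get(lab)
        if idx is None:
            idx = len(graphs)
            label_to_idx[lab] = idx
            graphs.append(g)
        return idx

    for s in seeds:
        s.graph.validate()
        if not s.graph.is_connected():
            raise ModelStructureError("seed species must be connected")
        idx = register(s.graph)
        seed_info[idx] = s

    # rxn key -> [factor, rule name, degradation]
    rxns: dict[tuple, list] = {}

    def add_rxn(reactants: tuple[int, ...], products: tuple[int, ...],
                rate: str, w: float, rule_name: str, degradation=False):
        key = (tuple(sorted(reactants)), tuple(sorted(products)), rate)
        rec = rxns.get(key)
        if rec is None:
            rxns[key] = [w, rule_name, degradation]
        else:
            rec[0] += w

    def apply_uni(rule: Rule, si: int) -> list[tuple[tuple[int, ...], float]]:
        g = graphs[si]
        results = []
        if rule.kind == "move":
            if match_embeddings(rule.reactants[0], g):
                ng = g.copy()
                ng.compartment = rule.target_compartment
                ng._label = None
                results.append(((register(normalize_comp(ng)),), 1.0))
        elif rule.kind == "degrade":
            if match_embeddings(rule.reactants[0], g):
                results.append(((), 1.0))
        else:
            w = 1.0 / rule.automorphisms
            for emb in find_embeddings(rule.reactants[0], g):
                prods = _apply_actions(g, rule, [emb], [0])
                results.append((tuple(register(normalize_comp(pg))
                                      for pg in prods), w))
        return results

    # embedding cache: (rule#, pattern#, species#) -> list of embeddings
    emb_cache: dict[tuple[int, int, int], list] = {}
    type_counts: list[dict[str, int]] = []

    def species_types(si: int) -> dict[str, int]:
        while len(type_counts) <= si:
            k = len(type_counts)
            tc: dict[str, int] = {}
            for m in graphs[k].mols:
                tc[m.type.name] = tc.get(m.type.name, 0) + 1
            type_counts.append(tc)
        return type_counts[si]

    def embs(ri: int, pi: int, p: PatternGraph, si: int) -> list:
        key = (ri, pi, si)
        hit = emb_cache.get(key)
        if hit is None:
            if not p.wildcard:
                tc = species_types(si)
                need: dict[str, int] = {}
                for pm in p.mols:
                    need[pm.type] = need.get(pm.type, 0) + 1
                if any(tc.get(t, 0) < n for t, n in need.items()):
                    emb_cache[key] = hit = []
                    return hit
            hit = find_embeddings(p, graphs[si])
            emb_cache[key] = hit
        return hit

    def apply_pair(rule: Rule, ri: int, i: int, j: int, w: float):
        """One ordered assignment: pattern A -> species i, pattern B -> j."""
        pA, pB = rule.reactants
        embsA = embs(ri, 0, pA, i)
        if not embsA:
            return
        embsB = embs(ri, 1, pB, j)
        if not embsB:
            return
        merged, off = _merge(graphs[i], graphs[j])
        for ea in embsA:
            for eb in embsB:
                prods = _apply_actions(merged, rule, [ea, eb], [0, off])
                add_rxn((i, j), tuple(register(normalize_comp(pg))
                                      for pg in prods),
                        rule.rate, w, rule.name)

    converged = False
    frontier = list(range(len(graphs)))
    processed = 0          # species 0..processed-1 have had all pairings done
    for _ in range(max_rounds):
        if not frontier:
            converged = True
            break
        new_start = len(graphs)
        for ri, rule in enumerate(rules):
            if rule.kind != "react" or len(rule.reactants) == 1:
                for si in frontier:
                    for prods, w in apply_uni(rule, si):
                        add_rxn((si,), prods, rule.rate, w, rule.name,
                                degradation=(rule.kind == "degrade"))
            else:
                w0 = 1.0 / rule.automorphisms
                pA, pB = rule.reactants
                known = processed + len(frontier)
                matchA = [i for i in range(known) if embs(ri, 0, pA, i)]
                if rule.symmetric:
                    for ai, i in enumerate(matchA):
                        for j in matchA[ai:]:
                            if i < processed and j < processed:
                                continue
                            if graphs[i].compartment != graphs[j].compartment:
                                continue
                            apply_pair(rule, ri, i, j,
                                       w0 * (0.5 if i == j else 1.0))
                else:
                    matchB = [j for j in range(known) if embs(ri, 1, pB, j)]
                    for i in matchA:
                        for j in matchB:
                            if i < processed and j < processed:
                                continue
                            if graphs[i].compartment != graphs[j].compartment:
                                continue
                            apply_pair(rule, ri, i, j, w0)
        processed += len(frontier)
        frontier = list(range(new_start, len(graphs)))
        if len(graphs) > max_species:
            break

    if not frontier:
        converged = True

    # finalise: canonical species order, remapped reactions
    order = sorted(range(len(graphs)), key=lambda k: graphs[k].canonical_label())
    remap = {old: new for new, old in enumerate(order)}
    species = [graphs[o] for o in order]
    labels = [g.canonical_label() for g in species]
    init = ["0"] * len(species)
    clamped = [False] * len(species)
    for old, seed in seed_info.items():
        init[remap[old]] = seed.amount
        clamped[remap[old]] = seed.clamped
    reactions = []
    for (rcts, prods, rate), (w, rname, deg) in sorted(
            rxns.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2])):
        reactions.append(Reaction(
            reactants=tuple(sorted(remap[r] for r in rcts)),
            products=tuple(sorted(remap[p] for p in prods)),
            rate=rate, factor=w, rule=rname, degradation=deg))
    reactions.sort(key=lambda r: (r.reactants, r.products, r.rate))
    return ReactionNetwork(species=species, labels=labels, init=init,
                           clamped=clamped, reactions=reactions,
                           observables=list(observables or []),
                           converged=converged)


# ---------------------------------------------------------------------------
# text syntax for species and patterns
# ---------------------------------------------------------------------------

_MOL_RE = re.compile(r"([A-Za-z_]\w*)\(([^()]*)\)")
_SITE_RE = re.compile(
    r"^([A-Za-z_]\w*)"         # site name
    r"(?:~(\w+))?"             # ~state
    r"(?:!(\+|\?|\d+))?$")     # !bond


def parse_pattern(text: str, types: dict[str, MoleculeType],
                  compartment: str | None = None) -> PatternGraph:
    """Parse ``Mol(site~st!1,...).Mol(...)`` pattern text (``*`` = wildcard)."""
    text = text.strip()
    if text == "*":
        return PatternGraph(wildcard=True, compartment=compartment)
    pos = 0
    mols: list[PatternMol] = []
    for m in _MOL_RE.finditer(text):
        if text[pos:m.start()].strip(". "):
            raise ModelStructureError(f"cannot parse pattern near {text[pos:m.start()]!r}")
        pos = m.end()
        tname, body = m.group(1), m.group(2)
        if tname not in types:
            raise ModelStructureError(f"unknown molecule type {tname!r}")
        mt = types[tname]
        psites = []
        if body.strip():
            counts: dict[str, int] = {}
            for tok in body.split(","):
                tok = tok.strip()
                sm = _SITE_RE.match(tok)
                if not sm:
                    raise ModelStructureError(f"cannot parse site token {tok!r}")
                sname, state, bond = sm.groups()
                if sname not in mt.sites:
                    raise ModelStructureError(
                        f"molecule {tname} has no site {sname!r}")
                counts[sname] = counts.get(sname, 0) + 1
                if counts[sname] > mt.sites.count(sname):
                    raise ModelStructureError(
                        f"site {sname!r} mentioned more often than declared in {tname}")
                if state is not None and state not in mt.allowed_states(sname):
                    raise ModelStructureError(
                        f"{tname}.{sname}: state {state!r} not declared")
                if bond is None:
                    b = FREE
                elif bond == "+":
                    b = ANY
                elif bond == "?":
                    b = WILD
                else:
                    b = int(bond)
                psites.append(PatternSite(sname, state, b))
        mols.append(PatternMol(tname, psites))
    if text[pos:].strip(". "):
        raise ModelStructureError(f"cannot parse pattern near {text[pos:]!r}")
    if not mols:
        raise ModelStructureError(f"empty pattern {text!r}")
    return PatternGraph(mols=mols, compartment=compartment)


def species_from_pattern(p: PatternGraph, types: dict[str, MoleculeType],
                         compartment: str = SURFACE) -> SpeciesGraph:
    """Build a concrete species from a *fully specified* pattern.

    Every declared site must be either mentioned, or stateless-and-free by
    default; stateful sites default to their first declared state.
    """
    if p.wildcard:
        raise ModelStructureError("wildcard is not a concrete species")
    mols = []
    bond_ends: dict[int, list[tuple[int, int]]] = {}
    for mi, pm in enumerate(p.mols):
        mt = types[pm.type]
        mol = Molecule(mt)
        used: list[int] = []
        for ps in pm.psites:
            slot = next(si for si in range(len(mt.sites))
                        if mt.sites[si] == ps.name and si not in used)
            used.append(slot)
            if ps.state is not None:
                mol.states[slot] = ps.state
            if isinstance(ps.bond, int):
                bond_ends.setdefault(ps.bond, []).append((mi, slot))
            elif ps.bond is ANY or ps.bond is WILD:
                raise ModelStructureError(
                    "concrete species cannot use !+ or !? bonds")
        mols.append(mol)
    g = SpeciesGraph(mols, p.compartment or compartment)
    for bid, ends in bond_ends.items():
        if len(ends) != 2:
            raise ModelStructureError(f"bond !{bid} has {len(ends)} ends")
        (ma, sa), (mb, sb) = ends
        g.mols[ma].bonds[sa] = (mb, sb)
        g.mols[mb].bonds[sb] = (ma, sa)
    g.validate()
    return g


def parse_species(text: str, types: dict[str, MoleculeType],
                  compartment: str = SURFACE) -> SpeciesGraph:
    return species_from_pattern(parse_pattern(text, types), types, compartment)
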