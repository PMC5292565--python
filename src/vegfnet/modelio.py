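"""Model-definition file I/O: BNGL-subset dialect, SBML export, CSV dumps.

The supported dialect covers the blocks ``parameters``, ``molecule types``,
``seed species``, ``observables`` and ``reaction rules``, with two documented
extensions needed for receptor trafficking:

* an optional compartment tag ``@surf`` / ``@endo`` on species, patterns and
  observables (complex-level, matching the whole-complex trafficking
  semantics of the model);
* whole-complex rule forms ``move PAT @c1 -> @c2 rate`` and
  ``degrade PAT @c rate``, where ``PAT`` may be ``*`` (any complex).

Everything else follows standard BNGL conventions: ``$`` marks a clamped
(constant-concentration) seed species, ``<->`` rules carry ``kf, kr``, and
only sites that are constrained or transformed are mentioned in a rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .params import ParameterSet, ParameterError
from .rules import (
    ANY, FREE, WILD, SURFACE, ENDOSOME, COMPARTMENTS,
    Action, ModelStructureError, MoleculeType, Observable, PatternGraph,
    ReactionNetwork, Rule, Seed, parse_pattern, species_from_pattern,
)


class ModelFileError(ValueError):
    """Unsupported or malformed construct, with the offending line."""

    def __init__(self, msg: str, lineno: int | None = None, line: str = ""):
        self.lineno = lineno
        loc = f" (line {lineno}: {line.strip()!r})" if lineno else ""
        super().__init__(msg + loc)


@dataclass
class ModelDefinition:
    """Parsed model: types, seeds, rules, observables, parameters."""

    types: dict[str, MoleculeType] = field(default_factory=dict)
    seeds: list[Seed] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    observables: list[Observable] = field(default_factory=list)
    params: ParameterSet = field(default_factory=ParameterSet)
    # molecule types that carry the endosomal location (trafficked receptors)
    anchor_types: set[str] = field(default_factory=set)
    # normalized source lines, for faithful write-back
    _blocks: dict[str, list[str]] = field(default_factory=dict)

    def generate(self, **kwargs):
        from .rules import generate_network
        return generate_network(self.seeds, self.rules, self.observables,
                                anchor_types=self.anchor_types or None,
                                **kwargs)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_COMP_RE = re.compile(r"@(\w+)\s*$")


def _split_comp(tok: str, lineno=None, line="") -> tuple[str, str | None]:
    """Strip a trailing ``@comp`` tag off a pattern token."""
    tok = tok.strip()
    m = _COMP_RE.search(tok)
    if not m:
        return tok, None
    comp = m.group(1)
    if comp not in COMPARTMENTS:
        raise ModelFileError(f"unknown compartment @{comp}", lineno, line)
    return tok[:m.start()].strip(), comp


def _parse_molecule_type(line: str, lineno: int) -> MoleculeType:
    m = re.match(r"^([A-Za-z_]\w*)\(([^()]*)\)$", line.strip())
    if not m:
        raise ModelFileError("cannot parse molecule type", lineno, line)
    name, body = m.groups()
    sites, states = [], {}
    if body.strip():
        for tok in body.split(","):
            parts = tok.strip().split("~")
            sites.append(parts[0])
            if len(parts) > 1:
                states[parts[0]] = tuple(parts[1:])
    return MoleculeType(name, tuple(sites), states)


def _flatten(patterns: list[PatternGraph]):
    """Flat molecule list with (reactant, pattern-mol) addresses."""
    out = []
    for ri, p in enumerate(patterns):
        for mi, pm in enumerate(p.mols):
            out.append((ri, mi, pm))
    return out


def _psite_occurrence_map(pm):
    """(site name, occurrence#) -> psite index, in written order."""
    seen: dict[str, int] = {}
    out = {}
    for si, ps in enumerate(pm.psites):
        k = seen.get(ps.name, 0)
        out[(ps.name, k)] = si
        seen[ps.name] = k + 1
    return out


def _derive_actions(lhs: list[PatternGraph], rhs: list[PatternGraph],
                    lineno: int, line: str) -> list[Action]:
    """Diff reactant and product patterns into primitive rewrite actions.

    Molecules are aligned positionally across the flattened pattern lists
    (the dialect's convention); within a molecule, repeated site names are
    aligned by occurrence order.
    """
    lmols, rmols = _flatten(lhs), _flatten(rhs)
    if len(lmols) != len(rmols) or any(
            a[2].type != b[2].type for a, b in zip(lmols, rmols)):
        raise ModelFileError(
            "unsupported construct: molecule synthesis/deletion in a plain rule "
            "(use move/degrade forms)", lineno, line)

    unbonds, bonds, states = [], [], []
    lhs_bonds: dict[tuple[int, int], list] = {}
    rhs_bonds: dict[tuple[int, int], list] = {}
    for store, mols in ((lhs_bonds, lmols), (rhs_bonds, rmols)):
        for flat_i, (ri, mi, pm) in enumerate(mols):
            for si, ps in enumerate(pm.psites):
                if isinstance(ps.bond, int):
                    store.setdefault((ri, ps.bond), []).append((flat_i, si))
    # normalize: bond key -> frozenset of (flat mol, occurrence-address)
    def bondset(store, mols):
        out = {}
        for key, ends in store.items():
            if len(ends) != 2:
                raise ModelFileError(f"bond !{key[1]} has {len(ends)} ends",
                                     lineno, line)
            out[frozenset(ends)] = key
        return out

    lset, rset = bondset(lhs_bonds, lmols), bondset(rhs_bonds, rmols)

    # per-molecule site alignment and state diffs
    addr_of: list[dict] = []
    for flat_i, ((ri, mi, lpm), (_, _, rpm)) in enumerate(zip(lmols, rmols)):
        lmap, rmap = _psite_occurrence_map(lpm), _psite_occurrence_map(rpm)
        if set(lmap) != set(rmap):
            raise ModelFileError(
                f"sites mentioned on only one side of the rule for {lpm.type}",
                lineno, line)
        addr_of.append((ri, mi, lmap, rmap))
        for key, lsi in lmap.items():
            rsi = rmap[key]
            lps, rps = lpm.psites[lsi], rpm.psites[rsi]
            if rps.state is not None and rps.state != lps.state:
                states.append(Action("state", (ri, mi, lsi), state=rps.state))

    def lhs_addr(flat_i: int, si: int):
        ri, mi, lmap, rmap = addr_of[flat_i]
        return (ri, mi, si)

    def rhs_to_lhs_addr(flat_i: int, rsi: int):
        ri, mi, lmap, rmap = addr_of[flat_i]
        for key, idx in rmap.items():
            if idx == rsi:
                return (ri, mi, lmap[key])
        raise AssertionError

    # translate RHS bond endpoints to LHS psite addresses for comparison
    rset_l = {frozenset(rhs_to_lhs_addr(f, s) for f, s in ends): ends
              for ends in rset}
    lset_l = {frozenset(lhs_addr(f, s) for f, s in ends): ends
              for ends in lset}
    for endpoints, ends in lset_l.items():
        if endpoints not in rset_l:
            a = next(iter(endpoints))
            unbonds.append(Action("unbond", a))
    for endpoints, ends in rset_l.items():
        if endpoints not in lset_l:
            a, b = sorted(endpoints)
            bonds.append(Action("bond", tuple(a), b=tuple(b)))
    return unbonds + states + bonds


_RULE_NAME_RE = re.compile(r"^([A-Za-z_]\w*)\s*:\s*(.*)$")


def _parse_rule_line(line: str, lineno: int, types) -> list[Rule]:
    text = line.strip()
    name = f"rule{lineno}"
    m = _RULE_NAME_RE.match(text)
    if m and m.group(1) not in ("move", "degrade"):
        name, text = m.group(1), m.group(2)

    if text.startswith("move ") or text.startswith("degrade "):
        kind = "move" if text.startswith("move") else "degrade"
        body = text.split(None, 1)[1]
        if kind == "move":
            mm = re.match(r"^(.*?)@(\w+)\s*->\s*@(\w+)\s+(\S+)$", body)
            if not mm:
                raise ModelFileError("cannot parse move rule", lineno, line)
            pat_txt, c_from, c_to, rate = mm.groups()
            pat = parse_pattern(pat_txt, types, compartment=c_from)
            return [Rule(name, "move", [pat], rate, target_compartment=c_to)]
        mm = re.match(r"^(.*?)@(\w+)\s+(\S+)$", body)
        if not mm:
            raise ModelFileError("cannot parse degrade rule", lineno, line)
        pat_txt, comp, rate = mm.groups()
        pat = parse_pattern(pat_txt, types, compartment=comp)
        return [Rule(name, "degrade", [pat], rate)]

    reversible = "<->" in text
    arrow = "<->" if reversible else "->"
    if arrow not in text:
        raise ModelFileError("rule has no arrow", lineno, line)
    lhs_txt, rest = text.split(arrow, 1)
    # rate expressions are the trailing whitespace-separated tokens
    if reversible:
        mm = re.match(r"^(.*?)\s+(\S+?)\s*,\s*(\S+)$", rest.strip())
        if not mm:
            raise ModelFileError("reversible rule needs 'kf, kr'", lineno, line)
        rhs_txt, kf, kr = mm.groups()
    else:
        parts = rest.strip().rsplit(None, 1)
        if len(parts) != 2:
            raise ModelFileError("rule needs a rate constant", lineno, line)
        rhs_txt, kf = parts
        kr = None

    def parse_side(side_txt: str) -> list[PatternGraph]:
        toks = re.split(r"\s\+\s", " " + side_txt.strip() + " ")
        pats = []
        for tok in toks:
            body, comp = _split_comp(tok, lineno, line)
            pats.append(parse_pattern(body, types, compartment=comp))
        return pats

    lhs = parse_side(lhs_txt)
    rhs = parse_side(rhs_txt)
    rules = [Rule(name, "react", lhs, kf,
                  actions=_derive_actions(lhs, rhs, lineno, line))]
    if reversible:
        rules.append(Rule(name + "_rev", "react", rhs, kr,
                          actions=_derive_actions(rhs, lhs, lineno, line)))
    return rules


def read_model(source) -> ModelDefinition:
    """Parse a model file (path or text) in the supported BNGL subset."""
    if isinstance(source, Path) or (isinstance(source, str)
                                    and "\n" not in source
                                    and source.endswith(".bngl")):
        text = Path(source).read_text()
    else:
        text = source

    model = ModelDefinition()
    block = None
    known_blocks = {"parameters", "molecule types", "seed species",
                    "observables", "reaction rules"}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        st = line.strip()
        if st.startswith("begin "):
            block = st[6:].strip()
            if block not in known_blocks:
                raise ModelFileError(f"unsupported construct: block {block!r}",
                                     lineno, raw)
            model._blocks.setdefault(block, [])
            continue
        if st.startswith("end "):
            block = None
            continue
        if block is None:
            raise ModelFileError("content outside begin/end block", lineno, raw)
        model._blocks[block].append(st)

    for st in model._blocks.get("parameters", []):
        mm = re.match(r"^([A-Za-z_]\w*)\s*=?\s+(.+)$", st)
        if not mm:
            raise ModelFileError(f"cannot parse parameter line {st!r}")
        model.params.exprs[mm.group(1)] = mm.group(2).strip()

    for st in model._blocks.get("molecule types", []):
        anchor = False
        if st.endswith(" anchor"):
            st, anchor = st[:-7].rstrip(), True
        mt = _parse_molecule_type(st, 0)
        if mt.name in model.types:
            raise ModelFileError(f"duplicate molecule type {mt.name}")
        model.types[mt.name] = mt
        if anchor:
            model.anchor_types.add(mt.name)

    for st in model._blocks.get("seed species", []):
        mm = re.match(r"^(\$?)(\S+)\s+(\S+)$", st)
        if not mm:
            raise ModelFileError(f"cannot parse seed species line {st!r}")
        clamp, pat_txt, amount = mm.groups()
        body, comp = _split_comp(pat_txt)
        g = species_from_pattern(parse_pattern(body, model.types),
                                 model.types, comp or SURFACE)
        model.seeds.append(Seed(g, amount, clamped=bool(clamp)))

    for st in model._blocks.get("observables", []):
        mm = re.match(r"^(Molecules|Species)\s+(\w+)\s+(\S+)$", st)
        if not mm:
            raise ModelFileError(f"cannot parse observable line {st!r}")
        mode, name, pat_txt = mm.groups()
        body, comp = _split_comp(pat_txt)
        pat = parse_pattern(body, model.types, compartment=comp)
        model.observables.append(Observable(name, pat, mode.lower()))

    for i, st in enumerate(model._blocks.get("reaction rules", [])):
        model.rules.extend(_parse_rule_line(st, i + 1, model.types))

    # every rate-constant reference must resolve
    for r in model.rules:
        try:
            model.params.evaluate(r.rate)
        except ParameterError as e:
            raise ModelFileError(f"rule {r.name}: {e}") from None
    return model


def write_model(model: ModelDefinition, path) -> None:
    """Write the model back out (normalized source lines)."""
    order = ["parameters", "molecule types", "seed species", "observables",
             "reaction rules"]
    lines = []
    for b in order:
        if b not in model._blocks:
            continue
        lines.append(f"begin {b}")
        lines.extend("  " + s for s in model._blocks[b])
        lines.append(f"end {b}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# SBML export
# ---------------------------------------------------------------------------

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
MATHML_NS = "http://www.w3.org/1998/Math/MathML"


def write_sbml(network: ReactionNetwork, params: ParameterSet, path) -> None:
    """Export the enumerated network as SBML Level 3 Version 2 core.

    Species amounts are per-cell counts (ligand pools in nM are exported as
    written); each reaction gets an irreversible mass-action kinetic law
    ``k * factor * reactant(s)`` with ``k`` evaluated from ``params``.
    """
    root = etree.Element(f"{{{SBML_NS}}}sbml", level="3", version="2",
                         nsmap={None: SBML_NS})
    mdl = etree.SubElement(root, f"{{{SBML_NS}}}model", id="vegfnet_network")

    comps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfCompartments")
    for cid in COMPARTMENTS:
        etree.SubElement(comps, f"{{{SBML_NS}}}compartment", id=cid,
                         constant="true", spatialDimensions="3", size="1")

    sps = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfSpecies")
    for i, g in enumerate(network.species):
        etree.SubElement(
            sps, f"{{{SBML_NS}}}species", id=f"s{i}",
            name=network.labels[i], compartment=g.compartment,
            initialAmount=repr(params.evaluate(network.init[i])),
            hasOnlySubstanceUnits="true",
            boundaryCondition="true" if network.clamped[i] else "false",
            constant="false")

    rxns = etree.SubElement(mdl, f"{{{SBML_NS}}}listOfReactions")
    for j, rx in enumerate(network.reactions):
        xr = etree.SubElement(rxns, f"{{{SBML_NS}}}reaction", id=f"r{j}",
                              reversible="false", name=rx.rule)
        if rx.reactants:
            lor = etree.SubElement(xr, f"{{{SBML_NS}}}listOfReactants")
            for si in rx.reactants:
                etree.SubElement(lor, f"{{{SBML_NS}}}speciesReference",
                                 species=f"s{si}", stoichiometry="1",
                                 constant="true")
        if rx.products:
            lop = etree.SubElement(xr, f"{{{SBML_NS}}}listOfProducts")
            for si in rx.products:
                etree.SubElement(lop, f"{{{SBML_NS}}}speciesReference",
                                 species=f"s{si}", stoichiometry="1",
                                 constant="true")
        kl = etree.SubElement(xr, f"{{{SBML_NS}}}kineticLaw")
        math = etree.SubElement(kl, f"{{{MATHML_NS}}}math",
                                nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, f"{{{MATHML_NS}}}apply")
        etree.SubElement(apply_, f"{{{MATHML_NS}}}times")
        cn = etree.SubElement(apply_, f"{{{MATHML_NS}}}cn")
        cn.text = repr(params.evaluate(rx.rate) * rx.factor)
        for si in rx.reactants:
            ci = etree.SubElement(apply_, f"{{{MATHML_NS}}}ci")
            ci.text = f"s{si}"
    etree.ElementTree(root).write(str(path), pretty_print=True,
                                  xml_declaration=True, encoding="UTF-8")


def read_sbml_summary(path) -> dict:
    """Structural summary of an SBML file (used to verify exports)."""
    tree = etree.parse(str(path))
    root = tree.getroot()
    ns = {"s": SBML_NS}
    species = root.findall(".//s:species", ns)
    reactions = root.findall(".//s:reaction", ns)
    return {
        "level": root.get("level"),
        "version": root.get("version"),
        "n_species": len(species),
        "n_reactions": len(reactions),
        "species_ids": [s.get("id") for s in species],
        "all_reactions_have_kinetics": all(
            r.find("s:kineticLaw", ns) is not None for r in reactions),
    }


# ---------------------------------------------------------------------------
# CSV dumps
# ---------------------------------------------------------------------------

def network_to_csv(network: ReactionNetwork, params: ParameterSet,
                   species_path, reactions_path) -> None:
    import pandas as pd
    sp = pd.DataFrame({
        "index": range(network.n_species),
        "label": network.labels,
        "compartment": [g.compartment for g in network.species],
        "clamped": network.clamped,
        "initial_amount": [params.evaluate(e) for e in network.init],
    })
    sp.to_csv(species_path, index=False)
    rx = pd.DataFrame({
        "reactants": ["+".join(map(str, r.reactants)) for r in network.reactions],
        "products": ["+".join(map(str, r.products)) for r in network.reactions],
        "rate_expression": [r.rate for r in network.reactions],
        "rate_value": [params.evaluate(r.rate) for r in network.reactions],
        "multiplicity": [r.factor for r in network.reactions],
        "rule": [r.rule for r in network.reactions],
        "degradation": [r.degradation for r in network.reactions],
    })
    rx.to_csv(reactions_path, index=False)
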