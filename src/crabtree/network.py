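"""Atom-transition network for central carbon metabolism.

The network underlies both the label simulator and the flux fitter: every
reaction carries, in addition to its stoichiometry, a carbon map telling
which substrate carbon each product carbon derives from.  Carbon positions
are 1-based, following biochemical numbering (glucose C1 = aldehyde carbon).

Rotationally symmetric intermediates (fumarate, succinate) are flagged on
the metabolite and handled by 50/50 orientation averaging in the simulator,
not by duplicating reactions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "AtomMapNetwork",
    "build_central_carbon_network",
    "validate_network",
    "stoichiometric_matrix",
    "network_to_json",
    "network_from_json",
    "network_to_tsv",
]

COMPARTMENTS = ("cytosol", "mitochondrion", "external")


@dataclass(frozen=True)
class Metabolite:
    """A metabolite pool.

    ``balanced`` is False for external/substrate pools (they may accumulate
    or deplete); ``symmetric`` marks 2-fold rotational carbon symmetry.
    """

    id: str
    n_carbons: int
    compartment: str = "cytosol"
    balanced: bool = True
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"metabolite {self.id}: n_carbons must be >= 1")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"metabolite {self.id}: unknown compartment {self.compartment!r}")
        if self.compartment == "external" and self.balanced:
            raise ValueError(f"metabolite {self.id}: external metabolites are never balanced")


@dataclass(frozen=True)
class Reaction:
    """A reaction with stoichiometry and a carbon transition map.

    ``substrates`` and ``products`` are lists of ``(metabolite id, coeff)``
    with positive integer coefficients.  Internally each molecule occurrence
    is an *instance*: for substrates ``[("A", 2)]`` the instances are
    ``A#0, A#1``.  ``atom_map`` is a list with one entry per product
    instance; the entry is a list over that product's carbons (1..n) of
    ``(substrate_instance_index, substrate_carbon_position)`` pairs.  A valid
    map is a bijection between all substrate carbons and all product carbons.
    """

    id: str
    substrates: tuple[tuple[str, int], ...]
    products: tuple[tuple[str, int], ...]
    atom_map: tuple[tuple[tuple[int, int], ...], ...]
    reversible: bool = False
    exchange_allowed: bool = False

    def __init__(self, id, substrates, products, atom_map, reversible=False,
                 exchange_allowed=False):
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "substrates",
                           tuple((str(m), int(c)) for m, c in substrates))
        object.__setattr__(self, "products",
                           tuple((str(m), int(c)) for m, c in products))
        object.__setattr__(self, "atom_map",
                           tuple(tuple(tuple(int(x) for x in pair) for pair in pm)
                                 for pm in atom_map))
        object.__setattr__(self, "reversible", bool(reversible))
        object.__setattr__(self, "exchange_allowed", bool(exchange_allowed))

    @property
    def substrate_instances(self) -> list[str]:
        return [m for m, c in self.substrates for _ in range(c)]

    @property
    def product_instances(self) -> list[str]:
        return [m for m, c in self.products for _ in range(c)]

    def net_coefficients(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for m, c in self.substrates:
            out[m] = out.get(m, 0) - c
        for m, c in self.products:
            out[m] = out.get(m, 0) + c
        return out


@dataclass
class AtomMapNetwork:
    """A set of metabolites and atom-mapped reactions plus labeling inputs.

    ``substrate_label`` maps an external substrate id to a list of
    ``(positional isotopomer pattern, fraction)`` pairs; the pattern is a
    string of 0/1 of length n_carbons ("100000" = [1-13C]).  Substrates
    without an entry are taken as unlabeled.  ``biomass_drains`` records the
    precursor demand weights used when scaling drain fluxes with growth.
    """

    name: str
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    substrate_label: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    biomass_drains: list[tuple[str, float]] = field(default_factory=list)

    def add_metabolite(self, *args, **kwargs) -> None:
        met = args[0] if args and isinstance(args[0], Metabolite) else Metabolite(*args, **kwargs)
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction {rxn.id}")
        self.reactions[rxn.id] = rxn

    @property
    def balanced_metabolites(self) -> list[str]:
        return [m for m, met in self.metabolites.items() if met.balanced]

    def reaction_ids(self) -> list[str]:
        return list(self.reactions)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_network(net: AtomMapNetwork) -> list[str]:
    """Return diagnostics; an empty list means the network is well formed.

    Checks: all references resolve; every reaction's atom map is a carbon
    bijection (no carbon created or destroyed, 1-based positions in range);
    substrate label patterns and fractions are consistent; every balanced
    metabolite has at least one producing and one consuming reaction.
    """
    diags: list[str] = []
    for rid, rxn in net.reactions.items():
        refs = [m for m, _ in rxn.substrates] + [m for m, _ in rxn.products]
        missing = [m for m in refs if m not in net.metabolites]
        if missing:
            diags.append(f"reaction {rid}: unknown metabolite(s) {sorted(set(missing))}")
            continue
        subs = rxn.substrate_instances
        prods = rxn.product_instances
        if len(rxn.atom_map) != len(prods):
            diags.append(f"reaction {rid}: atom_map has {len(rxn.atom_map)} product "
                         f"entries, expected {len(prods)}")
            continue
        seen: set[tuple[int, int]] = set()
        n_sub_carbons = sum(net.metabolites[m].n_carbons for m in subs)
        n_mapped = 0
        ok = True
        for pi, pmap in enumerate(rxn.atom_map):
            want = net.metabolites[prods[pi]].n_carbons
            if len(pmap) != want:
                diags.append(f"reaction {rid}: product {prods[pi]}#{pi} has {want} "
                             f"carbons but {len(pmap)} mapped (unmapped carbon)")
                ok = False
                continue
            for carbon_1based, (si, sc) in enumerate(pmap, start=1):
                if si < 0 or si >= len(subs):
                    diags.append(f"reaction {rid}: product carbon {prods[pi]}#{pi}:{carbon_1based} "
                                 f"references substrate instance {si} out of range")
                    ok = False
                    continue
                if sc < 1 or sc > net.metabolites[subs[si]].n_carbons:
                    diags.append(f"reaction {rid}: substrate carbon {subs[si]}#{si}:{sc} out of range")
                    ok = False
                    continue
                if (si, sc) in seen:
                    diags.append(f"reaction {rid}: substrate carbon {subs[si]}#{si}:{sc} mapped twice")
                    ok = False
                seen.add((si, sc))
                n_mapped += 1
        if ok and n_mapped != n_sub_carbons:
            diags.append(f"reaction {rid}: atom map covers {n_mapped} of "
                         f"{n_sub_carbons} substrate carbons (not a bijection)")
    for mid, patterns in net.substrate_label.items():
        if mid not in net.metabolites:
            diags.append(f"substrate_label: unknown metabolite {mid}")
            continue
        n = net.metabolites[mid].n_carbons
        for pat, _frac in patterns:
            if len(pat) != n or set(pat) - {"0", "1"}:
                diags.append(f"substrate_label {mid}: bad pattern {pat!r}")
        total = sum(f for _, f in patterns)
        if abs(total - 1.0) > 1e-9:
            diags.append(f"substrate_label {mid}: fractions sum to {total}, not 1")
    for pid, _w in net.biomass_drains:
        if pid not in net.metabolites:
            diags.append(f"biomass_drains: unknown precursor {pid}")
    produced: dict[str, int] = {}
    consumed: dict[str, int] = {}
    for rxn in net.reactions.values():
        for m, c in rxn.net_coefficients().items():
            if c > 0:
                produced[m] = produced.get(m, 0) + 1
            elif c < 0:
                consumed[m] = consumed.get(m, 0) + 1
        if rxn.reversible:
            for m, c in rxn.net_coefficients().items():
                if c > 0:
                    consumed[m] = consumed.get(m, 0) + 1
                elif c < 0:
                    produced[m] = produced.get(m, 0) + 1
    for mid in net.balanced_metabolites:
        if not produced.get(mid):
            diags.append(f"dead-end: balanced metabolite {mid} has no producing reaction")
        if not consumed.get(mid):
            diags.append(f"dead-end: balanced metabolite {mid} has no consuming reaction")
    return diags


def stoichiometric_matrix(net: AtomMapNetwork) -> pd.DataFrame:
    """Stoichiometric matrix (balanced metabolites x reactions).

    Entry (m, r) is the net coefficient of m in r in the forward direction;
    external metabolites are excluded.
    """
    diags = validate_network(net)
    if diags:
        raise ValueError("invalid network: " + "; ".join(diags[:5]))
    rows = net.balanced_metabolites
    cols = net.reaction_ids()
    S = np.zeros((len(rows), len(cols)))
    ridx = {m: i for i, m in enumerate(rows)}
    for j, rid in enumerate(cols):
        for m, c in net.reactions[rid].net_coefficients().items():
            if m in ridx:
                S[ridx[m], j] = c
    return pd.DataFrame(S, index=rows, columns=cols)


# ---------------------------------------------------------------------------
# Built-in central-carbon network
# ---------------------------------------------------------------------------

def _identity_map(n: int) -> list[list[int]]:
    return [[0, c] for c in range(1, n + 1)]


# Precursor demand weights (mmol per gDW, rounded standard yeast biomass
# composition) used to scale biomass drain fluxes with growth.
_BIOMASS_DEMANDS: list[tuple[str, float]] = [
    ("G6P", 2.1),
    ("R5P", 0.9),
    ("E4P", 0.35),
    ("GAP", 0.15),
    ("PEP", 2.0),
    ("PYRc", 2.8),
    ("AcCoAc", 2.8),
    ("OAAc", 1.8),
    ("AKG", 1.1),
]


def build_central_carbon_network(variant: str = "crabtree_negative") -> AtomMapNetwork:
    """Build the yeast central-carbon atom-transition network.

    Contains glycolysis (lumped between branch points), oxidative and
    non-oxidative PPP, the PDH bypass (PDC, acetaldehyde dehydrogenase,
    acetyl-CoA synthase), PDH, PYC, MAE, mitochondrial transport of pyruvate
    / oxaloacetate / acetyl-CoA, the TCA cycle with symmetric succinate and
    fumarate, the glyoxylate shunt (ICL, MLS), biomass precursor drains and
    secretion reactions (ethanol, glycerol, acetate, pyruvate).

    The two variants share the same topology: in a Crabtree-negative yeast
    the secretion fluxes are present but fit to ~0.  The substrate labeling
    defaults to 100% [1-13C]glucose.
    """
    if variant not in ("crabtree_positive", "crabtree_negative"):
        raise ValueError(f"unknown variant {variant!r}")
    net = AtomMapNetwork(name=f"central_carbon_{variant}")
    cy, mi, ex = COMPARTMENTS

    for mid, n, comp in [
        ("GLC", 6, ex), ("CO2", 1, ex), ("ETOH", 2, ex), ("GLYC", 3, ex),
        ("AC", 2, ex), ("PYRx", 3, ex),
    ]:
        net.add_metabolite(Metabolite(mid, n, comp, balanced=False))
    for mid, n in [("G6P", 6), ("F6P", 6), ("GAP", 3), ("PEP", 3), ("PYRc", 3),
                   ("Ru5P", 5), ("X5P", 5), ("R5P", 5), ("S7P", 7), ("E4P", 4),
                   ("AcAld", 2), ("ACE", 2), ("AcCoAc", 2)]:
        net.add_metabolite(Metabolite(mid, n, cy))
    for mid, n, sym in [("PYRm", 3, False), ("AcCoAm", 2, False), ("OAAc", 4, False),
                        ("OAAm", 4, False), ("CIT", 6, False), ("AKG", 5, False),
                        ("SUC", 4, True), ("FUMA", 4, True), ("MAL", 4, False),
                        ("GLX", 2, False)]:
        comp = cy if mid in ("OAAc", "GLX") else mi
        net.add_metabolite(Metabolite(mid, n, comp, symmetric=sym))

    R = Reaction
    add = net.add_reaction
    # glycolysis (G6P..PEP lumped between branch points)
    add(R("HXK", [("GLC", 1)], [("G6P", 1)], [_identity_map(6)]))
    add(R("PGI", [("G6P", 1)], [("F6P", 1)], [_identity_map(6)],
          reversible=True, exchange_allowed=True))
    # PFK+FBA+TPI: F6P C1-C3 -> GAP (reversed by TPI), C4-C6 -> GAP
    add(R("PFK", [("F6P", 1)], [("GAP", 2)],
          [[[0, 3], [0, 2], [0, 1]], [[0, 4], [0, 5], [0, 6]]]))
    add(R("ENO", [("GAP", 1)], [("PEP", 1)], [_identity_map(3)]))
    add(R("PYK", [("PEP", 1)], [("PYRc", 1)], [_identity_map(3)]))
    # pentose phosphate pathway
    add(R("ZWF", [("G6P", 1)], [("CO2", 1), ("Ru5P", 1)],
          [[[0, 1]], [[0, 2], [0, 3], [0, 4], [0, 5], [0, 6]]]))
    add(R("RPE", [("Ru5P", 1)], [("X5P", 1)], [_identity_map(5)],
          reversible=True, exchange_allowed=True))
    add(R("RKI", [("Ru5P", 1)], [("R5P", 1)], [_identity_map(5)],
          reversible=True, exchange_allowed=True))
    add(R("TKL1", [("X5P", 1), ("R5P", 1)], [("S7P", 1), ("GAP", 1)],
          [[[0, 1], [0, 2], [1, 1], [1, 2], [1, 3], [1, 4], [1, 5]],
           [[0, 3], [0, 4], [0, 5]]], reversible=True, exchange_allowed=True))
    add(R("TAL", [("S7P", 1), ("GAP", 1)], [("F6P", 1), ("E4P", 1)],
          [[[0, 1], [0, 2], [0, 3], [1, 1], [1, 2], [1, 3]],
           [[0, 4], [0, 5], [0, 6], [0, 7]]], reversible=True, exchange_allowed=True))
    add(R("TKL2", [("X5P", 1), ("E4P", 1)], [("F6P", 1), ("GAP", 1)],
          [[[0, 1], [0, 2], [1, 1], [1, 2], [1, 3], [1, 4]],
           [[0, 3], [0, 4], [0, 5]]], reversible=True, exchange_allowed=True))
    # PDH bypass and fermentative branch
    add(R("PDC", [("PYRc", 1)], [("CO2", 1), ("AcAld", 1)],
          [[[0, 1]], [[0, 2], [0, 3]]]))
    add(R("ADH", [("AcAld", 1)], [("ETOH", 1)], [_identity_map(2)]))
    add(R("ALD", [("AcAld", 1)], [("ACE", 1)], [_identity_map(2)]))
    add(R("ACS", [("ACE", 1)], [("AcCoAc", 1)], [_identity_map(2)]))
    # mitochondrial transport and pyruvate branch point
    add(R("PYT", [("PYRc", 1)], [("PYRm", 1)], [_identity_map(3)]))
    add(R("PDH", [("PYRm", 1)], [("CO2", 1), ("AcCoAm", 1)],
          [[[0, 1]], [[0, 2], [0, 3]]]))
    add(R("PYC", [("PYRc", 1), ("CO2", 1)], [("OAAc", 1)],
          [[[0, 1], [0, 2], [0, 3], [1, 1]]]))
    add(R("OAT", [("OAAc", 1)], [("OAAm", 1)], [_identity_map(4)]))
    add(R("ACT", [("AcCoAc", 1)], [("AcCoAm", 1)], [_identity_map(2)]))
    # TCA cycle; AcCoA C1 = carbonyl, C2 = methyl; CO2 at IDH comes from
    # OAA C4, CO2 at KGD from OAA C1 (first-turn biochemistry)
    add(R("CS", [("OAAm", 1), ("AcCoAm", 1)], [("CIT", 1)],
          [[[0, 1], [0, 2], [0, 3], [0, 4], [1, 2], [1, 1]]]))
    add(R("IDH", [("CIT", 1)], [("CO2", 1), ("AKG", 1)],
          [[[0, 4]], [[0, 1], [0, 2], [0, 3], [0, 5], [0, 6]]]))
    add(R("KGD", [("AKG", 1)], [("CO2", 1), ("SUC", 1)],
          [[[0, 1]], [[0, 2], [0, 3], [0, 4], [0, 5]]]))
    add(R("SDH", [("SUC", 1)], [("FUMA", 1)], [_identity_map(4)],
          reversible=True, exchange_allowed=True))
    add(R("FUM", [("FUMA", 1)], [("MAL", 1)], [_identity_map(4)],
          reversible=True, exchange_allowed=True))
    add(R("MDH", [("MAL", 1)], [("OAAm", 1)], [_identity_map(4)],
          reversible=True, exchange_allowed=True))
    add(R("MAE", [("MAL", 1)], [("CO2", 1), ("PYRm", 1)],
          [[[0, 4]], [[0, 1], [0, 2], [0, 3]]]))
    # glyoxylate shunt
    add(R("ICL", [("CIT", 1)], [("GLX", 1), ("SUC", 1)],
          [[[0, 1], [0, 2]], [[0, 3], [0, 4], [0, 5], [0, 6]]]))
    add(R("MLS", [("GLX", 1), ("AcCoAc", 1)], [("MAL", 1)],
          [[[0, 1], [0, 2], [1, 2], [1, 1]]]))
    # secretion
    add(R("EX_GLYC", [("GAP", 1)], [("GLYC", 1)], [_identity_map(3)]))
    add(R("EX_AC", [("ACE", 1)], [("AC", 1)], [_identity_map(2)]))
    add(R("EX_PYR", [("PYRc", 1)], [("PYRx", 1)], [_identity_map(3)]))
    # biomass precursor drains (each to an external sink pool)
    for pid, _w in _BIOMASS_DEMANDS:
        n = net.metabolites[pid].n_carbons
        sink = f"BIO_{pid}"
        net.add_metabolite(Metabolite(sink, n, ex, balanced=False))
        add(R(f"BM_{pid}", [(pid, 1)], [(sink, 1)], [_identity_map(n)]))

    net.substrate_label = {"GLC": [("100000", 1.0)]}
    net.biomass_drains = list(_BIOMASS_DEMANDS)
    return net


# ---------------------------------------------------------------------------
# I/O: JSON dialect and TSV summary
# ---------------------------------------------------------------------------

def network_to_json(net: AtomMapNetwork, path: str | Path | None = None) -> str:
    doc = {
        "name": net.name,
        "metabolites": [
            {"id": m.id, "n_carbons": m.n_carbons, "compartment": m.compartment,
             "balanced": m.balanced, "symmetric": m.symmetric}
            for m in net.metabolites.values()
        ],
        "reactions": [
            {"id": r.id,
             "substrates": [list(s) for s in r.substrates],
             "products": [list(p) for p in r.products],
             "atom_map": [[list(pair) for pair in pm] for pm in r.atom_map],
             "reversible": r.reversible,
             "exchange_allowed": r.exchange_allowed}
            for r in net.reactions.values()
        ],
        "substrate_label": {m: [[pat, frac] for pat, frac in pats]
                            for m, pats in net.substrate_label.items()},
        "biomass_drains": [[p, w] for p, w in net.biomass_drains],
    }
    text = json.dumps(doc, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def network_from_json(source: str | Path) -> AtomMapNetwork:
    text = Path(source).read_text() if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith(".json")
    ) else str(source)
    doc = json.loads(text)
    net = AtomMapNetwork(name=doc.get("name", "network"))
    for m in doc["metabolites"]:
        net.add_metabolite(Metabolite(m["id"], m["n_carbons"], m["compartment"],
                                      m["balanced"], m.get("symmetric", False)))
    for r in doc["reactions"]:
        net.add_reaction(Reaction(r["id"], r["substrates"], r["products"],
                                  r["atom_map"], r.get("reversible", False),
                                  r.get("exchange_allowed", False)))
    net.substrate_label = {m: [(p, f) for p, f in pats]
                           for m, pats in doc.get("substrate_label", {}).items()}
    net.biomass_drains = [(p, w) for p, w in doc.get("biomass_drains", [])]
    return net


def _atom_map_string(net: AtomMapNetwork, rxn: Reaction) -> str:
    subs = rxn.substrate_instances
    prods = rxn.product_instances
    parts = []
    for pi, pmap in enumerate(rxn.atom_map):
        entries = ",".join(f"{subs[si]}:{sc}" for si, sc in pmap)
        parts.append(f"{prods[pi]}[{entries}]")
    left = "+".join(subs)
    return f"{left}>{'+'.join(parts)}"


def network_to_tsv(net: AtomMapNetwork, path: str | Path | None = None) -> pd.DataFrame:
    """Human-readable one-reaction-per-row summary with atom-map strings."""
    rows = []
    for r in net.reactions.values():
        eq = " + ".join(f"{c} {m}" if c != 1 else m for m, c in r.substrates)
        eq += " <=> " if r.reversible else " --> "
        eq += " + ".join(f"{c} {m}" if c != 1 else m for m, c in r.products)
        rows.append({"reaction": r.id, "equation": eq,
                     "atom_map": _atom_map_string(net, r),
                     "reversible": r.reversible})
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
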