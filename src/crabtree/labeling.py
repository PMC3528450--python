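"""Steady-state 13C label propagation by EMU decomposition.

Given an atom-transition network and a steady-state flux distribution, this
module computes mass-isotopomer distributions (MIDs) of arbitrary carbon
fragments and the summed fractional labeling (SFL) of amino-acid fragments.

The EMU (elementary metabolite unit) framework decomposes the label balance
into linear systems ordered by fragment size: the MID of every fragment of
size s is a flux-weighted mixture of same-size fragment MIDs and of
convolutions of strictly smaller fragments (condensation reactions), so the
systems can be solved smallest first by dense direct solves.

Symmetric metabolites (2-fold rotational carbon symmetry, e.g. fumarate)
are orientation-averaged with weight 0.5 at the point of production.
Reversible reactions contribute a reverse direction whose atom map is the
inverse bijection; bidirectional exchange is parameterized by an extent
e in [0, 1) mapped to an exchange flux e/(1-e) (capped).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .network import AtomMapNetwork, Reaction, stoichiometric_matrix

__all__ = [
    "EMUFragment",
    "MassIsotopomerDistribution",
    "AminoAcidFragmentMap",
    "EMUSimulator",
    "decompose_emu",
    "simulate_mids",
    "sfl_from_mid",
    "simulate_sfl_dataset",
    "positional_enrichments",
    "default_fragment_map",
    "natural_abundance_convolve",
]

EXCHANGE_CAP = 1e3
STEADY_STATE_TOL = 1e-6


@dataclass(frozen=True)
class EMUFragment:
    """An ordered subset of a metabolite's carbons (1-based, increasing)."""

    metabolite: str
    positions: tuple[int, ...]

    def __init__(self, metabolite: str, positions: Iterable[int]):
        pos = tuple(int(p) for p in positions)
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValueError(f"positions must be strictly increasing: {pos}")
        if pos and pos[0] < 1:
            raise ValueError("carbon positions are 1-based")
        object.__setattr__(self, "metabolite", metabolite)
        object.__setattr__(self, "positions", pos)

    @property
    def size(self) -> int:
        return len(self.positions)

    def __repr__(self) -> str:
        return f"{self.metabolite}[{','.join(map(str, self.positions))}]"


@dataclass
class MassIsotopomerDistribution:
    """Fractions of fragment molecules with 0..n labeled carbons."""

    fragment: EMUFragment
    fractions: np.ndarray

    def __post_init__(self):
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.shape != (self.fragment.size + 1,):
            raise ValueError("fractions must have length n_positions + 1")
        if np.any(self.fractions < -1e-12):
            raise ValueError("negative MID fraction")
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("MID fractions must sum to 1")


# ---------------------------------------------------------------------------
# Decomposition
# ---------------------------------------------------------------------------

def _direction_producers(net: AtomMapNetwork, rxn: Reaction, sign: int):
    """Producing traces of one direction of a reaction.

    Returns (consumed instance metabolite ids,
             list of (produced metabolite id, carbon->(instance, pos) map)).
    For the forward direction products are produced; for the reverse
    direction the substrates are produced and the atom map is inverted.
    """
    subs = rxn.substrate_instances
    prods = rxn.product_instances
    if sign > 0:
        produced = [(prods[pi], {c + 1: tuple(pm[c]) for c in range(len(pm))})
                    for pi, pm in enumerate(rxn.atom_map)]
        return subs, produced
    inv: dict[int, dict[int, tuple[int, int]]] = {si: {} for si in range(len(subs))}
    for pi, pm in enumerate(rxn.atom_map):
        for c, (si, sc) in enumerate(pm, start=1):
            inv[si][sc] = (pi, c)
    produced = [(subs[si], inv[si]) for si in range(len(subs))]
    return prods, produced


def _producer_terms(net: AtomMapNetwork, frag: EMUFragment):
    """All producing terms of an EMU: (direction key, weight, source EMUs)."""
    terms = []
    n = net.metabolites[frag.metabolite].n_carbons
    for rxn in net.reactions.values():
        for sign in ((1, -1) if rxn.reversible else (1,)):
            consumed, produced = _direction_producers(net, rxn, sign)
            for pmet, cmap in produced:
                if pmet != frag.metabolite:
                    continue
                orientations = [frag.positions]
                weights = [1.0]
                if net.metabolites[pmet].symmetric:
                    flipped = tuple(sorted(n + 1 - p for p in frag.positions))
                    orientations = [frag.positions, flipped]
                    weights = [0.5, 0.5]
                for positions, w in zip(orientations, weights):
                    by_src: dict[int, list[int]] = {}
                    for p in positions:
                        si, sc = cmap[p]
                        by_src.setdefault(si, []).append(sc)
                    sources = tuple(
                        EMUFragment(consumed[si], sorted(pos))
                        for si, pos in sorted(by_src.items())
                    )
                    terms.append(((rxn.id, sign), w, sources))
    return terms


def _input_mid(net: AtomMapNetwork, frag: EMUFragment) -> np.ndarray:
    """MID of a fragment of an unbalanced (substrate/sink) metabolite."""
    patterns = net.substrate_label.get(frag.metabolite)
    mid = np.zeros(frag.size + 1)
    if not patterns:
        mid[0] = 1.0
        return mid
    for pat, fraction in patterns:
        k = sum(int(pat[p - 1]) for p in frag.positions)
        mid[k] += fraction
    return mid


class EMUSystem:
    """One linear label-balance system: all unknown EMUs of one size."""

    def __init__(self, size: int, unknowns: list[EMUFragment]):
        self.size = size
        self.unknowns = unknowns
        self.index = {f: i for i, f in enumerate(unknowns)}
        # per unknown: list of (direction key, orientation weight, sources)
        self.terms: list[list[tuple[tuple[str, int], float, tuple[EMUFragment, ...]]]] = [
            [] for _ in unknowns
        ]

    def __repr__(self) -> str:
        return f"EMUSystem(size={self.size}, n_unknowns={len(self.unknowns)})"


class EMUDecomposition:
    """Ordered systems plus bookkeeping of input and dangling fragments."""

    def __init__(self, net: AtomMapNetwork, targets: Sequence[EMUFragment]):
        self.net = net
        self.targets = list(targets)
        self.inputs: dict[EMUFragment, np.ndarray] = {}
        self.dangling: set[EMUFragment] = set()
        self.producer_map: dict[EMUFragment, list] = {}
        self._decompose()

    def _decompose(self) -> None:
        net = self.net
        for t in self.targets:
            met = net.metabolites.get(t.metabolite)
            if met is None:
                raise ValueError(f"target fragment references unknown metabolite {t.metabolite}")
            if t.positions and t.positions[-1] > met.n_carbons:
                raise ValueError(f"target {t!r} exceeds carbon count of {t.metabolite}")
        stack = list(self.targets)
        seen: set[EMUFragment] = set()
        while stack:
            frag = stack.pop()
            if frag in seen:
                continue
            seen.add(frag)
            if not net.metabolites[frag.metabolite].balanced:
                self.inputs[frag] = _input_mid(net, frag)
                continue
            terms = _producer_terms(net, frag)
            if not terms:
                # unreachable from any substrate: flagged, unlabeled MID
                self.dangling.add(frag)
                mid = np.zeros(frag.size + 1)
                mid[0] = 1.0
                self.inputs[frag] = mid
                continue
            self.producer_map[frag] = terms
            for _, _, sources in terms:
                stack.extend(sources)
        by_size: dict[int, list[EMUFragment]] = {}
        for frag in self.producer_map:
            by_size.setdefault(frag.size, []).append(frag)
        self.systems = [
            EMUSystem(size, sorted(by_size[size], key=repr))
            for size in sorted(by_size)
        ]
        for system in self.systems:
            for i, frag in enumerate(system.unknowns):
                system.terms[i] = self.producer_map[frag]

    @property
    def n_unknowns(self) -> int:
        return sum(len(s.unknowns) for s in self.systems)


def decompose_emu(net: AtomMapNetwork, targets: Sequence[EMUFragment]) -> EMUDecomposition:
    """Decompose targets into size-ascending linear label-balance systems."""
    return EMUDecomposition(net, targets)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _direction_fluxes(net: AtomMapNetwork, fluxes, exchange=None) -> dict[tuple[str, int], float]:
    """Map (reaction, direction) -> nonnegative direction flux."""
    net_flux = getattr(fluxes, "net", fluxes)
    exch = exchange if exchange is not None else getattr(fluxes, "exchange", {}) or {}
    out: dict[tuple[str, int], float] = {}
    for rid, rxn in net.reactions.items():
        v = float(net_flux.get(rid, 0.0))
        if not rxn.reversible and v < -1e-9:
            raise ValueError(f"irreversible reaction {rid} has negative flux {v}")
        x = 0.0
        e = float(exch.get(rid, 0.0))
        if e > 0:
            if not rxn.exchange_allowed:
                raise ValueError(f"reaction {rid} does not allow exchange")
            x = min(e / (1.0 - e), EXCHANGE_CAP) if e < 1.0 else EXCHANGE_CAP
        out[(rid, 1)] = max(v, 0.0) + x
        if rxn.reversible:
            out[(rid, -1)] = max(-v, 0.0) + x
    return out


class EMUSimulator:
    """Reusable simulator: decompose once, evaluate MIDs for many flux maps."""

    def __init__(self, net: AtomMapNetwork, targets: Sequence[EMUFragment],
                 check_steady_state: bool = True):
        self.net = net
        self.targets = list(targets)
        self.decomposition = decompose_emu(net, targets)
        self._S = stoichiometric_matrix(net).to_numpy() if check_steady_state else None
        self._rids = net.reaction_ids()

    def _check(self, fluxes) -> None:
        if self._S is None:
            return
        net_flux = getattr(fluxes, "net", fluxes)
        v = np.array([float(net_flux.get(r, 0.0)) for r in self._rids])
        resid = float(np.max(np.abs(self._S @ v))) if v.size else 0.0
        scale = max(1.0, float(np.max(np.abs(v))))
        if resid > STEADY_STATE_TOL * scale:
            raise ValueError(f"fluxes violate steady state (max residual {resid:.3g})")

    def mids(self, fluxes, exchange=None, strict: bool = True) -> dict[EMUFragment, np.ndarray]:
        self._check(fluxes)
        dirflux = _direction_fluxes(self.net, fluxes, exchange)
        solved: dict[EMUFragment, np.ndarray] = dict(self.decomposition.inputs)
        # determine which unknowns are actually needed under these fluxes
        needed: set[EMUFragment] = set()
        stack = [t for t in self.decomposition.targets
                 if t in self.decomposition.producer_map]
        while stack:
            frag = stack.pop()
            if frag in needed:
                continue
            needed.add(frag)
            for key, _w, sources in self.decomposition.producer_map[frag]:
                if dirflux.get(key, 0.0) > 0:
                    for s in sources:
                        if s in self.decomposition.producer_map and s not in needed:
                            stack.append(s)
        for system in self.decomposition.systems:
            live = [i for i, f in enumerate(system.unknowns) if f in needed]
            if not live:
                continue
            pos = {i: k for k, i in enumerate(live)}
            n = len(live)
            A = np.zeros((n, n))
            B = np.zeros((n, system.size + 1))
            for i in live:
                k = pos[i]
                inflow = 0.0
                for key, w, sources in system.terms[i]:
                    fw = dirflux.get(key, 0.0) * w
                    if fw <= 0:
                        continue
                    inflow += fw
                    if len(sources) == 1 and sources[0] in system.index:
                        j = system.index[sources[0]]
                        if j in pos:
                            A[k, pos[j]] -= fw
                            continue
                    mid = None
                    for s in sources:
                        smid = solved.get(s)
                        if smid is None:
                            raise RuntimeError(f"EMU {s!r} needed before being solved")
                        mid = smid if mid is None else np.convolve(mid, smid)
                    B[k] += fw * mid
                if inflow <= 0:
                    if strict:
                        raise ValueError(
                            f"singular label balance: pool {system.unknowns[i]!r} has zero inflow")
                    # tolerant mode (used inside optimization): unlabeled pool
                    A[k, k] = 1.0
                    B[k] = 0.0
                    B[k, 0] = 1.0
                    continue
                A[k, k] += inflow
            if strict:
                X = np.linalg.solve(A, B)
            else:
                # interior points of an optimization can form closed loops
                # with zero external inflow; nudge those toward unlabeled
                eps = 1e-9 * (1.0 + float(np.max(np.diag(A))))
                Ar = A + eps * np.eye(n)
                Br = B.copy()
                Br[:, 0] += eps
                try:
                    X = np.linalg.solve(Ar, Br)
                except np.linalg.LinAlgError:
                    X = np.linalg.lstsq(Ar, Br, rcond=None)[0]
            for i in live:
                solved[system.unknowns[i]] = X[pos[i]]
        out: dict[EMUFragment, np.ndarray] = {}
        for t in self.decomposition.targets:
            mid = solved.get(t)
            if mid is None:
                raise ValueError(f"singular label balance: pool {t!r} unreachable at these fluxes")
            m = np.clip(mid, 0.0, None)
            total = m.sum()
            if total <= 1e-12:
                m = np.zeros_like(m)
                m[0] = 1.0
                total = 1.0
            out[t] = m / total
        return out

    def mid_objects(self, fluxes, exchange=None) -> list[MassIsotopomerDistribution]:
        mids = self.mids(fluxes, exchange)
        return [MassIsotopomerDistribution(t, mids[t]) for t in self.targets]


def simulate_mids(net: AtomMapNetwork, fluxes, targets: Sequence[EMUFragment],
                  exchange=None) -> list[MassIsotopomerDistribution]:
    """Steady-state MIDs of target fragments (convenience one-shot wrapper)."""
    return EMUSimulator(net, targets).mid_objects(fluxes, exchange)


def positional_enrichments(net: AtomMapNetwork, fluxes, metabolite: str) -> np.ndarray:
    """Per-carbon 13C enrichment of a metabolite (fraction labeled)."""
    n = net.metabolites[metabolite].n_carbons
    targets = [EMUFragment(metabolite, (p,)) for p in range(1, n + 1)]
    sim = EMUSimulator(net, targets)
    mids = sim.mids(fluxes)
    return np.array([mids[t][1] for t in targets])


# ---------------------------------------------------------------------------
# SFL and amino-acid fragments
# ---------------------------------------------------------------------------

def sfl_from_mid(mid: MassIsotopomerDistribution | np.ndarray) -> float:
    """Summed fractional labeling in percent: 100 x sum_j j * fraction_j."""
    fractions = mid.fractions if isinstance(mid, MassIsotopomerDistribution) else np.asarray(mid)
    return float(100.0 * np.dot(np.arange(len(fractions)), fractions))


@dataclass
class AminoAcidFragmentMap:
    """Maps measured amino-acid fragments to precursor EMUs.

    Each entry is (fragment label, list of precursor EMUFragments); a list
    with more than one precursor denotes a condensation, whose MID is the
    convolution of the precursor MIDs.  The default map ships as editable
    package data, not code.
    """

    entries: list[tuple[str, list[EMUFragment]]]

    def validate(self, net: AtomMapNetwork) -> None:
        for label, parts in self.entries:
            for frag in parts:
                met = net.metabolites.get(frag.metabolite)
                if met is None:
                    raise ValueError(f"fragment map {label}: unknown metabolite {frag.metabolite}")
                if frag.positions[-1] > met.n_carbons:
                    raise ValueError(f"fragment map {label}: {frag!r} out of range")

    def all_precursors(self) -> list[EMUFragment]:
        seen: dict[EMUFragment, None] = {}
        for _, parts in self.entries:
            for frag in parts:
                seen[frag] = None
        return list(seen)

    @classmethod
    def from_dict(cls, doc: dict) -> "AminoAcidFragmentMap":
        entries = [
            (item["label"], [EMUFragment(m, pos) for m, pos in item["parts"]])
            for item in doc["fragments"]
        ]
        return cls(entries)


def default_fragment_map() -> AminoAcidFragmentMap:
    """The shipped proteinogenic amino-acid precursor fragment map."""
    import json
    from importlib import resources

    text = resources.files("crabtree").joinpath("data/amino_acid_fragments.json").read_text()
    return AminoAcidFragmentMap.from_dict(json.loads(text))


def simulate_sfl_dataset(net: AtomMapNetwork, fluxes,
                         frag_map: AminoAcidFragmentMap | None = None,
                         simulator: EMUSimulator | None = None) -> pd.DataFrame:
    """SFL (%) per mapped amino-acid fragment at the given fluxes."""
    if frag_map is None:
        frag_map = default_fragment_map()
    frag_map.validate(net)
    if simulator is None:
        simulator = EMUSimulator(net, frag_map.all_precursors())
    mids = simulator.mids(fluxes)
    rows = []
    for label, parts in frag_map.entries:
        mid = None
        for frag in parts:
            m = mids[frag]
            mid = m if mid is None else np.convolve(mid, m)
        rows.append({"fragment_id": label, "sfl_percent": sfl_from_mid(mid)})
    return pd.DataFrame(rows)


def natural_abundance_convolve(mid: np.ndarray, n_carbons: int,
                               abundance: float = 0.011,
                               inverse: bool = False) -> np.ndarray:
    """Apply (or invert) the binomial natural 13C abundance correction.

    Off by default in the simulator: synthetic data is generated without
    natural abundance so that simulator and fitter stay self-consistent.
    """
    from scipy.stats import binom

    nat = binom.pmf(np.arange(n_carbons + 1), n_carbons, abundance)
    M = np.zeros((n_carbons + 1, n_carbons + 1))
    for j in range(n_carbons + 1):
        for k in range(n_carbons + 1 - j):
            M[j + k, j] += nat[k]
    out = np.linalg.solve(M, mid) if inverse else M @ mid
    return out
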