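"""Independent oracles used by the test suite.

These are deliberately different algorithms from the package code paths:
exhaustive positional-isotopomer enumeration (fixed-point iteration over
all 2^n labeling states) as the reference for the EMU simulator, a
from-the-formula Welch test, and exhaustive k-subset enumeration for the
reporter background.
"""

from __future__ import annotations

import itertools
from math import comb, sqrt

import numpy as np

from crabtree.labeling import EMUFragment, _direction_fluxes, _direction_producers


def enumerate_isotopomers(net, fluxes, exchange=None, tol=1e-13, max_iter=50000):
    """Steady-state positional isotopomer distributions by fixed point.

    Returns {metabolite: array over 2^n labeling patterns} with bit order
    carbon 1 = most significant bit.
    """
    dirflux = _direction_fluxes(net, fluxes, exchange)
    mets = net.metabolites
    dist = {}
    for mid, met in mets.items():
        d = np.zeros(2 ** met.n_carbons)
        pats = net.substrate_label.get(mid)
        if not met.balanced and pats:
            for pat, frac in pats:
                d[int(pat, 2)] += frac
        else:
            d[0] = 1.0
        dist[mid] = d
    terms = {m: [] for m in mets if mets[m].balanced}
    for rxn in net.reactions.values():
        for sign in ((1, -1) if rxn.reversible else (1,)):
            w = dirflux.get((rxn.id, sign), 0.0)
            if w <= 0:
                continue
            consumed, produced = _direction_producers(net, rxn, sign)
            for pmet, cmap in produced:
                if not mets[pmet].balanced:
                    continue
                n = mets[pmet].n_carbons
                variants = [[cmap[c] for c in range(1, n + 1)]]
                wts = [w]
                if mets[pmet].symmetric:
                    variants.append([cmap[n + 1 - c] for c in range(1, n + 1)])
                    wts = [w / 2, w / 2]
                for var, wv in zip(variants, wts):
                    terms[pmet].append((wv, consumed, var))
    it = 0
    for it in range(max_iter):
        delta = 0.0
        new = {}
        for pmet, tl in terms.items():
            n = mets[pmet].n_carbons
            acc = np.zeros(2 ** n)
            tot = 0.0
            for wv, consumed, var in tl:
                tot += wv
                used = sorted({si for si, _ in var})
                dists = [dist[consumed[si]] for si in used]
                ncs = [mets[consumed[si]].n_carbons for si in used]
                out = np.zeros(2 ** n)
                for combo in itertools.product(*[range(2 ** nc) for nc in ncs]):
                    p = 1.0
                    for d, idx in zip(dists, combo):
                        p *= d[idx]
                    if p == 0:
                        continue
                    pat = 0
                    for c, (si, sc) in enumerate(var, start=1):
                        ui = used.index(si)
                        bit = (combo[ui] >> (ncs[ui] - sc)) & 1
                        pat |= bit << (n - c)
                    out[pat] += p
                acc += wv * out
            if tot <= 0:
                new[pmet] = dist[pmet]
                continue
            nd = acc / tot
            delta = max(delta, float(np.abs(nd - dist[pmet]).max()))
            new[pmet] = nd
        dist.update(new)
        if delta < tol:
            break
    return dist


def mid_from_isotopomers(net, dist, frag: EMUFragment) -> np.ndarray:
    n = net.metabolites[frag.metabolite].n_carbons
    mid = np.zeros(frag.size + 1)
    for idx, p in enumerate(dist[frag.metabolite]):
        if p == 0:
            continue
        k = sum((idx >> (n - pos)) & 1 for pos in frag.positions)
        mid[k] += p
    return mid


def welch_reference(a, b):
    """Welch t-test from first principles (mpmath-free closed form)."""
    from scipy.special import stdtr

    a = list(map(float, a))
    b = list(map(float, b))
    n1, n2 = len(a), len(b)
    m1 = sum(a) / n1
    m2 = sum(b) / n2
    v1 = sum((x - m1) ** 2 for x in a) / (n1 - 1)
    v2 = sum((x - m2) ** 2 for x in b) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * (1.0 - stdtr(df, abs(t)))
    return t, df, p


def exhaustive_background(z: np.ndarray, k: int) -> tuple[float, float]:
    """Exact mean and sd of sum(z)/sqrt(k) over all k-subsets."""
    stats = [sum(c) / sqrt(k) for c in itertools.combinations(z, k)]
    arr = np.array(stats)
    assert len(arr) == comb(len(z), k)
    return float(arr.mean()), float(arr.std(ddof=0))
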