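"""Reporter-features algorithm: aggregate gene-level significance onto the
features (metabolites, GO terms) of a bipartite gene-feature graph.

Each gene's p-value is transformed to z = Phi^-1(1 - p).  A feature with k
neighbor genes scores Z = sum(z) / sqrt(k); the score is corrected against
a sampled background of random k-gene sets drawn from the scored-gene
universe (mean mu_k, sd sigma_k), giving Z' = (Z - mu_k) / sigma_k and a
reporter p-value 1 - Phi(Z').  Directional scores run the procedure on the
two directional p-value sets and keep the more significant side with a
sign (+ = up in condition A, - = up in condition B).

Default cutoffs follow the study design: 0.01 for GO-term features and
0.05 for metabolite features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReporterGraph",
    "gene_zscores",
    "reporter_scores",
    "directional_scores",
    "REPORTER_CUTOFFS",
    "P_CLIP",
]

REPORTER_CUTOFFS = {"go_term": 0.01, "metabolite": 0.05}
P_CLIP = 1e-15


@dataclass
class ReporterGraph:
    """Bipartite gene-feature graph.

    ``feature_kinds`` maps each feature to its kind ("metabolite" or
    "go_term"); ``edges`` is a list of (gene, feature) pairs.
    """

    genes: set[str]
    feature_kinds: dict[str, str]
    edges: list[tuple[str, str]]
    _adj: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._adj = {}
        for g, f in self.edges:
            if g not in self.genes:
                raise ValueError(f"dangling edge: unknown gene {g}")
            if f not in self.feature_kinds:
                raise ValueError(f"dangling edge: unknown feature {f}")
            self._adj.setdefault(f, []).append(g)
        for f in self._adj:
            self._adj[f] = sorted(set(self._adj[f]))

    def neighbors(self, feature: str) -> list[str]:
        return self._adj.get(feature, [])

    @property
    def scored_features(self) -> list[str]:
        return sorted(f for f in self.feature_kinds if self._adj.get(f))

    @classmethod
    def from_tsv(cls, edges_path: str | Path,
                 kinds_path: Optional[str | Path] = None) -> "ReporterGraph":
        """Load from a two-column TSV (gene_id, feature_id) plus an
        optional feature-kind TSV (feature_id, kind)."""
        edges_df = pd.read_csv(edges_path, sep="\t")
        gcol, fcol = edges_df.columns[:2]
        edges = [(str(g), str(f)) for g, f in zip(edges_df[gcol], edges_df[fcol])]
        if kinds_path is not None:
            kdf = pd.read_csv(kinds_path, sep="\t")
            kinds = {str(f): str(k) for f, k in zip(kdf.iloc[:, 0], kdf.iloc[:, 1])}
        else:
            kinds = {f: "metabolite" for _, f in edges}
        genes = {g for g, _ in edges}
        return cls(genes=genes, feature_kinds=kinds, edges=edges)


def gene_zscores(pvalues: Mapping[str, float] | pd.Series) -> pd.Series:
    """z = Phi^-1(1 - p), with p clipped to [1e-15, 1 - 1e-15]."""
    s = pd.Series(pvalues, dtype=float)
    p = s.clip(P_CLIP, 1.0 - P_CLIP)
    return pd.Series(stats.norm.isf(p), index=s.index, name="z")


def _sample_ksubsets(rng: np.random.Generator, n_universe: int, k: int,
                     n_samples: int, chunk: int = 2000) -> "np.ndarray":
    """Index matrix (n_samples, k) of random k-subsets without replacement."""
    blocks = []
    remaining = n_samples
    while remaining > 0:
        m = min(chunk, remaining)
        keys = rng.random((m, n_universe))
        blocks.append(np.argpartition(keys, k - 1, axis=1)[:, :k])
        remaining -= m
    return np.vstack(blocks)


def _background(z: np.ndarray, ks: Iterable[int], n_background: int,
                rng: np.random.Generator) -> dict[int, tuple[float, float]]:
    """mu_k and sigma_k of sum(z)/sqrt(k) over random k-subsets.

    k values are processed in ascending order from a single seeded stream,
    making the result independent of feature ordering.  For a degenerate
    universe (k = universe size) the only sample is the full set and
    sigma_k = 0.
    """
    out: dict[int, tuple[float, float]] = {}
    n = len(z)
    for k in sorted(set(ks)):
        if k > n:
            raise ValueError(f"feature degree {k} exceeds the scored-gene universe ({n})")
        if k == n:
            stat = z.sum() / np.sqrt(k)
            out[k] = (float(stat), 0.0)
            continue
        idx = _sample_ksubsets(rng, n, k, n_background)
        stat = z[idx].sum(axis=1) / np.sqrt(k)
        mu = float(stat.mean())
        sigma = float(stat.std(ddof=0))
        if sigma <= 1e-9 * max(1.0, abs(mu)):   # constant z-field
            sigma = 0.0
        out[k] = (mu, sigma)
    return out


def reporter_scores(graph: ReporterGraph,
                    gene_p: Mapping[str, float] | pd.Series,
                    n_background: int = 10000,
                    seed: int = 0) -> pd.DataFrame:
    """Background-corrected reporter scores for every connected feature.

    Returns a DataFrame (feature, kind, k, z_raw, z_corrected, p) sorted by
    feature id.  The background universe is the set of scored genes.
    Deterministic given the seed.
    """
    zs = gene_zscores(gene_p).sort_index()  # order-independent universe
    universe = zs.index.to_list()
    uidx = {g: i for i, g in enumerate(universe)}
    zarr = zs.to_numpy()
    feats = []
    for f in graph.scored_features:
        neigh = [g for g in graph.neighbors(f) if g in uidx]
        missing = [g for g in graph.neighbors(f) if g not in uidx]
        if missing:
            raise ValueError(f"feature {f}: neighbor genes without scores: {missing[:3]}")
        feats.append((f, neigh))
    rng = np.random.default_rng(seed)
    bg = _background(zarr, (len(n) for _, n in feats), n_background, rng)
    rows = []
    for f, neigh in feats:
        k = len(neigh)
        raw = zarr[[uidx[g] for g in neigh]].sum() / np.sqrt(k)
        mu, sigma = bg[k]
        zc = (raw - mu) / sigma if sigma > 0 else 0.0
        rows.append({"feature": f, "kind": graph.feature_kinds[f], "k": k,
                     "z_raw": float(raw), "z_corrected": float(zc),
                     "p": float(stats.norm.sf(zc))})
    return pd.DataFrame(rows).set_index("feature")


def directional_scores(graph: ReporterGraph,
                       up_a_pvalues: Mapping[str, float] | pd.Series,
                       up_b_pvalues: Mapping[str, float] | pd.Series,
                       n_background: int = 10000,
                       seed: int = 0) -> pd.DataFrame:
    """Signed directional reporter scores.

    Runs the reporter procedure separately on the condition-A-up and
    condition-B-up p-value sets; each feature keeps its more significant
    side, signed +(-log10 p) for A-up and -(-log10 p) for B-up (by the
    study's convention, negative = higher in chemostat).  Equal p-values
    keep the A-up sign and are flagged as ties.
    """
    res_a = reporter_scores(graph, up_a_pvalues, n_background, seed)
    res_b = reporter_scores(graph, up_b_pvalues, n_background, seed)
    rows = []
    for f in res_a.index:
        pa, pb = res_a.loc[f, "p"], res_b.loc[f, "p"]
        tie = bool(pa == pb)
        if pb < pa:
            p, sign = pb, -1.0
        else:
            p, sign = pa, 1.0
        score = sign * (-np.log10(max(p, P_CLIP)))
        rows.append({"feature": f, "kind": res_a.loc[f, "kind"],
                     "k": int(res_a.loc[f, "k"]),
                     "p_up_a": pa, "p_up_b": pb, "p": p,
                     "signed_score": float(score), "tie": tie})
    return pd.DataFrame(rows).set_index("feature")
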