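"""Synthetic data generators with known ground truth for every stage.

Every generator is a pure function of its parameters and seed; with the
noise terms at zero the outputs are exact functions of the planted
parameters, so downstream stages can be tested for exact recovery.  The
default parameter values reproduce the study conditions: aerobic batch
cultures on 20 g/L glucose, chemostats at D = 0.1 1/h, 100% [1-13C]glucose
labeling, and two-group metabolome tables of protein-normalized
abundances.

Ground-truth flux scenarios
---------------------------
``reference_flux_scenario`` builds steady-state flux maps on the glucose =
100 scale for the four cultivations: the Crabtree-positive yeast in batch
(respiro-fermentative: large PDC flux to ethanol, PDH 4.3) and chemostat
(respiratory, PDH 61.7), and the Crabtree-negative yeast in batch and
chemostat (both respiratory, no secretion, slightly higher PDH and PPP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .fluxfit import FluxState, MeasurementSet, steady_state_flux_map
from .labeling import AminoAcidFragmentMap, simulate_sfl_dataset
from .network import AtomMapNetwork, build_central_carbon_network
from .physiology import (BIOMASS_G_PER_CMOL, CARBON_CONTENT,
                         FermentationProfile, MOLAR_GAS_VOLUME,
                         PRODUCT_SPECIES)
from .reporter import ReporterGraph

__all__ = [
    "SyntheticScenario",
    "make_batch_profile",
    "make_chemostat_profile",
    "make_sfl_dataset",
    "make_metabolome",
    "make_counts",
    "make_reporter_graph",
    "reference_flux_scenario",
    "example_fold_changes",
    "FLUX_SCENARIOS",
]


@dataclass
class SyntheticScenario:
    """Bundle of planted parameters for a full synthetic study."""

    seed: int = 0
    mu: float = 0.47
    X0: float = 0.05
    S0: float = 20.0
    D: float = 0.1
    S_in: float = 10.0
    yields: dict[str, float] = field(default_factory=lambda: {"Ysx": 0.55})
    flux_scenario: str = "negative_batch"
    concentration_cv: float = 0.0
    sfl_noise_sd: float = 0.0
    metabolome_cv: float = 0.3
    nb_dispersion: float = 0.05

    def __post_init__(self):
        for name in ("concentration_cv", "sfl_noise_sd", "metabolome_cv",
                     "nb_dispersion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# Fermentation profiles
# ---------------------------------------------------------------------------

def _check_yields(yields: dict[str, float]) -> None:
    spec_c = {"Ysx": 1000.0 / BIOMASS_G_PER_CMOL,
              "YsEtOH": CARBON_CONTENT["ethanol"],
              "YsGly": CARBON_CONTENT["glycerol"],
              "YsAc": CARBON_CONTENT["acetate"],
              "YsPyr": CARBON_CONTENT["pyruvate"]}
    c_out = sum(yields.get(k, 0.0) * c for k, c in spec_c.items())
    if c_out > CARBON_CONTENT["glucose"] * (1 + 1e-9):
        raise ValueError("infeasible yields: more carbon in products than in glucose")
    if any(v < 0 for v in yields.values()):
        raise ValueError("yields must be >= 0")


def _offgas_for(q_o2: np.ndarray, q_co2: np.ndarray, X: np.ndarray,
                volume: float = 1.0, gas_flow: float = 60.0,
                y_o2_in: float = 0.2095, y_co2_in: float = 0.0004,
                molar_volume: float = MOLAR_GAS_VOLUME) -> pd.DataFrame:
    """Outlet gas composition consistent with specific rates (mmol/gDW/h).

    Inverts the inert-gas balance exactly, so the physiology stage
    round-trips OTR/CTR to machine precision.
    """
    otr = q_o2 * X          # mmol/L/h
    ctr = q_co2 * X
    n_o2_in = gas_flow * y_o2_in / molar_volume * 1000.0   # mmol/h
    n_co2_in = gas_flow * y_co2_in / molar_volume * 1000.0
    n_inert = gas_flow * (1 - y_o2_in - y_co2_in) / molar_volume * 1000.0
    n_o2_out = n_o2_in - otr * volume
    n_co2_out = n_co2_in + ctr * volume
    if np.any(n_o2_out < 0):
        raise ValueError("off-gas construction: OTR exceeds oxygen supply")
    n_tot = n_inert + n_o2_out + n_co2_out
    return pd.DataFrame({
        "y_o2_in": y_o2_in, "y_co2_in": y_co2_in,
        "y_o2_out": n_o2_out / n_tot, "y_co2_out": n_co2_out / n_tot,
        "gas_flow": n_tot * molar_volume / 1000.0, "volume": volume,
    })


def _specific_gas_rates(mu: float, yields: dict[str, float],
                        rq: Optional[float]) -> tuple[float, float]:
    """(q_O2, q_CO2) in mmol/gDW/h from a carbon balance and a planted RQ.

    q_CO2 closes the carbon balance: whatever substrate carbon does not end
    in biomass or secreted products leaves as CO2.  q_O2 = q_CO2 / RQ.
    """
    ysx = yields.get("Ysx", 0.0)
    if ysx <= 0:
        raise ValueError("Ysx must be > 0")
    q_glc_mass = mu / ysx
    q_c_in = q_glc_mass * CARBON_CONTENT["glucose"]
    q_c_bio = mu * 1000.0 / BIOMASS_G_PER_CMOL
    spec = {"YsEtOH": "ethanol", "YsGly": "glycerol",
            "YsAc": "acetate", "YsPyr": "pyruvate"}
    q_c_prod = sum(yields.get(k, 0.0) * q_glc_mass * CARBON_CONTENT[sp]
                   for k, sp in spec.items())
    q_co2 = q_c_in - q_c_bio - q_c_prod
    if q_co2 < -1e-9:
        raise ValueError("infeasible yields: negative CO2 evolution")
    q_co2 = max(q_co2, 0.0)
    q_o2 = q_co2 / rq if rq else q_co2
    return q_o2, q_co2


def make_batch_profile(mu: float, X0: float = 0.05, S0: float = 20.0,
                       yields: Optional[dict[str, float]] = None,
                       noise_cv: float = 0.0, seed: int = 0,
                       n_points: int = 12, t_end: Optional[float] = None,
                       rq: float = 1.0, offgas: bool = True) -> FermentationProfile:
    """Exponential batch profile with planted growth rate and yields.

    X(t) = X0 exp(mu t) until glucose exhaustion; glucose and products
    track the planted yields.  ``noise_cv`` applies multiplicative
    lognormal noise to all concentrations (zero noise = exact values,
    independent of the seed).  Off-gas columns are constructed consistent
    with the implied q_s and the planted RQ.
    """
    if mu <= 0 or S0 <= 0 or X0 <= 0:
        raise ValueError("mu, X0 and S0 must be > 0")
    yields = dict(yields or {"Ysx": 0.55})
    _check_yields(yields)
    ysx = yields.get("Ysx", 0.55)
    t_exhaust = np.log(1 + ysx * S0 / X0 * 0.95) / mu
    T = min(t_end, t_exhaust) if t_end is not None else t_exhaust
    t = np.linspace(0.0, T, n_points)
    X = X0 * np.exp(mu * t)
    dX = X - X0
    S = S0 - dX / ysx
    data = {"time": t, "biomass": X, "glucose": S}
    spec = {"YsEtOH": "ethanol", "YsGly": "glycerol",
            "YsAc": "acetate", "YsPyr": "pyruvate"}
    for k, sp in spec.items():
        data[sp] = yields.get(k, 0.0) / ysx * dX
    df = pd.DataFrame(data)
    if offgas:
        q_o2, q_co2 = _specific_gas_rates(mu, yields, rq)
        df = pd.concat([df, _offgas_for(np.full_like(t, q_o2),
                                        np.full_like(t, q_co2), X)], axis=1)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1 + noise_cv ** 2))
        cols = ["biomass", "glucose"] + list(PRODUCT_SPECIES)
        for c in cols:
            df[c] = df[c] * rng.lognormal(-sigma ** 2 / 2, sigma, len(df))
    return FermentationProfile("batch", df)


def make_chemostat_profile(D: float, S_in: float = 10.0,
                           yields: Optional[dict[str, float]] = None,
                           noise_cv: float = 0.0, seed: int = 0,
                           n_points: int = 11, residence_times: float = 5.0,
                           S_res: float = 0.0, rq: float = 1.0,
                           offgas: bool = True) -> FermentationProfile:
    """Steady-state chemostat profile: X = Ysx (S_in - S_res), mu = D."""
    if D <= 0 or S_in <= 0:
        raise ValueError("D and S_in must be > 0")
    yields = dict(yields or {"Ysx": 0.55})
    _check_yields(yields)
    ysx = yields.get("Ysx", 0.55)
    X = ysx * (S_in - S_res)
    t = np.linspace(0.0, residence_times / D, n_points)
    data = {"time": t, "biomass": np.full_like(t, X),
            "glucose": np.full_like(t, S_res)}
    spec = {"YsEtOH": "ethanol", "YsGly": "glycerol",
            "YsAc": "acetate", "YsPyr": "pyruvate"}
    for k, sp in spec.items():
        data[sp] = np.full_like(t, yields.get(k, 0.0) * (S_in - S_res))
    df = pd.DataFrame(data)
    if offgas:
        q_o2, q_co2 = _specific_gas_rates(D, yields, rq)
        df = pd.concat([df, _offgas_for(np.full_like(t, q_o2),
                                        np.full_like(t, q_co2),
                                        df["biomass"].to_numpy())], axis=1)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log(1 + noise_cv ** 2))
        for c in ["biomass", "glucose"] + list(PRODUCT_SPECIES):
            df[c] = df[c] * rng.lognormal(-sigma ** 2 / 2, sigma, len(df))
    return FermentationProfile("chemostat", df, D=D, S_in=S_in)


# ---------------------------------------------------------------------------
# Ground-truth flux scenarios and SFL datasets
# ---------------------------------------------------------------------------

# Target fluxes (glucose uptake = 100 scale) pinning all 18 degrees of
# freedom of the central-carbon network.  The positive (S. cerevisiae)
# scenarios plant the reported PDH values (4.3 batch, 61.7 chemostat); the
# negative (S. stipitis) scenarios are respiratory in both modes with
# slightly higher PDH and a higher PPP flux in batch.
FLUX_SCENARIOS: dict[str, dict] = {
    "positive_batch": {
        "variant": "crabtree_positive", "drain_scale": 2.4,
        "targets": {"HXK": 100.0, "ZWF": 15.0, "ADH": 129.0, "EX_GLYC": 4.0,
                    "EX_AC": 3.0, "EX_PYR": 0.6, "MAE": 1.5, "ICL": 0.5,
                    "PDH": 4.3},
    },
    "positive_chemostat": {
        "variant": "crabtree_positive", "drain_scale": 7.0,
        "targets": {"HXK": 100.0, "ZWF": 40.0, "ADH": 0.0, "EX_GLYC": 0.0,
                    "EX_AC": 0.0, "EX_PYR": 0.0, "MAE": 4.0, "ICL": 2.0,
                    "PDH": 61.7},
    },
    "negative_batch": {
        "variant": "crabtree_negative", "drain_scale": 7.0,
        "targets": {"HXK": 100.0, "ZWF": 45.0, "ADH": 0.0, "EX_GLYC": 0.0,
                    "EX_AC": 0.0, "EX_PYR": 0.0, "MAE": 3.0, "ICL": 1.0,
                    "ACT": 2.0},
    },
    "negative_chemostat": {
        "variant": "crabtree_negative", "drain_scale": 7.0,
        "targets": {"HXK": 100.0, "ZWF": 40.0, "ADH": 0.0, "EX_GLYC": 0.0,
                    "EX_AC": 0.0, "EX_PYR": 0.0, "MAE": 3.0, "ICL": 1.0,
                    "ACT": 2.0},
    },
}


def reference_flux_scenario(name: str,
                            net: Optional[AtomMapNetwork] = None
                            ) -> tuple[AtomMapNetwork, FluxState]:
    """Network and planted ground-truth flux map for a named scenario."""
    if name not in FLUX_SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(FLUX_SCENARIOS)}")
    spec = FLUX_SCENARIOS[name]
    if net is None:
        net = build_central_carbon_network(spec["variant"])
    targets = dict(spec["targets"])
    for pid, w in net.biomass_drains:
        targets[f"BM_{pid}"] = w * spec["drain_scale"]
    return net, steady_state_flux_map(net, targets)


MEASURED_RATE_REACTIONS = ("ADH", "EX_GLYC", "EX_AC", "EX_PYR")


def make_sfl_dataset(net: AtomMapNetwork, fluxes: FluxState,
                     noise_sd: float = 0.0, seed: int = 0,
                     frag_map: Optional[AminoAcidFragmentMap] = None,
                     rate_sd: float = 0.5, drain_rel_sd: float = 0.02,
                     sd_floor: float = 0.1) -> MeasurementSet:
    """SFL measurement set simulated from a planted flux map.

    SFL values get additive Gaussian noise with sd ``noise_sd`` (the sd
    column records max(noise_sd, 0.1)).  Measured rates cover the secretion
    fluxes (absent products included as 0 +/- sd) and the biomass precursor
    drains; the rates themselves are noise-free.
    """
    sfl = simulate_sfl_dataset(net, fluxes, frag_map)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sfl["sfl_percent"] = sfl["sfl_percent"] + rng.normal(0, noise_sd, len(sfl))
    sfl["sd_percent"] = max(noise_sd, sd_floor)
    rate_rxns = [r for r in MEASURED_RATE_REACTIONS if r in net.reactions]
    rate_rxns += [f"BM_{p}" for p, _ in net.biomass_drains]
    rates = pd.DataFrame({
        "reaction": rate_rxns,
        "rate": [fluxes.net.get(r, 0.0) for r in rate_rxns],
        "sd": [rate_sd if not r.startswith("BM_")
               else max(drain_rel_sd * abs(fluxes.net.get(r, 0.0)), sd_floor)
               for r in rate_rxns],
    })
    return MeasurementSet(sfl, rates)


# ---------------------------------------------------------------------------
# Metabolome tables
# ---------------------------------------------------------------------------

def example_fold_changes() -> pd.DataFrame:
    """Representative planted fold-change map (group ratio Ss/Sc) with
    pathway labels, echoing the magnitudes seen in comparative yeast
    metabolome tables (e.g. strongly increased adenine and polyols,
    decreased amino acids)."""
    rows = [
        ("adenine", "NUCLEOTIDES", "Purine metabolism, adenine containing", 38.76),
        ("inosine", "NUCLEOTIDES", "Purine metabolism, (hypo)xanthine/inosine containing", 0.15),
        ("threonine", "AMINO ACIDS", "Glycine, serine and threonine metabolism", 0.19),
        ("glutamine", "AMINO ACIDS", "Glutamate metabolism", 0.26),
        ("histidine", "AMINO ACIDS", "Histidine metabolism", 0.22),
        ("phenylalanine", "AMINO ACIDS", "Phenylalanine & tyrosine metabolism", 0.22),
        ("phenylacetate", "AMINO ACIDS", "Phenylalanine & tyrosine metabolism", 1.67),
        ("isoleucine", "AMINO ACIDS", "Valine, leucine and isoleucine metabolism", 0.16),
        ("valine", "AMINO ACIDS", "Valine, leucine and isoleucine metabolism", 0.30),
        ("citramalate", "AMINO ACIDS", "Valine, leucine and isoleucine metabolism", 3.15),
        ("arginine", "AMINO ACIDS", "Urea cycle; arginine-, proline-, metabolism", 0.12),
        ("proline", "AMINO ACIDS", "Urea cycle; arginine-, proline-, metabolism", 0.19),
        ("glucose", "CARBOHYDRATES", "Glycolysis, gluconeogenesis, pyruvate metabolism", 0.21),
        ("pyruvate", "CARBOHYDRATES", "Glycolysis, gluconeogenesis, pyruvate metabolism", 0.17),
        ("trehalose", "CARBOHYDRATES", "Glycolysis, gluconeogenesis, pyruvate metabolism", 4.06),
        ("arabitol", "CARBOHYDRATES", "Nucleotide sugars, pentose metabolism", 317.22),
        ("ribitol", "CARBOHYDRATES", "Nucleotide sugars, pentose metabolism", 46.97),
        ("ribulose", "CARBOHYDRATES", "Nucleotide sugars, pentose metabolism", 4.31),
        ("citrate", "ENERGY METABOLISM", "Krebs cycle", 0.45),
        ("succinate", "ENERGY METABOLISM", "Krebs cycle", 0.56),
        ("fumarate", "ENERGY METABOLISM", "Krebs cycle", 7.52),
        ("malate", "ENERGY METABOLISM", "Krebs cycle", 4.75),
        ("linoleate (18:2n6)", "LIPIDS", "Essential fatty acid", 2.35),
        ("glycerol", "LIPIDS", "Glycerolipid metabolism", 0.10),
        ("choline", "LIPIDS", "Glycerolipid metabolism", 3.11),
    ]
    return pd.DataFrame(rows, columns=["metabolite", "super_pathway",
                                       "sub_pathway", "fold_change"])


def make_metabolome(n_per_group: int = 6,
                    fold_change_map: Optional[pd.DataFrame] = None,
                    cv: float = 0.3, seed: int = 0,
                    group_labels: tuple[str, str] = ("Ss", "Sc"),
                    baseline: float = 1.0):
    """Two-group metabolome table with exactly planted mean fold changes.

    Samples are lognormal with the given CV; after sampling, each group is
    rescaled so the realized mean ratio equals the planted fold change
    exactly (deterministic worked-example targets).  ``cv = 0`` gives zero
    within-group variance.
    """
    from .omics import MetaboliteAbundanceTable

    if fold_change_map is None:
        fold_change_map = example_fold_changes()
    if n_per_group < 2:
        raise ValueError("need at least 2 samples per group")
    if (fold_change_map["fold_change"] <= 0).any():
        raise ValueError("fold changes must be > 0")
    rng = np.random.default_rng(seed)
    g1, g2 = group_labels
    samples = [f"{g1}_{i+1}" for i in range(n_per_group)] + \
              [f"{g2}_{i+1}" for i in range(n_per_group)]
    groups = {s: (g1 if s.startswith(f"{g1}_") else g2) for s in samples}
    sigma = np.sqrt(np.log(1 + cv ** 2)) if cv > 0 else 0.0
    rows = []
    for _, rec in fold_change_map.iterrows():
        draw = (rng.lognormal(0.0, sigma, 2 * n_per_group)
                if sigma > 0 else np.ones(2 * n_per_group))
        a = draw[:n_per_group]
        b = draw[n_per_group:]
        a = a / a.mean() * (baseline * rec["fold_change"])
        b = b / b.mean() * baseline
        rows.append([rec["metabolite"], rec["super_pathway"], rec["sub_pathway"],
                     *a, *b])
    frame = pd.DataFrame(rows, columns=["metabolite", "super_pathway",
                                        "sub_pathway", *samples]).set_index("metabolite")
    return MetaboliteAbundanceTable(frame, groups)


# ---------------------------------------------------------------------------
# Counts and reporter graphs
# ---------------------------------------------------------------------------

def make_counts(n_genes: int = 200,
                lengths: Optional[np.ndarray] = None,
                library_sizes: tuple[float, ...] = (5.95e6, 5.95e6),
                dispersion: float = 0.05, seed: int = 0) -> pd.DataFrame:
    """Negative-binomial count table with gene lengths.

    Counts for gene g in sample s are NB with mean = relative expression *
    library size and variance mean + dispersion * mean^2 (Gamma-Poisson
    mixture; dispersion -> 0 recovers Poisson).  Library sizes default to
    the study's sequencing depth (~5.95 million read pairs per sample).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = np.round(rng.lognormal(np.log(1500), 0.4, n_genes)).astype(int)
        lengths = np.maximum(lengths, 150)
    rel = rng.dirichlet(np.full(n_genes, 0.5))
    data = {"gene": [f"g{i:04d}" for i in range(n_genes)], "length": lengths}
    for j, lib in enumerate(library_sizes):
        mean = rel * lib
        if dispersion > 0:
            lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
        else:
            lam = mean
        data[f"s{j+1}"] = rng.poisson(lam)
    return pd.DataFrame(data)


def make_reporter_graph(n_genes: int = 200, n_features: int = 40,
                        n_hot: int = 2, effect: float = 0.05,
                        degree_range: tuple[int, int] = (4, 8),
                        seed: int = 0,
                        feature_kind: str = "metabolite"
                        ) -> tuple[ReporterGraph, pd.DataFrame]:
    """Random bipartite gene-feature graph with planted hot features.

    Neighbor genes of the ``n_hot`` planted features draw p-values from
    Beta(effect, 1) (strongly skewed toward 0); all other genes are uniform
    null.  Returns the graph and a gene table with columns p, p_up_a,
    p_up_b (directional split: hot genes are up in condition A).
    """
    if n_genes < 1 or n_features < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    features = [f"f{i:03d}" for i in range(n_features)]
    edges = []
    neighbors: dict[str, list[str]] = {}
    for f in features:
        k = int(rng.integers(degree_range[0], degree_range[1] + 1))
        idx = rng.choice(n_genes, size=min(k, n_genes), replace=False)
        neighbors[f] = [genes[i] for i in idx]
        edges.extend((genes[i], f) for i in idx)
    hot = features[:n_hot]
    hot_genes = sorted({g for f in hot for g in neighbors[f]})
    p = rng.uniform(size=n_genes)
    gidx = {g: i for i, g in enumerate(genes)}
    for g in hot_genes:
        p[gidx[g]] = rng.beta(effect, 1.0)
    p = np.clip(p, 1e-15, 1 - 1e-15)
    # directional split: hot genes up in A; null genes get a random direction
    up_a = rng.uniform(size=n_genes) < 0.5
    up_a[[gidx[g] for g in hot_genes]] = True
    p_up_a = np.where(up_a, p / 2, 1 - p / 2)
    p_up_b = 1.0 - p_up_a
    graph = ReporterGraph(genes=set(genes),
                          feature_kinds={f: feature_kind for f in features},
                          edges=edges)
    table = pd.DataFrame({"gene": genes, "p": p,
                          "p_up_a": p_up_a, "p_up_b": p_up_b,
                          "hot_neighbor": [g in hot_genes for g in genes]})
    table.attrs["hot_features"] = hot
    return graph, table.set_index("gene")
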