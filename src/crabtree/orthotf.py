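"""Ortholog-family and transcription-factor comparison between two yeasts.

Consumes ortholog clusters in the OrthoMCL groups.txt dialect
("FAMID: tag|gene tag|gene ...") and per-species transcription-factor
catalogs; computes the shared/unique partition of TF-containing families
(Venn counts) and annotates unique families against a watchlist of TFs of
interest (e.g. the glucose-signalling regulators RGT1, MIG2, MIG3 or the
phospholipid regulators INO2/INO4).

A family is "shared" when it contains at least one TF gene from *each*
species (genes from both species alone are not enough); the looser
any-gene definition is available behind a flag.  TF genes absent from
every family are synthesized as singleton families, so that unique TFs
without detectable orthologs still count as (unique) families.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "OrthologFamilies",
    "TFCatalog",
    "VennCounts",
    "parse_groups",
    "write_groups",
    "tf_family_venn",
    "annotate_unique_families",
]


@dataclass
class OrthologFamilies:
    """family id -> set of (species tag, gene id); each gene in one family."""

    families: dict[str, set[tuple[str, str]]]

    def __post_init__(self):
        seen: dict[tuple[str, str], str] = {}
        for fam, members in self.families.items():
            for m in members:
                if m in seen:
                    raise ValueError(
                        f"gene {m[1]} ({m[0]}) appears in families {seen[m]} and {fam}")
                seen[m] = fam

    @property
    def n_families(self) -> int:
        return len(self.families)

    def species_of(self, fam: str) -> set[str]:
        return {sp for sp, _ in self.families[fam]}


@dataclass
class TFCatalog:
    """Per-species transcription-factor gene sets with optional annotation."""

    tfs: dict[str, set[str]]
    annotations: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        for sp, genes in self.tfs.items():
            if any(not g for g in genes):
                raise ValueError(f"empty TF gene id in species {sp}")

    @property
    def species(self) -> list[str]:
        return sorted(self.tfs)

    @classmethod
    def from_lists(cls, paths: dict[str, str | Path],
                   annotations: Optional[dict[str, tuple[str, str]]] = None) -> "TFCatalog":
        tfs = {}
        for sp, path in paths.items():
            genes = {line.strip() for line in Path(path).read_text().splitlines()
                     if line.strip() and not line.startswith("#")}
            tfs[sp] = genes
        return cls(tfs, annotations or {})


@dataclass
class VennCounts:
    shared: int
    unique_a: int
    unique_b: int

    @property
    def total(self) -> int:
        return self.shared + self.unique_a + self.unique_b


def parse_groups(source: str | Path, catalog: Optional[TFCatalog] = None,
                 separator: str = "|") -> OrthologFamilies:
    """Parse an OrthoMCL-style groups file.

    Lines look like ``FAM1: sc|YAL001C ps|PICST_1234``.  Malformed lines
    raise with their line number; a gene in two families raises.  When a
    ``catalog`` is given, TF genes absent from every family are added as
    singleton families (ids ``SINGLETON_<tag>_<gene>``).
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and source.endswith(".txt")):
        text = Path(source).read_text()
    else:
        text = str(source)
    families: dict[str, set[tuple[str, str]]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise ValueError(f"line {lineno}: missing 'FAMID:' prefix")
        fam, _, rest = line.partition(":")
        fam = fam.strip()
        if not fam:
            raise ValueError(f"line {lineno}: empty family id")
        if fam in families:
            raise ValueError(f"line {lineno}: duplicate family id {fam}")
        members = set()
        for token in rest.split():
            if separator not in token:
                raise ValueError(
                    f"line {lineno}: member {token!r} lacks the "
                    f"'tag{separator}gene' separator")
            sp, _, gene = token.partition(separator)
            if not sp or not gene:
                raise ValueError(f"line {lineno}: malformed member {token!r}")
            members.add((sp, gene))
        families[fam] = members
    out = OrthologFamilies(families)
    if catalog is not None:
        clustered = {m for members in out.families.values() for m in members}
        for sp, genes in sorted(catalog.tfs.items()):
            for gene in sorted(genes):
                if (sp, gene) not in clustered:
                    out.families[f"SINGLETON_{sp}_{gene}"] = {(sp, gene)}
    return out


def write_groups(families: OrthologFamilies, path: Optional[str | Path] = None,
                 separator: str = "|") -> str:
    lines = []
    for fam in sorted(families.families):
        members = " ".join(f"{sp}{separator}{g}"
                           for sp, g in sorted(families.families[fam]))
        lines.append(f"{fam}: {members}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def tf_family_venn(families: OrthologFamilies, catalog: TFCatalog,
                   shared_definition: str = "tf_both") -> tuple[VennCounts, pd.DataFrame]:
    """Shared/unique partition of TF-containing families.

    Families with at least one TF gene from either species are classified:
    shared = TFs from both species (or, with ``shared_definition
    ="any_gene"``, member genes from both species); unique_X = TFs from
    species X only.  Returns the counts and a per-family table.
    """
    if shared_definition not in ("tf_both", "any_gene"):
        raise ValueError(f"unknown shared_definition {shared_definition!r}")
    sps = catalog.species
    if len(sps) != 2:
        raise ValueError("exactly two species are required")
    if all(not genes for genes in catalog.tfs.values()):
        raise ValueError("empty TF catalog")
    sp_a, sp_b = sps
    rows = []
    shared = ua = ub = 0
    for fam, members in families.families.items():
        tf_a = sorted(g for sp, g in members if sp == sp_a and g in catalog.tfs[sp_a])
        tf_b = sorted(g for sp, g in members if sp == sp_b and g in catalog.tfs[sp_b])
        if not tf_a and not tf_b:
            continue
        if shared_definition == "tf_both":
            is_shared = bool(tf_a) and bool(tf_b)
        else:
            fam_species = {sp for sp, _ in members}
            is_shared = sp_a in fam_species and sp_b in fam_species
        if is_shared:
            cls = "shared"
            shared += 1
        elif tf_a:
            cls = f"unique_{sp_a}"
            ua += 1
        else:
            cls = f"unique_{sp_b}"
            ub += 1
        rows.append({"family": fam, "classification": cls,
                     f"tfs_{sp_a}": ";".join(tf_a), f"tfs_{sp_b}": ";".join(tf_b),
                     "n_members": len(members)})
    table = pd.DataFrame(rows).set_index("family").sort_index()
    return VennCounts(shared=shared, unique_a=ua, unique_b=ub), table


def annotate_unique_families(classification: pd.DataFrame, catalog: TFCatalog,
                             watchlist: Iterable[str] = ()) -> tuple[pd.DataFrame, list[str]]:
    """Join unique families with TF annotations and flag watchlist hits.

    Returns the annotated table of unique families plus the list of
    watchlist entries not found in any family.
    """
    watch = set(watchlist)
    uniq = classification[classification["classification"].str.startswith("unique_")].copy()
    tf_cols = [c for c in uniq.columns if c.startswith("tfs_")]
    names, descs, flags = [], [], []
    found: set[str] = set()
    for _, row in uniq.iterrows():
        genes = [g for c in tf_cols for g in str(row[c]).split(";") if g and g != "nan"]
        ann = [catalog.annotations.get(g) for g in genes]
        names.append(";".join(a[0] for a in ann if a))
        descs.append("; ".join(a[1] for a in ann if a))
        hits = {g for g in genes if g in watch}
        hits |= {catalog.annotations[g][0] for g in genes
                 if g in catalog.annotations and catalog.annotations[g][0] in watch}
        found |= hits
        flags.append(bool(hits))
    uniq["tf_name"] = names
    uniq["description"] = descs
    uniq["on_watchlist"] = flags
    not_found = sorted(watch - found)
    return uniq, not_found
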