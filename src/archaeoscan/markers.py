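"""Phyletic-pattern classification of methanogenesis marker families.

Given a boolean family x taxon presence matrix and a three-way grouping of
the taxa — the focal clade (the Methanomassiliicoccales), all other
methanogens, and non-methanogen archaea — each family is assigned to one of
six marker categories or to none:

1. present in and unique to all sequenced methanogens, absent from other
   archaea;
2. present in all sequenced methanogens and in less than 5% of other
   archaea;
3. present in more than 90% of sequenced methanogens (including the focal
   clade) and in less than 5% of other archaea;
4. absent from the focal clade but present in and unique to all other
   methanogens;
5. absent from the focal clade, present in more than 90% of other
   methanogens and in no other archaea;
6. absent from the focal clade, present in more than 90% of other
   methanogens and in less than 5% of other archaea.

Categories are evaluated in order 1..6 and the first satisfied one is
returned (category 1 implies category 2's condition, so ordered matching
yields the most specific label).  The >90% / <5% cut-offs are strict
inequalities by default; "not in other archaea" means an outgroup fraction
of exactly zero, and "all" means a fraction of exactly one.  Categories 1-3
require presence in every focal taxon and 4-6 absence from every focal
taxon, so the two ranges are mutually exclusive.  "Other methanogens"
fractions (categories 4-6) are computed over the non-focal methanogens
only.  The classifier is search-agnostic: any homology screen that produces
a presence matrix (e.g. the orthology module's screen_against) can feed it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class TaxonGroups:
    focal: list[str]
    other_ingroup: list[str]
    outgroup: list[str]

    def __post_init__(self) -> None:
        sets = [set(self.focal), set(self.other_ingroup), set(self.outgroup)]
        if not self.focal and not self.other_ingroup:
            raise ValueError("ingroup (focal + other_ingroup) must be non-empty")
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise ValueError("groups must be disjoint")

    @property
    def taxa(self) -> list[str]:
        return list(self.focal) + list(self.other_ingroup) + list(self.outgroup)


def _fraction(row: dict[str, bool], taxa: Sequence[str]) -> float:
    if not taxa:
        return 0.0
    return sum(bool(row[t]) for t in taxa) / len(taxa)


def classify_family(
    row: dict[str, bool],
    groups: TaxonGroups,
    strict: bool = True,
) -> Optional[int]:
    """Marker category (1-6) of one family's phyletic pattern, or None.

    ``row`` maps taxon id to presence.  With ``strict`` (default) the >90%
    and <5% thresholds are strict inequalities; set False for inclusive
    comparisons at the boundaries.
    """
    missing = [t for t in groups.taxa if t not in row]
    if missing:
        raise ValueError(f"row lacks taxa {missing}")
    f_focal = _fraction(row, groups.focal)
    f_other = _fraction(row, groups.other_ingroup)
    ingroup = list(groups.focal) + list(groups.other_ingroup)
    f_ingroup = _fraction(row, ingroup)
    f_out = _fraction(row, groups.outgroup)

    if strict:
        over90 = lambda x: x > 0.9
        under5 = lambda x: x < 0.05
    else:
        over90 = lambda x: x >= 0.9
        under5 = lambda x: x <= 0.05

    focal_all = f_focal == 1.0
    focal_none = f_focal == 0.0
    if focal_all:
        if f_other == 1.0 and f_out == 0.0:
            return 1
        if f_other == 1.0 and under5(f_out):
            return 2
        if over90(f_ingroup) and under5(f_out):
            return 3
    elif focal_none:
        if f_other == 1.0 and f_out == 0.0:
            return 4
        if over90(f_other) and f_out == 0.0:
            return 5
        if over90(f_other) and under5(f_out):
            return 6
    return None


def classify_matrix(
    matrix: pd.DataFrame,
    groups: TaxonGroups,
    strict: bool = True,
) -> tuple[pd.Series, dict]:
    """Row-wise classification of a families x taxa boolean matrix.

    Returns the per-family category series (None -> pandas NA) and a
    summary histogram over categories 1-6 plus "none".
    """
    if matrix.index.duplicated().any() or matrix.columns.duplicated().any():
        raise ValueError("duplicate family or taxon ids")
    cats = {}
    for fam in matrix.index:
        row = matrix.loc[fam].astype(bool).to_dict()
        cats[fam] = classify_family(row, groups, strict=strict)
    series = pd.Series(cats, name="category", dtype="object")
    hist = {str(c): 0 for c in (1, 2, 3, 4, 5, 6)}
    hist["none"] = 0
    for v in cats.values():
        hist[str(v) if v is not None else "none"] += 1
    return series, hist


def read_presence_matrix(path) -> pd.DataFrame:
    """Read a families x taxa 0/1 TSV into a boolean DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int).astype(bool)


def read_taxon_groups(path) -> TaxonGroups:
    """Read a taxon -> group TSV (groups: focal, other_ingroup, outgroup)."""
    focal, other, out = [], [], []
    bucket = {"focal": focal, "other_ingroup": other, "outgroup": out}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, group = line.split("\t")[:2]
            if group not in bucket:
                raise ValueError(f"unknown group {group!r} for taxon {taxon!r}")
            bucket[group].append(taxon)
    return TaxonGroups(focal, other, out)
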