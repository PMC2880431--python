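"""Familial relative risk attributable to a common susceptibility locus.

A biallelic locus with risk-allele frequency ``p`` (Hardy-Weinberg genotype
frequencies q^2, 2pq, p^2 for 0, 1, 2 copies) and genotypic relative risks
(1, r1, r2) induces a correlation in risk between relatives through shared
alleles. The familial relative risk attributable to the locus for a
first-degree pair is

    lambda* = E[risk(proband) * risk(relative)] / E[risk]^2

with the pair's joint genotype distribution given by Mendelian
transmission: an offspring receives one allele drawn from the parent's two
and one from the population (``kinship='offspring'``), while siblings each
receive one allele from each of two shared parents (``kinship='sibling'``).
lambda* >= 1 for any positive risks, with equality iff r1 = r2 = 1.

The locus's share of an observed familial relative risk lambda0 is
100 * log(lambda*) / log(lambda0) under a multiplicative joint-effect model
across loci, or 100 * (lambda* - 1) / (lambda0 - 1) under an additive one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


class LocusError(ValueError):
    """Invalid locus parameters."""


def _check_inputs(p: float, r1: float, r2: float) -> None:
    if not 0 < p < 1:
        raise LocusError(f"allele frequency must be in (0,1), got {p}")
    if r1 <= 0 or r2 <= 0:
        raise LocusError(f"genotypic relative risks must be positive, "
                         f"got r1={r1}, r2={r2}")


def _hwe(p: float) -> np.ndarray:
    q = 1 - p
    return np.array([q * q, 2 * p * q, p * p])


def offspring_joint(p: float) -> np.ndarray:
    """Joint genotype distribution P(parent=i, offspring=j), 3x3.

    The offspring inherits one allele transmitted by the parent (risk
    allele with probability i/2 for parent genotype i) and one population
    allele (risk allele with probability p).
    """
    q = 1 - p
    g = _hwe(p)
    t = np.array([0.0, 0.5, 1.0])  # P(transmit risk allele | parent genotype)
    J = np.empty((3, 3))
    for i in range(3):
        J[i] = g[i] * np.array([(1 - t[i]) * q,
                                t[i] * q + (1 - t[i]) * p,
                                t[i] * p])
    return J


def sibling_joint(p: float) -> np.ndarray:
    """Joint genotype distribution of two full siblings, 3x3.

    Both children draw one allele from each of the same two Hardy-Weinberg
    parents, independently given the parents.
    """
    g = _hwe(p)
    t = np.array([0.0, 0.5, 1.0])
    J = np.zeros((3, 3))
    for gm in range(3):
        for gf in range(3):
            pm, pf = t[gm], t[gf]
            # child genotype distribution given parents
            child = np.array([(1 - pm) * (1 - pf),
                              pm * (1 - pf) + (1 - pm) * pf,
                              pm * pf])
            J += g[gm] * g[gf] * np.outer(child, child)
    return J


_JOINTS = {"offspring": offspring_joint, "sibling": sibling_joint}


@dataclass(frozen=True)
class LocusFRR:
    """First-degree familial relative risk attributable to one locus."""

    lambda_star: float
    kinship: str = "offspring"

    def __float__(self) -> float:
        return self.lambda_star


def locus_frr(p: float, r1: float, r2: float,
              kinship: str = "offspring") -> LocusFRR:
    """lambda* for a biallelic locus and a first-degree kinship.

    Reduces to exactly 1 for a null locus (r1 = r2 = 1) and exceeds 1 for
    any other positive risks, including protective alleles.
    """
    _check_inputs(p, r1, r2)
    try:
        J = _JOINTS[kinship](p)
    except KeyError:
        raise LocusError(f"unknown kinship {kinship!r}; "
                         f"choose from {sorted(_JOINTS)}") from None
    r = np.array([1.0, r1, r2])
    mu = _hwe(p) @ r
    return LocusFRR(float(r @ J @ r / mu ** 2), kinship)


def pct_frr_multiplicative(lambda_star: float, lambda0: float) -> float:
    """Percent of log(lambda0) explained: 100 * ln(lambda*) / ln(lambda0)."""
    lambda_star = float(lambda_star)
    if lambda0 <= 1:
        raise LocusError(f"lambda0 must exceed 1, got {lambda0}")
    if lambda_star < 1 - 1e-9:
        raise LocusError(f"lambda* must be >= 1, got {lambda_star}")
    return 100.0 * math.log(max(lambda_star, 1.0)) / math.log(lambda0)


def pct_frr_additive(lambda_star: float, lambda0: float) -> float:
    """Percent of the excess FRR explained: 100 * (l*-1) / (lambda0-1)."""
    lambda_star = float(lambda_star)
    if lambda0 <= 1:
        raise LocusError(f"lambda0 must exceed 1, got {lambda0}")
    if lambda_star < 1 - 1e-9:
        raise LocusError(f"lambda* must be >= 1, got {lambda_star}")
    return 100.0 * (max(lambda_star, 1.0) - 1.0) / (lambda0 - 1.0)


# -- locus tables ----------------------------------------------------------


@dataclass(frozen=True)
class LocusSpec:
    """One susceptibility locus: listed-allele frequency and per-subtype
    heterozygote/rare-homozygote relative risks.

    ``p`` is the frequency of the listed allele as published, whether or
    not it is the minor one; no reordering is applied. ``risks`` maps a
    subtype label to an (r1, r2) pair.
    """

    name: str
    rsid: str
    p: float
    risks: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for subtype, (r1, r2) in self.risks.items():
            _check_inputs(self.p, r1, r2)


@dataclass(frozen=True)
class AttributionResult:
    """Percent contributions of one locus (or panel) to a subtype FRR."""

    pct_multiplicative: float
    pct_additive: float
    lambda0: float


def attribute(lambda_star: float, lambda0: float) -> AttributionResult:
    return AttributionResult(pct_frr_multiplicative(lambda_star, lambda0),
                             pct_frr_additive(lambda_star, lambda0),
                             lambda0)


_SUBTYPE_COLS = {"ER-negative": ("r1_erneg", "r2_erneg"),
                 "ER-positive": ("r1_erpos", "r2_erpos")}


def read_locus_table(path=None) -> list[LocusSpec]:
    """Read a locus CSV (``name,rsid,maf,r1_erneg,r2_erneg,r1_erpos,r2_erpos``).

    With no path, loads the packaged table of the 12 published breast-cancer
    susceptibility loci with ER-subtype-specific odds ratios.
    """
    if path is None:
        path = resources.files("famsubtype.data") / "susceptibility_loci.csv"
    df = pd.read_csv(path)
    needed = ["name", "rsid", "maf"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise LocusError(f"locus CSV missing columns {missing}")
    specs = []
    for row in df.itertuples():
        risks = {}
        for subtype, (c1, c2) in _SUBTYPE_COLS.items():
            if c1 in df.columns and c2 in df.columns:
                r1 = getattr(row, c1)
                r2 = getattr(row, c2)
                if pd.notna(r1) and pd.notna(r2):
                    risks[subtype] = (float(r1), float(r2))
        specs.append(LocusSpec(row.name, row.rsid, float(row.maf), risks))
    return specs


def build_locus_table(specs: Iterable[LocusSpec],
                      lambda0_by_subtype: Mapping[str, float],
                      kinship: str = "offspring") -> pd.DataFrame:
    """Per-locus lambda* and percent-FRR table with total rows.

    One row per locus with, per subtype, ``lambda_<s>``, ``pct_mult_<s>``
    and ``pct_add_<s>`` columns; loci missing a subtype's risks are skipped
    for that subtype (NaN). Two total rows follow: ``TOTAL_multiplicative``
    sums the per-locus multiplicative percentages (and carries the
    compounded product of the lambda* values in the lambda columns);
    ``TOTAL_additive`` sums the additive percentages.
    """
    subtypes = list(lambda0_by_subtype)
    rows = []
    for spec in specs:
        row = {"name": spec.name, "rsid": spec.rsid, "maf": spec.p}
        for s in subtypes:
            if s not in spec.risks:
                row[f"lambda_{s}"] = np.nan
                row[f"pct_mult_{s}"] = np.nan
                row[f"pct_add_{s}"] = np.nan
                continue
            r1, r2 = spec.risks[s]
            lam = locus_frr(spec.p, r1, r2, kinship).lambda_star
            row[f"lambda_{s}"] = lam
            row[f"pct_mult_{s}"] = pct_frr_multiplicative(
                lam, lambda0_by_subtype[s])
            row[f"pct_add_{s}"] = pct_frr_additive(lam, lambda0_by_subtype[s])
        rows.append(row)
    df = pd.DataFrame(rows)
    tot_m = {"name": "TOTAL_multiplicative", "rsid": "", "maf": np.nan}
    tot_a = {"name": "TOTAL_additive", "rsid": "", "maf": np.nan}
    for s in subtypes:
        if rows:
            tot_m[f"lambda_{s}"] = float(np.nanprod(df[f"lambda_{s}"]))
            tot_m[f"pct_mult_{s}"] = float(np.nansum(df[f"pct_mult_{s}"]))
            tot_a[f"pct_add_{s}"] = float(np.nansum(df[f"pct_add_{s}"]))
        else:
            tot_m[f"lambda_{s}"] = np.nan
            tot_m[f"pct_mult_{s}"] = 0.0
            tot_a[f"pct_add_{s}"] = 0.0
    return pd.concat([df, pd.DataFrame([tot_m, tot_a])], ignore_index=True)
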