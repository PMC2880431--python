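"""Single-locus Mendelian major-gene model of familial relative risk.

A rare dominant deleterious allele (frequency f, carriers = one or two
copies) confers genotype-specific, age-specific breast-cancer hazards that
may differ by tumour subtype. The age-specific familial relative risk to a
first-degree relative of a proband diagnosed with subtype s is the
likelihood ratio

    FRR(t) = P(relative affected by age t | proband affected with s)
             / P(woman affected by age t)

with the numerator summed over the exact biallelic parent-offspring (or
sibling) joint genotype distribution collapsed to carrier status -- no
rare-allele approximation. The overall FRR averages FRR(t) over relative
ages 20-70 weighted by the age distribution of breast-cancer cases, and
the gene's share of an observed familial relative risk lambda0 is
100 * log(FRR) / log(lambda0).

The subtype-specific variant restricts both the proband's and the
relative's disease to subtype s (concordance in pathology arising only
through genotype), with the population risk of subtype s as denominator.

This is deliberately a one-gene-at-a-time reduced model: no polygenic
background, no multi-gene composition, no pedigree structures beyond a
single first-degree pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from .locus_contribution import offspring_joint, sibling_joint
from .reference_rates import AgeWeights, normalize_weights

CARRIER, NONCARRIER = "carrier", "noncarrier"


class MajorGeneError(ValueError):
    """Invalid major-gene specification or query."""


@dataclass(frozen=True)
class PenetranceCurve:
    """Yearly subtype-specific hazards for one genotype.

    ``hazards[s][i]`` is the probability of a first breast cancer of
    subtype ``s`` during the year ``[ages[i], ages[i]+1)`` given disease
    free at its start. Cumulative incidence uses the discrete product
    ``1 - prod(1 - h_total)``; the subtype-specific cumulative incidences
    (survival-weighted sums of subtype hazards) add up exactly to the
    overall one.
    """

    ages: np.ndarray
    hazards: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(
            self, "hazards",
            {s: np.asarray(h, dtype=float) for s, h in self.hazards.items()})
        if np.any(np.diff(ages) != 1.0):
            raise MajorGeneError("age grid must be yearly and increasing")
        for s, h in self.hazards.items():
            if h.shape != ages.shape:
                raise MajorGeneError(f"hazard array for {s!r} does not match "
                                     "the age grid")
            if np.any(h < 0):
                raise MajorGeneError(f"negative hazard for subtype {s!r}")
        if np.any(self.total_hazard > 1):
            raise MajorGeneError("total yearly hazard exceeds 1")

    @property
    def subtypes(self) -> tuple[str, ...]:
        return tuple(self.hazards)

    @property
    def total_hazard(self) -> np.ndarray:
        return np.sum(list(self.hazards.values()), axis=0)

    @property
    def grid(self) -> np.ndarray:
        """Boundary ages at which cumulative incidence is evaluated."""
        return np.append(self.ages, self.ages[-1] + 1.0)

    def _survival(self) -> np.ndarray:
        """Disease-free probability at each boundary age."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.total_hazard)])

    def cumulative_incidence(self, subtype: Optional[str] = None
                             ) -> np.ndarray:
        """Cumulative incidence at each boundary age (starts at 0)."""
        S = self._survival()
        if subtype is None:
            return 1.0 - S
        inc = S[:-1] * self.hazards[subtype]
        return np.concatenate([[0.0], np.cumsum(inc)])

    def incidence(self, subtype: Optional[str] = None) -> np.ndarray:
        """Yearly probability of diagnosis in each age year."""
        S = self._survival()[:-1]
        h = self.total_hazard if subtype is None else self.hazards[subtype]
        return S * h

    def prob_by(self, t: float, subtype: Optional[str] = None) -> float:
        """Cumulative (subtype-restricted) risk by exact age ``t``."""
        grid = self.grid
        if not grid[0] <= t <= grid[-1]:
            raise MajorGeneError(
                f"age {t} outside penetrance grid [{grid[0]}, {grid[-1]}]")
        return float(np.interp(t, grid, self.cumulative_incidence(subtype)))


@dataclass(frozen=True)
class MajorGeneSpec:
    """Dominant single-locus model: allele frequency plus penetrance per
    carrier status."""

    allele_frequency: float
    penetrance: Mapping[str, PenetranceCurve]

    def __post_init__(self) -> None:
        f = self.allele_frequency
        if not 0 < f <= 0.05:
            raise MajorGeneError(
                f"deleterious-allele frequency must be in (0, 0.05], got {f}")
        if set(self.penetrance) != {CARRIER, NONCARRIER}:
            raise MajorGeneError(
                "penetrance must be given for exactly 'carrier' and "
                "'noncarrier'")
        c, n = self.penetrance[CARRIER], self.penetrance[NONCARRIER]
        if not np.array_equal(c.ages, n.ages):
            raise MajorGeneError("carrier and noncarrier age grids differ")
        if set(c.subtypes) != set(n.subtypes):
            raise MajorGeneError("carrier and noncarrier subtype sets differ")

    @property
    def carrier_frequency(self) -> float:
        f = self.allele_frequency
        return 2 * f * (1 - f) + f * f

    @property
    def subtypes(self) -> tuple[str, ...]:
        return self.penetrance[CARRIER].subtypes

    @property
    def ages(self) -> np.ndarray:
        return self.penetrance[CARRIER].ages

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "MajorGeneSpec":
        """Build from a config mapping.

        Expected keys: ``allele_frequency``; ``age_range: [lo, hi]``
        (yearly grid, hi inclusive); ``hazards: {genotype: {subtype:
        spec}}`` where each hazard spec is either a yearly list matching
        the grid or a list of ``[age_lo, age_hi, value]`` bands (half-open,
        covering the grid; uncovered years get 0).
        """
        lo, hi = d["age_range"]
        ages = np.arange(float(lo), float(hi) + 1.0)
        pen = {}
        for genotype, by_subtype in d["hazards"].items():
            hazards = {}
            for subtype, spec in by_subtype.items():
                spec = list(spec)
                if spec and isinstance(spec[0], (list, tuple)):
                    h = np.zeros_like(ages)
                    for a0, a1, v in spec:
                        h[(ages >= a0) & (ages < a1)] = v
                else:
                    h = np.asarray(spec, dtype=float)
                hazards[subtype] = h
            pen[genotype] = PenetranceCurve(ages, hazards)
        return cls(float(d["allele_frequency"]), pen)

    @classmethod
    def from_yaml(cls, path) -> "MajorGeneSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def genotype_joint(spec: MajorGeneSpec | float,
                   kinship: str = "offspring") -> np.ndarray:
    """Joint carrier-status distribution for (proband, relative), 2x2.

    Rows index the proband, columns the relative, order (noncarrier,
    carrier). Built by collapsing the exact biallelic joint genotype
    distribution; marginals equal the Hardy-Weinberg carrier frequency.
    ``kinship='first_degree'`` is an alias for offspring (parent-offspring
    and the analysis treats mothers and daughters symmetrically).
    """
    f = spec.allele_frequency if isinstance(spec, MajorGeneSpec) else float(spec)
    if kinship == "first_degree":
        kinship = "offspring"
    J3 = {"offspring": offspring_joint,
          "sibling": sibling_joint}[kinship](f)
    # collapse genotype (allele copies 0/1/2) to carrier status (0 copies vs >=1)
    out = np.empty((2, 2))
    out[0, 0] = J3[0, 0]
    out[0, 1] = J3[0, 1:].sum()
    out[1, 0] = J3[1:, 0].sum()
    out[1, 1] = J3[1:, 1:].sum()
    return out


def prob_affected_by(spec: MajorGeneSpec, genotype: str, t: float,
                     subtype: Optional[str] = None) -> float:
    """Cumulative (subtype-restricted) risk by age t for a carrier status."""
    return spec.penetrance[genotype].prob_by(t, subtype)


def _proband_likelihood(spec: MajorGeneSpec, subtype: Optional[str],
                        case_weights: Optional[AgeWeights],
                        diagnosis_age: Optional[float]) -> np.ndarray:
    """P(proband diagnosed with her subtype | carrier status), order
    (noncarrier, carrier).

    Averages the yearly (subtype-restricted) incidence over the case-age
    distribution, or uses the incidence in the year of a fixed diagnosis
    age.
    """
    like = np.empty(2)
    for k, g in enumerate((NONCARRIER, CARRIER)):
        curve = spec.penetrance[g]
        inc = curve.incidence(subtype)
        if diagnosis_age is not None:
            i = int(np.searchsorted(curve.ages, diagnosis_age, side="right")) - 1
            if i < 0 or i >= len(curve.ages):
                raise MajorGeneError(
                    f"diagnosis age {diagnosis_age} outside penetrance grid")
            like[k] = inc[i]
        else:
            if case_weights is None:
                raise MajorGeneError(
                    "either case_weights or diagnosis_age is required")
            w = np.interp(case_weights.ages, curve.ages, inc,
                          left=0.0, right=0.0)
            like[k] = float(case_weights.weights @ w)
    if like.sum() <= 0:
        raise MajorGeneError(
            f"proband subtype {subtype!r} has zero probability under the model")
    return like


def _marginal(spec: MajorGeneSpec) -> np.ndarray:
    fc = spec.carrier_frequency
    return np.array([1 - fc, fc])


def age_specific_frr(spec: MajorGeneSpec, proband_subtype: Optional[str],
                     t: float,
                     case_weights: Optional[AgeWeights] = None,
                     diagnosis_age: Optional[float] = None,
                     kinship: str = "first_degree",
                     relative_subtype: Optional[str] = None) -> float:
    """FRR(t): relative's risk by age t given the proband's diagnosis,
    relative to the population risk by age t.

    ``proband_subtype=None`` conditions on a diagnosis of any subtype;
    ``relative_subtype`` restricts the relative's outcome (used by the
    subtype-specific FRR). Raises when the population risk by ``t`` is
    still zero.
    """
    J = genotype_joint(spec, kinship)
    L = _proband_likelihood(spec, proband_subtype, case_weights, diagnosis_age)
    F = np.array([prob_affected_by(spec, g, t, relative_subtype)
                  for g in (NONCARRIER, CARRIER)])
    marg = _marginal(spec)
    den = float(marg @ F)
    if den <= 0:
        raise MajorGeneError(f"population risk by age {t} is zero")
    num = float(L @ J @ F) / float(L @ marg)
    return num / den


def overall_frr(spec: MajorGeneSpec, proband_subtype: Optional[str],
                weights: AgeWeights,
                case_weights: Optional[AgeWeights] = None,
                diagnosis_age: Optional[float] = None,
                kinship: str = "first_degree",
                relative_subtype: Optional[str] = None) -> float:
    """Weighted average of FRR(t) over the relative's attained ages.

    ``weights`` is the case-age distribution over (conventionally) ages
    20-70. Ages at which the population risk is still zero carry no
    information and are dropped, with the weights renormalized.
    """
    weights = normalize_weights(weights)
    marg = _marginal(spec)
    vals, ws = [], []
    for a, w in zip(weights.ages, weights.weights):
        if w == 0:
            continue
        F = np.array([prob_affected_by(spec, g, a)
                      for g in (NONCARRIER, CARRIER)])
        if float(marg @ F) <= 0 and relative_subtype is None:
            continue
        vals.append(age_specific_frr(
            spec, proband_subtype, a, case_weights=case_weights,
            diagnosis_age=diagnosis_age, kinship=kinship,
            relative_subtype=relative_subtype))
        ws.append(w)
    if not ws:
        raise MajorGeneError("no ages with positive weight and risk")
    ws = np.array(ws) / np.sum(ws)
    return float(ws @ np.array(vals))


def gene_pct_frr(frr_gene: float, lambda0: float) -> float:
    """Percent of log(lambda0) attributed to the gene."""
    if lambda0 <= 1:
        raise MajorGeneError(f"lambda0 must exceed 1, got {lambda0}")
    if frr_gene < 1 - 1e-9:
        raise MajorGeneError(f"gene FRR must be >= 1, got {frr_gene}")
    return 100.0 * math.log(max(frr_gene, 1.0)) / math.log(lambda0)


def subtype_specific_frr(spec: MajorGeneSpec, subtype: str,
                         weights: AgeWeights,
                         case_weights: Optional[AgeWeights] = None,
                         diagnosis_age: Optional[float] = None,
                         kinship: str = "first_degree") -> float:
    """FRR when both the proband's and the relative's disease are of
    subtype ``subtype``, against the population risk of that subtype.

    With a genotype-independent subtype mix this collapses to the
    any-subtype FRR; with carrier-enriched subtypes it exceeds it.
    """
    if subtype not in spec.subtypes:
        raise MajorGeneError(f"unknown subtype {subtype!r}")
    weights = normalize_weights(weights)
    marg = _marginal(spec)
    vals, ws = [], []
    for a, w in zip(weights.ages, weights.weights):
        if w == 0:
            continue
        F = np.array([prob_affected_by(spec, g, a, subtype)
                      for g in (NONCARRIER, CARRIER)])
        if float(marg @ F) <= 0:
            continue
        vals.append(age_specific_frr(
            spec, subtype, a, case_weights=case_weights,
            diagnosis_age=diagnosis_age, kinship=kinship,
            relative_subtype=subtype))
        ws.append(w)
    if not ws:
        raise MajorGeneError(f"subtype {subtype!r} has zero population risk")
    ws = np.array(ws) / np.sum(ws)
    return float(ws @ np.array(vals))


# -- demonstration parameterization ----------------------------------------


def demo_gene_spec(allele_frequency: float = 0.0006,
                   carrier_rr_young: float = 15.0,
                   carrier_rr_old: float = 6.0,
                   carrier_erneg_frac: float = 0.7,
                   noncarrier_erneg_frac: float = 0.2,
                   age_range: tuple[float, float] = (20.0, 85.0)
                   ) -> MajorGeneSpec:
    """An illustrative high-penetrance dominant gene.

    The defaults sketch a rare allele whose carriers face a 15-fold hazard
    before age 50 and 6-fold after, with tumours strongly shifted toward
    ER-negative disease -- published-order-of-magnitude values for a
    BRCA1-like gene, intended for demonstrations and tests, not a
    reproduction of any published penetrance analysis.
    """
    lo, hi = age_range
    ages = np.arange(lo, hi + 1.0)
    base = 2.5e-3 / (1.0 + np.exp(-(ages - 55.0) / 8.0))
    base[ages < 20] = 0.0
    rr = np.where(ages < 50.0, carrier_rr_young, carrier_rr_old)
    pen = {
        NONCARRIER: PenetranceCurve(ages, {
            "ER-negative": base * noncarrier_erneg_frac,
            "ER-positive": base * (1 - noncarrier_erneg_frac),
        }),
        CARRIER: PenetranceCurve(ages, {
            "ER-negative": base * rr * carrier_erneg_frac,
            "ER-positive": base * rr * (1 - carrier_erneg_frac),
        }),
    }
    return MajorGeneSpec(allele_frequency, pen)
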