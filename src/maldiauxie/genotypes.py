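"""Genotype and condition scenarios for the MAL regulon model.

Genetic perturbations map onto multiplicative parameter changes:

* ``ima1Δ`` — losing the dominant isomaltase gene cuts pooled *IMA*
  expression sharply (transcript levels of *IMA1* run about five-fold
  above *IMA5*'s and the enzymes have similar kinetics), so ``u_I_max``
  is scaled by 1/6 by default; ``ima5Δ`` by the milder 5/6.
* ``gal80Δ`` — constitutively active Gal4 keeps the *MAL11* promoter
  repressed, so ``K_T`` sits at its galactose-elevated value whether or
  not galactose is present.
* ``MAL11-OE`` — a strong constitutive promoter on the transporter raises
  the basal expression ``b_T``.
* extracellular galactose multiplies ``K_T`` by ``lambda_gal`` (an
  unmodelled GAL-induced repressor competing at the *MAL11* promoter).

Scenario predictions call the ON/OFF classification from the low branch
(cells start uninduced).  A parameter set in the unbounded regime — where
import outruns the isomaltase capacity for every palatinose level — is
reported as ON by runaway induction: ``p`` certainly exceeds ``K_T``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .regulon import ON, UNBOUNDED, Classification, RegulonParams, classify_regulon

__all__ = [
    "GenotypeSpec",
    "GenotypeFactors",
    "DEFAULT_FACTORS",
    "GENOTYPES",
    "apply_galactose",
    "genotype_params",
    "predict_scenario",
    "predict_scenarios",
]


@dataclass(frozen=True)
class GenotypeFactors:
    """Configurable effect sizes of the genetic perturbations."""

    ima1_u_I: float = 1.0 / 6.0  # five-fold IMA1:IMA5 transcript ratio, equal kinetics
    ima5_u_I: float = 5.0 / 6.0
    mal11_oe_b_T: float = 40.0  # strong constitutive promoter on MAL11
    lambda_gal: float = 3.0  # galactose-driven K_T elevation

    def __post_init__(self) -> None:
        if not (0 < self.ima1_u_I <= 1 and 0 < self.ima5_u_I <= 1):
            raise ValueError("isomaltase deletion factors must be in (0, 1]")
        if self.mal11_oe_b_T <= 1:
            raise ValueError("MAL11-OE must raise b_T (factor > 1)")
        if self.lambda_gal <= 1:
            raise ValueError("lambda_gal must exceed 1")


DEFAULT_FACTORS = GenotypeFactors()

#: Canonical genotype names (ASCII aliases accepted by :func:`genotype_params`).
GENOTYPES = ("WT", "gal80Δ", "ima1Δ", "ima5Δ", "MAL11-OE", "gal80Δ·ima1Δ")

_ALIASES = {
    "wt": "WT",
    "gal80d": "gal80Δ",
    "gal80δ": "gal80Δ",
    "ima1d": "ima1Δ",
    "ima1δ": "ima1Δ",
    "ima5d": "ima5Δ",
    "ima5δ": "ima5Δ",
    "mal11-oe": "MAL11-OE",
    "mal11oe": "MAL11-OE",
    "gal80d_ima1d": "gal80Δ·ima1Δ",
    "gal80δ·ima1δ": "gal80Δ·ima1Δ",
    "gal80d ima1d": "gal80Δ·ima1Δ",
}


def _canonical(name: str) -> str:
    key = name.strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(f"unknown genotype {name!r}; known: {', '.join(GENOTYPES)}")


@dataclass(frozen=True)
class GenotypeSpec:
    """A genotype together with its growth condition (palatinose is always
    present; ``galactose`` says whether galactose is too)."""

    name: str
    galactose: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "name", _canonical(self.name))


def apply_galactose(
    params: RegulonParams, galactose_present: bool, lambda_gal: float = DEFAULT_FACTORS.lambda_gal
) -> RegulonParams:
    """Elevate K_T by the factor ``lambda_gal`` when galactose is present."""
    if lambda_gal <= 1:
        raise ValueError("lambda_gal must exceed 1")
    if not galactose_present:
        return params
    return params.replace(K_T=params.K_T * lambda_gal)


def genotype_params(
    spec: GenotypeSpec,
    base: RegulonParams,
    factors: GenotypeFactors = DEFAULT_FACTORS,
) -> RegulonParams:
    """Deterministic parameter set for a genotype in its condition."""
    params = base
    name = spec.name
    if "ima1Δ" in name:
        params = params.replace(u_I_max=params.u_I_max * factors.ima1_u_I)
    if "ima5Δ" in name:
        params = params.replace(u_I_max=params.u_I_max * factors.ima5_u_I)
    if name == "MAL11-OE":
        params = params.replace(b_T=params.b_T * factors.mal11_oe_b_T)
    if "gal80Δ" in name:
        # constitutively active Gal4: K_T pinned at its elevated value
        params = apply_galactose(params, True, factors.lambda_gal)
    else:
        params = apply_galactose(params, spec.galactose, factors.lambda_gal)
    return params


def predict_scenario(
    spec: GenotypeSpec,
    base: RegulonParams,
    factors: GenotypeFactors = DEFAULT_FACTORS,
) -> dict:
    """Classify one genotype/condition and report the attained phenotype."""
    params = genotype_params(spec, base, factors)
    cls: Classification = classify_regulon(params, from_low=True)
    runaway = cls.label == UNBOUNDED
    attained = ON if runaway else cls.attained
    return {
        "genotype": spec.name,
        "galactose": spec.galactose,
        "label": cls.label,
        "attained": attained,
        "on": attained == ON,
        "runaway": runaway,
        "p_over_KT": cls.p_over_KT,
        "K_T": params.K_T,
        "ratio": params.ratio,
    }


#: The scenario panel matching the experiments: each (genotype, +/-galactose)
DEFAULT_SCENARIOS = (
    GenotypeSpec("WT", galactose=True),
    GenotypeSpec("WT", galactose=False),
    GenotypeSpec("ima1Δ", galactose=True),
    GenotypeSpec("ima5Δ", galactose=True),
    GenotypeSpec("MAL11-OE", galactose=True),
    GenotypeSpec("gal80Δ", galactose=True),
    GenotypeSpec("gal80Δ", galactose=False),
    GenotypeSpec("gal80Δ·ima1Δ", galactose=True),
)


def predict_scenarios(
    base: RegulonParams,
    scenarios: tuple[GenotypeSpec, ...] = DEFAULT_SCENARIOS,
    factors: GenotypeFactors = DEFAULT_FACTORS,
) -> pd.DataFrame:
    """Phenotype table over the scenario panel (one row per scenario)."""
    return pd.DataFrame([predict_scenario(s, base, factors) for s in scenarios])
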