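"""Synthetic F2 intercross generator and fixture simulators.

Emulates the study design the association machinery assumes: two founder
lines (a slow-growing local breed crossed with a commercial broiler line)
produce F1 hybrids; seven F1 sires are each mated to up to nine F1 dams, and
their offspring form an F2 population of ~783 birds of both sexes in two
hatches.  Phenotypes follow the same fixed-effect model the analysis fits:

    y = mu + a*x_a + d*x_d + sex + hatch + family + [b*(W - Wbar)] + e

with Falconer genotypic values: additive code x_a (II/ID/DD = +1/0/-1) and
heterozygote indicator x_d (II/ID/DD = 0/1/0), so the three genotype means
are mu+a, mu+d and mu-a and d is the heterozygote's deviation from the
homozygote midpoint.  The
slaughter-weight covariate term enters only for traits analysed under
Model II (body-size traits), and slaughter weight W is itself generated with
a genotype effect so that the covariate is realistically collinear with
genotype.

Everything is driven by one integer seed; the same :class:`SimConfig` always
reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypePanel, ValidationError
from .association import ADDITIVE_CODE
from .traits import model_for_trait

__all__ = ["SimConfig", "F2Cross", "simulate_cross", "simulate_phenos",
           "simulate_panel", "simulate_ct"]

_GT_FROM_ALLELES = {0: "DD", 1: "ID", 2: "II"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic F2 cross and its trait model.

    Frequencies are for the insertion (I) allele per founder line.  Trait
    units are grams throughout the defaults, scaled to an 84-day body/carcass
    weight around 1200 g; effect sizes default to the magnitude seen in
    carcass-weight association tables (a ~ 15 g, d ~ -5 g) with a residual
    standard deviation of 170 g.
    """

    seed: int = 0
    n_f2: int = 783
    n_families: int = 7
    max_dams_per_sire: int = 9
    founder_freq_I: tuple[float, float] = (0.68, 0.85)  # (local line, broiler line)
    family_sizes: tuple[int, ...] | None = None  # defaults to near-equal split
    # trait model (units: g)
    mu: float = 1200.0
    a: float = 15.0
    d: float = -5.0
    b: float = 0.35
    sex_effect: float = 120.0
    hatch_effect: float = 20.0
    family_sd: float = 30.0
    resid_sd: float = 170.0
    # slaughter weight generation (the Model II covariate)
    w_mu: float = 1200.0
    w_a: float = 15.0
    w_d: float = -5.0
    w_resid_sd: float = 170.0

    def __post_init__(self) -> None:
        for name in ("family_sd", "resid_sd", "w_resid_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for f in self.founder_freq_I:
            if not 0.0 <= f <= 1.0:
                raise ValidationError("founder allele frequencies must be in [0, 1]")
        if self.family_sizes is not None:
            if len(self.family_sizes) != self.n_families:
                raise ValidationError(
                    f"family_sizes has {len(self.family_sizes)} entries "
                    f"for n_families={self.n_families}"
                )
            if sum(self.family_sizes) != self.n_f2:
                raise ValidationError(
                    f"family_sizes sum to {sum(self.family_sizes)}, not n_f2={self.n_f2}"
                )

    def resolved_family_sizes(self) -> list[int]:
        if self.family_sizes is not None:
            return list(self.family_sizes)
        base, extra = divmod(self.n_f2, self.n_families)
        return [base + (1 if i < extra else 0) for i in range(self.n_families)]


@dataclass
class F2Cross:
    """Pedigree and genotypes of one simulated F2 population."""

    pedigree: pd.DataFrame  # individual_id, sire_id, dam_id, family, sex, hatch
    genotypes: pd.DataFrame  # individual_id, population, genotype

    def frame(self) -> pd.DataFrame:
        """Pedigree merged with genotype calls."""
        return self.pedigree.merge(self.genotypes[["individual_id", "genotype"]],
                                   on="individual_id")


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _draw_f1(rng: np.random.Generator, n: int, freq_a: float, freq_b: float
             ) -> np.ndarray:
    """F1 allele pairs: one allele from each founder line (columns = alleles,
    1 = insertion)."""
    return np.column_stack([
        rng.random(n) < freq_a,
        rng.random(n) < freq_b,
    ]).astype(np.int8)


def simulate_cross(config: SimConfig) -> F2Cross:
    """Simulate the two-line F2 intercross.

    F1 sires and dams each carry one allele drawn from each founder line's
    frequency; every F2 offspring receives one uniformly chosen allele from
    its sire and one from its randomly assigned dam within the family.
    Sex and hatch are assigned 50/50 at random.
    """
    rng = _rng(config, 0)
    sizes = config.resolved_family_sizes()
    f_local, f_broiler = config.founder_freq_I
    sires = _draw_f1(rng, config.n_families, f_local, f_broiler)
    dams = _draw_f1(rng, config.n_families * config.max_dams_per_sire,
                    f_local, f_broiler)

    rows = []
    idx = 0
    for fam in range(config.n_families):
        fam_dams = np.arange(fam * config.max_dams_per_sire,
                             (fam + 1) * config.max_dams_per_sire)
        for _ in range(sizes[fam]):
            dam = rng.choice(fam_dams)
            allele_s = sires[fam, rng.integers(2)]
            allele_d = dams[dam, rng.integers(2)]
            rows.append((
                f"F2_{idx:04d}", f"sire{fam + 1}", f"dam{dam + 1}",
                f"fam{fam + 1}", int(allele_s) + int(allele_d),
            ))
            idx += 1
    df = pd.DataFrame(rows, columns=["individual_id", "sire_id", "dam_id",
                                     "family", "n_I"])
    df["sex"] = np.where(rng.random(len(df)) < 0.5, "male", "female")
    df["hatch"] = np.where(rng.random(len(df)) < 0.5, "1", "2")
    genotypes = pd.DataFrame({
        "individual_id": df["individual_id"],
        "population": "F2",
        "genotype": df["n_I"].map(_GT_FROM_ALLELES),
    })
    pedigree = df[["individual_id", "sire_id", "dam_id", "family", "sex", "hatch"]]
    return F2Cross(pedigree=pedigree, genotypes=genotypes)


def simulate_phenos(cross: F2Cross, config: SimConfig,
                    traits: list[str]) -> pd.DataFrame:
    """Generate a phenotype table for a simulated cross.

    Every requested trait shares the configured effect sizes but has its own
    independently drawn family effects and residuals.  Slaughter weight is
    always generated (it is a phenotype of its own); the ``b*(W - Wbar)``
    term is added only to traits whose analysis policy is Model II.
    """
    if not traits:
        raise ValidationError("trait list is empty")
    rng = _rng(config, 1)
    frame = cross.frame()
    n = len(frame)
    x_a = frame["genotype"].map(ADDITIVE_CODE).to_numpy(dtype=float)
    x_d = (frame["genotype"] == "ID").to_numpy(dtype=float)
    sex = (frame["sex"] == "male").to_numpy(dtype=float)
    hatch = (frame["hatch"] == "2").to_numpy(dtype=float)
    fam_codes, fam_levels = pd.factorize(frame["family"])

    def factor_part(fam_effects: np.ndarray) -> np.ndarray:
        return (config.sex_effect * sex + config.hatch_effect * hatch
                + fam_effects[fam_codes])

    w_fam = rng.normal(0.0, config.family_sd, len(fam_levels))
    w = (config.w_mu + config.w_a * x_a + config.w_d * x_d + factor_part(w_fam)
         + rng.normal(0.0, config.w_resid_sd, n))
    w_centered = w - w.mean()

    out = frame[["individual_id", "sex", "hatch", "family"]].copy()
    out["slaughter_weight"] = w
    for trait in traits:
        fam_eff = rng.normal(0.0, config.family_sd, len(fam_levels))
        y = (config.mu + config.a * x_a + config.d * x_d + factor_part(fam_eff)
             + rng.normal(0.0, config.resid_sd, n))
        if model_for_trait(trait) == "II":
            y = y + config.b * w_centered
        out[trait] = y
    return out


def simulate_panel(n: int, p_I: float, F: float = 0.0,
                   seed: int | None = None,
                   population: str = "sim") -> GenotypePanel:
    """Draw a genotype count panel from inbreeding-adjusted HW proportions.

    Genotype probabilities with inbreeding coefficient F:
    P(DD) = q^2 + F p q, P(ID) = 2 p q (1 - F), P(II) = p^2 + F p q,
    where p = p_I and q = 1 - p_I.  F = 0 gives Hardy-Weinberg proportions,
    F = 1 eliminates heterozygotes.
    """
    if not 0.0 <= F <= 1.0:
        raise ValidationError(f"inbreeding coefficient F={F} outside [0, 1]")
    if not 0.0 <= p_I <= 1.0:
        raise ValidationError(f"allele frequency p_I={p_I} outside [0, 1]")
    rng = np.random.default_rng(seed)
    p, q = p_I, 1.0 - p_I
    probs = [q * q + F * p * q, 2 * p * q * (1 - F), p * p + F * p * q]
    n_dd, n_id, n_ii = rng.multinomial(n, probs)
    return GenotypePanel(population=population, n_DD=int(n_dd),
                         n_ID=int(n_id), n_II=int(n_ii))


def simulate_ct(fold_changes: dict[str, float], n_per_group: int = 6,
                calibrator_delta_ct: float = 6.0, ref_ct: float = 18.0,
                noise_sd: float = 0.15, tissue: str = "leg_muscle",
                seed: int | None = None) -> pd.DataFrame:
    """Generate a CT table in which each group has a known mean fold change.

    A fold change f relative to the calibrator shifts the target CT by
    -log2(f) cycles.  Gaussian technical noise (``noise_sd`` cycles) is added
    to both target and reference CTs.  Express one group with fold change 1.0
    to serve as the calibrator.
    """
    if not fold_changes:
        raise ValidationError("no groups requested")
    rng = np.random.default_rng(seed)
    rows = []
    for group, fold in fold_changes.items():
        if fold <= 0:
            raise ValidationError(f"fold change for {group!r} must be > 0")
        for i in range(n_per_group):
            ref = ref_ct + rng.normal(0.0, noise_sd)
            target = (ref + calibrator_delta_ct - np.log2(fold)
                      + rng.normal(0.0, noise_sd))
            rows.append((f"{group}_{i + 1}", group, tissue, target, ref))
    return pd.DataFrame(rows, columns=["sample_id", "group", "tissue",
                                       "ct_target", "ct_reference"])
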