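"""Trait registry: codes, display names, units and model policy.

The association analysis uses two fixed-effect models: Model I (genotype +
sex + hatch + family) for body weights, carcass, meat-quality and serum
traits, and Model II (Model I plus a covariate for centered slaughter
weight) for linear body-size measurements, where overall size must be
adjusted out.

Trait codes are unique even where field abbreviations collide: CW is used in
the literature both for chest width and carcass weight, and PW both for
pelvis width and pancreas weight, so the codes here carry a disambiguating
suffix.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["Trait", "TRAITS", "model_for_trait"]


@dataclass(frozen=True)
class Trait:
    code: str
    name: str
    unit: str
    category: str  # growth_weight | body_size | carcass | meat_quality | serum


_T = Trait
TRAITS: dict[str, Trait] = {t.code: t for t in [
    # growth: body weights (g)
    _T("BW0", "body weight, 0 weeks", "g", "growth_weight"),
    _T("BW2", "body weight, 2 weeks", "g", "growth_weight"),
    _T("BW4", "body weight, 4 weeks", "g", "growth_weight"),
    _T("BW6", "body weight, 6 weeks", "g", "growth_weight"),
    _T("BW8", "body weight, 8 weeks", "g", "growth_weight"),
    _T("BW10", "body weight, 10 weeks", "g", "growth_weight"),
    _T("BW12", "body weight, 12 weeks", "g", "growth_weight"),
    # body-size measurements (cm) — analysed with the slaughter-weight covariate
    _T("SL0", "shank length, 0 weeks", "cm", "body_size"),
    _T("SL4", "shank length, 4 weeks", "cm", "body_size"),
    _T("SL8", "shank length, 8 weeks", "cm", "body_size"),
    _T("SL12", "shank length, 12 weeks", "cm", "body_size"),
    _T("SG4", "shank girth, 4 weeks", "cm", "body_size"),
    _T("SG8", "shank girth, 8 weeks", "cm", "body_size"),
    _T("SG12", "shank girth, 12 weeks", "cm", "body_size"),
    _T("CW_chest4", "chest width, 4 weeks", "cm", "body_size"),
    _T("CW_chest8", "chest width, 8 weeks", "cm", "body_size"),
    _T("CW_chest12", "chest width, 12 weeks", "cm", "body_size"),
    _T("BSL4", "body slant length, 4 weeks", "cm", "body_size"),
    _T("BSL8", "body slant length, 8 weeks", "cm", "body_size"),
    _T("BSL12", "body slant length, 12 weeks", "cm", "body_size"),
    _T("PW_body4", "pelvis width, 4 weeks", "cm", "body_size"),
    _T("PW_body8", "pelvis width, 8 weeks", "cm", "body_size"),
    _T("PW_body12", "pelvis width, 12 weeks", "cm", "body_size"),
    # carcass traits (g unless noted)
    _T("CW_carcass", "carcass weight", "g", "carcass"),
    _T("SEW", "semi-evisceration weight", "g", "carcass"),
    _T("EW", "evisceration weight", "g", "carcass"),
    _T("CLW", "claw weight", "g", "carcass"),
    _T("WW", "wings weight", "g", "carcass"),
    _T("GW", "gizzard weight", "g", "carcass"),
    _T("PW_pancreas", "pancreas weight", "g", "carcass"),
    _T("CMW", "chest muscle weight", "g", "carcass"),
    _T("LW", "leg weight", "g", "carcass"),
    _T("LMW", "leg muscle weight", "g", "carcass"),
    _T("SW", "slaughter weight", "g", "carcass"),
    _T("LR", "leg rate", "%", "meat_quality"),
    _T("LMR", "leg muscle rate", "%", "meat_quality"),
    _T("PF", "pectoral fullness", "%", "meat_quality"),
    _T("WHC", "breast muscle water holding capacity", "%", "meat_quality"),
    # serum biochemistry
    _T("ALT", "alanine transaminase", "U/L", "serum"),
    _T("LDH", "lactate dehydrogenase", "U/L", "serum"),
]}

_MODEL_II_CATEGORIES = {"body_size"}


def model_for_trait(trait_code: str) -> str:
    """Model policy: Model II for body-size traits, Model I otherwise.

    Unknown codes default to Model I (no covariate), the conservative choice.
    """
    trait = TRAITS.get(trait_code)
    if trait is not None and trait.category in _MODEL_II_CATEGORIES:
        return "II"
    return "I"
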