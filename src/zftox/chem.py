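"""Elemental-formula arithmetic for biotransformation-product mass prediction.

Formulas are handled as :class:`pyteomics.mass.Composition` objects; monoisotopic
masses come from the pyteomics atomic-mass tables. A transformation rule is a
signed composition delta (e.g. ``+O`` for epoxidation, ``-CHNO`` for loss of the
carbamoyl group), an adduct a fixed mass offset for a singly charged positive ion.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

# Singly charged positive adduct offsets (Da): cation mass minus electron mass.
PROTON = 1.007276
SODIUM = 22.989218
POTASSIUM = 38.963158


def parse_formula(formula: str) -> _pmass.Composition:
    """Parse an elemental formula like ``C15H12N2O`` into a composition."""
    return _pmass.Composition(formula=formula)


def monoisotopic_mass(formula: str | _pmass.Composition) -> float:
    """Monoisotopic (exact) mass in Da of a neutral formula."""
    if isinstance(formula, str):
        formula = parse_formula(formula)
    return _pmass.calculate_mass(composition=formula)


def composition_to_formula(comp: _pmass.Composition) -> str:
    """Hill-ish string rendering (C, H, then alphabetical)."""
    elements = sorted(comp, key=lambda e: (e != "C", e != "H", e))
    out = []
    for el in elements:
        n = comp[el]
        if n == 0:
            continue
        out.append(el if n == 1 else f"{el}{n}")
    return "".join(out)


def ppm_error(observed: float, expected: float) -> float:
    """Signed mass error in parts per million: 1e6 * (obs - exp) / exp."""
    return 1e6 * (observed - expected) / expected


@dataclass(frozen=True)
class TransformationRule:
    """A biotransformation as a signed elemental delta.

    ``add`` and ``remove`` are formula strings; the monoisotopic mass delta is
    derived from them, so it is always consistent with the elemental delta.
    """

    name: str
    add: str = ""
    remove: str = ""

    @property
    def delta_composition(self) -> _pmass.Composition:
        comp = _pmass.Composition()
        if self.add:
            comp += parse_formula(self.add)
        if self.remove:
            comp -= parse_formula(self.remove)
        return comp

    @property
    def mass_delta(self) -> float:
        return _pmass.calculate_mass(composition=self.delta_composition)

    def apply(self, parent: _pmass.Composition) -> _pmass.Composition | None:
        """Product composition, or None if the rule removes atoms the parent lacks."""
        product = parent + self.delta_composition
        if any(v < 0 for v in product.values()):
            return None
        return _pmass.Composition({k: v for k, v in product.items() if v > 0})


@dataclass(frozen=True)
class AdductRule:
    """Positive-mode adduct: m/z = (neutral mass + mass_delta) / charge."""

    name: str
    mass_delta: float
    charge: int = 1

    def __post_init__(self):
        if self.charge <= 0:
            raise ValueError("adducts must carry positive charge")

    def mz(self, neutral_mass: float) -> float:
        return (neutral_mass + self.mass_delta) / self.charge


# Default library: the carbamazepine demo transformations. Extensible via config.
DEFAULT_RULES: tuple[TransformationRule, ...] = (
    TransformationRule("parent"),
    TransformationRule("epoxidation", add="O"),
    TransformationRule("dihydroxylation", add="O2"),
    TransformationRule("dihydrodiol", add="H2O2"),
    TransformationRule("glucuronidation", add="C6H8O6"),
    TransformationRule("carbamoyl_loss", remove="CHNO"),
)

DEFAULT_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]", PROTON),
    AdductRule("[M+Na]", SODIUM),
    AdductRule("[M+K]", POTASSIUM),
)

CBZ_FORMULA = "C15H12N2O"
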