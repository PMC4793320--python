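"""Trait catalog: the measured character codes and the derived cephalic size.

All linear measurements are in micrometres.  ``CS`` is derived as the
arithmetic mean of ``CL`` and ``CWb`` and acts as the size denominator for
every dimensionless ratio.  ``Cdep`` and ``PSTI`` are recorded for a small
subset of taxa only and are excluded from multivariate work by default.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Trait",
    "TraitCatalog",
    "MEASURED_CODES",
    "DERIVED_CODES",
    "PARTIAL_CODES",
    "DEFAULT_CATALOG",
    "default_multivariate_traits",
]

#: The 23 measured character codes, alphabetical.
MEASURED_CODES: tuple[str, ...] = (
    "CL", "CW", "CWb", "Cdep", "EL", "FRS", "ML", "MW", "MPST", "NOH",
    "NOL", "PEH", "PEL", "PEW", "PoOC", "PPH", "PPL", "PPW", "PSTI",
    "SL", "SPBA", "SPST", "SPTI",
)

#: Codes computed from measured ones.
DERIVED_CODES: tuple[str, ...] = ("CS",)

#: Characters measured only on a subset of specimens/taxa.
PARTIAL_CODES: tuple[str, ...] = ("Cdep", "PSTI")

_DESCRIPTIONS = {
    "CL": "maximum cephalic length in median line",
    "CW": "maximum width of the head including compound eyes",
    "CWb": "maximum width of head capsule without the compound eyes",
    "CS": "absolute cephalic size, arithmetic mean of CL and CWb",
    "Cdep": "antero-median clypeal depression depth",
    "EL": "maximum diameter of the compound eye",
    "FRS": "frontal carina distance",
    "ML": "mesosoma (Weber) length",
    "MW": "mesosoma width",
    "MPST": "propodeal stigma to metapleuron corner distance",
    "NOH": "maximum height of the petiolar node",
    "NOL": "length of the petiolar node",
    "PEH": "maximum petiole height",
    "PEL": "diagonal petiolar length in lateral view",
    "PEW": "maximum width of petiole in dorsal view",
    "PoOC": "postocular distance",
    "PPH": "maximum height of the postpetiole in lateral view",
    "PPL": "postpetiole length",
    "PPW": "maximum width of postpetiole in dorsal view",
    "PSTI": "apical distance of pronotal spines in dorsal view",
    "SL": "maximum straight-line scape length",
    "SPBA": "minimum propodeal spine distance at base",
    "SPST": "propodeal spine length from stigma center",
    "SPTI": "apical propodeal spine distance",
}


@dataclass(frozen=True)
class Trait:
    code: str
    description: str
    kind: str  # "measured" | "derived"


class TraitCatalog:
    """Immutable registry of known trait codes."""

    def __init__(self) -> None:
        traits = [Trait(c, _DESCRIPTIONS[c], "measured") for c in MEASURED_CODES]
        traits += [Trait(c, _DESCRIPTIONS[c], "derived") for c in DERIVED_CODES]
        codes = [t.code for t in traits]
        if len(set(codes)) != len(codes):  # pragma: no cover - defensive
            raise ValueError("duplicate trait codes in catalog")
        self._by_code = {t.code: t for t in traits}

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    def __getitem__(self, code: str) -> Trait:
        return self._by_code[code]

    def __iter__(self):
        return iter(self._by_code.values())

    def __len__(self) -> int:
        return len(self._by_code)

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(self._by_code)

    @property
    def measured(self) -> tuple[str, ...]:
        return tuple(t.code for t in self if t.kind == "measured")


DEFAULT_CATALOG = TraitCatalog()


def default_multivariate_traits(available: tuple[str, ...] | list[str] | None = None,
                                exclude: tuple[str, ...] = ("PPL",)) -> list[str]:
    """Measured traits used in multivariate analyses.

    Drops the partially recorded characters (Cdep, PSTI) and any code in
    ``exclude`` (PPL by default, the trait screened out for error variance).
    If ``available`` is given, the result is further restricted to it.
    """
    drop = set(PARTIAL_CODES) | set(exclude)
    codes = [c for c in MEASURED_CODES if c not in drop]
    if available is not None:
        avail = set(available)
        codes = [c for c in codes if c in avail]
    return codes
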