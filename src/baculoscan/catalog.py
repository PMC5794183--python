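"""Gene-class catalog for baculovirus comparative genomics.

Three packaged gene lists drive the per-class identity summaries:

* the 38 *core genes* conserved in every sequenced baculovirus genome;
* the 22 genes conserved across all lepidopteran baculoviruses
  (alpha- and betabaculoviruses);
* genes found only in Group I alphabaculoviruses (gp64-type viruses).
  No authoritative enumeration of this list is packaged with genome
  annotations, so the catalog ships a representative set of eleven genes;
  it is easy to override.

Gene names in deposited annotations are inconsistent (p74 vs pif0,
vp91/p95, ac-number aliases), so lookups are resolved through a synonym
table after normalisation (lower-case, punctuation stripped).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = ["GeneClassCatalog", "default_catalog", "CORE_GENES",
           "LEPIDOPTERAN_CONSERVED_GENES", "GROUP1_SPECIFIC_GENES"]

CORE_GENES: tuple[str, ...] = (
    # replication
    "alk-exo", "helicase", "dna-pol", "lef1", "lef2",
    # transcription
    "lef5", "lef4", "vlf-1", "lef9", "lef8", "p47",
    # structure
    "odv-ec27", "odv-e18", "49k", "odv-ec43", "p48", "p40", "p6.9", "38k",
    "odv-e25", "p18", "p33", "vp39", "ac81", "gp41", "ac78", "desmoplakin",
    "vp1054", "ac53",
    # oral infectivity
    "pif5", "p74", "pif1", "pif3", "pif4", "vp91", "pif6", "pif2", "ac110",
)

LEPIDOPTERAN_CONSERVED_GENES: tuple[str, ...] = (
    "ie-1", "me53", "lef3", "dbp", "lef11",
    "pk-1", "lef6", "39k",
    "polyhedrin", "p12", "tlp-20", "fp25k", "f", "calyx",
    "ac108",
    "38.7k", "adprase",
    "ac146", "ac145", "ac106", "ac76", "ac75",
)

GROUP1_SPECIFIC_GENES: tuple[str, ...] = (
    "gp64", "ie-2", "ptp", "pkip", "odv-e26", "ac5", "ac16", "ac30",
    "ac72", "ac73", "ac124",
)

# alias (normalised) -> canonical (normalised)
_SYNONYMS = {
    "pif0": "p74",
    "pif7": "ac110",
    "pif8": "vp91",
    "p95": "vp91",
    "vp91p95": "vp91",
    "sf58": "ac108",
    "p45": "p48",
    "p48p45": "p48",
    "pep": "calyx",
    "calyxpep": "calyx",
    "polh": "polyhedrin",
    "ph": "polyhedrin",
    "ac66": "desmoplakin",
    "ac46": "odve66",
    "alkaliexonuclease": "alkexo",
    "alkalineexonuclease": "alkexo",
    "dnapolymerase": "dnapol",
    "vlf1": "vlf1",
    "ie0": "ie1",
    "ie01": "ie1",
    "adpribosepyrophosphatase": "adprase",
    "pp31": "39k",
    "vp15": "p69",  # p6.9 basic protein alias
}

_norm_re = re.compile(r"[^a-z0-9]")


def _norm(name: str) -> str:
    return _norm_re.sub("", name.lower())


@dataclass
class GeneClassCatalog:
    core: tuple[str, ...] = CORE_GENES
    lepidopteran_conserved: tuple[str, ...] = LEPIDOPTERAN_CONSERVED_GENES
    group1_specific: tuple[str, ...] = GROUP1_SPECIFIC_GENES
    synonyms: dict[str, str] = field(default_factory=lambda: dict(_SYNONYMS))

    def __post_init__(self) -> None:
        sets = [set(map(_norm, self.core)),
                set(map(_norm, self.lepidopteran_conserved)),
                set(map(_norm, self.group1_specific))]
        if len(self.core) != 38:
            raise ValueError(f"core list must have 38 entries, got {len(self.core)}")
        for i in range(3):
            for j in range(i + 1, 3):
                common = sets[i] & sets[j]
                if common:
                    raise ValueError(f"gene lists overlap: {sorted(common)}")
        self._lookup: dict[str, str] = {}
        for cls, names in (("core", self.core),
                           ("lepidopteran_conserved", self.lepidopteran_conserved),
                           ("group1_specific", self.group1_specific)):
            for name in names:
                self._lookup[_norm(name)] = cls

    def resolve(self, name: str) -> str:
        """Normalise a gene label, following synonyms."""
        key = _norm(name)
        return self.synonyms.get(key, key)

    def classify(self, name: str) -> str:
        """Return 'core', 'lepidopteran_conserved', 'group1_specific' or
        'other'."""
        return self._lookup.get(self.resolve(name), "other")


def default_catalog() -> GeneClassCatalog:
    return GeneClassCatalog()
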