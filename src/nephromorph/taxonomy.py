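"""Class taxonomy for multiclass kidney-histology segmentations.

The default taxonomy mirrors the 20-class scheme used for PAS-stained
kidney sections: a tissue silhouette split into cortex and medulla, with
glomerular subclasses (non-sclerosed, globally sclerosed, empty capsule),
tubulointerstitial subclasses (tubules, proximal/distal, tubular-atrophy
clusters), and vascular subclasses (arteries/arterioles with arteriolar
hyalinosis, intimal thickening and lumen; interlobar arteries in medulla).

Classes are stored as (code, name) pairs plus a single-parent containment
tree.  Spatial overlap between *sibling* classes is allowed (the storage
model is multilayer, one mask per class); the only spatial constraint the
tree imposes is child-region ⊆ parent-region.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class TaxonomyError(ValueError):
    """Unknown class code/name or ill-formed containment relation."""


# Compartment tags: which top-level region a class logically lives in.
TISSUE_LEVEL = "tissue-level"
CORTEX_LEVEL = "cortex-level"
MEDULLA_LEVEL = "medulla-level"


@dataclass(frozen=True)
class ClassDef:
    code: int
    name: str
    compartment: str


@dataclass
class ClassTaxonomy:
    """A set of named integer-coded classes with a containment tree.

    Parameters
    ----------
    classes
        ``ClassDef`` entries; codes and names must each be unique.
    containment
        ``(child_code, parent_code)`` pairs. Every class except the single
        root must appear exactly once as a child; the relation must be
        acyclic.
    """

    classes: list[ClassDef]
    containment: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        codes = [c.code for c in self.classes]
        names = [c.name for c in self.classes]
        if len(set(codes)) != len(codes):
            raise TaxonomyError("duplicate class codes")
        if len(set(names)) != len(names):
            raise TaxonomyError("duplicate class names")
        self._by_code = {c.code: c for c in self.classes}
        self._by_name = {c.name: c for c in self.classes}
        parent: dict[int, int] = {}
        for child, par in self.containment:
            if child not in self._by_code or par not in self._by_code:
                raise TaxonomyError(f"containment refers to unknown code: ({child}, {par})")
            if child in parent:
                raise TaxonomyError(f"class {child} has more than one parent")
            parent[child] = par
        self._parent = parent
        roots = [c for c in codes if c not in parent]
        if self.containment and len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root class, found {roots}")
        # acyclicity: walk each chain to the root
        for code in codes:
            seen = set()
            cur = code
            while cur in self._parent:
                if cur in seen:
                    raise TaxonomyError(f"containment cycle through class {cur}")
                seen.add(cur)
                cur = self._parent[cur]

    # -- lookups ---------------------------------------------------------

    def code(self, name: str) -> int:
        try:
            return self._by_name[name].code
        except KeyError:
            raise TaxonomyError(f"unknown class name: {name!r}") from None

    def name(self, code: int) -> str:
        try:
            return self._by_code[code].name
        except KeyError:
            raise TaxonomyError(f"unknown class code: {code}") from None

    def compartment(self, code: int) -> str:
        return self._by_code[code].compartment

    def __contains__(self, key: int | str) -> bool:
        return key in self._by_code or key in self._by_name

    def parent(self, code: int) -> int | None:
        """Parent code, or None for the root."""
        return self._parent.get(code)

    def children(self, code: int) -> list[int]:
        return [c for c, p in self._parent.items() if p == code]

    def depth(self, code: int) -> int:
        d = 0
        while (p := self._parent.get(code)) is not None:
            code = p
            d += 1
        return d

    @property
    def codes(self) -> list[int]:
        return [c.code for c in self.classes]

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.classes]


# Canonical class names for the default 20-class model.
TISSUE = "Tissue"
CORTEX = "Cortex"
TA_CLUSTER = "Tubular atrophy cluster"
CORTEX_EXCL = "Cortex excluding arteries and atrophic tubules"
TUBULOINTERSTITIUM = "Tubulointerstitium"
TUBULES = "Tubules"
DISTAL_TUBULE = "Distal tubule"
PROXIMAL_TUBULE = "Proximal tubule"
GLOMERULAR_AREA = "Glomerular area"
GSG = "Globally sclerosed glomeruli"
EMPTY_CAPSULE = "Empty capsule"
NSG = "Nonglobally sclerosed glomeruli"
ARTERIES = "Arteries and arterioles"
AH = "Arteriolar hyalinosis"
INTIMA = "Intimal thickening"
ARTERIAL_LUMEN = "Arterial lumen"
MEDULLA = "Medulla"
INTERLOBAR = "Interlobar arteries"
INTIMA_MED = "Intimal thickening (medullary)"
ARTERY_LUMEN_MED = "Artery lumen"

_DEFAULT = [
    # (code, name, compartment, parent name)
    (1, TISSUE, TISSUE_LEVEL, None),
    (2, CORTEX, CORTEX_LEVEL, TISSUE),
    (3, TA_CLUSTER, CORTEX_LEVEL, TUBULOINTERSTITIUM),
    (4, CORTEX_EXCL, CORTEX_LEVEL, CORTEX),
    (5, TUBULOINTERSTITIUM, CORTEX_LEVEL, CORTEX),
    (6, TUBULES, CORTEX_LEVEL, TUBULOINTERSTITIUM),
    (7, DISTAL_TUBULE, CORTEX_LEVEL, TUBULES),
    (8, PROXIMAL_TUBULE, CORTEX_LEVEL, TUBULES),
    (9, GLOMERULAR_AREA, CORTEX_LEVEL, CORTEX),
    (10, GSG, CORTEX_LEVEL, GLOMERULAR_AREA),
    (11, EMPTY_CAPSULE, CORTEX_LEVEL, GLOMERULAR_AREA),
    (12, NSG, CORTEX_LEVEL, GLOMERULAR_AREA),
    (13, ARTERIES, CORTEX_LEVEL, CORTEX),
    (14, AH, CORTEX_LEVEL, ARTERIES),
    (15, INTIMA, CORTEX_LEVEL, ARTERIES),
    (16, ARTERIAL_LUMEN, CORTEX_LEVEL, ARTERIES),
    (17, MEDULLA, MEDULLA_LEVEL, TISSUE),
    (18, INTERLOBAR, MEDULLA_LEVEL, MEDULLA),
    (19, INTIMA_MED, MEDULLA_LEVEL, INTERLOBAR),
    (20, ARTERY_LUMEN_MED, MEDULLA_LEVEL, INTERLOBAR),
]


def default_taxonomy() -> ClassTaxonomy:
    """The default 20-class kidney taxonomy.

    Tubular-atrophy clusters nest under the tubulointerstitium so that the
    interstitium-and-TA fraction (%ITA) has the tubulointerstitial
    compartment, TA included, as its denominator. The aggregate class
    "Cortex excluding arteries and atrophic tubules" sits directly under
    Cortex and overlaps the tubulointerstitium layer; that overlap is
    intentional (multilayer storage).
    """
    name_to_code = {name: code for code, name, _, _ in _DEFAULT}
    classes = [ClassDef(code, name, comp) for code, name, comp, _ in _DEFAULT]
    containment = [
        (code, name_to_code[par]) for code, name, _, par in _DEFAULT if par is not None
    ]
    return ClassTaxonomy(classes=classes, containment=containment)
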