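"""Enumeration of the directed model spaces over default-mode-network regions.

The spaces are built from two orthogonal ingredients:

* eight *base families* (labelled ``a``–``h``) describing how the four core
  DMN regions (mPFC, PCC, LIPC, RIPC) are coupled: a fully connected digraph,
  three "driver-dominant" variants in which a driver set (mPFC, PCC, or the
  bilateral parietal pair) influences the rest but receives nothing back, and
  the same four topologies with the LIPC<->RIPC reciprocal pair deleted;
* twelve *inclusion patterns* (labelled ``1``–``12``) describing how one
  additional region (a hippocampal seed) is wired into the core set.

Crossing the two gives 96 five-node models per added region.  Removing PCC
from the base families collapses them onto six distinct three-node topologies
(labelled a', e', b', f', d', h'), giving a reduced space of 72 four-node
models.  A single six-node model combines the best LHIP and RHIP inclusion
patterns on the fully connected core.

Masks follow the convention ``mask[i][j] == 1`` iff the directed influence
region ``j`` -> region ``i`` is allowed.  Diagonals are always zero:
self-connections are handled implicitly by the inversion engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CORE_REGIONS = ("mPFC", "PCC", "LIPC", "RIPC")

#: MNI center coordinates (mm) of the regions of interest.
MNI_COORDS = {
    "mPFC": (3, 54, -2),
    "PCC": (0, -52, 26),
    "LIPC": (-50, -63, 32),
    "RIPC": (48, -69, 35),
    "LHIP": (-22, -23, -14),
    "RHIP": (19, -20, -10),
}


@dataclass(frozen=True)
class ModelSpec:
    """A named directed binary adjacency over an ordered region set."""

    regions: tuple[str, ...]
    mask: np.ndarray  # (n, n) int, mask[i, j] = 1 means j -> i allowed
    base_family: str = "none"
    pattern: str = "none"
    name: str = field(default="")

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=int)
        n = len(self.regions)
        if mask.shape != (n, n):
            raise ValueError(
                f"mask shape {mask.shape} does not match {n} regions"
            )
        if len(set(self.regions)) != n:
            raise ValueError("region labels must be unique")
        if np.any(np.diag(mask) != 0):
            raise ValueError("mask diagonal must be zero")
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        object.__setattr__(self, "mask", mask)
        if not self.name:
            object.__setattr__(
                self, "name", f"{self.base_family}_{self.pattern}"
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    @property
    def n_edges(self) -> int:
        return int(self.mask.sum())

    def edges(self) -> set[tuple[str, str]]:
        """Directed edges as (source, target) label pairs."""
        return {
            (self.regions[j], self.regions[i])
            for i, j in zip(*np.nonzero(self.mask))
        }

    def index(self, label: str) -> int:
        return self.regions.index(label)

    def same_mask(self, other: "ModelSpec") -> bool:
        return self.regions == other.regions and np.array_equal(
            self.mask, other.mask
        )

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "family": self.base_family,
            "pattern": self.pattern,
            "regions": list(self.regions),
            "mask": self.mask.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            regions=tuple(d["regions"]),
            mask=np.asarray(d["mask"], dtype=int),
            base_family=d.get("family", "none"),
            pattern=d.get("pattern", "none"),
            name=d.get("name", ""),
        )


def _mask_from_edges(
    regions: tuple[str, ...], edges: set[tuple[str, str]]
) -> np.ndarray:
    idx = {r: k for k, r in enumerate(regions)}
    mask = np.zeros((len(regions), len(regions)), dtype=int)
    for src, dst in edges:
        mask[idx[dst], idx[src]] = 1
    return mask


def _complete_edges(regions: tuple[str, ...]) -> set[tuple[str, str]]:
    return {(a, b) for a in regions for b in regions if a != b}


def base_families(
    regions: tuple[str, ...] = CORE_REGIONS,
) -> list[ModelSpec]:
    """The eight base topologies (a-h) over the four core DMN regions.

    ``a`` is the complete digraph.  ``b``, ``c``, ``d`` are driver-dominant:
    every edge *into* the driver set ({mPFC}, {PCC}, {LIPC, RIPC}
    respectively) from outside it is removed, all other couplings remain
    reciprocal (for ``d`` the LIPC<->RIPC pair is inside the driver set and
    therefore retained).  ``e``-``h`` repeat ``a``-``d`` with both
    LIPC<->RIPC edges deleted.
    """
    driver_sets: list[set[str]] = [
        set(),  # a: complete
        {"mPFC"},  # b
        {"PCC"},  # c
        {"LIPC", "RIPC"},  # d
    ]
    specs = []
    for letter, lesion in zip("abcdefgh", driver_sets + driver_sets):
        edges = _complete_edges(regions)
        # driver-dominant: nothing outside the driver set feeds the drivers
        edges = {
            (s, t)
            for (s, t) in edges
            if not (t in lesion and s not in lesion)
        }
        if letter in "efgh":
            edges -= {("LIPC", "RIPC"), ("RIPC", "LIPC")}
        specs.append(
            ModelSpec(
                regions=regions,
                mask=_mask_from_edges(regions, edges),
                base_family=letter,
                pattern="none",
                name=letter,
            )
        )
    return specs


def inclusion_patterns(
    new_region: str, base: tuple[str, ...] = CORE_REGIONS
) -> list[tuple[str, set[tuple[str, str]]]]:
    """The twelve ways to wire ``new_region`` into the base region set.

    Returns ``(pattern_label, edge_set)`` templates.  Patterns 5-8 use the
    bilateral parietal pair as the privileged partner set; patterns 9-12 are
    the same four flows with {mPFC, PCC} substituted.  For a reduced (PCC-free)
    base, PCC-touching edges are simply absent from the templates.
    """
    parietal = [r for r in ("LIPC", "RIPC") if r in base]
    midline = [r for r in ("mPFC", "PCC") if r in base]
    if not parietal or not midline:
        raise ValueError(
            f"base {base} lacks the parietal/midline substitution sets"
        )
    r = new_region

    def inputs(srcs) -> set[tuple[str, str]]:
        return {(s, r) for s in srcs}

    def outputs(dsts) -> set[tuple[str, str]]:
        return {(r, d) for d in dsts}

    all_ = list(base)
    templates = [
        ("1", inputs(all_) | outputs(all_)),
        ("2", set()),
        ("3", outputs(all_)),
        ("4", inputs(all_)),
        ("5", inputs(all_) | outputs(parietal)),
        ("6", inputs(parietal) | outputs(all_)),
        ("7", inputs(parietal)),
        ("8", outputs(parietal)),
        ("9", inputs(all_) | outputs(midline)),
        ("10", inputs(midline) | outputs(all_)),
        ("11", inputs(midline)),
        ("12", outputs(midline)),
    ]
    return templates


def full_space(region: str = "LHIP") -> list[ModelSpec]:
    """The 96-model space: 8 base families x 12 inclusion patterns."""
    if region not in ("LHIP", "RHIP"):
        raise ValueError("inclusion region must be LHIP or RHIP")
    specs = []
    for fam in base_families():
        regions = fam.regions + (region,)
        for label, extra in inclusion_patterns(region, fam.regions):
            edges = fam.edges() | extra
            specs.append(
                ModelSpec(
                    regions=regions,
                    mask=_mask_from_edges(regions, edges),
                    base_family=fam.base_family,
                    pattern=label,
                )
            )
    return specs


#: Post-deduplication labels of the PCC-free base families, in the order the
#: surviving a-h representatives appear (c collapses into a, g into e).
REDUCED_FAMILY_LABELS = ("a'", "b'", "d'", "e'", "f'", "h'")


def reduced_base_families() -> list[ModelSpec]:
    """Delete PCC from each base family and deduplicate identical masks."""
    regions = tuple(r for r in CORE_REGIONS if r != "PCC")
    survivors: list[ModelSpec] = []
    collapse: dict[str, str] = {}
    for fam in base_families():
        edges = {
            (s, t) for (s, t) in fam.edges() if "PCC" not in (s, t)
        }
        mask = _mask_from_edges(regions, edges)
        dup = next(
            (s for s in survivors if np.array_equal(s.mask, mask)), None
        )
        if dup is not None:
            collapse[fam.base_family] = dup.base_family
            continue
        survivors.append(
            ModelSpec(
                regions=regions,
                mask=mask,
                base_family=fam.base_family + "'",
                pattern="none",
                name=fam.base_family + "'",
            )
        )
    labels = tuple(sorted(s.base_family for s in survivors))
    if labels != tuple(sorted(REDUCED_FAMILY_LABELS)):
        raise RuntimeError(
            f"PCC removal produced families {labels}, expected "
            f"{REDUCED_FAMILY_LABELS}; base-family construction is wrong"
        )
    return survivors


def reduced_space(region: str = "LHIP") -> list[ModelSpec]:
    """The 72-model PCC-removed space: 6 deduplicated families x 12 patterns."""
    specs = []
    for fam in reduced_base_families():
        regions = fam.regions + (region,)
        for label, extra in inclusion_patterns(region, fam.regions):
            edges = fam.edges() | extra
            specs.append(
                ModelSpec(
                    regions=regions,
                    mask=_mask_from_edges(regions, edges),
                    base_family=fam.base_family,
                    pattern=label + "'",
                )
            )
    return specs


def combine_best(include_cross_hippocampal: bool = True) -> ModelSpec:
    """Six-node model joining the best RHIP (pattern 1) and LHIP (pattern 6)
    inclusions on the fully connected core family ``a``.

    ``include_cross_hippocampal`` adds both LHIP<->RHIP couplings; the
    inversion shrinks whichever direction the data do not support.
    """
    fam_a = base_families()[0]
    regions = fam_a.regions + ("LHIP", "RHIP")
    edges = fam_a.edges()
    edges |= dict(inclusion_patterns("RHIP", fam_a.regions))["1"]
    edges |= dict(inclusion_patterns("LHIP", fam_a.regions))["6"]
    if include_cross_hippocampal:
        edges |= {("LHIP", "RHIP"), ("RHIP", "LHIP")}
    return ModelSpec(
        regions=regions,
        mask=_mask_from_edges(regions, edges),
        base_family="a",
        pattern="1+6",
        name="a_1+6",
    )


def family_map(space: list[ModelSpec], by: str = "base") -> dict[str, str]:
    """Model-name -> family-label map for family-level model selection.

    ``by='base'`` groups by base family; ``by='pattern'`` by inclusion
    pattern.
    """
    if by == "base":
        return {m.name: m.base_family for m in space}
    if by == "pattern":
        return {m.name: m.pattern for m in space}
    raise ValueError("by must be 'base' or 'pattern'")
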