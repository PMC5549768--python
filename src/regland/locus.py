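"""Geometry of a multi-enhancer locus.

A :class:`LocusModel` describes a single chromosome carrying a promoter,
a set of cis-regulatory elements (enhancers, a CTCF site cluster) and an
ordered tiling of topologically associating domains (TADs).  The default
model is a 2 Mb toy chromosome scaled 1:4 from the mouse Krox20 locus:
five TADs labelled -2, -1, Krox20, +1, +2, with the promoter and elements
A/B/C/NE inside the central (Krox20) TAD and a CTCF cluster between the
Nrbf2-side transition zone and element A.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import yaml

VALID_ROLES = frozenset({"promoter", "enhancer", "ctcf_cluster"})


class LocusValidationError(ValueError):
    """Raised when a locus description violates a geometric invariant."""


@dataclass(frozen=True)
class Element:
    name: str
    start: int
    end: int
    role: str

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def width(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TAD:
    label: str
    start: int
    end: int


@dataclass
class LocusModel:
    """Validated geometry of one chromosome.

    All coordinates are 0-based, half-open base pairs.  TADs are sorted and
    non-overlapping; element names are unique and intervals lie within the
    chromosome.
    """

    chrom_name: str
    chrom_length: int
    elements: list[Element] = field(default_factory=list)
    tads: list[TAD] = field(default_factory=list)
    viewpoints: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.chrom_length <= 0:
            raise LocusValidationError("chrom_length must be positive")
        seen: set[str] = set()
        for el in self.elements:
            if el.name in seen:
                raise LocusValidationError(f"duplicate element name {el.name!r}")
            seen.add(el.name)
            if el.role not in VALID_ROLES:
                raise LocusValidationError(
                    f"element {el.name!r}: unknown role {el.role!r}"
                )
            if not (0 <= el.start < el.end <= self.chrom_length):
                raise LocusValidationError(
                    f"element {el.name!r}: interval [{el.start}, {el.end}) outside "
                    f"[0, {self.chrom_length})"
                )
        prev: TAD | None = None
        for tad in sorted(self.tads, key=lambda t: t.start):
            if not (0 <= tad.start < tad.end <= self.chrom_length):
                raise LocusValidationError(
                    f"TAD {tad.label!r}: interval [{tad.start}, {tad.end}) outside "
                    f"[0, {self.chrom_length})"
                )
            if prev is not None and tad.start < prev.end:
                raise LocusValidationError(
                    f"TADs {prev.label!r} and {tad.label!r} overlap"
                )
            prev = tad
        self.tads = sorted(self.tads, key=lambda t: t.start)
        for name, pos in self.viewpoints.items():
            if not (0 <= pos < self.chrom_length):
                raise LocusValidationError(
                    f"viewpoint {name!r} at {pos} outside chromosome"
                )

    # -- lookups ---------------------------------------------------------
    def element(self, name: str) -> Element:
        for el in self.elements:
            if el.name == name:
                return el
        raise KeyError(name)

    def tad_of(self, position: int) -> str | None:
        """Label of the TAD containing ``position``, or None between TADs."""
        for tad in self.tads:
            if tad.start <= position < tad.end:
                return tad.label
        return None

    def tad(self, label: str) -> TAD:
        for t in self.tads:
            if t.label == label:
                return t
        raise KeyError(label)


def build_locus_model(config: dict) -> LocusModel:
    """Build a validated :class:`LocusModel` from a structured description.

    ``config`` carries ``chrom_name``, ``chrom_length`` and lists of
    ``elements`` (name, start, end, role), ``tads`` (label, start, end) and
    optionally ``viewpoints`` (name -> position).  Deterministic; raises
    :class:`LocusValidationError` naming the offending entry.
    """
    if not config.get("tads"):
        raise LocusValidationError("config must define at least one TAD")
    if not config.get("elements"):
        raise LocusValidationError("config must define at least one element")
    elements = [
        Element(str(e["name"]), int(e["start"]), int(e["end"]), str(e["role"]))
        for e in config["elements"]
    ]
    tads = [
        TAD(str(t["label"]), int(t["start"]), int(t["end"])) for t in config["tads"]
    ]
    viewpoints = {str(k): int(v) for k, v in config.get("viewpoints", {}).items()}
    return LocusModel(
        chrom_name=str(config.get("chrom_name", "chrS")),
        chrom_length=int(config["chrom_length"]),
        elements=elements,
        tads=tads,
        viewpoints=viewpoints,
    )


def load_locus_model(path: str) -> LocusModel:
    with open(path) as fh:
        return build_locus_model(yaml.safe_load(fh))


def default_locus() -> LocusModel:
    """The default 2 Mb toy locus (1:4 scale of the real geometry).

    Five 400-kb TADs; the promoter sits in the central "Krox20" TAD with
    enhancers A (~54 kb upstream), B (~41 kb), C (~36 kb) and NE (~27 kb
    downstream), mirroring the 217/164/144/107 kb distances of the real
    locus at quarter scale.  A CTCF cluster lies between the Nrbf2
    viewpoint and element A, where the repositioned TAD boundary goes.
    """
    return LocusModel(
        chrom_name="chrS",
        chrom_length=2_000_000,
        elements=[
            Element("promoter", 1_099_750, 1_100_250, "promoter"),
            Element("A", 1_045_500, 1_046_000, "enhancer"),
            Element("B", 1_059_000, 1_059_500, "enhancer"),
            Element("C", 1_064_000, 1_064_500, "enhancer"),
            Element("NE", 1_126_500, 1_127_000, "enhancer"),
            Element("ctcf_cluster", 1_030_000, 1_032_000, "ctcf_cluster"),
        ],
        tads=[
            TAD("-2", 0, 400_000),
            TAD("-1", 400_000, 800_000),
            TAD("Krox20", 800_000, 1_200_000),
            TAD("+1", 1_200_000, 1_600_000),
            TAD("+2", 1_600_000, 2_000_000),
        ],
        viewpoints={"promoter": 1_100_000, "A": 1_045_750, "Nrbf2": 1_010_000},
    )
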