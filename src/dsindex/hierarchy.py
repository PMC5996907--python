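"""Feature hierarchy: a rooted tree grouping features into modality branches.

The Disease State Index aggregates per-feature evidence bottom-up through a
tree whose internal nodes are named groups (typically the four measurement
modalities: neuropsychology ``NP``, cerebrospinal fluid ``CSF``, visual MRI
ratings ``VMRI`` and automatic MRI quantifications ``AMRI``) and whose leaves
are individual features.  Each leaf carries tags that drive pair-specific
feature filtering at training time:

``modality``
    One of ``NP``, ``CSF``, ``VMRI``, ``AMRI``.
``structural``
    Whether the feature measures structural brain change.  Structural
    features are excluded from every pairwise classification involving the
    vascular-dementia class, because vascular dementia has no specific
    structural signature.
``pair_restriction``
    Optional set of unordered class pairs.  Features generated specifically
    to separate one class pair (e.g. pairwise tensor- or voxel-based
    morphometry scores) are only used for that pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

MODALITIES = ("NP", "CSF", "VMRI", "AMRI")


@dataclass(frozen=True)
class FeatureLeaf:
    """A single feature with its filtering tags."""

    name: str
    modality: str
    structural: bool = False
    pair_restriction: frozenset[frozenset[str]] | None = None

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(
                f"feature {self.name!r}: unknown modality {self.modality!r}; "
                f"expected one of {MODALITIES}"
            )

    def allowed_for_pair(self, i: str, j: str, vascular_class: str | None) -> bool:
        """Whether this leaf may be used when classifying class i vs class j."""
        if self.pair_restriction is not None and frozenset((i, j)) not in self.pair_restriction:
            return False
        if self.structural and vascular_class is not None and vascular_class in (i, j):
            return False
        return True

    def to_dict(self) -> dict:
        d: dict = {"modality": self.modality, "structural": self.structural}
        if self.pair_restriction is not None:
            d["pair_restriction"] = [sorted(p) for p in self.pair_restriction]
        return d


@dataclass
class FeatureGroup:
    """A named internal node holding leaves and/or sub-groups."""

    name: str
    children: list["FeatureGroup | FeatureLeaf"] = field(default_factory=list)

    def leaves(self) -> Iterator[FeatureLeaf]:
        for child in self.children:
            if isinstance(child, FeatureLeaf):
                yield child
            else:
                yield from child.leaves()


class FeatureHierarchy:
    """Rooted tree of feature groups; validates uniqueness and tags."""

    def __init__(self, root: FeatureGroup):
        self.root = root
        names = [leaf.name for leaf in root.leaves()]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"features appear in more than one leaf: {dupes}")
        if not names:
            raise ValueError("hierarchy has no feature leaves")

    @property
    def feature_names(self) -> list[str]:
        return [leaf.name for leaf in self.root.leaves()]

    def leaves(self) -> list[FeatureLeaf]:
        return list(self.root.leaves())

    def modality_of(self) -> dict[str, str]:
        """Map feature name -> modality tag."""
        return {leaf.name: leaf.modality for leaf in self.root.leaves()}

    def prune(self, keep: Callable[[FeatureLeaf], bool]) -> "FeatureHierarchy | None":
        """New hierarchy retaining only leaves satisfying ``keep``.

        Internal nodes left with no descendants are dropped.  Returns None if
        nothing survives.
        """

        def _prune(node: FeatureGroup) -> FeatureGroup | None:
            kept: list[FeatureGroup | FeatureLeaf] = []
            for child in node.children:
                if isinstance(child, FeatureLeaf):
                    if keep(child):
                        kept.append(child)
                else:
                    sub = _prune(child)
                    if sub is not None:
                        kept.append(sub)
            if not kept:
                return None
            return FeatureGroup(node.name, kept)

        pruned = _prune(self.root)
        if pruned is None:
            return None
        return FeatureHierarchy(pruned)

    def restrict_to_modalities(self, modalities) -> "FeatureHierarchy | None":
        mods = set(modalities)
        unknown = mods - set(MODALITIES)
        if unknown:
            raise ValueError(f"unknown modalities: {sorted(unknown)}")
        return self.prune(lambda leaf: leaf.modality in mods)

    # -- config round-trip ---------------------------------------------------

    @classmethod
    def from_dict(cls, spec: dict) -> "FeatureHierarchy":
        """Build from a config mapping ``group name -> group spec``.

        Each group spec may contain a ``modality`` default for its features, a
        ``features`` mapping of ``name -> {structural, pair_restriction}`` and
        nested ``groups``.
        """

        def _group(name: str, gspec: dict, inherited_modality: str | None) -> FeatureGroup:
            modality = gspec.get("modality", inherited_modality or name)
            children: list[FeatureGroup | FeatureLeaf] = []
            for fname, fspec in (gspec.get("features") or {}).items():
                fspec = fspec or {}
                restriction = fspec.get("pair_restriction")
                if restriction is not None:
                    restriction = frozenset(frozenset(pair) for pair in restriction)
                children.append(
                    FeatureLeaf(
                        name=fname,
                        modality=fspec.get("modality", modality),
                        structural=bool(fspec.get("structural", False)),
                        pair_restriction=restriction,
                    )
                )
            for gname, sub in (gspec.get("groups") or {}).items():
                children.append(_group(gname, sub or {}, modality))
            return FeatureGroup(name, children)

        root = FeatureGroup("all", [_group(name, gspec or {}, None) for name, gspec in spec.items()])
        return cls(root)

    def to_dict(self) -> dict:
        def _node(node: FeatureGroup) -> dict:
            out: dict = {}
            feats = {c.name: c.to_dict() for c in node.children if isinstance(c, FeatureLeaf)}
            groups = {c.name: _node(c) for c in node.children if isinstance(c, FeatureGroup)}
            if feats:
                out["features"] = feats
            if groups:
                out["groups"] = groups
            return out

        return {c.name: _node(c) if isinstance(c, FeatureGroup) else {"features": {c.name: c.to_dict()}}
                for c in self.root.children}
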