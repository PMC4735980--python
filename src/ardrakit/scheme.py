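"""Greedy construction and traversal of restriction-enzyme identification keys.

The scheme builder turns a restriction map (taxa x enzymes -> band patterns)
into a decision tree.  At each node it picks, from the enzymes not yet used on
the path, the one that splits the node's group of taxa into the largest number
of classes — an enzyme under which every taxon shows a different band count
would identify them all in a single digest, while an enzyme giving everyone
the same count carries no information.  The group is partitioned by observed
class and the builder recurses until groups are singletons (``identified``
leaves) or no remaining enzyme can split them (``indistinguishable`` leaves).

Two discrimination modes are supported:

* ``count_only`` — a class is a band *count*; this is what a quick gel read
  gives.
* ``count_and_length`` — a class is the (count, band-length profile) pair,
  with two profiles considered equal when every positionally matched pair of
  lengths differs by less than ``merge_delta``.  Folding lengths into enzyme
  selection (not merely into tie-breaking at stuck nodes) is what lets
  fewer enzymes suffice; the same tolerance is used at identification time,
  since a gel cannot resolve at lookup what it could not resolve in a lane.

Identification replays the tree against observed patterns (measured on a gel,
or computed in silico from an unknown sequence).  An observation matching no
branch at some node means the unknown is not in the scheme's population and
identification fails explicitly.

Enzyme selection ties are broken by lexicographic enzyme name; the greedy
makes no optimality promise, but determinism makes schemes reproducible
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

from .digestion import BandPattern
from .errors import ValidationError
from .restriction_map import RestrictionMap

MODES = ("count_only", "count_and_length")

SCHEME_FORMAT = "ardrakit-scheme"
SCHEME_VERSION = 1


@dataclass(frozen=True)
class BranchKey:
    """The observation labelling an edge: a band count, optionally with the
    band-length profile (descending lengths)."""

    count: int
    profile: "tuple[int, ...] | None" = None

    def matches(self, pattern: BandPattern, merge_delta: int) -> bool:
        """Does an observed pattern take this branch?

        Counts must agree exactly; in count-and-length mode each band must
        additionally be within ``merge_delta`` of the stored profile band.
        """
        if pattern.count != self.count:
            return False
        if self.profile is None:
            return True
        return all(abs(a - b) < merge_delta
                   for a, b in zip(self.profile, pattern.bands))

    def label(self) -> str:
        if self.profile is None:
            return str(self.count)
        return f"{self.count}:" + ",".join(map(str, self.profile))


@dataclass
class SchemeNode:
    """A node of the identification tree.

    Internal nodes carry the enzyme to apply and children keyed by the
    observation; leaves carry a status: ``identified`` (singleton group) or
    ``indistinguishable`` (no enzyme can split the group).
    """

    group: tuple[str, ...]
    enzyme: "str | None" = None
    n_classes: int = 1
    children: "dict[BranchKey, SchemeNode]" = field(default_factory=dict)
    leaf_status: str = "none"  # identified | indistinguishable | none

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class IdentificationScheme:
    """A finished identification key plus its bookkeeping.

    ``enzymes_used`` counts distinct enzymes anywhere in the tree (the full
    panel a lab must stock); ``max_path``/``min_path`` are the most and
    fewest digests any single taxon needs.
    """

    root: SchemeNode
    mode: str
    gene: str
    enzyme_pool: tuple[str, ...]
    entry_members: dict[str, tuple[str, ...]]
    merge_delta: int
    min_fragment: int
    enzymes_used: tuple[str, ...] = ()
    max_path: int = 0
    min_path: int = 0


@dataclass(frozen=True)
class IdentificationResult:
    """Outcome of a traversal: the matched member names and the enzymes
    applied with the observation that chose each branch."""

    status: str  # identified | indistinguishable_set | failed
    members: tuple[str, ...]
    path: tuple[tuple[str, str], ...]


def _profile_key(pattern: BandPattern, mode: str) -> BranchKey:
    if mode == "count_only":
        return BranchKey(pattern.count)
    return BranchKey(pattern.count, pattern.bands)


def partition_group(group: Sequence[str], enzyme_name: str, rmap: RestrictionMap,
                    mode: str, merge_delta: "int | None" = None
                    ) -> dict[BranchKey, tuple[str, ...]]:
    """Split a group of entries by what one enzyme's digest would show.

    In count-only mode the class is the band count.  In count-and-length
    mode entries join the first existing class whose representative profile
    they match within ``merge_delta`` (near-equality is not transitive, so
    classes are seeded greedily in sorted entry order — deterministic).
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")
    if enzyme_name not in rmap.enzyme_names:
        raise KeyError(f"enzyme {enzyme_name!r} not in restriction map")
    delta = rmap.merge_delta if merge_delta is None else merge_delta
    classes: dict[BranchKey, list[str]] = {}
    for entry_id in sorted(group):
        pat = rmap.pattern(entry_id, enzyme_name)
        placed = False
        for key, members in classes.items():
            if key.matches(pat, delta) if mode == "count_and_length" \
                    else key.count == pat.count:
                members.append(entry_id)
                placed = True
                break
        if not placed:
            classes[_profile_key(pat, mode)] = [entry_id]
    return {k: tuple(v) for k, v in classes.items()}


def select_enzyme(group: Sequence[str], rmap: RestrictionMap, mode: str,
                  used_on_path: "frozenset[str] | set[str]" = frozenset(),
                  merge_delta: "int | None" = None) -> tuple["str | None", int]:
    """Pick the most discriminative unused enzyme for a group.

    Returns ``(enzyme_name, n_classes)`` maximizing the number of classes the
    enzyme induces on the group; ties go to the lexicographically first name.
    Returns ``(None, 1)`` when no candidate splits the group at all.
    """
    best_name: "str | None" = None
    best_classes = 1
    for name in sorted(set(rmap.enzyme_names) - set(used_on_path)):
        n = len(partition_group(group, name, rmap, mode, merge_delta))
        if n > best_classes:
            best_name, best_classes = name, n
    return best_name, best_classes


def create_scheme(rmap: RestrictionMap, mode: str = "count_only",
                  gene: str = "") -> IdentificationScheme:
    """Build the identification tree for a restriction map.

    The root group is the whole population (before any digest every sample is
    one intact fragment, so nothing is yet distinguished).  Construction is
    fully deterministic: the same map and mode always serialize to the same
    bytes.
    """
    if mode not in MODES:
        raise ValidationError(f"unknown mode {mode!r}; expected one of {MODES}")

    def build(group: tuple[str, ...], used: frozenset[str]) -> SchemeNode:
        if len(group) == 1:
            return SchemeNode(group, leaf_status="identified")
        enzyme, n_classes = select_enzyme(group, rmap, mode, used)
        if enzyme is None or n_classes < 2:
            return SchemeNode(group, leaf_status="indistinguishable")
        parts = partition_group(group, enzyme, rmap, mode)
        children = {key: build(sub, used | {enzyme})
                    for key, sub in parts.items()}
        return SchemeNode(group, enzyme, n_classes, children)

    root = build(tuple(sorted(rmap.entry_ids)), frozenset())

    used: set[str] = set()
    depths: list[int] = []

    def walk(node: SchemeNode, depth: int) -> None:
        if node.is_leaf:
            depths.append(depth)
            return
        used.add(node.enzyme)
        for child in node.children.values():
            walk(child, depth + 1)

    walk(root, 0)
    return IdentificationScheme(
        root=root, mode=mode, gene=gene,
        enzyme_pool=tuple(rmap.enzyme_names),
        entry_members={e.entry_id: e.member_names for e in rmap.entries},
        merge_delta=rmap.merge_delta, min_fragment=rmap.min_fragment,
        enzymes_used=tuple(sorted(used)),
        max_path=max(depths), min_path=min(depths),
    )


PatternProvider = Callable[[str], BandPattern]


def identify(scheme: IdentificationScheme,
             pattern_provider: "PatternProvider | Mapping[str, BandPattern]"
             ) -> IdentificationResult:
    """Traverse the scheme against observed band patterns.

    ``pattern_provider`` maps an enzyme name to the observed pattern — either
    a dict of measurements or a callable (e.g. an in-silico digest of a
    candidate sequence).  A missing enzyme raises ``KeyError`` naming it: in
    lab use that is the instruction "run this digest next".
    """
    if isinstance(pattern_provider, Mapping):
        provider = pattern_provider.__getitem__
    else:
        provider = pattern_provider

    def members_of(group: Sequence[str]) -> tuple[str, ...]:
        out: list[str] = []
        for entry_id in group:
            out.extend(scheme.entry_members.get(entry_id, (entry_id,)))
        return tuple(out)

    node = scheme.root
    path: list[tuple[str, str]] = []
    while not node.is_leaf:
        try:
            observed = provider(node.enzyme)
        except KeyError:
            raise KeyError(
                f"no observed pattern for enzyme {node.enzyme!r}; "
                f"apply this digest next") from None
        next_node = None
        for key, child in node.children.items():
            if key.matches(observed, scheme.merge_delta):
                next_node = child
                path.append((node.enzyme, key.label()))
                break
        if next_node is None:
            path.append((node.enzyme, _profile_key(observed, scheme.mode).label()))
            return IdentificationResult("failed", (), tuple(path))
        node = next_node
    if node.leaf_status == "identified":
        return IdentificationResult("identified", members_of(node.group),
                                    tuple(path))
    return IdentificationResult("indistinguishable_set", members_of(node.group),
                                tuple(path))


def patterns_from_sequence(seq, rmap_or_enzymes, min_fragment: int,
                           merge_delta: int) -> dict[str, BandPattern]:
    """In-silico pattern provider for an unknown sequence: digest it with
    every enzyme of a map or enzyme collection."""
    from .digestion import RestrictionEnzyme, digest_linear, to_band_pattern
    if isinstance(rmap_or_enzymes, RestrictionMap):
        enzymes = rmap_or_enzymes.enzymes
    else:
        enzymes = tuple(rmap_or_enzymes)
    return {
        z.name: to_band_pattern(digest_linear(seq, z).raw_fragments,
                                min_fragment, merge_delta)
        for z in enzymes
    }


def patterns_from_copies(seqs: Sequence, rmap_or_enzymes, min_fragment: int,
                         merge_delta: int) -> dict[str, BandPattern]:
    """Pooled in-silico pattern provider for one isolate's gene copies.

    All copies of a multi-copy marker are amplified and digested together in
    the lab, so the observable lane is the pooled pattern — the counterpart
    of how map cells are built for multi-copy entries.
    """
    from .digestion import RestrictionEnzyme, pool_bands
    if isinstance(rmap_or_enzymes, RestrictionMap):
        enzymes = rmap_or_enzymes.enzymes
    else:
        enzymes = tuple(rmap_or_enzymes)
    per_copy = [patterns_from_sequence(s, enzymes, min_fragment, merge_delta)
                for s in seqs]
    return {z.name: pool_bands([p[z.name] for p in per_copy], merge_delta)
            for z in enzymes}


# ---------------------------------------------------------------------------
# serialization

def _node_to_json(node: SchemeNode) -> dict:
    return {
        "group": list(node.group),
        "enzyme": node.enzyme,
        "n_classes": node.n_classes,
        "leaf_status": node.leaf_status,
        "children": [
            {"key": {"count": k.count,
                     "bands": list(k.profile) if k.profile is not None else None},
             "node": _node_to_json(child)}
            for k, child in node.children.items()
        ],
    }


def _node_from_json(obj: dict) -> SchemeNode:
    if not isinstance(obj, dict) or "group" not in obj:
        raise ValidationError("scheme JSON: malformed node record")
    children: dict[BranchKey, SchemeNode] = {}
    for rec in obj.get("children", []):
        key = rec.get("key", {})
        if "count" not in key:
            raise ValidationError("scheme JSON: branch key missing 'count'")
        bands = key.get("bands")
        bk = BranchKey(int(key["count"]),
                       tuple(int(b) for b in bands) if bands is not None else None)
        children[bk] = _node_from_json(rec["node"])
    return SchemeNode(
        group=tuple(obj["group"]),
        enzyme=obj.get("enzyme"),
        n_classes=int(obj.get("n_classes", 1)),
        children=children,
        leaf_status=obj.get("leaf_status", "none"),
    )


def save_scheme(scheme: IdentificationScheme, path: "str | Path") -> None:
    """Serialize a scheme to versioned JSON (stable key order)."""
    doc = {
        "format": SCHEME_FORMAT,
        "version": SCHEME_VERSION,
        "mode": scheme.mode,
        "gene": scheme.gene,
        "enzyme_pool": list(scheme.enzyme_pool),
        "entry_members": {k: list(v) for k, v in scheme.entry_members.items()},
        "merge_delta": scheme.merge_delta,
        "min_fragment": scheme.min_fragment,
        "enzymes_used": list(scheme.enzymes_used),
        "max_path": scheme.max_path,
        "min_path": scheme.min_path,
        "root": _node_to_json(scheme.root),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_scheme(path: "str | Path") -> IdentificationScheme:
    """Load and validate a scheme JSON file."""
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"{path}: not valid JSON: {exc}") from exc
    if doc.get("format") != SCHEME_FORMAT:
        raise ValidationError(f"{path}: not a scheme file (format "
                              f"{doc.get('format')!r})")
    if doc.get("version") != SCHEME_VERSION:
        raise ValidationError(f"{path}: unsupported scheme version "
                              f"{doc.get('version')!r}")
    for req in ("mode", "root", "enzyme_pool", "merge_delta", "min_fragment"):
        if req not in doc:
            raise ValidationError(f"{path}: scheme JSON missing {req!r}")
    if doc["mode"] not in MODES:
        raise ValidationError(f"{path}: unknown mode {doc['mode']!r}")
    return IdentificationScheme(
        root=_node_from_json(doc["root"]),
        mode=doc["mode"],
        gene=doc.get("gene", ""),
        enzyme_pool=tuple(doc["enzyme_pool"]),
        entry_members={k: tuple(v)
                       for k, v in doc.get("entry_members", {}).items()},
        merge_delta=int(doc["merge_delta"]),
        min_fragment=int(doc["min_fragment"]),
        enzymes_used=tuple(doc.get("enzymes_used", ())),
        max_path=int(doc.get("max_path", 0)),
        min_path=int(doc.get("min_path", 0)),
    )


def export_dot(scheme: IdentificationScheme, path: "str | Path") -> None:
    """Write the tree as Graphviz DOT: one node per tree node, edges labelled
    with the branch observation."""
    lines = ["digraph identification_scheme {", '  node [shape=box];']
    counter = [0]

    def emit(node: SchemeNode) -> str:
        name = f"n{counter[0]}"
        counter[0] += 1
        if node.is_leaf:
            label = "\\n".join(
                m for e in node.group
                for m in scheme.entry_members.get(e, (e,)))
            shape = "ellipse" if node.leaf_status == "identified" else "octagon"
            lines.append(f'  {name} [label="{label}", shape={shape}];')
        else:
            lines.append(f'  {name} [label="{node.enzyme}"];')
        for key, child in node.children.items():
            child_name = emit(child)
            lines.append(f'  {name} -> {child_name} [label="{key.label()}"];')
        return name

    emit(scheme.root)
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
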