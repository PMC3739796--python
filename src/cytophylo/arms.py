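"""Permutation model of polytene chromosome-arm banding sequences.

A chromosome arm is represented as an ordered sequence of uniquely labelled
segments (a :class:`SegmentOrder`).  Paracentric inversions act on the order
by reversing a contiguous window of segments (:class:`Reversal`,
:func:`apply_reversal`).  The model is *unsigned*: published banding notation
tracks only the order of lettered fragments, not within-fragment orientation,
and an arm has a fixed centromere-to-telomere reading direction, so an order
and its mirror image are distinct.

Named rearrangements (inversions, band enhancements, heterochromatic blocks,
supernumerary chromosomes) live in a registry of :class:`NamedRearrangement`
records; only inversions may carry a coordinate window, defined relative to a
stated reference arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import (
    ComparabilityError,
    FormatError,
    NoDifferenceError,
    NotOneStepError,
    RegistryError,
    WindowError,
)

ARM_IDS = ("IS", "IL", "IIS", "IIL", "IIIS", "IIIL")

REARRANGEMENT_KINDS = (
    "inversion",
    "band_enhancement",
    "heterochromatic_block",
    "supernumerary",
)

# Characters stripped on parse: the bracket/pipe notation used in published
# stepwise derivations carries no machine information.
_NOTATION_CHARS = "|[]*"


@dataclass(frozen=True)
class SegmentOrder:
    """Ordered segment labels for one chromosome arm.

    Parameters
    ----------
    arm_id :
        Arm label, one of ``IS, IL, IIS, IIL, IIIS, IIIL``.
    segments :
        Ordered sequence of unique, opaque segment labels.  Published worked
        examples use single letters ``a``–``n``.

    Notes
    -----
    Two orders are comparable (for distances, window inference, breakpoint
    counts) only if they share the same arm and the same label set.
    """

    arm_id: str
    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise FormatError("empty segment order")
        seen: set[str] = set()
        for s in self.segments:
            if s in seen:
                raise FormatError(f"duplicate segment label {s!r}")
            seen.add(s)
        object.__setattr__(self, "segments", tuple(self.segments))

    def __len__(self) -> int:
        return len(self.segments)

    def label_set(self) -> frozenset[str]:
        return frozenset(self.segments)

    def is_comparable(self, other: "SegmentOrder") -> bool:
        return self.arm_id == other.arm_id and self.label_set() == other.label_set()


@dataclass(frozen=True)
class Reversal:
    """Half-open window ``[start, end)`` reversed by one inversion.

    Coordinates are 0-based; ``end - start >= 2`` is required because a
    one-segment window is a no-op in the unsigned model and almost certainly a
    data-entry error.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise WindowError(f"invalid window [{self.start}, {self.end})")
        if self.end - self.start < 2:
            raise WindowError(
                f"window [{self.start}, {self.end}) spans a single segment; "
                "a one-segment reversal is a no-op in the unsigned model"
            )

    def check_against(self, order: SegmentOrder) -> None:
        if self.end > len(order):
            raise WindowError(
                f"window [{self.start}, {self.end}) exceeds order length {len(order)}"
            )


@dataclass(frozen=True)
class NamedRearrangement:
    """Registry entry for a named chromosomal rearrangement.

    ``id`` follows the field convention ``<arm>-<number>`` (e.g. ``IIIL-38``)
    or a marker suffix (``IL-eb``, ``IIIS-hb1``).  Only ``kind="inversion"``
    entries may carry a window, expressed relative to the arrangement named in
    ``ref_arrangement``.
    """

    id: str
    arm_id: str
    kind: str
    window: Reversal | None = None
    ref_arrangement: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in REARRANGEMENT_KINDS:
            raise FormatError(f"unknown rearrangement kind {self.kind!r}")
        if self.window is not None and self.kind != "inversion":
            raise FormatError(
                f"{self.id}: only inversions may carry a window (kind={self.kind})"
            )


@dataclass
class Registry:
    """Collection of named rearrangements with unique ids."""

    entries: dict[str, NamedRearrangement] = field(default_factory=dict)

    def add(self, entry: NamedRearrangement) -> None:
        if entry.id in self.entries:
            raise RegistryError(f"duplicate rearrangement id {entry.id!r}")
        self.entries[entry.id] = entry

    def resolve(self, rid: str) -> NamedRearrangement:
        try:
            return self.entries[rid]
        except KeyError:
            raise RegistryError(f"rearrangement id {rid!r} not in registry") from None

    def __contains__(self, rid: str) -> bool:
        return rid in self.entries

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def ids(self) -> list[str]:
        return list(self.entries)


def parse_arrangement(
    text: str, arm_id: str, *, delimiter: str | None = None
) -> SegmentOrder:
    """Parse an arrangement string into a :class:`SegmentOrder`.

    Whitespace, pipes and brackets (the published derivation notation) are
    ignored.  By default each remaining character is one segment label; pass
    ``delimiter=","`` for multi-character tokens.

    Raises
    ------
    FormatError
        If the input is empty after stripping, or a label repeats.
    """
    cleaned = text.strip()
    for ch in _NOTATION_CHARS:
        cleaned = cleaned.replace(ch, " ")
    if delimiter is None:
        tokens = [ch for ch in cleaned if not ch.isspace()]
    else:
        tokens = [t.strip() for t in cleaned.split(delimiter) if t.strip()]
    if not tokens:
        raise FormatError("empty arrangement text")
    return SegmentOrder(arm_id=arm_id, segments=tuple(tokens))


def format_arrangement(order: SegmentOrder, *, delimiter: str = "") -> str:
    """Canonical writer: concatenated labels (or delimiter-joined tokens)."""
    return delimiter.join(order.segments)


def apply_reversal(order: SegmentOrder, rev: Reversal) -> SegmentOrder:
    """Return a new order with ``[rev.start, rev.end)`` reversed.

    The operation is an involution: applying the same window twice restores
    the original order.
    """
    rev.check_against(order)
    seg = order.segments
    new = seg[: rev.start] + tuple(reversed(seg[rev.start : rev.end])) + seg[rev.end :]
    return SegmentOrder(arm_id=order.arm_id, segments=new)


def _check_comparable(a: SegmentOrder, b: SegmentOrder) -> None:
    if not a.is_comparable(b):
        raise ComparabilityError(
            f"orders not comparable: arm {a.arm_id!r} vs {b.arm_id!r}, "
            f"labels {sorted(a.label_set())} vs {sorted(b.label_set())}"
        )


def infer_window(reference: SegmentOrder, derived: SegmentOrder) -> Reversal:
    """Find the unique reversal carrying ``reference`` onto ``derived``.

    Used to register named inversions from pairs of published arrangements.

    Raises
    ------
    NoDifferenceError
        If the two orders are identical.
    NotOneStepError
        If no single reversal explains the difference (the caller should fall
        back to multi-step scenario search).
    """
    _check_comparable(reference, derived)
    ref, der = reference.segments, derived.segments
    if ref == der:
        raise NoDifferenceError("orders are identical; no window to infer")
    n = len(ref)
    start = 0
    while ref[start] == der[start]:
        start += 1
    end = n
    while ref[end - 1] == der[end - 1]:
        end -= 1
    # The mismatching core must be exactly reversed.
    if ref[start:end] != tuple(reversed(der[start:end])):
        raise NotOneStepError(
            "no single reversal transforms the reference into the derived order"
        )
    return Reversal(start=start, end=end)


# Sentinel anchors flanking an arrangement; adjacency to an anchor encodes
# "first"/"last" position so terminal moves count as breakpoints too.
class _Anchor:
    __slots__ = ("_name",)

    def __init__(self, name: str) -> None:
        self._name = name

    def __repr__(self) -> str:  # pragma: no cover
        return self._name


_LEFT = _Anchor("<left>")
_RIGHT = _Anchor("<right>")


def adjacency_set(segments: Sequence[str]) -> frozenset[frozenset]:
    """Unordered adjacency pairs of a sequence, with virtual end anchors."""
    chain = (_LEFT, *segments, _RIGHT)
    return frozenset(frozenset(p) for p in zip(chain, chain[1:]))


def breakpoint_count(order: SegmentOrder, reference: SegmentOrder) -> int:
    """Number of adjacencies of ``order`` absent from ``reference``.

    Adjacency is orientation-free (``xy`` matches ``yx``) and includes the
    virtual anchor pairs before the first and after the last segment, so the
    count is symmetric in its arguments and zero iff the orders are equal.
    Each reversal can repair at most two breakpoints, making
    ``ceil(breakpoints / 2)`` an admissible lower bound on reversal distance.
    """
    _check_comparable(order, reference)
    ref_adj = adjacency_set(reference.segments)
    chain = (_LEFT, *order.segments, _RIGHT)
    return sum(1 for p in zip(chain, chain[1:]) if frozenset(p) not in ref_adj)


# ---------------------------------------------------------------------------
# File formats


def read_arrangement_file(
    path: str | Path, arm_id: str = "IIIL", *, delimiter: str | None = None
) -> dict[str, SegmentOrder]:
    """Read a ``name<TAB>segments`` arrangement file ('#' comments allowed)."""
    out: dict[str, SegmentOrder] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        try:
            name, text = line.split("\t", 1)
        except ValueError:
            raise FormatError(f"{path}:{lineno}: expected '<name>\\t<segments>'")
        if name in out:
            raise FormatError(f"{path}:{lineno}: duplicate arrangement name {name!r}")
        out[name] = parse_arrangement(text, arm_id, delimiter=delimiter)
    return out


def write_arrangement_file(
    path: str | Path, arrangements: Mapping[str, SegmentOrder]
) -> None:
    lines = ["# name\tsegments"]
    for name, order in arrangements.items():
        lines.append(f"{name}\t{format_arrangement(order)}")
    Path(path).write_text("\n".join(lines) + "\n")


_REGISTRY_HEADER = ["id", "arm", "kind", "ref_arrangement_name", "start", "end"]


def read_registry(path: str | Path) -> Registry:
    """Read a rearrangement registry TSV (columns: id, arm, kind,
    ref_arrangement_name, start, end; start/end blank for non-inversions or
    windowless inversions)."""
    reg = Registry()
    lines = [
        ln
        for ln in Path(path).read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines or lines[0].split("\t") != _REGISTRY_HEADER:
        raise FormatError(f"{path}: missing or wrong registry header")
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != 6:
            raise FormatError(f"{path}:{lineno}: expected 6 tab-separated fields")
        rid, arm, kind, ref_name, start, end = (f.strip() for f in fields)
        window = None
        if start or end:
            try:
                window = Reversal(start=int(start), end=int(end))
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer window bounds")
        reg.add(
            NamedRearrangement(
                id=rid,
                arm_id=arm,
                kind=kind,
                window=window,
                ref_arrangement=ref_name or None,
            )
        )
    return reg


def write_registry(path: str | Path, registry: Registry | Iterable[NamedRearrangement]) -> None:
    lines = ["\t".join(_REGISTRY_HEADER)]
    for e in registry:
        start = str(e.window.start) if e.window else ""
        end = str(e.window.end) if e.window else ""
        lines.append(
            "\t".join([e.id, e.arm_id, e.kind, e.ref_arrangement or "", start, end])
        )
    Path(path).write_text("\n".join(lines) + "\n")
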