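"""Coronary vessel-tree data model and I/O.

A coronary system is represented as a forest of tube segments rooted at the
aortic ostia: every segment has a length and a mean radius (both in cm, CGS
throughout), belongs to one of the three main arteries (LAD, LCX, RCA), and
optionally carries a stenosis flag and/or a distal pressure-measurement site.
Stenosis severity is encoded implicitly by ``mean_radius_cm``, which is the
mean lumen radius averaged along the lesion — there is no separate lesion
object.

Files are stored in a fixed CSV dialect (exact header, ``true``/``false``
booleans, empty string for a null parent) or an equivalent JSON form, and
round-trip exactly.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from .errors import FormatError, SiteLookupError, TopologyError

__all__ = [
    "Artery",
    "VesselSegment",
    "CoronaryTree",
    "load_tree",
    "save_tree",
    "path_to_site",
    "CSV_HEADER",
]


class Artery(str, Enum):
    """The three main coronary arteries."""

    LAD = "LAD"
    LCX = "LCX"
    RCA = "RCA"


CSV_HEADER = [
    "segment_id",
    "parent_id",
    "artery",
    "length_cm",
    "mean_radius_cm",
    "has_stenosis",
    "is_measurement_site",
    "site_distance_cm",
]


@dataclass(frozen=True)
class VesselSegment:
    """One tube element of the coronary tree.

    ``parent_id is None`` means the segment attaches directly to the aortic
    root. ``site_distance_cm`` is the ostium-to-measurement-site length and is
    required exactly when ``is_measurement_site`` is set.
    """

    segment_id: str
    parent_id: str | None
    artery: Artery
    length_cm: float
    mean_radius_cm: float
    has_stenosis: bool = False
    is_measurement_site: bool = False
    site_distance_cm: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "artery", Artery(self.artery))
        if not self.segment_id:
            raise ValueError("segment_id must be non-empty")
        if not (self.length_cm > 0):
            raise ValueError(
                f"segment {self.segment_id}: length_cm must be > 0, "
                f"got {self.length_cm}"
            )
        if not (self.mean_radius_cm > 0):
            raise ValueError(
                f"segment {self.segment_id}: mean_radius_cm must be > 0, "
                f"got {self.mean_radius_cm}"
            )
        if self.is_measurement_site:
            if self.site_distance_cm is None or self.site_distance_cm < 0:
                raise ValueError(
                    f"segment {self.segment_id}: measurement sites require "
                    "site_distance_cm >= 0"
                )
        elif self.site_distance_cm is not None:
            raise ValueError(
                f"segment {self.segment_id}: site_distance_cm given but "
                "is_measurement_site is false"
            )


@dataclass
class CoronaryTree:
    """A validated forest of vessel segments under a common aortic root."""

    segments: list[VesselSegment]
    _index: dict[str, VesselSegment] = field(init=False, repr=False)
    _children: dict[str, list[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {}
        for seg in self.segments:
            if seg.segment_id in self._index:
                raise TopologyError(f"duplicate segment id {seg.segment_id!r}")
            self._index[seg.segment_id] = seg
        self._children = {s.segment_id: [] for s in self.segments}
        for seg in self.segments:
            if seg.parent_id is not None:
                if seg.parent_id not in self._index:
                    raise TopologyError(
                        f"segment {seg.segment_id!r} references unknown parent "
                        f"{seg.parent_id!r}"
                    )
                self._children[seg.parent_id].append(seg.segment_id)
        self._validate()

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        if not self.segments:
            raise TopologyError("tree has no segments")
        # cycle check + artery consistency by walking each parent chain
        for seg in self.segments:
            seen = {seg.segment_id}
            cur = seg
            while cur.parent_id is not None:
                if cur.parent_id in seen:
                    raise TopologyError(
                        f"cycle detected through segment {seg.segment_id!r}"
                    )
                seen.add(cur.parent_id)
                parent = self._index[cur.parent_id]
                if parent.artery != cur.artery:
                    raise TopologyError(
                        f"segment {cur.segment_id!r} ({cur.artery.value}) has "
                        f"parent in a different artery ({parent.artery.value})"
                    )
                cur = parent
        for seg in self.segments:
            if seg.is_measurement_site:
                total = self.cumulative_length_cm(seg.segment_id)
                if seg.site_distance_cm is not None and (
                    seg.site_distance_cm > total + 1e-9
                ):
                    raise ValueError(
                        f"site {seg.segment_id!r}: site_distance_cm "
                        f"{seg.site_distance_cm} exceeds cumulative ostium "
                        f"distance {total}"
                    )

    # -- queries -----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.segments)

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self._index

    def get(self, segment_id: str) -> VesselSegment:
        try:
            return self._index[segment_id]
        except KeyError:
            raise SiteLookupError(f"unknown segment id {segment_id!r}") from None

    def children(self, segment_id: str) -> list[VesselSegment]:
        return [self._index[c] for c in self._children[segment_id]]

    @property
    def roots(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.parent_id is None]

    def roots_of(self, artery: Artery | str) -> list[VesselSegment]:
        artery = Artery(artery)
        return [s for s in self.roots if s.artery == artery]

    @property
    def arteries_present(self) -> list[Artery]:
        present = {s.artery for s in self.segments}
        return [a for a in Artery if a in present]

    def artery_segments(self, artery: Artery | str) -> list[VesselSegment]:
        artery = Artery(artery)
        return [s for s in self.segments if s.artery == artery]

    def leaves(self) -> list[VesselSegment]:
        return [s for s in self.segments if not self._children[s.segment_id]]

    @property
    def measurement_sites(self) -> list[VesselSegment]:
        return [s for s in self.segments if s.is_measurement_site]

    def path_from_root(self, segment_id: str) -> list[VesselSegment]:
        """Ostium-to-segment chain, root first."""
        chain: list[VesselSegment] = []
        cur = self.get(segment_id)
        while True:
            chain.append(cur)
            if cur.parent_id is None:
                break
            cur = self._index[cur.parent_id]
        chain.reverse()
        return chain

    def cumulative_length_cm(self, segment_id: str) -> float:
        return math.fsum(s.length_cm for s in self.path_from_root(segment_id))


# -- I/O -------------------------------------------------------------------


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "json"):
            raise ValueError(f"unknown tree format {fmt!r}")
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def _parse_bool(raw: str, where: str) -> bool:
    if raw == "true":
        return True
    if raw == "false":
        return False
    raise FormatError(f"{where}: booleans must be 'true'/'false', got {raw!r}")


def _segment_from_record(rec: dict, where: str) -> VesselSegment:
    try:
        parent = rec["parent_id"]
        if parent in ("", None):
            parent = None
        site_dist = rec["site_distance_cm"]
        if site_dist in ("", None):
            site_dist = None
        else:
            site_dist = float(site_dist)
        has_sten = rec["has_stenosis"]
        is_site = rec["is_measurement_site"]
        if isinstance(has_sten, str):
            has_sten = _parse_bool(has_sten, where)
        if isinstance(is_site, str):
            is_site = _parse_bool(is_site, where)
        return VesselSegment(
            segment_id=str(rec["segment_id"]),
            parent_id=parent,
            artery=Artery(rec["artery"]),
            length_cm=float(rec["length_cm"]),
            mean_radius_cm=float(rec["mean_radius_cm"]),
            has_stenosis=has_sten,
            is_measurement_site=is_site,
            site_distance_cm=site_dist,
        )
    except KeyError as e:
        raise FormatError(f"{where}: missing field {e.args[0]!r}") from None
    except (TypeError, ValueError) as e:
        if isinstance(e, ValueError) and "must be" in str(e):
            raise  # validation error from VesselSegment, not a parse error
        raise FormatError(f"{where}: {e}") from None


def load_tree(path: str | Path, format: str | None = None) -> CoronaryTree:
    """Read a vessel tree from CSV or JSON and validate all invariants.

    Raises :class:`FormatError` for dialect violations, :class:`TopologyError`
    for cycles/orphans, ``ValueError`` for non-positive geometry.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            try:
                header = next(reader)
            except StopIteration:
                raise FormatError(f"{path}: empty file") from None
            if header != CSV_HEADER:
                raise FormatError(
                    f"{path}: bad header {header!r}; expected {CSV_HEADER!r}"
                )
            segments = []
            for i, row in enumerate(reader, start=2):
                if not row:
                    continue
                if len(row) != len(CSV_HEADER):
                    raise FormatError(f"{path}:{i}: expected "
                                      f"{len(CSV_HEADER)} fields, got {len(row)}")
                rec = dict(zip(CSV_HEADER, row))
                segments.append(_segment_from_record(rec, f"{path}:{i}"))
    else:
        with open(path, encoding="utf-8") as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as e:
                raise FormatError(f"{path}: invalid JSON ({e})") from None
        if not isinstance(payload, dict) or "segments" not in payload:
            raise FormatError(f"{path}: JSON must be an object with 'segments'")
        segments = [
            _segment_from_record(rec, f"{path}[segments][{i}]")
            for i, rec in enumerate(payload["segments"])
        ]
    return CoronaryTree(segments)


def _segment_to_record(seg: VesselSegment) -> dict:
    return {
        "segment_id": seg.segment_id,
        "parent_id": "" if seg.parent_id is None else seg.parent_id,
        "artery": seg.artery.value,
        "length_cm": seg.length_cm,
        "mean_radius_cm": seg.mean_radius_cm,
        "has_stenosis": seg.has_stenosis,
        "is_measurement_site": seg.is_measurement_site,
        "site_distance_cm": "" if seg.site_distance_cm is None
        else seg.site_distance_cm,
    }


def save_tree(tree: CoronaryTree, path: str | Path, format: str | None = None) -> None:
    """Write a tree so that :func:`load_tree` reproduces it exactly.

    Floats are written with ``repr`` (shortest round-trip representation).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_HEADER)
            for seg in tree.segments:
                rec = _segment_to_record(seg)
                writer.writerow(
                    [
                        rec["segment_id"],
                        rec["parent_id"],
                        rec["artery"],
                        repr(rec["length_cm"]),
                        repr(rec["mean_radius_cm"]),
                        "true" if rec["has_stenosis"] else "false",
                        "true" if rec["is_measurement_site"] else "false",
                        "" if rec["site_distance_cm"] == ""
                        else repr(rec["site_distance_cm"]),
                    ]
                )
    else:
        payload = {
            "segments": [
                {
                    **_segment_to_record(seg),
                    "parent_id": seg.parent_id,
                    "site_distance_cm": seg.site_distance_cm,
                }
                for seg in tree.segments
            ]
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
            fh.write("\n")


def path_to_site(tree: CoronaryTree, segment_id: str) -> list[VesselSegment]:
    """Ostium-to-measurement-site segment chain, root first.

    The queried segment must be flagged as a measurement site; the chain is
    the set of segments whose Poiseuille resistances (and compliances) are
    accumulated when converting a distal pressure into a local flow rate.
    """
    seg = tree.get(segment_id)
    if not seg.is_measurement_site:
        raise SiteLookupError(f"segment {segment_id!r} is not a measurement site")
    return tree.path_from_root(segment_id)
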