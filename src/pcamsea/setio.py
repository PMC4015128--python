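"""Metabolite-set (pathway) list I/O: two-column CSV, XML, and GMT.

A :class:`MetaboliteSetList` is an ordered mapping from pathway name to a
set of metabolite IDs.  IDs are opaque strings matched by exact,
case-sensitive equality — no synonym resolution or database mapping.

Supported formats:

* two-column CSV — one ``pathway,metabolite`` pair per row, rows grouped
  by pathway in first-appearance order;
* GMT — tab-separated ``name<TAB>description<TAB>member...`` lines;
* an XML dialect: root ``<pathway_list>``, children ``<pathway name=...>``
  with grandchildren ``<metabolite id=...>``, UTF-8.  The write/read pair
  is an exact round trip (names, membership, order).
"""

from __future__ import annotations

import csv
import warnings
import xml.etree.ElementTree as ET
from pathlib import Path

__all__ = [
    "MetaboliteSetList",
    "read_csv_sets",
    "write_csv_sets",
    "read_gmt",
    "write_gmt",
    "read_xml",
    "write_xml",
    "restrict_to_universe",
]


class MetaboliteSetList:
    """Ordered mapping of pathway name -> set of metabolite IDs."""

    def __init__(self, entries=()):
        self._names: list[str] = []
        self._sets: dict[str, set[str]] = {}
        for name, members in entries:
            self.add(name, members)

    def add(self, name: str, members) -> None:
        name = str(name)
        if name in self._sets:
            raise ValueError(f"duplicate pathway name: {name!r}")
        self._names.append(name)
        self._sets[name] = {str(m) for m in members}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def members(self, name: str) -> set[str]:
        return set(self._sets[name])

    def __len__(self) -> int:
        return len(self._names)

    def __iter__(self):
        for name in self._names:
            yield name, set(self._sets[name])

    def __contains__(self, name) -> bool:
        return name in self._sets

    def __eq__(self, other) -> bool:
        if not isinstance(other, MetaboliteSetList):
            return NotImplemented
        return self._names == other._names and self._sets == other._sets

    def __repr__(self) -> str:
        return f"MetaboliteSetList({len(self)} pathways)"


def read_csv_sets(path) -> MetaboliteSetList:
    """Read a two-column pathway,metabolite CSV.

    Rows are grouped by pathway preserving first-appearance order;
    duplicate pairs are deduplicated with a warning.  A row without
    exactly two fields raises with its line number.
    """
    entries: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(row)}"
                )
            name, mid = row[0].strip(), row[1].strip()
            bucket = entries.setdefault(name, [])
            if mid in bucket:
                warnings.warn(
                    f"{path}: line {lineno}: duplicate pair ({name}, {mid})"
                )
            else:
                bucket.append(mid)
    return MetaboliteSetList(entries.items())


def write_csv_sets(sets: MetaboliteSetList, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        for name, members in sets:
            for mid in sorted(members):
                w.writerow([name, mid])


def read_gmt(path) -> MetaboliteSetList:
    """Read a GMT file (name, description, members...); description dropped."""
    entries = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if len(members) != len(set(members)):
                warnings.warn(f"{path}: line {lineno}: duplicate members")
            entries.append((name, members))
    return MetaboliteSetList(entries)


def write_gmt(sets: MetaboliteSetList, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets:
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def write_xml(sets: MetaboliteSetList, path=None) -> str:
    """Serialize to the XML dialect; write to ``path`` if given.

    Returns the document as a string either way.
    """
    root = ET.Element("pathway_list")
    for name, members in sets:
        pw = ET.SubElement(root, "pathway", name=name)
        for mid in sorted(members):
            ET.SubElement(pw, "metabolite", id=mid)
    ET.indent(root)
    doc = ET.tostring(root, encoding="unicode", xml_declaration=True)
    if path is not None:
        Path(path).write_text(doc, encoding="utf-8")
    return doc


def read_xml(path) -> MetaboliteSetList:
    """Parse the XML dialect back into a MetaboliteSetList.

    Unknown extra attributes are ignored with a warning; structural
    violations raise with the offending element path.
    """
    tree = ET.parse(path)
    root = tree.getroot()
    if root.tag != "pathway_list":
        raise ValueError(f"/{root.tag}: expected root element 'pathway_list'")
    entries = []
    for i, pw in enumerate(root):
        where = f"/pathway_list/*[{i + 1}]"
        if pw.tag != "pathway":
            raise ValueError(f"{where}: expected element 'pathway', got {pw.tag!r}")
        if "name" not in pw.attrib:
            raise ValueError(f"{where}: missing required attribute 'name'")
        extra = set(pw.attrib) - {"name"}
        if extra:
            warnings.warn(f"{where}: ignoring attributes {sorted(extra)}")
        members = []
        for j, met in enumerate(pw):
            mwhere = f"{where}/*[{j + 1}]"
            if met.tag != "metabolite":
                raise ValueError(
                    f"{mwhere}: expected element 'metabolite', got {met.tag!r}"
                )
            if "id" not in met.attrib:
                raise ValueError(f"{mwhere}: missing required attribute 'id'")
            mextra = set(met.attrib) - {"id"}
            if mextra:
                warnings.warn(f"{mwhere}: ignoring attributes {sorted(mextra)}")
            members.append(met.attrib["id"])
        entries.append((pw.attrib["name"], members))
    return MetaboliteSetList(entries)


def restrict_to_universe(sets: MetaboliteSetList, universe) -> MetaboliteSetList:
    """Intersect every pathway with the detected-metabolite universe.

    Pathways emptied by the restriction are retained (so downstream code
    can flag them) and reported in a warning along with the number of
    dropped IDs.
    """
    universe = {str(u) for u in universe}
    out = MetaboliteSetList()
    dropped = 0
    emptied = []
    for name, members in sets:
        kept = members & universe
        dropped += len(members) - len(kept)
        if members and not kept:
            emptied.append(name)
        out.add(name, kept)
    if dropped:
        msg = f"universe restriction dropped {dropped} metabolite ID(s)"
        if emptied:
            msg += f"; pathways left empty: {', '.join(emptied)}"
        warnings.warn(msg)
    return out
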