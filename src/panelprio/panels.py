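"""Diagnostic-grade virtual panels: gene lists with per-gene inheritance modes.

A virtual panel restricts the analysis of a large sequenced capture to the
genes linked to the patient's phenotype; it is the first and strongest filter
of the prioritization cascade. Each gene carries the inheritance modes under
which it causes disease (AD/AR/XLD/XLR) and optional exception flags for the
variant classes that are allowed to bypass frequency and zygosity filtering
(known-pathogenic alleles, hypomorphic alleles, incomplete penetrance or
variable expressivity).
"""

from __future__ import annotations

import enum
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from .types import AnnotatedVariant

logger = logging.getLogger(__name__)


class Mode(str, enum.Enum):
    AD = "AD"
    AR = "AR"
    XLD = "XLD"
    XLR = "XLR"


class ExceptionFlag(str, enum.Enum):
    KNOWN_PATHOGENIC = "KNOWN_PATHOGENIC"
    HYPOMORPHIC = "HYPOMORPHIC"
    INCOMPLETE_PENETRANCE = "INCOMPLETE_PENETRANCE"


@dataclass
class GenePanelEntry:
    gene: str
    modes: set[Mode]
    exception_flags: set[ExceptionFlag] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be non-empty")
        if not self.modes:
            raise ValueError(f"gene {self.gene!r} has no inheritance modes")

    def united_with(self, other: "GenePanelEntry") -> "GenePanelEntry":
        return GenePanelEntry(
            gene=self.gene,
            modes=self.modes | other.modes,
            exception_flags=self.exception_flags | other.exception_flags,
        )


@dataclass
class VirtualPanel:
    id: str
    name: str = ""
    category: str = ""
    subcategory: str | None = None
    entries: list[GenePanelEntry] = field(default_factory=list)
    version: str = "1"

    def __post_init__(self) -> None:
        genes = [e.gene.upper() for e in self.entries]
        if len(genes) != len(set(genes)):
            raise ValueError(f"panel {self.id!r} has duplicate gene symbols")

    @property
    def genes(self) -> set[str]:
        return {e.gene.upper() for e in self.entries}

    def entry(self, gene: str) -> GenePanelEntry | None:
        """Case-insensitive lookup by gene symbol (no alias resolution)."""
        g = gene.upper()
        for e in self.entries:
            if e.gene.upper() == g:
                return e
        return None


@dataclass
class PanelLibrary:
    panels: dict[str, VirtualPanel] = field(default_factory=dict)
    design_version: str = "D1"

    def __getitem__(self, panel_id: str) -> VirtualPanel:
        try:
            return self.panels[panel_id]
        except KeyError:
            raise KeyError(
                f"unknown panel id {panel_id!r}; "
                f"library has {sorted(self.panels)}"
            ) from None


def _collapse_entries(rows: list[GenePanelEntry], context: str) -> list[GenePanelEntry]:
    """Unite duplicate gene rows by union of modes/flags, preserving order."""
    merged: dict[str, GenePanelEntry] = {}
    dups = 0
    for e in rows:
        g = e.gene.upper()
        if g in merged:
            merged[g] = merged[g].united_with(e)
            dups += 1
        else:
            merged[g] = e
    if dups:
        logger.warning("%s: collapsed %d duplicate gene rows", context, dups)
    return list(merged.values())


def _parse_entry(gene: str, modes_str: str, flags_str: str, where: str) -> GenePanelEntry:
    modes: set[Mode] = set()
    for tok in filter(None, modes_str.split(";")):
        try:
            modes.add(Mode(tok.strip().upper()))
        except ValueError:
            raise ValueError(
                f"{where}: unknown inheritance mode token {tok!r}"
            ) from None
    flags: set[ExceptionFlag] = set()
    for tok in filter(None, (flags_str or "").split(";")):
        try:
            flags.add(ExceptionFlag(tok.strip().upper()))
        except ValueError:
            raise ValueError(
                f"{where}: unknown exception flag token {tok!r}"
            ) from None
    return GenePanelEntry(gene=gene, modes=modes, exception_flags=flags)


def load_panels(path: str | Path) -> PanelLibrary:
    """Load a panel library from TSV or its JSON mirror.

    TSV columns: ``panel_id, panel_name, category, subcategory, gene,
    modes`` (semicolon-separated), ``exception_flags`` (semicolon-separated,
    may be empty). Duplicate gene rows within one panel are collapsed by
    uniting modes and flags, with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _load_panels_json(path)
    raw: dict[str, dict] = {}
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for col in ("panel_id", "gene", "modes"):
            if col not in idx:
                raise ValueError(f"panel TSV missing column {col!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            pid = parts[idx["panel_id"]]
            entry = _parse_entry(
                parts[idx["gene"]],
                parts[idx["modes"]],
                parts[idx["exception_flags"]] if "exception_flags" in idx else "",
                f"line {lineno}",
            )
            slot = raw.setdefault(
                pid,
                {
                    "name": parts[idx.get("panel_name", idx["panel_id"])],
                    "category": parts[idx["category"]] if "category" in idx else "",
                    "subcategory": parts[idx["subcategory"]]
                    if "subcategory" in idx and parts[idx["subcategory"]]
                    else None,
                    "rows": [],
                },
            )
            slot["rows"].append(entry)
    lib = PanelLibrary()
    for pid, slot in raw.items():
        lib.panels[pid] = VirtualPanel(
            id=pid,
            name=slot["name"],
            category=slot["category"],
            subcategory=slot["subcategory"],
            entries=_collapse_entries(slot["rows"], f"panel {pid}"),
        )
    return lib


def _load_panels_json(path: Path) -> PanelLibrary:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    lib = PanelLibrary(design_version=doc.get("design_version", "D1"))
    for p in doc["panels"]:
        rows = [
            _parse_entry(
                e["gene"],
                e["modes"] if isinstance(e["modes"], str) else ";".join(e["modes"]),
                e.get("exception_flags", "")
                if isinstance(e.get("exception_flags", ""), str)
                else ";".join(e["exception_flags"]),
                f"panel {p['id']} gene {e['gene']}",
            )
            for e in p["entries"]
        ]
        lib.panels[p["id"]] = VirtualPanel(
            id=p["id"],
            name=p.get("name", p["id"]),
            category=p.get("category", ""),
            subcategory=p.get("subcategory"),
            entries=_collapse_entries(rows, f"panel {p['id']}"),
            version=p.get("version", "1"),
        )
    return lib


def write_panels(lib: PanelLibrary, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "panel_id\tpanel_name\tcategory\tsubcategory\tgene\tmodes\texception_flags\n"
        )
        for panel in lib.panels.values():
            for e in panel.entries:
                modes = ";".join(sorted(m.value for m in e.modes))
                flags = ";".join(sorted(f.value for f in e.exception_flags))
                fh.write(
                    f"{panel.id}\t{panel.name}\t{panel.category}\t"
                    f"{panel.subcategory or ''}\t{e.gene}\t{modes}\t{flags}\n"
                )


def merge_panels(library: PanelLibrary, ids: list[str]) -> VirtualPanel:
    """Union the gene sets of several ordered panels into one working panel.

    Per-gene modes and exception flags are united across panels; the merged
    id is the sorted ``+``-joined concatenation of the input ids. Merging a
    single panel returns it unchanged.
    """
    if not ids:
        raise ValueError("merge_panels needs >= 1 panel id")
    panels = [library[i] for i in ids]
    if len(panels) == 1:
        return panels[0]
    rows: list[GenePanelEntry] = []
    for p in panels:
        rows.extend(p.entries)
    return VirtualPanel(
        id="+".join(sorted(ids)),
        name=" + ".join(p.name or p.id for p in panels),
        category=panels[0].category,
        entries=_collapse_entries(rows, "merge"),
        version="merged",
    )


def customize_panel(
    panel: VirtualPanel, extra: list[GenePanelEntry]
) -> VirtualPanel:
    """Append clinician-chosen genes; collisions unite modes/flags."""
    entries = _collapse_entries(list(panel.entries) + list(extra), f"panel {panel.id}")
    return replace(panel, entries=entries, version=panel.version + "+custom")


def apply_panel(
    variants: list[AnnotatedVariant], panel: VirtualPanel
) -> list[AnnotatedVariant]:
    """Keep exactly the variants whose gene is on the panel, in input order.

    Retained variants are stamped with ``panel:<id>`` in their flag set.
    """
    genes = panel.genes
    kept = []
    for v in variants:
        if v.gene.upper() in genes:
            v.flags.add(f"panel:{panel.id}")
            kept.append(v)
    return kept
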