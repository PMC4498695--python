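"""Virtual gene panel configuration.

A panel is a mapping gene symbol -> :class:`~mendelsieve.model.GenePanelEntry`
loaded from a YAML file.  Two panels ship with the package, pinned as config
because curated disease-gene lists drift over time:

* ``stgd`` — the five genes implicated in Stargardt / Stargardt-like macular
  dystrophy (ABCA4, ELOVL4, PROM1, PRPH2, BEST1).
* ``full`` — those five plus 209 further retinal-dystrophy genes (214 total),
  emulating a RetNet-derived virtual panel.

ABCA4 and PROM1 default to autosomal recessive; ELOVL4, PRPH2 and BEST1 to
autosomal dominant.  Users may override any gene's mode in their own YAML.
X-linked panel genes are carried with mode AR (hemizygous logic is out of
scope in this version).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .model import GenePanelEntry

__all__ = ["PanelError", "load_panel", "load_builtin_panel", "BUILTIN_PANELS"]

BUILTIN_PANELS = ("stgd", "full")


class PanelError(ValueError):
    """Panel config is missing, empty or schema-invalid."""


def _build(entries: list, origin: str) -> dict[str, GenePanelEntry]:
    if not isinstance(entries, list) or not entries:
        raise PanelError(f"{origin}: panel file is empty or not a list of entries")
    panel: dict[str, GenePanelEntry] = {}
    for i, raw in enumerate(entries):
        if not isinstance(raw, Mapping) or "gene" not in raw:
            raise PanelError(f"{origin}: entry {i} lacks a 'gene' key")
        gene = str(raw["gene"])
        if gene in panel:
            raise PanelError(f"{origin}: duplicate gene {gene!r}")
        try:
            entry = GenePanelEntry(
                gene=gene,
                inheritance_mode=str(raw.get("inheritance_mode", "")),
                phenotype_group=str(raw.get("phenotype_group", "")),
            )
        except ValueError as exc:
            raise PanelError(f"{origin}: {exc}") from exc
        panel[gene] = entry
    return panel


def load_panel(path: str | Path) -> dict[str, GenePanelEntry]:
    """Load and validate a panel YAML file.

    The file holds ``panel: [{gene, inheritance_mode, phenotype_group}, ...]``
    (a bare top-level list is also accepted).  Duplicate genes and unknown
    inheritance modes are rejected.
    """
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if doc is None:
        raise PanelError(f"{path}: panel file is empty")
    entries = doc.get("panel") if isinstance(doc, Mapping) else doc
    return _build(entries, str(path))


def load_builtin_panel(name: str = "full") -> dict[str, GenePanelEntry]:
    """Load one of the packaged panels (``stgd`` or ``full``)."""
    if name not in BUILTIN_PANELS:
        raise PanelError(f"unknown builtin panel {name!r}; choose from {BUILTIN_PANELS}")
    ref = resources.files("mendelsieve.data").joinpath(f"panel_{name}.yaml")
    doc = yaml.safe_load(ref.read_text())
    return _build(doc["panel"], f"builtin:{name}")
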