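"""Serialization: section JSON, species CSV, Newick trees, result reports.

The section schema is versioned JSON with all coordinates in µm:

    {"schema_version": 1, "units": "um", "specimen_id": ..., "cusp_id": ...,
     "species": ..., "edj": [[u, v], ...], "outer_surface": [[u, v], ...],
     "enamel_lines": [{"kind": ..., "day_index": ..., "accentuated": ...,
                       "points": [[u, v], ...]}, ...],
     "dentine_lines": [...], "truth": {...} | null}

Round-trips are lossless to full float precision.  Schema violations raise
:class:`SchemaError` carrying a JSON pointer to the offending member.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Union

import dendropy
import numpy as np
import pandas as pd

from .section import EDJCurve, EnamelSection, IncrementLine, Polyline
from .simulate import SectionConfig, SpeciesTable

__all__ = ["SchemaError", "write_section", "read_section",
           "read_species_csv", "write_species_csv", "read_tree",
           "write_tree"]

SCHEMA_VERSION = 1
SPECIES_COLUMNS = ["species", "group", "body_mass_g", "dsr_um_d", "cer_um_d"]


class SchemaError(ValueError):
    """A section file violates the schema; ``pointer`` locates the issue."""

    def __init__(self, pointer: str, message: str) -> None:
        self.pointer = pointer
        super().__init__(f"{pointer}: {message}")


def _line_to_json(ln: IncrementLine) -> dict:
    return {"kind": ln.kind, "day_index": ln.day_index,
            "accentuated": ln.accentuated,
            "points": ln.path.points.tolist()}


def _truth_to_json(truth) -> Optional[dict]:
    if truth is None:
        return None
    d = dataclasses.asdict(truth)
    if isinstance(d.get("edj_shape"), np.ndarray):
        d["edj_shape"] = d["edj_shape"].tolist()
    for key in ("cer_schedule", "dsr_schedule"):
        v = d.get(key)
        if not np.isscalar(v):
            d[key] = [list(map(float, pair)) for pair in v]
    return d


def write_section(section: EnamelSection, path: Union[str, Path]) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "units": "um",
        "specimen_id": section.specimen_id,
        "cusp_id": section.cusp_id,
        "species": section.species,
        "edj": section.edj.points.tolist(),
        "outer_surface": section.outer_surface.points.tolist(),
        "enamel_lines": [_line_to_json(ln) for ln in section.enamel_lines],
        "dentine_lines": [_line_to_json(ln) for ln in section.dentine_lines],
        "truth": _truth_to_json(section.truth),
    }
    Path(path).write_text(json.dumps(doc))


def _require(doc: dict, key: str, pointer: str):
    if key not in doc:
        raise SchemaError(f"{pointer}/{key}", "missing required member")
    return doc[key]


def _line_from_json(obj: dict, pointer: str) -> IncrementLine:
    kind = _require(obj, "kind", pointer)
    if kind not in ("long_period", "short_period", "von_ebner"):
        raise SchemaError(f"{pointer}/kind", f"unknown line kind {kind!r}")
    pts = _require(obj, "points", pointer)
    try:
        path = Polyline(pts)
    except ValueError as exc:
        raise SchemaError(f"{pointer}/points", str(exc)) from exc
    return IncrementLine(path=path, kind=kind,
                         day_index=obj.get("day_index"),
                         accentuated=bool(obj.get("accentuated", False)))


def read_section(path: Union[str, Path]) -> EnamelSection:
    doc = json.loads(Path(path).read_text())
    version = _require(doc, "schema_version", "")
    if version != SCHEMA_VERSION:
        raise SchemaError("/schema_version",
                          f"unsupported version {version}")
    if doc.get("units", "um") != "um":
        raise SchemaError("/units", "units must be 'um'")
    try:
        edj = EDJCurve(_require(doc, "edj", ""))
    except ValueError as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError("/edj", str(exc)) from exc
    try:
        outer = Polyline(_require(doc, "outer_surface", ""))
    except ValueError as exc:
        if isinstance(exc, SchemaError):
            raise
        raise SchemaError("/outer_surface", str(exc)) from exc
    enamel = [_line_from_json(o, f"/enamel_lines/{i}")
              for i, o in enumerate(doc.get("enamel_lines", []))]
    dentine = [_line_from_json(o, f"/dentine_lines/{i}")
               for i, o in enumerate(doc.get("dentine_lines", []))]
    truth = doc.get("truth")
    if truth is not None:
        for key in ("cer_schedule", "dsr_schedule"):
            v = truth.get(key)
            if isinstance(v, list):
                truth[key] = [tuple(pair) for pair in v]
        if isinstance(truth.get("edj_shape"), list):
            truth["edj_shape"] = np.asarray(truth["edj_shape"])
        truth = SectionConfig(**truth)
    return EnamelSection(edj=edj, outer_surface=outer, enamel_lines=enamel,
                         dentine_lines=dentine,
                         specimen_id=doc.get("specimen_id", ""),
                         cusp_id=doc.get("cusp_id", ""),
                         species=doc.get("species", ""), truth=truth)


def read_species_csv(path: Union[str, Path]) -> SpeciesTable:
    df = pd.read_csv(path)
    missing = [c for c in SPECIES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species CSV missing columns: {missing}")
    dup = df.species[df.species.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate species: {dup}")
    return SpeciesTable.from_dataframe(df[SPECIES_COLUMNS])


def write_species_csv(table: SpeciesTable, path: Union[str, Path]) -> None:
    table.to_dataframe().to_csv(path, index=False)


def read_tree(path: Union[str, Path]) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has a branch without a length; Brownian "
                             "covariance is undefined")
    return tree


def write_tree(tree: dendropy.Tree, path: Union[str, Path]) -> None:
    tree.write(path=str(path), schema="newick",
               unquoted_underscores=True)
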