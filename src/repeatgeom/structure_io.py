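"""Reading structures and repeat annotations; writing descriptor tables.

Structures are reduced to a Calpha-only model: per residue one coordinate,
keyed by (chain id, author residue number, insertion code).  PDB and mmCIF
are read through gemmi.  Repeat-region annotations are consumed from a small
JSON or TSV dialect carrying unit and insertion spans (author numbering,
1-based inclusive, the convention curated repeat databases use).

Descriptor tables are written as a single CSV: per-pair rows carry
``row_type="pair"``; the region-level mean and standard deviation of
curvature, twist and pitch are appended as ``row_type="mean"``/``"std"``
rows in the same file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gemmi
import numpy as np
import pandas as pd

from .errors import (RegionResolutionError, RegionValidationError,
                     StructureParseError, UnitTooShortError)
from .geometry import LocalFrame

logger = logging.getLogger(__name__)


class ResidueKey(NamedTuple):
    """Identity of one residue: chain, author number, insertion code."""

    chain: str
    seq_num: int
    icode: str = ""


class UnitSpan(NamedTuple):
    """Inclusive author-numbered residue span on one chain."""

    chain: str
    start: int
    end: int


@dataclass
class Structure:
    """Calpha-only coordinates of one model, in file order."""

    coords: dict[ResidueKey, np.ndarray]
    model_id: str = "1"
    source: str = ""

    def __len__(self) -> int:
        return len(self.coords)

    def keys(self) -> list[ResidueKey]:
        return list(self.coords)

    def array(self) -> np.ndarray:
        """All Calpha coordinates as an Nx3 array, file order."""
        return np.array([self.coords[k] for k in self.coords], dtype=float)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray
                    ) -> "Structure":
        """Copy with every coordinate mapped through ``R p + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        return Structure({k: R @ v + t for k, v in self.coords.items()},
                         self.model_id, self.source)

    def mirrored(self) -> "Structure":
        """Copy reflected through the yz-plane (x negated)."""
        flip = np.array([-1.0, 1.0, 1.0])
        return Structure({k: v * flip for k, v in self.coords.items()},
                         self.model_id, self.source)


@dataclass
class RegionSpec:
    """Ordered repeat-unit spans plus insertion spans to exclude."""

    region_id: str
    units: list[UnitSpan]
    insertions: list[UnitSpan] = field(default_factory=list)

    def validate(self) -> "RegionSpec":
        rid = self.region_id
        if len(self.units) < 3:
            raise RegionValidationError(
                f"region {rid!r}: needs at least 3 units, got "
                f"{len(self.units)}")
        self.units = sorted(self.units, key=lambda u: (u.chain, u.start))
        for u in self.units + self.insertions:
            if u.end < u.start:
                raise RegionValidationError(
                    f"region {rid!r}: span {u.start}-{u.end} is reversed")
        for a, b in zip(self.units, self.units[1:]):
            if a.chain == b.chain and b.start <= a.end:
                raise RegionValidationError(
                    f"region {rid!r}: units {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap")
        for ins in self.insertions:
            inside = any(u.chain == ins.chain
                         and self.units[0].start <= ins.start
                         and ins.end <= self.units[-1].end
                         for u in self.units)
            if not inside:
                raise RegionValidationError(
                    f"region {rid!r}: insertion {ins.start}-{ins.end} lies "
                    f"outside the region")
        return self

    @property
    def n_units(self) -> int:
        return len(self.units)


@dataclass
class GeometryTable:
    """Per-pair descriptor rows plus region-level summary.

    ``pairs`` has one row per consecutive unit pair; ``summary`` holds the
    arithmetic mean and (sample) standard deviation of curvature, twist and
    pitch over the pairs.
    """

    region_id: str
    pairs: pd.DataFrame
    summary: pd.DataFrame


#: Column order of the per-pair table.
PAIR_COLUMNS = [
    "region_id", "pair_index", "chain",
    "unit_i_start", "unit_i_end", "unit_j_start", "unit_j_end",
    "curvature", "twist", "pitch",
    "twist_handedness", "pitch_handedness",
    "rmsd", "aligned_length", "radius", "crown_inner", "crown_outer",
    "yaw_residual", "flags",
]


# ---------------------------------------------------------------------------
# structure reading / writing


def _pick_model(st: gemmi.Structure, model: int | None) -> gemmi.Model:
    if len(st) == 0:
        raise StructureParseError(f"{st.name or 'structure'}: no models")
    if model is None:
        return st[0]
    for m in st:
        if m.num == model:
            return m
    raise StructureParseError(f"model {model} not present "
                              f"(available: {[m.num for m in st]})")


def parse_structure(path: str | Path, model: int | None = None,
                    chains: Sequence[str] | None = None) -> Structure:
    """Read a PDB or mmCIF file into a Calpha-only :class:`Structure`.

    The format is auto-detected.  Only the requested model is kept (default:
    the first).  For alternate conformations the highest-occupancy CA is
    kept (ties: first encountered).  Residues lacking a CA atom are omitted
    with a logged warning.  Calcium ions (atom name CA, element Ca) are not
    alpha carbons and are ignored.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError, OSError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    mod = _pick_model(st, model)

    coords: dict[ResidueKey, np.ndarray] = {}
    n_missing = 0
    for chain in mod:
        if chains is not None and chain.name not in chains:
            continue
        for res in chain:
            if res.is_water():
                continue
            best = None
            has_atoms = False
            for atom in res:
                has_atoms = True
                if atom.name != "CA" or atom.element.name != "C":
                    continue
                if best is None or atom.occ > best.occ:
                    best = atom
            if best is None:
                if has_atoms:
                    n_missing += 1
                continue
            key = ResidueKey(chain.name, res.seqid.num,
                             (res.seqid.icode or " ").strip())
            if key in coords:
                continue
            coords[key] = np.array([best.pos.x, best.pos.y, best.pos.z])
    if n_missing:
        logger.warning("%s: %d residue(s) without a CA atom were skipped",
                       path.name, n_missing)
    if not coords:
        raise StructureParseError(f"{path}: no Calpha atoms in selection")
    return Structure(coords, model_id=str(mod.num), source=str(path))


def _to_gemmi(structure: Structure, name: str = "model") -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = name
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for key, xyz in structure.coords.items():
        chain = chains.get(key.chain)
        if chain is None:
            chain = gemmi.Chain(key.chain)
            chains[key.chain] = chain
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(key.seq_num, key.icode or " ")
        atom = gemmi.Atom()
        atom.name = "CA"
        atom.element = gemmi.Element("C")
        atom.occ = 1.0
        # Quantize to PDB coordinate precision so PDB and mmCIF output of
        # the same structure carry identical values.
        atom.pos = gemmi.Position(*(float(round(c, 3)) for c in xyz))
        res.add_atom(atom)
        chain.add_residue(res)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st


def write_ca_pdb(structure: Structure, path: str | Path) -> None:
    """Write the Calpha trace as a PDB file (poly-alanine records)."""
    _to_gemmi(structure, Path(path).stem).write_pdb(str(path))


def write_ca_mmcif(structure: Structure, path: str | Path) -> None:
    """Write the Calpha trace as an mmCIF file."""
    st = _to_gemmi(structure, Path(path).stem)
    st.make_mmcif_document().write_file(str(path))


# ---------------------------------------------------------------------------
# region annotations


def _spans(raw, chain: str, rid: str, kind: str) -> list[UnitSpan]:
    spans = []
    for item in raw:
        try:
            start, end = int(item[0]), int(item[1])
        except (TypeError, ValueError, IndexError) as exc:
            raise RegionValidationError(
                f"region {rid!r}: malformed {kind} span {item!r}") from exc
        spans.append(UnitSpan(chain, start, end))
    return spans


def _regions_from_json(data) -> list[RegionSpec]:
    if isinstance(data, dict):
        data = [data]
    regions = []
    for entry in data:
        rid = str(entry.get("region_id", f"region{len(regions) + 1}"))
        chain = str(entry.get("chain", "A"))
        units = _spans(entry.get("units", []), chain, rid, "unit")
        insertions = _spans(entry.get("insertions", []), chain, rid,
                            "insertion")
        regions.append(RegionSpec(rid, units, insertions).validate())
    return regions


def _regions_from_tsv(path: Path) -> list[RegionSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"region_id", "chain", "start", "end"}
    if not required.issubset(df.columns):
        raise RegionValidationError(
            f"{path}: TSV needs columns {sorted(required)}")
    regions = []
    for rid, grp in df.groupby("region_id", sort=False):
        units, insertions = [], []
        for _, row in grp.iterrows():
            span = UnitSpan(str(row["chain"]), int(row["start"]),
                            int(row["end"]))
            flag = str(row.get("is_insertion", "0")).strip().lower()
            if flag in ("1", "true", "yes"):
                insertions.append(span)
            else:
                units.append(span)
        regions.append(RegionSpec(str(rid), units, insertions).validate())
    return regions


def parse_region_spec(path: str | Path) -> list[RegionSpec]:
    """Read repeat-region annotations from the JSON or TSV dialect.

    JSON: a list of objects ``{"region_id", "chain", "units": [[start, end],
    ...], "insertions": [[start, end], ...]}``.  TSV: one row per span with
    columns ``region_id, chain, start, end, is_insertion``.  Spans are
    author-numbered, 1-based, inclusive.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if path.suffix.lower() == ".json" or stripped[:1] in ("[", "{"):
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise RegionValidationError(f"{path}: invalid JSON: {exc}") from exc
        return _regions_from_json(data)
    return _regions_from_tsv(path)


def _unit_coords(structure: Structure, unit: UnitSpan,
                 insertions: Iterable[UnitSpan]) -> np.ndarray:
    """Ordered Calpha coordinates of one unit, insertions removed."""
    excluded = [ins for ins in insertions if ins.chain == unit.chain]
    picked = []
    for key, xyz in structure.coords.items():
        if key.chain != unit.chain or not unit.start <= key.seq_num <= unit.end:
            continue
        if any(ins.start <= key.seq_num <= ins.end for ins in excluded):
            continue
        picked.append(xyz)
    if not picked:
        raise RegionResolutionError(
            f"unit {unit.chain}:{unit.start}-{unit.end} resolves to no "
            f"Calpha atoms in the structure")
    if len(picked) < 3:
        raise UnitTooShortError(
            f"unit {unit.chain}:{unit.start}-{unit.end} resolves to only "
            f"{len(picked)} Calpha atoms; superposition needs at least 3")
    return np.array(picked, dtype=float)


def extract_unit_coordinates(structure: Structure,
                             region: RegionSpec) -> list[np.ndarray]:
    """Per-unit Calpha coordinates for a region, insertion spans excluded."""
    return [_unit_coords(structure, u, region.insertions)
            for u in region.units]


# ---------------------------------------------------------------------------
# table output


def write_geometry_csv(table: GeometryTable, path: str | Path) -> None:
    """Write a region table as one CSV (pair rows + mean/std rows)."""
    pairs = table.pairs.copy()
    pairs.insert(0, "row_type", "pair")
    extra = []
    for stat in table.summary.index:
        row = {c: np.nan for c in pairs.columns}
        row["row_type"] = stat
        row["region_id"] = table.region_id
        for col in table.summary.columns:
            row[col] = table.summary.loc[stat, col]
        extra.append(row)
    out = pd.concat([pairs, pd.DataFrame(extra)], ignore_index=True)
    out.to_csv(path, index=False, float_format="%.10g")


def read_geometry_csv(path: str | Path) -> GeometryTable:
    """Read back a CSV written by :func:`write_geometry_csv`."""
    df = pd.read_csv(path)
    pairs = (df[df["row_type"] == "pair"]
             .drop(columns=["row_type"]).reset_index(drop=True))
    stats = df[df["row_type"] != "pair"]
    summary = (stats.set_index("row_type")[["curvature", "twist", "pitch"]]
               if len(stats) else
               pd.DataFrame(columns=["curvature", "twist", "pitch"]))
    summary.index.name = None
    rid = str(df["region_id"].iloc[0]) if len(df) else ""
    return GeometryTable(rid, pairs, summary)


# ---------------------------------------------------------------------------
# axes visualization


#: Axis display colors, matching the convention twist=x=red, pitch=y=green,
#: curvature=z=blue.
AXIS_COLORS = {"x": "red", "y": "green", "z": "blue"}


def export_axes_visualization(structure: Structure, region: RegionSpec,
                              frames: Sequence[LocalFrame],
                              path: str | Path,
                              axis_length: float = 5.0,
                              pseudo_pdb: str | Path | None = None) -> None:
    """Write a plain-text PyMOL script tracing each unit-pair frame.

    For every frame three pseudo-atom pairs (base at the unit centroid, tip
    one ``axis_length`` along the axis) and colored distance objects are
    emitted: x red, y green, z blue.  No viewer is required to write the
    file.  If ``pseudo_pdb`` is given, the same segments are also written as
    a pseudo-atom PDB (one chain per axis: X, Y, Z).
    """
    if not frames:
        raise ValueError("no frames to draw")
    lines = [
        f"# repeatgeom axes for region {region.region_id}: "
        f"{len(frames)} frame(s), axis length {axis_length:g} A",
        "bg_color white",
    ]
    for k, frame in enumerate(frames):
        lines.append(f"# frame {k}")
        base = frame.anchor
        for axis in ("x", "y", "z"):
            tip = base + axis_length * getattr(frame, axis)
            b = f"f{k}_{axis}_base"
            t = f"f{k}_{axis}_tip"
            lines.append(
                f"pseudoatom {b}, pos=[{base[0]:.3f}, {base[1]:.3f}, "
                f"{base[2]:.3f}]")
            lines.append(
                f"pseudoatom {t}, pos=[{tip[0]:.3f}, {tip[1]:.3f}, "
                f"{tip[2]:.3f}]")
            lines.append(f"distance f{k}_{axis}, {b}, {t}")
            lines.append(f"color {AXIS_COLORS[axis]}, f{k}_{axis}")
    lines.append("hide labels")
    Path(path).write_text("\n".join(lines) + "\n")

    if pseudo_pdb is not None:
        pseudo = {}
        for k, frame in enumerate(frames):
            for axis in ("x", "y", "z"):
                chain = axis.upper()
                base_key = ResidueKey(chain, 2 * k + 1, "")
                tip_key = ResidueKey(chain, 2 * k + 2, "")
                pseudo[base_key] = np.asarray(frame.anchor, dtype=float)
                pseudo[tip_key] = (frame.anchor
                                   + axis_length * getattr(frame, axis))
        write_ca_pdb(Structure(pseudo, source="axes"), pseudo_pdb)
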