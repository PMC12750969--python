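"""Landmark and metadata I/O: Morphologika files, ecology tables, protocols.

The landmark interchange format is the plain-text Morphologika dialect:
bracketed ``[individuals]``, ``[landmarks]``, ``[dimensions]`` counts, an
optional ``[names]`` block, then ``[rawpoints]`` with one whitespace-separated
coordinate triple per landmark.  Specimen metadata rides in the name as
``species|specimen_id|position`` (pipe-separated; trailing fields optional).

Also implements the sampling protocol used throughout the package: presacral
columns are subsampled to 10 homologous positions (first/middle/last per
region, diaphragmatic supplied as observed metadata), and every vertebra is
consolidated to a common 30-landmark scheme so that serially homologous
elements are comparable in one analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gpa import AlignedBlock

__all__ = [
    "POSITIONS",
    "SPEED_LEVELS",
    "HUNTING_LEVELS",
    "LandmarkConfiguration",
    "LandmarkDataset",
    "EcologyTable",
    "MorphologikaError",
    "read_morphologika",
    "write_morphologika",
    "consolidate_landmarks",
    "select_positions",
    "species_mean_shapes",
    "read_ecology_table",
]

#: The 10 homologous vertebral positions: first/middle/last cervical,
#: first/middle/diaphragmatic/last thoracic, first/middle/last lumbar.
POSITIONS = ("CF", "CM", "CL", "TF", "TM", "TD", "TL", "LF", "LM", "LL")

SPEED_LEVELS = ("fast", "intermediate", "slow")
HUNTING_LEVELS = ("pursuit", "ambush", "pounce", "occasional")

# speed synonyms accepted on input (normalized, lowercase)
_SPEED_ALIASES = {"half-bound": "intermediate", "halfbound": "intermediate"}

#: Per-region landmark consolidation: (expected input count, 1-based rows to drop).
CONSOLIDATION = {
    "cervical": (34, (16, 17, 33, 34)),
    "thoracic": (32, (16, 17)),
    "lumbar": (36, (16, 17, 18, 19, 35, 36)),
}

TARGET_LANDMARKS = 30


class MorphologikaError(ValueError):
    """Malformed Morphologika file; message names the offending line."""


@dataclass
class LandmarkConfiguration:
    """One specimen's landmarks at one vertebral position."""

    specimen_id: str
    species: str
    position: str
    coords: np.ndarray  # (n_landmarks, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_landmarks, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(
                f"non-finite coordinate in specimen {self.specimen_id!r}"
            )

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[0]

    @property
    def name(self) -> str:
        parts = [self.species, self.specimen_id]
        if self.position:
            parts.append(self.position)
        return "|".join(parts)


@dataclass
class LandmarkDataset:
    """Collection of landmark configurations with a position index."""

    configurations: list[LandmarkConfiguration] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def position_index(self) -> dict[str, list[LandmarkConfiguration]]:
        index: dict[str, list[LandmarkConfiguration]] = {}
        for cfg in self.configurations:
            index.setdefault(cfg.position, []).append(cfg)
        return index

    @property
    def species(self) -> list[str]:
        seen: dict[str, None] = {}
        for cfg in self.configurations:
            seen.setdefault(cfg.species)
        return list(seen)

    @property
    def specimen_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for cfg in self.configurations:
            seen.setdefault(cfg.specimen_id)
        return list(seen)

    def at_position(self, position: str) -> "LandmarkDataset":
        subset = [c for c in self.configurations if c.position == position]
        return LandmarkDataset(subset)

    def validate(self) -> None:
        """Enforce per-position uniform landmark counts and unique specimens."""
        for position, cfgs in self.position_index.items():
            counts = {c.n_landmarks for c in cfgs}
            if len(counts) > 1:
                raise ValueError(
                    f"position {position!r}: heterogeneous landmark counts {sorted(counts)}"
                )
            ids = [c.specimen_id for c in cfgs]
            if len(ids) != len(set(ids)):
                raise ValueError(f"position {position!r}: duplicate specimen ids")


def _parse_name(name: str) -> tuple[str, str, str]:
    parts = name.split("|")
    if len(parts) >= 3:
        return parts[0], parts[1], parts[2]
    if len(parts) == 2:
        return parts[0], parts[1], ""
    return name, name, ""


def read_morphologika(path: "str | Path") -> LandmarkDataset:
    """Parse a Morphologika landmark file into a :class:`LandmarkDataset`.

    Accepts both bracketed headers (``[individuals]`` then the count on the
    next line) and a bare leading count triple; the ``[names]`` block and
    apostrophe-prefixed labels inside ``[rawpoints]`` are both honoured, the
    names block taking precedence.  Coordinate order is preserved exactly.
    """
    path = Path(path)
    lines = path.read_text().splitlines()

    n_individuals = n_landmarks = n_dims = None
    names: list[str] = []
    coords_rows: list[tuple[int, str]] = []  # (line number, text)
    raw_labels: list[tuple[int, str]] = []  # (row index where label occurred, label)

    section = None
    pending_scalar = None  # which header count the next bare number fills
    bare_header: list[int] = []

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            key = line[1:-1].strip().lower()
            if key in {"individuals", "landmarks", "dimensions"}:
                section = None
                pending_scalar = key
            elif key in {"names", "labels"}:
                section = "names"
            elif key == "rawpoints":
                section = "rawpoints"
            else:
                section = "ignore"  # unknown blocks (e.g. [labelvalues]) skipped
            continue
        if pending_scalar is not None:
            try:
                value = int(line.split()[0])
            except ValueError as exc:
                raise MorphologikaError(
                    f"line {lineno}: expected integer for [{pending_scalar}], got {line!r}"
                ) from exc
            if pending_scalar == "individuals":
                n_individuals = value
            elif pending_scalar == "landmarks":
                n_landmarks = value
            else:
                n_dims = value
            pending_scalar = None
            continue
        if section == "names":
            names.append(line)
            continue
        if section == "ignore":
            continue
        if section == "rawpoints":
            if line.startswith("'"):
                raw_labels.append((len(coords_rows), line[1:].strip()))
                continue
            coords_rows.append((lineno, line))
            continue
        # no section yet: bare header dialect
        for tok in line.split():
            try:
                bare_header.append(int(tok))
            except ValueError as exc:
                raise MorphologikaError(
                    f"line {lineno}: unexpected content {line!r} before any section"
                ) from exc
        if len(bare_header) >= 3 and n_individuals is None:
            n_individuals, n_landmarks, n_dims = bare_header[:3]
            section = "rawpoints"  # bare dialect: coordinates follow directly

    if n_individuals is None or n_landmarks is None or n_dims is None:
        raise MorphologikaError("missing individuals/landmarks/dimensions declaration")
    if n_dims != 3:
        raise MorphologikaError(f"expected 3 dimensions, file declares {n_dims}")
    expected_rows = n_individuals * n_landmarks
    if len(coords_rows) != expected_rows:
        raise MorphologikaError(
            f"landmark-count mismatch: declared {n_individuals} x {n_landmarks} "
            f"= {expected_rows} coordinate rows, found {len(coords_rows)}"
        )

    values = np.empty((expected_rows, 3))
    for i, (lineno, text) in enumerate(coords_rows):
        toks = text.split()
        if len(toks) != 3:
            raise MorphologikaError(
                f"line {lineno}: expected 3 coordinates, got {len(toks)}"
            )
        try:
            values[i] = [float(t) for t in toks]
        except ValueError as exc:
            raise MorphologikaError(
                f"line {lineno}: non-numeric coordinate in {text!r}"
            ) from exc

    if not names and raw_labels:
        by_block = {idx // n_landmarks: lab for idx, lab in raw_labels}
        names = [by_block.get(i, str(i)) for i in range(n_individuals)]
    if names and len(names) != n_individuals:
        raise MorphologikaError(
            f"[names] lists {len(names)} entries for {n_individuals} individuals"
        )
    if not names:
        names = [str(i) for i in range(n_individuals)]

    configurations = []
    blocks = values.reshape(n_individuals, n_landmarks, 3)
    for name, block in zip(names, blocks):
        species, specimen_id, position = _parse_name(name)
        configurations.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                species=species,
                position=position,
                coords=block,
            )
        )
    return LandmarkDataset(configurations)


def write_morphologika(dataset: LandmarkDataset, path: "str | Path") -> Path:
    """Write a dataset in the bracketed Morphologika dialect.

    Refuses empty datasets and heterogeneous landmark counts; the emitted file
    round-trips through :func:`read_morphologika` with coordinates preserved
    to full ``repr`` precision.
    """
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    counts = {c.n_landmarks for c in dataset.configurations}
    if len(counts) != 1:
        raise ValueError(f"heterogeneous landmark counts {sorted(counts)}")
    (n_landmarks,) = counts

    out = []
    out.append("[individuals]")
    out.append(str(len(dataset)))
    out.append("[landmarks]")
    out.append(str(n_landmarks))
    out.append("[dimensions]")
    out.append("3")
    out.append("[names]")
    for cfg in dataset.configurations:
        out.append(cfg.name)
    out.append("[rawpoints]")
    for cfg in dataset.configurations:
        out.append(f"'{cfg.name}")
        for row in cfg.coords:
            out.append(" ".join(repr(float(v)) for v in row))
    path = Path(path)
    path.write_text("\n".join(out) + "\n")
    return path


def consolidate_landmarks(
    config: LandmarkConfiguration, region: str
) -> LandmarkConfiguration:
    """Reduce a region-specific landmark scheme to the common 30 landmarks.

    Cervical vertebrae carry 34 landmarks (rows 16, 17, 33, 34 dropped),
    thoracic 32 (16, 17 dropped) and lumbar 36 (16-19, 35, 36 dropped);
    exclusion indices are 1-based.  The relative order of retained landmarks
    is preserved.
    """
    if region not in CONSOLIDATION:
        raise ValueError(f"unknown region {region!r}")
    expected, dropped = CONSOLIDATION[region]
    if config.n_landmarks == TARGET_LANDMARKS:
        return config  # already consolidated
    if config.n_landmarks != expected:
        raise ValueError(
            f"{region} configuration has {config.n_landmarks} landmarks, expected {expected}"
        )
    keep = [i for i in range(expected) if (i + 1) not in dropped]
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        species=config.species,
        position=config.position,
        coords=config.coords[keep],
    )


def select_positions(region_counts: dict[str, int]) -> dict[str, int]:
    """Map region vertebra counts to first/middle/last ordinal indices.

    For each of ``cervical``, ``thoracic``, ``lumbar`` (counts refer to the
    candidate vertebrae: C3..Cn for the cervical region, C1/C2 excluded), the
    first, middle and last vertebrae are sampled; for even counts the vertebra
    after the middle is taken (middle index ``n/2 + 1``).  The diaphragmatic
    thoracic (TD) is observational metadata, not computed here.
    """
    labels = {"cervical": ("CF", "CM", "CL"), "thoracic": ("TF", "TM", "TL"),
              "lumbar": ("LF", "LM", "LL")}
    out: dict[str, int] = {}
    for region, (first, middle, last) in labels.items():
        if region not in region_counts:
            continue
        n = int(region_counts[region])
        if n < 3:
            raise ValueError(
                f"{region}: need at least 3 vertebrae to pick first/middle/last, got {n}"
            )
        out[first] = 1
        out[middle] = n // 2 + 1 if n % 2 == 0 else (n + 1) // 2
        out[last] = n
    return out


def species_mean_shapes(
    block: AlignedBlock, species_map: dict[str, str]
) -> AlignedBlock:
    """Average Procrustes-aligned configurations within species.

    Means of unaligned configurations would conflate orientation with shape,
    so this operates on GPA output only.  Single-specimen species pass through
    unchanged; the output has one configuration per species, labelled by
    species name, in first-appearance order.  Centroid sizes are averaged the
    same way (species-mean size covariate).
    """
    missing = [s for s in block.specimen_ids if s not in species_map]
    if missing:
        raise KeyError(f"specimens missing from species map: {missing}")
    order: list[str] = []
    members: dict[str, list[int]] = {}
    for i, spec in enumerate(block.specimen_ids):
        sp = species_map[spec]
        if sp not in members:
            members[sp] = []
            order.append(sp)
        members[sp].append(i)
    aligned = np.stack([block.aligned[members[sp]].mean(axis=0) for sp in order])
    sizes = np.array([block.centroid_sizes[members[sp]].mean() for sp in order])
    return AlignedBlock(
        position=block.position,
        aligned=aligned,
        consensus=aligned.mean(axis=0),
        centroid_sizes=sizes,
        iterations=block.iterations,
        converged=block.converged,
        specimen_ids=order,
    )


@dataclass
class EcologyTable:
    """Species-level ecological categories: running speed and hunting mode."""

    table: pd.DataFrame  # columns: species, speed, hunting

    def __post_init__(self) -> None:
        required = {"species", "speed", "hunting"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"ecology table needs columns {sorted(required)}")
        if self.table["species"].duplicated().any():
            dupes = self.table.loc[self.table["species"].duplicated(), "species"]
            raise ValueError(f"duplicate species rows: {sorted(set(dupes))}")
        bad_speed = set(self.table["speed"]) - set(SPEED_LEVELS)
        if bad_speed:
            raise ValueError(f"unknown speed categories: {sorted(bad_speed)}")
        bad_hunt = set(self.table["hunting"]) - set(HUNTING_LEVELS)
        if bad_hunt:
            raise ValueError(f"unknown hunting categories: {sorted(bad_hunt)}")

    def speed_of(self, species: "list[str] | np.ndarray") -> np.ndarray:
        return self._lookup("speed", species)

    def hunting_of(self, species: "list[str] | np.ndarray") -> np.ndarray:
        return self._lookup("hunting", species)

    def _lookup(self, column: str, species) -> np.ndarray:
        mapping = dict(zip(self.table["species"], self.table[column]))
        missing = [s for s in species if s not in mapping]
        if missing:
            raise KeyError(f"species missing from ecology table: {missing}")
        return np.array([mapping[s] for s in species])

    def to_csv(self, path: "str | Path") -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path


def read_ecology_table(path: "str | Path") -> EcologyTable:
    """Read and validate the species,speed,hunting CSV.

    Speed entries are lowercased; the literature synonym ``half-bound`` is
    normalized to ``intermediate``.  Unknown category levels raise with the
    offending rows named.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"species", "speed", "hunting"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected header with columns {sorted(required)}")
    df["species"] = df["species"].astype(str).str.strip()
    for col in ("speed", "hunting"):
        df[col] = df[col].astype(str).str.strip().str.lower()
        # normalize the unicode hyphen occasionally found in the literature
        df[col] = df[col].str.replace("‐", "-", regex=False)
    df["speed"] = df["speed"].replace(_SPEED_ALIASES)
    bad = df.loc[~df["speed"].isin(SPEED_LEVELS) | ~df["hunting"].isin(HUNTING_LEVELS)]
    if len(bad):
        rows = ", ".join(
            f"{r.species}({r.speed}/{r.hunting})" for r in bad.itertuples()
        )
        raise ValueError(f"{path}: invalid category level(s) in rows: {rows}")
    return EcologyTable(df[["species", "speed", "hunting"]].reset_index(drop=True))
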