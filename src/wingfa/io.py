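"""Landmark data model and file I/O.

Holds labeled bilateral landmark data — individual, side (L/R), digitization
replicate, genotype, sex — and reads/writes the two community formats used for
such data: TPS landmark files and flat CSV tables.

TPS files have no native side/replicate fields, so metadata is encoded in the
``ID=`` string as ``<individual>_<L|R>_r<replicate>`` (case-insensitive on
read, canonical on write).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SIDES = ("L", "R")

_ID_RE = re.compile(r"^(?P<ind>.+)_(?P<side>[LlRr])_r(?P<rep>\d+)$")


class FormatError(ValueError):
    """Malformed landmark file (inconsistent block structure, bad counts)."""


class MetadataError(ValueError):
    """Record metadata missing or unparseable (side, replicate, ...)."""


class SchemaError(ValueError):
    """Tabular input lacks a required column."""


@dataclass(frozen=True)
class LandmarkConfiguration:
    """A single k-landmark 2D configuration.

    Coordinates are in whatever units the dataset carries (pixels or mm);
    they are never converted.
    """

    coords: np.ndarray  # (k, 2) float

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError(f"coords must be (k, 2), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass(frozen=True)
class SpecimenRecord:
    """One digitization of one side of one individual (or a scalar trait)."""

    individual_id: str
    side: str  # "L" or "R"
    replicate: int
    genotype: str
    sex: str
    configuration: LandmarkConfiguration | None = None
    value: float | None = None  # univariate traits (wing length, femur length)

    def __post_init__(self) -> None:
        side = str(self.side).upper()
        if side not in SIDES:
            raise MetadataError(f"side must be L or R, got {self.side!r}")
        object.__setattr__(self, "side", side)
        if self.replicate < 1:
            raise MetadataError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def key(self) -> tuple[str, str, int]:
        return (self.individual_id, self.side, self.replicate)


@dataclass
class LandmarkDataset:
    """Labeled collection of specimen records with its experimental design.

    Invariants enforced on construction: unique (individual, side, replicate)
    keys and a common landmark count k across all configurations.
    """

    records: list[SpecimenRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        k = None
        for rec in self.records:
            if rec.key in seen:
                raise MetadataError(f"duplicate record key {rec.key}")
            seen.add(rec.key)
            if rec.configuration is not None:
                if k is None:
                    k = rec.configuration.k
                elif rec.configuration.k != k:
                    raise FormatError(
                        f"inconsistent landmark count: {rec.configuration.k} != {k}"
                        f" for record {rec.key}"
                    )

    @property
    def k(self) -> int | None:
        for rec in self.records:
            if rec.configuration is not None:
                return rec.configuration.k
        return None

    @property
    def individuals(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.individual_id not in out:
                out.append(rec.individual_id)
        return out

    def subset(self, **labels: str) -> "LandmarkDataset":
        """Records matching all given label values (genotype=..., sex=...)."""
        recs = [
            r
            for r in self.records
            if all(getattr(r, k) == v for k, v in labels.items())
        ]
        return LandmarkDataset(recs)

    def design_summary(self) -> pd.DataFrame:
        """Individual counts per genotype x sex cell (the sample-size table)."""
        rows = {}
        for rec in self.records:
            rows.setdefault((rec.genotype, rec.sex), set()).add(rec.individual_id)
        return pd.DataFrame(
            [
                {"genotype": g, "sex": s, "n": len(ids)}
                for (g, s), ids in sorted(rows.items())
            ]
        )


def interlandmark_distance(config: LandmarkConfiguration, i: int, j: int) -> float:
    """Euclidean distance between landmarks i and j (1-based indices).

    This is how wing length (landmarks 3 and 13) and femur length are
    measured from digitized configurations.
    """
    k = config.k
    if not (1 <= i <= k) or not (1 <= j <= k):
        raise IndexError(f"landmark index out of range 1..{k}: ({i}, {j})")
    if i == j:
        raise IndexError("landmark indices must differ")
    return float(np.linalg.norm(config.coords[i - 1] - config.coords[j - 1]))


# ---------------------------------------------------------------------------
# TPS format
# ---------------------------------------------------------------------------


def _parse_id(id_string: str, block: int) -> tuple[str, str, int]:
    m = _ID_RE.match(id_string.strip())
    if m is None:
        raise MetadataError(
            f"TPS block {block}: ID {id_string!r} does not follow "
            "'<individual>_<L|R>_r<replicate>'"
        )
    return m.group("ind"), m.group("side").upper(), int(m.group("rep"))


def read_tps(
    path,
    genotype: str = "unknown",
    sex: str = "unknown",
) -> LandmarkDataset:
    """Read a TPS landmark file into a dataset.

    Genotype/sex are not representable in TPS; they are applied uniformly
    from the arguments (split files per group, or use CSV for full designs).
    ``SCALE=`` lines, when present, multiply the block's coordinates.
    """
    records: list[SpecimenRecord] = []
    block_coords: list[list[float]] | None = None
    expected = None
    block_id: str | None = None
    scale = None
    k_common: int | None = None
    n_block = 0

    def flush() -> None:
        nonlocal block_coords, block_id, scale, k_common
        if block_coords is None:
            return
        if len(block_coords) != expected:
            raise FormatError(
                f"TPS block {n_block}: expected {expected} landmarks, "
                f"got {len(block_coords)}"
            )
        if k_common is None:
            k_common = expected
        elif expected != k_common:
            raise FormatError(
                f"TPS block {n_block}: landmark count {expected} != {k_common}"
            )
        if block_id is None:
            raise MetadataError(f"TPS block {n_block}: missing ID= line")
        ind, side, rep = _parse_id(block_id, n_block)
        coords = np.array(block_coords, dtype=float)
        if scale is not None:
            coords = coords * scale
        records.append(
            SpecimenRecord(
                individual_id=ind,
                side=side,
                replicate=rep,
                genotype=genotype,
                sex=sex,
                configuration=LandmarkConfiguration(coords),
            )
        )
        block_coords, block_id, scale = None, None, None

    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM="):
                flush()
                n_block += 1
                expected = int(line.split("=", 1)[1])
                block_coords = []
            elif upper.startswith("ID="):
                block_id = line.split("=", 1)[1]
            elif upper.startswith("SCALE="):
                scale = float(line.split("=", 1)[1])
            elif upper.startswith("IMAGE="):
                continue
            else:
                if block_coords is None:
                    raise FormatError(f"coordinate line outside LM= block: {line!r}")
                parts = line.split()
                if len(parts) != 2:
                    raise FormatError(f"expected 'x y' pair, got {line!r}")
                block_coords.append([float(parts[0]), float(parts[1])])
    flush()
    return LandmarkDataset(records)


def write_tps(dataset: LandmarkDataset, path) -> None:
    """Write dataset in TPS format, metadata encoded in the ID string."""
    with open(path, "w") as fh:
        for rec in dataset.records:
            if rec.configuration is None:
                continue
            fh.write(f"LM={rec.configuration.k}\n")
            for x, y in rec.configuration.coords:
                fh.write(f"{float(x)!r} {float(y)!r}\n")
            fh.write(f"ID={rec.individual_id}_{rec.side}_r{rec.replicate}\n")


# ---------------------------------------------------------------------------
# CSV table format
# ---------------------------------------------------------------------------

_META_COLS = ["individual", "side", "replicate", "genotype", "sex"]


def write_landmark_table(dataset: LandmarkDataset, path) -> None:
    """Write as CSV with columns individual,side,replicate,genotype,sex,x1..xk,y1..yk.

    Coordinates are written with full repr precision so a read-back is
    bitwise identical.
    """
    k = dataset.k
    if k is None:
        raise ValueError("dataset has no landmark configurations")
    cols = _META_COLS + [f"x{i}" for i in range(1, k + 1)] + [
        f"y{i}" for i in range(1, k + 1)
    ]
    rows = []
    for rec in dataset.records:
        c = rec.configuration.coords
        rows.append(
            [rec.individual_id, rec.side, rec.replicate, rec.genotype, rec.sex]
            + list(c[:, 0])
            + list(c[:, 1])
        )
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format=None)


def read_landmark_table(path) -> LandmarkDataset:
    """Read the CSV table written by :func:`write_landmark_table`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    xcols = sorted(
        (c for c in df.columns if re.fullmatch(r"x\d+", c)),
        key=lambda c: int(c[1:]),
    )
    ycols = sorted(
        (c for c in df.columns if re.fullmatch(r"y\d+", c)),
        key=lambda c: int(c[1:]),
    )
    if not xcols or len(xcols) != len(ycols):
        raise SchemaError("coordinate columns x1..xk / y1..yk incomplete")
    try:
        xs = df[xcols].to_numpy(dtype=float)
        ys = df[ycols].to_numpy(dtype=float)
    except ValueError as exc:
        raise SchemaError(f"non-numeric coordinate value: {exc}") from exc
    records = []
    for row, x, y in zip(df.itertuples(index=False), xs, ys):
        records.append(
            SpecimenRecord(
                individual_id=str(row.individual),
                side=str(row.side).upper(),
                replicate=int(row.replicate),
                genotype=str(row.genotype),
                sex=str(row.sex),
                configuration=LandmarkConfiguration(np.column_stack([x, y])),
            )
        )
    return LandmarkDataset(records)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass
class ValidationReport:
    balanced: bool
    replicate_counts: dict  # (individual, side) -> replicate count
    incomplete_individuals: list[str]  # missing a side
    design: pd.DataFrame  # genotype x sex cell counts
    n_records: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        status = "balanced" if self.balanced else "UNBALANCED"
        return (
            f"{self.n_records} records, {status}, "
            f"{len(self.incomplete_individuals)} incomplete individual(s)"
        )


def validate_dataset(dataset: LandmarkDataset) -> ValidationReport:
    """Report side/replicate balance and per-cell sample sizes (never raises)."""
    reps: dict[tuple[str, str], int] = {}
    sides: dict[str, set[str]] = {}
    for rec in dataset.records:
        reps[(rec.individual_id, rec.side)] = reps.get((rec.individual_id, rec.side), 0) + 1
        sides.setdefault(rec.individual_id, set()).add(rec.side)
    incomplete = sorted(ind for ind, ss in sides.items() if ss != set(SIDES))
    counts = set(reps.values())
    balanced = len(counts) <= 1 and not incomplete
    return ValidationReport(
        balanced=balanced,
        replicate_counts=reps,
        incomplete_individuals=incomplete,
        design=dataset.design_summary(),
        n_records=len(dataset.records),
    )
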