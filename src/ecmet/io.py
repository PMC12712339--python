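"""Readers and writers for every text format the pipeline touches.

All tabular files are UTF-8 TSV. Missing intensities are encoded as ``NA``.
Lines starting with ``#`` at the top of a file are provenance comments and
are skipped on read. Readers reject malformed input rather than coercing it,
and every error message names the file and the offending line.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

VALID_STATES = frozenset({"proliferating", "quiescent", "transitional"})
VALID_BEDS = frozenset({"LEC", "BEC"})

METADATA_COLUMNS = (
    "sample_id",
    "cell_type",
    "day",
    "state",
    "vascular_bed",
    "replicate",
    "treatment",
    "acquisition_index",
)


# ---------------------------------------------------------------------------
# intensity matrices


@dataclass
class OmicsMatrix:
    """Non-negative feature x sample intensity table; NaN marks missing.

    ``data`` is a float DataFrame with feature ids on the index and sample
    ids on the columns; both must be unique. Values are finite and >= 0,
    or NaN.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValidationError(f"duplicate feature id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        values = df.to_numpy(dtype=float)
        bad = ~(np.isnan(values) | (np.isfinite(values) & (values >= 0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"invalid intensity {values[i, j]!r} for feature "
                f"{df.index[i]!r}, sample {df.columns[j]!r}"
            )
        self.data = df.astype(float)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def equals(self, other: "OmicsMatrix") -> bool:
        return self.data.equals(other.data)


def _data_lines(path: str) -> list[tuple[int, str]]:
    """Read a text file, dropping blank and leading '#' comment lines.

    Returns (1-based line number, line) pairs.
    """
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            if line.startswith("#"):
                continue
            out.append((lineno, line))
    return out


def read_matrix(path: str) -> OmicsMatrix:
    """Read a feature x sample TSV (header = sample ids, column 1 = feature ids)."""
    lines = _data_lines(path)
    if not lines:
        raise FormatError(f"{path}: empty matrix file")
    header_no, header = lines[0]
    cols = header.split("\t")
    sample_ids = cols[1:]
    if len(set(sample_ids)) != len(sample_ids):
        dup = next(s for s in sample_ids if sample_ids.count(s) > 1)
        raise FormatError(f"{path}:{header_no}: duplicate sample id {dup!r}")
    n_fields = len(cols)
    feature_ids: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != n_fields:
            raise FormatError(
                f"{path}:{lineno}: expected {n_fields} fields, got {len(fields)}"
            )
        fid = fields[0]
        if fid in seen:
            raise FormatError(f"{path}:{lineno}: duplicate feature id {fid!r}")
        seen.add(fid)
        row = []
        for cell in fields[1:]:
            if cell == "NA":
                row.append(np.nan)
                continue
            try:
                row.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric cell {cell!r}"
                ) from None
        feature_ids.append(fid)
        rows.append(row)
    df = pd.DataFrame(rows, index=feature_ids, columns=sample_ids, dtype=float)
    try:
        return OmicsMatrix(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_matrix(m: OmicsMatrix, path: str, header: str | None = None) -> None:
    """Write a matrix as TSV with NA for missing; optional '#' provenance header."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("feature_id\t" + "\t".join(map(str, m.sample_ids)) + "\n")
        for fid, row in m.data.iterrows():
            cells = ["NA" if np.isnan(v) else repr(float(v)) for v in row.to_numpy()]
            fh.write(str(fid) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# sample metadata


@dataclass
class SampleAnnotation:
    """Per-sample design table, indexed by sample_id.

    Columns: cell_type, day, state, vascular_bed, replicate, treatment
    (None allowed), acquisition_index.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in METADATA_COLUMNS[1:] if c not in t.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns {missing}")
        if t.index.has_duplicates:
            dup = t.index[t.index.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        for sid, row in t.iterrows():
            if row["state"] not in VALID_STATES:
                raise ValidationError(
                    f"sample {sid!r}: unknown state {row['state']!r} "
                    f"(expected one of {sorted(VALID_STATES)})"
                )
            if row["vascular_bed"] not in VALID_BEDS:
                raise ValidationError(
                    f"sample {sid!r}: unknown vascular_bed {row['vascular_bed']!r}"
                )
            if int(row["day"]) < 1:
                raise ValidationError(f"sample {sid!r}: day must be >= 1")
            if int(row["acquisition_index"]) < 0:
                raise ValidationError(
                    f"sample {sid!r}: acquisition_index must be >= 0"
                )
        # a cell type belongs to exactly one vascular bed
        beds = t.groupby("cell_type")["vascular_bed"].nunique()
        if (beds > 1).any():
            ct = beds[beds > 1].index[0]
            raise ValidationError(
                f"cell type {ct!r} maps to more than one vascular bed"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching all column == value conditions."""
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return list(self.table.index[mask])


def read_metadata(path: str) -> SampleAnnotation:
    try:
        t = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error paths
        raise FormatError(f"{path}: {exc}") from None
    if "sample_id" not in t.columns:
        raise FormatError(f"{path}: missing required column 'sample_id'")
    t = t.set_index("sample_id")
    for col, kind in (("day", int), ("replicate", int), ("acquisition_index", int)):
        if col not in t.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        try:
            t[col] = t[col].astype(kind)
        except ValueError as exc:
            raise FormatError(f"{path}: column {col!r}: {exc}") from None
    if "treatment" in t.columns:
        t["treatment"] = t["treatment"].replace({"NA": None, "none": None})
    try:
        return SampleAnnotation(t)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_metadata(ann: SampleAnnotation, path: str, header: str | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        t = ann.table.reset_index(names="sample_id").copy()
        t["treatment"] = t["treatment"].fillna("NA")
        fh.write(t.to_csv(sep="\t", index=False))


# ---------------------------------------------------------------------------
# gene/pathway sets (GMT)


@dataclass
class GeneSetCollection:
    """pathway_id -> (name, member ids); members deduplicated, non-empty."""

    names: dict[str, str] = field(default_factory=dict)
    members: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pid, mem in self.members.items():
            if not mem:
                raise ValidationError(f"pathway {pid!r} has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, pid: str) -> bool:
        return pid in self.members

    def restrict_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``; drop sets that become empty."""
        names, members = {}, {}
        for pid, mem in self.members.items():
            inter = mem & frozenset(universe)
            if inter:
                names[pid] = self.names[pid]
                members[pid] = inter
        return GeneSetCollection(names, members)


def read_gmt(path: str) -> GeneSetCollection:
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT line needs id, description and >= 1 member"
            )
        pid = fields[0]
        if pid in members:
            raise FormatError(f"{path}:{lineno}: duplicate pathway id {pid!r}")
        names[pid] = fields[1]
        members[pid] = frozenset(f for f in fields[2:] if f)
    return GeneSetCollection(names, members)


def write_gmt(sets: GeneSetCollection, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sets:
            mem = "\t".join(sorted(sets.members[pid]))
            fh.write(f"{pid}\t{sets.names[pid]}\t{mem}\n")


# ---------------------------------------------------------------------------
# reference mass lists


@dataclass
class ReferenceMassList:
    """Neutral monoisotopic masses (Da) of candidate compounds."""

    table: pd.DataFrame  # columns: compound_id, name, monoisotopic_mass

    def __post_init__(self) -> None:
        t = self.table
        for col in ("compound_id", "name", "monoisotopic_mass"):
            if col not in t.columns:
                raise ValidationError(f"mass list missing column {col!r}")
        if t["compound_id"].duplicated().any():
            dup = t.loc[t["compound_id"].duplicated(), "compound_id"].iloc[0]
            raise ValidationError(f"duplicate compound id {dup!r}")
        if (t["monoisotopic_mass"].astype(float) <= 0).any():
            raise ValidationError("monoisotopic masses must be > 0")
        self.table = t.reset_index(drop=True)


def read_mass_list(path: str) -> ReferenceMassList:
    t = pd.read_csv(path, sep="\t", comment="#")
    try:
        return ReferenceMassList(t)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from None


def write_mass_list(ref: ReferenceMassList, path: str) -> None:
    ref.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# long-format tables (supernatant series, growth, migration)


def _read_long_table(path: str, required: tuple[str, ...], numeric: tuple[str, ...]):
    t = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in required if c not in t.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
    for col in numeric:
        try:
            t[col] = t[col].astype(float)
        except ValueError as exc:
            raise FormatError(f"{path}: column {col!r}: {exc}") from None
    return t


def read_supernatant(path: str) -> pd.DataFrame:
    """Timed supernatant table: ion_id, condition, replicate, hour, intensity."""
    t = _read_long_table(
        path,
        ("ion_id", "condition", "replicate", "hour", "intensity"),
        ("hour", "intensity"),
    )
    if (t["hour"] < 0).any():
        raise FormatError(f"{path}: negative hour value")
    if (t["intensity"].dropna() < 0).any():
        raise FormatError(f"{path}: negative intensity value")
    return t


def read_growth(path: str) -> pd.DataFrame:
    """Growth-curve table: condition, replicate, hour, confluence."""
    t = _read_long_table(
        path, ("condition", "replicate", "hour", "confluence"), ("hour", "confluence")
    )
    if (t["confluence"] < 0).any():
        raise FormatError(f"{path}: negative confluence value")
    return t


def read_migration(path: str) -> pd.DataFrame:
    """Scratch-assay table: condition, replicate, width_0h_um, width_12h_um."""
    return _read_long_table(
        path,
        ("condition", "replicate", "width_0h_um", "width_12h_um"),
        ("width_0h_um", "width_12h_um"),
    )
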