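"""Tabular I/O: cohort summary tables, subject tables, FreeSurfer aseg.stats parsing.

The package works on two table shapes:

* **cohort summary tables** — one row per brain region holding the per-group
  sample size, mean and SD of the eTIV-normalized volume.  These are the unit
  of the replication/reproducibility analysis and can be transcribed from a
  published table (two such transcriptions ship with the package).
* **subject tables** — one row per participant with group label (HC/IBS), sex,
  age, IBS-SSS severity score, raw regional volumes in mm^3, eTIV, and
  age-corrected cognitive index scores.  These feed the multivariate and
  classification analyses.

CSV dialect throughout: comma-separated, UTF-8, "." decimal, missing = empty
cell.
"""

from __future__ import annotations

import importlib.resources
import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GroupStats",
    "RegionSummary",
    "CohortSummaryTable",
    "SubjectTable",
    "FeaturePanel",
    "AsegStats",
    "AsegParseError",
    "GROUP_CODING",
    "REGION_PANEL",
    "COGNITIVE_INDICES",
    "parse_aseg_stats",
    "write_aseg_stats",
    "aseg_to_subject_features",
    "etiv_normalize",
    "read_summary_table",
    "write_summary_table",
    "read_subject_table",
    "write_subject_table",
    "load_fixture_summary",
    "load_aseg_aliases",
    "load_panel",
    "default_panel",
]

#: Fixed group coding used everywhere: healthy controls 0, patients 1.
GROUP_CODING = {"HC": 0, "IBS": 1}

SSS_RANGE = (0.0, 500.0)


def _data_text(name: str) -> str:
    return importlib.resources.files("morphorep.data").joinpath(name).read_text("utf-8")


def load_aseg_aliases() -> dict[str, str]:
    """Map from aseg StructName / measure spellings to canonical region labels."""
    return dict(yaml.safe_load(_data_text("aseg_aliases.yaml")))


@dataclass(frozen=True)
class GroupStats:
    """Sample size, mean and SD of one group for one feature."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class RegionSummary:
    """Per-region two-group summary of an eTIV-normalized volume."""

    region: str
    hc: GroupStats
    ibs: GroupStats


@dataclass
class CohortSummaryTable:
    """A cohort's per-region summary statistics, the unit of replication analysis."""

    cohort_id: str
    records: list[RegionSummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [r.region for r in self.records]
        if len(set(labels)) != len(labels):
            dupes = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate region labels: {dupes}")

    @property
    def regions(self) -> list[str]:
        return [r.region for r in self.records]

    def __getitem__(self, region: str) -> RegionSummary:
        for rec in self.records:
            if rec.region == region:
                return rec
        raise KeyError(region)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": r.region,
                "hc_n": r.hc.n, "hc_mean": r.hc.mean, "hc_sd": r.hc.sd,
                "ibs_n": r.ibs.n, "ibs_mean": r.ibs.mean, "ibs_sd": r.ibs.sd,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, cohort_id: str) -> "CohortSummaryTable":
        required = {"region", "hc_n", "hc_mean", "hc_sd", "ibs_n", "ibs_mean", "ibs_sd"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"summary table missing columns: {sorted(missing)}")
        records = [
            RegionSummary(
                region=str(row.region),
                hc=GroupStats(int(row.hc_n), float(row.hc_mean), float(row.hc_sd)),
                ibs=GroupStats(int(row.ibs_n), float(row.ibs_mean), float(row.ibs_sd)),
            )
            for row in df.itertuples()
        ]
        return cls(cohort_id=cohort_id, records=records)


def read_summary_table(path, cohort_id: str) -> CohortSummaryTable:
    return CohortSummaryTable.from_frame(pd.read_csv(path), cohort_id)


def write_summary_table(table: CohortSummaryTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def load_fixture_summary(name: str) -> CohortSummaryTable:
    """Load one of the shipped published-table transcriptions.

    ``name`` is ``"skrobisz"`` (reference cohort, FS 6.0, 19 HC / 20 IBS) or
    ``"bergen"`` (FS 6.0.1, 29 HC / 49 IBS).
    """
    fname = {"skrobisz": "skrobisz_table3.csv", "bergen": "bergen_table3.csv"}[name]
    df = pd.read_csv(io.StringIO(_data_text(fname)))
    return CohortSummaryTable.from_frame(df, cohort_id=name)


#: The fixed 35-region volumetric panel, in canonical order.
REGION_PANEL: tuple[str, ...] = tuple(
    pd.read_csv(io.StringIO(_data_text("bergen_table3.csv")))["region"]
)

#: The six age-corrected cognitive index scores (population mean 100, SD 15).
COGNITIVE_INDICES: tuple[str, ...] = (
    "Full-scale RBANS",
    "Memory Index",
    "Visuospatial Index",
    "Verbal Skills Index",
    "Attention Index",
    "Recall Index",
)


@dataclass(frozen=True)
class FeaturePanel:
    """Declares which subject-table columns are regional volumes vs cognitive scores."""

    region_columns: tuple[str, ...]
    cognitive_columns: tuple[str, ...] = ()
    include_etiv: bool = True

    @property
    def morphometric_features(self) -> list[str]:
        cols = list(self.region_columns)
        if self.include_etiv:
            cols.append("eTIV")
        return cols

    @property
    def all_features(self) -> list[str]:
        return self.morphometric_features + list(self.cognitive_columns)


def load_panel(path) -> FeaturePanel:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    return FeaturePanel(
        region_columns=tuple(cfg["region_columns"]),
        cognitive_columns=tuple(cfg.get("cognitive_columns", ())),
        include_etiv=bool(cfg.get("include_etiv", True)),
    )


def default_panel() -> FeaturePanel:
    return FeaturePanel(
        region_columns=REGION_PANEL,
        cognitive_columns=COGNITIVE_INDICES,
        include_etiv=True,
    )


# --------------------------------------------------------------------------
# Subject tables
# --------------------------------------------------------------------------

_META_COLUMNS = ("subject_id", "group", "sex", "age", "ibs_sss", "eTIV")


@dataclass
class SubjectTable:
    """One row per participant; regional volumes and cognitive indices as columns.

    ``data`` holds the metadata columns (subject_id, group, sex, age, ibs_sss,
    eTIV) plus one column per panel feature.  Group coding is fixed HC -> 0,
    IBS -> 1.
    """

    data: pd.DataFrame
    panel: FeaturePanel

    def __post_init__(self) -> None:
        df = self.data
        for col in ("subject_id", "group", "sex", "age"):
            if col not in df.columns:
                raise ValueError(f"subject table missing required column {col!r}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
            raise ValueError(f"duplicate subject_id values: {dupes}")
        bad = set(df["group"].unique()) - set(GROUP_CODING)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}; expected HC/IBS")
        if "ibs_sss" in df.columns:
            sss = df["ibs_sss"].dropna()
            lo, hi = SSS_RANGE
            if ((sss < lo) | (sss > hi)).any():
                raise ValueError(f"ibs_sss values outside [{lo:g}, {hi:g}]")
        if "eTIV" in df.columns and (df["eTIV"].dropna() <= 0).any():
            raise ValueError("eTIV must be > 0")
        missing = [c for c in self.panel.all_features if c not in df.columns]
        if missing:
            raise ValueError(f"subject table missing panel features: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def labels(self) -> np.ndarray:
        """Numeric class labels (HC -> 0, IBS -> 1)."""
        return self.data["group"].map(GROUP_CODING).to_numpy()

    def group_sizes(self) -> dict[str, int]:
        counts = self.data["group"].value_counts()
        return {g: int(counts.get(g, 0)) for g in GROUP_CODING}

    def features(self, columns: list[str] | None = None) -> pd.DataFrame:
        return self.data[columns if columns is not None else self.panel.all_features]

    def subset(self, mask) -> "SubjectTable":
        return SubjectTable(self.data.loc[mask].reset_index(drop=True), self.panel)


def read_subject_table(path, panel: FeaturePanel | None = None) -> SubjectTable:
    """Read a subject CSV.  Missing severity scores stay missing (NaN), never 0."""
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"subject table {path} is empty")
    if panel is None:
        meta = set(_META_COLUMNS)
        cognitive = tuple(c for c in COGNITIVE_INDICES if c in df.columns)
        regions = tuple(c for c in df.columns if c not in meta and c not in cognitive)
        panel = FeaturePanel(regions, cognitive, include_etiv="eTIV" in df.columns)
    return SubjectTable(df, panel)


def write_subject_table(table: SubjectTable, path) -> None:
    # full repr so that write -> read round trips are bit-exact for finite values
    table.data.to_csv(path, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# FreeSurfer aseg.stats
# --------------------------------------------------------------------------


class AsegParseError(ValueError):
    """Raised when an aseg.stats file deviates from the expected layout."""


@dataclass
class AsegStats:
    """Parsed content of one aseg.stats file (header measures + structure rows)."""

    measures: dict[str, float]
    structures: dict[str, float]

    @property
    def etiv(self) -> float:
        return self.measures["EstimatedTotalIntraCranialVol"]


_MEASURE_RE = re.compile(
    r"^#\s*Measure\s+(?P<key>[^,]+),\s*(?P<name>[^,]+),\s*(?P<desc>[^,]+),\s*"
    r"(?P<value>[-+0-9.eE]+),\s*(?P<unit>\S+)\s*$"
)


def parse_aseg_stats(text: str) -> AsegStats:
    """Parse aseg.stats content into header measures and per-structure volumes.

    The layout is a comment header containing ``# Measure`` lines followed by a
    whitespace-delimited table whose columns are declared by ``# ColHeaders``.
    Every structure row is preserved, including structures unknown to the
    package's region panel.
    """
    measures: dict[str, float] = {}
    structures: dict[str, float] = {}
    col_headers: list[str] | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            if stripped.startswith("# Measure"):
                m = _MEASURE_RE.match(stripped)
                if m is None:
                    raise AsegParseError(f"malformed '# Measure' header at line {lineno}: {stripped!r}")
                # measure names appear inconsistently in the first or second
                # field (eTIV vs the volume measures); register both spellings
                value = float(m.group("value"))
                measures[m.group("key").strip()] = value
                measures[m.group("name").strip()] = value
            elif stripped.startswith("# ColHeaders"):
                col_headers = stripped.removeprefix("# ColHeaders").split()
            continue
        if col_headers is None:
            raise AsegParseError(f"structure row before '# ColHeaders' at line {lineno}")
        parts = stripped.split()
        if len(parts) != len(col_headers):
            raise AsegParseError(
                f"line {lineno}: expected {len(col_headers)} columns, got {len(parts)}"
            )
        row = dict(zip(col_headers, parts))
        try:
            structures[row["StructName"]] = float(row["Volume_mm3"])
        except KeyError as exc:
            raise AsegParseError(f"line {lineno}: missing column {exc}") from None
    if "EstimatedTotalIntraCranialVol" not in measures:
        raise AsegParseError("missing '# Measure' line for EstimatedTotalIntraCranialVol")
    return AsegStats(measures=measures, structures=structures)


def write_aseg_stats(stats: AsegStats) -> str:
    """Serialize an :class:`AsegStats` back to the stats-file layout (round-trip aid)."""
    lines = []
    for name, value in stats.measures.items():
        lines.append(f"# Measure {name}, {name}, {name}, {value:.6f}, mm^3")
    lines.append("# ColHeaders Index SegId NVoxels Volume_mm3 StructName")
    for i, (name, vol) in enumerate(stats.structures.items(), start=1):
        lines.append(f"{i:3d} {i:4d} {int(round(vol)):8d} {vol:10.1f} {name}")
    return "\n".join(lines) + "\n"


def aseg_to_subject_features(stats: AsegStats) -> dict[str, float]:
    """Map parsed aseg output onto canonical panel labels (raw mm^3 + eTIV)."""
    aliases = load_aseg_aliases()
    out: dict[str, float] = {}
    for name, vol in stats.structures.items():
        if name in aliases:
            out[aliases[name]] = vol
    for name, val in stats.measures.items():
        if name in aliases:
            out[aliases[name]] = val
    return out


def etiv_normalize(table: SubjectTable) -> SubjectTable:
    """Divide each regional volume by the subject's eTIV; eTIV itself is retained raw.

    Scale-equivariant: multiplying all raw volumes and eTIV of a subject by any
    c > 0 leaves the normalized values unchanged.
    """
    if "eTIV" not in table.data.columns:
        raise ValueError("subject table has no eTIV column")
    etiv = table.data["eTIV"]
    if (etiv <= 0).any() or etiv.isna().any():
        raise ValueError("eTIV must be > 0 for every subject")
    df = table.data.copy()
    for col in table.panel.region_columns:
        df[col] = df[col] / etiv
    return SubjectTable(df, table.panel)
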