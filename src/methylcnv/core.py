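"""Shared data model for methylation-array CNV calling.

Three tabular artifacts flow through the pipeline: a probe manifest that
anchors every probe to a genomic position and design type, per-sample
two-channel raw intensities, and the common segment table that every
calling route reads and writes.

Coordinates are 1-based, fully closed intervals throughout, matching the
SNP-array segmentation CSV convention. Strand is ignored everywhere:
copy-number inference from methylation arrays is strand-agnostic.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Probe design classes. Type I probes read both alleles in one colour
#: channel and leave an out-of-band measurement in the other; type II
#: probes split methylated (green) and unmethylated (red) across channels.
DESIGNS = ("typeI_grn", "typeI_red", "typeII")

GROUPS = ("tumor", "control")

#: Copy states used by the threshold caller.
STATES = ("loss", "neutral", "gain")

SEGMENT_COLUMNS = ("sample", "chrom", "start", "end", "num_mark", "seg_mean", "state")


class SchemaError(ValueError):
    """An input table is missing a required column."""


class ValidationError(ValueError):
    """An input table has the right shape but inconsistent content."""


class ConfigurationError(ValueError):
    """A requested run configuration cannot be satisfied by the inputs."""


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------

class ProbeManifest:
    """Genomic placement and design metadata for every array probe.

    The manifest is the coordinate backbone for every downstream track:
    probe order within a chromosome defines the segmentation axis, and the
    ``arm`` column carries the chromosome-arm label ("1p", "3p", "19q", ...)
    used by synthetic truth events and large-scale-event classification.

    Rows are stored sorted by chromosome (order of first appearance) and
    position. ``probe_id`` must be unique and ``pos`` is a 1-based bp
    coordinate.
    """

    REQUIRED = ("probe_id", "chrom", "pos", "design", "arm")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"manifest missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(self.REQUIRED)].copy()
        df["probe_id"] = df["probe_id"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["arm"] = df["arm"].astype(str)
        df["pos"] = df["pos"].astype(np.int64)
        dups = df["probe_id"][df["probe_id"].duplicated()]
        if len(dups):
            raise ValidationError(f"duplicate probe_id(s): {sorted(set(dups))}")
        if (df["pos"] < 1).any():
            raise ValidationError("probe positions must be >= 1")
        bad = set(df["design"]) - set(DESIGNS)
        if bad:
            raise ValidationError(f"unknown design value(s): {sorted(bad)}")
        order = {c: i for i, c in enumerate(pd.unique(df["chrom"]))}
        df = (
            df.assign(_c=df["chrom"].map(order))
            .sort_values(["_c", "pos"], kind="mergesort")
            .drop(columns="_c")
            .reset_index(drop=True)
        )
        self.df = df

    @property
    def n_probes(self) -> int:
        return len(self.df)

    @property
    def chroms(self) -> list[str]:
        return list(pd.unique(self.df["chrom"]))

    def chrom_rows(self, chrom: str) -> np.ndarray:
        """Row indices of all probes on ``chrom`` (position-sorted)."""
        return np.flatnonzero((self.df["chrom"] == chrom).to_numpy())

    def arm_of(self, chrom: str, pos: int) -> str:
        """Arm label at a genomic position: the arm of the nearest probe."""
        rows = self.chrom_rows(chrom)
        if rows.size == 0:
            raise ConfigurationError(f"chromosome {chrom!r} not in manifest")
        p = self.df["pos"].to_numpy()[rows]
        return str(self.df["arm"].iat[rows[int(np.argmin(np.abs(p - pos)))]])

    def arm_extent(self, arm: str) -> tuple[str, int, int]:
        """(chrom, first probe pos, last probe pos) of a chromosome arm."""
        sub = self.df[self.df["arm"] == arm]
        if sub.empty:
            raise ConfigurationError(f"arm {arm!r} not present in manifest")
        return str(sub["chrom"].iat[0]), int(sub["pos"].min()), int(sub["pos"].max())


def write_manifest(manifest: ProbeManifest, path: str | Path) -> None:
    manifest.df.to_csv(path, index=False)


def read_manifest(path: str | Path) -> ProbeManifest:
    return ProbeManifest(pd.read_csv(path, keep_default_na=False))


# ---------------------------------------------------------------------------
# Sample sheet
# ---------------------------------------------------------------------------

class SampleSheet:
    """Maps sample names to intensity sources and tumor/control groups.

    The sheet path is decoupled from the intensity paths it references, so
    a single sheet can describe files anywhere. Unknown extra columns are
    preserved as metadata (e.g. a ``matched_normal`` pairing column).
    """

    REQUIRED = ("sample_name", "intensity_path", "group")

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise SchemaError(f"sample sheet missing column(s): {', '.join(missing)}")
        if len(df) == 0:
            raise ValidationError("sample sheet has no rows")
        df = df.copy().reset_index(drop=True)
        df["sample_name"] = df["sample_name"].astype(str)
        df["group"] = df["group"].astype(str)
        dups = df["sample_name"][df["sample_name"].duplicated()]
        if len(dups):
            raise ValidationError(f"duplicate sample_name(s): {sorted(set(dups))}")
        bad = set(df["group"]) - set(GROUPS)
        if bad or (df["group"] == "").any():
            raise ValidationError(f"group must be one of {GROUPS}; got {sorted(bad)}")
        self.df = df

    @property
    def samples(self) -> list[str]:
        return list(self.df["sample_name"])

    @property
    def tumors(self) -> list[str]:
        return list(self.df.loc[self.df["group"] == "tumor", "sample_name"])

    @property
    def controls(self) -> list[str]:
        return list(self.df.loc[self.df["group"] == "control", "sample_name"])

    def group_of(self, sample: str) -> str:
        row = self.df[self.df["sample_name"] == sample]
        if row.empty:
            raise ValidationError(f"unknown sample {sample!r}")
        return str(row["group"].iat[0])


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a sample-sheet CSV.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`ValidationError` for duplicate sample names or an empty file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"sample sheet {path} is empty") from None
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Intensity cohort
# ---------------------------------------------------------------------------

@dataclass
class IntensityCohort:
    """Per-probe, per-sample two-channel raw intensities plus mask flags.

    ``meth`` and ``unmeth`` hold the methylated (green-allele) and
    unmethylated (red-allele) signal; ``oob`` holds the out-of-band
    intensity of type I probes (zero for type II rows). ``mask`` marks
    probe/sample entries excluded from every downstream statistic; masking
    is monotone — stages may add mask flags but never remove them.
    """

    manifest: ProbeManifest
    meth: np.ndarray
    unmeth: np.ndarray
    oob: np.ndarray
    mask: np.ndarray
    sample_names: list[str]

    def __post_init__(self):
        n, s = self.manifest.n_probes, len(self.sample_names)
        for name in ("meth", "unmeth", "oob", "mask"):
            arr = getattr(self, name)
            if arr.shape != (n, s):
                raise ValidationError(
                    f"{name} has shape {arr.shape}, expected ({n}, {s})"
                )
        if self.mask.dtype != bool:
            self.mask = self.mask.astype(bool)
        for name in ("meth", "unmeth", "oob"):
            arr = getattr(self, name)
            if np.any(arr[np.isfinite(arr)] < 0):
                raise ValidationError(f"{name} intensities must be >= 0")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise ValidationError("sample_names must be unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def total(self) -> np.ndarray:
        """Combined in-band intensity I = meth + unmeth (the CNV signal)."""
        return self.meth + self.unmeth

    def sample_index(self, name: str) -> int:
        try:
            return self.sample_names.index(name)
        except ValueError:
            raise ValidationError(f"unknown sample {name!r}") from None

    def copy(self) -> "IntensityCohort":
        return IntensityCohort(
            self.manifest,
            self.meth.copy(),
            self.unmeth.copy(),
            self.oob.copy(),
            self.mask.copy(),
            list(self.sample_names),
        )


def write_intensities(cohort: IntensityCohort, path: str | Path) -> None:
    """Write the cohort as a long-format CSV (probe_id, sample, meth, unmeth, oob)."""
    n = cohort.manifest.n_probes
    probe_ids = cohort.manifest.df["probe_id"].to_numpy()
    frames = []
    for j, s in enumerate(cohort.sample_names):
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": probe_ids,
                    "sample": np.repeat(s, n),
                    "meth": cohort.meth[:, j],
                    "unmeth": cohort.unmeth[:, j],
                    "oob": cohort.oob[:, j],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_intensities(
    manifest: ProbeManifest, path: str | Path, sample_order: list[str] | None = None
) -> IntensityCohort:
    """Read a long-format intensity CSV into an :class:`IntensityCohort`."""
    df = pd.read_csv(path)
    missing = [c for c in ("probe_id", "sample", "meth", "unmeth", "oob") if c not in df.columns]
    if missing:
        raise SchemaError(f"intensity table missing column(s): {', '.join(missing)}")
    samples = sample_order or list(pd.unique(df["sample"]))
    probe_pos = {p: i for i, p in enumerate(manifest.df["probe_id"])}
    n, s = manifest.n_probes, len(samples)
    meth = np.zeros((n, s))
    unmeth = np.zeros((n, s))
    oob = np.zeros((n, s))
    seen = np.zeros((n, s), dtype=bool)
    col = {name: j for j, name in enumerate(samples)}
    rows = df["probe_id"].map(probe_pos)
    if rows.isna().any():
        unknown = sorted(set(df.loc[rows.isna(), "probe_id"]))[:5]
        raise ValidationError(f"intensity table references unknown probe(s): {unknown}")
    cols = df["sample"].map(col)
    if cols.isna().any():
        raise ValidationError("intensity table references samples absent from sample_order")
    r = rows.to_numpy(dtype=int)
    c = cols.to_numpy(dtype=int)
    meth[r, c] = df["meth"].to_numpy()
    unmeth[r, c] = df["unmeth"].to_numpy()
    oob[r, c] = df["oob"].to_numpy()
    seen[r, c] = True
    if not seen.all():
        raise ValidationError("intensity table does not cover every probe/sample pair")
    return IntensityCohort(manifest, meth, unmeth, oob, np.zeros((n, s), dtype=bool), samples)


# ---------------------------------------------------------------------------
# Segment table
# ---------------------------------------------------------------------------

def _normalize_state(v):
    if v is None:
        return None
    if isinstance(v, float) and np.isnan(v):
        return None
    s = str(v)
    return s if s != "" else None


class SegmentTable:
    """The common cross-routine segment format.

    Columns are fixed as (sample, chrom, start, end, num_mark, seg_mean,
    state). ``state`` is either ``None`` (not yet called), one of
    ``loss``/``neutral``/``gain`` (threshold mode) or a stringified integer
    copy number (formula mode). Within one sample and chromosome segments
    must be ordered and non-overlapping.
    """

    def __init__(self, df: pd.DataFrame | None = None, provenance: dict | None = None):
        if df is None:
            df = pd.DataFrame(
                {
                    "sample": pd.Series(dtype=str),
                    "chrom": pd.Series(dtype=str),
                    "start": pd.Series(dtype=np.int64),
                    "end": pd.Series(dtype=np.int64),
                    "num_mark": pd.Series(dtype=np.int64),
                    "seg_mean": pd.Series(dtype=float),
                    "state": pd.Series(dtype=object),
                }
            )
        missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"segment table missing column(s): {', '.join(missing)}")
        df = df.loc[:, list(SEGMENT_COLUMNS)].copy().reset_index(drop=True)
        df["sample"] = df["sample"].astype(str)
        df["chrom"] = df["chrom"].astype(str)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        df["num_mark"] = df["num_mark"].astype(np.int64)
        df["seg_mean"] = df["seg_mean"].astype(float)
        df["state"] = df["state"].map(_normalize_state).astype(object)
        self.df = df
        self.provenance = dict(provenance or {})
        self._validate()

    def _validate(self):
        df = self.df
        if len(df) == 0:
            return
        bad = df["start"] > df["end"]
        if bad.any():
            raise ValidationError(
                f"segment start > end at row(s) {list(df.index[bad])[:5]}"
            )
        if (df["num_mark"] < 1).any():
            raise ValidationError("num_mark must be >= 1 for every segment")
        for (sample, chrom), g in df.groupby(["sample", "chrom"], sort=False):
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if np.any(np.diff(starts) < 0):
                raise ValidationError(
                    f"segments of {sample}/{chrom} are not ordered by start"
                )
            if np.any(starts[1:] <= ends[:-1]):
                raise ValidationError(
                    f"overlapping segments within {sample}/{chrom}"
                )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(pd.unique(self.df["sample"]))

    def for_sample(self, sample: str) -> "SegmentTable":
        return SegmentTable(self.df[self.df["sample"] == sample], self.provenance)

    def equals(self, other: "SegmentTable") -> bool:
        return self.df.equals(other.df)


def write_segments(table: SegmentTable, path: str | Path) -> None:
    """Write a segment table CSV (validates invariants first).

    ``seg_mean`` is serialized at full repr precision so that
    ``read_segments(write_segments(x)) == x`` field-for-field.
    """
    table._validate()
    out = table.df.copy()
    out["state"] = out["state"].map(lambda v: "" if v is None else v)
    out.to_csv(path, index=False)


def read_segments(path: str | Path, provenance: dict | None = None) -> SegmentTable:
    df = pd.read_csv(
        path,
        keep_default_na=False,
        dtype={"sample": str, "chrom": str, "state": str},
        float_precision="round_trip",
    )
    return SegmentTable(df, provenance)
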