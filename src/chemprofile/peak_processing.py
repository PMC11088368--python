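"""Raw GC-MS peak lists: reading, cross-sample alignment, filtering, normalization.

A chromatogram is reduced to a list of (retention time, integrated area)
pairs, one list per sample.  Because retention times drift slightly between
runs, peaks have to be aligned across samples before the table of abundances
can be analysed.  Alignment here is a deliberately simple greedy clustering
of the pooled, globally sorted peaks: a cluster grows while the next peak
stays within ``2 * rt_tolerance`` of the cluster's first retention time, and
each cluster becomes one "substance" column labelled by its mean retention
time.  This approximates, but does not replicate, the multi-step
drift-correction algorithms of dedicated alignment packages; an already
aligned matrix can be ingested directly (`AlignedPeakMatrix.read`) to bypass
this stage.

Downstream filtering removes contamination (any substance seen in a
solvent-only blank run) and noise (substances seen in a single sample), and
abundances are normalised to percent relative abundance per sample followed
by a log(X+1) transform that boosts the weight of low-abundance substances.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RT_DECIMALS",
    "RawPeakList",
    "AlignedPeakMatrix",
    "PeakParseError",
    "MetadataError",
    "StageError",
    "read_peak_lists",
    "read_metadata",
    "align_peaks",
    "filter_substances",
    "normalize_relative",
    "log_transform",
]

#: reporting precision for retention times (decimals of a minute)
RT_DECIMALS = 2

STAGES = ("aligned", "filtered", "relative", "log_relative")

METADATA_COLUMNS = ["sample_id", "sex", "pair_id", "days_after_laying", "is_blank"]


class PeakParseError(ValueError):
    """A peak-list file could not be parsed."""


class MetadataError(ValueError):
    """Sample metadata is inconsistent with the peak lists."""


class StageError(ValueError):
    """An operation was applied to a matrix in the wrong processing stage."""


@dataclass(frozen=True)
class RawPeakList:
    """One sample's chromatogram peaks before alignment.

    Parameters
    ----------
    sample_id : str
        Identifier matching a row of the sample metadata.
    rt : ndarray
        Retention times in minutes, strictly positive, unique after rounding
        to `RT_DECIMALS`.
    area : ndarray
        Integrated peak areas (arbitrary detector units, >= 0), same length
        as `rt`.
    """

    sample_id: str
    rt: np.ndarray
    area: np.ndarray

    def __post_init__(self):
        rt = np.asarray(self.rt, dtype=float)
        area = np.asarray(self.area, dtype=float)
        if rt.shape != area.shape or rt.ndim != 1:
            raise PeakParseError(
                f"sample {self.sample_id!r}: rt and area must be 1-D and equal length"
            )
        if rt.size and rt.min() <= 0:
            raise PeakParseError(f"sample {self.sample_id!r}: retention times must be > 0")
        if area.size and area.min() < 0:
            raise PeakParseError(f"sample {self.sample_id!r}: negative peak area")
        rounded = np.round(rt, RT_DECIMALS)
        if np.unique(rounded).size != rounded.size:
            # co-reported duplicates at the file precision are one peak
            agg = pd.Series(area).groupby(rounded).sum()
            warnings.warn(
                f"sample {self.sample_id!r}: duplicate retention times at "
                f"{RT_DECIMALS} decimals; areas summed",
                stacklevel=2,
            )
            rounded = agg.index.to_numpy(dtype=float)
            area = agg.to_numpy(dtype=float)
        else:
            order = np.argsort(rounded, kind="stable")
            rounded, area = rounded[order], area[order]
        object.__setattr__(self, "rt", rounded)
        object.__setattr__(self, "area", area)

    @property
    def n_peaks(self) -> int:
        return int(self.rt.size)


@dataclass
class AlignedPeakMatrix:
    """Samples x substances abundance matrix with a processing-stage tag.

    ``data`` is a DataFrame indexed by sample id whose columns are consensus
    retention times (float minutes, increasing).  Zero means "not detected".
    ``stage`` is one of ``aligned``, ``filtered``, ``relative`` or
    ``log_relative`` and gates which operations apply.
    """

    data: pd.DataFrame
    stage: str = "aligned"

    def __post_init__(self):
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        self.data = self.data.astype(float)
        cols = np.asarray(self.data.columns, dtype=float)
        if np.any(np.diff(cols) < 0):
            order = np.argsort(cols, kind="stable")
            self.data = self.data.iloc[:, order]
            cols = cols[order]
        self.data.columns = cols
        if (self.data.to_numpy() < 0).any():
            raise ValueError("abundances must be >= 0")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def substance_rts(self) -> np.ndarray:
        return np.asarray(self.data.columns, dtype=float)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_substances(self) -> int:
        return self.data.shape[1]

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, matrix is {self.stage!r}"
            )

    # -- plain-text round trip ------------------------------------------------
    def write(self, path: str | Path) -> None:
        """Write wide CSV (first column sample_id) plus a `.json` stage sidecar."""
        path = Path(path)
        out = self.data.copy()
        out.columns = [f"{c:.{RT_DECIMALS}f}" for c in self.substance_rts]
        out.index.name = "sample_id"
        out.to_csv(path)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(
            json.dumps({"stage": self.stage, "rt_decimals": RT_DECIMALS}) + "\n"
        )

    @classmethod
    def read(cls, path: str | Path, stage: str | None = None) -> "AlignedPeakMatrix":
        path = Path(path)
        df = pd.read_csv(path, index_col="sample_id")
        df.columns = [float(c) for c in df.columns]
        if stage is None:
            sidecar = path.with_suffix(path.suffix + ".json")
            stage = (
                json.loads(sidecar.read_text())["stage"] if sidecar.exists() else "aligned"
            )
        return cls(df, stage=stage)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_metadata(metadata_path: str | Path) -> pd.DataFrame:
    """Read the sample metadata table.

    Expected columns: ``sample_id, sex, pair_id, days_after_laying, is_blank``
    (empty string meaning "absent"; is_blank coded 0/1).  Blanks must carry no
    sex, pair id or laying day; non-blank samples must carry sex and laying
    day, and a pair id may be shared by at most two non-blank samples.
    """
    meta = pd.read_csv(metadata_path, dtype={"sample_id": str, "pair_id": str})
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise MetadataError(f"metadata missing columns: {sorted(missing)}")
    meta = meta[METADATA_COLUMNS].copy()
    if meta["sample_id"].duplicated().any():
        dup = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise MetadataError(f"duplicate sample_id in metadata: {dup}")
    meta["is_blank"] = meta["is_blank"].astype(int).astype(bool)
    meta["pair_id"] = meta["pair_id"].replace("", np.nan)
    meta["days_after_laying"] = pd.to_numeric(meta["days_after_laying"], errors="coerce")
    validate_metadata(meta)
    return meta.reset_index(drop=True)


def validate_metadata(meta: pd.DataFrame) -> None:
    blanks = meta[meta["is_blank"]]
    if (blanks["sex"].fillna("not-applicable") != "not-applicable").any():
        raise MetadataError("blank samples must have sex = not-applicable")
    if blanks["pair_id"].notna().any():
        raise MetadataError("blank samples cannot belong to a pair")
    biol = meta[~meta["is_blank"]]
    bad_sex = ~biol["sex"].isin(["female", "male"])
    if bad_sex.any():
        raise MetadataError(
            f"non-blank samples need sex in {{female, male}}: "
            f"{biol.loc[bad_sex, 'sample_id'].tolist()}"
        )
    if biol["days_after_laying"].isna().any():
        missing = biol.loc[biol["days_after_laying"].isna(), "sample_id"].tolist()
        raise MetadataError(f"non-blank samples need days_after_laying: {missing}")
    counts = biol["pair_id"].value_counts()
    if (counts > 2).any():
        raise MetadataError(
            f"pair_id shared by more than 2 samples: {counts[counts > 2].index.tolist()}"
        )


def _read_one_peak_file(path: Path, sample_id: str) -> RawPeakList:
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # noqa: BLE001 - surface file name
        raise PeakParseError(f"{path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "rt" not in cols or "area" not in cols:
        raise PeakParseError(f"{path}: expected columns 'rt' and 'area', got {list(df.columns)}")
    rt = pd.to_numeric(df[cols["rt"]], errors="coerce")
    area = pd.to_numeric(df[cols["area"]], errors="coerce")
    for name, col in (("rt", rt), ("area", area)):
        if col.isna().any():
            line = int(col.index[col.isna()][0]) + 2  # header + 1-based
            raise PeakParseError(f"{path}, line {line}: non-numeric {name}")
    if len(df) == 0:
        warnings.warn(f"{path}: empty peak list for sample {sample_id!r}", stacklevel=2)
    return RawPeakList(sample_id, rt.to_numpy(), area.to_numpy())


def read_peak_lists(
    paths: Iterable[str | Path], metadata_path: str | Path
) -> tuple[list[RawPeakList], pd.DataFrame]:
    """Read per-sample peak-list files plus the metadata table.

    Each file holds one sample (header ``rt,area``; comma or tab delimited)
    and its filename stem is the sample id.  A single long-format file with a
    ``sample_id`` column is also accepted.  Every sample id found in the peak
    files must appear exactly once in the metadata and vice versa.
    """
    meta = read_metadata(metadata_path)
    peak_lists: list[RawPeakList] = []
    for p in map(Path, paths):
        head = pd.read_csv(p, sep=None, engine="python", nrows=0)
        if "sample_id" in {c.strip().lower() for c in head.columns}:
            long = pd.read_csv(p, sep=None, engine="python", dtype={"sample_id": str})
            long.columns = [c.strip().lower() for c in long.columns]
            for sid, grp in long.groupby("sample_id", sort=False):
                peak_lists.append(
                    RawPeakList(
                        str(sid),
                        pd.to_numeric(grp["rt"]).to_numpy(),
                        pd.to_numeric(grp["area"]).to_numpy(),
                    )
                )
        else:
            peak_lists.append(_read_one_peak_file(p, p.stem))
    ids = [pl.sample_id for pl in peak_lists]
    if len(set(ids)) != len(ids):
        raise MetadataError("duplicate sample ids across peak files")
    meta_ids = set(meta["sample_id"])
    missing_meta = sorted(set(ids) - meta_ids)
    if missing_meta:
        raise MetadataError(f"peak files without metadata entry: {missing_meta}")
    missing_files = sorted(meta_ids - set(ids))
    if missing_files:
        raise MetadataError(f"metadata samples without a peak file: {missing_files}")
    order = {sid: i for i, sid in enumerate(ids)}
    meta = meta.sort_values("sample_id", key=lambda s: s.map(order)).reset_index(drop=True)
    return peak_lists, meta


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _greedy_clusters(peaks: pd.DataFrame, rt_tolerance: float) -> list[pd.DataFrame]:
    """Single-pass merge over globally sorted peaks.

    A cluster absorbs the next peak while it lies within ``2*rt_tolerance``
    of the cluster's first (lowest) retention time, bounding the within-
    cluster span by twice the tolerance.
    """
    clusters: list[pd.DataFrame] = []
    start = 0
    rts = peaks["rt"].to_numpy()
    for i in range(1, len(peaks) + 1):
        if i == len(peaks) or rts[i] - rts[start] > 2 * rt_tolerance:
            clusters.append(peaks.iloc[start:i])
            start = i
    return clusters


def align_peaks(
    peak_lists: Sequence[RawPeakList], rt_tolerance: float = 0.05
) -> AlignedPeakMatrix:
    """Cluster peaks across samples into substance columns by retention time.

    Within each greedy cluster a sample may contribute at most one peak: the
    peak nearest the cluster's consensus (mean) retention time wins, ties
    resolved toward the earlier retention time, and every displaced peak is
    re-clustered so it seeds a column of its own.  Columns are labelled by
    the mean retention time of their member peaks.

    Deterministic and invariant to the order of `peak_lists`.
    """
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be > 0")
    if len(peak_lists) < 2:
        raise ValueError("alignment needs at least 2 samples")
    sample_ids = [pl.sample_id for pl in peak_lists]
    pooled = pd.DataFrame(
        {
            "sample": np.repeat(sample_ids, [pl.n_peaks for pl in peak_lists]),
            "rt": np.concatenate([pl.rt for pl in peak_lists] or [[]]),
            "area": np.concatenate([pl.area for pl in peak_lists] or [[]]),
        }
    ).sort_values(["rt", "sample"], kind="stable", ignore_index=True)

    resolved: list[tuple[float, pd.DataFrame]] = []  # (consensus_rt, members)
    todo = pooled
    while len(todo):
        displaced = []
        for cluster in _greedy_clusters(todo, rt_tolerance):
            consensus = float(cluster["rt"].mean())
            keep_idx = []
            for _, grp in cluster.groupby("sample", sort=False):
                if len(grp) == 1:
                    keep_idx.append(grp.index[0])
                else:
                    # nearest to consensus wins; tie -> earlier retention time
                    dist = (grp["rt"] - consensus).abs()
                    winner = grp.loc[dist <= dist.min() + 1e-9, "rt"].idxmin()
                    keep_idx.append(winner)
                    displaced.append(grp.drop(index=winner))
            members = cluster.loc[sorted(keep_idx)]
            resolved.append((float(members["rt"].mean()), members))
        todo = (
            pd.concat(displaced).sort_values(["rt", "sample"], kind="stable")
            if displaced
            else pooled.iloc[:0]
        )

    resolved.sort(key=lambda c: c[0])
    data = pd.DataFrame(
        0.0, index=pd.Index(sample_ids, name="sample_id"), columns=[c[0] for c in resolved]
    )
    for j, (_, members) in enumerate(resolved):
        data.iloc[:, j] = members.set_index("sample")["area"].reindex(sample_ids).fillna(0.0)
    return AlignedPeakMatrix(data, stage="aligned")


# ---------------------------------------------------------------------------
# filtering and normalisation
# ---------------------------------------------------------------------------

def filter_substances(
    matrix: AlignedPeakMatrix, metadata: pd.DataFrame
) -> AlignedPeakMatrix:
    """Drop blank-borne and singleton substances, then drop the blank rows.

    Rule (a): any substance with non-zero abundance in at least one blank
    sample is treated as solvent/instrument contamination and removed — no
    abundance threshold, detection is categorical.  Rule (b): any substance
    detected in exactly one non-blank sample is removed as unreplicated.
    Column order is preserved; the result has stage ``filtered``.  The
    operation is idempotent: re-filtering an already filtered matrix (whose
    blank rows are gone) changes nothing.
    """
    matrix.require_stage("aligned", "filtered")
    meta = metadata.set_index("sample_id").reindex(matrix.sample_ids)
    if meta["is_blank"].isna().any():
        raise MetadataError("matrix contains samples absent from metadata")
    is_blank = meta["is_blank"].to_numpy(dtype=bool)
    if (~is_blank).sum() == 0:
        raise MetadataError("no non-blank samples")
    X = matrix.values
    in_blank = (X[is_blank] > 0).any(axis=0)
    detected_biol = (X[~is_blank] > 0).sum(axis=0)
    singleton = (~in_blank) & (detected_biol == 1)
    keep = ~(in_blank | singleton)
    if not keep.any():
        raise ValueError(
            "all substances removed: "
            f"{int(in_blank.sum())} blank-borne, {int(singleton.sum())} singleton"
        )
    data = matrix.data.loc[np.asarray(matrix.sample_ids)[~is_blank], matrix.data.columns[keep]]
    return AlignedPeakMatrix(data, stage="filtered")


def normalize_relative(matrix: AlignedPeakMatrix, scale: float = 100.0) -> AlignedPeakMatrix:
    """Convert areas to relative abundance: area / chromatogram total.

    Percent scale (0-100) by default, so that the subsequent log(X+1)
    transform spreads low-abundance substances instead of compressing
    everything toward zero.
    """
    matrix.require_stage("filtered")
    totals = matrix.values.sum(axis=1)
    if (totals <= 0).any():
        bad = [sid for sid, t in zip(matrix.sample_ids, totals) if t <= 0]
        raise ValueError(f"zero total area for samples {bad}")
    data = matrix.data.div(totals, axis=0) * scale
    return AlignedPeakMatrix(data, stage="relative")


def log_transform(matrix: AlignedPeakMatrix) -> AlignedPeakMatrix:
    """log(X+1) of relative abundances; zeros (non-detections) stay zero."""
    matrix.require_stage("relative")
    return AlignedPeakMatrix(np.log1p(matrix.data), stage="log_relative")


def process_pipeline(
    peak_lists: Sequence[RawPeakList],
    metadata: pd.DataFrame,
    rt_tolerance: float = 0.05,
    scale: float = 100.0,
    prealigned: AlignedPeakMatrix | None = None,
) -> AlignedPeakMatrix:
    """Convenience chain: align (unless pre-aligned) -> filter -> relative -> log."""
    aligned = prealigned if prealigned is not None else align_peaks(peak_lists, rt_tolerance)
    return log_transform(normalize_relative(filter_substances(aligned, metadata), scale))
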