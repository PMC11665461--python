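"""Domain types and on-disk formats for the peak-network pipeline.

The pipeline operates on three joined tables: a peaks x samples matrix of
normalized chromatin-accessibility values, a per-sample clinical table, and a
peak-to-gene relationship map, plus a GMT gene-set collection for enrichment.
Coordinates follow the BED convention (0-based, half-open) everywhere; peaks
are fixed-width 501-bp windows around summits in production inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

#: pack-years at or above which a patient counts as a heavy smoker
PACK_YEAR_CUTOFF = 20.0

#: fixed peak width of the reference peak set (summit +/- 250 bp)
CANONICAL_PEAK_WIDTH = 501

_COORD_COLUMNS = ("peak_id", "chrom", "start", "end")


@dataclass(frozen=True)
class Peak:
    """A fixed-width accessible-chromatin interval (BED half-open)."""

    peak_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"peak {self.peak_id!r}: end ({self.end}) must exceed start ({self.start})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


def default_peak_id(chrom: str, start: int, end: int) -> str:
    """Deterministic peak identifier used when an input lacks explicit ids."""
    return f"{chrom}:{start}-{end}"


@dataclass
class PeakMatrix:
    """Peaks x samples matrix of non-negative normalized accessibility.

    Rows are peaks, columns are samples; ``sample_group`` optionally labels
    each sample with its cancer type (used by the per-group low-quality
    filter and for cohort subsetting).
    """

    peaks: list[Peak]
    sample_ids: list[str]
    values: np.ndarray
    sample_group: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array (peaks x samples)")
        if self.values.shape != (len(self.peaks), len(self.sample_ids)):
            raise ValueError(
                f"shape mismatch: values {self.values.shape} vs "
                f"{len(self.peaks)} peaks x {len(self.sample_ids)} samples"
            )
        _check_unique([p.peak_id for p in self.peaks], "peak_id")
        _check_unique(self.sample_ids, "sample_id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(f"non-finite value at peak row {bad[0]}, sample column {bad[1]}")
        if np.any(self.values < 0):
            bad = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at peak {self.peaks[bad[0]].peak_id!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        off_width = sum(1 for p in self.peaks if p.width != CANONICAL_PEAK_WIDTH)
        if off_width:
            logger.warning(
                "%d/%d peaks deviate from the canonical %d-bp width",
                off_width, len(self.peaks), CANONICAL_PEAK_WIDTH,
            )
        if self.sample_group is not None:
            missing = [s for s in self.sample_ids if s not in self.sample_group]
            if missing:
                raise ValueError(f"sample_group lacks labels for {missing[:5]}")

    # -- conveniences -----------------------------------------------------

    @property
    def peak_ids(self) -> list[str]:
        return [p.peak_id for p in self.peaks]

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def groups(self) -> dict[str, np.ndarray]:
        """Sample-column indices per cancer-type group.

        Without group labels the whole cohort forms a single pseudo-group.
        """
        if self.sample_group is None:
            return {"all": np.arange(self.n_samples)}
        out: dict[str, list[int]] = {}
        for j, s in enumerate(self.sample_ids):
            out.setdefault(self.sample_group[s], []).append(j)
        return {g: np.asarray(ix) for g, ix in out.items()}

    def subset_peaks(self, peak_ids: Sequence[str]) -> "PeakMatrix":
        index = {p.peak_id: i for i, p in enumerate(self.peaks)}
        rows = [index[pid] for pid in peak_ids]
        return PeakMatrix(
            peaks=[self.peaks[i] for i in rows],
            sample_ids=list(self.sample_ids),
            values=self.values[rows],
            sample_group=dict(self.sample_group) if self.sample_group else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "PeakMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        group = None
        if self.sample_group is not None:
            group = {s: self.sample_group[s] for s in sample_ids}
        return PeakMatrix(
            peaks=list(self.peaks),
            sample_ids=list(sample_ids),
            values=self.values[:, cols],
            sample_group=group,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.peak_ids, columns=self.sample_ids)


@dataclass
class ClinicalRecord:
    """Per-patient covariates and right-censored survival endpoints.

    ``pack_years`` may be missing (None); zero is a meaningful value (a
    never-smoker) and is never used as a missing-data token.
    """

    sample_id: str
    pack_years: float | None = None
    os_time: float | None = None
    os_event: bool | None = None
    pfs_time: float | None = None
    pfs_event: bool | None = None
    age: float | None = None
    gender: str | None = None
    stage: str | None = None
    t_factor: str | None = None
    n_factor: str | None = None
    m_factor: str | None = None
    cancer_type: str | None = None

    def __post_init__(self) -> None:
        for name in ("pack_years", "os_time", "pfs_time"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.sample_id}: {name} must be non-negative, got {v}")

    @property
    def smoking_group(self) -> str:
        """'heavy' iff pack-years >= 20, 'light' below, 'unknown' if missing."""
        if self.pack_years is None:
            return "unknown"
        return "heavy" if self.pack_years >= PACK_YEAR_CUTOFF else "light"


@dataclass
class PeakGeneMap:
    """Many-to-many peak-to-gene relationships (as distributed alongside the
    reference pan-cancer peak set)."""

    entries: list[tuple[str, str]]

    def genes_for(self, peak_ids: Iterable[str]) -> list[str]:
        wanted = set(peak_ids)
        return sorted({g for p, g in self.entries if p in wanted})

    def all_genes(self) -> list[str]:
        return sorted({g for _, g in self.entries})

    def mapped_peaks(self) -> set[str]:
        return {p for p, _ in self.entries}


@dataclass
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    @property
    def size(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_unique(ids: Sequence[str], label: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {label}: {x!r}")
        seen.add(x)


def read_peak_matrix(path: str | Path, format: str = "tsv") -> PeakMatrix:
    """Read a peaks x samples matrix.

    ``tsv``: header row names samples; leading columns ``peak_id`` and
    optionally ``chrom``/``start``/``end``. ``mtx_triplet``: a Matrix Market
    file with sidecars ``<stem>.peaks.tsv`` (peak_id, chrom, start, end) and
    ``<stem>.samples.tsv`` (one sample id per line).
    """
    path = Path(path)
    if format == "tsv":
        return _read_matrix_tsv(path)
    if format == "mtx_triplet":
        return _read_matrix_mtx(path)
    raise ValueError(f"unknown matrix format {format!r}")


def _placeholder_peaks(peak_ids: Sequence[str]) -> list[Peak]:
    logger.warning("matrix lacks peak coordinates; using placeholder records")
    return [
        Peak(pid, "chrUn", i * CANONICAL_PEAK_WIDTH, (i + 1) * CANONICAL_PEAK_WIDTH)
        for i, pid in enumerate(peak_ids)
    ]


def _read_matrix_tsv(path: Path) -> PeakMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # check the raw header: pandas would silently mangle duplicate columns
    _check_unique(header, "column")
    df = pd.read_csv(path, sep="\t", dtype={"peak_id": str, "chrom": str})
    if "peak_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'peak_id' column")
    has_coords = {"chrom", "start", "end"}.issubset(df.columns)
    sample_cols = [c for c in df.columns if c not in _COORD_COLUMNS]
    _check_unique(sample_cols, "sample_id")
    _check_unique(df["peak_id"].tolist(), "peak_id")
    if has_coords:
        peaks = [
            Peak(r.peak_id, r.chrom, int(r.start), int(r.end))
            for r in df.itertuples(index=False)
        ]
    else:
        peaks = _placeholder_peaks(df["peak_id"].tolist())
    raw = df[sample_cols]
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at peak "
            f"{df['peak_id'].iat[i]!r}, sample {sample_cols[j]!r}"
        )
    return PeakMatrix(peaks=peaks, sample_ids=sample_cols, values=numeric.to_numpy(float))


def _read_matrix_mtx(path: Path) -> PeakMatrix:
    stem = path.with_suffix("")
    peaks_df = pd.read_csv(f"{stem}.peaks.tsv", sep="\t")
    sample_ids = Path(f"{stem}.samples.tsv").read_text().split()
    mat = scipy.io.mmread(path)
    values = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=float)
    peaks = [
        Peak(str(r.peak_id), str(r.chrom), int(r.start), int(r.end))
        for r in peaks_df.itertuples(index=False)
    ]
    return PeakMatrix(peaks=peaks, sample_ids=sample_ids, values=values)


def write_peak_matrix(matrix: PeakMatrix, path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if format == "tsv":
        df = pd.DataFrame(
            {
                "peak_id": matrix.peak_ids,
                "chrom": [p.chrom for p in matrix.peaks],
                "start": [p.start for p in matrix.peaks],
                "end": [p.end for p in matrix.peaks],
            }
        )
        df = pd.concat([df, matrix.to_frame().reset_index(drop=True)], axis=1)
        df.to_csv(path, sep="\t", index=False)
    elif format == "mtx_triplet":
        stem = path.with_suffix("")
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(matrix.values))
        pd.DataFrame(
            {
                "peak_id": matrix.peak_ids,
                "chrom": [p.chrom for p in matrix.peaks],
                "start": [p.start for p in matrix.peaks],
                "end": [p.end for p in matrix.peaks],
            }
        ).to_csv(f"{stem}.peaks.tsv", sep="\t", index=False)
        Path(f"{stem}.samples.tsv").write_text("\n".join(matrix.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def write_bed(matrix: PeakMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in matrix.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\n")


_CLINICAL_FLOATS = ("pack_years", "os_time", "pfs_time", "age")
_CLINICAL_BOOLS = ("os_event", "pfs_event")
_CLINICAL_STRS = ("gender", "stage", "t_factor", "n_factor", "m_factor", "cancer_type")


def _parse_event(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("", "na", "nan"):
            return None
        if s in ("1", "true", "yes", "event", "dead", "progressed"):
            return True
        if s in ("0", "false", "no", "censored", "alive"):
            return False
        raise ValueError(f"cannot interpret event flag {v!r}")
    return bool(int(v))


def read_clinical(path: str | Path) -> list[ClinicalRecord]:
    """Read the per-sample clinical TSV; unknown columns are ignored and
    missing values stay missing (empty / NA tokens, never 0)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required 'sample_id' column")
    _check_unique(df["sample_id"].tolist(), "sample_id")
    records = []
    for row in df.to_dict("records"):
        kwargs: dict = {"sample_id": row["sample_id"]}
        for c in _CLINICAL_FLOATS:
            if c in row and pd.notna(row[c]) and str(row[c]).strip() != "":
                kwargs[c] = float(row[c])
        for c in _CLINICAL_BOOLS:
            if c in row:
                kwargs[c] = _parse_event(row[c])
        for c in _CLINICAL_STRS:
            if c in row and pd.notna(row[c]) and str(row[c]).strip() != "":
                kwargs[c] = str(row[c])
        records.append(ClinicalRecord(**kwargs))
    return records


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    cols = ["sample_id", *_CLINICAL_FLOATS, *_CLINICAL_BOOLS, *_CLINICAL_STRS]
    rows = []
    for r in records:
        row = {}
        for c in cols:
            v = getattr(r, c)
            if c in _CLINICAL_BOOLS and v is not None:
                v = int(v)
            row[c] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def clinical_index(records: Sequence[ClinicalRecord]) -> dict[str, ClinicalRecord]:
    return {r.sample_id: r for r in records}


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, tab-separated genes)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >=3")
            name, desc = fields[0], fields[1]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g.strip()))
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            coll.sets[name] = GeneSet(name, desc, genes)
    if not coll.sets:
        logger.warning("%s: empty GMT file", path)
    logger.info("read %d gene sets from %s", len(coll), path)
    return coll


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def read_peak_gene_map(path: str | Path) -> PeakGeneMap:
    """Read a two-column (peak_id, gene) TSV; a header row is optional."""
    entries: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and fields[0].lower() in ("peak_id", "peak"):
                continue
            entries.append((fields[0], fields[1]))
    logger.info("read %d peak-gene links from %s", len(entries), path)
    return PeakGeneMap(entries=entries)


def write_peak_gene_map(pgmap: PeakGeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tgene\n")
        for p, g in pgmap.entries:
            fh.write(f"{p}\t{g}\n")
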