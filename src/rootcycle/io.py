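"""Readers and writers for the formats the pipeline touches.

Count matrices travel as Matrix Market sparse triplets with ``genes.tsv`` /
``barcodes.tsv`` sidecars (genes as rows) or as dense CSV; internally the
orientation is always genes x cells. Nucleus tracks and ROI measurements are
flat CSV tables. Every reader/writer pair round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Malformed input file: the message names the offending record."""


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse genes x cells matrix of non-negative integer counts."""

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes or len(self.cell_ids) != n_cells:
            raise FormatError(
                f"ID sidecars ({len(self.gene_ids)} genes, {len(self.cell_ids)} cells) "
                f"do not match matrix shape {self.counts.shape}"
            )
        for label, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = pd.Index(ids).duplicated()
            if dup.any():
                raise FormatError(f"duplicate {label} id: {ids[dup][0]!r}")
        data = self.counts.data
        if data.size and (data < 0).any():
            g, c = _first_offender(self.counts, data < 0)
            raise FormatError(f"negative count at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}")
        if data.size and np.any(data != np.round(data)):
            g, c = _first_offender(self.counts, data != np.round(data))
            raise FormatError(f"non-integer count at gene {self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}")
        self.counts = self.counts.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.gene_ids, columns=self.cell_ids)


def _first_offender(m: sp.csr_matrix, mask: np.ndarray) -> tuple[int, int]:
    coo = m.tocoo()
    i = int(np.flatnonzero(mask)[0])
    return int(coo.row[i]), int(coo.col[i])


def read_count_matrix(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Read a count matrix from an MTX directory or a dense CSV file.

    ``mtx_dir`` expects ``matrix.mtx`` plus ``genes.tsv`` and ``barcodes.tsv``
    sidecars with one ID per line; ``dense_csv`` expects genes as rows with a
    header of cell IDs.
    """
    path = Path(path)
    if format == "mtx_dir":
        mtx = path / "matrix.mtx"
        genes = path / "genes.tsv"
        barcodes = path / "barcodes.tsv"
        for f in (mtx, genes, barcodes):
            if not f.exists():
                raise FileNotFoundError(f)
        try:
            counts = sp.csr_matrix(scipy.io.mmread(mtx))
        except Exception as exc:  # scipy raises bare ValueError on bad headers
            raise FormatError(f"malformed Matrix Market file {mtx}: {exc}") from exc
        gene_ids = genes.read_text().split()
        cell_ids = barcodes.read_text().split()
        return CountMatrix(counts, np.array(gene_ids, dtype=object), np.array(cell_ids, dtype=object))
    if format == "dense_csv":
        df = pd.read_csv(path, index_col=0)
        dup = df.index.duplicated()
        if dup.any():
            raise FormatError(f"duplicate gene id: {df.index[dup][0]!r}")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError(f"non-numeric entries in {path}")
        return CountMatrix(
            sp.csr_matrix(values),
            df.index.to_numpy(dtype=object),
            df.columns.to_numpy(dtype=object),
        )
    raise ValueError(f"unknown format {format!r}")


def write_count_matrix(m: CountMatrix, path: str | Path, format: str = "mtx_dir") -> None:
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", m.counts.tocoo(), field="integer")
        (path / "genes.tsv").write_text("\n".join(map(str, m.gene_ids)) + "\n")
        (path / "barcodes.tsv").write_text("\n".join(map(str, m.cell_ids)) + "\n")
    elif format == "dense_csv":
        m.to_frame().to_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# cell metadata
# ---------------------------------------------------------------------------

LIBRARIES = ("control", "G1_enriched", "S_enriched", "G2M_enriched")
PHASES = ("G1", "S", "G2M")


def read_cell_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-cell metadata TSV (cell_id, library, cell_type[, true_phase])."""
    meta = pd.read_csv(path, sep="\t", dtype=str)
    return validate_cell_metadata(meta)


def validate_cell_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    required = {"cell_id", "library", "cell_type"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"cell metadata missing columns: {sorted(missing)}")
    dup = meta["cell_id"].duplicated()
    if dup.any():
        raise FormatError(f"duplicate cell id in metadata: {meta['cell_id'][dup].iloc[0]!r}")
    if meta["library"].isna().any() or (meta["library"] == "").any():
        raise FormatError("empty library label in metadata")
    unknown = set(meta["library"]) - set(LIBRARIES)
    if unknown:
        raise FormatError(f"unknown library label(s): {sorted(unknown)}")
    return meta.reset_index(drop=True)


def write_cell_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# nucleus tracks
# ---------------------------------------------------------------------------

TRACK_COLUMNS = ("track_id", "frame", "time_h", "cfp", "mcherry", "yfp",
                 "cell_file", "x", "y", "ablation_time_h")


@dataclass
class NucleusTrack:
    """Per-frame three-channel intensities for one tracked nucleus."""

    track_id: str
    cell_file: str
    time_h: np.ndarray
    cfp: np.ndarray
    mcherry: np.ndarray
    yfp: np.ndarray
    x: np.ndarray
    y: np.ndarray
    ablation_time_h: float | None = None
    truth: pd.DataFrame | None = field(default=None, repr=False)  # synthetic only

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        for name in ("cfp", "mcherry", "yfp", "x", "y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if len(self.time_h) < 2:
            raise FormatError(f"track {self.track_id!r} has fewer than 2 frames")
        if not np.all(np.diff(self.time_h) > 0):
            raise FormatError(f"non-monotone time within track {self.track_id!r}")

    @property
    def n_frames(self) -> int:
        return len(self.time_h)


def read_track_table(path: str | Path) -> list[NucleusTrack]:
    """Read nucleus tracks from CSV; rows are grouped by track and time-sorted.

    Row order in the file is irrelevant: the same set of rows always yields the
    same tracks. Duplicated (track_id, frame) rows are rejected.
    """
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"track table missing columns: {sorted(missing)}")
    if df.duplicated(subset=["track_id", "frame"]).any():
        bad = df[df.duplicated(subset=["track_id", "frame"])].iloc[0]
        raise FormatError(f"duplicated frame {bad['frame']} in track {bad['track_id']!r}")
    return tracks_from_frame(df)


def tracks_from_frame(df: pd.DataFrame) -> list[NucleusTrack]:
    tracks: list[NucleusTrack] = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("time_h")
        abl = g["ablation_time_h"].iloc[0]
        tracks.append(NucleusTrack(
            track_id=str(tid),
            cell_file=str(g["cell_file"].iloc[0]),
            time_h=g["time_h"].to_numpy(),
            cfp=g["cfp"].to_numpy(),
            mcherry=g["mcherry"].to_numpy(),
            yfp=g["yfp"].to_numpy(),
            x=g["x"].to_numpy(),
            y=g["y"].to_numpy(),
            ablation_time_h=None if pd.isna(abl) else float(abl),
        ))
    return tracks


def tracks_to_frame(tracks: Iterable[NucleusTrack]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for i in range(t.n_frames):
            rows.append({
                "track_id": t.track_id, "frame": i, "time_h": t.time_h[i],
                "cfp": t.cfp[i], "mcherry": t.mcherry[i], "yfp": t.yfp[i],
                "cell_file": t.cell_file, "x": t.x[i], "y": t.y[i],
                "ablation_time_h": np.nan if t.ablation_time_h is None else t.ablation_time_h,
            })
    return pd.DataFrame(rows, columns=list(TRACK_COLUMNS))


def write_track_table(tracks: Iterable[NucleusTrack], path: str | Path) -> None:
    tracks_to_frame(tracks).to_csv(path, index=False)


def frame_interval(tracks: Iterable[NucleusTrack]) -> float:
    """Median spacing between consecutive frames across all tracks (hours)."""
    gaps = np.concatenate([np.diff(t.time_h) for t in tracks])
    return float(np.median(gaps))
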