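"""Reference overlap store.

The method precomputes, for every CpG probe on the array, whether its position
falls inside a regulatory-region interval (DNase hotspot or histone-mark peak)
of each reference sample.  Per probe the result is a bitstring across the
samples of a dataset panel; bitstrings live in a single-file SQLite store,
organized by dataset so new panels append as new tables without touching
existing ones.

Coordinate conventions: manifests carry 1-based CpG positions; BED intervals
are 0-based half-open; a probe at 1-based position ``pos`` overlaps interval
``[start, end)`` iff ``start <= pos - 1 < end``.  Chromosome names must use
the chr-prefixed dialect (``chrN``); bare names are rejected, not coerced.
"""

from __future__ import annotations

import gzip
import io
import re
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import BedParseError, ManifestError, StoreError

FORMAT_VERSION = "1"

METADATA_COLUMNS = (
    "sample_id", "cell", "tissue", "datatype", "consortium", "accession", "filename",
)

Interval = tuple[str, int, int]


@dataclass(frozen=True)
class ProbeRecord:
    """One CpG probe: identifier, chr-prefixed chromosome, 1-based position, annotations."""

    probe_id: str
    chrom: str
    pos: int
    gene_group: str
    cpg_relation: str


@dataclass
class HotspotTrack:
    """One reference sample's merged regulatory intervals plus its metadata."""

    sample_id: str
    intervals: list[Interval]
    cell: str = ""
    tissue: str = ""
    datatype: str = "DNase"
    consortium: str = ""
    accession: str = ""
    filename: str = ""

    @classmethod
    def make(cls, sample_id: str, intervals: Iterable[Interval], **meta) -> "HotspotTrack":
        """Build a track, sorting and merging the intervals defensively."""
        return cls(sample_id=sample_id, intervals=merge_intervals(intervals), **meta)

    def metadata_row(self) -> dict[str, str]:
        return {c: getattr(self, c) for c in METADATA_COLUMNS}


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_bed(path) -> list[Interval]:
    """Read a BED3+ file into 0-based half-open intervals, in file order.

    Extra columns beyond the first three are ignored.  Malformed coordinates,
    zero- or negative-length intervals and non-chr-prefixed chromosome names
    raise :class:`BedParseError` naming the offending line.  An empty file
    yields an empty list.
    """
    intervals: list[Interval] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}")
            chrom = fields[0]
            if not chrom.startswith("chr"):
                raise BedParseError(
                    f"{path}: line {lineno}: chromosome {chrom!r} lacks the required "
                    f"'chr' prefix (chrN dialect)")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}") from None
            if start < 0:
                raise BedParseError(f"{path}: line {lineno}: negative start {start}")
            if end <= start:
                raise BedParseError(
                    f"{path}: line {lineno}: zero- or negative-length interval "
                    f"[{start}, {end})")
            intervals.append((chrom, start, end))
    return intervals


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Sort intervals by (chrom, start) and coalesce overlapping or abutting ones.

    The union of covered bases is preserved exactly; chromosomes are
    independent.  Empty input yields empty output.
    """
    merged: list[Interval] = []
    for chrom, start, end in sorted(intervals):
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            if end > prev[2]:
                merged[-1] = (chrom, prev[1], end)
        else:
            merged.append((chrom, start, end))
    return merged


@dataclass
class OverlapMatrix:
    """Boolean probe x sample overlap matrix with explicit orderings."""

    probe_ids: list[str]
    sample_ids: list[str]
    bits: np.ndarray  # bool, shape (n_probes, n_samples)

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise StoreError(
                f"overlap matrix shape {self.bits.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples")

    @property
    def probe_index(self) -> pd.Index:
        return pd.Index(self.probe_ids)

    def bitstring(self, i: int, cols: slice | None = None) -> str:
        row = self.bits[i] if cols is None else self.bits[i, cols]
        return "".join("1" if b else "0" for b in row)

    def select_samples(self, sample_ids: Sequence[str]) -> "OverlapMatrix":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [pos[s] for s in sample_ids]
        except KeyError as exc:
            raise StoreError(f"sample {exc.args[0]!r} not in store") from exc
        return OverlapMatrix(list(self.probe_ids), list(sample_ids),
                             self.bits[:, cols])


def _chrom_arrays(intervals: Sequence[Interval]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    out: dict[str, list[list[int]]] = {}
    for chrom, start, end in intervals:
        out.setdefault(chrom, [[], []])
        out[chrom][0].append(start)
        out[chrom][1].append(end)
    return {c: (np.asarray(s), np.asarray(e)) for c, (s, e) in out.items()}


def build_overlap_matrix(manifest, tracks: Sequence[HotspotTrack]) -> OverlapMatrix:
    """Point-in-interval containment of every probe against every track.

    ``bit[i, j]`` is 1 iff probe *i*'s 0-based position (``pos - 1``) lies in
    some merged interval of track *j* on the same chromosome.  Tracks whose
    intervals miss a probe's chromosome simply contribute zeros.
    """
    df = _as_manifest_frame(manifest)
    probe_ids = list(df["probe_id"])
    pos0 = df["pos"].to_numpy(dtype=np.int64) - 1
    chroms = df["chrom"].to_numpy()
    bits = np.zeros((len(probe_ids), len(tracks)), dtype=bool)
    chrom_rows = {c: np.flatnonzero(chroms == c) for c in pd.unique(chroms)}
    for j, track in enumerate(tracks):
        for chrom, (starts, ends) in _chrom_arrays(track.intervals).items():
            rows = chrom_rows.get(chrom)
            if rows is None or len(rows) == 0:
                continue
            q = pos0[rows]
            # merged + sorted intervals: the only candidate is the rightmost
            # interval starting at or before the query point
            idx = np.searchsorted(starts, q, side="right") - 1
            hit = idx >= 0
            hit[hit] = q[hit] < ends[idx[hit]]
            bits[rows, j] = hit
    return OverlapMatrix(probe_ids, [t.sample_id for t in tracks], bits)


# ---------------------------------------------------------------------------
# Manifest / metadata readers

_DEFAULT_MANIFEST_ALIASES = {
    "probe_id": ("probe_id", "IlmnID", "Name", "probe"),
    "chrom": ("chrom", "CHR", "chr", "chromosome"),
    "pos": ("pos", "MAPINFO", "position"),
    "gene_group": ("gene_group", "UCSC_RefGene_Group", "gene_annotation"),
    "cpg_relation": ("cpg_relation", "Relation_to_UCSC_CpG_Island", "cpg_island_relation"),
}

_GENE_TOKEN_FIXES = {
    "3'UTR": "3UTR", "5'UTR": "5UTR", "3′UTR": "3UTR", "5′UTR": "5UTR",
}


def first_gene_group(value: str) -> str:
    """Default reducer for multi-valued gene annotations: first semicolon-separated token."""
    return str(value).split(";")[0].strip()


def _as_manifest_frame(manifest) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        return manifest
    if manifest and isinstance(manifest[0], ProbeRecord):
        return pd.DataFrame(
            {
                "probe_id": [p.probe_id for p in manifest],
                "chrom": [p.chrom for p in manifest],
                "pos": [p.pos for p in manifest],
                "gene_group": [p.gene_group for p in manifest],
                "cpg_relation": [p.cpg_relation for p in manifest],
            }
        )
    raise ManifestError("manifest must be a DataFrame or a list of ProbeRecord")


def read_manifest(path, *, columns: dict[str, str] | None = None,
                  gene_group_reducer=first_gene_group) -> pd.DataFrame:
    """Read a probe manifest (tab- or comma-separated, header required).

    Column names are resolved through ``columns`` (canonical -> file column) or
    a built-in alias list covering both the synthetic-fixture and
    Illumina-style headers.  Multi-valued gene annotations are collapsed by
    ``gene_group_reducer`` (default: first listed group); empty gene
    annotation becomes IGR and empty island relation becomes OpenSea.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    resolved: dict[str, str] = {}
    for canon, aliases in _DEFAULT_MANIFEST_ALIASES.items():
        wanted = (columns or {}).get(canon)
        cands = (wanted,) if wanted else aliases
        col = next((c for c in cands if c in df.columns), None)
        if col is None:
            raise ManifestError(
                f"manifest {path}: no column found for {canon!r} "
                f"(tried {', '.join(filter(None, cands))})")
        resolved[canon] = col
    out = pd.DataFrame({canon: df[col] for canon, col in resolved.items()})
    out["gene_group"] = (
        out["gene_group"].fillna("").map(gene_group_reducer)
        .map(lambda t: _GENE_TOKEN_FIXES.get(t, t))
        .replace("", "IGR")
    )
    out["cpg_relation"] = out["cpg_relation"].fillna("OpenSea").replace("", "OpenSea")
    bad_chrom = ~out["chrom"].fillna("").str.startswith("chr")
    if bad_chrom.any():
        example = out.loc[bad_chrom, "chrom"].iloc[0]
        raise ManifestError(
            f"manifest {path}: chromosome names must use the chr-prefixed dialect "
            f"(chrN); found {example!r}")
    try:
        out["pos"] = out["pos"].astype(np.int64)
    except (TypeError, ValueError) as exc:
        raise ManifestError(f"manifest {path}: non-integer probe position: {exc}") from None
    if (out["pos"] < 1).any():
        raise ManifestError(f"manifest {path}: probe positions must be >= 1 (1-based)")
    dup = out["probe_id"].duplicated()
    if dup.any():
        raise ManifestError(
            f"manifest {path}: duplicate probe id {out.loc[dup, 'probe_id'].iloc[0]!r}")
    return out.reset_index(drop=True)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the tab-separated sample sheet (sample_id, cell, tissue, datatype, consortium, accession, filename)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestError(f"sample sheet {path}: missing columns {missing}")
    return df[list(METADATA_COLUMNS)]


# ---------------------------------------------------------------------------
# SQLite persistence

_DATASET_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")


def _validate_metadata(metadata: pd.DataFrame, matrix: OverlapMatrix) -> pd.DataFrame:
    meta = metadata.copy()
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise StoreError(f"sample metadata missing columns {missing}")
    if list(meta["sample_id"]) != list(matrix.sample_ids):
        raise StoreError("sample metadata rows must match matrix sample order")
    return meta[list(METADATA_COLUMNS)].fillna("")


def persist_store(matrix: OverlapMatrix, metadata: pd.DataFrame, path, *,
                  dataset: str = "panel", append: bool = False) -> None:
    """Write (or append) one dataset panel of per-probe bitstrings to a SQLite store.

    Appending adds a new bitstring table and its sample metadata without
    rewriting existing datasets; the probe universe must match the store's.
    """
    if not _DATASET_NAME_RE.match(dataset):
        raise StoreError(f"dataset name {dataset!r} must match [A-Za-z0-9_]+")
    meta = _validate_metadata(metadata, matrix)
    path = Path(path)
    if not append and path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    try:
        cur = con.cursor()
        if append:
            version = dict(cur.execute("SELECT key, value FROM store_info")).get(
                "format_version")
            if version != FORMAT_VERSION:
                raise StoreError(
                    f"store {path}: format version {version!r} != {FORMAT_VERSION!r}")
            stored = [r[0] for r in cur.execute(
                "SELECT probe_id FROM probes ORDER BY idx")]
            if stored != list(matrix.probe_ids):
                raise StoreError(
                    "appended panel's probe universe differs from the store's")
            if cur.execute("SELECT 1 FROM datasets WHERE name = ?", (dataset,)).fetchone():
                raise StoreError(f"dataset {dataset!r} already in store {path}")
        else:
            cur.executescript(
                """
                CREATE TABLE store_info (key TEXT PRIMARY KEY, value TEXT);
                CREATE TABLE probes (idx INTEGER PRIMARY KEY, probe_id TEXT UNIQUE);
                CREATE TABLE datasets (ord INTEGER PRIMARY KEY, name TEXT UNIQUE,
                                       n_samples INTEGER);
                CREATE TABLE samples (dataset TEXT, idx INTEGER, sample_id TEXT,
                                      cell TEXT, tissue TEXT, datatype TEXT,
                                      consortium TEXT, accession TEXT, filename TEXT,
                                      PRIMARY KEY (dataset, idx));
                """
            )
            cur.execute("INSERT INTO store_info VALUES ('format_version', ?)",
                        (FORMAT_VERSION,))
            cur.executemany("INSERT INTO probes VALUES (?, ?)",
                            list(enumerate(matrix.probe_ids)))
        cur.execute("INSERT INTO datasets (name, n_samples) VALUES (?, ?)",
                    (dataset, len(matrix.sample_ids)))
        cur.executemany(
            "INSERT INTO samples VALUES (?, ?, ?, ?, ?, ?, ?, ?, ?)",
            [(dataset, j, *[row[c] for c in METADATA_COLUMNS])
             for j, (_, row) in enumerate(meta.iterrows())],
        )
        cur.execute(
            f'CREATE TABLE "bits_{dataset}" (probe_id TEXT PRIMARY KEY, bits TEXT)')
        cur.executemany(
            f'INSERT INTO "bits_{dataset}" VALUES (?, ?)',
            [(pid, matrix.bitstring(i)) for i, pid in enumerate(matrix.probe_ids)],
        )
        con.commit()
    finally:
        con.close()


def store_datasets(path) -> list[str]:
    """Names of the dataset panels in a store, in insertion order."""
    con = _open_store(path)
    try:
        return [r[0] for r in con.execute("SELECT name FROM datasets ORDER BY ord")]
    finally:
        con.close()


def _open_store(path) -> sqlite3.Connection:
    path = Path(path)
    if not path.exists():
        raise StoreError(f"store {path}: no such file")
    con = sqlite3.connect(path)
    try:
        ok = con.execute("PRAGMA integrity_check").fetchone()
        if ok is None or ok[0] != "ok":
            raise StoreError(f"store {path}: failed integrity check (truncated or corrupt)")
        version = dict(con.execute("SELECT key, value FROM store_info")).get(
            "format_version")
        if version != FORMAT_VERSION:
            raise StoreError(
                f"store {path}: format version {version!r}, expected {FORMAT_VERSION!r}")
    except sqlite3.DatabaseError as exc:
        con.close()
        raise StoreError(f"store {path}: unreadable ({exc})") from exc
    except StoreError:
        con.close()
        raise
    return con


def load_store(path, *, datasets: Sequence[str] | None = None
               ) -> tuple[OverlapMatrix, pd.DataFrame]:
    """Load bitstrings back into an :class:`OverlapMatrix` plus sample metadata.

    Round-trips :func:`persist_store` exactly (bits, probe order, sample
    order, metadata).  ``datasets`` selects panels; default is all, in
    insertion order.  The returned metadata gains a ``dataset`` column.
    """
    con = _open_store(path)
    try:
        probe_ids = [r[0] for r in con.execute(
            "SELECT probe_id FROM probes ORDER BY idx")]
        available = [r[0] for r in con.execute(
            "SELECT name FROM datasets ORDER BY ord")]
        chosen = list(datasets) if datasets is not None else available
        unknown = set(chosen) - set(available)
        if unknown:
            raise StoreError(f"store {path}: unknown dataset(s) {sorted(unknown)}")
        blocks: list[np.ndarray] = []
        sample_ids: list[str] = []
        meta_rows: list[tuple] = []
        for name in chosen:
            rows = con.execute(
                "SELECT sample_id, cell, tissue, datatype, consortium, accession, "
                "filename FROM samples WHERE dataset = ? ORDER BY idx", (name,)
            ).fetchall()
            n_samples = len(rows)
            sample_ids.extend(r[0] for r in rows)
            meta_rows.extend((*r, name) for r in rows)
            bit_of = dict(con.execute(f'SELECT probe_id, bits FROM "bits_{name}"'))
            try:
                strings = [bit_of[pid] for pid in probe_ids]
            except KeyError as exc:
                raise StoreError(
                    f"store {path}: dataset {name!r} missing probe {exc.args[0]!r}"
                ) from exc
            if any(len(s) != n_samples for s in strings):
                raise StoreError(
                    f"store {path}: dataset {name!r} bitstring length mismatch")
            block = (np.frombuffer("".join(strings).encode("ascii"), dtype=np.uint8)
                     .reshape(len(probe_ids), n_samples) == ord("1"))
            blocks.append(block)
        bits = (np.hstack(blocks) if blocks
                else np.zeros((len(probe_ids), 0), dtype=bool))
        metadata = pd.DataFrame(meta_rows,
                                columns=[*METADATA_COLUMNS, "dataset"])
        return OverlapMatrix(probe_ids, sample_ids, bits), metadata
    except sqlite3.DatabaseError as exc:
        raise StoreError(f"store {path}: unreadable ({exc})") from exc
    finally:
        con.close()
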