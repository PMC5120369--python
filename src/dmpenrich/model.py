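"""Enrichment model and results.

:class:`EnrichmentModel` bundles a probe-set input, an overlap store, and a
manifest; :meth:`EnrichmentModel.fit` runs the whole pipeline — resolve and
filter the input, draw 1,000 annotation-matched background sets, count
hotspot overlaps per reference sample, compute the log-space binomial tail
p-value and background Z-score, BY-correct across the panel, and tier each
sample — returning an :class:`EnrichmentResults` with the per-sample table,
a text summary, TSV/JSON writers, and the significance plot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .annotation import BinIndex, build_bin_index
from .errors import DmpEnrichError, StoreError
from .sampling import (DEFAULT_MAX_PROBES, DEFAULT_MIN_PROBES,
                       DEFAULT_N_BACKGROUNDS, DEFAULT_PROXIMITY_BP,
                       BackgroundEnsemble, TestSet, build_test_set,
                       proximity_filter, sample_background)
from .stats import (bh_adjust, binom_upper_tail_log, by_adjust,
                    p_threshold_for_q, zscore)
from .store import (METADATA_COLUMNS, OverlapMatrix, load_store, read_manifest,
                    _as_manifest_frame, _open_text)

Q_RED = 0.01
Q_PINK = 0.05

TSV_COLUMNS = ["Zscore", "Pvalue", "Cell", "Tissue", "Datatype", "File",
               "Probe", "Accession", "Qvalue"]


def tier_for_q(q: float) -> str:
    """Significance tier from the BY q-value: red < 0.01 <= pink < 0.05 <= blue."""
    if q < Q_RED:
        return "red"
    if q < Q_PINK:
        return "pink"
    return "blue"


@dataclass
class EnrichmentRecord:
    """Per-sample test result as written to the output table."""

    sample_id: str
    cell: str
    tissue: str
    datatype: str
    filename: str
    accession: str
    k: int
    n: int
    p0: float
    z: float
    log_p: float
    p: float
    q_by: float
    q_bh: float
    tier: str
    contributing_probes: list[str] = field(default_factory=list)


@dataclass
class RunConfig:
    """File-level configuration for one analysis run."""

    input: str
    store: str
    manifest: str
    input_format: str = "auto"
    panel: str | None = None
    n_backgrounds: int = DEFAULT_N_BACKGROUNDS
    proximity_bp: int = DEFAULT_PROXIMITY_BP
    min_probes: int = DEFAULT_MIN_PROBES
    max_probes: int = DEFAULT_MAX_PROBES
    strict: bool = True
    probe_allowlist: str | None = None
    seed: int | None = None
    outdir: str | None = None
    basename: str = "enrichment"


class EnrichmentModel:
    """Probe-set enrichment against a reference overlap store.

    Parameters
    ----------
    probes : path or iterable of lines
        Input probe set (probe ids one per line, or BED records).
    store : path, or (OverlapMatrix, metadata DataFrame)
        The reference overlap store; a path is loaded from SQLite.
    manifest : path or DataFrame
        Probe manifest with coordinates and annotations.
    panel : str, optional
        Restrict to one dataset panel of the store.
    where : dict, optional
        Metadata filters, e.g. ``{"datatype": "H3K4me1"}``.
    """

    def __init__(self, probes, store, manifest, *, panel: str | None = None,
                 where: dict[str, str] | None = None,
                 input_format: str = "auto",
                 n_backgrounds: int = DEFAULT_N_BACKGROUNDS,
                 proximity_bp: int = DEFAULT_PROXIMITY_BP,
                 min_probes: int = DEFAULT_MIN_PROBES,
                 max_probes: int = DEFAULT_MAX_PROBES,
                 strict: bool = True,
                 probe_allowlist=None,
                 min_bin_size: int = 0):
        self.probes = probes
        if isinstance(store, (str, Path)):
            datasets = [panel] if panel else None
            matrix, metadata = load_store(store, datasets=datasets)
        else:
            matrix, metadata = store
            if panel is not None and "dataset" in metadata.columns:
                keep = metadata["dataset"] == panel
                matrix = matrix.select_samples(list(metadata.loc[keep, "sample_id"]))
                metadata = metadata.loc[keep].reset_index(drop=True)
        if where:
            mask = np.ones(len(metadata), dtype=bool)
            for col, val in where.items():
                mask &= (metadata[col] == val).to_numpy()
            metadata = metadata.loc[mask].reset_index(drop=True)
            matrix = matrix.select_samples(list(metadata["sample_id"]))
        if len(matrix.sample_ids) == 0:
            raise StoreError("no reference samples selected for the analysis")
        self.matrix = matrix
        self.metadata = metadata.set_index("sample_id", drop=False)
        self.manifest = (read_manifest(manifest)
                         if isinstance(manifest, (str, Path))
                         else _as_manifest_frame(manifest))
        self.panel = panel
        self.input_format = input_format
        self.n_backgrounds = int(n_backgrounds)
        self.proximity_bp = int(proximity_bp)
        self.min_probes = int(min_probes)
        self.max_probes = int(max_probes)
        self.strict = bool(strict)
        if isinstance(probe_allowlist, (str, Path)):
            with _open_text(probe_allowlist) as fh:
                probe_allowlist = [ln.strip() for ln in fh if ln.strip()]
        self.probe_allowlist = probe_allowlist
        self._bin_index: BinIndex | None = None
        self._min_bin_size = min_bin_size

    @classmethod
    def from_files(cls, input_path, store_path, manifest_path, **kwargs
                   ) -> "EnrichmentModel":
        return cls(input_path, store_path, manifest_path, **kwargs)

    @property
    def bin_index(self) -> BinIndex:
        if self._bin_index is None:
            self._bin_index = build_bin_index(self.manifest,
                                              min_bin_size=self._min_bin_size)
        return self._bin_index

    def fit(self, seed: int | None = None) -> "EnrichmentResults":
        """Run the full analysis; deterministic given ``seed``."""
        rng = np.random.default_rng(seed)
        test_set = build_test_set(
            self.probes, self.manifest, fmt=self.input_format,
            proximity_bp=self.proximity_bp, min_probes=self.min_probes,
            max_probes=self.max_probes, strict=self.strict,
            probe_allowlist=self.probe_allowlist, rng=rng, rng_seed=seed)
        ensemble = sample_background(test_set.probe_ids, self.bin_index,
                                     n_sets=self.n_backgrounds, rng=rng,
                                     rng_seed=seed)
        records = _test_records(test_set, ensemble, self.matrix, self.metadata)
        return EnrichmentResults(records=records, test_set=test_set,
                                 seed=seed, params=self._params())

    def _params(self) -> dict:
        return {
            "panel": self.panel,
            "n_backgrounds": self.n_backgrounds,
            "proximity_bp": self.proximity_bp,
            "min_probes": self.min_probes,
            "max_probes": self.max_probes,
            "strict": self.strict,
            "n_samples": len(self.matrix.sample_ids),
            "rng": "numpy PCG64 (default_rng)",
            "version": _version,
        }


def _overlap_counts(matrix: OverlapMatrix, test_ids: Sequence[str],
                    ensemble: BackgroundEnsemble
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(k per sample, background counts (n_sets, n_samples), test-row bits)."""
    index = matrix.probe_index
    rows = index.get_indexer(list(test_ids))
    if (rows < 0).any():
        missing = [p for p, r in zip(test_ids, rows) if r < 0]
        raise StoreError(
            f"{len(missing)} analyzable probe(s) absent from the overlap store "
            f"(first: {missing[0]!r})")
    test_bits = matrix.bits[rows]
    k_vec = test_bits.sum(axis=0)
    flat = index.get_indexer(ensemble.sets.ravel().tolist())
    if (flat < 0).any():
        raise StoreError("background probe absent from the overlap store")
    bg_idx = flat.reshape(ensemble.sets.shape)
    bg_counts = matrix.bits[bg_idx].sum(axis=1)
    return k_vec, bg_counts, test_bits


def _test_records(test_set: TestSet, ensemble: BackgroundEnsemble,
                  matrix: OverlapMatrix, metadata: pd.DataFrame
                  ) -> list[EnrichmentRecord]:
    n = test_set.size
    n_sets = ensemble.n_sets
    k_vec, bg_counts, test_bits = _overlap_counts(matrix, test_set.probe_ids,
                                                  ensemble)
    # pooled background overlap proportion per sample, floored at half a
    # pseudo-count so enrichment over an empty background stays reportable
    p0 = bg_counts.sum(axis=0) / float(n_sets * n)
    floor = 1.0 / (2.0 * n_sets * n)
    p0 = np.where(p0 == 0.0, floor, p0)
    log_p = np.array([binom_upper_tail_log(int(k), n, float(q))
                      for k, q in zip(k_vec, p0)])
    p = np.minimum(np.exp(log_p), 1.0)
    z = np.array([zscore(float(k), bg_counts[:, j])
                  for j, k in enumerate(k_vec)])
    q_by = by_adjust(p)
    q_bh = bh_adjust(p)
    records = []
    probe_arr = np.asarray(test_set.probe_ids, dtype=object)
    for j, sid in enumerate(matrix.sample_ids):
        meta = metadata.loc[sid]
        records.append(EnrichmentRecord(
            sample_id=sid, cell=str(meta["cell"]), tissue=str(meta["tissue"]),
            datatype=str(meta["datatype"]), filename=str(meta["filename"]),
            accession=str(meta["accession"]), k=int(k_vec[j]), n=n,
            p0=float(p0[j]), z=float(z[j]), log_p=float(log_p[j]),
            p=float(p[j]), q_by=float(q_by[j]), q_bh=float(q_bh[j]),
            tier=tier_for_q(float(q_by[j])),
            contributing_probes=list(probe_arr[test_bits[:, j]]),
        ))
    return records


def _sorted_records(records: Sequence[EnrichmentRecord]) -> list[EnrichmentRecord]:
    # cells grouped alphabetically within each tissue; tissues alphabetical
    return sorted(records, key=lambda r: (r.tissue, r.cell, r.sample_id))


class EnrichmentResults:
    """Fitted per-sample enrichment results."""

    def __init__(self, records: list[EnrichmentRecord], test_set: TestSet,
                 seed: int | None, params: dict):
        self.records = records
        self.test_set = test_set
        self.seed = seed
        self.params = params

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            d = asdict(r)
            d["contributing_probes"] = ",".join(r.contributing_probes)
            rows.append(d)
        return pd.DataFrame(rows)

    def top(self) -> EnrichmentRecord:
        """The most enriched sample (smallest q, ties by smallest p)."""
        return min(self.records, key=lambda r: (r.q_by, r.p))

    def summary(self) -> str:
        ts = self.test_set
        par = self.params
        lines = [
            "Probe-set regulatory-region enrichment",
            "=" * 54,
            f"Analyzable probes : {ts.size}   "
            f"(off-array: {len(ts.excluded_missing)}, "
            f"proximity-filtered: {len(ts.excluded_proximal)})",
            f"Reference samples : {par['n_samples']}"
            + (f"   panel: {par['panel']}" if par.get("panel") else ""),
            f"Backgrounds       : {par['n_backgrounds']} annotation-matched sets"
            f"   seed: {self.seed}   rng: {par['rng']}",
            "Correction        : Benjamini-Yekutieli across the panel "
            "(BH co-reported)",
            "-" * 54,
            f"{'sample':<12}{'tissue':<12}{'k':>5}{'n':>6}{'Z':>9}"
            f"{'p':>12}{'q_BY':>12}  tier",
        ]
        for r in sorted(self.records, key=lambda x: (x.q_by, x.p))[:10]:
            z_txt = f"{r.z:9.2f}" if np.isfinite(r.z) else f"{'inf*':>9}"
            lines.append(
                f"{r.sample_id:<12}{r.tissue:<12}{r.k:>5}{r.n:>6}{z_txt}"
                f"{r.p:>12.3e}{r.q_by:>12.3e}  {r.tier}")
        n_red = sum(r.tier == "red" for r in self.records)
        n_pink = sum(r.tier == "pink" for r in self.records)
        lines.append("-" * 54)
        lines.append(f"Tiers: {n_red} red (q<{Q_RED}), {n_pink} pink "
                     f"(q<{Q_PINK}), "
                     f"{len(self.records) - n_red - n_pink} blue")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        write_tsv(self.records, path)

    def plot(self, path=None, ax=None):
        return render_plot(self.records, path, ax=ax)

    def to_json(self, path=None):
        payload = {
            "seed": self.seed,
            "params": self.params,
            "n_probes": self.test_set.size,
            "excluded_missing": self.test_set.excluded_missing,
            "excluded_proximal": self.test_set.excluded_proximal,
            "samples": [
                {k: v for k, v in asdict(r).items() if k != "contributing_probes"}
                for r in _sorted_records(self.records)
            ],
        }
        if path is None:
            return payload
        Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")
        return payload

    def write_log(self, path) -> None:
        ts = self.test_set
        lines = [
            f"# dmpenrich {self.params['version']}",
            f"seed\t{self.seed}",
            f"rng\t{self.params['rng']}",
        ]
        lines += [f"{key}\t{self.params[key]}" for key in
                  ("panel", "n_backgrounds", "proximity_bp", "min_probes",
                   "max_probes", "strict", "n_samples")]
        lines.append(f"analyzable_probes\t{ts.size}")
        lines.append("excluded_missing\t" + ",".join(ts.excluded_missing))
        lines.append("excluded_proximal\t" + ",".join(ts.excluded_proximal))
        Path(path).write_text("\n".join(lines) + "\n")


def write_tsv(records: Sequence[EnrichmentRecord], path) -> None:
    """Write the per-sample table: Zscore, Pvalue, Cell, Tissue, Datatype, File, Probe, Accession, Qvalue.

    Rows sort by tissue then cell (alphabetical); floats use shortest
    round-trip serialization so a re-parse reproduces them exactly; the Probe
    column comma-joins the contributing probes (empty for k = 0).
    """
    if not records:
        raise ValueError("no records to write")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for r in _sorted_records(records):
            fh.write("\t".join([
                repr(r.z), repr(r.p), r.cell, r.tissue, r.datatype, r.filename,
                ",".join(r.contributing_probes), r.accession, repr(r.q_by),
            ]) + "\n")


def read_tsv(path) -> pd.DataFrame:
    """Parse a results table written by :func:`write_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("Zscore", "Pvalue", "Qvalue"):
        df[col] = df[col].astype(float)
    return df


_TIER_COLORS = {"blue": "#4575b4", "pink": "#f768a1", "red": "#d73027"}


def render_plot(records: Sequence[EnrichmentRecord], path=None, *, ax=None):
    """Significance plot: one point per sample, -log10(binomial p) on y.

    Samples are grouped alphabetically by tissue then cell on x; points are
    colored by q-tier, and dashed lines mark the raw-p boundaries implied by
    the family's BY q = 0.05 and q = 0.01 thresholds.
    """
    import matplotlib
    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    recs = _sorted_records(records)
    if ax is None:
        fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(recs)), 4.5))
    else:
        fig = ax.figure
    y = [-np.log10(max(r.p, 1e-300)) for r in recs]
    colors = [_TIER_COLORS[r.tier] for r in recs]
    ax.scatter(range(len(recs)), y, c=colors, s=36, zorder=3)
    pvals = [r.p for r in recs]
    for q_thr, color, label in ((Q_PINK, "green", "q = 0.05"),
                                (Q_RED, "red", "q = 0.01")):
        p_b = p_threshold_for_q(pvals, q_thr, method="by")
        ax.axhline(-np.log10(p_b), color=color, linestyle="--", linewidth=1,
                   label=label)
    ax.set_xticks(range(len(recs)))
    ax.set_xticklabels([f"{r.cell}\n({r.tissue})" for r in recs], rotation=90,
                       fontsize=7)
    ax.set_ylabel(r"$-\log_{10}$ binomial p")
    ax.set_xlabel("reference sample (grouped by tissue, alphabetical)")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return ax


def run_analysis(config: RunConfig) -> list[EnrichmentRecord]:
    """File-to-file orchestration of one run, per the run configuration.

    Writes, when ``config.outdir`` is set: the results TSV, a run log with
    seed and exclusion lists, a JSON summary, and the significance plot.
    """
    model = EnrichmentModel(
        config.input, config.store, config.manifest, panel=config.panel,
        input_format=config.input_format, n_backgrounds=config.n_backgrounds,
        proximity_bp=config.proximity_bp, min_probes=config.min_probes,
        max_probes=config.max_probes, strict=config.strict,
        probe_allowlist=config.probe_allowlist)
    results = model.fit(seed=config.seed)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        base = config.basename
        results.to_tsv(outdir / f"{base}.tsv")
        results.write_log(outdir / f"{base}.log")
        results.to_json(outdir / f"{base}.json")
        results.plot(outdir / f"{base}.pdf")
    return results.records


def fp_benchmark(store, manifest, *, sizes=(5, 10, 15, 20, 30, 40, 50, 100),
                 runs_per_size: int = 10,
                 n_backgrounds: int = DEFAULT_N_BACKGROUNDS,
                 proximity_bp: int = DEFAULT_PROXIMITY_BP,
                 seed: int | None = None, count_only: bool = False
                 ) -> pd.DataFrame:
    """Null false-positive benchmark on randomly drawn probe sets.

    For every size in ``sizes``, draws ``runs_per_size`` uniform random probe
    sets from the manifest, runs the full analysis (lenient size bounds, the
    grid deliberately spans sets smaller than the recommended minimum), and
    tabulates sample tests reaching q < 0.05 and q < 0.01 under both BH and
    BY.  ``count_only`` skips the statistics and only accumulates the
    bookkeeping (sets drawn, sample tests counted), which is how the protocol
    total (sets x panel size) is audited.

    Returns one row per size with columns ``size, runs, tests, bh_q05,
    bh_q01, by_q05, by_q01`` (count_only leaves the q columns at 0).
    """
    rng = np.random.default_rng(seed)
    if isinstance(store, (str, Path)):
        matrix, metadata = load_store(store)
    else:
        matrix, metadata = store
    manifest_df = (read_manifest(manifest) if isinstance(manifest, (str, Path))
                   else _as_manifest_frame(manifest))
    n_samples = len(matrix.sample_ids)
    all_ids = manifest_df["probe_id"].to_numpy(dtype=object)
    bin_index = None if count_only else build_bin_index(manifest_df, min_bin_size=0)
    meta_indexed = metadata.set_index("sample_id", drop=False)
    rows = []
    for size in sizes:
        counters = {"tests": 0, "bh_q05": 0, "bh_q01": 0, "by_q05": 0, "by_q01": 0}
        for _ in range(runs_per_size):
            ids = list(rng.choice(all_ids, size=size, replace=False))
            if count_only:
                counters["tests"] += n_samples
                continue
            retained, _prox = proximity_filter(ids, manifest_df,
                                               min_bp=proximity_bp, rng=rng)
            test_set = TestSet(retained)
            ensemble = sample_background(retained, bin_index,
                                         n_sets=n_backgrounds, rng=rng)
            records = _test_records(test_set, ensemble, matrix, meta_indexed)
            counters["tests"] += len(records)
            counters["bh_q05"] += sum(r.q_bh < Q_PINK for r in records)
            counters["bh_q01"] += sum(r.q_bh < Q_RED for r in records)
            counters["by_q05"] += sum(r.q_by < Q_PINK for r in records)
            counters["by_q01"] += sum(r.q_by < Q_RED for r in records)
        rows.append({"size": size, "runs": runs_per_size, **counters})
    out = pd.DataFrame(rows)
    out.attrs["total_tests"] = int(out["tests"].sum())
    out.attrs["seed"] = seed
    return out
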