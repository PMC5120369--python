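"""Synthetic fixtures: toy manifests, hotspot panels, and planted probe sets.

The generator emulates only the structure the method consumes — probe
coordinates with annotations, and per-sample interval tracks that cover each
probe independently with a null probability pi0 (or an elevated pi1 for a
designated probe subset in "planted" samples).  Everything is driven by one
explicitly seeded generator (numpy PCG64 via ``default_rng``) so fixtures and
analyses replay exactly; ground truth is written from the same draw that
produced the data, never re-estimated.
"""

from __future__ import annotations

import bisect
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import CPG_RELATIONS_RAW, GENE_GROUPS, all_bin_labels
from .errors import FixtureError
from .store import METADATA_COLUMNS, HotspotTrack

RNG_NAME = "numpy PCG64 (default_rng)"

_RAW_FOR_CATEGORY = {
    "Island": ("Island",),
    "Shore_Shelf": ("N_Shore", "S_Shore", "N_Shelf", "S_Shelf"),
    "OpenSea": ("OpenSea",),
}


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study.

    Defaults give a 3 x 10 Mb toy genome with 5,000 probes and a 20-sample
    panel: small enough for quadratic brute-force oracles, large enough that
    every background bin can supply matched draws.  ``pi0`` is the per-probe
    null coverage probability; planted samples cover the planted probe subset
    with ``pi1`` instead.
    """

    n_probes: int = 5000
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000,
                                 "chr3": 10_000_000})
    bin_fractions: dict | None = None       # BinLabel -> fraction; None = uniform
    exact_quota: bool = False
    n_samples: int = 20
    pi0: float = 0.1
    pi1: float = 0.8
    planted_samples: tuple[str, ...] = ("S01",)
    planted_set_size: int = 50
    min_spacing_bp: int = 1000              # pairwise spacing of the planted set
    interval_extent: tuple[int, int] = (50, 500)

    def __post_init__(self):
        if not (0.0 <= self.pi0 <= 1.0 and 0.0 <= self.pi1 <= 1.0):
            raise FixtureError("coverage probabilities must lie in [0, 1]")
        if self.bin_fractions is not None:
            total = sum(self.bin_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise FixtureError(f"bin fractions sum to {total}, not 1")

    def sample_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


def _bin_quotas(spec: FixtureSpec) -> tuple[list, np.ndarray]:
    labels = all_bin_labels()
    if spec.bin_fractions is None:
        fracs = np.full(len(labels), 1.0 / len(labels))
    else:
        fracs = np.array([spec.bin_fractions.get(lab, 0.0) for lab in labels])
    return labels, fracs


def generate_manifest(spec: FixtureSpec,
                      rng: np.random.Generator | None = None,
                      seed: int | None = None) -> pd.DataFrame:
    """Toy manifest: probes placed uniformly with >= 2 bp spacing, labels per the spec.

    Positions are drawn without replacement from the odd 1-based coordinates
    of each chromosome, which enforces the spacing by construction.  In
    ``exact_quota`` mode every bin receives exactly its share of probes
    (remainder to the first bins); otherwise counts are multinomial.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    lengths = np.array(list(spec.chromosomes.values()), dtype=np.int64)
    capacity = (lengths + 1) // 2
    if spec.n_probes > capacity.sum():
        raise FixtureError(
            f"{spec.n_probes} probes exceed the {int(capacity.sum())} placeable "
            f"positions at 2 bp spacing")
    per_chrom = rng.multinomial(spec.n_probes, lengths / lengths.sum())
    while (per_chrom > capacity).any():  # extremely short chromosomes only
        over = per_chrom > capacity
        excess = (per_chrom - capacity).clip(min=0).sum()
        per_chrom = np.minimum(per_chrom, capacity)
        room = capacity - per_chrom
        per_chrom += rng.multinomial(excess, room / room.sum())
    chroms, positions = [], []
    for (name, length), count in zip(spec.chromosomes.items(), per_chrom):
        pos = np.sort(rng.choice(np.arange(1, length + 1, 2), size=int(count),
                                 replace=False))
        chroms.extend([name] * int(count))
        positions.extend(pos.tolist())
    labels, fracs = _bin_quotas(spec)
    if spec.exact_quota:
        base = np.full(len(labels), spec.n_probes // len(labels))
        base[: spec.n_probes % len(labels)] += 1
        assign = np.repeat(np.arange(len(labels)), base)
        rng.shuffle(assign)
    else:
        assign = rng.choice(len(labels), size=spec.n_probes, p=fracs)
    gene = [labels[i].gene_category for i in assign]
    cpg_raw = [
        labels[i].cpg_category if labels[i].cpg_category != "Shore_Shelf"
        else _RAW_FOR_CATEGORY["Shore_Shelf"][rng.integers(4)]
        for i in assign
    ]
    return pd.DataFrame({
        "probe_id": [f"cg{i:08d}" for i in range(spec.n_probes)],
        "chrom": chroms,
        "pos": np.asarray(positions, dtype=np.int64),
        "gene_group": gene,
        "cpg_relation": cpg_raw,
    })


def generate_hotspot_panel(manifest: pd.DataFrame, spec: FixtureSpec,
                           rng: np.random.Generator | None = None,
                           seed: int | None = None,
                           planted_probes=None, out_dir=None
                           ) -> tuple[list[HotspotTrack], pd.DataFrame, dict]:
    """Per-sample hotspot tracks with independent Bernoulli probe coverage.

    Each covered probe emits one interval of random width (``interval_extent``
    bp) containing its position at a random offset; intervals are then merged.
    Returns (tracks, sample metadata, truth), where truth records the realized
    per-sample coverage of the manifest from the same Bernoulli draw.  With
    ``out_dir`` set, BED files and the metadata sheet are also written.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n = len(manifest)
    pos0 = manifest["pos"].to_numpy(dtype=np.int64) - 1
    chroms = manifest["chrom"].to_numpy()
    planted_mask = np.zeros(n, dtype=bool)
    if planted_probes is not None:
        planted_mask = manifest["probe_id"].isin(set(planted_probes)).to_numpy()
    lo, hi = spec.interval_extent
    tissues = ("blood", "brain", "kidney", "lung")
    tracks: list[HotspotTrack] = []
    meta_rows = []
    truth_cov: dict[str, float] = {}
    for i, sid in enumerate(spec.sample_ids()):
        planted_sample = sid in spec.planted_samples and planted_probes is not None
        prob = np.full(n, spec.pi0)
        if planted_sample:
            prob[planted_mask] = spec.pi1
        covered = rng.random(n) < prob
        idx = np.flatnonzero(covered)
        widths = rng.integers(lo, hi + 1, size=len(idx))
        offsets = rng.integers(0, widths)  # start <= pos0 < start + width
        starts = np.maximum(pos0[idx] - offsets, 0)
        ends = starts + widths
        intervals = list(zip(chroms[idx].tolist(), starts.tolist(), ends.tolist()))
        meta = {
            "sample_id": sid, "cell": f"cell_{sid}",
            "tissue": tissues[i % len(tissues)], "datatype": "DNase",
            "consortium": "SYNTH", "accession": f"SYN{i:04d}",
            "filename": f"{sid}.bed",
        }
        tracks.append(HotspotTrack.make(intervals=intervals, **meta))
        meta_rows.append(meta)
        truth_cov[sid] = float(covered.mean())
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    truth = {
        "generator": RNG_NAME,
        "pi0": spec.pi0,
        "pi1": spec.pi1,
        "planted_samples": (list(spec.planted_samples)
                            if planted_probes is not None else []),
        "realized_coverage": truth_cov,
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "tracks").mkdir(parents=True, exist_ok=True)
        for track in tracks:
            with open(out_dir / "tracks" / track.filename, "w") as fh:
                for chrom, start, end in track.intervals:
                    fh.write(f"{chrom}\t{start}\t{end}\n")
        metadata.to_csv(out_dir / "metadata.tsv", sep="\t", index=False)
    return tracks, metadata, truth


def plant_test_set(manifest: pd.DataFrame, spec: FixtureSpec,
                   rng: np.random.Generator | None = None,
                   seed: int | None = None, out_path=None) -> list[str]:
    """Pick the planted probe subset: random manifest probes, pairwise spaced.

    Members are at least ``min_spacing_bp`` apart on every chromosome, so the
    proximity filter keeps the whole set.  Raises if the manifest cannot host
    a spaced set of the requested size.
    """
    if not 1 <= spec.planted_set_size <= len(manifest):
        raise FixtureError("planted set size out of range for this manifest")
    rng = rng if rng is not None else np.random.default_rng(seed)
    order = rng.permutation(len(manifest))
    chrom_col = manifest["chrom"].to_numpy()
    pos_col = manifest["pos"].to_numpy(dtype=np.int64)
    pid_col = manifest["probe_id"].to_numpy(dtype=object)
    chosen: list[str] = []
    taken: dict[str, list[int]] = {}
    for i in order:
        chrom, pos = chrom_col[i], int(pos_col[i])
        lst = taken.setdefault(chrom, [])
        j = bisect.bisect_left(lst, pos)
        if ((j == 0 or pos - lst[j - 1] >= spec.min_spacing_bp)
                and (j == len(lst) or lst[j] - pos >= spec.min_spacing_bp)):
            lst.insert(j, pos)
            chosen.append(str(pid_col[i]))
            if len(chosen) == spec.planted_set_size:
                break
    if len(chosen) < spec.planted_set_size:
        raise FixtureError(
            f"could only place {len(chosen)} of {spec.planted_set_size} probes "
            f"at {spec.min_spacing_bp} bp spacing")
    if out_path is not None:
        Path(out_path).write_text("\n".join(chosen) + "\n")
    return chosen


def make_fixtures(spec: FixtureSpec, out_dir, seed: int | None = None) -> dict:
    """Emit a complete fixture directory.

    Writes ``manifest.tsv``, ``tracks/*.bed``, ``metadata.tsv``,
    ``testset.txt`` and ``truth.json``; returns the truth record.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = generate_manifest(spec, rng)
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    planted = plant_test_set(manifest, spec, rng, out_path=out_dir / "testset.txt")
    _tracks, _metadata, truth = generate_hotspot_panel(
        manifest, spec, rng, planted_probes=planted, out_dir=out_dir)
    truth["seed"] = seed
    truth["planted_probes"] = planted
    truth["spec"] = {k: v for k, v in asdict(spec).items() if k != "bin_fractions"}
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")
    return truth
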