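"""Input resolution, proximity filtering, and matched background sampling.

An input probe set arrives either as array probe identifiers (one per line)
or as BED records whose coordinates identify manifest probes exactly.  Probes
absent from the array are excluded and reported, proximal probes (within 1 kb
of an already-selected probe, visited in random order) are dropped to avoid
retesting correlated CpGs, and 1,000 background sets are then drawn that
reproduce, bin by bin, the annotation composition of the test set.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import BinIndex, BinLabel
from .errors import (BackgroundPoolError, InputFormatError, ProbeSetSizeError)
from .store import _open_text

DEFAULT_N_BACKGROUNDS = 1000
DEFAULT_PROXIMITY_BP = 1000
DEFAULT_MIN_PROBES = 20
DEFAULT_MAX_PROBES = 1000


@dataclass
class TestSet:
    """The analyzable probe set after exclusion and proximity filtering."""

    probe_ids: list[str]
    excluded_missing: list[str] = field(default_factory=list)
    excluded_proximal: list[str] = field(default_factory=list)
    rng_seed: int | None = None

    @property
    def size(self) -> int:
        return len(self.probe_ids)


@dataclass
class BackgroundEnsemble:
    """Bin-matched random probe sets; ``sets[s]`` has the test set's bin composition."""

    sets: np.ndarray  # object array of probe ids, shape (n_sets, set_size)
    rng_seed: int | None = None

    @property
    def n_sets(self) -> int:
        return int(self.sets.shape[0])

    @property
    def set_size(self) -> int:
        return int(self.sets.shape[1])


def _iter_lines(source) -> Iterable[str]:
    if isinstance(source, (str, Path)):
        with _open_text(source) as fh:
            yield from fh
    else:
        yield from source


def _classify_line(fields: list[str]) -> str:
    if len(fields) >= 3:
        try:
            int(fields[1]), int(fields[2])
            return "bed"
        except ValueError:
            pass
    if len(fields) == 1 and fields[0] and not fields[0][0].isdigit():
        return "probeid"
    raise InputFormatError(
        f"cannot classify input line {fields!r} as a probe id or a BED record")


def resolve_input(source, manifest: pd.DataFrame, *, fmt: str = "auto"
                  ) -> tuple[list[str], list[str]]:
    """Resolve a probe-id or BED input to manifest probe ids.

    BED records (0-based half-open, chrN) map to probes via exact coordinate
    match: record ``(chrom, pos-1, pos)`` names the probe at 1-based ``pos``.
    Probes or records not on the array go to the excluded list; duplicates are
    dropped with a warning; mixed formats in one file, or zero resolvable
    probes, are errors.

    Returns ``(probe_ids, excluded_missing)``.
    """
    if fmt not in ("auto", "probeid", "bed"):
        raise InputFormatError(f"unknown input format {fmt!r}")
    known = set(manifest["probe_id"])
    by_coord = {(c, int(p)): pid for pid, c, p in
                zip(manifest["probe_id"], manifest["chrom"], manifest["pos"])}
    resolved: list[str] = []
    seen: set[str] = set()
    missing: list[str] = []
    dupes = 0
    detected = None if fmt == "auto" else fmt
    for lineno, raw in enumerate(_iter_lines(source), start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        kind = _classify_line(fields)
        if detected is None:
            detected = kind
        elif kind != detected:
            raise InputFormatError(
                f"line {lineno}: mixed input formats ({kind!r} record in a "
                f"{detected!r} file)")
        if detected == "probeid":
            key, pid = fields[0].strip(), None
            if key in known:
                pid = key
        else:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if not chrom.startswith("chr"):
                raise InputFormatError(
                    f"line {lineno}: chromosome {chrom!r} lacks the 'chr' prefix")
            key = f"{chrom}:{start}-{end}"
            pid = by_coord.get((chrom, start + 1)) if end == start + 1 else None
        if pid is None:
            missing.append(key)
        elif pid in seen:
            dupes += 1
        else:
            seen.add(pid)
            resolved.append(pid)
    if dupes:
        warnings.warn(f"{dupes} duplicate input probe(s) dropped", UserWarning,
                      stacklevel=2)
    if not resolved:
        raise InputFormatError(
            "no input probe resolved against the manifest "
            f"({len(missing)} excluded as off-array)")
    return resolved, missing


def proximity_filter(probe_ids: Sequence[str], manifest: pd.DataFrame, *,
                     min_bp: int = DEFAULT_PROXIMITY_BP,
                     rng: np.random.Generator | None = None
                     ) -> tuple[list[str], list[str]]:
    """Greedy 1-kb thinning of the test set, visiting probes in random order.

    A probe is retained iff its position is at least ``min_bp`` away from every
    already-retained probe on the same chromosome ("within min_bp" excluded).
    Deterministic given the generator state.  Returns (retained, excluded),
    each in visit order.
    """
    if min_bp < 0:
        raise ValueError("min_bp must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    coords = manifest.set_index("probe_id")
    retained: list[str] = []
    excluded: list[str] = []
    by_chrom: dict[str, list[int]] = {}
    order = rng.permutation(len(probe_ids))
    for i in order:
        pid = probe_ids[int(i)]
        chrom = coords.at[pid, "chrom"]
        pos = int(coords.at[pid, "pos"])
        taken = by_chrom.setdefault(chrom, [])
        j = bisect.bisect_left(taken, pos)
        ok = ((j == 0 or pos - taken[j - 1] >= min_bp)
              and (j == len(taken) or taken[j] - pos >= min_bp))
        if ok:
            taken.insert(j, pos)
            retained.append(pid)
        else:
            excluded.append(pid)
    return retained, excluded


def validate_size(size, *, min_probes: int = DEFAULT_MIN_PROBES,
                  max_probes: int = DEFAULT_MAX_PROBES, strict: bool = True) -> bool:
    """Check the analyzable set size against the suggested bounds.

    Strict mode raises on violation; lenient mode warns and lets the run
    proceed (the bounds are a recommendation, not a hard property of the
    statistics).  Accepts a :class:`TestSet` or an integer.
    """
    n = size.size if isinstance(size, TestSet) else int(size)
    if min_probes <= n <= max_probes:
        return True
    msg = (f"analyzable probe set has {n} probes, outside the recommended "
           f"[{min_probes}, {max_probes}] range")
    if strict:
        raise ProbeSetSizeError(msg)
    warnings.warn(msg, UserWarning, stacklevel=2)
    return False


def sample_background(test_probe_ids: Sequence[str], bin_index: BinIndex, *,
                      n_sets: int = DEFAULT_N_BACKGROUNDS,
                      rng: np.random.Generator | None = None,
                      rng_seed: int | None = None) -> BackgroundEnsemble:
    """Draw ``n_sets`` annotation-matched background sets.

    Each set draws, per background bin, exactly as many probes as the test set
    has in that bin, uniformly without replacement from the bin's pool minus
    the test probes themselves; draws are independent across sets (a probe may
    recur in different sets, never within one).
    """
    rng = rng if rng is not None else np.random.default_rng(rng_seed)
    labels = bin_index.labels_for(test_probe_ids)
    need: dict[BinLabel, int] = {}
    for lab in labels:
        need[lab] = need.get(lab, 0) + 1
    test_ids = set(test_probe_ids)
    columns: list[np.ndarray] = []
    for lab in sorted(need):
        count = need[lab]
        pool = np.asarray([p for p in bin_index.by_bin[lab] if p not in test_ids],
                          dtype=object)
        if len(pool) < count:
            raise BackgroundPoolError(
                f"bin {lab}: test set needs {count} matched probe(s) but the pool "
                f"holds {len(pool)} (shortfall {count - len(pool)})")
        # uniform random subsets: the `count` smallest of iid uniforms per row
        keys = rng.random((n_sets, len(pool)))
        picks = np.argpartition(keys, count - 1, axis=1)[:, :count]
        columns.append(pool[picks])
    sets = np.concatenate(columns, axis=1)
    return BackgroundEnsemble(sets=sets, rng_seed=rng_seed)


def build_test_set(source, manifest: pd.DataFrame, *, fmt: str = "auto",
                   proximity_bp: int = DEFAULT_PROXIMITY_BP,
                   min_probes: int = DEFAULT_MIN_PROBES,
                   max_probes: int = DEFAULT_MAX_PROBES, strict: bool = True,
                   probe_allowlist: Iterable[str] | None = None,
                   rng: np.random.Generator | None = None,
                   rng_seed: int | None = None) -> TestSet:
    """Full input stage: resolve, allow-list, proximity-filter, size-check."""
    rng = rng if rng is not None else np.random.default_rng(rng_seed)
    ids, missing = resolve_input(source, manifest, fmt=fmt)
    if probe_allowlist is not None:
        allow = set(probe_allowlist)
        kept = [p for p in ids if p in allow]
        missing = missing + [p for p in ids if p not in allow]
        ids = kept
        if not ids:
            raise InputFormatError("no input probe survived the allow-list")
    retained, proximal = proximity_filter(ids, manifest, min_bp=proximity_bp, rng=rng)
    validate_size(len(retained), min_probes=min_probes, max_probes=max_probes,
                  strict=strict)
    return TestSet(retained, excluded_missing=missing, excluded_proximal=proximal,
                   rng_seed=rng_seed)
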