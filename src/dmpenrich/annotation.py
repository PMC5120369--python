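"""Probe annotation bins.

Matched background sampling is stratified on two Illumina-manifest annotation
axes: the gene-model category of the CpG (7 levels: 1stExon, 3UTR, 5UTR, Body,
IGR, TSS1500, TSS200) and its position relative to CpG islands.  The raw
island annotation has five informative tokens (Island, N_Shore, S_Shore,
N_Shelf, S_Shelf) plus open sea; shores and shelves are merged into a single
``Shore_Shelf`` stratum so every bin keeps a large enough probe pool, giving
7 x 3 = 21 background bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnnotationError

GENE_GROUPS: tuple[str, ...] = (
    "1stExon",
    "3UTR",
    "5UTR",
    "Body",
    "IGR",
    "TSS1500",
    "TSS200",
)

#: Raw CpG-island relation tokens accepted from a manifest.
CPG_RELATIONS_RAW: tuple[str, ...] = (
    "Island",
    "N_Shore",
    "S_Shore",
    "N_Shelf",
    "S_Shelf",
    "OpenSea",
)

#: Merged CpG categories used for binning.
CPG_CATEGORIES: tuple[str, ...] = ("Island", "Shore_Shelf", "OpenSea")

_SHORE_SHELF = frozenset({"N_Shore", "S_Shore", "N_Shelf", "S_Shelf"})


@dataclass(frozen=True, order=True)
class BinLabel:
    """One of the 21 background strata: a (gene category, merged CpG category) pair."""

    gene_category: str
    cpg_category: str

    def __str__(self) -> str:  # serialized form used in logs and error messages
        return f"{self.gene_category}|{self.cpg_category}"


def all_bin_labels() -> list[BinLabel]:
    """The full, ordered list of the 21 possible bin labels."""
    return [BinLabel(g, c) for g in GENE_GROUPS for c in CPG_CATEGORIES]


def merge_cpg_relation(raw: str | None, *, probe_id: str | None = None) -> str:
    """Collapse a raw island-relation token to one of the three merged categories.

    Empty / missing / ``NA`` tokens mean the probe sits in open sea.
    """
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return "OpenSea"
    token = str(raw).strip()
    if token in ("", "NA", "nan", "OpenSea"):
        return "OpenSea"
    if token == "Island":
        return "Island"
    if token in _SHORE_SHELF:
        return "Shore_Shelf"
    who = f" (probe {probe_id})" if probe_id else ""
    raise AnnotationError(f"unknown CpG-island relation token {token!r}{who}")


def bin_label(gene_group: str | None, cpg_relation: str | None,
              *, probe_id: str | None = None) -> BinLabel:
    """Map raw annotation tokens to the probe's background bin.

    Missing gene annotation means the probe is intergenic (IGR).
    """
    if gene_group is None or (isinstance(gene_group, float) and np.isnan(gene_group)):
        gene = "IGR"
    else:
        gene = str(gene_group).strip() or "IGR"
    if gene not in GENE_GROUPS:
        who = f" (probe {probe_id})" if probe_id else ""
        raise AnnotationError(f"unknown gene-annotation token {gene!r}{who}")
    return BinLabel(gene, merge_cpg_relation(cpg_relation, probe_id=probe_id))


def assign_bin(probe) -> BinLabel:
    """Bin label for a probe record (anything with ``gene_group`` and ``cpg_relation`` attributes)."""
    raw = getattr(probe, "cpg_relation", None)
    if raw is None:
        raw = getattr(probe, "cpg_relation_raw", None)
    return bin_label(probe.gene_group, raw, probe_id=getattr(probe, "probe_id", None))


class BinIndex:
    """Manifest partitioned into the 21 background bins.

    Attributes
    ----------
    by_bin : dict mapping BinLabel -> ndarray of probe ids (manifest order)
    label_of : dict mapping probe id -> BinLabel
    """

    def __init__(self, by_bin: Mapping[BinLabel, np.ndarray],
                 label_of: Mapping[str, BinLabel]):
        self.by_bin = dict(by_bin)
        self.label_of = dict(label_of)

    @property
    def sizes(self) -> dict[BinLabel, int]:
        return {b: len(v) for b, v in self.by_bin.items()}

    @property
    def n_probes(self) -> int:
        return sum(len(v) for v in self.by_bin.values())

    def labels_for(self, probe_ids: Iterable[str]) -> list[BinLabel]:
        try:
            return [self.label_of[p] for p in probe_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise AnnotationError(f"probe {exc.args[0]!r} not in the bin index") from exc


def build_bin_index(manifest: pd.DataFrame, *, min_bin_size: int = 1000) -> BinIndex:
    """Partition a manifest into the 21 bins and report undersized pools.

    Bins with fewer probes than ``min_bin_size`` (default 1,000, the floor the
    method assumes on the full 450k array) trigger a single consolidated
    warning; small synthetic manifests routinely do, so the threshold is
    configurable.
    """
    labels = [
        bin_label(g, c, probe_id=p)
        for p, g, c in zip(manifest["probe_id"], manifest["gene_group"],
                           manifest["cpg_relation"])
    ]
    by_bin: dict[BinLabel, list[str]] = {b: [] for b in all_bin_labels()}
    label_of: dict[str, BinLabel] = {}
    for pid, lab in zip(manifest["probe_id"], labels):
        by_bin[lab].append(pid)
        label_of[pid] = lab
    index = BinIndex({b: np.asarray(v, dtype=object) for b, v in by_bin.items()},
                     label_of)
    small = [f"{b} ({n})" for b, n in index.sizes.items() if n < min_bin_size]
    if small:
        warnings.warn(
            f"{len(small)} background bin(s) below the minimum pool size "
            f"{min_bin_size}: " + ", ".join(small),
            UserWarning,
            stacklevel=2,
        )
    return index
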