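"""Per-feature read counting and the CountMatrix container.

Counting is plain interval-overlap tallying: a read overlapping k features
increments all k (no fractional assignment, no unique-only mode), with a
configurable minimum overlap of 1 base. Gene counting is typically run with
strand_mode="same" (nascent RNA signal is stranded); enhancer and eRNA
counting with strand_mode="ignore" (enhancer transcription is
bidirectional).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

import numpy as np
import pandas as pd

from .genomic_core import GenomicInterval, build_trees, _strand_ok


@dataclass
class CountMatrix:
    """Features x samples integer counts with spike-in flags and conditions.

    ``counts`` is a pandas DataFrame (index = feature ids, columns = sample
    ids); ``is_spikein`` is a boolean Series over the same index;
    ``conditions`` maps sample id -> condition label (e.g. "0h"/"4h"/"24h").
    """

    counts: pd.DataFrame
    is_spikein: pd.Series
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = self.counts.astype(np.int64)
        self.is_spikein = self.is_spikein.reindex(self.counts.index)
        if self.is_spikein.isna().any():
            missing = self.is_spikein.index[self.is_spikein.isna()].tolist()
            raise ValueError(f"spike-in flag missing for features {missing[:5]}")
        self.is_spikein = self.is_spikein.astype(bool)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions.get(s) == condition]

    def subset_features(self, ids: Iterable[str]) -> "CountMatrix":
        ids = list(ids)
        return CountMatrix(self.counts.loc[ids], self.is_spikein.loc[ids], dict(self.conditions))


def count_reads(
    reads_by_sample: Mapping[str, list[GenomicInterval]],
    features: list[GenomicInterval],
    strand_mode: str = "ignore",
    spikein_ids: Iterable[str] = (),
    conditions: Mapping[str, str] | None = None,
    min_overlap: int = 1,
) -> CountMatrix:
    """Tally reads overlapping each named feature, per sample.

    Feature names must be unique. ``min_overlap`` bases of overlap are
    required for a read to count (default 1).
    """
    ids = [f.name for f in features]
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = [i for i in ids if i in seen or seen.add(i)]
        raise ValueError(f"duplicate feature ids: {sorted(set(dupes))[:5]}")
    trees = build_trees(features)
    sample_ids = list(reads_by_sample)
    mat = np.zeros((len(features), len(sample_ids)), dtype=np.int64)
    for s_idx, sample in enumerate(sample_ids):
        for read in reads_by_sample[sample]:
            tree = trees.get(read.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(read.start, read.end):
                j = hit.data
                f = features[j]
                if min(read.end, f.end) - max(read.start, f.start) < min_overlap:
                    continue
                if _strand_ok(read.strand, f.strand, strand_mode):
                    mat[j, s_idx] += 1
    spike = set(spikein_ids)
    counts = pd.DataFrame(mat, index=ids, columns=sample_ids)
    flags = pd.Series([i in spike for i in ids], index=ids)
    return CountMatrix(counts, flags, dict(conditions or {}))


def merge_matrices(parts: list[CountMatrix]) -> CountMatrix:
    """Column-concatenate matrices over identical feature sets.

    Sample sets must be disjoint; spike-in flags must agree per feature.
    """
    if not parts:
        raise ValueError("nothing to merge")
    first = parts[0]
    for p in parts[1:]:
        if set(p.feature_ids) != set(first.feature_ids):
            diff = set(p.feature_ids) ^ set(first.feature_ids)
            raise ValueError(f"feature sets differ: {sorted(diff)[:10]}")
        if set(p.sample_ids) & set(first.sample_ids):
            raise ValueError("sample sets must be disjoint")
        flags = p.is_spikein.reindex(first.counts.index)
        if not flags.equals(first.is_spikein):
            bad = first.counts.index[flags != first.is_spikein].tolist()
            raise ValueError(f"conflicting is_spikein flags for {bad[:5]}")
    counts = pd.concat([first.counts] + [p.counts.reindex(first.counts.index) for p in parts[1:]], axis=1)
    conditions: dict[str, str] = {}
    for p in parts:
        conditions.update(p.conditions)
    return CountMatrix(counts, first.is_spikein.copy(), conditions)


# ---------------------------------------------------------------------------
# TSV round trip: feature_id <TAB> is_spikein <TAB> <sample...>
# ---------------------------------------------------------------------------


def write_counts_tsv(matrix: CountMatrix, stream: TextIO, condition_row: bool = True) -> None:
    stream.write("feature_id\tis_spikein\t" + "\t".join(matrix.sample_ids) + "\n")
    if condition_row and matrix.conditions:
        conds = [matrix.conditions.get(s, "") for s in matrix.sample_ids]
        stream.write("#condition\t-\t" + "\t".join(conds) + "\n")
    spike = matrix.is_spikein
    for fid, row in matrix.counts.iterrows():
        flag = "1" if spike[fid] else "0"
        stream.write(f"{fid}\t{flag}\t" + "\t".join(str(v) for v in row) + "\n")


def read_counts_tsv(stream: TextIO) -> CountMatrix:
    header = stream.readline().rstrip("\n").split("\t")
    if header[:2] != ["feature_id", "is_spikein"]:
        raise ValueError("counts TSV must start with feature_id<TAB>is_spikein")
    sample_ids = header[2:]
    conditions: dict[str, str] = {}
    rows: list[tuple[str, bool, list[int]]] = []
    for line in stream:
        line = line.rstrip("\n")
        if not line:
            continue
        cols = line.split("\t")
        if cols[0] == "#condition":
            conditions = dict(zip(sample_ids, cols[2:]))
            continue
        rows.append((cols[0], cols[1] == "1", [int(v) for v in cols[2:]]))
    counts = pd.DataFrame(
        [r[2] for r in rows], index=[r[0] for r in rows], columns=sample_ids
    )
    flags = pd.Series([r[1] for r in rows], index=counts.index)
    return CountMatrix(counts, flags, conditions)
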