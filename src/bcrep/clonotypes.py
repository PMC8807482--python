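"""Clonotype tables and per-repertoire summaries.

Two clonotype definitions are supported, mirroring the two ways antigen-specific
repertoires are collapsed here:

* ``cdr3_aa`` — reads sharing the CDR3 amino-acid sequence (anchors included);
* ``vdj_nt``  — reads sharing the full VDJ nucleotide string, taken from the
  start of the V alignment through the end of the J alignment.

The headline diversity statistic is deliberately simple: unique clonotype count
divided by total read count of the repertoire (a richness / sequencing-depth
ratio in (0, 1]).  Shannon and Simpson indices are provided as optional extras
only.  V-gene usage and mutation summaries are computed over clonotypes, not
reads, to avoid confounding by clonal expansion; read-weighted variants are
available via ``weight="reads"``.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

MODES = ("cdr3_aa", "vdj_nt")


@dataclass
class ClonotypeTable:
    """Clonotype -> read count for one repertoire under a stated definition."""

    repertoire_id: str
    mode: str
    entries: Dict[str, int]
    total_reads: int
    dropped: int = 0  # input records excluded by pass_filter

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown clonotype mode {self.mode!r}")
        if self.entries and self.total_reads != sum(self.entries.values()):
            raise ValueError("total_reads does not equal the sum of entry counts")

    @property
    def n_clonotypes(self) -> int:
        return len(self.entries)

    def frequencies(self) -> Dict[str, float]:
        return {k: c / self.total_reads for k, c in self.entries.items()}

    def keys(self) -> set:
        return set(self.entries)


@dataclass
class RepertoireProfile:
    """Per-repertoire summary: diversity, V usage, mutation load."""

    repertoire_id: str
    mode: str
    n_clonotypes: int
    total_reads: int
    normalized_diversity: float
    v_usage: Dict[str, float]
    mutation_by_family: Dict[str, float]
    mean_mutations: float

    def to_dict(self) -> dict:
        return {
            "repertoire_id": self.repertoire_id, "mode": self.mode,
            "n_clonotypes": self.n_clonotypes, "total_reads": self.total_reads,
            "normalized_diversity": self.normalized_diversity,
            "v_usage": self.v_usage, "mutation_by_family": self.mutation_by_family,
            "mean_mutations": self.mean_mutations,
        }


def _passing(records: pd.DataFrame) -> pd.DataFrame:
    if "pass_filter" not in records.columns:
        return records
    pf = records["pass_filter"]
    if pf.dtype == object:
        pf = pf.astype(str).str.lower().isin(("true", "t", "1"))
    return records[pf.astype(bool)]


def clonotype_key(records: pd.DataFrame, mode: str) -> pd.Series:
    if mode == "cdr3_aa":
        return records["junction_aa"].astype(str)
    if mode == "vdj_nt":
        start = records["v_read_start"].astype(int)
        end = records["j_read_end"].astype(int)
        return pd.Series(
            [s[a:b] for s, a, b in zip(records["sequence"].astype(str), start, end)],
            index=records.index,
        )
    raise ValueError(f"unknown clonotype mode {mode!r}")


def build_clonotypes(records: pd.DataFrame, mode: str,
                     repertoire_id: str = "") -> ClonotypeTable:
    """Exact multiset count of clonotype keys over filter-passing records."""
    if mode not in MODES:
        raise ValueError(f"unknown clonotype mode {mode!r}")
    kept = _passing(records)
    dropped = len(records) - len(kept)
    counts = Counter(clonotype_key(kept, mode)) if len(kept) else Counter()
    counts.pop("", None)
    total = sum(counts.values())
    dropped += len(kept) - total  # empty-key records, if any
    return ClonotypeTable(repertoire_id=repertoire_id, mode=mode,
                          entries=dict(counts), total_reads=total, dropped=dropped)


def normalized_diversity(table: ClonotypeTable) -> float:
    """Unique clonotypes divided by read count (depth-normalized richness)."""
    if table.total_reads < 1:
        raise ValueError("diversity undefined for an empty repertoire")
    return table.n_clonotypes / table.total_reads


def diversity_indices(table: ClonotypeTable) -> Dict[str, float]:
    """Optional extras: Shannon entropy (nats) and Simpson (1 - sum p^2)."""
    if table.total_reads < 1:
        raise ValueError("diversity undefined for an empty repertoire")
    ps = [c / table.total_reads for c in table.entries.values()]
    return {
        "shannon": -sum(p * math.log(p) for p in ps),
        "simpson": 1.0 - sum(p * p for p in ps),
    }


def _gene(v_call: str) -> str:
    return v_call.split("*", 1)[0]


def _family(v_call: str) -> str:
    return _gene(v_call).split("-", 1)[0]


def _modal(values: Iterable[str]) -> str:
    counts = Counter(v for v in values if v)
    if not counts:
        return ""
    return min(counts, key=lambda k: (-counts[k], k))


def v_usage(records: pd.DataFrame, mode: str = "cdr3_aa",
            weight: str = "clones", level: str = "gene") -> Dict[str, float]:
    """Per-V-gene usage fractions (sums to 1).

    ``weight="clones"`` (default) counts each clonotype once, assigning it the
    modal V call of its reads; ``weight="reads"`` counts reads.
    ``level`` is "gene" (allele stripped) or "allele".
    """
    kept = _passing(records)
    kept = kept[kept["v_call"].astype(str) != ""]
    if not len(kept):
        raise ValueError("no passing records with a V call")
    namer = (lambda v: v) if level == "allele" else _gene
    if weight == "reads":
        counts = Counter(namer(v) for v in kept["v_call"].astype(str))
    elif weight == "clones":
        keys = clonotype_key(kept, mode)
        per_clone = kept.groupby(keys)["v_call"].agg(_modal)
        counts = Counter(namer(v) for v in per_clone)
    else:
        raise ValueError(f"unknown weight {weight!r}")
    total = sum(counts.values())
    return {k: c / total for k, c in sorted(counts.items())}


def mutation_summary(records: pd.DataFrame, mode: str = "cdr3_aa",
                     weight: str = "clones") -> Tuple[Dict[str, float], float]:
    """Mean V-region mutation count per V family, and overall.

    Default averaging is clonotype-level: reads are collapsed to clonotypes
    first (per-clonotype mean), then clonotypes are averaged; ``weight="reads"``
    averages reads directly.
    """
    kept = _passing(records)
    kept = kept[kept["v_call"].astype(str) != ""]
    if not len(kept):
        return {}, float("nan")
    muts = kept["v_mutation_count"].astype(float)
    if weight == "reads":
        fam = kept["v_call"].astype(str).map(_family)
        by_fam = muts.groupby(fam).mean().to_dict()
        return dict(sorted(by_fam.items())), float(muts.mean())
    if weight != "clones":
        raise ValueError(f"unknown weight {weight!r}")
    keys = clonotype_key(kept, mode)
    grouped = pd.DataFrame({"key": keys, "mut": muts, "v": kept["v_call"].astype(str)})
    per_clone = grouped.groupby("key").agg(mut=("mut", "mean"), v=("v", _modal))
    fam = per_clone["v"].map(_family)
    by_fam = per_clone["mut"].groupby(fam).mean().to_dict()
    return dict(sorted(by_fam.items())), float(per_clone["mut"].mean())


def repertoire_profile(records: pd.DataFrame, repertoire_id: str,
                       mode: str = "cdr3_aa") -> RepertoireProfile:
    """Build the full per-repertoire summary used by the study figures."""
    table = build_clonotypes(records, mode, repertoire_id)
    mut_by_fam, mean_mut = mutation_summary(records, mode=mode)
    return RepertoireProfile(
        repertoire_id=repertoire_id, mode=mode,
        n_clonotypes=table.n_clonotypes, total_reads=table.total_reads,
        normalized_diversity=normalized_diversity(table),
        v_usage=v_usage(records, mode=mode),
        mutation_by_family=mut_by_fam, mean_mutations=mean_mut,
    )


def pool_records(frames: List[pd.DataFrame]) -> pd.DataFrame:
    """Concatenate passing records from several repertoires (e.g. IgG2b+2c)."""
    return pd.concat(frames, ignore_index=True)


def write_table(table: ClonotypeTable, path) -> None:
    rows = [{"clonotype_key": k, "count": c} for k, c in
            sorted(table.entries.items(), key=lambda kv: (-kv[1], kv[0]))]
    pd.DataFrame(rows, columns=["clonotype_key", "count"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
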