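"""Synthetic AIRR repertoire generator emulating the study design.

Two cohorts (``rna_loaded`` ~ TLR7-stimulating, RNA-packaged VLP; ``rna_free``
~ RNase-treated VLP) x two time points (d10, d17) x three IgG subclasses.
Cohort defaults encode the qualitative contrasts the design implies — the
RNA-loaded group has more clones, a flatter clone-size law and an
IgG2b/2c-dominant isotype mix — and are artifact defaults, not measurements.

Model summary (details in docs/methods.md):

* V(D)J rearrangement: biased V choice, uniform D/J, bounded-geometric exonuclease
  trimming, uniform-nucleotide N1/N2 insertions; non-productive juctions resampled.
* Clonal expansion: Zipf (power-law) clone sizes over ranks, allocated exactly to
  ``reads_per_sample`` by largest remainder; one AIRR row per read
  (``duplicate_count`` = 1).
* SHM: uniform substitution-only point mutations applied once per clone lineage,
  so reads of a clone share their mutations.
* Class switching: each clone draws a category (IgG1 vs the IgG2b/2c pool);
  pool clones then draw IgG2b/IgG2c membership flags, so the IgG2b and IgG2c
  repertoires of a sample sample from a common clone set.
* Library sequencing: each sample x isotype library is written as its own AIRR
  file and receives a near-equal share of the sample's read budget, emulating
  saturating per-subclass PCR followed by equimolar pooling (per-library depth
  reflects pooling, not cellular isotype composition).
* Public clonotypes: ``n_public`` fixed CDR3 amino-acid strings re-embedded by
  reverse translation into every sample (CDR3 masked from SHM, and guaranteed at
  least one read), giving exactly recoverable cross-sample sharing.

Everything is reproducible from ``CohortConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import SimulationError
from .germline import GermlineReference, GermlineSegment, translate

ISOTYPES = ("IgG1", "IgG2b", "IgG2c")

#: Fixed public CDR3 amino-acid strings (10 AA, Cys...Trp/Phe) used for spike-ins.
PUBLIC_CDR3_AA: Tuple[str, ...] = (
    "CARDYYGSSW",
    "CARGGYDGYW",
    "CTRDNWDAYF",
    "CARSSGYWYF",
    "CARDGTTGTW",
    "CAREGYSNYW",
    "CARWDGSYYF",
    "CARDLRRGAW",
)

#: Deterministic reverse-translation table (one fixed codon per residue).
REVTRANS: Dict[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "AGA", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

AIRR_COLUMNS = (
    "sequence_id", "sequence", "v_call", "d_call", "j_call", "junction",
    "junction_aa", "c_call", "duplicate_count", "sample_id",
)

_NT = np.array(list("ACGT"))


def reverse_translate(aa: str) -> str:
    return "".join(REVTRANS[c] for c in aa)


@dataclass(frozen=True)
class JunctionModel:
    """Distributions for junctional diversification (all lengths in nt)."""

    p_trim: float = 0.45       # geometric success prob for trimming lengths
    v_trim_max: int = 6
    d_trim_max: int = 4
    j_trim_max: int = 8
    p_ins: float = 0.35        # geometric success prob for N-region lengths
    ins_max: int = 8

    def draw_trim(self, rng: np.random.Generator, cap: int) -> int:
        if cap <= 0:
            return 0
        return min(int(rng.geometric(self.p_trim)) - 1, cap)

    def draw_insert(self, rng: np.random.Generator) -> str:
        if self.ins_max <= 0:
            return ""
        n = min(int(rng.geometric(self.p_ins)) - 1, self.ins_max)
        return "".join(_NT[rng.integers(0, 4, size=n)])


@dataclass(frozen=True)
class CloneGenotype:
    """One recombined heavy-chain clone and its junction bookkeeping."""

    v_name: str
    d_name: Optional[str]
    j_name: str
    v_trim: int
    d_trim5: int
    d_trim3: int
    j_trim: int
    n1: str
    n2: str
    full_nt: str
    cdr3_nt: str
    productive: bool
    cdr3_start: int  # position of cdr3_nt within full_nt
    v_region_end: int  # read prefix matching the (trimmed) germline V

    @property
    def cdr3_aa(self) -> str:
        return translate(self.cdr3_nt)


@dataclass
class GroupParams:
    """Per-cohort knobs: richness, expansion skew, SHM load, isotype mix."""

    n_clones: int
    zipf_exponent: float
    shm_rate: float
    isotype_proportions: Dict[str, float]

    def validate(self) -> None:
        if self.n_clones <= 0:
            raise ValueError("n_clones must be positive")
        if not 0.0 <= self.shm_rate <= 1.0:
            raise ValueError(f"shm_rate {self.shm_rate} outside [0,1]")
        total = sum(self.isotype_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"isotype proportions sum to {total}, expected 1")
        if set(self.isotype_proportions) - set(ISOTYPES):
            raise ValueError(f"unknown isotypes in {self.isotype_proportions}")


@dataclass
class CohortConfig:
    """Full study configuration: groups x time points x samples."""

    groups: Dict[str, GroupParams]
    v_usage_bias: Dict[str, float]
    n_samples: int = 2            # mice per group x time point
    time_points: Tuple[str, ...] = ("d10", "d17")
    n_public: int = 5
    reads_per_sample: int = 2500
    seed: int = 0
    correlated_switching: bool = True
    shm_time_factor: Dict[str, float] = field(default_factory=lambda: {"d10": 1.0, "d17": 1.5})
    junction: JunctionModel = field(default_factory=JunctionModel)

    def validate(self) -> None:
        for g in self.groups.values():
            g.validate()
        if self.n_samples <= 0 or self.reads_per_sample <= 0 or self.n_public < 0:
            raise ValueError("counts must be positive (n_public may be 0)")
        if self.n_public > len(PUBLIC_CDR3_AA):
            raise ValueError(f"n_public > {len(PUBLIC_CDR3_AA)} preset public CDR3s")
        total = sum(self.v_usage_bias.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"v_usage_bias sums to {total}, expected 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        d = dict(d)
        d["groups"] = {k: GroupParams(**v) for k, v in d["groups"].items()}
        if "junction" in d and isinstance(d["junction"], dict):
            d["junction"] = JunctionModel(**d["junction"])
        if "time_points" in d:
            d["time_points"] = tuple(d["time_points"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_v_bias(reference: GermlineReference, dominant: str = "IGHV1-7*01",
                   weight: float = 0.6) -> Dict[str, float]:
    """Dominant-gene usage bias: ``weight`` on one V, the rest uniform."""
    others = [s.name for s in reference.v_segments if s.name != dominant]
    if dominant not in reference:
        raise ValueError(f"{dominant} not in reference")
    bias = {dominant: weight}
    for name in others:
        bias[name] = (1.0 - weight) / len(others)
    return bias


def default_config(reference: GermlineReference, seed: int = 0,
                   reads_per_sample: int = 2500, n_samples: int = 2) -> CohortConfig:
    """Study-design defaults: RNA-loaded cohort richer, flatter, IgG2b/2c-dominant."""
    groups = {
        "rna_loaded": GroupParams(
            n_clones=500, zipf_exponent=1.1, shm_rate=0.02,
            isotype_proportions={"IgG1": 0.2, "IgG2b": 0.4, "IgG2c": 0.4},
        ),
        "rna_free": GroupParams(
            n_clones=150, zipf_exponent=1.6, shm_rate=0.02,
            isotype_proportions={"IgG1": 0.6, "IgG2b": 0.3, "IgG2c": 0.1},
        ),
    }
    return CohortConfig(groups=groups, v_usage_bias=default_v_bias(reference),
                        n_samples=n_samples, reads_per_sample=reads_per_sample, seed=seed)


def _choose(rng: np.random.Generator, names: Sequence[str], weights=None) -> str:
    i = int(rng.choice(len(names), p=weights))
    return names[i]


def simulate_rearrangement(
    reference: GermlineReference,
    rng: np.random.Generator,
    v_usage_bias: Optional[Dict[str, float]] = None,
    junction: JunctionModel = JunctionModel(),
    max_attempts: int = 1000,
) -> CloneGenotype:
    """Draw one productive V(D)J rearrangement.

    Resamples until the junction is in-frame, stop-free and anchor-intact;
    raises :class:`SimulationError` after ``max_attempts`` failures (which
    signals an inconsistent reference/anchor table).
    """
    v_names = [s.name for s in reference.v_segments]
    if v_usage_bias is not None:
        weights = np.array([v_usage_bias.get(n, 0.0) for n in v_names])
        weights = weights / weights.sum()
    else:
        weights = None
    for _ in range(max_attempts):
        v = reference[_choose(rng, v_names, weights)]
        d = reference[_choose(rng, [s.name for s in reference.d_segments])]
        j = reference[_choose(rng, [s.name for s in reference.j_segments])]
        v_trim = junction.draw_trim(rng, min(junction.v_trim_max, len(v.sequence) - v.anchor - 3))
        d_trim5 = junction.draw_trim(rng, min(junction.d_trim_max, len(d.sequence) // 2))
        d_trim3 = junction.draw_trim(rng, min(junction.d_trim_max,
                                              len(d.sequence) - d_trim5 - 1))
        j_trim = junction.draw_trim(rng, min(junction.j_trim_max, j.anchor))
        n1 = junction.draw_insert(rng)
        n2 = junction.draw_insert(rng)
        v_part = v.sequence[: len(v.sequence) - v_trim]
        d_part = d.sequence[d_trim5 : len(d.sequence) - d_trim3]
        j_part = j.sequence[j_trim:]
        full = v_part + n1 + d_part + n2 + j_part
        cdr3_start = v.anchor
        cdr3_end = len(v_part) + len(n1) + len(d_part) + len(n2) + (j.anchor - j_trim) + 3
        cdr3 = full[cdr3_start:cdr3_end]
        productive = False
        if len(cdr3) >= 6 and len(cdr3) % 3 == 0:
            aa = translate(cdr3)
            productive = aa.startswith("C") and aa[-1] in "WF" and "*" not in aa
        if productive:
            return CloneGenotype(
                v_name=v.name, d_name=d.name, j_name=j.name,
                v_trim=v_trim, d_trim5=d_trim5, d_trim3=d_trim3, j_trim=j_trim,
                n1=n1, n2=n2, full_nt=full, cdr3_nt=cdr3, productive=True,
                cdr3_start=cdr3_start, v_region_end=len(v_part),
            )
    raise SimulationError(f"no productive rearrangement in {max_attempts} attempts")


def make_public_clone(reference: GermlineReference, cdr3_aa: str,
                      v_name: str, j_name: str) -> CloneGenotype:
    """Embed a preset CDR3 amino-acid string into a V...J scaffold.

    The J segment's anchor residue (Trp or Phe) must match the CDR3's final
    residue, otherwise the junction would contradict the germline anchor.
    """
    v, j = reference[v_name], reference[j_name]
    j_anchor_aa = translate(j.sequence[j.anchor : j.anchor + 3])
    if j_anchor_aa != cdr3_aa[-1]:
        raise ValueError(
            f"CDR3 {cdr3_aa!r} ends {cdr3_aa[-1]!r} but {j_name} anchors {j_anchor_aa!r}")
    cdr3_nt = reverse_translate(cdr3_aa)
    full = v.sequence[: v.anchor] + cdr3_nt + j.sequence[j.anchor + 3 :]
    return CloneGenotype(
        v_name=v.name, d_name=None, j_name=j.name,
        v_trim=0, d_trim5=0, d_trim3=0, j_trim=0, n1="", n2="",
        full_nt=full, cdr3_nt=cdr3_nt, productive=True,
        cdr3_start=v.anchor, v_region_end=v.anchor + 3,
    )


def apply_shm(nt_sequence: str, shm_rate: float, rng: np.random.Generator,
              protect: Optional[Tuple[int, int]] = None) -> Tuple[str, Tuple[int, ...]]:
    """Uniform substitution-only somatic hypermutation.

    Each position is independently substituted with probability ``shm_rate`` to
    one of the three other bases (uniformly).  ``protect`` is an optional
    half-open interval excluded from mutation (used for public-CDR3 spikes).
    Returns the mutated sequence and sorted 0-based substitution positions.
    """
    if not 0.0 <= shm_rate <= 1.0:
        raise ValueError(f"shm_rate {shm_rate} outside [0,1]")
    n = len(nt_sequence)
    hit = rng.random(n) < shm_rate
    if protect is not None:
        hit[protect[0] : protect[1]] = False
    positions = np.flatnonzero(hit)
    if positions.size == 0:
        return nt_sequence, ()
    arr = np.frombuffer(nt_sequence.encode("ascii"), dtype=np.uint8).copy()
    code = np.zeros(n, dtype=np.int64)
    for b, c in zip(b"ACGT", range(4)):
        code[arr == b] = c
    shift = rng.integers(1, 4, size=positions.size)
    new_codes = (code[positions] + shift) % 4
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    arr[positions] = lut[new_codes]
    return arr.tobytes().decode("ascii"), tuple(int(p) for p in positions)


def zipf_sizes(n_clones: int, exponent: float, total_reads: int) -> np.ndarray:
    """Deterministic Zipf rank-size allocation summing exactly to total_reads."""
    ranks = np.arange(1, n_clones + 1, dtype=float)
    w = ranks ** (-exponent)
    w /= w.sum()
    raw = w * total_reads
    sizes = np.floor(raw).astype(int)
    short = total_reads - sizes.sum()
    # largest remainder, ties to lower rank
    order = np.lexsort((ranks, -(raw - sizes)))
    sizes[order[:short]] += 1
    return sizes


def gini(sizes: np.ndarray) -> float:
    """Gini coefficient of a size vector (expansion-skew summary)."""
    x = np.sort(np.asarray(sizes, dtype=float))
    n = x.size
    if n == 0 or x.sum() == 0:
        return 0.0
    cum = np.cumsum(x)
    return float((n + 1 - 2 * (cum / cum[-1]).sum()) / n)


def draw_isotype_memberships(rng: np.random.Generator, proportions: Dict[str, float],
                             n: int, correlated: bool = True) -> List[frozenset]:
    """Per-clone isotype memberships under the class-switch model.

    With ``correlated=True`` (default) a clone is either IgG1 or a member of
    the IgG2b/2c pool; pool clones draw independent IgG2b / IgG2c membership
    flags with probabilities proportional to the configured IgG2b:IgG2c ratio
    (falling back to the dominant subclass if both flags come up empty), which
    makes the IgG2b and IgG2c repertoires of a sample share clones.  With
    ``correlated=False`` every clone gets exactly one isotype drawn from
    ``proportions``.
    """
    p1 = proportions.get("IgG1", 0.0)
    p2b, p2c = proportions.get("IgG2b", 0.0), proportions.get("IgG2c", 0.0)
    tot2 = p2b + p2c
    q2b = p2b / tot2 if tot2 else 0.0
    q2c = p2c / tot2 if tot2 else 0.0
    fallback = "IgG2b" if q2b >= q2c else "IgG2c"
    out: List[frozenset] = []
    for _ in range(n):
        if rng.random() < p1 or tot2 == 0.0:
            out.append(frozenset({"IgG1"}))
        elif not correlated:
            out.append(frozenset({"IgG2b" if rng.random() < q2b else "IgG2c"}))
        else:
            mem = set()
            if rng.random() < q2b:
                mem.add("IgG2b")
            if rng.random() < q2c:
                mem.add("IgG2c")
            if not mem:
                mem.add(fallback)
            out.append(frozenset(mem))
    return out


def membership_expectations(proportions: Dict[str, float],
                            correlated: bool = True) -> Dict[str, float]:
    """Exact per-clone membership probabilities implied by the switch model
    (the oracle for recovery tests)."""
    p1 = proportions.get("IgG1", 0.0)
    p2b, p2c = proportions.get("IgG2b", 0.0), proportions.get("IgG2c", 0.0)
    tot2 = p2b + p2c
    if tot2 == 0.0:
        return {"IgG1": 1.0, "IgG2b": 0.0, "IgG2c": 0.0}
    q2b, q2c = p2b / tot2, p2c / tot2
    if not correlated:
        return {"IgG1": p1, "IgG2b": (1 - p1) * q2b, "IgG2c": (1 - p1) * q2c}
    if q2b >= q2c:
        in2b = q2b + (1 - q2b) * (1 - q2c)
        in2c = q2c
    else:
        in2b = q2b
        in2c = q2c + (1 - q2c) * (1 - q2b)
    return {"IgG1": p1, "IgG2b": (1 - p1) * in2b, "IgG2c": (1 - p1) * in2c}


def _sample_ids(config: CohortConfig) -> List[Tuple[str, str, str]]:
    out = []
    for group in config.groups:
        for tp in config.time_points:
            for i in range(1, config.n_samples + 1):
                out.append((group, tp, f"{group}_{tp}_m{i}"))
    return out


def simulate_cohort(config: CohortConfig, reference: GermlineReference,
                    out_dir) -> Tuple[Dict[str, List[Path]], pd.DataFrame]:
    """Simulate the full study and write AIRR TSVs (one per sample x isotype),
    a truth table and a sample sheet under ``out_dir``.

    Returns (mapping sample_id -> written AIRR paths, truth DataFrame).
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    root_ss = np.random.SeedSequence(config.seed)
    samples = _sample_ids(config)
    child_seeds = root_ss.spawn(len(samples) + 1)
    pub_rng = np.random.default_rng(child_seeds[-1])

    # Public clones are built once so every sample carries identical CDR3s.
    v_names = list(config.v_usage_bias) or [s.name for s in reference.v_segments]
    v_w = np.array([config.v_usage_bias.get(n, 0.0) for n in v_names])
    v_w = v_w / v_w.sum() if v_w.sum() else None
    j_by_anchor: Dict[str, List[str]] = {}
    for s in reference.j_segments:
        aa = translate(s.sequence[s.anchor : s.anchor + 3])
        j_by_anchor.setdefault(aa, []).append(s.name)
    publics = []
    for aa in PUBLIC_CDR3_AA[: config.n_public]:
        vn = v_names[int(pub_rng.choice(len(v_names), p=v_w))]
        compatible = j_by_anchor.get(aa[-1]) or j_by_anchor["W"]
        jn = compatible[int(pub_rng.integers(len(compatible)))]
        publics.append(make_public_clone(reference, aa, vn, jn))

    files: Dict[str, List[Path]] = {}
    truth_rows: List[dict] = []
    sheet_rows: List[dict] = []
    for (group, tp, sample_id), seed in zip(samples, child_seeds):
        rng = np.random.default_rng(seed)
        params = config.groups[group]
        shm = min(1.0, params.shm_rate * config.shm_time_factor.get(tp, 1.0))
        clones = [
            simulate_rearrangement(reference, rng, config.v_usage_bias, config.junction)
            for _ in range(params.n_clones)
        ]
        clones = clones + list(publics)
        is_public = np.zeros(len(clones), dtype=bool)
        is_public[params.n_clones :] = True

        # class-switch memberships: publics span all isotypes, privates follow
        # the switch model
        memberships = draw_isotype_memberships(
            rng, params.isotype_proportions, params.n_clones,
            correlated=config.correlated_switching)
        memberships += [frozenset(ISOTYPES)] * config.n_public

        # lineage SHM once per clone; cells whose SHM destroys the CDR3 are
        # never sorted as productive B cells, so resample until it is intact
        lineages = []
        for ci, clone in enumerate(clones):
            protect = ((clone.cdr3_start, clone.cdr3_start + len(clone.cdr3_nt))
                       if is_public[ci] else None)
            for _ in range(100):
                mutated, positions = apply_shm(clone.full_nt, shm, rng, protect=protect)
                cdr3_nt = mutated[clone.cdr3_start : clone.cdr3_start + len(clone.cdr3_nt)]
                aa = translate(cdr3_nt)
                if aa.startswith("C") and aa[-1] in "WF" and "*" not in aa:
                    break
            lineages.append((mutated, positions, cdr3_nt, aa))

        # one library per isotype, sequenced at a near-equal share of the
        # sample's read budget (saturating per-subclass PCR, equimolar pooling)
        members = {iso: [ci for ci in range(len(clones)) if iso in memberships[ci]]
                   for iso in ISOTYPES}
        present = [iso for iso in ISOTYPES if members[iso]]
        base, extra = divmod(config.reads_per_sample, len(present))
        budgets = {iso: base + (1 if i < extra else 0) for i, iso in enumerate(present)}
        rows_by_iso: Dict[str, List[dict]] = {iso: [] for iso in ISOTYPES}
        for iso in present:
            lib = members[iso]
            order = rng.permutation(len(lib))
            ranked = zipf_sizes(len(lib), params.zipf_exponent, budgets[iso])
            sizes = np.zeros(len(lib), dtype=int)
            sizes[order] = ranked
            # guarantee every public clone is observed in every library
            for k, ci in enumerate(lib):
                if is_public[ci] and sizes[k] == 0:
                    donor = int(np.argmax(sizes))
                    sizes[donor] -= 1
                    sizes[k] = 1
            for k, ci in enumerate(lib):
                mutated, positions, cdr3_nt, cdr3_aa = lineages[ci]
                clone = clones[ci]
                for r in range(int(sizes[k])):
                    sid = f"{sample_id}_c{ci:04d}_{iso}_r{r:03d}"
                    rows_by_iso[iso].append({
                        "sequence_id": sid, "sequence": mutated, "v_call": "",
                        "d_call": "", "j_call": "", "junction": "", "junction_aa": "",
                        "c_call": iso, "duplicate_count": 1, "sample_id": sample_id,
                    })
                    truth_rows.append({
                        "sequence_id": sid, "sample_id": sample_id, "group": group,
                        "time_point": tp, "clone_id": f"{sample_id}_c{ci:04d}",
                        "is_public": bool(is_public[ci]), "v_call": clone.v_name,
                        "d_call": clone.d_name or "", "j_call": clone.j_name,
                        "cdr3_nt": cdr3_nt, "cdr3_aa": cdr3_aa, "c_call": iso,
                        "v_region_end": clone.v_region_end,
                        "mutation_positions": ",".join(map(str, positions)),
                    })
        paths = []
        for iso in ISOTYPES:
            path = out_dir / f"{sample_id}_{iso}.airr.tsv"
            df = pd.DataFrame(rows_by_iso[iso], columns=list(AIRR_COLUMNS))
            df.to_csv(path, sep="\t", index=False, lineterminator="\n")
            paths.append(path)
            sheet_rows.append({"file": path.name, "sample_id": sample_id, "group": group,
                               "time_point": tp, "isotype": iso})
        files[sample_id] = paths

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.tsv", sep="\t", index=False, lineterminator="\n")
    pd.DataFrame(sheet_rows).to_csv(out_dir / "sample_sheet.tsv", sep="\t",
                                    index=False, lineterminator="\n")
    return files, truth
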