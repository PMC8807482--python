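"""End-to-end orchestration: simulate -> annotate -> profile -> compare.

A run is fully reproducible from (config, seed): every stage output is written
under the run directory, row counts are reconciled across stages, and a
manifest (config echo, tallies, SHA-256 checksums) is written last.  External
data — AIRR read-level TSVs or clonotype-level exports in a MiXCR-style
dialect — enter through the same path via ``analyze`` mode / ``import``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .annotate import Annotator, annotate_file
from .clonotypes import (ClonotypeTable, build_clonotypes, repertoire_profile,
                         write_table)
from .compare import (build_tree, consensus_profile, modal_length_stratum,
                      per_repertoire_shared_fraction, repertoire_distance,
                      sharing_spectrum, venn3)
from .errors import BcrepError, DialectError, FormatError
from .germline import GermlineReference, load_germline
from .simulate import CohortConfig, default_config, simulate_cohort

log = logging.getLogger("bcrep")

SAMPLE_SHEET_COLUMNS = ("file", "sample_id", "group", "time_point", "isotype")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    out_dir: str
    mode: str = "simulate"                     # "simulate" or "analyze"
    cohort: Optional[CohortConfig] = None      # simulate mode; default study if None
    input_dir: Optional[str] = None            # analyze mode: dir with sample_sheet.tsv
    germline_fasta: Optional[str] = None
    germline_anchors: Optional[str] = None
    clonotype_modes: Tuple[str, ...] = ("cdr3_aa", "vdj_nt")
    sharing_min_occupancy: int = 2
    top_shared_threshold: int = 6              # "top shared" = occupancy strictly above
    tree_metric: str = "jaccard"
    seed: int = 0
    make_figures: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("simulate", "analyze"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "analyze":
            if not self.input_dir or not Path(self.input_dir).is_dir():
                raise FileNotFoundError(f"input_dir {self.input_dir!r} does not exist")


@dataclass
class RunManifest:
    config: dict
    version: str
    stage_counts: Dict[str, dict]
    checksums: Dict[str, str]
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_reference(config: RunConfig) -> GermlineReference:
    if config.germline_fasta:
        return load_germline(config.germline_fasta, config.germline_anchors)
    return load_germline()


def run_pipeline(config: RunConfig) -> RunManifest:
    """Execute all stages in order; abort (with a FAILED marker) on stage error."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    stage = "init"
    stage_counts: Dict[str, dict] = {}
    try:
        stage = "germline"
        reference = _load_reference(config)
        stage_counts["germline"] = {
            "v": len(reference.v_segments), "d": len(reference.d_segments),
            "j": len(reference.j_segments)}

        stage = "simulate"
        if config.mode == "simulate":
            cohort = config.cohort or default_config(reference, seed=config.seed)
            if config.cohort is None:
                cohort.seed = config.seed
            raw_dir = out / "airr_raw"
            simulate_cohort(cohort, reference, raw_dir)
            cohort_echo = cohort.to_dict()
        else:
            raw_dir = Path(config.input_dir)
            cohort_echo = None
        sheet_path = raw_dir / "sample_sheet.tsv"
        if not sheet_path.exists():
            raise FormatError(f"missing sample sheet {sheet_path}")
        sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
        for col in SAMPLE_SHEET_COLUMNS:
            if col not in sheet.columns:
                raise FormatError(f"sample sheet missing column {col!r}")
        for f in sheet["file"]:
            if not (raw_dir / f).exists():
                raise FileNotFoundError(f"sample sheet references missing file {f}")
        stage_counts["simulate"] = {"files": len(sheet)}
        log.info("stage simulate: %d AIRR files", len(sheet))

        stage = "annotate"
        ann_dir = out / "annotated"
        annotator = Annotator(reference)
        annotated: Dict[str, pd.DataFrame] = {}
        meta: Dict[str, dict] = {}
        n_in = n_pass = 0
        for _, row in sheet.iterrows():
            rep_id = f"{row['sample_id']}_{row['isotype']}"
            df = annotate_file(raw_dir / row["file"], reference,
                               ann_dir / row["file"], annotator=annotator)
            annotated[rep_id] = df
            meta[rep_id] = dict(row)
            n_in += len(df)
            n_pass += int(df["pass_filter"].sum()) if len(df) else 0
        stage_counts["annotate"] = {"reads_in": n_in, "reads_pass": n_pass,
                                    "reads_dropped": n_in - n_pass}
        log.info("stage annotate: %d reads, %d pass filter", n_in, n_pass)

        stage = "profile"
        clono_dir = out / "clonotypes"
        clono_dir.mkdir(parents=True, exist_ok=True)
        tables: Dict[str, Dict[str, ClonotypeTable]] = {m: {} for m in config.clonotype_modes}
        profiles: Dict[str, list] = {m: [] for m in config.clonotype_modes}
        skipped: List[str] = []
        clono_conserved = 0
        for rep_id, df in annotated.items():
            for mode in config.clonotype_modes:
                table = build_clonotypes(df, mode, rep_id)
                if table.total_reads == 0:
                    if mode == config.clonotype_modes[0]:
                        skipped.append(rep_id)
                    continue
                assert table.total_reads + table.dropped == len(df)
                clono_conserved += table.total_reads
                tables[mode][rep_id] = table
                profiles[mode].append(repertoire_profile(df, rep_id, mode).to_dict())
                write_table(table, clono_dir / f"{rep_id}.{mode}.tsv")
        for mode in config.clonotype_modes:
            with open(out / f"profiles_{mode}.json", "w") as fh:
                json.dump(profiles[mode], fh, indent=2, sort_keys=True)
        stage_counts["profile"] = {
            "repertoires": len(annotated), "skipped_empty": len(skipped),
            "clonotyped_reads": clono_conserved}

        stage = "compare"
        cmp_dir = out / "compare"
        cmp_dir.mkdir(parents=True, exist_ok=True)
        mode0 = "cdr3_aa" if "cdr3_aa" in config.clonotype_modes else config.clonotype_modes[0]
        sets = {rid: t.keys() for rid, t in tables[mode0].items()}
        report_all = sharing_spectrum(sets, config.sharing_min_occupancy,
                                      config.top_shared_threshold)
        sharing_out = {
            "all": _sharing_dict(report_all, config.sharing_min_occupancy),
            "per_repertoire_shared_fraction": per_repertoire_shared_fraction(
                sets, config.sharing_min_occupancy),
        }
        groups = sorted({m["group"] for m in meta.values()})
        for g in groups:
            gs = {rid: s for rid, s in sets.items() if meta[rid]["group"] == g}
            if len(gs) >= 2:
                sharing_out[g] = _sharing_dict(
                    sharing_spectrum(gs, config.sharing_min_occupancy,
                                     config.top_shared_threshold),
                    config.sharing_min_occupancy)
        with open(cmp_dir / "sharing.json", "w") as fh:
            json.dump(sharing_out, fh, indent=2, sort_keys=True)

        venns = {}
        time_points = sorted({m["time_point"] for m in meta.values()})
        for g in groups:
            for tp in time_points:
                iso_sets = {}
                for rid, s in sets.items():
                    m = meta[rid]
                    if m["group"] == g and m["time_point"] == tp:
                        iso_sets.setdefault(m["isotype"], set()).update(s)
                if len(iso_sets) == 3:
                    labels = tuple(sorted(iso_sets))
                    v = venn3(*(iso_sets[k] for k in labels), labels=labels)
                    venns[f"{g}_{tp}"] = {
                        "labels": list(labels), "regions": v.regions,
                        "pairwise": {f"{a}&{b}": c for (a, b), c in v.pairwise.items()},
                    }
        with open(cmp_dir / "venn.json", "w") as fh:
            json.dump(venns, fh, indent=2, sort_keys=True)

        consensus_out = None
        top = report_all.top_shared
        stratum = modal_length_stratum(top)
        if stratum:
            prof = consensus_profile(stratum)
            consensus_out = {
                "n_top_shared": len(top), "stratum_length": prof.length,
                "n_in_stratum": prof.n_sequences, "consensus": prof.consensus,
                "conservation": prof.conservation,
            }
            with open(cmp_dir / "consensus.json", "w") as fh:
                json.dump(consensus_out, fh, indent=2, sort_keys=True)
            with open(cmp_dir / "top_shared.fasta", "w") as fh:
                for i, s in enumerate(top):
                    fh.write(f">top_shared_{i + 1} occupancy={report_all.occupancy[s]}\n{s}\n")

        dist_input = tables[mode0] if config.tree_metric == "bray_curtis" else sets
        labels, D = repertoire_distance(dist_input, metric=config.tree_metric)
        pd.DataFrame(D, index=labels, columns=labels).to_csv(
            cmp_dir / "distance_matrix.tsv", sep="\t", lineterminator="\n")
        tree = build_tree(D, labels)
        tree.to_newick_file(cmp_dir / "tree.nwk")
        stage_counts["compare"] = {
            "repertoires": len(sets), "universe": report_all.universe_size,
            "shared_percent": report_all.shared_percent(config.sharing_min_occupancy)}

        if config.make_figures:
            stage = "figures"
            from . import plots
            fig_dir = out / "figures"
            plots.diversity_bars(profiles, fig_dir / "diversity.png")
            plots.usage_bars(profiles[mode0], fig_dir / "v_usage.png")
            plots.jaccard_heatmap(labels, D, fig_dir / "distance_heatmap.png")
            for key, v in venns.items():
                plots.venn3_figure(v, fig_dir / f"venn_{key}.png")
            plots.tree_figure(tree, fig_dir / "tree.png")

        stage = "manifest"
        checksums = {}
        for p in sorted(out.rglob("*")):
            if p.is_file() and p.suffix in (".tsv", ".json", ".nwk", ".fasta") \
                    and p.name != "manifest.json":
                checksums[str(p.relative_to(out))] = _sha256(p)
        manifest = RunManifest(
            config={**dataclasses.asdict(config), "cohort": cohort_echo},
            version=__version__, stage_counts=stage_counts,
            checksums=checksums, seed=config.seed)
        with open(out / "manifest.json", "w") as fh:
            fh.write(manifest.to_json())
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}\n{exc!r}\n")
        raise BcrepError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _sharing_dict(report, min_occ: int) -> dict:
    return {
        "n_repertoires": report.n_repertoires,
        "universe_size": report.universe_size,
        "shared_percent": report.shared_percent(min_occ),
        "shared_fraction_at_k": report.shared_fraction_at_k,
        "n_top_shared": len(report.top_shared),
    }


MIXCR_COLUMNS = ("cloneCount", "aaSeqCDR3")


def import_external_clonotypes(path, dialect: str, repertoire_id: Optional[str] = None,
                               mode: str = "cdr3_aa") -> ClonotypeTable:
    """Read one externally produced file into a :class:`ClonotypeTable`.

    ``dialect="airr_tsv"``: read-level AIRR Rearrangement TSV with junction_aa
    (and, for vdj_nt mode, sequence/v_read_start/j_read_end) columns; rows are
    weighted by duplicate_count when present.

    ``dialect="mixcr_export_tsv"``: clonotype-level export with cloneCount /
    aaSeqCDR3 (nSeqCDR3, allVHitsWithScore optional).
    """
    path = Path(path)
    rid = repertoire_id or path.name.split(".")[0]
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if dialect == "airr_tsv":
        if "junction_aa" not in df.columns:
            raise DialectError(
                "airr_tsv requires columns: sequence_id, junction_aa "
                f"(got {list(df.columns)[:8]}...)")
        from .clonotypes import build_clonotypes as _bc
        if "duplicate_count" in df.columns:
            dup = pd.to_numeric(df["duplicate_count"], errors="coerce").fillna(1).astype(int)
            df = df.loc[df.index.repeat(dup)].reset_index(drop=True)
        return _bc(df, mode, rid)
    if dialect == "mixcr_export_tsv":
        missing = [c for c in MIXCR_COLUMNS if c not in df.columns]
        if missing:
            raise DialectError(
                f"mixcr_export_tsv requires columns {list(MIXCR_COLUMNS)}; "
                f"missing {missing} (got {list(df.columns)})")
        entries: Dict[str, int] = {}
        for _, row in df.iterrows():
            key = row["nSeqCDR3"] if mode == "vdj_nt" and "nSeqCDR3" in df.columns \
                else row["aaSeqCDR3"]
            if not key:
                continue
            entries[key] = entries.get(key, 0) + int(round(float(row["cloneCount"])))
        return ClonotypeTable(repertoire_id=rid, mode=mode, entries=entries,
                              total_reads=sum(entries.values()))
    raise DialectError(f"unknown dialect {dialect!r}; expected airr_tsv or mixcr_export_tsv")
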