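"""Shared fixtures: germline reference, small simulated cohorts, and the
20-seed study used for parameter-recovery checks."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bcrep.annotate import Annotator, annotate_table
from bcrep.clonotypes import build_clonotypes, normalized_diversity
from bcrep.compare import jaccard
from bcrep.germline import load_germline
from bcrep.simulate import default_config, simulate_cohort

settings.register_profile("suite", derandomize=True, deadline=None, max_examples=50)
settings.load_profile("suite")

N_STUDY_SEEDS = 20


@pytest.fixture(scope="session")
def reference():
    return load_germline()


@pytest.fixture(scope="session")
def annotator(reference):
    return Annotator(reference)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, reference):
    """One small simulated study (1 mouse per group x time, 600 reads each)."""
    cfg = default_config(reference, seed=7, reads_per_sample=600, n_samples=1)
    out = tmp_path_factory.mktemp("sim_small")
    files, truth = simulate_cohort(cfg, reference, out)
    return cfg, out, files, truth


@pytest.fixture(scope="session")
def small_annotated(small_cohort, reference, annotator):
    """Annotated tables of the small cohort, keyed by repertoire id."""
    cfg, out, files, truth = small_cohort
    sheet = pd.read_csv(out / "sample_sheet.tsv", sep="\t", dtype=str)
    tables = {}
    for _, row in sheet.iterrows():
        df = pd.read_csv(out / row["file"], sep="\t", dtype=str, keep_default_na=False)
        rid = f"{row['sample_id']}_{row['isotype']}"
        tables[rid] = (annotate_table(df, annotator), dict(row))
    return tables, truth


def summarize_study(seed, reference, annotator, tmp_dir):
    """Simulate + annotate one full-size study and aggregate what the
    recovery checks need (diversities, CDR3 sets, SHM tallies, V-call accuracy)."""
    cfg = default_config(reference, seed=seed)
    _, truth = simulate_cohort(cfg, reference, tmp_dir)
    truth = truth.set_index("sequence_id")
    sheet = pd.read_csv(tmp_dir / "sample_sheet.tsv", sep="\t", dtype=str)
    diversity = {}   # (mode, group, isotype) -> list of per-repertoire values
    sets = {}        # repertoire -> CDR3 aa set
    sample_sets = {} # sample -> pooled CDR3 aa set
    meta = {}
    v_ok = v_tot = 0
    shm_obs = []     # per passing read: measured v_mutations
    shm_true = []    # per passing read: planted mutations within measured V span
    clone_ids = []
    for _, row in sheet.iterrows():
        df = pd.read_csv(tmp_dir / row["file"], sep="\t", dtype=str, keep_default_na=False)
        ann = annotate_table(df, annotator)
        rid = f"{row['sample_id']}_{row['isotype']}"
        meta[rid] = dict(row)
        ok = ann[ann["pass_filter"]]
        for mode in ("cdr3_aa", "vdj_nt"):
            t = build_clonotypes(ann, mode, rid)
            if t.total_reads:
                key = (mode, row["group"], row["isotype"])
                diversity.setdefault(key, []).append(normalized_diversity(t))
        sets[rid] = set(ok["junction_aa"])
        sample_sets.setdefault(row["sample_id"], set()).update(ok["junction_aa"])
        tr = truth.loc[ok["sequence_id"]]
        v_ok += int((ok["v_call"].values == tr["v_call"].values).sum())
        v_tot += len(ok)
        spans = list(zip(ok["v_read_start"].astype(int), ok["v_read_end"].astype(int)))
        for (s, e), mp, m in zip(spans, tr["mutation_positions"], ok["v_mutation_count"]):
            pos = [int(x) for x in str(mp).split(",")] if str(mp) else []
            shm_true.append(sum(s <= p < e for p in pos))
            shm_obs.append(int(m))
        clone_ids.extend(tr["clone_id"])
    # truth-level binomial tally on the pre-anchor V region (clean of any
    # CDR3-productivity conditioning): per clone, mutations in [0, anchor)
    anchor_of = {s.name: s.anchor for s in reference.v_segments}
    clones = truth.drop_duplicates("clone_id")
    shm_rates = {
        tp: cfg.groups[g].shm_rate * cfg.shm_time_factor[tp]
        for g in cfg.groups for tp in cfg.time_points
    }
    exp = var = obs = 0.0
    for _, c in clones.iterrows():
        a = anchor_of[c["v_call"]]
        p = cfg.groups[c["group"]].shm_rate * cfg.shm_time_factor[c["time_point"]]
        exp += a * p
        var += a * p * (1 - p)
        mp = str(c["mutation_positions"])
        obs += sum(1 for x in mp.split(",") if x and int(x) < a)
    return {
        "config": cfg,
        "diversity": diversity,
        "sets": sets,
        "sample_sets": sample_sets,
        "meta": meta,
        "v_accuracy": v_ok / v_tot,
        "shm_obs": np.array(shm_obs),
        "shm_true": np.array(shm_true),
        "clone_ids": clone_ids,
        "truth_shm": (obs, exp, var, len(clones)),
    }


@pytest.fixture(scope="session")
def study20(tmp_path_factory, reference, annotator):
    """Twenty independent simulated studies (~2e4 reads each), annotated."""
    out = []
    for seed in range(N_STUDY_SEEDS):
        tmp = tmp_path_factory.mktemp(f"study_{seed}")
        out.append(summarize_study(seed, reference, annotator, tmp))
    return out
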