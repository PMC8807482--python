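"""Annotation: germline calls, CDR3 extraction, mutation counting, filters."""

import numpy as np
import pandas as pd
import pytest

from bcrep.annotate import Annotator, annotate_file, annotate_table
from bcrep.errors import FormatError
from bcrep.germline import translate
from bcrep.simulate import (JunctionModel, default_config, make_public_clone,
                            simulate_cohort, simulate_rearrangement)


@pytest.fixture(scope="module")
def shm0_cohort(tmp_path_factory, reference):
    cfg = default_config(reference, seed=13, reads_per_sample=300, n_samples=1)
    for g in cfg.groups.values():
        g.shm_rate = 0.0
    out = tmp_path_factory.mktemp("sim_shm0")
    files, truth = simulate_cohort(cfg, reference, out)
    return out, files, truth


class TestCalls:
    def test_unmutated_reads_recover_truth_exactly(self, shm0_cohort, reference, annotator):
        out, files, truth = shm0_cohort
        truth = truth.set_index("sequence_id")
        df = annotate_file(next(iter(files.values()))[0], reference, annotator=annotator)
        assert len(df) > 0
        assert df["pass_filter"].all()
        assert (df["v_mutation_count"].astype(int) == 0).all()
        tr = truth.loc[df["sequence_id"]]
        assert (df["v_call"].values == tr["v_call"].values).all()
        assert (df["j_call"].values == tr["j_call"].values).all()
        assert (df["junction_aa"].values == tr["cdr3_aa"].values).all()

    def test_v_call_accuracy_on_mutated_reads(self, small_annotated):
        """>= 95% correct V assignment at the study's SHM load."""
        tables, truth = small_annotated
        truth = truth.set_index("sequence_id")
        ok = tot = 0
        for df, _ in tables.values():
            keep = df[df["pass_filter"]]
            tr = truth.loc[keep["sequence_id"]]
            ok += int((keep["v_call"].values == tr["v_call"].values).sum())
            tot += len(keep)
        assert tot >= 2000
        assert ok / tot >= 0.95

    def test_mutated_j_anchor_fails_unproductive(self, reference, annotator):
        clone = make_public_clone(reference, "CARDYYGSSW", "IGHV1-7*01", "IGHJ1*01")
        seq = list(clone.full_nt)
        end = clone.cdr3_start + len(clone.cdr3_nt)
        assert translate("".join(seq[end - 3 : end])) == "W"
        seq[end - 3 : end] = "CGG"  # Trp -> Arg
        rec = annotator.annotate_read("x", "".join(seq))
        assert not rec.pass_filter
        assert rec.fail_reason == "unproductive_cdr3"

    def test_short_read_flagged_not_errored(self, annotator):
        rec = annotator.annotate_read("x", "ACGTACGT")
        assert not rec.pass_filter
        assert rec.fail_reason == "too_short"

    def test_junk_read_has_no_v(self, annotator):
        rng = np.random.default_rng(0)
        junk = "".join(rng.choice(list("ACGT"), size=80))
        rec = annotator.annotate_read("x", junk)
        assert not rec.pass_filter
        assert rec.fail_reason in ("no_v", "no_j")


class TestMutationCounting:
    def test_counts_match_planted_positions(self, small_annotated):
        """Measured V-span substitutions agree with the planted truth."""
        tables, truth = small_annotated
        truth = truth.set_index("sequence_id")
        diffs = []
        for df, _ in tables.values():
            keep = df[df["pass_filter"]]
            tr = truth.loc[keep["sequence_id"]]
            for (s, e, m), mp in zip(
                zip(keep["v_read_start"].astype(int), keep["v_read_end"].astype(int),
                    keep["v_mutation_count"].astype(int)),
                tr["mutation_positions"],
            ):
                pos = [int(x) for x in str(mp).split(",")] if str(mp) else []
                diffs.append(m - sum(s <= p < e for p in pos))
        diffs = np.array(diffs)
        assert np.abs(diffs).mean() < 0.05
        assert (diffs == 0).mean() > 0.97

    def test_mean_matches_binomial_expectation(self, small_annotated):
        """Clone-collapsed mean V mutation count sits within 3 cluster-SE of
        rate x (aligned V length - anchor codon); the anchor codon is excluded
        because CDR3 productivity selection conditions on it."""
        tables, truth = small_annotated
        truth = truth.set_index("sequence_id")
        rows = []
        for df, meta in tables.values():
            if meta["time_point"] != "d10":
                continue
            keep = df[df["pass_filter"]]
            tr = truth.loc[keep["sequence_id"]]
            for m, s, e, cid in zip(keep["v_mutation_count"].astype(int),
                                    keep["v_read_start"].astype(int),
                                    keep["v_read_end"].astype(int), tr["clone_id"]):
                rows.append((cid, m, e - s))
        d = pd.DataFrame(rows, columns=["clone", "m", "L"]).groupby("clone").mean()
        rate = 0.02  # d10 SHM rate of both default groups
        expected = rate * (d["L"] - 3)
        resid = d["m"] - expected
        se = resid.std(ddof=1) / np.sqrt(len(d))
        assert abs(resid.mean()) < 3 * se + 0.05


class TestFileInterface:
    def test_empty_input_gives_extended_header(self, tmp_path, reference, annotator):
        src = tmp_path / "empty.airr.tsv"
        src.write_text("sequence_id\tsequence\tc_call\n")
        out = annotate_file(src, reference, tmp_path / "out.tsv", annotator=annotator)
        assert len(out) == 0
        assert "v_call" in out.columns and "pass_filter" in out.columns

    def test_idempotent(self, shm0_cohort, reference, annotator, tmp_path):
        out_dir, files, _ = shm0_cohort
        src = next(iter(files.values()))[0]
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        annotate_file(src, reference, p1, annotator=annotator)
        annotate_file(p1, reference, p2, annotator=annotator)
        assert p1.read_bytes() == p2.read_bytes()

    def test_missing_mandatory_column_named(self, annotator):
        with pytest.raises(FormatError, match="sequence"):
            annotate_table(pd.DataFrame({"sequence_id": ["a"]}), annotator)

    def test_row_order_independence(self, small_annotated, annotator):
        """Annotation is a per-read function: a permuted table yields the
        same result for each sequence_id."""
        tables, _ = small_annotated
        df = next(iter(tables.values()))[0].head(40)
        base = df[["sequence_id", "sequence"]].reset_index(drop=True)
        shuffled = base.sample(frac=1, random_state=1).reset_index(drop=True)
        a = annotate_table(base, annotator).set_index("sequence_id")
        b = annotate_table(shuffled, annotator).set_index("sequence_id")
        b = b.loc[a.index]
        for col in ("v_call", "j_call", "junction_aa", "v_mutation_count"):
            assert (a[col].values == b[col].values).all()
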