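"""Repertoire simulator: rearrangement assembly, SHM model, cohort structure."""

import numpy as np
import pandas as pd
import pytest

from bcrep.simulate import (PUBLIC_CDR3_AA, CohortConfig, GroupParams,
                            JunctionModel, apply_shm, default_config, gini,
                            reverse_translate, simulate_cohort,
                            simulate_rearrangement, zipf_sizes)

NO_JUNCTION = JunctionModel(v_trim_max=0, d_trim_max=0, j_trim_max=0, ins_max=0)


class TestRearrangement:
    def test_zero_trims_give_plain_concatenation(self, reference):
        rng = np.random.default_rng(0)
        clone = simulate_rearrangement(reference, rng, junction=NO_JUNCTION)
        v = reference[clone.v_name].sequence
        d = reference[clone.d_name].sequence
        j = reference[clone.j_name].sequence
        assert clone.full_nt == v + d + j
        assert clone.cdr3_nt in clone.full_nt

    def test_assembly_identity(self, reference):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = simulate_rearrangement(reference, rng)
            v = reference[c.v_name].sequence
            d = reference[c.d_name].sequence
            j = reference[c.j_name].sequence
            expect = (v[: len(v) - c.v_trim] + c.n1
                      + d[c.d_trim5 : len(d) - c.d_trim3] + c.n2 + j[c.j_trim :])
            assert c.full_nt == expect
            assert c.full_nt[c.cdr3_start : c.cdr3_start + len(c.cdr3_nt)] == c.cdr3_nt

    def test_always_productive(self, reference):
        rng = np.random.default_rng(2)
        for _ in range(50):
            aa = simulate_rearrangement(reference, rng).cdr3_aa
            assert aa.startswith("C") and aa[-1] in "WF" and "*" not in aa

    def test_seed_determinism(self, reference):
        a = simulate_rearrangement(reference, np.random.default_rng(42))
        b = simulate_rearrangement(reference, np.random.default_rng(42))
        assert a == b


class TestShm:
    def test_zero_rate_identity(self):
        seq = "ACGT" * 30
        out, pos = apply_shm(seq, 0.0, np.random.default_rng(0))
        assert out == seq and pos == ()

    def test_rate_one_changes_every_base(self):
        seq = "ACGT" * 30
        out, pos = apply_shm(seq, 1.0, np.random.default_rng(0))
        assert all(a != b for a, b in zip(seq, out))
        assert pos == tuple(range(len(seq)))

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            apply_shm("ACGT", 1.5, np.random.default_rng(0))

    def test_protect_interval_untouched(self):
        seq = "ACGT" * 30
        out, pos = apply_shm(seq, 1.0, np.random.default_rng(0), protect=(40, 60))
        assert out[40:60] == seq[40:60]
        assert not any(40 <= p < 60 for p in pos)

    def test_binomial_mean(self):
        """Mean mutation count over replicates matches n*p within 3 SE."""
        n, rate, reps = 300, 0.02, 10_000
        rng = np.random.default_rng(3)
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=n))
        counts = [len(apply_shm(seq, rate, rng)[1]) for _ in range(reps)]
        expected = n * rate
        se = np.sqrt(n * rate * (1 - rate) / reps)
        assert abs(np.mean(counts) - expected) < 3 * se


class TestCohort:
    def test_read_budget_conserved(self, small_cohort):
        cfg, out, files, truth = small_cohort
        per_sample = truth.groupby("sample_id").size()
        assert (per_sample == cfg.reads_per_sample).all()
        # files agree with the truth table
        for sample_id, paths in files.items():
            rows = sum(len(pd.read_csv(p, sep="\t")) for p in paths)
            assert rows == cfg.reads_per_sample

    def test_publics_spiked_into_every_sample(self, small_cohort):
        cfg, out, files, truth = small_cohort
        expected = set(PUBLIC_CDR3_AA[: cfg.n_public])
        for _, sub in truth.groupby("sample_id"):
            assert expected <= set(sub[sub.is_public].cdr3_aa)

    def test_seed_determinism_byte_identical(self, reference, tmp_path):
        cfg = default_config(reference, seed=11, reads_per_sample=200, n_samples=1)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_cohort(cfg, reference, d1)
        simulate_cohort(cfg, reference, d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_zipf_exponent_orders_gini(self):
        """A steeper clone-size law concentrates reads: Gini(2.0) > Gini(1.1)."""
        flat = gini(zipf_sizes(200, 1.1, 2000))
        steep = gini(zipf_sizes(200, 2.0, 2000))
        assert steep > flat

    def test_zipf_sizes_sum_exactly(self):
        for n, total in [(7, 100), (200, 2000), (505, 2500)]:
            assert zipf_sizes(n, 1.3, total).sum() == total

    def test_v_usage_bias_recovered(self, reference):
        """Empirical V choice over 2000 clones within 3 sigma of the bias."""
        cfg = default_config(reference)
        rng = np.random.default_rng(5)
        n = 2000
        hits = sum(
            simulate_rearrangement(reference, rng, cfg.v_usage_bias).v_name == "IGHV1-7*01"
            for _ in range(n)
        )
        p = cfg.v_usage_bias["IGHV1-7*01"]
        assert abs(hits / n - p) < 3 * np.sqrt(p * (1 - p) / n)

    def test_isotype_memberships_match_switch_model(self):
        """Clone-level isotype memberships over 10,000 draws match the exact
        expectations of the class-switch model within 3 sigma."""
        from bcrep.simulate import draw_isotype_memberships, membership_expectations

        props = {"IgG1": 0.2, "IgG2b": 0.4, "IgG2c": 0.4}
        n = 10_000
        mems = draw_isotype_memberships(np.random.default_rng(8), props, n)
        expect = membership_expectations(props)
        for iso in ("IgG1", "IgG2b", "IgG2c"):
            frac = sum(iso in m for m in mems) / n
            p = expect[iso]
            assert abs(frac - p) < 3 * np.sqrt(p * (1 - p) / n), iso

    def test_uncorrelated_mode_gives_single_isotypes(self):
        from bcrep.simulate import draw_isotype_memberships

        props = {"IgG1": 0.3, "IgG2b": 0.4, "IgG2c": 0.3}
        mems = draw_isotype_memberships(np.random.default_rng(1), props, 500,
                                        correlated=False)
        assert all(len(m) == 1 for m in mems)

    def test_library_depths_near_equal(self, small_cohort):
        """Each sample's isotype libraries are sequenced at near-equal depth
        (equimolar pooling), regardless of cellular isotype composition."""
        cfg, out, files, truth = small_cohort
        depth = truth.groupby(["sample_id", "c_call"]).size()
        for _, sub in depth.groupby(level=0):
            assert sub.max() - sub.min() <= 1

    def test_rna_free_isotypes_skew_igg1(self, small_cohort):
        """More of the rna_free group's clones are IgG1-committed."""
        cfg, out, files, truth = small_cohort
        priv = truth[~truth.is_public]
        share = priv.groupby("group").apply(
            lambda g: g.groupby("clone_id")["c_call"]
            .agg(lambda s: set(s) == {"IgG1"}).mean(),
            include_groups=False)
        assert share["rna_free"] > share["rna_loaded"]


class TestConfig:
    def test_validation_catches_bad_proportions(self, reference):
        cfg = default_config(reference)
        cfg.groups["rna_loaded"].isotype_proportions = {"IgG1": 0.5, "IgG2b": 0.6}
        with pytest.raises(ValueError):
            cfg.validate()

    def test_yaml_roundtrip(self, reference, tmp_path):
        cfg = default_config(reference, seed=3)
        path = tmp_path / "cohort.yaml"
        cfg.to_yaml(path)
        again = CohortConfig.from_yaml(path)
        assert again == cfg

    def test_reverse_translate_inverts_translation(self):
        from bcrep.germline import translate
        for aa in PUBLIC_CDR3_AA:
            assert translate(reverse_translate(aa)) == aa
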